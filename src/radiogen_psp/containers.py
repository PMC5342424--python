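"""Core in-memory containers shared across the pipeline.

The analysis couples two data blocks measured on the same patients:

* a longitudinal imaging-feature tensor ``X`` of shape ``(n, d, T)`` —
  ``n`` samples, ``d`` morphological features, ``T`` MRI time points;
* a gene-expression matrix ``Y`` of shape ``(n, c)`` with a PsP/TTP
  group label per sample.

The regression couples them through a coefficient tensor ``W`` of shape
``(d, c, T)`` whose mode-1 unfolding ``W_(1) = [W_1 | W_2 | ... | W_T]``
(a ``d x (c*T)`` matrix) carries the trace-norm penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PSP = "PsP"
TTP = "TTP"

__all__ = [
    "PSP",
    "TTP",
    "LongitudinalFeatureTensor",
    "ExpressionMatrix",
    "CoefficientTensor",
    "DimensionError",
]


class DimensionError(ValueError):
    """Raised when array dimensions disagree with their metadata or each other."""


def _default_names(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


@dataclass
class LongitudinalFeatureTensor:
    """Imaging features for ``n`` samples x ``d`` features x ``T`` time points."""

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    time_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DimensionError(
                f"feature tensor must be 3-D (n, d, T), got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DimensionError("feature tensor contains non-finite entries")
        n, d, T = self.values.shape
        if not self.sample_ids:
            self.sample_ids = _default_names("s", n)
        if not self.feature_names:
            self.feature_names = _default_names("f", d)
        if not self.time_labels:
            self.time_labels = [f"T{t + 1}" for t in range(T)]
        for axis, (meta, size) in enumerate(
            [(self.sample_ids, n), (self.feature_names, d), (self.time_labels, T)]
        ):
            if len(meta) != size:
                raise DimensionError(
                    f"metadata length {len(meta)} does not match axis {axis} size {size}"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    def timepoint(self, t: int) -> np.ndarray:
        """The ``n x d`` design matrix ``X_t``."""
        return self.values[:, :, t]


@dataclass
class ExpressionMatrix:
    """Gene expression for ``n`` samples x ``c`` genes, with PsP/TTP labels."""

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    gene_symbols: list[str] = field(default_factory=list)
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError(
                f"expression matrix must be 2-D (n, c), got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DimensionError("expression matrix contains non-finite entries")
        n, c = self.values.shape
        if not self.sample_ids:
            self.sample_ids = _default_names("s", n)
        if not self.gene_symbols:
            self.gene_symbols = _default_names("g", c)
        if len(self.sample_ids) != n:
            raise DimensionError("sample_ids length does not match sample axis")
        if len(self.gene_symbols) != c:
            raise DimensionError("gene_symbols length does not match gene axis")
        if self.groups is not None:
            self.groups = np.asarray(self.groups, dtype=object)
            if self.groups.shape != (n,):
                raise DimensionError("groups must be one label per sample")
            bad = set(self.groups) - {PSP, TTP}
            if bad:
                raise DimensionError(f"unknown group labels: {sorted(map(str, bad))}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def group_mask(self, group: str) -> np.ndarray:
        if self.groups is None:
            raise DimensionError("expression matrix carries no group labels")
        return self.groups == group

    def subset_genes(self, indices) -> "ExpressionMatrix":
        indices = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            values=self.values[:, indices],
            sample_ids=list(self.sample_ids),
            gene_symbols=[self.gene_symbols[j] for j in indices],
            groups=None if self.groups is None else self.groups.copy(),
        )


@dataclass
class CoefficientTensor:
    """Regression coefficients ``W`` of shape ``(d, c, T)``.

    ``W[:, :, t]`` is the per-time-point coefficient matrix ``W_t`` mapping
    the ``d`` imaging features to the ``c`` genes.
    """

    values: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    gene_symbols: list[str] = field(default_factory=list)
    time_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DimensionError(
                f"coefficient tensor must be 3-D (d, c, T), got shape {self.values.shape}"
            )
        d, c, T = self.values.shape
        if not self.feature_names:
            self.feature_names = _default_names("f", d)
        if not self.gene_symbols:
            self.gene_symbols = _default_names("g", c)
        if not self.time_labels:
            self.time_labels = [f"T{t + 1}" for t in range(T)]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    def timepoint(self, t: int) -> np.ndarray:
        return self.values[:, :, t]

    def unfold(self) -> np.ndarray:
        """Mode-1 unfolding ``W_(1) = [W_1 | ... | W_T]`` (``d x (c*T)``).

        Values are rearranged, never changed; column ``t*c + j`` of the
        unfolding is ``W[:, j, t]``.
        """
        d, c, T = self.values.shape
        return np.ascontiguousarray(self.values.transpose(0, 2, 1)).reshape(d, T * c)


def unfold_coefficients(W: np.ndarray) -> np.ndarray:
    """Mode-1 unfolding of a raw ``(d, c, T)`` array (see CoefficientTensor)."""
    W = np.asarray(W, dtype=float)
    d, c, T = W.shape
    return np.ascontiguousarray(W.transpose(0, 2, 1)).reshape(d, T * c)
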