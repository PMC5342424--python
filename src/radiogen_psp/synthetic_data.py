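"""Synthetic cohorts with the statistical structure the analysis assumes.

The study cohorts are private clinical data, so this module generates
stand-ins with the same shape and the same planted structure the method is
designed to exploit:

* a longitudinal imaging-feature tensor ``X`` (standardized per feature per
  time point);
* gene expression ``Y = (1/T) * sum_t X_t W_t + group shift + noise``, where
  the planted coefficient tensor ``W_true`` is row-sparse per gene,
  temporally smooth and low-rank in its mode-1 unfolding;
* a PsP/TTP label per sample, with biomarker genes shifted upward in the
  PsP group;
* parametric labeled tumor-mask stacks (0 background, 1 enhanced,
  2 necrotic) for the morphometrics module.

Defaults mirror the study conditions: 17 discovery samples (5 PsP / 12 TTP),
225 imaging features, 119 genes, 4 time points, and an independent
validation cohort of 21 samples (6 PsP / 15 TTP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import (
    PSP,
    TTP,
    CoefficientTensor,
    ExpressionMatrix,
    LongitudinalFeatureTensor,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "MaskStack",
    "ShapeSpec",
    "SimulationConfigError",
    "MaskGeometryError",
    "small_profile",
    "generate_coefficients",
    "generate_dataset",
    "generate_validation_cohort",
    "generate_mask_stack",
]

#: Magnitude of planted nonzero coefficients. Together with the default
#: noise_sd this keeps the per-gene signal standard deviation around 0.3,
#: so a standardized group shift of 2 separates the groups by roughly
#: three total standard deviations — strong but not degenerate expression
#: differences, as expected of genes that survive a stringent screen.
COEF_SCALE = 0.3


class SimulationConfigError(ValueError):
    """Invalid simulation configuration."""


class MaskGeometryError(ValueError):
    """Invalid mask geometry (e.g. inner radius >= outer radius)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort generator.

    Counts default to the discovery cohort of the study design
    (17 samples, 5 PsP, 225 features, 119 genes, 4 time points).
    """

    n_samples: int = 17
    n_psp: int = 5
    n_features_d: int = 225
    n_genes_c: int = 119
    n_timepoints_T: int = 4
    n_active_genes: int = 10
    n_active_features_per_gene: int = 5
    effect_size: float = 2.0
    temporal_jitter: float = 0.05
    coeff_rank: int = 5
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_psp": self.n_psp,
            "n_features_d": self.n_features_d,
            "n_genes_c": self.n_genes_c,
            "n_timepoints_T": self.n_timepoints_T,
            "coeff_rank": self.coeff_rank,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise SimulationConfigError(f"{name} must be a positive integer, got {value}")
        if self.n_active_genes < 0 or self.n_active_features_per_gene < 0:
            raise SimulationConfigError("active-support sizes must be non-negative")
        if self.n_psp >= self.n_samples:
            raise SimulationConfigError(
                f"n_psp ({self.n_psp}) must be smaller than n_samples ({self.n_samples})"
            )
        if self.n_active_genes > self.n_genes_c:
            raise SimulationConfigError(
                f"n_active_genes ({self.n_active_genes}) exceeds n_genes_c ({self.n_genes_c})"
            )
        if self.coeff_rank > min(self.n_features_d, self.n_genes_c * self.n_timepoints_T):
            raise SimulationConfigError(
                f"coeff_rank ({self.coeff_rank}) exceeds "
                f"min(d, c*T) = {min(self.n_features_d, self.n_genes_c * self.n_timepoints_T)}"
            )
        if self.n_active_genes > 0:
            rank = min(self.coeff_rank, self.n_active_genes)
            needed = rank * self.n_active_features_per_gene
            if needed > self.n_features_d:
                raise SimulationConfigError(
                    "disjoint per-component feature blocks do not fit: "
                    f"coeff_rank * n_active_features_per_gene = {needed} > "
                    f"n_features_d = {self.n_features_d}"
                )
        if self.temporal_jitter < 0 or self.noise_sd < 0:
            raise SimulationConfigError("temporal_jitter and noise_sd must be >= 0")


def small_profile(seed: int = 0, **overrides) -> SimulationConfig:
    """Fast-test profile: n=30, d=20, c=15, T=3 with a small planted support."""
    cfg = SimulationConfig(
        n_samples=30,
        n_psp=10,
        n_features_d=20,
        n_genes_c=15,
        n_timepoints_T=3,
        n_active_genes=4,
        n_active_features_per_gene=3,
        coeff_rank=3,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth for recovery experiments."""

    X: LongitudinalFeatureTensor
    Y: ExpressionMatrix
    labels: np.ndarray
    W_true: CoefficientTensor
    active_genes: np.ndarray
    active_features: dict[int, np.ndarray]
    config: SimulationConfig = field(repr=False, default=None)


@dataclass
class MaskStack:
    """Ordered 2-D labeled mask slices (0 background, 1 enhanced, 2 necrotic)."""

    slices: list[np.ndarray]
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if not self.slices:
            raise MaskGeometryError("mask stack must contain at least one slice")
        shape = self.slices[0].shape
        for i, s in enumerate(self.slices):
            s = np.asarray(s)
            if s.shape != shape:
                raise MaskGeometryError(f"slice {i} shape {s.shape} != {shape}")
            if not np.isin(s, (0, 1, 2)).all():
                raise MaskGeometryError(f"slice {i} contains labels outside {{0,1,2}}")
            self.slices[i] = s.astype(np.uint8)


# ---------------------------------------------------------------------------
# Planted coefficient tensor
# ---------------------------------------------------------------------------

def _plant_coefficients(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray]]:
    """Draw (W, active_genes, per-gene feature supports).

    Construction: the mode-1 unfolding is the factor product ``A @ B`` with
    ``A`` of shape ``(d, r)`` and ``B`` of shape ``(r, c*T)``, which bounds
    its rank by ``r = min(coeff_rank, n_active_genes)`` exactly. Each rank
    component owns a disjoint block of ``n_active_features_per_gene``
    features; active genes are assigned to components round-robin, so every
    active gene's row support is its component's block and supports are
    identical across time points. Temporal smoothness: the per-(gene, time)
    loading is ``1 + (temporal_jitter / COEF_SCALE) * z`` with standard
    normal ``z``, giving each nonzero entry a temporal standard deviation of
    ``temporal_jitter`` around its base value.
    """
    d, c, T = config.n_features_d, config.n_genes_c, config.n_timepoints_T
    m, k = config.n_active_genes, config.n_active_features_per_gene
    W = np.zeros((d, c, T))
    if m == 0 or k == 0:
        return W, np.array([], dtype=int), {}

    r = min(config.coeff_rank, m)
    active_genes = np.sort(rng.choice(c, size=m, replace=False))
    feature_perm = rng.permutation(d)
    blocks = [np.sort(feature_perm[ell * k : (ell + 1) * k]) for ell in range(r)]
    A = np.zeros((d, r))
    for ell in range(r):
        A[blocks[ell], ell] = COEF_SCALE * rng.choice([-1.0, 1.0], size=k)

    supports: dict[int, np.ndarray] = {}
    for i, j in enumerate(active_genes):
        ell = i % r
        supports[int(j)] = blocks[ell]
        if config.temporal_jitter > 0:
            loadings = 1.0 + (config.temporal_jitter / COEF_SCALE) * rng.standard_normal(T)
        else:
            loadings = np.ones(T)
        W[:, j, :] = A[:, ell][:, None] * loadings[None, :]
    return W, active_genes, supports


def generate_coefficients(config: SimulationConfig) -> CoefficientTensor:
    """Planted coefficient tensor: row-sparse, temporally smooth, low rank."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    W, _, _ = _plant_coefficients(config, rng)
    return CoefficientTensor(values=W)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _standardize_features(X: np.ndarray) -> np.ndarray:
    """Z-score every feature column at every time point (ddof=1)."""
    mu = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _labels(n: int, n_psp: int) -> np.ndarray:
    return np.array([PSP] * n_psp + [TTP] * (n - n_psp), dtype=object)


def _assemble(
    config: SimulationConfig,
    rng: np.random.Generator,
    n: int,
    n_psp: int,
    W: np.ndarray,
    shift_genes: np.ndarray,
    active_genes: np.ndarray,
    supports: dict[int, np.ndarray],
) -> SyntheticCohort:
    d, c, T = config.n_features_d, config.n_genes_c, config.n_timepoints_T
    X = _standardize_features(rng.standard_normal((n, d, T)))
    signal = np.zeros((n, c))
    for t in range(T):
        signal += X[:, :, t] @ W[:, :, t]
    signal /= T
    labels = _labels(n, n_psp)
    if len(shift_genes) and config.effect_size != 0:
        signal[np.ix_(labels == PSP, shift_genes)] += config.effect_size
    if config.noise_sd > 0:
        signal = signal + config.noise_sd * rng.standard_normal((n, c))
    return SyntheticCohort(
        X=LongitudinalFeatureTensor(values=X),
        Y=ExpressionMatrix(values=signal, groups=labels),
        labels=labels,
        W_true=CoefficientTensor(values=W),
        active_genes=active_genes,
        active_features=supports,
        config=config,
    )


def generate_dataset(config: SimulationConfig) -> SyntheticCohort:
    """Discovery cohort: standardized X, Y = time-averaged X_t W_t + shift + noise.

    The group shift (``effect_size``) is added to the active-gene columns of
    PsP samples; equal seeds yield bitwise-identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    W, active_genes, supports = _plant_coefficients(config, rng)
    return _assemble(
        config, rng, config.n_samples, config.n_psp, W, active_genes, active_genes, supports
    )


def generate_validation_cohort(
    config: SimulationConfig,
    biomarkers,
    n_samples: int = 21,
    n_psp: int = 6,
) -> SyntheticCohort:
    """Independent cohort (defaults 21 samples, 6 PsP) with elevated biomarkers.

    New samples are drawn from the same generative model (same planted W);
    the given biomarker-gene columns — not the full active set — are shifted
    upward in the PsP group by ``effect_size``. With an empty biomarker set a
    warning is issued and a plain null cohort (no group shift) is returned.
    """
    config.validate()
    biomarkers = np.asarray(biomarkers, dtype=int)
    if biomarkers.size and (
        biomarkers.min() < 0 or biomarkers.max() >= config.n_genes_c
    ):
        raise SimulationConfigError("biomarker indices out of range for n_genes_c")
    if biomarkers.size == 0:
        warnings.warn(
            "empty biomarker set: returning a null validation cohort with no group shift",
            stacklevel=2,
        )
    # Same planted biology as the discovery cohort, independent sampling stream.
    rng = np.random.default_rng(config.seed)
    W, active_genes, supports = _plant_coefficients(config, rng)
    rng_val = np.random.default_rng([config.seed, 0x5EED])
    return _assemble(config, rng_val, n_samples, n_psp, W, biomarkers, active_genes, supports)


# ---------------------------------------------------------------------------
# Parametric tumor masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeSpec:
    """One slice's tumor geometry.

    shape: 'disk', 'ring', 'ellipse' or 'multi-blob'. ``outer`` is the outer
    radius (semi-axes ``axes`` for ellipse); ``inner`` the necrotic-core
    radius (0 for none); ``n_blobs`` only applies to 'multi-blob'.
    """

    shape: str = "disk"
    center: tuple[float, float] = (0.0, 0.0)  # (row, col) offset from image center
    outer: float = 10.0
    inner: float = 0.0
    axes: tuple[float, float] = (12.0, 6.0)  # (row, col) semi-axes for 'ellipse'
    n_blobs: int = 2


def _inside_ellipse(rr, cc, center, ax_r, ax_c):
    return ((rr - center[0]) / ax_r) ** 2 + ((cc - center[1]) / ax_c) ** 2 <= 1.0


def _rasterize(spec: ShapeSpec, image_shape, rng) -> np.ndarray:
    """Label one slice; a pixel belongs to a shape iff its center is inside."""
    h, w = image_shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    center = (h / 2.0 + spec.center[0], w / 2.0 + spec.center[1])
    mask = np.zeros(image_shape, dtype=np.uint8)

    if spec.shape in ("disk", "ring"):
        if spec.outer <= 0:
            raise MaskGeometryError("outer radius must be > 0")
        if spec.inner < 0 or (spec.inner > 0 and spec.inner >= spec.outer):
            raise MaskGeometryError(
                f"inner radius ({spec.inner}) must be 0 or < outer ({spec.outer})"
            )
        outer = _inside_ellipse(rr, cc, center, spec.outer, spec.outer)
        inner = (
            _inside_ellipse(rr, cc, center, spec.inner, spec.inner)
            if spec.inner > 0
            else np.zeros_like(outer)
        )
        mask[outer] = 1
        mask[inner] = 2
    elif spec.shape == "ellipse":
        ar, ac = spec.axes
        if ar <= 0 or ac <= 0:
            raise MaskGeometryError("ellipse semi-axes must be > 0")
        if spec.inner < 0 or (spec.inner > 0 and spec.inner >= min(ar, ac)):
            raise MaskGeometryError("inner radius must be 0 or < min semi-axis")
        outer = _inside_ellipse(rr, cc, center, ar, ac)
        mask[outer] = 1
        if spec.inner > 0:
            mask[_inside_ellipse(rr, cc, center, spec.inner, spec.inner)] = 2
    elif spec.shape == "multi-blob":
        if spec.outer <= 0:
            raise MaskGeometryError("blob radius must be > 0")
        for _ in range(spec.n_blobs):
            c_r = rng.uniform(spec.outer + 1, h - spec.outer - 1)
            c_c = rng.uniform(spec.outer + 1, w - spec.outer - 1)
            mask[_inside_ellipse(rr, cc, (c_r, c_c), spec.outer, spec.outer)] = 1
    else:
        raise MaskGeometryError(f"unknown shape {spec.shape!r}")
    return mask


def generate_mask_stack(
    geometry,
    image_shape: tuple[int, int] = (128, 128),
    pixel_size: float = 1.0,
    seed: int | None = 0,
) -> MaskStack:
    """Rasterize a stack of labeled tumor-mask slices from parametric shapes.

    ``geometry`` is a ShapeSpec or a sequence of ShapeSpec, one per slice.
    Enhanced tissue (label 1) is the outer shape minus the necrotic core
    (label 2, the inner shape).
    """
    if isinstance(geometry, ShapeSpec):
        geometry = [geometry]
    rng = np.random.default_rng(seed)
    slices = [_rasterize(spec, image_shape, rng) for spec in geometry]
    return MaskStack(slices=slices, pixel_size=pixel_size)
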