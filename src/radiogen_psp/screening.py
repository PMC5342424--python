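"""Differential-expression screening and gene clustering.

Genes are screened by a two-sided Wilcoxon rank-sum (Mann-Whitney U) test
between the PsP and TTP groups at a raw threshold (default p < 0.005, no
multiple-testing adjustment; Benjamini-Hochberg available via a flag).
The exact null distribution is used whenever the smaller group has at most
12 samples and the gene has no tied values; otherwise the normal
approximation with tie and continuity corrections is used.

Surviving genes are ordered by average-linkage (UPGMA) hierarchical
clustering on the correlation dissimilarity 1 - Pearson r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import PSP, TTP, ExpressionMatrix

__all__ = [
    "ScreenResult",
    "ClusterResult",
    "EmptyGroupError",
    "ZeroVarianceError",
    "EXACT_MAX_GROUP",
    "wilcoxon_rank_sum",
    "wilcoxon_screen",
    "hierarchical_cluster",
    "cluster_to_newick",
]

#: Largest min(n1, n2) for which the exact null distribution is used.
EXACT_MAX_GROUP = 12


class EmptyGroupError(ValueError):
    """A group has no (or too few) samples."""


class ZeroVarianceError(ValueError):
    """Genes with zero variance cannot enter correlation clustering."""


@dataclass
class ScreenResult:
    """Per-gene screening outcome."""

    p_values: np.ndarray
    pass_mask: np.ndarray
    retained: np.ndarray  # gene indices passing alpha, sorted by p ascending
    direction: np.ndarray  # sign of PsP-minus-TTP median difference
    alpha: float
    gene_symbols: list[str] = field(default_factory=list)

    @property
    def retained_symbols(self) -> list[str]:
        return [self.gene_symbols[j] for j in self.retained] if self.gene_symbols else []


@dataclass
class ClusterResult:
    """Average-linkage merge tree over genes (or samples)."""

    linkage: np.ndarray  # scipy linkage matrix, (m-1) x 4
    leaf_order: np.ndarray
    labels: list[str] = field(default_factory=list)


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney U p-value for each column of ``a`` vs ``b``.

    ``a`` and ``b`` are (n1, m) and (n2, m); returns m p-values. Columns
    with no ties and min(n1, n2) <= EXACT_MAX_GROUP use the exact null
    distribution; the rest use the tie-corrected normal approximation with
    continuity correction.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.ndim == 2 and a.shape[1] != b.shape[1]:
        raise ValueError("a and b must have the same number of columns")
    n1, m = a.shape
    n2 = b.shape[0]
    if n1 == 0 or n2 == 0:
        raise EmptyGroupError("both groups must be non-empty")

    combined = np.vstack([a, b])
    has_ties = np.array(
        [len(np.unique(combined[:, j])) < n1 + n2 for j in range(m)]
    )
    exact_ok = (min(n1, n2) <= EXACT_MAX_GROUP) & ~has_ties

    p = np.empty(m)
    if exact_ok.any():
        res = stats.mannwhitneyu(
            a[:, exact_ok], b[:, exact_ok], alternative="two-sided", method="exact", axis=0
        )
        p[exact_ok] = np.minimum(np.atleast_1d(res.pvalue), 1.0)
    rest = ~exact_ok
    if rest.any():
        res = stats.mannwhitneyu(
            a[:, rest],
            b[:, rest],
            alternative="two-sided",
            method="asymptotic",
            use_continuity=True,
            axis=0,
        )
        p[rest] = np.minimum(np.atleast_1d(res.pvalue), 1.0)
    return p


def _resolve_groups(Y, labels):
    if isinstance(Y, ExpressionMatrix):
        values = Y.values
        symbols = list(Y.gene_symbols)
        labels = Y.groups if labels is None else np.asarray(labels, dtype=object)
    else:
        values = np.asarray(Y, dtype=float)
        symbols = []
        labels = None if labels is None else np.asarray(labels, dtype=object)
    if labels is None:
        raise EmptyGroupError("group labels are required")
    return values, symbols, labels


def wilcoxon_screen(
    Y,
    labels=None,
    alpha: float = 0.005,
    adjust: str | None = None,
) -> ScreenResult:
    """Screen genes differentially expressed between PsP and TTP.

    Parameters
    ----------
    Y : ExpressionMatrix or (n, c) array
    labels : per-sample group labels ('PsP'/'TTP'); taken from ``Y`` if it
        is an ExpressionMatrix.
    alpha : raw significance threshold (default 0.005).
    adjust : None (raw p-values, as in a fixed-threshold screen) or 'bh'
        for Benjamini-Hochberg adjusted p-values.
    """
    values, symbols, labels = _resolve_groups(Y, labels)
    for group in (PSP, TTP):
        n_g = int(np.sum(labels == group))
        if n_g == 0:
            raise EmptyGroupError(f"group {group!r} has no samples")
        if n_g < 2:
            raise EmptyGroupError(f"group {group!r} has fewer than 2 samples")

    a = values[labels == PSP]
    b = values[labels == TTP]
    p = wilcoxon_rank_sum(a, b)
    if adjust == "bh":
        p = stats.false_discovery_control(p, method="bh")
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")

    pass_mask = p < alpha
    order = np.argsort(p, kind="stable")
    retained = order[pass_mask[order]]
    direction = np.sign(np.median(a, axis=0) - np.median(b, axis=0)).astype(int)
    return ScreenResult(
        p_values=p,
        pass_mask=pass_mask,
        retained=retained,
        direction=direction,
        alpha=alpha,
        gene_symbols=symbols,
    )


def hierarchical_cluster(Y_screened, axis: str = "genes", labels=None) -> ClusterResult:
    """UPGMA merge tree on 1 - Pearson correlation distance.

    ``Y_screened`` is an (n_samples, n_genes) array or ExpressionMatrix;
    ``axis`` selects whether genes (columns, the default) or samples (rows)
    are clustered.
    """
    if isinstance(Y_screened, ExpressionMatrix):
        values = Y_screened.values
        default_labels = (
            list(Y_screened.gene_symbols) if axis == "genes" else list(Y_screened.sample_ids)
        )
    else:
        values = np.asarray(Y_screened, dtype=float)
        default_labels = []
    if axis == "genes":
        obs = values.T
    elif axis == "samples":
        obs = values
    else:
        raise ValueError("axis must be 'genes' or 'samples'")
    if obs.shape[0] < 2:
        raise ValueError("need at least 2 observations to cluster")

    variances = obs.var(axis=1)
    degenerate = np.flatnonzero(variances == 0)
    if degenerate.size:
        names = (
            [default_labels[i] for i in degenerate] if default_labels else degenerate.tolist()
        )
        raise ZeroVarianceError(f"zero-variance {axis} cannot be clustered: {names}")

    dist = pdist(obs, metric="correlation")
    dist = np.clip(dist, 0.0, None)  # guard tiny negative rounding
    Z = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(Z)
    out_labels = labels if labels is not None else default_labels
    return ClusterResult(linkage=Z, leaf_order=order, labels=list(out_labels))


def cluster_to_newick(result: ClusterResult) -> str:
    """Merge tree in nested-parenthesis (Newick) form with branch lengths."""
    tree = hierarchy.to_tree(result.linkage)
    labels = result.labels

    def name(node) -> str:
        if labels and node.id < len(labels):
            return str(labels[node.id])
        return f"L{node.id}"

    def render(node, parent_height: float) -> str:
        branch = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{name(node)}:{branch:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{branch:.6g}"

    return render(tree, tree.dist) + ";"
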