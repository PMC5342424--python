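"""Multi-task longitudinal sparse regression of gene expression on imaging.

The model couples one expression matrix ``Y`` (n x c) with T per-time-point
imaging design matrices ``X_t`` (n x d) through coefficient matrices
``W_t`` (d x c), minimizing

    sum_t ||X_t W_t - Y||_F^2
      + theta1 * sum_k sqrt( sum_t ||W_t^k - (1/T) sum_s W_s^k||^2 )
      + theta2 * ||W_(1)||_*

where ``W_t^k`` is the k-th row of ``W_t``, ``W_(1) = [W_1 | ... | W_T]``
is the mode-1 unfolding and ``||.||_*`` the trace (nuclear) norm. The
middle term is a group l2,1 norm over feature rows of the *temporal
deviations*: it simultaneously smooths coefficients across time points and
zeroes out whole feature rows; the trace norm removes redundancy among
correlated imaging features by keeping the unfolded coefficient matrix
low-rank.

The solver is an iteratively reweighted closed-form update. Given the
current iterate it forms

* ``D``     - diagonal, D_kk = 1 / (2*sqrt(group deviation of row k + eps)),
* ``Dbar``  - the time-mean (1/T) sum_t W_t,
* ``Ddbar`` - (1/2) (W_(1) W_(1)^T + eps*I)^(-1/2),

and updates each time point by the stationarity condition

    W_t = (X_t^T X_t + theta1*D + theta2*Ddbar)^(-1) (X_t^T Y + theta1*D*Dbar).

Each update minimizes a quadratic majorizer of the objective, so the
objective trace is non-increasing (up to the eps smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .containers import (
    CoefficientTensor,
    DimensionError,
    ExpressionMatrix,
    LongitudinalFeatureTensor,
)

__all__ = [
    "RegressionConfig",
    "IterationState",
    "WeightMap",
    "SingularSystemError",
    "objective",
    "update_reweighting",
    "fit",
    "overall_weights",
    "top_genes",
]


class SingularSystemError(np.linalg.LinAlgError):
    """The normal-equation system is singular and no regularizer is active."""


@dataclass(frozen=True)
class RegressionConfig:
    """Solver hyperparameters.

    theta1 weights the temporal-smoothness group l2,1 penalty, theta2 the
    trace-norm penalty. ``tol`` is the relative objective-change stopping
    criterion (None = fixed iteration count, as in the hyperparameter-grid
    runs). ``epsilon`` smooths both reweighting square roots at exact zeros.
    ``ridge_init`` regularizes the deterministic per-time ridge initializer
    (and, when theta1 = theta2 = 0, the otherwise unregularized update).
    ``standardize_y`` z-scores expression columns before fitting.
    """

    theta1: float = 1.0
    theta2: float = 1.0
    max_iter: int = 100
    tol: float | None = 1e-6
    epsilon: float = 1e-8
    ridge_init: float = 1e-3
    standardize_y: bool = True

    def validate(self) -> None:
        if self.theta1 < 0 or self.theta2 < 0:
            raise ValueError("theta1 and theta2 must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol is not None and self.tol <= 0:
            raise ValueError("tol must be > 0 (or None to disable)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.ridge_init < 0:
            raise ValueError("ridge_init must be >= 0")


@dataclass
class IterationState:
    """Reweighting matrices and diagnostics of one solver pass."""

    D: np.ndarray  # (d,) diagonal of the row-group reweighting matrix
    Dbar: np.ndarray  # (d, c) time-mean of W
    Ddbar: np.ndarray  # (d, d) trace-norm reweighting, SPD
    singular_values: np.ndarray  # singular values of W_(1)
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)


@dataclass
class WeightMap:
    """Per-gene overall weights W'(t, j) = sum_i |W_t(i, j)| and their ranking."""

    weights: np.ndarray  # (T, c)
    avg_weight: np.ndarray  # (c,)
    order: np.ndarray  # gene indices, descending by avg_weight, ties by index
    gene_symbols: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Input coercion
# ---------------------------------------------------------------------------

def _coerce_inputs(X, Y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(X, LongitudinalFeatureTensor):
        X = X.values
    X = np.asarray(X, dtype=float)
    if isinstance(Y, ExpressionMatrix):
        Y = Y.values
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 3:
        raise DimensionError(f"X must be (n, d, T), got shape {X.shape}")
    if Y.ndim != 2:
        raise DimensionError(f"Y must be (n, c), got shape {Y.shape}")
    if X.shape[0] != Y.shape[0]:
        raise DimensionError(
            f"sample axis mismatch: X has n={X.shape[0]}, Y has n={Y.shape[0]}"
        )
    return X, Y


def _coerce_W(W) -> np.ndarray:
    if isinstance(W, CoefficientTensor):
        W = W.values
    W = np.asarray(W, dtype=float)
    if W.ndim != 3:
        raise DimensionError(f"W must be (d, c, T), got shape {W.shape}")
    return W


def _unfold(W: np.ndarray) -> np.ndarray:
    d, c, T = W.shape
    return np.ascontiguousarray(W.transpose(0, 2, 1)).reshape(d, T * c)


def _group_deviation(W: np.ndarray) -> np.ndarray:
    """Per feature row k: sum_t ||W_t^k - Wbar^k||^2 (>= 0)."""
    Wbar = W.mean(axis=2, keepdims=True)
    return ((W - Wbar) ** 2).sum(axis=(1, 2))


# ---------------------------------------------------------------------------
# Objective and reweighting
# ---------------------------------------------------------------------------

def objective(X, Y, W, config: RegressionConfig) -> float:
    """Value of the penalized longitudinal regression objective.

    Residual + theta1 * group l2,1 of temporal deviations + theta2 * trace
    norm of the unfolding. Does not standardize Y: the value refers to the
    arrays exactly as passed.
    """
    X, Y = _coerce_inputs(X, Y)
    W = _coerce_W(W)
    n, d, T = X.shape
    c = Y.shape[1]
    if W.shape != (d, c, T):
        raise DimensionError(
            f"W shape {W.shape} does not match (d={d}, c={c}, T={T}) from X and Y"
        )
    rss = 0.0
    for t in range(T):
        rss += float(np.linalg.norm(X[:, :, t] @ W[:, :, t] - Y) ** 2)
    group = float(np.sqrt(_group_deviation(W)).sum())
    trace = float(np.linalg.svd(_unfold(W), compute_uv=False).sum())
    return rss + config.theta1 * group + config.theta2 * trace


def update_reweighting(W, epsilon: float = 1e-8) -> IterationState:
    """Reweighting matrices D, Dbar, Ddbar evaluated at the current W.

    ``Ddbar`` is computed by symmetric eigendecomposition of
    ``W_(1) W_(1)^T + eps*I`` with eigenvalues clipped at eps, which keeps it
    symmetric positive definite even for rank-deficient W.
    """
    W = _coerce_W(W)
    if not np.all(np.isfinite(W)):
        raise ValueError("W contains non-finite entries")
    D = 1.0 / (2.0 * np.sqrt(_group_deviation(W) + epsilon))
    Dbar = W.mean(axis=2)
    M = _unfold(W)
    gram = M @ M.T
    gram[np.diag_indices_from(gram)] += epsilon
    eigvals, eigvecs = np.linalg.eigh(gram)
    eigvals = np.maximum(eigvals, epsilon)
    Ddbar = 0.5 * (eigvecs * (1.0 / np.sqrt(eigvals))) @ eigvecs.T
    singular = np.sqrt(np.maximum(eigvals - epsilon, 0.0))[::-1]
    return IterationState(D=D, Dbar=Dbar, Ddbar=Ddbar, singular_values=singular)


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

def _solve_spd(M: np.ndarray, rhs: np.ndarray, theta1: float, theta2: float) -> np.ndarray:
    try:
        c_and_lower = linalg.cho_factor(M, lower=True, check_finite=False)
    except np.linalg.LinAlgError as err:
        if theta1 == 0 and theta2 == 0:
            raise SingularSystemError(
                "X_t'X_t is rank-deficient and theta1 = theta2 = 0: the update has "
                "no regularizer. Set theta1/theta2 > 0 or ridge_init > 0."
            ) from err
        raise
    return linalg.cho_solve(c_and_lower, rhs, check_finite=False)


def fit(
    X,
    Y,
    config: RegressionConfig,
    snapshot_iters=None,
) -> tuple[CoefficientTensor, IterationState]:
    """Fit the longitudinal sparse regression by reweighted closed-form updates.

    Initialization is a deterministic per-time-point ridge solution, so
    fixed-iteration grid runs are reproducible without a seed. Iteration
    stops after ``config.max_iter`` updates or, if ``config.tol`` is set,
    when the relative objective change falls below it.

    ``snapshot_iters`` (optional, sorted iteration counts <= max_iter)
    stores a copy of W after exactly those many updates in
    ``state.snapshots`` — each snapshot is identical to the result of an
    independent fixed-count run because the iteration is deterministic.

    Returns the coefficient tensor and the final IterationState, whose
    ``objective_trace`` holds the objective at initialization and after
    every update.
    """
    config.validate()
    X_arr, Y_arr = _coerce_inputs(X, Y)
    n, d, T = X_arr.shape
    c = Y_arr.shape[1]
    if config.standardize_y:
        mu = Y_arr.mean(axis=0, keepdims=True)
        sd = Y_arr.std(axis=0, ddof=1, keepdims=True) if n > 1 else np.ones((1, c))
        sd = np.where(sd == 0, 1.0, sd)
        Y_arr = (Y_arr - mu) / sd
    snapshots_wanted = sorted(set(int(s) for s in snapshot_iters)) if snapshot_iters else []
    if snapshots_wanted and snapshots_wanted[-1] > config.max_iter:
        raise ValueError("snapshot iteration exceeds max_iter")

    th1, th2, eps = config.theta1, config.theta2, config.epsilon
    # With both penalties off the update is unregularized least squares; the
    # ridge term is then kept in the system so ridge_init > 0 can rescue a
    # rank-deficient design (with full-rank X and ridge_init = 0 this is OLS).
    base_ridge = config.ridge_init if (th1 == 0 and th2 == 0) else 0.0

    G = np.empty((T, d, d))
    H = np.empty((T, d, c))
    for t in range(T):
        Xt = X_arr[:, :, t]
        G[t] = Xt.T @ Xt
        H[t] = Xt.T @ Y_arr

    # Deterministic per-time ridge initialization (minimum-norm least squares
    # when ridge_init = 0, so rank-deficient designs still initialize).
    W = np.empty((d, c, T))
    for t in range(T):
        if config.ridge_init > 0:
            M0 = G[t].copy()
            M0[np.diag_indices_from(M0)] += config.ridge_init
            W[:, :, t] = _solve_spd(M0, H[t], th1 + config.ridge_init, th2)
        else:
            W[:, :, t] = np.linalg.lstsq(X_arr[:, :, t], Y_arr, rcond=None)[0]

    def current_objective(state: IterationState) -> float:
        rss = 0.0
        for t in range(T):
            rss += float(np.linalg.norm(X_arr[:, :, t] @ W[:, :, t] - Y_arr) ** 2)
        group = float(np.sqrt(_group_deviation(W)).sum())
        return rss + th1 * group + th2 * float(state.singular_values.sum())

    trace: list[float] = []
    state = update_reweighting(W, eps)
    trace.append(current_objective(state))
    converged = False
    n_iter = 0
    snapshots: dict[int, np.ndarray] = {}
    for it in range(1, config.max_iter + 1):
        rhs_smooth = (th1 * state.D)[:, None] * state.Dbar if th1 > 0 else None
        for t in range(T):
            M = G[t].copy()
            diag = M.reshape(-1)[:: d + 1]
            if th1 > 0:
                diag += th1 * state.D
            if base_ridge > 0:
                diag += base_ridge
            if th2 > 0:
                M += th2 * state.Ddbar
            rhs = H[t] if rhs_smooth is None else H[t] + rhs_smooth
            W[:, :, t] = _solve_spd(M, rhs, th1 + base_ridge, th2)
        n_iter = it
        state = update_reweighting(W, eps)
        trace.append(current_objective(state))
        if it in snapshots_wanted:
            snapshots[it] = W.copy()
        if config.tol is not None and len(trace) >= 2:
            prev, curr = trace[-2], trace[-1]
            if abs(prev - curr) <= config.tol * max(1.0, abs(prev)):
                converged = True
                break

    state.objective_trace = trace
    state.n_iter = n_iter
    state.converged = converged
    state.snapshots = snapshots
    feature_names = X.feature_names if isinstance(X, LongitudinalFeatureTensor) else []
    gene_symbols = Y.gene_symbols if isinstance(Y, ExpressionMatrix) else []
    time_labels = X.time_labels if isinstance(X, LongitudinalFeatureTensor) else []
    coeff = CoefficientTensor(
        values=W,
        feature_names=list(feature_names),
        gene_symbols=list(gene_symbols),
        time_labels=list(time_labels),
    )
    return coeff, state


# ---------------------------------------------------------------------------
# Gene ranking
# ---------------------------------------------------------------------------

def overall_weights(W, gene_symbols=None) -> WeightMap:
    """Overall gene weights: W'(t, j) = sum_i |W_t(i, j)|, averaged over time.

    Absolute coefficients are summed (a signed sum would let positive and
    negative feature effects cancel); genes are ranked by descending
    time-average weight, ties broken by gene index.
    """
    symbols = list(gene_symbols) if gene_symbols is not None else None
    if isinstance(W, CoefficientTensor) and symbols is None:
        symbols = list(W.gene_symbols)
    W = _coerce_W(W)
    d, c, T = W.shape
    weights = np.abs(W).sum(axis=0).T  # (T, c)
    avg = weights.mean(axis=0)
    order = np.lexsort((np.arange(c), -avg))
    return WeightMap(
        weights=weights, avg_weight=avg, order=order, gene_symbols=symbols or []
    )


def top_genes(weight_map: WeightMap, k: int = 50) -> np.ndarray:
    """Indices of the k genes with the largest average overall weight."""
    c = weight_map.avg_weight.shape[0]
    if k > c:
        raise ValueError(f"k = {k} exceeds the number of genes ({c})")
    if k < 1:
        raise ValueError("k must be >= 1")
    return weight_map.order[:k].copy()
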