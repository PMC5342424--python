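"""End-to-end discovery + validation pipeline on one cohort.

Mirrors the study workflow: screen differentially expressed genes (Wilcoxon,
raw p < alpha), regress the screened genes on the longitudinal imaging
features over the full hyperparameter grid, select candidate genes by
coverage rate, then re-test the candidates on an independent cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, LongitudinalFeatureTensor
from .longreg import RegressionConfig
from .screening import ScreenResult, wilcoxon_screen
from .selection import CoverageTable, GridSpec, coverage_select, run_grid
from .synthetic_data import SimulationConfig, SyntheticCohort, generate_dataset, generate_validation_cohort
from .validation import ValidationReport, validate_biomarkers

__all__ = ["DiscoveryResult", "run_discovery", "run_synthetic_study"]


@dataclass
class DiscoveryResult:
    """Everything the discovery phase produces."""

    screen: ScreenResult
    coverage: CoverageTable
    candidates: np.ndarray  # indices into the *full* gene axis
    candidate_symbols: list[str]
    screened_genes: np.ndarray
    grid: GridSpec
    validation: ValidationReport | None = None
    extras: dict = field(default_factory=dict)


def run_discovery(
    X: LongitudinalFeatureTensor,
    Y: ExpressionMatrix,
    grid: GridSpec | None = None,
    base_config: RegressionConfig | None = None,
    alpha: float = 0.005,
    P: float = 0.8,
) -> DiscoveryResult:
    """Screen, fit the grid on the screened genes, select by coverage rate.

    ``grid.top_k`` is capped at the number of screened genes, since the
    regression runs on the screened subset.
    """
    screen = wilcoxon_screen(Y, alpha=alpha)
    screened = np.sort(screen.retained)
    if screened.size < 2:
        raise ValueError(
            f"only {screened.size} genes passed screening at alpha={alpha}; "
            "cannot run the association step"
        )
    Y_sub = Y.subset_genes(screened)
    grid = grid or GridSpec()
    if grid.top_k > screened.size:
        grid = GridSpec(
            theta_values=grid.theta_values,
            iteration_counts=grid.iteration_counts,
            top_k=int(screened.size),
        )
    coverage = run_grid(X, Y_sub, grid, base_config)
    selected_local = coverage_select(coverage, P)
    candidates = screened[selected_local]
    return DiscoveryResult(
        screen=screen,
        coverage=coverage,
        candidates=candidates,
        candidate_symbols=[Y.gene_symbols[j] for j in candidates],
        screened_genes=screened,
        grid=grid,
    )


def run_synthetic_study(
    config: SimulationConfig,
    grid: GridSpec | None = None,
    base_config: RegressionConfig | None = None,
    alpha: float = 0.005,
    P: float = 0.8,
    validation_alpha: float = 0.05,
) -> tuple[SyntheticCohort, DiscoveryResult]:
    """Generate a synthetic cohort, run discovery, validate the candidates.

    The validation cohort is an independent draw in which the *selected*
    candidate genes are shifted upward in the PsP group, emulating the
    biomarkers' behaviour in an external dataset.
    """
    cohort = generate_dataset(config)
    result = run_discovery(cohort.X, cohort.Y, grid, base_config, alpha=alpha, P=P)
    if result.candidates.size:
        val_cohort = generate_validation_cohort(config, result.candidates)
        result.validation = validate_biomarkers(
            val_cohort.Y, [int(j) for j in result.candidates], alpha=validation_alpha
        )
        result.extras["validation_cohort"] = val_cohort
    return cohort, result
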