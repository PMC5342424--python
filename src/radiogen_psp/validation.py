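"""Independent-cohort validation of selected biomarkers.

Each biomarker is re-tested on an independent expression cohort with the
same two-sided Wilcoxon rank-sum engine used for screening; the report
carries the p-value, the direction of the group difference (by median,
with the mean also reported) and the per-group boxplot five-number
summaries. The report's significance threshold defaults to 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PSP, TTP, ExpressionMatrix
from .screening import EmptyGroupError, wilcoxon_rank_sum

__all__ = [
    "ValidationReport",
    "MissingGeneError",
    "HIGHER_IN_PSP",
    "HIGHER_IN_TTP",
    "NO_DIRECTION",
    "validate_biomarkers",
]

HIGHER_IN_PSP = "higher-in-PsP"
HIGHER_IN_TTP = "higher-in-TTP"
NO_DIRECTION = "none"


class MissingGeneError(KeyError):
    """Requested biomarkers are absent from the validation cohort."""


@dataclass
class ValidationReport:
    """Per-biomarker test results and boxplot statistics."""

    frame: pd.DataFrame
    alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["p_value"] < self.alpha]


def _five_numbers(x: np.ndarray, prefix: str) -> dict[str, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        f"{prefix}_min": float(np.min(x)),
        f"{prefix}_q1": float(q1),
        f"{prefix}_median": float(med),
        f"{prefix}_q3": float(q3),
        f"{prefix}_max": float(np.max(x)),
        f"{prefix}_mean": float(np.mean(x)),
    }


def validate_biomarkers(
    Y_indep: ExpressionMatrix,
    biomarkers,
    alpha: float = 0.05,
) -> ValidationReport:
    """Wilcoxon rank-sum validation of biomarkers on an independent cohort.

    ``biomarkers`` may be gene symbols or integer gene indices. Raises
    MissingGeneError listing any symbol absent from the cohort.
    """
    if Y_indep.groups is None:
        raise EmptyGroupError("validation cohort carries no group labels")
    for group in (PSP, TTP):
        if not np.any(Y_indep.groups == group):
            raise EmptyGroupError(f"group {group!r} has no samples")

    biomarkers = list(biomarkers)
    if biomarkers and all(isinstance(b, (int, np.integer)) for b in biomarkers):
        indices = [int(b) for b in biomarkers]
        bad = [j for j in indices if not 0 <= j < Y_indep.n_genes]
        if bad:
            raise MissingGeneError(f"gene indices out of range: {bad}")
        symbols = [Y_indep.gene_symbols[j] for j in indices]
    else:
        symbols = [str(b) for b in biomarkers]
        lookup = {g: j for j, g in enumerate(Y_indep.gene_symbols)}
        missing = [g for g in symbols if g not in lookup]
        if missing:
            raise MissingGeneError(f"genes absent from validation cohort: {missing}")
        indices = [lookup[g] for g in symbols]

    psp = Y_indep.values[np.ix_(Y_indep.group_mask(PSP), indices)]
    ttp = Y_indep.values[np.ix_(Y_indep.group_mask(TTP), indices)]
    p_values = wilcoxon_rank_sum(psp, ttp) if indices else np.array([])

    rows = []
    for i, (gene, j) in enumerate(zip(symbols, indices)):
        med_diff = float(np.median(psp[:, i]) - np.median(ttp[:, i]))
        if med_diff > 0:
            direction = HIGHER_IN_PSP
        elif med_diff < 0:
            direction = HIGHER_IN_TTP
        else:
            direction = NO_DIRECTION
        row = {
            "gene": gene,
            "gene_index": j,
            "p_value": float(p_values[i]),
            "direction": direction,
            "median_difference": med_diff,
            "significant": bool(p_values[i] < alpha),
        }
        row.update(_five_numbers(psp[:, i], "psp"))
        row.update(_five_numbers(ttp[:, i], "ttp"))
        rows.append(row)
    frame = pd.DataFrame(rows)
    return ValidationReport(frame=frame, alpha=alpha)
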