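"""Double-positive (hybrid) cell quantification.

A hybrid cell co-expresses the canonical markers of two populations (e.g.
MUC5AC for goblet cells and FOXJ1 for multiciliated cells) and is read as a
differentiation intermediate. Positivity is either "detected" (normalized
value > 0) or "percentile" (value strictly above the median of the gene's
positive cells — the top-50-percentile display rule). The double-positive
fraction comes with an exact Clopper-Pearson 95% confidence interval.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .io import CountMatrix

POSITIVITY_MODES = ("detected", "percentile")


def positive_cells(
    matrix: CountMatrix, gene: str, rule: str = "detected"
) -> np.ndarray:
    """Boolean flag per cell for positivity of ``gene`` under ``rule``."""
    if rule not in POSITIVITY_MODES:
        raise ValueError(f"unknown positivity rule {rule!r}")
    row = matrix.values[matrix.gene_index(gene), :]
    if rule == "detected":
        return row > 0
    positive = row[row > 0]
    if positive.size == 0:
        return np.zeros(matrix.n_cells, dtype=bool)
    return row > np.median(positive)


@dataclasses.dataclass
class DoublePositiveResult:
    fraction: float          # NaN when the denominator is empty
    n_double: int
    n_denominator: int
    ci_low: float
    ci_high: float
    rule: str
    denominator: str

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def double_positive_fraction(
    matrix: CountMatrix,
    gene_a: str,
    gene_b: str,
    rule: str = "detected",
    denominator: str | np.ndarray = "either",
) -> DoublePositiveResult:
    """Fraction of cells positive for both genes, with exact 95% CI.

    ``denominator`` is ``"either"`` (cells positive for at least one of the
    two genes — the share of the union population, e.g. "% of GCs and
    MCCs"), ``"all"`` (all cells), or an explicit boolean/index cell subset.
    The CI is Clopper-Pearson. Symmetric in (gene_a, gene_b).
    """
    pos_a = positive_cells(matrix, gene_a, rule)
    pos_b = positive_cells(matrix, gene_b, rule)
    both = pos_a & pos_b
    if isinstance(denominator, str):
        if denominator == "either":
            denom_mask = pos_a | pos_b
        elif denominator == "all":
            denom_mask = np.ones(matrix.n_cells, dtype=bool)
        else:
            raise ValueError(f"unknown denominator mode {denominator!r}")
        denom_name = denominator
    else:
        denom_mask = np.zeros(matrix.n_cells, dtype=bool)
        denom_mask[np.asarray(denominator)] = True
        denom_name = "subset"
    n_denom = int(denom_mask.sum())
    n_double = int((both & denom_mask).sum())
    if n_denom == 0:
        return DoublePositiveResult(
            float("nan"), 0, 0, float("nan"), float("nan"), rule, denom_name
        )
    lo, hi = proportion_confint(n_double, n_denom, alpha=0.05, method="beta")
    return DoublePositiveResult(
        fraction=n_double / n_denom,
        n_double=n_double,
        n_denominator=n_denom,
        ci_low=float(lo),
        ci_high=float(hi),
        rule=rule,
        denominator=denom_name,
    )
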