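"""Contingency statistics for oocyte maturation outcomes.

2x2 tables (rows = treatment groups, columns = matured / not matured) are
tested with the Pearson chi-square statistic on 1 degree of freedom
(optionally Yates-corrected; default uncorrected, which reproduces the
worked examples to their printed precision), and maturation rates are
simple percentages.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def chi_square_2x2(table, continuity_correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of a 2x2 table.

    ``table`` is a 2x2 array-like or flat (a, b, c, d) in row-major order.
    Returns (statistic, p_value) with the upper-tail chi-square(1) p.
    """
    arr = np.asarray(table, dtype=float).reshape(2, 2)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if arr.sum() == 0:
        raise ValueError("empty table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: chi-square undefined")
    res = stats.chi2_contingency(arr, correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)


def chi_square_pvalue(statistic: float, df: int = 1) -> float:
    """Upper-tail chi-square probability for a given statistic."""
    if statistic < 0:
        raise ValueError("statistic must be >= 0")
    return float(stats.chi2.sf(statistic, df))


def maturation_rate(matured: int, total: int) -> float:
    """Percentage of oocytes that matured."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= matured <= total:
        raise ValueError("matured must be between 0 and total")
    return 100.0 * matured / total
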