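"""Group-comparison statistics for cohort tables.

Two-sample t-tests (raw-data and summary-statistic forms), Pearson's
chi-square on 2x2 contingency tables, and Bonferroni correction for
multiple comparisons. These are the tests used to compare demographic,
CSF, MRI and neuropsychological measures between the NC/AD training
groups and the MCInc/MCIc test groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "two_sample_t",
    "two_sample_t_summary",
    "chi2_2x2",
    "bonferroni",
]

_T_VARIANTS = ("pooled", "welch")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-group hypothesis test."""

    statistic: float
    df: float
    p_value: float
    method: str  # "t_pooled" | "t_welch" | "chi2_pearson"

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "method": self.method,
        }


def _check_variant(variant: str) -> None:
    if variant not in _T_VARIANTS:
        raise ValueError(f"unknown t-test variant {variant!r}; use one of {_T_VARIANTS}")


def two_sample_t(sample_a, sample_b, variant: str = "pooled") -> TestResult:
    """Two-sided two-sample t-test on raw observations.

    ``variant="pooled"`` assumes equal variances (classical Student t);
    ``variant="welch"`` uses the Welch-Satterthwaite approximation.
    """
    _check_variant(variant)
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError("zero variance in both samples; t-test undefined")
    res = _sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), f"t_{variant}")


def two_sample_t_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    variant: str = "pooled",
) -> TestResult:
    """Two-sided two-sample t-test from summary statistics (mean, SD, n).

    Useful for re-testing printed "mean +/- SD" table rows.
    """
    _check_variant(variant)
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd_a == 0.0 and sd_b == 0.0:
        raise ValueError("zero variance in both samples; t-test undefined")
    res = _sps.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(n_a + n_b - 2)
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return TestResult(float(res.statistic), float(df), float(res.pvalue), f"t_{variant}")


def chi2_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square test on a 2x2 table, no continuity correction.

    The table is ``[[a, b], [c, d]]`` (e.g. a = males in group 1,
    b = non-males in group 1, ...). Uses the closed form
    ``N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` with df = 1.
    """
    cells = (a, b, c, d)
    for x in cells:
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined: a table margin is zero")
    stat = n * (a * d - b * c) ** 2 / float(np.prod([float(m) for m in margins]))
    p = float(_sps.chi2.sf(stat, df=1))
    return TestResult(float(stat), 1.0, p, "chi2_pearson")


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: ``min(1, m * p)`` for m comparisons."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1 or m != int(m):
        raise ValueError("m must be a positive integer")
    return min(1.0, int(m) * p)
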