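"""Conversion-time analysis of MCIc predictive values.

Converters are binned by their conversion month (6/12/18/24) and the
distribution of SVM decision values is summarised per bin; early
(within 12 months, i.e. the 6- and 12-month bins) and late (after 12
months) converters are compared with a two-sample t-test. Under the
severity-gradient generative model, earlier converters sit deeper on
the AD side of the hyperplane, so their decision values are more
negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import TestResult, two_sample_t

__all__ = ["MonthBin", "ConversionSummary", "summarize_by_month", "compare_conversion_groups"]

DEFAULT_MONTHS = (6, 12, 18, 24)


@dataclass(frozen=True)
class MonthBin:
    month: int
    n: int
    mean: float  # nan for empty bins
    sd: float  # sample SD (n-1 denominator); nan if n < 2


@dataclass
class ConversionSummary:
    """Per-month decision-value summaries plus the raw values per bin."""

    bins: tuple
    values_by_month: dict
    cutoff: int = 12

    @property
    def n_total(self) -> int:
        return sum(b.n for b in self.bins)

    def group_values(self, cutoff: int | None = None):
        """(early, late) raw decision values split at ``cutoff`` months
        (inclusive on the early side)."""
        cutoff = self.cutoff if cutoff is None else cutoff
        early = np.concatenate(
            [v for m, v in self.values_by_month.items() if m <= cutoff] or [np.empty(0)]
        )
        late = np.concatenate(
            [v for m, v in self.values_by_month.items() if m > cutoff] or [np.empty(0)]
        )
        return early, late

    def group_stats(self, cutoff: int | None = None) -> dict:
        early, late = self.group_values(cutoff)
        def _stats(v):
            return {
                "n": int(v.size),
                "mean": float(v.mean()) if v.size else float("nan"),
                "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
            }
        return {"early": _stats(early), "late": _stats(late)}

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "bins": [
                {"month": b.month, "n": b.n, "mean": b.mean, "sd": b.sd} for b in self.bins
            ],
            "groups": self.group_stats(),
        }


def summarize_by_month(records, months=DEFAULT_MONTHS, cutoff: int = 12) -> ConversionSummary:
    """Per-bin mean +/- SD of decision values for true MCIc converters.

    ``records`` outside the MCIc group are ignored; an MCIc record
    without a conversion month is an error. Empty bins are reported with
    n = 0 and undefined moments.
    """
    values = {int(m): [] for m in months}
    for r in records:
        if r.true_label != "MCIc":
            continue
        if r.conversion_month is None:
            raise ValueError(f"MCIc record {r.subject_id!r} has no conversion month")
        values.setdefault(int(r.conversion_month), []).append(r.decision_value)
    values = {m: np.asarray(v, dtype=float) for m, v in values.items()}
    bins = tuple(
        MonthBin(
            month=m,
            n=int(v.size),
            mean=float(v.mean()) if v.size else float("nan"),
            sd=float(v.std(ddof=1)) if v.size > 1 else float("nan"),
        )
        for m, v in sorted(values.items())
    )
    return ConversionSummary(bins=bins, values_by_month=values, cutoff=cutoff)


def compare_conversion_groups(
    summary: ConversionSummary, cutoff: int = 12, variant: str = "pooled"
) -> TestResult:
    """Two-sample t-test of decision values: converters at <= ``cutoff``
    months vs later converters."""
    early, late = summary.group_values(cutoff)
    if early.size < 2 or late.size < 2:
        raise ValueError("both conversion groups need n >= 2")
    return two_sample_t(early, late, variant=variant)
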