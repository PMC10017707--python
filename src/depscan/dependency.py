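"""Dependency scoring from cell-competition assays, and PTF scores.

The competition assay mixes a Cre-recombined (Tomato+, oncogene-null) and a
GFP+ (oncogene-intact) population 50/50 and follows both fractions by flow
cytometry over sequential passages.  Under exponential growth the log2 odds

    log2( count_test(t) / count_ref(t) )

is linear in time with slope equal to the difference of the two log2 growth
rates (units: log2 fold-change per day).  We estimate that slope by ordinary
least squares; the *dependency score* is its negation, so that lines whose
knockout population collapses fastest score highest.

The PTF score counts how many of the five progenitor transcription factors
(Sox2, Sox5, Twist2, Nr2f1, Nr2f2) are highly expressed in a line.  "Highly
expressed" is an operational call: expression at least a fraction ``frac``
(default 0.25) of the panel maximum for that factor, and nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PTF_FACTORS",
    "CompetitionTimeSeries",
    "DependencyScore",
    "PtfScore",
    "relative_growth_rate",
    "ptf_score",
    "group_lines",
]

PTF_FACTORS = ("Sox2", "Sox5", "Twist2", "Nr2f1", "Nr2f2")


@dataclass
class CompetitionTimeSeries:
    """FACS counts of the test (Tm+) and reference (GFP+) populations."""

    line_id: str
    days: np.ndarray
    count_test: np.ndarray
    count_ref: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.count_test = np.asarray(self.count_test)
        self.count_ref = np.asarray(self.count_ref)
        if not (len(self.days) == len(self.count_test) == len(self.count_ref)):
            raise ValueError("days/count_test/count_ref lengths differ")
        if len(self.days) < 2:
            raise ValueError("need at least two timepoints")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.count_test < 0) or np.any(self.count_ref < 0):
            raise ValueError("counts must be nonnegative")


@dataclass
class DependencyScore:
    line_id: str
    log2_rel_growth: float  # OLS slope, log2 units per day
    standard_error: float
    yap_dependency: float = field(init=False)

    def __post_init__(self) -> None:
        # higher = more dependent: the knockout population shrinks faster
        self.yap_dependency = -self.log2_rel_growth


@dataclass
class PtfScore:
    line_id: str
    calls: dict[str, bool]
    score: int = field(init=False)

    def __post_init__(self) -> None:
        self.score = int(sum(bool(v) for v in self.calls.values()))


def relative_growth_rate(series: CompetitionTimeSeries) -> DependencyScore:
    """OLS slope of log2(count_test/count_ref) against days.

    Timepoints where either count is zero carry no finite log-odds and are
    dropped; fewer than two usable timepoints is an error.  The standard
    error is the OLS slope SE from residuals (0 when only two points remain).
    """
    usable = (series.count_test > 0) & (series.count_ref > 0)
    days = series.days[usable]
    if len(days) < 2:
        raise ValueError(
            f"{series.line_id}: fewer than 2 timepoints with both counts > 0"
        )
    log2_odds = np.log2(series.count_test[usable] / series.count_ref[usable])
    res = stats.linregress(days, log2_odds)
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return DependencyScore(series.line_id, float(res.slope), se)


def ptf_score(
    expression: pd.DataFrame, frac: float = 0.25, factors=PTF_FACTORS
) -> list[PtfScore]:
    """Score each line (row) by its number of highly expressed PTFs.

    A factor is called highly expressed in a line iff its value is > 0 and
    >= ``frac`` times the panel maximum of that factor.
    """
    missing = [f for f in factors if f not in expression.columns]
    if missing:
        raise ValueError(f"missing factor column(s): {missing}")
    out = []
    maxima = expression[list(factors)].max(axis=0)
    for line_id, row in expression.iterrows():
        calls = {
            f: bool(row[f] > 0 and maxima[f] > 0 and row[f] >= frac * maxima[f])
            for f in factors
        }
        out.append(PtfScore(str(line_id), calls))
    return out


def group_lines(scores: list[PtfScore], low_max: int = 2) -> dict[str, list[str]]:
    """Partition lines into Low (score <= low_max) and High PTF groups."""
    for s in scores:
        if not 0 <= s.score <= 5:
            raise ValueError(f"{s.line_id}: PTF score {s.score} outside 0-5")
    return {
        "low": [s.line_id for s in scores if s.score <= low_max],
        "high": [s.line_id for s in scores if s.score > low_max],
    }
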