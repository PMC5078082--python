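"""Statistics for ordinal immunohistochemistry (IHC) score tables.

Staining is graded from the percentage of positively labeled cells:
below 5% -> grade 0 (-), 5-30% -> 1 (+), above 30 up to 70% -> 2 (++),
above 70% -> 3 (+++). A group's *positive rate* is the fraction of specimens
at grade + or higher. Association between groups and grades is tested with
the Pearson chi-square statistic (no continuity correction) on the count
table after dropping all-zero rows and columns.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2_contingency

GRADES = ("-", "+", "++", "+++")


@dataclass
class ScoreTable:
    """Groups x ordered staining grades count matrix."""

    groups: list[str]
    grades: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.groups), len(self.grades)):
            raise ValueError("counts shape must be (groups, grades)")
        if len(self.groups) < 2 or len(self.grades) < 2:
            raise ValueError("need at least 2 groups and 2 grades")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        if self.counts.sum() == 0:
            raise ValueError("need at least one positive count")

    def row(self, group: str) -> np.ndarray:
        return self.counts[self.groups.index(group)]


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    dropped_rows: list[str] = field(default_factory=list)
    dropped_cols: list[str] = field(default_factory=list)


def grade_from_percent(percent_positive: float) -> int:
    """Map a percent-positive-cells reading to the ordinal grade 0-3.

    Breakpoints are treated as <5 -> 0, <=30 -> 1, <=70 -> 2, else 3, which
    makes the mapping total and monotone (readings between 30 and 31 fall in
    grade 2, the nearest stated interval).
    """
    if not np.isfinite(percent_positive) or not (0.0 <= percent_positive <= 100.0):
        raise ValueError(f"percent must be a finite value in [0, 100], got {percent_positive!r}")
    if percent_positive < 5:
        return 0
    if percent_positive <= 30:
        return 1
    if percent_positive <= 70:
        return 2
    return 3


def positive_rate(row: np.ndarray) -> float:
    """Fraction of specimens with staining grade + or higher."""
    row = np.asarray(row)
    total = row.sum()
    if total < 1:
        raise ValueError("row total must be at least 1")
    return float(row[1:].sum() / total)


def chi_square(table: ScoreTable) -> ChiSquareResult:
    """Pearson chi-square on the table after dropping all-zero margins.

    Expected counts come from margin products over the grand total; no
    continuity correction; df = (r'-1)(c'-1) for the reduced table.
    """
    counts = table.counts
    row_keep = counts.sum(axis=1) > 0
    col_keep = counts.sum(axis=0) > 0
    reduced = counts[np.ix_(row_keep, col_keep)]
    if reduced.shape[0] < 2 or reduced.shape[1] < 2:
        raise ValueError("reduced table smaller than 2x2")
    stat, p, df, _ = chi2_contingency(reduced, correction=False)
    return ChiSquareResult(
        statistic=float(stat),
        df=int(df),
        p=float(p),
        dropped_rows=[g for g, keep in zip(table.groups, row_keep) if not keep],
        dropped_cols=[g for g, keep in zip(table.grades, col_keep) if not keep],
    )
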