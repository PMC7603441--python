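"""Categorical association statistics for palate-shape x mandible-shape tables.

Pearson chi-squared for r x c tables with the full expected-count and
per-cell contribution blocks, collapse of an r x c table onto a 2 x 2
indicator table, Fisher's exact test with the point-probability two-sided
rule, and Bonferroni adjustment.  No Yates continuity correction anywhere:
the study reports the uncorrected Pearson statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

#: Relative tolerance for probability ties in the two-sided Fisher rule.
FISHER_TIE_RTOL = 1e-7

#: Palate x mandible joint counts from the reference validation cohort
#: (n = 100 orthodontic subjects).  Rows: palate shape; columns: mandible shape.
STUDY_SHAPE_COUNTS = np.array([
    #  curved  horizontal  oblique
    [9, 13, 6],    # concave palate
    [5, 3, 15],    # convex palate
    [21, 15, 13],  # horizontal palate
])
STUDY_PALATE_LABELS = ("concave", "convex", "horizontal")
STUDY_MANDIBLE_LABELS = ("curved", "horizontal", "oblique")


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be 2-D")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.all(c == np.round(c)):
                raise ValueError("counts must be integers")
            c = c.astype(np.int64)
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if c.sum() == 0:
            raise ValueError("empty table")
        if len(self.row_labels) != c.shape[0] or len(self.col_labels) != c.shape[1]:
            raise ValueError("label counts do not match table dimensions")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def cell(self, row_label: str, col_label: str) -> int:
        return int(self.counts[self.row_labels.index(row_label),
                               self.col_labels.index(col_label)])


def study_shape_table() -> ContingencyTable:
    """The reference cohort's palate x mandible contingency table."""
    return ContingencyTable(STUDY_SHAPE_COUNTS.copy(),
                            STUDY_PALATE_LABELS, STUDY_MANDIBLE_LABELS)


@dataclass(frozen=True)
class ChiSquareResult:
    expected: np.ndarray
    contributions: np.ndarray
    statistic: float
    df: int
    p: float

    def expected_cell(self, t: ContingencyTable, row_label: str, col_label: str) -> float:
        return float(self.expected[t.row_labels.index(row_label),
                                   t.col_labels.index(col_label)])

    def contribution_cell(self, t: ContingencyTable, row_label: str, col_label: str) -> float:
        return float(self.contributions[t.row_labels.index(row_label),
                                        t.col_labels.index(col_label)])


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float
    odds_ratio: float


def chi_square_independence(t: ContingencyTable) -> ChiSquareResult:
    """Uncorrected Pearson chi-squared test of independence for an r x c table."""
    obs = t.counts.astype(float)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero row or column margin: expected counts vanish")
    expected = np.outer(rows, cols) / obs.sum()
    contributions = (obs - expected) ** 2 / expected
    statistic = float(contributions.sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ChiSquareResult(expected=expected, contributions=contributions,
                           statistic=statistic, df=df,
                           p=float(stats.chi2.sf(statistic, df)))


def collapse_to_2x2(t: ContingencyTable, row_category: str,
                    col_category: str) -> ContingencyTable:
    """Binarise both factors onto target categories, preserving the total.

    Output rows are (row_category, not), columns (col_category, not).
    """
    if row_category not in t.row_labels:
        raise ValueError(f"unknown row category {row_category!r}")
    if col_category not in t.col_labels:
        raise ValueError(f"unknown column category {col_category!r}")
    i = t.row_labels.index(row_category)
    j = t.col_labels.index(col_category)
    both = t.counts[i, j]
    row_only = t.counts[i, :].sum() - both
    col_only = t.counts[:, j].sum() - both
    rest = t.total - both - row_only - col_only
    return ContingencyTable(
        np.array([[both, row_only], [col_only, rest]]),
        (row_category, f"not_{row_category}"),
        (col_category, f"not_{col_category}"),
    )


def fisher_exact_2x2(t: ContingencyTable) -> FisherResult:
    """Two-sided Fisher exact test by the point-probability rule.

    With margins fixed, sums the hypergeometric probabilities of every table
    whose point probability is at most the observed table's (within
    ``FISHER_TIE_RTOL`` relative tolerance).  Odds ratio is ad/bc
    (infinite when bc = 0).
    """
    c = t.counts
    if c.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 needs a 2x2 table")
    a, b = int(c[0, 0]), int(c[0, 1])
    cc, d = int(c[1, 0]), int(c[1, 1])
    n = a + b + cc + d
    r1, c1 = a + b, a + cc
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        raise ValueError("degenerate margins: exact test undefined")
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + FISHER_TIE_RTOL)].sum())
    odds = float("inf") if b * cc == 0 else (a * d) / (b * cc)
    return FisherResult(p_two_sided=min(p, 1.0), odds_ratio=odds)


def bonferroni_adjust(p: float, m: int) -> float:
    """min(1, m * p) for m simultaneous comparisons."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be a positive count")
    return min(1.0, m * p)


def association_table(t: ContingencyTable, res: ChiSquareResult) -> str:
    """TSV rendering with observed / expected / contribution blocks and footer."""
    lines = ["\t".join(["", *t.col_labels, "All"])]
    for i, rl in enumerate(t.row_labels):
        obs = [str(int(v)) for v in t.counts[i]]
        lines.append("\t".join([rl, *obs, str(int(t.counts[i].sum()))]))
        lines.append("\t".join(["  expected", *(f"{v:.3f}" for v in res.expected[i]), ""]))
        lines.append("\t".join(["  chi-square", *(f"{v:.4f}" for v in res.contributions[i]), ""]))
    col_tot = [str(int(v)) for v in t.counts.sum(axis=0)]
    lines.append("\t".join(["All", *col_tot, str(t.total)]))
    lines.append(f"statistic\t{res.statistic:.3f}\tdf\t{res.df}\tp\t{res.p:.3g}")
    return "\n".join(lines) + "\n"
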