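"""Hypothesis tests and indices for stomatal counts and density samples.

The stomatal index is 100 x stomata / (stomata + non-stomatal epidermal
cells).  Index comparisons between groups use a Pearson chi-squared test of
independence on the 2x2 contingency table (no continuity correction, df=1);
density samples, which are small (typically 6-10 cotyledons per genotype)
and not assumed normal, are compared with the Mann-Whitney U test (exact
when the combined sample is small, normal approximation with tie correction
otherwise) and the Kruskal-Wallis test for three or more groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["ContingencyTable2x2", "stomatal_index", "chi_square_2x2", "mann_whitney_u", "kruskal_wallis"]

#: combined sample size at or below which Mann-Whitney uses exact enumeration
MWU_EXACT_MAX_N = 20


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Stoma / non-stomatal cell counts for two groups."""

    group_a: str
    group_b: str
    stomata_a: int
    other_a: int
    stomata_b: int
    other_b: int

    def __post_init__(self) -> None:
        counts = (self.stomata_a, self.other_a, self.stomata_b, self.other_b)
        if any(c < 0 or int(c) != c for c in counts):
            raise ValueError("counts must be non-negative integers")
        if self.stomata_a + self.other_a == 0 or self.stomata_b + self.other_b == 0:
            raise ValueError("each group must have a positive total")

    def as_array(self) -> np.ndarray:
        return np.array([[self.stomata_a, self.other_a], [self.stomata_b, self.other_b]], dtype=float)


def stomatal_index(stomata: int, non_stomatal: int) -> float:
    """Stomatal index in percent: 100*s/(s + n)."""
    if stomata < 0 or non_stomatal < 0:
        raise ValueError("counts must be non-negative")
    total = stomata + non_stomatal
    if total == 0:
        raise ValueError("total cell count must be positive")
    return 100.0 * stomata / total


def chi_square_2x2(t: ContingencyTable2x2 | np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared test of independence on a 2x2 table.

    No continuity correction; df = 1; upper-tail p.  Uses the closed form
    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), which also vectorizes over
    stacked tables (see :func:`chi_square_2x2_many`).  A zero margin makes
    the test undefined and raises.
    """
    table = t.as_array() if isinstance(t, ContingencyTable2x2) else np.asarray(t, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    stat, p = chi_square_2x2_many(
        table[0, 0][None], table[0, 1][None], table[1, 0][None], table[1, 1][None]
    )
    return float(stat[0]), float(p[0])


def chi_square_2x2_many(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson chi-squared over many 2x2 tables [[a, b], [c, d]]."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if np.any(margins == 0):
        raise ValueError("zero margin: chi-squared test undefined")
    stat = n * (a * d - b * c) ** 2 / margins
    return stat, sps.chi2.sf(stat, df=1)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when the combined sample size is at most
    ``MWU_EXACT_MAX_N`` and there are no ties; normal approximation with tie
    correction (and continuity correction) otherwise.  Returns the U
    statistic of the first sample and the two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (a.size + b.size <= MWU_EXACT_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H test (tie-corrected) with the chi-squared approximation.

    Accepts two or more samples; all-identical observations give H=0, p=1.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("groups must be non-empty")
    if len(np.unique(np.concatenate(arrays))) == 1:
        return 0.0, 1.0
    res = sps.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)
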