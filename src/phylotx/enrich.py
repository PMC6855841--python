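"""Fisher exact enrichment of gene sets and phylostrata in clusters.

The 2x2 test is computed from the exact hypergeometric distribution in
integer arithmetic: for a table [[a, b], [c, d]] with row margins
r1 = a + b, r2 = c + d and column margin c1 = a + c, the probability of
a table with top-left cell k is

    P(k) = C(r1, k) C(r2, c1 - k) / C(n, c1).

The one-sided (enrichment) p-value sums P(k) for k >= a; the two-sided
p-value sums P(k) over all k with P(k) <= P(a), with ties decided by
exact integer comparison of the numerators (no floating-point
tolerance). Each p-value is a single integer ratio, so the only
rounding is the final float conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "fisher_2x2",
    "stratum_cluster_enrichment",
    "set_overlap_enrichment",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = in set / not, cols = in cluster / not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    table: ContingencyTable2x2
    odds_ratio: float  # ad/bc, inf when bc == 0 and ad > 0, nan for 0/0
    p_one_sided: float
    p_two_sided: float
    adjusted_p: Optional[float] = None


def fisher_2x2(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> EnrichmentResult:
    """Fisher's exact test for a 2x2 table.

    One-sided tests enrichment (upper tail of the top-left cell given
    the margins); two-sided sums all tables with probability at most
    that of the observed one.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    n = table.n
    if n == 0:
        return EnrichmentResult(table, float("nan"), 1.0, 1.0)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    denom = comb(n, c1)
    obs = nums[a - lo]
    p_one = sum(nums[a - lo :]) / denom
    p_two = sum(x for x in nums if x <= obs) / denom
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(table, odds, min(p_one, 1.0), min(p_two, 1.0))


def _bh_adjust(results: Sequence[EnrichmentResult], use: str = "p_one_sided") -> None:
    """Benjamini-Hochberg adjustment across a family, in place."""
    if not results:
        return
    raw = [getattr(r, use) for r in results]
    adj = multipletests(raw, method="fdr_bh")[1]
    for r, p in zip(results, adj):
        r.adjusted_p = float(p)


def stratum_cluster_enrichment(
    ages: pd.DataFrame | pd.Series,
    assignment: pd.Series,
    adjust: bool = True,
) -> pd.DataFrame:
    """Fisher enrichment of every stratum in every cluster.

    The universe is every gene of ``assignment`` (assigned or not).
    For each (cluster, stratum) pair the table counts genes of that
    stratum inside/outside the cluster. BH adjustment is applied over
    the whole family of pairs (on the one-sided p) unless disabled.
    """
    strata = ages["stratum"] if isinstance(ages, pd.DataFrame) else ages
    universe = assignment.index
    missing = universe.difference(strata.index)
    if len(missing):
        raise ValueError(f"gene(s) in assignment without an age: {list(missing[:5])}")
    strata = strata.loc[universe]
    clusters = sorted(assignment.dropna().unique())
    rows, results = [], []
    for cl in clusters:
        in_cl = (assignment == cl).fillna(False).astype(bool)
        n_cl = int(in_cl.sum())
        if n_cl == 0:
            continue
        for st in sorted(strata.unique()):
            in_st = strata == st
            a = int((in_st & in_cl).sum())
            b = int((in_st & ~in_cl).sum())
            c = n_cl - a
            d = int(len(universe)) - a - b - c
            res = fisher_2x2(ContingencyTable2x2(a, b, c, d))
            results.append(res)
            rows.append(
                {
                    "cluster": int(cl),
                    "stratum": int(st),
                    "a": a, "b": b, "c": c, "d": d,
                    "odds_ratio": res.odds_ratio,
                    "p_one": res.p_one_sided,
                    "p_two": res.p_two_sided,
                }
            )
    if adjust:
        _bh_adjust(results)
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = [r.adjusted_p if adjust else np.nan for r in results]
    return out


def set_overlap_enrichment(
    set_a: Sequence[str], set_b: Sequence[str], universe: Sequence[str]
) -> EnrichmentResult:
    """Fisher test of the overlap between two gene sets in a universe.

    Builds the table [[|A and B|, |A - B|], [|B - A|, |rest|]] and runs
    :func:`fisher_2x2`; a one-sided p near 0 means A and B overlap more
    than chance expects.
    """
    uni = set(universe)
    if len(uni) != len(list(universe)):
        raise ValueError("universe contains duplicates")
    A, B = set(set_a), set(set_b)
    if not A <= uni or not B <= uni:
        raise ValueError("set_a and set_b must be subsets of the universe")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(uni) - a - b - c
    return fisher_2x2(ContingencyTable2x2(a, b, c, d))
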