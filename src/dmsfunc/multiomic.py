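"""Quadrant concordance of paired region/gene log2 fold changes.

Given differential chromatin-accessibility L2FC for a regulatory region and
differential expression L2FC for its annotated gene, each pair falls in one
of four sign quadrants.  Concordance is the fraction of pairs where both
members move the same way; association between the two sign margins is
tested with a two-sided Fisher exact test on the 2x2 sign table (the only
contingency construction under which the exact test is defined; a skewed but
independent margin is deliberately not penalized).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

__all__ = ["QuadrantTable", "fisher_exact_2x2", "quadrant_concordance"]


@dataclass
class QuadrantTable:
    """Counts by sign quadrant of (region_l2fc, gene_l2fc).

    q_pp/q_pm/q_mp/q_mm: (+,+), (+,-), (-,+), (-,-).  Concordant pairs share
    a sign: fraction = (q_pp + q_mm) / total.
    """

    q_pp: int
    q_pm: int
    q_mp: int
    q_mm: int
    concordance_fraction: float
    odds_ratio: float
    fisher_p: float
    degenerate: bool

    @property
    def total(self) -> int:
        return self.q_pp + self.q_pm + self.q_mp + self.q_mm


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Exact integer hypergeometric enumeration over all tables with the
    observed margins, summing the probability of every table whose
    probability is <= that of the observed one.  Degenerate margins give
    p = 1.  Exact because table probabilities are compared as integers
    (the common C(n, c1) denominator cancels).
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    observed = comb(r1, a) * comb(r2, c1 - a)
    num = sum(
        t for k in range(lo, hi + 1)
        if (t := comb(r1, k) * comb(r2, c1 - k)) <= observed
    )
    return num / comb(n, c1)


def quadrant_concordance(pairs: pd.DataFrame, l2fc_min: float = 1.0) -> QuadrantTable:
    """Quadrant counts, concordance fraction and Fisher exact p for paired
    L2FC values.

    ``pairs`` needs columns region_l2fc and gene_l2fc; rows must pass
    |l2fc| > l2fc_min on both members (the usual effect-size filter for
    differential peaks/genes).
    """
    region = pairs["region_l2fc"].to_numpy(dtype=float)
    gene = pairs["gene_l2fc"].to_numpy(dtype=float)
    keep = (np.abs(region) > l2fc_min) & (np.abs(gene) > l2fc_min)
    keep &= np.isfinite(region) & np.isfinite(gene)
    region, gene = region[keep], gene[keep]
    if region.size == 0:
        raise ValueError(f"no pairs with |L2FC| > {l2fc_min} on both members")
    rp, gp = region > 0, gene > 0
    q_pp = int((rp & gp).sum())
    q_pm = int((rp & ~gp).sum())
    q_mp = int((~rp & gp).sum())
    q_mm = int((~rp & ~gp).sum())
    total = q_pp + q_pm + q_mp + q_mm
    frac = (q_pp + q_mm) / total
    degenerate = (q_pp + q_pm == 0 or q_mp + q_mm == 0
                  or q_pp + q_mp == 0 or q_pm + q_mm == 0)
    p = fisher_exact_2x2(q_pp, q_pm, q_mp, q_mm)
    if q_pm * q_mp > 0:
        odds = (q_pp * q_mm) / (q_pm * q_mp)
    else:
        odds = np.inf if q_pp * q_mm > 0 else np.nan
    return QuadrantTable(q_pp=q_pp, q_pm=q_pm, q_mp=q_mp, q_mm=q_mm,
                         concordance_fraction=frac, odds_ratio=odds,
                         fisher_p=p, degenerate=degenerate)
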