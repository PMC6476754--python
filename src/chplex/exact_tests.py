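"""Exact inference on community polymorphism and sharing counts.

Two procedures:

* **Fisher's exact test** (two-sided) on 2x2 tables, using the
  point-probability rule: the p-value sums, over all tables with the
  observed margins, the hypergeometric probabilities not exceeding that of
  the observed table (ties detected with a small relative tolerance, since
  probability masses are compared in floating point).

* **Binomial tail probabilities** under a uniform-rate null: for a genus
  with ``n`` trials (species, or species pairs) and ``k`` successes at null
  rate ``p0``, ``p_minus = P(X <= k)`` and ``p_plus = P(X >= k)`` — both
  tails include the observed count, so ``p_minus + p_plus = 1 + P(X = k)``.
  Tails are exact partial sums of the binomial pmf (no normal
  approximation), accumulated with compensated summation.

Two genus-level scans apply the binomial tails to every genus with at least
``min_species`` analyzed species: one to polymorphic-species counts (null
rate = the community-wide polymorphic fraction, focal genus included) and
one to haplotype-sharing species-pair counts (null rate = the
community-wide fraction of sharing pairs over the whole restricted
universe).  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import fsum
from typing import List, Sequence, Tuple

import numpy as np
from scipy.stats import binom, hypergeom

from .community_stats import SharingSummary, SpeciesSummary
from .errors import ValidationError

__all__ = [
    "ContingencyResult",
    "BinomialScanRow",
    "fisher_two_sided",
    "binomial_tails",
    "genus_polymorphism_scan",
    "genus_pair_sharing_scan",
]

#: Relative tolerance for detecting probability-mass ties in the Fisher sum.
FISHER_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyResult:
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    p_two_sided: float


@dataclass(frozen=True)
class BinomialScanRow:
    genus: str
    n: int
    k: int
    p0: float
    p_minus: float
    p_plus: float


def fisher_two_sided(table) -> ContingencyResult:
    """Two-sided Fisher's exact test on a 2x2 table of nonnegative counts.

    Conditional on both margins, the count in the top-left cell follows a
    hypergeometric law; the two-sided p-value is the total probability of
    all tables whose point probability is at most the observed one.  An
    all-zero table returns p = 1 by convention.
    """
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    cells = [int(t[i, j]) for i in range(2) for j in range(2)]
    if any(c < 0 for c in cells):
        raise ValidationError(f"negative cell in table {cells}")
    a, b, c, d = cells
    n_total = a + b + c + d
    frozen = ((a, b), (c, d))
    if n_total == 0:
        return ContingencyResult(frozen, 1.0)
    row1 = a + b
    col1 = a + c
    rv = hypergeom(n_total, col1, row1)
    lo = max(0, row1 - (n_total - col1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1.0 + FISHER_TIE_RTOL)].sum())
    if p > 1.0 - len(pmf) * 1e-15:  # full support selected up to rounding
        p = 1.0
    return ContingencyResult(frozen, min(p, 1.0))


def binomial_tails(n: int, k: int, p0: float) -> Tuple[float, float]:
    """Inclusive lower and upper binomial tails ``(P(X<=k), P(X>=k))``.

    Both tails are exact partial sums of the Binomial(n, p0) pmf.  The
    smaller tail is summed directly; the other is recovered through the
    identity ``p_minus + p_plus = 1 + P(X=k)``, which therefore holds to
    machine precision.
    """
    if not (0 <= k <= n):
        raise ValidationError(f"k={k} outside 0..{n}")
    if not (0.0 < p0 < 1.0):
        raise ValidationError(f"p0={p0} outside (0, 1)")
    pmf_k = float(binom.pmf(k, n, p0))
    # sum directly on the side of the mode where k sits, so a small tail is
    # always a direct sum and never the difference of two near-one numbers
    if k <= n * p0:
        p_minus = fsum(binom.pmf(np.arange(0, k + 1), n, p0))
        p_minus = min(p_minus, 1.0)
        p_plus = 1.0 - p_minus + pmf_k
    else:
        p_plus = fsum(binom.pmf(np.arange(k, n + 1), n, p0))
        p_plus = min(p_plus, 1.0)
        p_minus = 1.0 - p_plus + pmf_k
    return (min(p_minus, 1.0), min(p_plus, 1.0))


def genus_polymorphism_scan(
    summaries: Sequence[SpeciesSummary], min_species: int = 8
) -> List[BinomialScanRow]:
    """Binomial enrichment scan of polymorphic-species counts per genus.

    Genera with at least *min_species* included species are scanned; the
    null rate is the polymorphic fraction over *all* included species
    (the focal genus is not excluded from the null).  Rows are sorted by
    species count, then genus name.
    """
    included = [s for s in summaries if not s.excluded]
    n_included = len(included)
    n_poly = sum(1 for s in included if s.polymorphic)
    if n_included == 0:
        return []
    if n_poly == 0 or n_poly == n_included:
        raise ValidationError(
            "degenerate community: polymorphic fraction is 0 or 1, "
            "no binomial null can be formed"
        )
    p0 = n_poly / n_included
    by_genus = {}
    for s in included:
        by_genus.setdefault(s.genus, []).append(s)
    rows = []
    for genus, spp in by_genus.items():
        if len(spp) < min_species:
            continue
        n = len(spp)
        k = sum(1 for s in spp if s.polymorphic)
        pm, pp = binomial_tails(n, k, p0)
        rows.append(BinomialScanRow(genus, n, k, p0, pm, pp))
    rows.sort(key=lambda r: (r.n, r.genus))
    return rows


def genus_pair_sharing_scan(
    sharing: SharingSummary, min_species: int = 8
) -> List[BinomialScanRow]:
    """Binomial scan of haplotype-sharing species-pair counts per genus.

    ``n`` is the number of congeneric species pairs C(k, 2) of each genus
    with at least *min_species* analyzed species; the null rate is the
    fraction of sharing pairs over all pairs of the whole restricted
    universe (all genera with >=2 analyzed species).
    """
    total_pairs = sum(g.n_pairs for g in sharing.genus_pairs)
    total_sharing = sum(g.n_pairs_sharing for g in sharing.genus_pairs)
    if total_pairs == 0:
        return []
    if total_sharing == 0 or total_sharing == total_pairs:
        raise ValidationError(
            "degenerate sharing universe: sharing-pair fraction is 0 or 1"
        )
    p0 = total_sharing / total_pairs
    rows = []
    for g in sharing.genus_pairs:
        if g.n_species_analyzed < min_species:
            continue
        pm, pp = binomial_tails(g.n_pairs, g.n_pairs_sharing, p0)
        rows.append(
            BinomialScanRow(g.genus, g.n_pairs, g.n_pairs_sharing, p0, pm, pp)
        )
    rows.sort(key=lambda r: (r.n, r.genus))
    return rows
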