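"""Exact inferential procedures: Fisher's test and binomial tail scans.

Printed p-values from the published community tables are recomputed from
their count tables; implementations are cross-checked against exact
rational-arithmetic oracles and scipy.
"""

import random
from fractions import Fraction
from math import comb

import pytest
from scipy.stats import fisher_exact

from chplex.community_stats import GenusPairs, SharingSummary, SpeciesSummary
from chplex.errors import ValidationError
from chplex.exact_tests import (
    binomial_tails,
    fisher_two_sided,
    genus_pair_sharing_scan,
    genus_polymorphism_scan,
)


def fisher_oracle(table):
    """Exact-rational enumeration of the point-probability two-sided test."""
    (a, b), (c, d) = table
    n, row1, col1 = a + b + c + d, a + b, a + c
    if n == 0:
        return Fraction(1)
    denom = comb(n, row1)
    masses = {}
    for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        masses[x] = Fraction(comb(col1, x) * comb(n - col1, row1 - x), denom)
    p_obs = masses[a]
    return sum(m for m in masses.values() if m <= p_obs)


def binom_oracle(n, k, p0: Fraction):
    """Exact-rational inclusive tails."""
    pmf = [comb(n, x) * p0**x * (1 - p0) ** (n - x) for x in range(n + 1)]
    return sum(pmf[: k + 1]), sum(pmf[k:])


class TestFisher:
    @pytest.mark.parametrize(
        "table, printed, decimals",
        [
            ([[0, 22], [9, 25]], 0.008, 3),      # abiotic polymorphism contrast
            ([[11, 78], [106, 251]], 0.001, 3),  # all species
            ([[89, 112], [66, 171]], 0.0004, 4),  # sharing by polymorphism
            ([[22, 67], [34, 323]], 0.0003, 4),  # abiotic fraction by group
        ],
    )
    def test_reproduces_printed_pvalues(self, table, printed, decimals):
        assert round(fisher_two_sided(table).p_two_sided, decimals) == printed

    def test_balanced_table_is_one(self):
        assert fisher_two_sided([[1, 1], [1, 1]]).p_two_sided == 1.0

    def test_diagonal_table_by_enumeration(self):
        # margins 5/5, 5/5: only the two diagonal tables have minimal mass
        assert fisher_two_sided([[5, 0], [0, 5]]).p_two_sided == pytest.approx(
            2 / 252, rel=1e-12
        )

    def test_all_zero_convention(self):
        assert fisher_two_sided([[0, 0], [0, 0]]).p_two_sided == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            fisher_two_sided([[-1, 2], [3, 4]])

    def test_matches_exact_enumeration_and_scipy(self):
        rng = random.Random(424242)
        for _ in range(150):
            total = rng.randint(1, 60)
            cuts = sorted(rng.randint(0, total) for _ in range(3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = total - a - b - c
            table = [[a, b], [c, d]]
            p = fisher_two_sided(table).p_two_sided
            assert p == pytest.approx(float(fisher_oracle(table)), rel=1e-9)
            assert p == pytest.approx(fisher_exact(table)[1], rel=1e-7)


class TestBinomialTails:
    P0_POLY = 115 / 446
    P0_PAIRS = 173 / 1262

    @pytest.mark.parametrize(
        "n, k, p0, printed_plus, decimals",
        [
            (10, 7, P0_POLY, 0.004, 3),   # strongest polymorphism excess
            (11, 6, P0_POLY, 0.04, 2),
            (21, 13, P0_POLY, 0.001, 3),
            (8, 3, P0_POLY, 0.34, 2),
        ],
    )
    def test_upper_tail_matches_printed(self, n, k, p0, printed_plus, decimals):
        _, p_plus = binomial_tails(n, k, p0)
        assert round(p_plus, decimals) == printed_plus

    @pytest.mark.parametrize(
        "n, k, printed_minus, decimals",
        [
            (66, 0, 0.00006, 5),   # no sharing at all among 66 pairs
            (28, 0, 0.02, 2),
            (136, 9, 0.007, 3),
            (190, 11, 0.0004, 4),
        ],
    )
    def test_lower_tail_matches_printed(self, n, k, printed_minus, decimals):
        p_minus, _ = binomial_tails(n, k, self.P0_PAIRS)
        assert round(p_minus, decimals) == printed_minus

    def test_extreme_upper_tail(self):
        _, p_plus = binomial_tails(253, 71, self.P0_PAIRS)
        assert p_plus < 1e-8

    def test_closed_forms_at_boundaries(self):
        pm, pp = binomial_tails(12, 0, 0.3)
        assert pm == pytest.approx(0.7**12, rel=1e-12) and pp == 1.0
        pm, pp = binomial_tails(8, 8, 0.1)
        assert pp == pytest.approx(0.1**8, rel=1e-12) and pm == 1.0

    def test_matches_rational_oracle(self):
        rng = random.Random(3)
        for _ in range(60):
            n = rng.randint(1, 30)
            k = rng.randint(0, n)
            p0 = Fraction(rng.randint(1, 99), 100)
            pm, pp = binomial_tails(n, k, float(p0))
            om, op = binom_oracle(n, k, p0)
            assert pm == pytest.approx(float(om), rel=1e-10, abs=1e-13)
            assert pp == pytest.approx(float(op), rel=1e-10, abs=1e-13)

    @pytest.mark.parametrize("n", [5, 100, 10_000])
    def test_inclusive_tail_identity(self, n):
        from scipy.stats import binom as binom_dist

        rng = random.Random(n)
        for _ in range(20):
            k = rng.randint(0, n)
            p0 = rng.uniform(0.01, 0.99)
            pm, pp = binomial_tails(n, k, p0)
            assert pm + pp == pytest.approx(
                1.0 + float(binom_dist.pmf(k, n, p0)), abs=1e-12
            )

    def test_upper_tail_monotone_in_k(self):
        tails = [binomial_tails(40, k, 0.3)[1] for k in range(41)]
        assert all(x >= y for x, y in zip(tails, tails[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            binomial_tails(5, 6, 0.5)
        with pytest.raises(ValidationError):
            binomial_tails(5, 2, 0.0)


def summaries_with(genus_sizes, p0_num, p0_den):
    """Community of included species realizing per-genus (n, k) plus filler
    so the global polymorphic fraction is exactly p0_num/p0_den."""
    rows = []
    used_n = sum(n for n, _ in genus_sizes.values())
    used_k = sum(k for _, k in genus_sizes.values())
    fill_n, fill_k = p0_den - used_n, p0_num - used_k
    assert fill_n >= fill_k >= 0
    items = list(genus_sizes.items()) + [
        (f"Fill{i}", (1, 1 if i < fill_k else 0)) for i in range(fill_n)
    ]
    for genus, (n, k) in items:
        for j in range(n):
            rows.append(
                SpeciesSummary(
                    genus=genus, species=f"{genus}-s{j}", n_individuals=3,
                    n_haplotypes=2 if j < k else 1, excluded=False,
                    polymorphic=j < k, group=2, dispersal_class="biotic",
                )
            )
    return rows


class TestScans:
    TABLE2 = {
        "Talisia": (8, 3), "Tovomita": (8, 1), "Eschweilera": (10, 7),
        "Ocotea": (11, 3), "Eugenia": (11, 2), "Protium": (11, 6),
        "Sloanea": (10, 2), "Licania": (16, 7), "Pouteria": (19, 4),
        "Inga": (21, 13),
    }
    # genus -> (species pairs, pairs sharing); printed lower/upper tails
    TABLE3 = {
        "Talisia": (28, 2), "Tovomita": (28, 0), "Eschweilera": (45, 8),
        "Ocotea": (66, 8), "Eugenia": (66, 0), "Protium": (78, 5),
        "Sloanea": (91, 13), "Licania": (136, 9), "Pouteria": (190, 11),
        "Inga": (253, 71),
    }

    def test_genus_below_threshold_absent(self):
        summaries = summaries_with({"Big": (8, 2), "Small": (7, 2)}, 115, 446)
        rows = genus_polymorphism_scan(summaries, min_species=8)
        assert [r.genus for r in rows] == ["Big"]

    def test_polymorphism_scan_reproduces_upper_tail_column(self):
        summaries = summaries_with(self.TABLE2, 115, 446)
        rows = {r.genus: r for r in genus_polymorphism_scan(summaries)}
        assert rows["Inga"].p0 == pytest.approx(115 / 446, rel=1e-12)
        printed_plus = {
            "Talisia": (0.34, 2), "Tovomita": (0.91, 2), "Eschweilera": (0.004, 3),
            "Ocotea": (0.57, 2), "Eugenia": (0.82, 2), "Protium": (0.04, 2),
            "Sloanea": (0.77, 2), "Licania": (0.09, 2), "Pouteria": (0.76, 2),
            "Inga": (0.001, 3),
        }
        for genus, (value, decimals) in printed_plus.items():
            assert round(rows[genus].p_plus, decimals) == value, genus

    def test_scan_rows_sorted_by_size_then_genus(self):
        summaries = summaries_with(self.TABLE2, 115, 446)
        rows = genus_polymorphism_scan(summaries)
        assert [(r.n, r.genus) for r in rows] == sorted((r.n, r.genus) for r in rows)

    def test_saturated_genus_closed_form(self):
        summaries = summaries_with({"Full": (8, 8)}, 115, 446)
        rows = {r.genus: r for r in genus_polymorphism_scan(summaries)}
        assert rows["Full"].p_plus == pytest.approx((115 / 446) ** 8, rel=1e-9)

    def test_pair_sharing_scan_reproduces_lower_tail_column(self):
        genus_pairs = [
            GenusPairs(g, next(k for k in range(60) if comb(k, 2) == n), n, s)
            for g, (n, s) in self.TABLE3.items()
        ]
        used_pairs = sum(g.n_pairs for g in genus_pairs)
        used_sharing = sum(g.n_pairs_sharing for g in genus_pairs)
        # filler genera below the scan threshold bring the universe to the
        # community totals of 1,262 pairs and 173 sharing pairs
        fill_pairs, fill_sharing = 1262 - used_pairs, 173 - used_sharing
        fillers = []
        i = 0
        while fill_pairs > 0:
            n = min(21, fill_pairs)  # 7 species -> 21 pairs, below threshold
            while not any(comb(k, 2) == n for k in range(8)):
                n -= 1
            k = next(k for k in range(8) if comb(k, 2) == n)
            s = min(n, fill_sharing)
            fillers.append(GenusPairs(f"Fill{i}", k, n, s))
            fill_pairs -= n
            fill_sharing -= s
            i += 1
        assert fill_sharing == 0
        sharing = SharingSummary((), tuple(genus_pairs + fillers))
        rows = {r.genus: r for r in genus_pair_sharing_scan(sharing)}
        assert rows["Inga"].p0 == pytest.approx(173 / 1262, rel=1e-12)
        printed_minus = {
            "Talisia": (0.24, 2), "Tovomita": (0.02, 2), "Eschweilera": (0.84, 2),
            "Ocotea": (0.44, 2), "Eugenia": (0.00006, 5), "Protium": (0.035, 3),
            "Sloanea": (0.64, 2), "Licania": (0.007, 3), "Pouteria": (0.0004, 4),
        }
        for genus, (value, decimals) in printed_minus.items():
            assert round(rows[genus].p_minus, decimals) == value, genus
        assert rows["Inga"].p_minus == pytest.approx(1.0, abs=1e-6)
        assert rows["Inga"].p_plus < 1e-8
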