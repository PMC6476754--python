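"""Difference metric and haplotype collapsing.

The distance decomposes into substitutions, indel events (one per maximal
gap-vs-base run) and inversion events (one per reverse-complement segment);
sequences within one unit collapse into the same haplotype by single
linkage, except for species-diagnostic single-unit states.
"""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chplex.errors import ValidationError
from chplex.haplotyping import (
    COMPLEMENT,
    collapse_haplotypes,
    detect_inversions,
    pairwise_difference,
    sequence_difference,
)

from conftest import random_genus, rec

BASES = "ACGT"


def brute_force_inversions(a, b, min_len, max_len=None):
    """Independent reference: scan every window left-to-right, longest first."""
    n = len(a)
    a, b = a.upper(), b.upper()
    cap = max_len if max_len is not None else n
    res, s = [], 0
    while s <= n - min_len:
        found = None
        for e in range(min(n, s + cap), s + min_len - 1, -1):
            seg_a, seg_b = a[s:e], b[s:e]
            if any(c not in BASES for c in seg_a + seg_b):
                continue
            if seg_b != "".join(COMPLEMENT[c] for c in reversed(seg_a)):
                continue
            if seg_a == seg_b:  # identical palindrome, no mismatching column
                continue
            found = (s, e)
            break
        if found:
            res.append(found)
            s = found[1]
        else:
            s += 1
    return res


class TestSequenceDifference:
    @pytest.mark.parametrize(
        "a, b, subs, indels, invs",
        [
            ("ACGTACGT", "ACGTACGT", 0, 0, 0),
            ("ACGTACGT", "ACGAACGT", 1, 0, 0),
            ("ACG---GT", "ACGTTAGT", 0, 1, 0),  # one maximal gap run = one event
            ("ATGCCCGA", "ATGGGGGA", 0, 0, 1),  # GGG = revcomp(CCC)
            ("A--T--AA", "AGGTGGAA", 0, 2, 0),  # two separate gap runs
            ("AC-TA", "AC-TA", 0, 0, 0),        # shared gap columns ignored
            ("A-GTA", "AG-TA", 0, 2, 0),        # gap flips side: two events
            ("ACGN", "ACGT", 0, 0, 0),          # ambiguity excluded from counting
            ("AN-T", "ACAT", 0, 1, 0),
        ],
    )
    def test_examples(self, a, b, subs, indels, invs):
        d = sequence_difference(a, b)
        assert (d.substitutions, d.indel_events, d.inversion_events) == (
            subs, indels, invs,
        )
        assert d.total_units == subs + indels + invs

    def test_site_mode_counts_gap_columns(self):
        d = sequence_difference("ACG---GT", "ACGTTAGT", indel_mode="site")
        assert d.indel_events == 3 and d.total_units == 3

    def test_case_insensitive(self):
        assert sequence_difference("acgt", "ACGT").total_units == 0

    @given(
        st.text(alphabet="ACGT-", min_size=1, max_size=40),
        st.data(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetry(self, a, data):
        b = data.draw(st.text(alphabet="ACGT-", min_size=len(a), max_size=len(a)))
        d_ab = sequence_difference(a, b)
        d_ba = sequence_difference(b, a)
        assert d_ab.total_units == d_ba.total_units
        assert d_ab.substitutions == d_ba.substitutions

    def test_identity_iff_zero(self):
        assert sequence_difference("ACGT-A", "ACGT-A").total_units == 0
        assert sequence_difference("ACGT-A", "ACGT-C").total_units > 0

    def test_record_preconditions(self):
        with pytest.raises(ValidationError, match="genera"):
            pairwise_difference(rec("a", "ACGT"), rec("b", "ACGT", genus="Protium"))
        with pytest.raises(ValidationError, match="length"):
            pairwise_difference(rec("a", "ACGT"), rec("b", "ACG"))


class TestDetectInversions:
    @pytest.mark.parametrize(
        "a, b, min_len, expected",
        [
            ("AAAA", "AAAA", 3, []),
            ("ATGCCCGA", "ATGGGGGA", 3, [(3, 6)]),
            ("ACGT", "ACGT", 4, []),  # palindrome guard
            ("ATGCCCGA", "ATGGGGGA", 4, []),  # below min length
        ],
    )
    def test_examples(self, a, b, min_len, expected):
        assert detect_inversions(a, b, min_len) == expected

    def test_inversion_not_counted_as_substitutions(self):
        d = sequence_difference("ATGCCCGA", "ATGGGGGA", min_inversion_len=3)
        assert d.inversion_events == 1 and d.substitutions == 0

    def test_min_len_precondition(self):
        with pytest.raises(ValidationError):
            detect_inversions("ACGT", "ACGT", 1)

    def test_matches_window_scan_oracle(self):
        rng = random.Random(20240917)
        comp = COMPLEMENT
        for _ in range(400):
            n = rng.randint(4, 40)
            a = "".join(
                rng.choice("ACGT-") if rng.random() < 0.1 else rng.choice("ACGT")
                for _ in range(n)
            )
            b = list(a)
            for _ in range(rng.randint(0, 3)):
                i = rng.randrange(n)
                b[i] = rng.choice("ACGT")
            if rng.random() < 0.5 and n >= 8:
                s = rng.randrange(0, n - 5)
                e = s + rng.randint(3, 6)
                seg = [rng.choice("ACGT") for _ in range(e - s)]
                b[s:e] = seg
                a_l = list(a)
                a_l[s:e] = [comp[c] for c in reversed(seg)]
                a = "".join(a_l)
            b = "".join(b)
            min_len = rng.choice([2, 3, 4])
            cap = rng.choice([None, 6, 12])
            assert detect_inversions(a, b, min_len, cap) == brute_force_inversions(
                a, b, min_len, cap
            )


def components_oracle(records, **kwargs):
    """Brute-force single linkage: all-pairs distances, boolean transitive
    closure, frozenset-of-members components."""
    n = len(records)
    adj = np.eye(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_difference(records[i], records[j], **kwargs)
            adj[i, j] = adj[j, i] = d.total_units <= 1
    closure = adj.copy()
    for _ in range(n):
        new = closure @ closure
        if (new == closure).all():
            break
        closure = new
    comps = set()
    for i in range(n):
        comps.add(frozenset(records[j].sample_id for j in range(n) if closure[i, j]))
    return comps


class TestCollapse:
    def test_identical_sequences_one_cluster(self):
        clusters = collapse_haplotypes([rec("a", "ACGT"), rec("b", "ACGT")])
        assert len(clusters) == 1
        assert clusters[0].member_sample_ids == {"a", "b"}

    def test_two_substitutions_split(self):
        clusters = collapse_haplotypes([rec("a", "ACGTACGT"), rec("b", "AAGTACGA")])
        assert len(clusters) == 2

    def test_single_unit_merges(self):
        clusters = collapse_haplotypes([rec("a", "ACGTACGT"), rec("b", "ACGTACGA")])
        assert len(clusters) == 1

    def test_species_diagnostic_exception_splits(self):
        base = "ACGTACGT"
        with_t = base[:5] + "T" + base[6:]
        records = [
            rec("s1", with_t, species="X"), rec("s2", with_t, species="X"),
            rec("s3", base, species="Y"), rec("s4", base, species="Y"),
        ]
        clusters = collapse_haplotypes(records)
        assert len(clusters) == 2
        members = {frozenset(c.member_sample_ids) for c in clusters}
        assert members == {frozenset({"s1", "s2"}), frozenset({"s3", "s4"})}

    def test_diagnostic_exception_needs_fixation(self):
        # species X is not uniform for the variant: no split
        base = "ACGTACGT"
        with_t = base[:5] + "T" + base[6:]
        records = [
            rec("s1", with_t, species="X"), rec("s2", base, species="X"),
            rec("s3", base, species="Y"),
        ]
        assert len(collapse_haplotypes(records)) == 1

    def test_diagnostic_gap_run_counts_as_one_unit(self):
        # a species-fixed 2-column deletion is a single diagnostic unit
        base = "ACGTACGTAC"
        gapped = base[:4] + "--" + base[6:]
        records = [
            rec("s1", gapped, species="X"), rec("s2", gapped, species="X"),
            rec("s3", base, species="Y"), rec("s4", base, species="Y"),
        ]
        assert len(collapse_haplotypes(records)) == 2

    def test_chain_is_single_linkage(self):
        a = "ACGTACGT"
        b = a[:7] + "A"          # 1 unit from a
        c = a[:3] + "A" + a[4:7] + "A"  # 1 from b, 2 from a
        clusters = collapse_haplotypes([rec("a", a), rec("b", b), rec("c", c)])
        assert len(clusters) == 1 and len(clusters[0].member_sample_ids) == 3

    def test_id_order_and_representative(self):
        records = [
            rec("z9", "ACGT"), rec("a1", "ACGT"),
            rec("m5", "TGCA", species="sp2"),
            rec("m6", "TGCA", species="sp2"), rec("m7", "TGCA", species="sp2"),
        ]
        clusters = collapse_haplotypes(records)
        assert [c.haplotype_id for c in clusters] == ["H1", "H2"]
        assert clusters[0].member_sample_ids == {"m5", "m6", "m7"}
        assert clusters[1].representative == "ACGT"  # lexicographically smallest id a1

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            collapse_haplotypes([])

    def test_conservation_and_permutation_invariance(self):
        rng = random.Random(7)
        for trial in range(25):
            records = random_genus(rng, rng.randint(2, 10), rng.randint(12, 40))
            clusters = collapse_haplotypes(records)
            assert sum(len(c.member_sample_ids) for c in clusters) == len(records)
            shuffled = records[:]
            rng.shuffle(shuffled)
            again = collapse_haplotypes(shuffled)
            assert {frozenset(c.member_sample_ids) for c in clusters} == {
                frozenset(c.member_sample_ids) for c in again
            }

    def test_matches_transitive_closure_oracle(self):
        rng = random.Random(99)
        for trial in range(60):
            records = random_genus(rng, rng.randint(2, 10), rng.randint(12, 50))
            got = {
                frozenset(c.member_sample_ids)
                for c in collapse_haplotypes(records, diagnostic_exception=False)
            }
            assert got == components_oracle(records)
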