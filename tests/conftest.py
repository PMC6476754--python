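"""Shared fixtures and builders for the test suite.

All fixtures are generated programmatically; no data files are stored.
"""

from __future__ import annotations

import random
from typing import Dict, List, Tuple

import pytest

from chplex.seqio import AlignedSeqRecord, SampleMeta


def rec(sample_id: str, residues: str, genus: str = "Inga", species: str = "sp1"):
    return AlignedSeqRecord(sample_id, genus, species, residues)


def meta(sample_id: str, genus: str = "Inga", species: str = "sp1",
         dispersal: str = "zoochorous", voucher: bool = True):
    return SampleMeta(sample_id, genus, species, dispersal, voucher)


def mutate_seq(seq: str, positions_and_bases) -> str:
    chars = list(seq)
    for pos, base in positions_and_bases:
        chars[pos] = base
    return "".join(chars)


@pytest.fixture
def toy_sharing_genus():
    """Species A carries haplotype H1; species B carries H1 and H2.

    Built from sequences so the whole stack (collapse -> summaries ->
    sharing) can run on it: H1 and H2 differ by two substitutions.
    """
    base = "ACGTACGTACGTACGTACGT"
    h2 = mutate_seq(base, [(0, "T"), (5, "A")])
    records = [
        rec("a1", base, species="A"),
        rec("a2", base, species="A"),
        rec("b1", base, species="B"),
        rec("b2", h2, species="B"),
    ]
    metadata = [
        meta("a1", species="A"),
        meta("a2", species="A"),
        meta("b1", species="B"),
        meta("b2", species="B"),
    ]
    inventory = {"Inga": 2}
    return records, metadata, inventory


def table1_community() -> Tuple[List[AlignedSeqRecord], List[SampleMeta], Dict[str, int]]:
    """A full synthetic community whose per-stratum included-species counts
    equal the published community's: abiotic group1 0/22 polymorphic, group2
    9/34; biotic group1 11/67, group2 97/323.

    Every species gets its own genus and two individuals; polymorphic
    species carry two haplotypes two substitutions apart; group-2 status
    comes from the inventory recording an unsequenced congener.
    """
    base = "ACGTACGTACGTACGTACGTACGTACGTACGT"
    alt = mutate_seq(base, [(1, "T"), (6, "C")])
    design = [
        # (dispersal, group, n_polymorphic, n_monomorphic)
        ("anemochorous", 1, 0, 22),
        ("anemochorous", 2, 9, 25),
        ("zoochorous", 1, 11, 56),
        ("zoochorous", 2, 97, 226),
    ]
    records, metadata, inventory = [], [], {}
    g = 0
    for dispersal, group, n_poly, n_mono in design:
        for is_poly in (True,) * n_poly + (False,) * n_mono:
            g += 1
            genus, species = f"X{g:03d}", f"X{g:03d}-sp1"
            inventory[genus] = 1 if group == 1 else 2
            seqs = (base, alt) if is_poly else (base, base)
            for k, s in enumerate(seqs, 1):
                sid = f"{genus}-i{k}"
                records.append(AlignedSeqRecord(sid, genus, species, s))
                metadata.append(SampleMeta(sid, genus, species, dispersal, True))
    return records, metadata, inventory


def random_genus(rng: random.Random, n_seqs: int, length: int,
                 n_species: int = 3, genus: str = "Rnd") -> List[AlignedSeqRecord]:
    """Random small genus with substitutions, indels and occasional planted
    inversions relative to a shared ancestral sequence."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    anc = "".join(rng.choice("ACGT") for _ in range(length))
    out = []
    for i in range(n_seqs):
        chars = list(anc)
        for _ in range(rng.randrange(0, 4)):
            kind = rng.random()
            if kind < 0.55:  # substitution
                p = rng.randrange(length)
                chars[p] = rng.choice([b for b in "ACGT" if b != chars[p]])
            elif kind < 0.85:  # short deletion
                p = rng.randrange(length)
                for q in range(p, min(length, p + rng.randrange(1, 4))):
                    chars[q] = "-"
            else:  # planted inversion
                seg = rng.randrange(3, 7)
                p = rng.randrange(0, max(1, length - seg))
                window = chars[p:p + seg]
                if all(c in comp for c in window):
                    chars[p:p + seg] = [comp[c] for c in reversed(window)]
        out.append(
            AlignedSeqRecord(
                f"{genus}-s{i:02d}", genus, f"sp{rng.randrange(n_species) + 1}",
                "".join(chars),
            )
        )
    return out
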