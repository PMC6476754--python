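"""Haplotype collapsing for aligned noncoding cpDNA sequences.

Two aligned sequences are compared by counting *difference units* of three
kinds: substitutions (column-wise base mismatches), indel events (one unit
per maximal contiguous gap-vs-base run, regardless of its length — the
event-based convention standard for chloroplast microstructural variation),
and inversion events (one unit per detected reverse-complement segment,
whose internal columns are then excluded from the substitution count, since
a small inversion is a single mutational event).

Sequences are collapsed into haplotypes under a conservative rule designed
to absorb sequencing error: two sequences belong to the same haplotype when
they differ by at most one unit.  Because that pairwise relation is not
transitive, clusters are formed by single linkage (connected components of
the <=1-unit graph) — the most conservative merger, yielding the fewest
haplotypes.  One exception applies: if, inside a provisional cluster, all
individuals of one species share a single-unit variant state that no
individual of any other species in the cluster carries, that state is
treated as species-diagnostic and the species is split into its own
haplotype.

Columns where either sequence carries a non-{A,C,G,T,-} symbol (IUPAC
ambiguity codes) are excluded from difference counting; columns where both
sequences have ``-`` are ignored.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from .errors import ValidationError
from .seqio import AlignedSeqRecord

__all__ = [
    "DifferenceCount",
    "HaplotypeCluster",
    "COMPLEMENT",
    "detect_inversions",
    "pairwise_difference",
    "sequence_difference",
    "collapse_haplotypes",
]

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class DifferenceCount:
    """Decomposition of the distance between two aligned sequences."""

    substitutions: int
    indel_events: int
    inversion_events: int

    @property
    def total_units(self) -> int:
        return self.substitutions + self.indel_events + self.inversion_events


@dataclass(frozen=True)
class HaplotypeCluster:
    """A genus-scoped haplotype: its members and representative sequence.

    ``representative`` is the residue string of the lexicographically
    smallest member sample id; ``haplotype_id`` (``H1``, ``H2``, ...) is
    assigned per genus in order of descending member count, ties broken by
    smallest member id.
    """

    genus: str
    haplotype_id: str
    member_sample_ids: FrozenSet[str]
    representative: str
    species_set: FrozenSet[str]


def _mismatch_columns(a: str, b: str) -> List[int]:
    return [
        i
        for i, (x, y) in enumerate(zip(a, b))
        if x != y and x in _BASES and y in _BASES
    ]


def detect_inversions(
    a: str,
    b: str,
    min_inversion_len: int = 3,
    max_inversion_len: Optional[int] = None,
) -> List[Tuple[int, int]]:
    """Find putative inversion segments between two aligned sequences.

    Returns non-overlapping, gap-free, unambiguous column intervals
    ``[start, end)`` of length >= *min_inversion_len* where ``b``'s segment
    equals the reverse complement of ``a``'s segment and at least one column
    inside the segment mismatches (the mismatch guard stops identical
    palindromic segments from being flagged).  Selection is greedy
    left-to-right with a longest-first tie-break at each start position.

    *max_inversion_len* optionally caps the segment length considered;
    ``None`` (the default) leaves it unbounded.

    The search exploits a symmetry fact: within a reverse-complement-matching
    window, the mirror of a mismatching column is itself a mismatching
    column, so every admissible window is centred on the midpoint of a pair
    of mismatches.  Candidate centres are therefore enumerated from mismatch
    pairs and each is extended outward incrementally.
    """
    if len(a) != len(b):
        raise ValidationError("sequences must have equal aligned length")
    if min_inversion_len < 2:
        raise ValidationError("min_inversion_len must be >= 2")
    n = len(a)
    a = a.upper()
    b = b.upper()
    mism = _mismatch_columns(a, b)
    if not mism:
        return []
    comp = COMPLEMENT
    cap = max_inversion_len if max_inversion_len is not None else n

    def ok_pair(lo: int, hi: int) -> bool:
        if lo < 0 or hi >= n:
            return False
        ca, cb = a[hi], a[lo]
        if ca not in _BASES or cb not in _BASES:
            return False
        if b[lo] not in _BASES or b[hi] not in _BASES:
            return False
        return b[lo] == comp[ca] and b[hi] == comp[cb]

    # best window length achievable at each start position
    best_at: Dict[int, int] = {}

    def register(center_lo: int, center_hi: int) -> None:
        # window columns are center_lo-r .. center_hi+r for r = 0,1,...
        # (odd windows have center_lo == center_hi)
        r = 0
        r_ok = -1
        while center_hi - center_lo + 1 + 2 * r <= cap:
            lo, hi = center_lo - r, center_hi + r
            if lo == hi:  # single-column core of an odd window
                if not (0 <= lo < n and a[lo] in _BASES and b[lo] in _BASES
                        and b[lo] == comp[a[lo]]):
                    break
            elif not ok_pair(lo, hi):
                break
            r_ok = r
            r += 1
        if r_ok < 0:
            return
        # smallest radius whose window already contains a mismatch
        i = bisect_left(mism, center_lo)
        nearest = None
        for j in (i - 1, i):
            if 0 <= j < len(mism):
                m = mism[j]
                d = max(center_lo - m, m - center_hi, 0)
                nearest = d if nearest is None else min(nearest, d)
        if nearest is None or nearest > r_ok:
            return
        core = center_hi - center_lo + 1
        r_min = max(nearest, -(-(min_inversion_len - core) // 2))
        for r in range(max(r_min, 0), r_ok + 1):
            s, length = center_lo - r, core + 2 * r
            if length >= min_inversion_len and length > best_at.get(s, 0):
                best_at[s] = length

    seen_centers = set()
    for i, m1 in enumerate(mism):
        for m2 in mism[i:]:
            if m2 - m1 + 1 > cap:
                break
            tot = m1 + m2
            center = (tot // 2, tot // 2) if tot % 2 == 0 else (tot // 2, tot // 2 + 1)
            if center not in seen_centers:
                seen_centers.add(center)
                register(*center)

    intervals: List[Tuple[int, int]] = []
    s = 0
    starts = sorted(best_at)
    si = 0
    while si < len(starts):
        st = starts[si]
        if st < s:
            si += 1
            continue
        # longest-first at this start
        intervals.append((st, st + best_at[st]))
        s = st + best_at[st]
        si += 1
    return intervals


def sequence_difference(
    a: str,
    b: str,
    min_inversion_len: int = 3,
    indel_mode: str = "event",
    max_inversion_len: Optional[int] = None,
) -> DifferenceCount:
    """Difference units between two aligned residue strings.

    ``indel_mode='event'`` counts one unit per maximal gap-vs-base run (the
    default); ``'site'`` counts every gapped column as one unit.
    """
    if len(a) != len(b):
        raise ValidationError("sequences must have equal aligned length")
    if indel_mode not in {"event", "site"}:
        raise ValidationError(f"unknown indel_mode {indel_mode!r}")
    a = a.upper()
    b = b.upper()
    inversions = detect_inversions(a, b, min_inversion_len, max_inversion_len)
    inverted = set()
    for s, e in inversions:
        inverted.update(range(s, e))

    substitutions = 0
    indel_events = 0
    indel_sites = 0
    run_side = 0  # 0 none, 1 gap in a, 2 gap in b
    for i, (x, y) in enumerate(zip(a, b)):
        gx, gy = x == "-", y == "-"
        if gx and gy:
            side = 0
        elif gx or gy:
            base = y if gx else x
            if base not in _BASES:
                # ambiguity code opposite a gap: excluded from counting,
                # and it interrupts any ongoing indel run
                side = 0
            else:
                side = 1 if gx else 2
                indel_sites += 1
                if side != run_side:
                    indel_events += 1
        else:
            side = 0
            if x in _BASES and y in _BASES and x != y and i not in inverted:
                substitutions += 1
        run_side = side

    indels = indel_events if indel_mode == "event" else indel_sites
    return DifferenceCount(
        substitutions=substitutions,
        indel_events=indels,
        inversion_events=len(inversions),
    )


def pairwise_difference(
    a: AlignedSeqRecord,
    b: AlignedSeqRecord,
    min_inversion_len: int = 3,
    indel_mode: str = "event",
    max_inversion_len: Optional[int] = None,
) -> DifferenceCount:
    """Difference units between two records of the same genus."""
    if a.genus != b.genus:
        raise ValidationError(
            f"cannot compare records of different genera ({a.genus!r} vs {b.genus!r})"
        )
    if len(a.residues) != len(b.residues):
        raise ValidationError(
            f"records {a.sample_id!r} and {b.sample_id!r} have unequal aligned lengths"
        )
    return sequence_difference(
        a.residues, b.residues, min_inversion_len, indel_mode, max_inversion_len
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


def _diagnostic_units(cols: List[int], states: Dict[int, str]) -> int:
    """Count diagnostic units among diagnostic columns.

    Consecutive diagnostic columns at which the focal species' shared state
    is ``-`` throughout are merged into one unit (a species-diagnostic gap
    run is one indel event); all other columns count individually.
    """
    units = 0
    prev = None
    for c in sorted(cols):
        if (
            prev is not None
            and c == prev + 1
            and states[c] == "-"
            and states[prev] == "-"
        ):
            prev = c
            continue
        units += 1
        prev = c
    return units


def collapse_haplotypes(
    records: Sequence[AlignedSeqRecord],
    min_inversion_len: int = 3,
    indel_mode: str = "event",
    max_inversion_len: Optional[int] = None,
    diagnostic_exception: bool = True,
) -> List[HaplotypeCluster]:
    """Collapse one genus' aligned records into haplotype clusters.

    Steps: (1) connect records differing by <=1 unit; (2) provisional
    clusters are the connected components (single linkage); (3) apply the
    species-diagnostic exception within each provisional cluster; (4) assign
    genus-scoped ids ``H1..Hk`` ordered by descending member count, then by
    smallest member sample id.  Setting ``diagnostic_exception=False`` stops
    after step (2), which is useful for cross-checking against a plain
    transitive-closure oracle.
    """
    if not records:
        raise ValidationError("collapse_haplotypes requires at least one record")
    genera = {r.genus for r in records}
    if len(genera) != 1:
        raise ValidationError(f"records span multiple genera: {sorted(genera)}")
    genus = next(iter(genera))
    lengths = {len(r.residues) for r in records}
    if len(lengths) != 1:
        raise ValidationError(f"genus {genus!r}: records have unequal aligned lengths")

    ordered = sorted(records, key=lambda r: r.sample_id)

    # deduplicate identical sequences: identical residues are trivially the
    # same haplotype, and this keeps the pairwise stage quadratic in the
    # number of *distinct* sequences only
    seq_to_idx: Dict[str, int] = {}
    uniq: List[str] = []
    rec_of_uniq: List[List[AlignedSeqRecord]] = []
    for r in ordered:
        j = seq_to_idx.get(r.residues)
        if j is None:
            seq_to_idx[r.residues] = len(uniq)
            uniq.append(r.residues)
            rec_of_uniq.append([r])
        else:
            rec_of_uniq[j].append(r)

    uf = _UnionFind(len(uniq))
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            if uf.find(i) == uf.find(j):
                continue
            d = sequence_difference(
                uniq[i], uniq[j], min_inversion_len, indel_mode, max_inversion_len
            )
            if d.total_units <= 1:
                uf.union(i, j)

    components: Dict[int, List[AlignedSeqRecord]] = {}
    for j in range(len(uniq)):
        components.setdefault(uf.find(j), []).extend(rec_of_uniq[j])

    provisional = [sorted(v, key=lambda r: r.sample_id) for _, v in sorted(components.items())]

    final_groups: List[List[AlignedSeqRecord]] = []
    for group in provisional:
        if diagnostic_exception:
            final_groups.extend(_apply_diagnostic_exception(group))
        else:
            final_groups.append(group)

    final_groups.sort(key=lambda g: (-len(g), g[0].sample_id))
    clusters = []
    for idx, g in enumerate(final_groups, start=1):
        rep = min(g, key=lambda r: r.sample_id)
        clusters.append(
            HaplotypeCluster(
                genus=genus,
                haplotype_id=f"H{idx}",
                member_sample_ids=frozenset(r.sample_id for r in g),
                representative=rep.residues,
                species_set=frozenset(r.species for r in g),
            )
        )
    return clusters


def _apply_diagnostic_exception(
    group: List[AlignedSeqRecord],
) -> List[List[AlignedSeqRecord]]:
    """Split out species fixed for a single-unit diagnostic state.

    A species splits when all of its records share one state (a base or a
    gap run) at exactly one difference unit and no record of another species
    in the cluster carries that state.
    """
    species = sorted({r.species for r in group})
    if len(species) < 2:
        return [group]
    ncols = len(group[0].residues)
    split_off: List[List[AlignedSeqRecord]] = []
    remaining: List[AlignedSeqRecord] = []
    for sp in species:
        mine = [r for r in group if r.species == sp]
        others = [r for r in group if r.species != sp]
        diag_cols: List[int] = []
        states: Dict[int, str] = {}
        for c in range(ncols):
            mine_states = {r.residues[c] for r in mine}
            if len(mine_states) != 1:
                continue
            st = next(iter(mine_states))
            if any(r.residues[c] == st for r in others):
                continue
            diag_cols.append(c)
            states[c] = st
        if diag_cols and _diagnostic_units(diag_cols, states) == 1:
            split_off.append(mine)
        else:
            remaining.extend(mine)
    if not split_off:
        return [group]
    out = split_off
    if remaining:
        out = out + [sorted(remaining, key=lambda r: r.sample_id)]
    return [sorted(g, key=lambda r: r.sample_id) for g in out]
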