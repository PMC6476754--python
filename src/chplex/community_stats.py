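"""Species- and genus-level summaries of community cpDNA variation.

This module turns haplotype clusters plus sample metadata into the
quantities every downstream test consumes:

* a per-species polymorphism call (a species is *polymorphic* when its
  sampled individuals fall into at least two haplotypes; species with a
  single sequenced individual are flagged *excluded* and never enter
  polymorphism rates);
* a congener grouping — *group 1* species belong to genera with exactly one
  species recorded at the study site, *group 2* species have at least one
  congener at the site (classification uses the full site inventory, not the
  sequenced subset);
* a dispersal dichotomy — autochorous/anemochorous/hydrochorous syndromes
  are *abiotic*, zoochorous and mixed are *biotic*;
* shared/private haplotype accounting over (species, haplotype) incidences,
  restricted to genera with at least two analyzed species, and per-genus
  species-pair sharing counts.

Note the two genus filters are deliberately distinct: group membership is a
property of the *site* (inventory counts), while the sharing universe is a
property of the *analysis* (number of species actually analyzed).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .haplotyping import HaplotypeCluster
from .seqio import DISPERSAL_VOCAB, SampleMeta

__all__ = [
    "SpeciesSummary",
    "Incidence",
    "GenusPairs",
    "SharingSummary",
    "classify_dispersal",
    "classify_group",
    "summarize_species",
    "polymorphism_contingency",
    "sharing_incidences",
    "sharing_by_polymorphism",
    "review_report",
]

_ABIOTIC = frozenset({"autochorous", "anemochorous", "hydrochorous"})


@dataclass(frozen=True)
class SpeciesSummary:
    """Polymorphism call and strata for one sequenced species.

    ``polymorphic`` is ``None`` for excluded (single-individual) species.
    """

    genus: str
    species: str
    n_individuals: int
    n_haplotypes: int
    excluded: bool
    polymorphic: Optional[bool]
    group: int
    dispersal_class: str


@dataclass(frozen=True)
class Incidence:
    """One (species, haplotype) occurrence in the sharing universe."""

    genus: str
    species: str
    haplotype_id: str
    shared: bool


@dataclass(frozen=True)
class GenusPairs:
    """Species-pair sharing counts for one genus in the sharing universe."""

    genus: str
    n_species_analyzed: int
    n_pairs: int
    n_pairs_sharing: int


@dataclass(frozen=True)
class SharingSummary:
    incidences: Tuple[Incidence, ...]
    genus_pairs: Tuple[GenusPairs, ...]

    @property
    def n_shared(self) -> int:
        return sum(1 for i in self.incidences if i.shared)

    @property
    def n_private(self) -> int:
        return sum(1 for i in self.incidences if not i.shared)


def classify_dispersal(dispersal_raw: str) -> str:
    """Collapse the five raw syndromes into abiotic vs biotic.

    Mixed-strategy species go to the biotic class, so *abiotic* means a
    purely abiotic seed-dispersal strategy.
    """
    if dispersal_raw not in DISPERSAL_VOCAB:
        raise ValidationError(f"unknown dispersal syndrome {dispersal_raw!r}")
    return "abiotic" if dispersal_raw in _ABIOTIC else "biotic"


def classify_group(genus: str, inventory: Mapping[str, int]) -> int:
    """Group 1 if the genus has a single species recorded at the site, else 2."""
    if genus not in inventory:
        raise ValidationError(f"genus {genus!r} absent from site inventory")
    return 1 if inventory[genus] == 1 else 2


def summarize_species(
    clusters: Sequence[HaplotypeCluster],
    metadata: Sequence[SampleMeta],
    inventory: Mapping[str, int],
) -> List[SpeciesSummary]:
    """One summary row per sequenced species (excluded species are flagged,
    not dropped)."""
    meta_by_id = {m.sample_id: m for m in metadata}
    individuals: Dict[Tuple[str, str], int] = {}
    haplos: Dict[Tuple[str, str], set] = {}
    dispersal: Dict[Tuple[str, str], str] = {}
    for m in metadata:
        key = (m.genus, m.species)
        individuals[key] = individuals.get(key, 0) + 0  # ensure key exists
        dispersal[key] = m.dispersal_raw
    for c in clusters:
        for sid in c.member_sample_ids:
            m = meta_by_id.get(sid)
            if m is None:
                raise ValidationError(
                    f"sample {sid!r} appears in clusters but not in metadata"
                )
            key = (m.genus, m.species)
            individuals[key] = individuals.get(key, 0) + 1
            haplos.setdefault(key, set()).add((c.genus, c.haplotype_id))

    out: List[SpeciesSummary] = []
    for (genus, species) in sorted(individuals):
        n_ind = individuals[(genus, species)]
        if n_ind == 0:
            raise ValidationError(
                f"species {genus} {species}: in metadata but no sequenced sample "
                "is covered by the clusters"
            )
        n_hap = len(haplos[(genus, species)])
        excluded = n_ind == 1
        out.append(
            SpeciesSummary(
                genus=genus,
                species=species,
                n_individuals=n_ind,
                n_haplotypes=n_hap,
                excluded=excluded,
                polymorphic=None if excluded else n_hap >= 2,
                group=classify_group(genus, inventory),
                dispersal_class=classify_dispersal(dispersal[(genus, species)]),
            )
        )
    return out


def polymorphism_contingency(
    summaries: Sequence[SpeciesSummary], stratum: str = "all"
) -> np.ndarray:
    """2x2 table of included species: rows group1/group2, columns
    polymorphic/monomorphic, within one dispersal stratum (or ``all``)."""
    if stratum not in {"abiotic", "biotic", "all"}:
        raise ValidationError(f"unknown stratum {stratum!r}")
    table = np.zeros((2, 2), dtype=int)
    for s in summaries:
        if s.excluded:
            continue
        if stratum != "all" and s.dispersal_class != stratum:
            continue
        table[s.group - 1, 0 if s.polymorphic else 1] += 1
    if table.sum() == 0:
        raise ValidationError(f"no included species in stratum {stratum!r}")
    return table


def sharing_incidences(
    clusters: Sequence[HaplotypeCluster],
    summaries: Sequence[SpeciesSummary],
    include_singleton_species: bool = True,
) -> SharingSummary:
    """Shared/private accounting over (species, haplotype) incidences.

    The universe is restricted to genera with at least two analyzed species.
    An incidence is *shared* when the haplotype occurs in at least one other
    congeneric species.  Single-individual (excluded) species are genuine
    occurrences of their haplotypes, so by default they count as analyzed
    species for the pair universe and toward each haplotype's species set —
    but they never contribute incidence rows themselves, because an
    incidence is classified downstream by its species' polymorphism status,
    which is undefined for them.  Set ``include_singleton_species=False`` to
    drop them from the sharing universe entirely.

    A species pair of a genus counts as *sharing* when some haplotype
    contains both species.
    """
    by_genus: Dict[str, List[SpeciesSummary]] = {}
    for s in summaries:
        if include_singleton_species or not s.excluded:
            by_genus.setdefault(s.genus, []).append(s)
    universe = {g: spp for g, spp in by_genus.items() if len(spp) >= 2}
    excluded_species = {(s.genus, s.species) for s in summaries if s.excluded}

    cluster_species: Dict[Tuple[str, str], set] = {}
    species_haplos: Dict[Tuple[str, str], List[str]] = {}
    for c in clusters:
        spp = set(c.species_set)
        if not include_singleton_species:
            spp = {sp for sp in spp if (c.genus, sp) not in excluded_species}
        cluster_species[(c.genus, c.haplotype_id)] = spp
        for sp in spp:
            species_haplos.setdefault((c.genus, sp), []).append(c.haplotype_id)

    incidences: List[Incidence] = []
    genus_rows: List[GenusPairs] = []
    for genus in sorted(universe):
        spp = sorted(universe[genus], key=lambda s: s.species)
        for s in spp:
            if s.excluded:
                continue
            for hid in sorted(species_haplos.get((genus, s.species), [])):
                others = cluster_species[(genus, hid)] - {s.species}
                incidences.append(
                    Incidence(genus, s.species, hid, shared=bool(others))
                )
        k = len(spp)
        sharing_pairs = 0
        for s1, s2 in combinations(spp, 2):
            h1 = set(species_haplos.get((genus, s1.species), []))
            h2 = set(species_haplos.get((genus, s2.species), []))
            if h1 & h2:
                sharing_pairs += 1
        genus_rows.append(GenusPairs(genus, k, comb(k, 2), sharing_pairs))
    return SharingSummary(tuple(incidences), tuple(genus_rows))


def sharing_by_polymorphism(
    summaries: Sequence[SpeciesSummary], sharing: SharingSummary
) -> np.ndarray:
    """2x2 incidence table: rows polymorphic/monomorphic species, columns
    shared/private."""
    poly = {
        (s.genus, s.species): s.polymorphic
        for s in summaries
        if not s.excluded
    }
    table = np.zeros((2, 2), dtype=int)
    for inc in sharing.incidences:
        is_poly = poly.get((inc.genus, inc.species))
        if is_poly is None:
            continue
        table[0 if is_poly else 1, 0 if inc.shared else 1] += 1
    return table


def review_report(
    clusters: Sequence[HaplotypeCluster],
    metadata: Sequence[SampleMeta],
) -> List[Dict[str, str]]:
    """Advisory list of samples whose haplotype is shared across species.

    These are exactly the individuals whose sequences and botanical
    identifications deserve manual rechecking, since a cross-species shared
    haplotype can reflect either genuine sharing or a misidentified voucher.
    Rows are ordered by (genus, haplotype_id, sample_id).
    """
    meta_by_id = {m.sample_id: m for m in metadata}
    rows: List[Dict[str, str]] = []
    for c in clusters:
        if len(c.species_set) < 2:
            continue
        for sid in sorted(c.member_sample_ids):
            m = meta_by_id.get(sid)
            species = m.species if m is not None else ""
            others = sorted(c.species_set - {species})
            rows.append(
                {
                    "genus": c.genus,
                    "haplotype_id": c.haplotype_id,
                    "sample_id": sid,
                    "species": species,
                    "shared_with": ",".join(others),
                }
            )
    rows.sort(key=lambda r: (r["genus"], r["haplotype_id"], r["sample_id"]))
    return rows
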