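"""Input/output for aligned chloroplast sequences and community tables.

The pipeline consumes three plain-text inputs:

* per-genus aligned FASTA files, gap character ``-``, with headers of the form
  ``sample_id|genus|species`` (fields joined by ``|``);
* a sample metadata TSV (``sample_id  genus  species  dispersal  voucher``);
* a site inventory TSV (``genus  species_count``) listing how many species of
  each genus are recorded at the study site — including species that were
  never sequenced, since congener status is a property of the site, not of
  the sample.

Sequences are required to be pre-aligned *within* each genus only; the
pipeline never compares residues across genera (chloroplast haplotypes are
genus-scoped throughout).  All text I/O is UTF-8 TSV without quoting, so
outputs are reproducible byte-for-byte.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from Bio import SeqIO

from .errors import ParseError, ValidationError

__all__ = [
    "AlignedSeqRecord",
    "SampleMeta",
    "DISPERSAL_VOCAB",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "read_metadata",
    "write_metadata",
    "read_inventory",
    "write_inventory",
    "write_haplotype_table",
    "read_haplotype_table",
    "cross_validate",
]

#: Closed vocabulary of raw seed-dispersal syndromes.
DISPERSAL_VOCAB = frozenset(
    {"autochorous", "anemochorous", "hydrochorous", "zoochorous", "mixed"}
)

# IUPAC nucleotide codes accepted on input (plus the alignment gap).
_IUPAC = frozenset("ACGTRYSWKMBDHVN-")

_HEADER_DELIM = "|"


@dataclass(frozen=True)
class AlignedSeqRecord:
    """One sample's aligned cpDNA sequence with its taxonomic identity.

    ``residues`` is an uppercase string over A/C/G/T, IUPAC ambiguity codes
    and ``-``; all records of one genus share the same (aligned) length.
    """

    sample_id: str
    genus: str
    species: str
    residues: str


@dataclass(frozen=True)
class SampleMeta:
    """Metadata row for one sampled individual."""

    sample_id: str
    genus: str
    species: str
    dispersal_raw: str
    voucher: bool


def _validate_residues(sample_id: str, residues: str) -> str:
    if not residues:
        raise ValidationError(f"record {sample_id!r}: empty sequence")
    up = residues.upper()
    for pos, ch in enumerate(up):
        if ch not in _IUPAC:
            raise ValidationError(
                f"record {sample_id!r}: illegal character {ch!r} at position {pos}"
            )
    return up


def read_alignment_fasta(path, genus: Optional[str] = None) -> List[AlignedSeqRecord]:
    """Read one aligned FASTA file into :class:`AlignedSeqRecord` objects.

    Headers must be ``sample_id|genus|species``.  If *genus* is given, every
    record must belong to it.  Residues are upper-cased; within each genus the
    equal-length (alignment) invariant is enforced, and an error lists every
    offending record id.
    """
    path = Path(path)
    records: List[AlignedSeqRecord] = []
    seen: set = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split(_HEADER_DELIM)
        if len(parts) != 3 or not all(p.strip() for p in parts):
            raise ParseError(
                f"{path}: malformed FASTA header {rec.description!r} "
                f"(expected sample_id{_HEADER_DELIM}genus{_HEADER_DELIM}species)"
            )
        sample_id, rec_genus, species = (p.strip() for p in parts)
        if genus is not None and rec_genus != genus:
            raise ValidationError(
                f"{path}: record {sample_id!r} has genus {rec_genus!r}, expected {genus!r}"
            )
        if sample_id in seen:
            raise ValidationError(f"{path}: duplicate sample_id {sample_id!r}")
        seen.add(sample_id)
        residues = _validate_residues(sample_id, str(rec.seq))
        records.append(AlignedSeqRecord(sample_id, rec_genus, species, residues))
    _check_genus_lengths(records, source=str(path))
    return records


def _check_genus_lengths(records: Iterable[AlignedSeqRecord], source: str = "") -> None:
    by_genus: Dict[str, Dict[int, List[str]]] = {}
    for r in records:
        by_genus.setdefault(r.genus, {}).setdefault(len(r.residues), []).append(
            r.sample_id
        )
    for genus, lengths in by_genus.items():
        if len(lengths) > 1:
            detail = "; ".join(
                f"length {ln}: {', '.join(sorted(ids))}" for ln, ids in sorted(lengths.items())
            )
            prefix = f"{source}: " if source else ""
            raise ValidationError(
                f"{prefix}unequal aligned lengths within genus {genus!r} ({detail})"
            )


def write_alignment_fasta(records: Sequence[AlignedSeqRecord], path) -> None:
    """Write records as aligned FASTA with ``sample_id|genus|species`` headers."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for r in records:
            fh.write(f">{r.sample_id}{_HEADER_DELIM}{r.genus}{_HEADER_DELIM}{r.species}\n")
            fh.write(r.residues + "\n")


def read_metadata(path) -> List[SampleMeta]:
    """Read the sample metadata TSV; enforces the dispersal vocabulary and
    sample-id uniqueness."""
    path = Path(path)
    out: List[SampleMeta] = []
    seen: set = set()
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "genus", "species", "dispersal", "voucher"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(f"{path}: metadata header must contain {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            sid = row["sample_id"].strip()
            if not sid:
                raise ParseError(f"{path}: row {i}: empty sample_id")
            if sid in seen:
                raise ValidationError(f"{path}: row {i}: duplicate sample_id {sid!r}")
            seen.add(sid)
            disp = row["dispersal"].strip()
            if disp not in DISPERSAL_VOCAB:
                raise ValidationError(
                    f"{path}: row {i} (sample {sid!r}): unknown dispersal value {disp!r}"
                )
            voucher_raw = row["voucher"].strip().lower()
            if voucher_raw not in {"true", "false", "1", "0"}:
                raise ParseError(
                    f"{path}: row {i} (sample {sid!r}): voucher must be boolean, got "
                    f"{row['voucher']!r}"
                )
            out.append(
                SampleMeta(
                    sample_id=sid,
                    genus=row["genus"].strip(),
                    species=row["species"].strip(),
                    dispersal_raw=disp,
                    voucher=voucher_raw in {"true", "1"},
                )
            )
    return out


def write_metadata(metadata: Sequence[SampleMeta], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tgenus\tspecies\tdispersal\tvoucher\n")
        for m in metadata:
            fh.write(
                f"{m.sample_id}\t{m.genus}\t{m.species}\t{m.dispersal_raw}\t"
                f"{'true' if m.voucher else 'false'}\n"
            )


def read_inventory(path) -> Dict[str, int]:
    """Read the site inventory TSV mapping genus -> species count at the site."""
    path = Path(path)
    inv: Dict[str, int] = {}
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"genus", "species_count"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(f"{path}: inventory header must contain {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            genus = row["genus"].strip()
            try:
                count = int(row["species_count"])
            except ValueError:
                raise ParseError(
                    f"{path}: row {i} (genus {genus!r}): species_count "
                    f"{row['species_count']!r} is not an integer"
                ) from None
            if count <= 0:
                raise ValidationError(
                    f"{path}: row {i} (genus {genus!r}): species_count must be positive, "
                    f"got {count}"
                )
            if genus in inv:
                raise ValidationError(f"{path}: duplicate genus {genus!r}")
            inv[genus] = count
    return inv


def write_inventory(inventory: Mapping[str, int], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("genus\tspecies_count\n")
        for genus in sorted(inventory):
            fh.write(f"{genus}\t{inventory[genus]}\n")


def cross_validate(
    records: Sequence[AlignedSeqRecord],
    metadata: Sequence[SampleMeta],
    inventory: Mapping[str, int],
) -> None:
    """Joint consistency of the three inputs.

    Checks: every sequenced sample has a metadata row and vice versa (with
    matching genus/species); every genus in the metadata appears in the
    inventory with a count at least the number of distinct sampled species.
    """
    meta_by_id = {m.sample_id: m for m in metadata}
    rec_ids = {r.sample_id for r in records}
    missing_meta = sorted(rec_ids - meta_by_id.keys())
    if missing_meta:
        raise ValidationError(f"samples missing from metadata: {', '.join(missing_meta)}")
    missing_seq = sorted(meta_by_id.keys() - rec_ids)
    if missing_seq:
        raise ValidationError(
            f"metadata samples missing from alignments: {', '.join(missing_seq)}"
        )
    for r in records:
        m = meta_by_id[r.sample_id]
        if (m.genus, m.species) != (r.genus, r.species):
            raise ValidationError(
                f"sample {r.sample_id!r}: FASTA says {r.genus} {r.species}, "
                f"metadata says {m.genus} {m.species}"
            )
    species_per_genus: Dict[str, set] = {}
    for m in metadata:
        species_per_genus.setdefault(m.genus, set()).add(m.species)
    for genus, spp in sorted(species_per_genus.items()):
        if genus not in inventory:
            raise ValidationError(f"genus {genus!r} absent from site inventory")
        if inventory[genus] < len(spp):
            raise ValidationError(
                f"genus {genus!r}: inventory count {inventory[genus]} is below the "
                f"{len(spp)} distinct sampled species"
            )


def write_haplotype_table(clusters, path) -> None:
    """Write haplotype clusters as TSV.

    Columns: genus, haplotype_id, n_members, member_sample_ids (comma-joined,
    sorted), representative.  Haplotype ids are genus-scoped (``H1`` restarts
    for every genus), so the designation is consistent within each genus.
    """
    if not clusters:
        raise ValidationError("cannot write an empty cluster list")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("genus\thaplotype_id\tn_members\tmember_sample_ids\trepresentative\n")
        for c in clusters:
            members = ",".join(sorted(c.member_sample_ids))
            fh.write(
                f"{c.genus}\t{c.haplotype_id}\t{len(c.member_sample_ids)}\t"
                f"{members}\t{c.representative}\n"
            )


def read_haplotype_table(path):
    """Read a haplotype TSV back into :class:`~chplex.haplotyping.HaplotypeCluster`
    objects (species sets are not stored in the table and are left empty)."""
    from .haplotyping import HaplotypeCluster

    path = Path(path)
    out = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=2):
            members = frozenset(row["member_sample_ids"].split(","))
            n = int(row["n_members"])
            if n != len(members):
                raise ValidationError(
                    f"{path}: row {i}: n_members={n} but {len(members)} member ids"
                )
            out.append(
                HaplotypeCluster(
                    genus=row["genus"],
                    haplotype_id=row["haplotype_id"],
                    member_sample_ids=members,
                    representative=row["representative"],
                    species_set=frozenset(),
                )
            )
    return out
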