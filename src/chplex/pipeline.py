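"""End-to-end wiring of the analysis stages.

:func:`analyze_community` runs haplotype collapsing, species summaries,
contingency tables, sharing accounting and both binomial scans on in-memory
inputs and returns all results in one object.  :func:`run_all` is the
file-level entry point behind the command line: it reads (or simulates) the
inputs, analyzes them, and writes every report plus a run manifest with
input checksums.  Data go to files only and logging goes to standard error
only, so outputs are byte-reproducible across reruns.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from . import __version__
from .community_stats import (
    SharingSummary,
    SpeciesSummary,
    polymorphism_contingency,
    review_report,
    sharing_by_polymorphism,
    sharing_incidences,
    summarize_species,
)
from .errors import ChplexError, ValidationError
from .exact_tests import (
    BinomialScanRow,
    ContingencyResult,
    fisher_two_sided,
    genus_pair_sharing_scan,
    genus_polymorphism_scan,
)
from .haplotyping import HaplotypeCluster, collapse_haplotypes
from .seqio import (
    AlignedSeqRecord,
    SampleMeta,
    cross_validate,
    read_alignment_fasta,
    read_inventory,
    read_metadata,
    write_haplotype_table,
)

__all__ = ["AnalysisResult", "analyze_community", "run_all", "RunPaths"]


@dataclass
class AnalysisResult:
    clusters: List[HaplotypeCluster]
    summaries: List[SpeciesSummary]
    contingency_all: np.ndarray
    fisher_all: ContingencyResult
    contingency_by_stratum: Dict[str, np.ndarray]
    fisher_by_stratum: Dict[str, ContingencyResult]
    sharing: SharingSummary
    sharing_by_polymorphism: np.ndarray
    fisher_sharing: ContingencyResult
    polymorphism_scan: List[BinomialScanRow]
    pair_sharing_scan: List[BinomialScanRow]


def analyze_community(
    records: Sequence[AlignedSeqRecord],
    metadata: Sequence[SampleMeta],
    inventory: Mapping[str, int],
    min_inversion_len: int = 3,
    indel_mode: str = "event",
    min_species_for_scan: int = 8,
) -> AnalysisResult:
    """Run every analysis stage on in-memory inputs."""
    cross_validate(records, metadata, inventory)
    by_genus: Dict[str, List[AlignedSeqRecord]] = {}
    for r in records:
        by_genus.setdefault(r.genus, []).append(r)
    clusters: List[HaplotypeCluster] = []
    for genus in sorted(by_genus):
        clusters.extend(
            collapse_haplotypes(
                by_genus[genus],
                min_inversion_len=min_inversion_len,
                indel_mode=indel_mode,
            )
        )
    summaries = summarize_species(clusters, metadata, inventory)

    contingency_by_stratum: Dict[str, np.ndarray] = {}
    fisher_by_stratum: Dict[str, ContingencyResult] = {}
    for stratum in ("abiotic", "biotic"):
        try:
            tab = polymorphism_contingency(summaries, stratum)
        except ValidationError:
            continue  # stratum can be empty in small simulated communities
        contingency_by_stratum[stratum] = tab
        fisher_by_stratum[stratum] = fisher_two_sided(tab)
    contingency_all = polymorphism_contingency(summaries, "all")
    fisher_all = fisher_two_sided(contingency_all)

    sharing = sharing_incidences(clusters, summaries)
    shr_tab = sharing_by_polymorphism(summaries, sharing)
    fisher_sharing = fisher_two_sided(shr_tab)

    try:
        poly_scan = genus_polymorphism_scan(summaries, min_species_for_scan)
    except ValidationError:
        poly_scan = []
    try:
        pair_scan = genus_pair_sharing_scan(sharing, min_species_for_scan)
    except ValidationError:
        pair_scan = []

    return AnalysisResult(
        clusters=clusters,
        summaries=summaries,
        contingency_all=contingency_all,
        fisher_all=fisher_all,
        contingency_by_stratum=contingency_by_stratum,
        fisher_by_stratum=fisher_by_stratum,
        sharing=sharing,
        sharing_by_polymorphism=shr_tab,
        fisher_sharing=fisher_sharing,
        polymorphism_scan=poly_scan,
        pair_sharing_scan=pair_scan,
    )


@dataclass
class RunPaths:
    out_dir: Path
    files: Dict[str, Path] = field(default_factory=dict)


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _fmt_p(p: float, decimals: int) -> str:
    return f"{p:.{decimals}g}" if p < 10 ** (-decimals) else f"{round(p, decimals)}"


def run_all(
    out_dir,
    fasta_paths: Optional[Sequence] = None,
    metadata_path=None,
    inventory_path=None,
    records: Optional[Sequence[AlignedSeqRecord]] = None,
    metadata: Optional[Sequence[SampleMeta]] = None,
    inventory: Optional[Mapping[str, int]] = None,
    min_inversion_len: int = 3,
    indel_mode: str = "event",
    min_species_for_scan: int = 8,
    decimals: int = 3,
) -> RunPaths:
    """Read inputs (or use the in-memory ones), analyze, and write reports.

    Outputs: haplotypes.tsv, species_summary.tsv, contingency_report.tsv,
    polymorphism_scan.tsv, pair_sharing_scan.tsv, sharing_incidences.tsv,
    genus_pairs.tsv, review_report.tsv and manifest.json.  p-values are
    rounded only in the written reports; internal values keep full
    precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    input_checksums: Dict[str, str] = {}

    if records is None:
        if not fasta_paths or metadata_path is None or inventory_path is None:
            raise ValidationError(
                "run_all needs either in-memory inputs or fasta_paths + "
                "metadata_path + inventory_path"
            )
        records = []
        for p in sorted(Path(x) for x in fasta_paths):
            recs = read_alignment_fasta(p)
            _log(f"[seqio] {p}: {len(recs)} records")
            records.extend(recs)
            input_checksums[str(p)] = _sha256(p)
        metadata = read_metadata(metadata_path)
        inventory = read_inventory(inventory_path)
        input_checksums[str(metadata_path)] = _sha256(Path(metadata_path))
        input_checksums[str(inventory_path)] = _sha256(Path(inventory_path))
    assert metadata is not None and inventory is not None

    _log(
        f"[pipeline] {len(records)} sequences, {len(metadata)} metadata rows, "
        f"{len(inventory)} genera in inventory"
    )
    res = analyze_community(
        records,
        metadata,
        inventory,
        min_inversion_len=min_inversion_len,
        indel_mode=indel_mode,
        min_species_for_scan=min_species_for_scan,
    )
    _log(
        f"[haplotyping] {len(res.clusters)} haplotypes across "
        f"{len({c.genus for c in res.clusters})} genera"
    )

    paths = RunPaths(out)

    paths.files["haplotypes"] = out / "haplotypes.tsv"
    write_haplotype_table(res.clusters, paths.files["haplotypes"])

    paths.files["species_summary"] = out / "species_summary.tsv"
    with paths.files["species_summary"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "genus\tspecies\tn_individuals\tn_haplotypes\texcluded\t"
            "polymorphic\tgroup\tdispersal_class\n"
        )
        for s in res.summaries:
            poly = "" if s.polymorphic is None else str(s.polymorphic).lower()
            fh.write(
                f"{s.genus}\t{s.species}\t{s.n_individuals}\t{s.n_haplotypes}\t"
                f"{str(s.excluded).lower()}\t{poly}\t{s.group}\t{s.dispersal_class}\n"
            )

    paths.files["contingency"] = out / "contingency_report.tsv"
    with paths.files["contingency"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "comparison\tstratum\tgroup1_polymorphic\tgroup1_monomorphic\t"
            "group2_polymorphic\tgroup2_monomorphic\tp_value\n"
        )
        items = list(res.contingency_by_stratum.items()) + [("all", res.contingency_all)]
        for stratum, tab in items:
            p = (
                res.fisher_by_stratum[stratum].p_two_sided
                if stratum in res.fisher_by_stratum
                else res.fisher_all.p_two_sided
            )
            fh.write(
                f"polymorphism_by_group\t{stratum}\t{tab[0,0]}\t{tab[0,1]}\t"
                f"{tab[1,0]}\t{tab[1,1]}\t{_fmt_p(p, decimals)}\n"
            )
        shr = res.sharing_by_polymorphism
        fh.write(
            f"sharing_by_polymorphism\tall\t{shr[0,0]}\t{shr[0,1]}\t"
            f"{shr[1,0]}\t{shr[1,1]}\t{_fmt_p(res.fisher_sharing.p_two_sided, decimals)}\n"
        )

    for name, scan in (
        ("polymorphism_scan", res.polymorphism_scan),
        ("pair_sharing_scan", res.pair_sharing_scan),
    ):
        paths.files[name] = out / f"{name}.tsv"
        with paths.files[name].open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("genus\tn\tk\tp0\tp_minus\tp_plus\n")
            for row in scan:
                fh.write(
                    f"{row.genus}\t{row.n}\t{row.k}\t{row.p0:.6g}\t"
                    f"{_fmt_p(row.p_minus, decimals)}\t{_fmt_p(row.p_plus, decimals)}\n"
                )

    paths.files["sharing_incidences"] = out / "sharing_incidences.tsv"
    with paths.files["sharing_incidences"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("genus\tspecies\thaplotype_id\tshared\n")
        for inc in res.sharing.incidences:
            fh.write(
                f"{inc.genus}\t{inc.species}\t{inc.haplotype_id}\t"
                f"{str(inc.shared).lower()}\n"
            )

    paths.files["genus_pairs"] = out / "genus_pairs.tsv"
    with paths.files["genus_pairs"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("genus\tn_species_analyzed\tn_pairs\tn_pairs_sharing\n")
        for g in res.sharing.genus_pairs:
            fh.write(
                f"{g.genus}\t{g.n_species_analyzed}\t{g.n_pairs}\t{g.n_pairs_sharing}\n"
            )

    paths.files["review_report"] = out / "review_report.tsv"
    rows = review_report(res.clusters, list(metadata))
    with paths.files["review_report"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("genus\thaplotype_id\tsample_id\tspecies\tshared_with\n")
        for r in rows:
            fh.write(
                f"{r['genus']}\t{r['haplotype_id']}\t{r['sample_id']}\t"
                f"{r['species']}\t{r['shared_with']}\n"
            )

    manifest = {
        "version": __version__,
        "parameters": {
            "min_inversion_len": min_inversion_len,
            "indel_mode": indel_mode,
            "min_species_for_scan": min_species_for_scan,
            "decimals": decimals,
        },
        "inputs": input_checksums,
        "outputs": {
            name: _sha256(path) for name, path in sorted(paths.files.items())
        },
    }
    paths.files["manifest"] = out / "manifest.json"
    paths.files["manifest"].write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    _log(f"[pipeline] wrote {len(paths.files)} files to {out}")
    return paths
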