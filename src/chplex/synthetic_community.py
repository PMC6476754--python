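"""Synthetic tropical-tree-community generator with known truth.

Emulates the statistical structure of a hyperdiverse forest plot sampled at
one noncoding cpDNA marker, so every pipeline stage can be exercised
without any real data:

* genera receive skewed species counts (truncated Zipf, mean ~2.9 species
  per genus as observed for the emulated site);
* 1-11 individuals are sequenced per species (1 + Binomial(10, 0.26), mean
  3.6), and only a fraction of the site's species are sequenced at all, so
  congener status must come from the inventory, not from the sample;
* ~13% of species are abiotically dispersed;
* each genus descends from a random ancestral sequence; species carry
  private mutation-derived haplotypes, and two controllable processes move
  haplotypes across species boundaries:

  - **incomplete lineage sorting** (``ils_retention``): a congeneric
    species pair retains the ancestral haplotype — both species' base
    haplotype *is* the ancestral sequence, which creates cross-species
    sharing without touching within-species diversity;
  - **introgression** (``intro_rate``, boosted by ``abiotic_multiplier``
    for abiotic recipients): a donor haplotype is copied into a recipient
    congener's pool, which adds both sharing *and* within-species
    diversity — the asymmetry the downstream statistics are designed to
    detect.

Distinct intended haplotypes within a genus are kept at least two
difference units apart (three when sequencing-noise injection is on), so
the two-difference collapsing rule recovers the truth exactly; the
``noise_rate`` option plants one-unit duplicates to exercise collapsing.

All randomness flows from a single seeded generator with deterministic
draw order, so identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .haplotyping import sequence_difference
from .seqio import (
    AlignedSeqRecord,
    SampleMeta,
    write_alignment_fasta,
    write_inventory,
    write_metadata,
)

__all__ = [
    "SimulationConfig",
    "TruthLog",
    "SimulatedCommunity",
    "simulate_community",
    "write_community",
    "scenario_suite",
    "SCENARIOS",
]

_ABIOTIC_RAW = ("autochorous", "anemochorous", "hydrochorous")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic community.

    Calibration defaults mirror the emulated site: 238 genera with a
    truncated-Zipf species abundance (exponent 1.8769 on 1..34 gives mean
    2.9 species per genus), 67% of species sequenced, 1 + Binomial(10,
    0.26) individuals per sequenced species (mean 3.6 on 1..11), 13%
    abiotically dispersed species, and a within-species haplotype count of
    1 + Poisson(theta) with theta = 0.45, which yields about 26% of
    included species polymorphic under default sampling.
    """

    n_genera: int = 238
    seq_length: int = 450
    zipf_exponent: float = 1.8769
    max_species_per_genus: int = 34
    ind_binom_n: int = 10
    ind_binom_p: float = 0.26
    abiotic_fraction: float = 0.13
    sequenced_prob: float = 0.67
    theta: float = 0.45
    divergence_mean: float = 4.0
    indel_fraction: float = 0.15
    pool_freq_ratio: float = 0.5
    ils_retention: float = 0.0
    intro_rate: float = 0.0
    abiotic_multiplier: float = 1.0
    noise_rate: float = 0.0
    voucher_prob: float = 0.71
    mixed_fraction_of_biotic: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "abiotic_fraction": self.abiotic_fraction,
            "sequenced_prob": self.sequenced_prob,
            "ils_retention": self.ils_retention,
            "noise_rate": self.noise_rate,
            "voucher_prob": self.voucher_prob,
            "ind_binom_p": self.ind_binom_p,
            "mixed_fraction_of_biotic": self.mixed_fraction_of_biotic,
            "indel_fraction": self.indel_fraction,
        }
        for name, v in probs.items():
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if not (0.0 < self.pool_freq_ratio <= 1.0):
            raise ValidationError("pool_freq_ratio must be in (0, 1]")
        if self.n_genera <= 0 or self.seq_length <= 0:
            raise ValidationError("n_genera and seq_length must be positive")
        if self.max_species_per_genus < 1:
            raise ValidationError("max_species_per_genus must be >= 1")
        if self.theta < 0 or self.intro_rate < 0 or self.divergence_mean <= 0:
            raise ValidationError("rates must be nonnegative (divergence_mean > 0)")
        if self.abiotic_multiplier < 1.0:
            raise ValidationError("abiotic_multiplier must be >= 1")

    @property
    def min_separation(self) -> int:
        # with noise on, a 1-unit mutant of one haplotype must not come
        # within 1 unit of a different haplotype, so intended haplotypes
        # need >= 3 units of separation
        return 3 if self.noise_rate > 0 else 2

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Parse a flat ``key=value`` text file into a config."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected key=value")
            key, value = (x.strip() for x in line.split("=", 1))
            if key not in known:
                raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
            caster = int if known[key] in ("int", int) else float
            kwargs[key] = caster(value)
        return cls(**kwargs)


@dataclass
class TruthLog:
    """Ground truth of one simulated community.

    ``species_haplotypes`` maps (genus, species) to the list of
    (haplotype_key, provenance, donor_species) triples in the species'
    pool; provenance is ``mutation``, ``ancestral-shared`` or
    ``introgressed``.  ``events`` holds one row per ILS-retention or
    introgression event, and ``sample_haplotype`` records which pool
    haplotype each sequenced individual drew (before any noise mutation).
    """

    species_haplotypes: Dict[Tuple[str, str], List[Tuple[str, str, Optional[str]]]] = field(
        default_factory=dict
    )
    events: List[Tuple[str, str, str, str]] = field(default_factory=list)
    sample_haplotype: Dict[str, str] = field(default_factory=dict)
    noisy_samples: List[str] = field(default_factory=list)

    def transfer_events(self) -> List[Tuple[str, str, str, str]]:
        return [e for e in self.events if e[0] == "introgression"]

    def retention_events(self) -> List[Tuple[str, str, str, str]]:
        return [e for e in self.events if e[0] == "ils-retention"]


@dataclass
class SimulatedCommunity:
    config: SimulationConfig
    records: List[AlignedSeqRecord]
    metadata: List[SampleMeta]
    inventory: Dict[str, int]
    truth: TruthLog


def _zipf_pmf(exponent: float, kmax: int) -> np.ndarray:
    k = np.arange(1, kmax + 1, dtype=float)
    w = k ** (-exponent)
    return w / w.sum()


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _mutate(
    rng: np.random.Generator,
    seq: str,
    n_events: int,
    indel_fraction: float,
) -> str:
    """Apply mutation events: substitutions and short deletion runs.

    Deletions are represented in alignment space (columns become ``-``), so
    every sequence of the genus keeps the ancestral coordinate system.
    """
    chars = list(seq)
    L = len(chars)
    for _ in range(n_events):
        if rng.random() < indel_fraction:
            run = int(rng.integers(1, 4))
            start = int(rng.integers(0, max(1, L - run)))
            for i in range(start, min(L, start + run)):
                chars[i] = "-"
        else:
            pos = int(rng.integers(0, L))
            if chars[pos] == "-":
                pos = next((i for i in range(L) if chars[i] != "-"), None)
                if pos is None:
                    continue
            alternatives = [b for b in "ACGT" if b != chars[pos]]
            chars[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def _distinct_enough(seq: str, pool: Sequence[str], min_sep: int) -> bool:
    return all(
        sequence_difference(seq, other).total_units >= min_sep for other in pool
    )


def simulate_community(config: SimulationConfig) -> SimulatedCommunity:
    """Generate a full synthetic community (sequences, metadata, inventory,
    truth log) under *config*; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    zipf = _zipf_pmf(config.zipf_exponent, config.max_species_per_genus)

    records: List[AlignedSeqRecord] = []
    metadata: List[SampleMeta] = []
    inventory: Dict[str, int] = {}
    truth = TruthLog()
    sample_counter = 0

    for g in range(config.n_genera):
        genus = f"G{g + 1:03d}"
        n_sp = int(rng.choice(len(zipf), p=zipf)) + 1
        inventory[genus] = n_sp
        species_names = [f"{genus}-sp{j + 1:02d}" for j in range(n_sp)]
        ancestral = _random_seq(rng, config.seq_length)

        # ILS retention: marked pairs collapse both species onto the
        # ancestral base haplotype
        retained: set = set()
        for i in range(n_sp):
            for j in range(i + 1, n_sp):
                if config.ils_retention > 0 and rng.random() < config.ils_retention:
                    retained.add(i)
                    retained.add(j)
                    truth.events.append(
                        ("ils-retention", genus, species_names[i], species_names[j])
                    )

        # base + within-species mutation haplotypes, kept min_separation
        # units apart from every other intended haplotype of the genus
        genus_pool: List[str] = [ancestral]  # ancestral is always reserved
        pools: List[List[Tuple[str, str, Optional[str]]]] = []
        seqs: Dict[str, str] = {"anc": ancestral}

        def fresh_haplotype(parent: str, mean_events: float) -> Optional[str]:
            for _ in range(200):
                n_events = max(1, int(rng.poisson(mean_events)))
                cand = _mutate(rng, seqs[parent], n_events, config.indel_fraction)
                if cand not in seqs.values() and _distinct_enough(
                    cand, genus_pool, config.min_separation
                ):
                    return cand
            return None

        for i in range(n_sp):
            pool: List[Tuple[str, str, Optional[str]]] = []
            if i in retained:
                pool.append(("anc", "ancestral-shared", None))
            else:
                hap = fresh_haplotype("anc", config.divergence_mean)
                if hap is None:
                    raise ValidationError(
                        f"genus {genus}: could not place a base haplotype "
                        f">= {config.min_separation} units from the rest; "
                        "increase seq_length or lower divergence_mean"
                    )
                key = f"{species_names[i]}-base"
                seqs[key] = hap
                genus_pool.append(hap)
                pool.append((key, "mutation", None))
            for v in range(int(rng.poisson(config.theta))):
                parent_key = pool[0][0]
                hap = fresh_haplotype(parent_key, 2.0)
                if hap is None:
                    continue
                key = f"{species_names[i]}-var{v + 1}"
                seqs[key] = hap
                genus_pool.append(hap)
                pool.append((key, "mutation", None))
            pools.append(pool)

        # dispersal syndromes (needed before introgression for the
        # abiotic-recipient boost)
        dispersal_raw: List[str] = []
        for i in range(n_sp):
            if rng.random() < config.abiotic_fraction:
                dispersal_raw.append(_ABIOTIC_RAW[int(rng.integers(0, 3))])
            else:
                dispersal_raw.append(
                    "mixed"
                    if rng.random() < config.mixed_fraction_of_biotic
                    else "zoochorous"
                )

        # introgression over ordered congeneric pairs; donors are drawn from
        # the pre-introgression pools for a well-defined event order
        donor_pools = [list(p) for p in pools]
        if config.intro_rate > 0:
            for d in range(n_sp):
                for r in range(n_sp):
                    if d == r:
                        continue
                    rate = config.intro_rate
                    if dispersal_raw[r] in _ABIOTIC_RAW:
                        rate *= config.abiotic_multiplier
                    for _ in range(int(rng.poisson(rate))):
                        donor_keys = [k for k, _, _ in donor_pools[d]]
                        key = donor_keys[int(rng.integers(0, len(donor_keys)))]
                        if key not in {k for k, _, _ in pools[r]}:
                            pools[r].append((key, "introgressed", species_names[d]))
                        truth.events.append(
                            ("introgression", genus, species_names[d], species_names[r])
                        )

        for i in range(n_sp):
            truth.species_haplotypes[(genus, species_names[i])] = list(pools[i])

        # sequencing: subset of species, skewed haplotype frequencies
        monomorphic_cols = [
            c
            for c in range(config.seq_length)
            if len({seqs[k][c] for k, _, _ in sum(pools, [])}) == 1
            and ancestral[c] != "-"
        ]
        for i in range(n_sp):
            if rng.random() >= config.sequenced_prob:
                continue
            n_ind = 1 + int(rng.binomial(config.ind_binom_n, config.ind_binom_p))
            weights = config.pool_freq_ratio ** np.arange(len(pools[i]), dtype=float)
            weights /= weights.sum()
            draw = rng.choice(len(pools[i]), size=n_ind, p=weights)
            hap_of_ind = [pools[i][int(x)][0] for x in draw]
            # noise injection: only individuals whose haplotype is carried by
            # another conspecific individual may mutate, so the unmutated
            # parent stays observable and no species-diagnostic state arises
            for j in range(n_ind):
                sample_counter += 1
                sid = f"{genus}-s{sample_counter:05d}"
                key = hap_of_ind[j]
                residues = seqs[key]
                truth.sample_haplotype[sid] = key
                carriers = [jj for jj in range(n_ind) if hap_of_ind[jj] == key]
                if (
                    config.noise_rate > 0
                    and len(carriers) >= 2
                    and j != carriers[0]
                    and monomorphic_cols
                    and rng.random() < config.noise_rate
                ):
                    col = monomorphic_cols[int(rng.integers(0, len(monomorphic_cols)))]
                    state = residues[col]
                    if state in "ACGT":
                        alt = [x for x in "ACGT" if x != state]
                        residues = (
                            residues[:col]
                            + alt[int(rng.integers(0, 3))]
                            + residues[col + 1 :]
                        )
                        truth.noisy_samples.append(sid)
                records.append(
                    AlignedSeqRecord(sid, genus, species_names[i], residues)
                )
                metadata.append(
                    SampleMeta(
                        sample_id=sid,
                        genus=genus,
                        species=species_names[i],
                        dispersal_raw=dispersal_raw[i],
                        voucher=bool(rng.random() < config.voucher_prob),
                    )
                )

    return SimulatedCommunity(config, records, metadata, inventory, truth)


def write_community(sim: SimulatedCommunity, out_dir) -> Dict[str, Path]:
    """Write a simulated community in the pipeline's input formats plus a
    ``truth_log.tsv``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta_dir = out / "fasta"
    fasta_dir.mkdir(exist_ok=True)
    paths: Dict[str, Path] = {}
    by_genus: Dict[str, List[AlignedSeqRecord]] = {}
    for r in sim.records:
        by_genus.setdefault(r.genus, []).append(r)
    for genus in sorted(by_genus):
        p = fasta_dir / f"{genus}.fasta"
        write_alignment_fasta(sorted(by_genus[genus], key=lambda r: r.sample_id), p)
        paths[f"fasta/{genus}"] = p
    paths["metadata"] = out / "metadata.tsv"
    write_metadata(sim.metadata, paths["metadata"])
    paths["inventory"] = out / "inventory.tsv"
    write_inventory(sim.inventory, paths["inventory"])
    paths["truth_log"] = out / "truth_log.tsv"
    with paths["truth_log"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("record_type\tgenus\tspecies\thaplotype_key\tprovenance\tdonor\n")
        for (genus, sp), pool in sorted(sim.truth.species_haplotypes.items()):
            for key, prov, donor in pool:
                fh.write(f"pool\t{genus}\t{sp}\t{key}\t{prov}\t{donor or ''}\n")
        for etype, genus, a, b in sim.truth.events:
            fh.write(f"event\t{genus}\t{a}\t{etype}\t\t{b}\n")
        for sid in sorted(sim.truth.sample_haplotype):
            fh.write(
                f"sample\t{sid.split('-s')[0]}\t\t{sim.truth.sample_haplotype[sid]}"
                f"\tsampled\t{sid}\n"
            )
    return paths


#: Named parameter regimes for the introgression-vs-ILS contrast.
SCENARIOS: Mapping[str, Dict[str, float]] = {
    "null": {"ils_retention": 0.0, "intro_rate": 0.0},
    "ils": {"ils_retention": 0.3, "intro_rate": 0.0},
    "introgression": {"ils_retention": 0.0, "intro_rate": 0.25},
    "both": {"ils_retention": 0.3, "intro_rate": 0.25},
}


def scenario_suite(
    base_config: SimulationConfig,
    n_replicates: int = 200,
    seed: int = 0,
    scenarios: Optional[Mapping[str, Dict[str, float]]] = None,
):
    """Run the full pipeline over replicate communities per scenario.

    Returns a pandas DataFrame with one row per (scenario, replicate):
    group-wise polymorphism rates and their difference, the two-sided
    Fisher p-value of the group contrast, and shared-incidence fractions
    among polymorphic and monomorphic species.
    """
    import pandas as pd

    from .pipeline import analyze_community

    if scenarios is None:
        scenarios = SCENARIOS
    master = np.random.default_rng(seed)
    rows = []
    for name in scenarios:
        overrides = scenarios[name]
        for rep in range(n_replicates):
            rep_seed = int(master.integers(0, 2**31 - 1))
            cfg = replace(base_config, seed=rep_seed, **overrides)
            sim = simulate_community(cfg)
            try:
                res = analyze_community(sim.records, sim.metadata, sim.inventory)
            except ValidationError as exc:
                raise ValidationError(
                    f"scenario {name!r} replicate {rep}: {exc}"
                ) from exc
            tab = res.contingency_all
            g1 = tab[0, 0] / max(1, tab[0].sum())
            g2 = tab[1, 0] / max(1, tab[1].sum())
            shr = res.sharing_by_polymorphism
            poly_tot = shr[0].sum()
            mono_tot = shr[1].sum()
            rows.append(
                {
                    "scenario": name,
                    "replicate": rep,
                    "seed": rep_seed,
                    "poly_rate_group1": g1,
                    "poly_rate_group2": g2,
                    "poly_rate_diff": g2 - g1,
                    "fisher_p": res.fisher_all.p_two_sided,
                    "shared_frac_polymorphic": (
                        shr[0, 0] / poly_tot if poly_tot else np.nan
                    ),
                    "shared_frac_monomorphic": (
                        shr[1, 0] / mono_tot if mono_tot else np.nan
                    ),
                    "n_included": int(tab.sum()),
                }
            )
    return pd.DataFrame(rows)
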