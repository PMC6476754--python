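# Methods

`chplex` analyzes chloroplast DNA variation across an entire tree
community: many species, each sampled at a handful of individuals, all
sequenced at one noncoding cpDNA marker (a trnH–psbA-style intergenic
spacer).  The scientific question it operationalizes is how to tell
**introgression** (chloroplast capture following hybridization between
coexisting congeners) apart from **incomplete lineage sorting** (retention
of ancestral haplotypes across speciation) as the source of haplotype
sharing between species.  The package's statistics exploit two community-
scale signatures of introgression: species with congeners at the site
should be more often polymorphic than species without congeners, and
haplotypes of polymorphic species should be more often shared with
congeners than haplotypes of monomorphic species.

## Difference metric and haplotype collapsing

Sequences are consumed pre-aligned within each genus (gap character `-`);
no cross-genus residue comparison is ever made, and haplotype names are
genus-scoped.  The distance between two aligned sequences is a count of
*difference units* of three kinds:

* **substitution** — a column where both sequences carry a base and the
  bases differ;
* **indel event** — one unit per maximal contiguous run of gap-vs-base
  columns, regardless of run length.  Event counting (rather than
  per-site counting) is the standard treatment for chloroplast
  microstructural variation; it stops long mononucleotide-repeat indels
  from inflating the distance.  A per-site mode (`indel_mode="site"`)
  is available.
* **inversion event** — one unit per detected segment where one sequence
  equals the reverse complement of the other; the columns inside the
  segment are removed from the substitution count, because a small
  inversion is a single mutational event.

Columns where either sequence carries an IUPAC ambiguity code are excluded
from all counting (a conservative stance toward sequencing error); columns
where both sequences are gapped are ignored.

**Inversion detection.**  A segment qualifies if it is gap-free and
unambiguous, at least `min_inversion_len` columns long (default 3:
length-1 "inversions" are indistinguishable from substitutions and
length-2 windows flag too many coincidences), reverse-complement matching,
and contains at least one mismatching column — the last condition prevents
an identical palindromic segment from being flagged.  Segments are chosen
greedily left to right, longest first at each start.  The implementation
rests on a symmetry property: inside a reverse-complement-matching window
the mirror image of a mismatching column is itself a mismatching column,
so every admissible window is centred on the midpoint of a pair of
mismatches.  Candidate centres are enumerated from mismatch pairs and
extended outward incrementally, which makes the scan effectively linear on
realistic data; it is verified against a naive every-window oracle in the
tests.  An optional `max_inversion_len` cap exists but defaults to
unbounded.

**Collapsing rule.**  Two sequences belong to the same haplotype when they
differ by at most one unit — a deliberate tolerance for single sequencing
errors.  Because that relation is not transitive, a clustering convention
is required; we use single linkage (connected components of the ≤1-unit
graph), the most conservative merger, i.e. the fewest haplotypes.  One
exception: if all individuals of one species inside a provisional cluster
share a state at exactly one difference unit that no individual of any
other species in the cluster carries, the state is treated as
species-diagnostic and that species is split into its own haplotype.  The
exception pass works on aligned column states with `-` treated as a state;
consecutive diagnostic columns that form one shared gap run are merged
into a single diagnostic unit, so a species-fixed indel of length *k*
counts as one unit, consistent with the event-based distance.  Diagnostic
inversions are not given special treatment: a multi-column diagnostic
inversion presents as several diagnostic columns and therefore does not
trigger a split (conservative).

Cluster identifiers are `H1..Hk` per genus, ordered by descending member
count with ties broken by the smallest member sample id; the
representative sequence is that of the lexicographically smallest member.
This makes outputs byte-reproducible.

## Community summaries

A species with a single sequenced individual is *excluded*: its
polymorphism status is undefined, though its haplotypes remain real
observations.  An included species is *polymorphic* when its individuals
fall in ≥2 clusters.  *Group 1* species belong to genera with exactly one
species recorded at the study site; *group 2* species have ≥1 congener at
the site.  Group status uses the full site inventory, not the sequenced
subset — coexistence is a property of the site.  Dispersal syndromes
collapse to *abiotic* (autochorous, anemochorous, hydrochorous) vs
*biotic* (zoochorous, mixed); mixed-strategy species count as biotic so
that "abiotic" means purely abiotic.

Sharing is accounted over **(species, haplotype) incidences** within
genera having at least two analyzed species.  An incidence is *shared*
when the haplotype also occurs in another congeneric species.  Excluded
(single-individual) species participate in the universe asymmetrically:
they count as analyzed species for the species-pair universe and toward
each haplotype's species set, but they contribute no incidence rows, since
an incidence is classified downstream by its species' polymorphism status.
This asymmetry mirrors the internal arithmetic of the community dataset
the package emulates, and is configurable
(`include_singleton_species=False` removes singletons entirely).  A
species pair counts as *sharing* when some haplotype contains both
species; every counted pair therefore has a witness haplotype.

The review report lists every sample whose haplotype is shared across
species — exactly the individuals whose sequences and vouchers deserve
manual rechecking, since misidentification mimics introgression.  It is
advisory only.

## Exact tests

**Fisher's exact test** (two-sided) on 2×2 tables uses the
point-probability rule: conditioning on both margins, the p-value is the
total hypergeometric probability of all tables whose point probability
does not exceed the observed one.  Ties are detected with a relative
tolerance of 1e-7, since probability masses are compared in floating
point.  The computation enumerates the full hypergeometric support (never
a normal approximation); an all-zero table returns p = 1 by convention.
The implementation is cross-checked in the tests against exact-rational
enumeration and against an independent library routine.

**Binomial tails** under a uniform-rate null are inclusive on both sides:
`p_minus = P(X ≤ k)` and `p_plus = P(X ≥ k)`, so
`p_minus + p_plus = 1 + P(X = k)`.  The tail on the small side of the
distribution's mode is an exact compensated partial sum of the pmf; the
other tail follows from the identity, which therefore holds to machine
precision, and a small tail is never produced by cancellation.

Two genus-level scans apply the tails to every genus with at least eight
analyzed species (configurable): one to polymorphic-species counts with
the community-wide polymorphic fraction as the null rate, and one to
haplotype-sharing pair counts with the community-wide sharing-pair
fraction as the null.  The focal genus is included in the null rate — each
genus is compared against the overall community trend.  No
multiple-testing correction is applied, matching the descriptive,
per-genus reading of the scan.

## Synthetic community generator

The generator emulates the community structure of a hyperdiverse tropical
plot, with defaults frozen to the emulated site's statistics:

| parameter | default | meaning |
|---|---|---|
| `n_genera` | 238 | genera recorded at the site |
| species per genus | Zipf(1.8769) truncated to 1..34 | skewed, mean ≈ 2.9 |
| individuals per species | 1 + Binomial(10, 0.26) | support 1..11, mean 3.6 |
| `sequenced_prob` | 0.67 | fraction of site species sequenced |
| `abiotic_fraction` | 0.13 | abiotically dispersed species |
| `theta` | 0.45 | within-species extra haplotypes ~ Poisson(theta) |
| `divergence_mean` | 4.0 | mutation events separating a species base from the genus ancestor |
| `seq_length` | 450 | aligned marker length (typical for the spacer) |
| `ils_retention` | 0 | per-congeneric-pair ancestral-retention probability |
| `intro_rate` | 0 | expected introgression events per ordered congeneric pair |
| `abiotic_multiplier` | 1 | boost on `intro_rate` for abiotic recipients |
| `noise_rate` | 0 | per-individual 1-unit sequencing-noise duplicates |

`theta = 0.45` was calibrated by Monte Carlo so that ≈26% of included
species are polymorphic under default sampling, the rate observed in the
emulated community; the Zipf exponent solves the mean-2.9 constraint
exactly.

Each genus descends from a random ancestral sequence.  Species base
haplotypes apply Poisson(`divergence_mean`) mutation events (substitutions
and short deletions in alignment coordinates — insertions are not modelled
since the analysis consumes aligned columns only, and inversions are not
generated, though the collapser handles them).  Distinct intended
haplotypes within a genus are kept ≥2 difference units apart by rejection
(≥3 when noise injection is on), which makes the truth well-defined under
the collapsing rule and gives the exact-recovery property: with noise off,
the clusters found for a species are exactly its distinct sampled
haplotypes.

**ILS model.**  Retention is haplotype identity, not genealogy: a marked
congeneric pair shares the ancestral haplotype because both species' base
haplotype *is* the ancestral sequence.  Retention replaces the base rather
than adding a pool member — adding would raise within-species diversity
precisely for species with congeners and thereby manufacture the group
contrast that retention, under the hypotheses being tested, should not
produce.  A consequence worth noting: under pure retention the
sharing-by-polymorphism contrast is systematically *negative* (a retained
monomorphic species contributes one all-shared incidence, while a retained
polymorphic species dilutes its shared incidence with private variants).
That is the classical expectation that common, old alleles are the
preferentially shared ones under ancestral sorting, and it is the mirror
image of the positive contrast introgression produces — the scenario suite
verifies both signs.

**Introgression model.**  For each ordered congeneric pair, a
Poisson(`intro_rate`, × `abiotic_multiplier` for abiotic recipients)
number of events each copy one donor-pool haplotype into the recipient's
pool, raising the recipient's diversity *and* creating sharing.  Only
genera with ≥2 site species can experience either process, so group-1
species are never donors or recipients — an invariant asserted from the
truth log.

Individuals draw haplotypes from their species' pool with geometric
weights (ratio 0.5, base haplotype most frequent).  Noise duplicates are
only ever planted on individuals whose haplotype is carried unmutated by
another conspecific individual, and only at genus-monomorphic columns, so
a noise mutation can neither orphan a haplotype nor create a
species-diagnostic state.

All draws come from one seeded generator in a fixed order, so identical
configurations yield byte-identical outputs.

### What the generator does and does not emulate

It reproduces the sampling design (skewed genus sizes, few individuals
per species, partial sequencing, dispersal composition) and the two
processes under study as haplotype-identity mechanisms.  It does not model
coalescent genealogies, mutation-rate heterogeneity, spatial structure,
misidentification, or alignment error.  Passing tests therefore show that
the *pipeline* recovers known truth and that the *statistics* respond to
the two processes with the expected signs and calibration — not that real
communities are free of the confounders listed above.

## Scenario suite and problem sizes

The suite runs the full pipeline on replicate communities under four
regimes — null (neither process), ILS-only (retention 0.3),
introgression-only (rate 0.25), both — and tabulates the group-wise
polymorphism contrast with its Fisher p-value and the shared-incidence
fractions among polymorphic vs monomorphic species.  Replicates use
60-genus communities at 450→300 bp (scaled-down site, ~100–120 included
species per replicate), 200 replicates per scenario in the acceptance
tests; at these sizes the suite completes in a few minutes on one core.
Under the null the group-contrast Fisher test rejects at ≈5% (slightly
under, as expected for a discrete exact test); under introgression-only
group 2 exceeds group 1 in essentially all replicates and the sharing
contrast is positive; under ILS-only there is no systematic group
contrast and the sharing contrast is non-positive.

## Numerical and degenerate-input conventions

* Fisher p-values are clipped to [0, 1]; a sum that selects the entire
  support within accumulated rounding snaps to exactly 1.
* Binomial scans refuse degenerate communities (polymorphic fraction 0 or
  1) rather than emit infinities.
* Empty dispersal strata raise; the pipeline skips a stratum that a small
  simulated community happens not to populate.
* Reported p-values are rounded only at presentation time (3 decimals by
  default, configurable); internal values keep full precision.
* All tabular output is UTF-8, tab-separated, unquoted, with sorted
  deterministic ordering; the run manifest records input/output SHA-256
  checksums so reruns are verifiable.

## Known limitations

* The collapsing rule's species-diagnostic exception operates within
  provisional clusters only; a cluster held together solely by a split-off
  species is not re-partitioned afterwards.
* The difference counting is defined only within a genus;
  cross-genus contamination cannot be detected here and should be caught
  upstream.
* Binomial scans treat species (and pairs) as exchangeable under the
  null; genus-specific sampling depth is not modelled.
* The generator's exact-recovery guarantee rests on the enforced ≥2-unit
  separation of intended haplotypes; real communities offer no such
  guarantee, and collapsing error there is bounded only by the
  conservative single-linkage design.
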