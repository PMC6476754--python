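"""Run the whole analysis on a simulated community, in memory.

Simulation -> haplotype collapsing -> species summaries -> group/dispersal
contingency tables with Fisher p-values -> sharing accounting -> per-genus
binomial scans.
"""

from chplex import SimulationConfig, analyze_community, simulate_community

cfg = SimulationConfig(n_genera=120, seq_length=300, intro_rate=0.2, seed=3)
sim = simulate_community(cfg)
res = analyze_community(sim.records, sim.metadata, sim.inventory)

print(f"{len(sim.records)} sequences -> {len(res.clusters)} haplotypes")

tab = res.contingency_all
print("\nPolymorphism by congener group (rows group1/group2, "
      "cols polymorphic/monomorphic):")
print(tab)
g1 = tab[0, 0] / tab[0].sum()
g2 = tab[1, 0] / tab[1].sum()
print(f"group1 {g1:.0%} vs group2 {g2:.0%} polymorphic, "
      f"Fisher p = {res.fisher_all.p_two_sided:.2g}")

shr = res.sharing_by_polymorphism
print("\nSharing by polymorphism (rows polymorphic/monomorphic incidences, "
      "cols shared/private):")
print(shr)
print(f"Fisher p = {res.fisher_sharing.p_two_sided:.3f}")

if res.polymorphism_scan:
    print("\nPer-genus polymorphism scan (genera with >= 8 analyzed species):")
    for row in res.polymorphism_scan:
        print(f"  {row.genus}: {row.k}/{row.n} polymorphic, "
              f"P- = {row.p_minus:.3f}, P+ = {row.p_plus:.3f}")

print(
    "\nWith introgression switched on, group-2 species (congeners present)"
    "\nshow elevated polymorphism and shared incidences concentrate in"
    "\npolymorphic species - the introgression signature."
)
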