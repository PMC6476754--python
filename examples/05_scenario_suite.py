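"""Contrast introgression against incomplete lineage sorting.

Runs the full pipeline over replicate communities under four regimes and
tabulates the two discriminating statistics.  With the small replicate
count used here this takes under a minute.
"""

import numpy as np

from chplex import SimulationConfig, scenario_suite

base = SimulationConfig(n_genera=60, seq_length=300)
df = scenario_suite(base, n_replicates=25, seed=1)

print(f"{len(df)} pipeline runs ({df.replicate.max() + 1} replicates x "
      f"{df.scenario.nunique()} scenarios)\n")
print(f"{'scenario':14s} {'reject@5%':>9s} {'grp2-grp1':>10s} {'sharing contrast':>17s}")
for name, g in df.groupby("scenario"):
    rej = (g.fisher_p < 0.05).mean()
    diff = g.poly_rate_diff.mean()
    contrast = (g.shared_frac_polymorphic - g.shared_frac_monomorphic).dropna()
    c = contrast.mean() if len(contrast) else float("nan")
    print(f"{name:14s} {rej:9.2f} {diff:+10.3f} {c:+17.3f}")

print(
    "\nReading: under the null the group-contrast test rejects at ~5% and"
    "\nboth contrasts sit near zero.  Introgression pushes group-2"
    "\npolymorphism up and makes shared incidences concentrate in"
    "\npolymorphic species (positive contrast).  Lineage sorting creates"
    "\nsharing without a group contrast, and its sharing contrast is"
    "\nnon-positive: under ancestral retention, monomorphic species'"
    "\nhaplotypes are the preferentially shared ones."
)
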