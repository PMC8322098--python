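"""Per-colony diversity (theta_pi, Watterson's theta, Tajima's D),
per-individual heterozygosity, and the windowed RoH / F_RoH scan.

The RoH scan needs a dense site spacing (of the order of one informative
site per 500 bp) for the 100 kb window heterozygosity to resolve the
low-heterozygosity cutoff, so it runs on a dedicated dense simulation of the
bottlenecked colony rather than on the sparse genome-wide panel.

Run:  python analysis/03_diversity_roh.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from glpop.sfs import (call_roh_and_froh, individual_heterozygosity, roh_cutoff,
                       sfs1d_em, sfs_summary_stats, window_het_track)
from glpop.simdata import simulate_dataset

out = Path("results/diversity")
out.mkdir(parents=True, exist_ok=True)

ds = simulate_dataset(seed=1)
gl = ds.gl
keep = [i for i, c in enumerate(gl.colonies) if c != "Outgroup"]
glp = gl.subset_individuals(keep)

rows, het_rows = [], []
for colony in dict.fromkeys(glp.colonies):
    sub = glp.by_colony(colony)
    stats = sfs_summary_stats(sfs1d_em(sub))
    rows.append({"colony": colony, "theta_pi": stats.theta_pi_per_site,
                 "theta_w": stats.theta_w_per_site,
                 "tajimas_d": stats.tajimas_d, "S": stats.segregating_sites})
    for ind in sub.individuals:
        j = glp.individuals.index(ind)
        est = individual_heterozygosity(sfs1d_em(glp.subset_individuals([j])))
        het_rows.append({"colony": colony, "individual": ind, "het": est})

div = pd.DataFrame(rows)
het = pd.DataFrame(het_rows)
div.to_csv(out / "colony_diversity.tsv", sep="\t", index=False, float_format="%.6g")
het.to_csv(out / "individual_het.tsv", sep="\t", index=False, float_format="%.6g")

print("colony diversity (per panel site):")
print(div.round(4).to_string(index=False))
cm = het.groupby("colony")["het"].mean().sort_values()
print(f"\nlowest mean heterozygosity: {cm.index[0]} ({cm.iloc[0]:.4f}); "
      f"highest: {cm.index[-1]} ({cm.iloc[-1]:.4f})")

# dense RoH study: one bottlenecked colony, implanted tract fraction 0.16
roh_cfg = {
    "colonies": ["A"], "tree": {"A": ("root", 0.05)}, "mixtures": {},
    "clusters": {"A": "one"}, "admixture_events": [], "outgroup": None,
    "n_sites": 50_000, "chromosomes": {"chr1": 25_000_000, "chr2": 25_000_000},
    "depth_range": (10.0, 10.0),
    "bottleneck": {"colony": "A", "roh_fraction": 0.16,
                   "tract_length_range": (500_000, 2_500_000)},
}
roh_ds = simulate_dataset(roh_cfg, seed=2)
tracks = [window_het_track(roh_ds.gl, ind) for ind in roh_ds.gl.individuals]
cutoff = roh_cutoff(tracks)
roh_rows = []
for t in tracks:
    segs, froh = call_roh_and_froh(t, cutoff)
    roh_rows.append({"individual": t.individual, "froh": froh,
                     "n_segments": len(segs),
                     "longest_bp": max((s.length for s in segs), default=0)})
roh = pd.DataFrame(roh_rows)
roh.to_csv(out / "froh.tsv", sep="\t", index=False, float_format="%.6g")
print(f"\nRoH scan (implanted tract fraction 0.16, cutoff {cutoff:.4g}):")
print(roh.round(4).to_string(index=False))
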