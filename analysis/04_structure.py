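"""Genomic population structure: GL-based PCA, admixture proportions over a
range of K with replicate averaging, and Evanno delta-K model choice.

Run:  python analysis/04_structure.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from glpop.simdata import simulate_dataset
from glpop.structure import (admixture_em, align_and_average_replicates,
                             evanno_best_k, pca_gl)

out = Path("results/structure")
out.mkdir(parents=True, exist_ok=True)

ds = simulate_dataset(seed=1)
gl = ds.gl
keep = [i for i, c in enumerate(gl.colonies) if c != "Outgroup"]
glp = gl.subset_individuals(keep)

res = pca_gl(glp)
coords = pd.DataFrame(res.coords(4), index=glp.individuals,
                      columns=["PC1", "PC2", "PC3", "PC4"])
coords.insert(0, "colony", glp.colonies)
coords.to_csv(out / "pca_coords.tsv", sep="\t", float_format="%.6g")
print("variance explained: " + ", ".join(
    f"PC{i+1} {v*100:.2f}%" for i, v in enumerate(res.variance_explained[:4])))

# admixture over K = 1..5 on a 2,000-site subsample, 3 replicates each
rng = np.random.default_rng(1001)
gls = glp.subset_sites(np.sort(rng.choice(glp.n_sites, 2000, replace=False)))
logls = {}
for K in range(1, 6):
    runs = [admixture_em(gls, K=K, seed=100 * K + r, tol=0.05, max_iter=800,
                         n_init=2) for r in range(3)]
    logls[K] = [r.log_likelihood for r in runs]
    avg, clusters = align_and_average_replicates(runs)
    q = pd.DataFrame(avg.Q, index=gls.individuals)
    q.insert(0, "colony", gls.colonies)
    q.to_csv(out / f"admixture_K{K}.tsv", sep="\t", float_format="%.4f")

ev = evanno_best_k(logls)
ev.table.to_csv(out / "evanno.tsv", sep="\t", index=False, float_format="%.6g")
print(f"Evanno delta-K selects K = {ev.best_k}")
q4 = pd.read_csv(out / "admixture_K4.tsv", sep="\t", index_col=0)
bjo = q4[q4["colony"] == "Bjornoya"].drop(columns="colony")
print("mean ancestry of the admixed colony at K=4:",
      np.round(bjo.mean().to_numpy(), 3))
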