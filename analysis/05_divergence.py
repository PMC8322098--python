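"""Pairwise Hudson F_ST with Slatkin linearisation, sliding-window F_ST for
one cluster contrast, and the f3 / D admixture tests for the contact-zone
colony.

Run:  python analysis/05_divergence.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from glpop.divergence import dstat, f3stat, fst_from_sfs2d, sliding_window_fst
from glpop.sfs import sfs2d_em
from glpop.simdata import simulate_dataset

out = Path("results/divergence")
out.mkdir(parents=True, exist_ok=True)

ds = simulate_dataset(seed=1)
gl = ds.gl
colonies = [c for c in dict.fromkeys(gl.colonies) if c != "Outgroup"]

fst = pd.DataFrame(0.0, index=colonies, columns=colonies)
slatkin = fst.copy()
for i, a in enumerate(colonies):
    for b in colonies[i + 1:]:
        est = fst_from_sfs2d(sfs2d_em(gl.by_colony(a), gl.by_colony(b)))
        fst.loc[a, b] = fst.loc[b, a] = est.fst
        slatkin.loc[a, b] = slatkin.loc[b, a] = max(est.slatkin, 0.0)
fst.to_csv(out / "pairwise_fst.tsv", sep="\t", float_format="%.6g")
slatkin.to_csv(out / "pairwise_slatkin.tsv", sep="\t", float_format="%.6g")

arctic = fst.loc["Spitsbergen"].drop("Spitsbergen")
within = [fst.loc[a, b] for a, b in
          [("Hornoya", "Rost"), ("Faroe", "Papey"), ("GannetIsl", "GullIsl")]]
print(f"F_ST involving the high-Arctic colony: "
      f"{arctic.min():.3f}-{arctic.max():.3f}; "
      f"adjacent within-cluster pairs: {min(within):.4f}-{max(within):.4f}")

prior = sfs2d_em(gl.by_colony("Spitsbergen"), gl.by_colony("Hornoya"))
tab = sliding_window_fst(gl.by_colony("Spitsbergen"), gl.by_colony("Hornoya"),
                         prior, window=50_000, step=12_500)
tab.to_csv(out / "fst_windows_arctic_vs_central.tsv", sep="\t", index=False,
           float_format="%.6g")
usable = tab[tab["usable"]]
print(f"sliding-window F_ST (50 kb / 12.5 kb): {len(usable)} usable windows, "
      f"median {usable['fst'].median():.3f}, "
      f"genome-wide {tab['alpha'].sum() / tab['beta'].sum():.3f}")

f3 = f3stat(gl, "Bjornoya", "Spitsbergen", "Hornoya")
d = dstat(gl, "Vestmannaeyjar", "Bjornoya", "Spitsbergen", "Outgroup", seed=7)
d0 = dstat(gl, "GannetIsl", "GullIsl", "Hornoya", "Outgroup", seed=7)
pd.DataFrame([
    {"test": "f3(Bjornoya; Spitsbergen, Hornoya)", **f3},
    {"test": "D(Vestmannaeyjar, Bjornoya; Spitsbergen)", **d},
    {"test": "D(GannetIsl, GullIsl; Hornoya) control", **d0},
]).to_csv(out / "admixture_tests.tsv", sep="\t", index=False, float_format="%.6g")
print(f"f3 for the contact-zone colony: {f3['f3']:.5f} (Z = {f3['Z']:.1f}); "
      f"D: {d['D']:.3f} (Z = {d['Z']:.1f}); control D Z = {d0['Z']:.1f}")
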