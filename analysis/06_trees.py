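"""Individual-level neighbor-joining tree from consensus-base p-distances,
rooted on the outgroup, with block-bootstrap support.

Run:  python analysis/06_trees.py
"""

from pathlib import Path

import numpy as np

from glpop.simdata import simulate_dataset
from glpop.trees import bipartitions, bootstrap_support

out = Path("results/trees")
out.mkdir(parents=True, exist_ok=True)

ds = simulate_dataset(seed=1)
gl = ds.gl
rng = np.random.default_rng(61)
sub = gl.subset_sites(np.sort(rng.choice(gl.n_sites, 5000, replace=False)))

tree, supports = bootstrap_support(sub, n_reps=100, block_bp=5_000_000,
                                   seed=62, outgroup="Outgroup_00")
(out / "nj_individuals.nwk").write_text(tree.to_newick() + "\n")

allset = frozenset(tree.leaves())
for cluster, members in [
    ("high-Arctic colony", [f"Spitsbergen_{i:02d}" for i in range(6)]),
    ("southern colony", [f"IsleOfMay_{i:02d}" for i in range(6)]),
    ("western cluster", [f"{c}_{i:02d}" for c in ("GannetIsl", "GullIsl")
                         for i in range(6)]),
]:
    side = frozenset(members)
    key = tuple(sorted(min(side, allset - side, key=lambda s: sorted(s))))
    sup = supports.get(key)
    status = f"monophyletic, bootstrap {sup:.0f}%" if sup is not None \
        else "NOT monophyletic in the main tree"
    print(f"{cluster}: {status}")
print(f"tree written to {out}/nj_individuals.nwk "
      f"({len(bipartitions(tree))} internal splits)")
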