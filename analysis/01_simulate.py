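"""Simulate the default twelve-colony study and write every input the later
stages consume: the Beagle-GL panel, sample/colony tables, ground truth,
the mitochondrial alignment, and the rasterised sea map.

Run from the repository root:  python analysis/01_simulate.py [seed]
"""

import json
import sys
from pathlib import Path

import pandas as pd

from glpop import io as gio
from glpop.simdata import simulate_dataset

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
out = Path("results/sim")
out.mkdir(parents=True, exist_ok=True)

ds = simulate_dataset(seed=seed)
gio.write_beagle(ds.gl, out / "panel.beagle")
pd.DataFrame({"individual": ds.gl.individuals, "colony": ds.gl.colonies}).to_csv(
    out / "individuals.tsv", sep="\t", index=False)
(out / "chromosomes.json").write_text(json.dumps(ds.model.chromosomes, indent=1))
ds.truth.ancestry.to_csv(out / "truth_ancestry.tsv", sep="\t", float_format="%.6f")
ds.truth.expected_fst.to_csv(out / "truth_fst.tsv", sep="\t", float_format="%.8f")
ds.truth.roh_intervals.to_csv(out / "truth_roh.tsv", sep="\t", index=False)
gio.write_fasta(ds.mito, out / "mito.fasta")
gio.write_ascii_grid(ds.geography, out / "water_mask.asc")
gio.write_colonies_tsv(ds.geography.colonies, out / "colony_coords.tsv")

print(f"seed {seed}: {ds.gl.n_sites} biallelic sites, "
      f"{ds.gl.n_individuals} individuals "
      f"({len(ds.model.colonies)} colonies x {ds.model.n_per_colony} diploids "
      f"+ outgroup), genome "
      f"{sum(ds.model.chromosomes.values())/1e6:.0f} Mb")
print(f"implanted RoH tracts: {len(ds.truth.roh_intervals)} in colony "
      f"{ds.model.bottleneck['colony']}")
print(f"wrote inputs to {out}/")
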