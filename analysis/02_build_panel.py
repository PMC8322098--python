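"""Build the analysis panel from the simulated Beagle-GL table: keep sites
covered in all individuals with minor-allele frequency >= 0.05, then prune
linked sites (r^2 > 0.2), keeping the most central site of each block.

Run after 01_simulate.py:  python analysis/02_build_panel.py
"""

import json
from pathlib import Path

import pandas as pd

from glpop import io as gio
from glpop.gl import filter_sites, ld_prune

sim = Path("results/sim")
out = Path("results/panel")
out.mkdir(parents=True, exist_ok=True)

inds = pd.read_csv(sim / "individuals.tsv", sep="\t")
colonies = dict(zip(inds["individual"], inds["colony"]))
lengths = json.loads((sim / "chromosomes.json").read_text())
gl = gio.read_beagle(sim / "panel.beagle", colonies=colonies, chrom_lengths=lengths)

filtered, report = filter_sites(gl, maf_min=0.05, max_missing=0.0)
pruned, blocks = ld_prune(filtered, r2_threshold=0.2, max_dist_bp=100_000)
report["n_linked_blocks"] = len(blocks)
report["n_after_prune"] = pruned.n_sites

gio.write_beagle(pruned, out / "panel.filtered.beagle")
(out / "filter_report.json").write_text(json.dumps(report, indent=1))

print(f"input sites: {report['n_input']}")
print(f"removed (missingness > 0): {report['removed_missing']}; "
      f"removed (MAF < 0.05): {report['removed_maf']}")
print(f"linked blocks collapsed: {report['n_linked_blocks']}; "
      f"final panel: {report['n_after_prune']} sites "
      f"-> {out}/panel.filtered.beagle")
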