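"""Generate a synthetic WGBS study and inspect its composition.

Builds the default simulated cohort (12 neuron + 12 glia samples, ages
0-23 years, a 3-Mb genome with planted UMR/LMR/PMD/DMV features and
cell-type x age DMRs), prints the marginal methylation distributions, and
writes one per-cytosine report file per sample plus the truth ledger.
"""

import sys
from pathlib import Path

import numpy as np

import cortexmeth as cm

out = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("scratch/sim_study")
out.mkdir(parents=True, exist_ok=True)

cfg = cm.SimulationConfig(seed=1)
matrix, meta, truth = cm.simulate_methylome(cfg)

cpg = matrix.select_context("CpG")
cph = matrix.select_context("CpH")
print(f"{matrix.n_sites:,} cytosines ({cpg.n_sites:,} CpG, {cph.n_sites:,} CpH) "
      f"across {matrix.n_samples} samples")
print(f"mean coverage: {matrix.total.mean():.1f}x  "
      "(negative-binomial around the 15x study depth)")
print(f"CpGs with beta > 80%: {np.nanmean(cpg.beta() > 0.8):.1%}  "
      "(highly methylated background, as in somatic methylomes)")
print(f"CpHs with beta < 20%: {np.nanmean(cph.beta() < 0.2):.1%}  "
      "(non-CpG methylation is sparse and low-level)")
print("\nplanted features:")
print(truth.regions["kind"].value_counts().to_string())

for sample in matrix.samples[:2]:      # two example reports; all look alike
    cm.write_cytosine_report(matrix, sample, out / f"{sample}.CX_report.txt")
meta.to_csv(out / "samples.tsv", sep="\t", index=False)
truth.to_json(out / "truth.json")
print(f"\nwrote example cytosine reports, metadata and truth ledger to {out}/")
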