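"""Associate single-cytosine methylation with gene expression.

Twenty-two donors with matched methylomes and expression tables; planted
cis effects link a cytosine's methylation to a nearby gene's
log2(FPKM + 1). The scan tests every (cytosine, gene) pair within 1 kb,
rescues marginal CpG associations near significant CpH hits to classify
features as CpH-exclusive or shared, and summarises the filtered records.
"""

import cortexmeth as cm
from cortexmeth.assoc import (
    annotate_records, cis_scan, filter_associations, filter_expression,
    marginal_cpg_rescue, summarize_associations, age_confound_check,
)

layout = cm.FeatureLayout(n_umr=0, n_lmr=0, n_dmv=0, n_pmd=0,
                          n_dmr_cell=0, n_dmr_inter=0)
cfg = cm.SimulationConfig(seed=12, n_neuron=22, n_glia=0,
                          genome_length=2_000_000, n_gaps=0, layout=layout)
matrix, meta, truth = cm.simulate_methylome(cfg)
tables = cm.simulate_expression(cfg, truth, meta)
donors = meta["sample_id"].tolist()

filt = cm.filter_by_coverage(matrix, 3)
genes = truth.genes.rename(columns={"gene_id": "feature_id"})
genes["gene_id"] = genes["feature_id"]
expr = filter_expression(tables["gene"], "gene", donors)
print(f"{len(expr)} of {len(tables['gene'])} genes pass the mean-FPKM filter")

scan = cis_scan(filt, expr, genes, donors, feature_type="gene")
print(f"{len(scan)} (cytosine, gene) pairs at p < 5e-4 "
      f"out of {scan.attrs['n_tested']:,} tested")

cph_hits = scan[(scan["context"] != "CpG") & (scan["q"] < 0.05)]
if len(cph_hits):
    _, cls = marginal_cpg_rescue(cph_hits, filt, expr, genes, donors)
    print("CpH-associated genes:",
          ", ".join(f"{g} ({c})" for g, c in cls.items()))

records = filter_associations(scan, truth.genes)
records = annotate_records(records, truth.genes)
records = age_confound_check(records, filt, {"gene": expr}, meta, donors)
summary = summarize_associations(records)
cols = ["meth_type", "direction", "n", "n_unique_features",
        "mean_expr_change", "prop_gene_body", "prop_age_confounded"]
print("\nassociation summary (per context and direction):")
print(summary[cols].to_string(index=False))
print("\n'direction' is the sign of the expression change per unit "
      "methylation; mean_expr_change is |slope| x the cytosine's observed "
      "methylation range, i.e. the expression shift across donors.")
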