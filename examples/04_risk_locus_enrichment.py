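"""Assign risk loci to genes and test module enrichment by permutation.

Loci are mapped to every gene within a 250 kb window. Each module's fraction
of risk genes is compared with a null in which random gene sets of the same
size are drawn with probability proportional to total network connectivity
k, so the null accounts for well-connected genes being easier to assign to
modules. A generic Fisher's exact test handles arbitrary user gene sets.
"""

import coexpair as cx
from coexpair.enrich import module_enrichment_table

ds = cx.simulate_dataset(cx.SimConfig(n_genes=1500, seed=17))
adj = cx.adjacency(ds.expr_base, beta=4)
dend = cx.average_linkage(cx.network.dist_tom(cx.tom(adj)))
assign, _ = cx.merge_close_modules(
    ds.expr_base, cx.cut_tree_dynamic(dend, min_size=50, cut_height=0.99)
)

risk = cx.assign_risk_genes(ds.gene_annot, ds.risk_loci, window_bp=250_000)
print(f"{len(ds.risk_loci)} risk loci -> {len(risk.genes)} risk genes "
      f"(250 kb window)")

k = cx.connectivity(adj)
table = module_enrichment_table(assign, risk, k, B=2000, seed=1)
print(table.round(3).to_string())
print()
print("percent_risk is each module's share of risk genes; empirical_p is the")
print("add-one permutation P against connectivity-weighted random gene sets.")
print("The responder module was planted with an elevated risk fraction, the")
print("grey background with the baseline rate.")

# Fisher route for a user-supplied gene set (here: the true risk set itself)
odds, p, fold = cx.fisher_gene_set_enrichment(
    assign.index[assign != "grey"], risk.genes, assign.index
)
print(f"\nFisher check, all assigned genes vs risk set: "
      f"fold = {fold:.2f}, two-sided P = {p:.3g}")
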