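"""Differential genes and pathway activation between marker strata.

Mann-Whitney per feature with BH-FDR; genes additionally require fold
change > 2.  The marker-negative stratum is the reference, so "up in alt"
means upregulated in marker-positive tumors.
"""

from tertscape import (
    DiffConfig, SimConfig, classify_tert, cnr, differential_genes,
    differential_pal, enrich_list, group_report, normalize, pal_matrix,
    simulate_cohort,
)

cohort = simulate_cohort(SimConfig(seed=1))
tumors = cohort.samples.index[cohort.samples["role"] == "tumor"]
strata = classify_tert(cohort.counts).loc[tumors]
ref_ids = list(strata.index[strata == "neg"])
alt_ids = list(strata.index[strata == "pos"])

norm = normalize(cohort.counts)
diff_genes = differential_genes(norm, ref_ids, alt_ids, DiffConfig())

ratios = cnr(norm, cohort.samples)
pal, _ = pal_matrix(ratios, cohort.library)
diff_pal, untestable = differential_pal(pal, ref_ids, alt_ids, DiffConfig())

report = group_report(diff_genes, diff_pal)
print(f"differential genes: {report['genes_total']} "
      f"({report['genes_up_alt']} up in marker-positive, "
      f"{report['genes_up_ref']} up in marker-negative)")
print(f"differential pathways: {report['pathways_total']} "
      f"({report['pathways_up_alt']} up in marker-positive)")

# over-representation of the upregulated gene list against the library
up_genes = set(diff_genes.index[diff_genes["significant"] & (diff_genes["up_in"] == "alt")])
universe = set(norm.index)
enriched = enrich_list(up_genes, cohort.library, universe)
top = enriched.iloc[0]
print(f"top enriched pathway: {enriched.index[0]} "
      f"(overlap {top['overlap']}/{top['term_size']}, adjusted p {top['p_adj']:.2e})")
# Planted active pathways should dominate the enrichment ranking.
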