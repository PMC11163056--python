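"""L1 retrotransposon subfamily comparison between marker strata.

Instance counts are summed per subfamily (L1HS, L1PA2), normalized with
size factors derived from the gene matrix, and compared between strata
with the Mann-Whitney test.
"""

from tertscape import (
    SimConfig, aggregate_subfamilies, classify_tert, simulate_cohort,
    te_group_compare,
)

cohort = simulate_cohort(SimConfig(seed=1))
tumors = cohort.samples.index[cohort.samples["role"] == "tumor"]
strata = classify_tert(cohort.counts).loc[tumors]
ref_ids = list(strata.index[strata == "neg"])   # marker-negative = reference
alt_ids = list(strata.index[strata == "pos"])

sub, n_instances = aggregate_subfamilies(cohort.te_counts, cohort.te_subfamily)
print("instances per subfamily:", n_instances.to_dict())

res = te_group_compare(sub, cohort.counts.loc[:, tumors], ref_ids, alt_ids)
for sid, row in res.iterrows():
    where = {"ref": "marker-negative", "alt": "marker-positive"}.get(row["up_in"], "neither")
    print(f"{sid}: log2FC {row['log2fc']:+.2f}, adjusted p {row['p_adj']:.2e} "
          f"-> higher in {where} tumors")
# The generator plants a 3-fold elevation in marker-negative tumors, so both
# subfamilies should come out significantly higher in that group.
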