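"""Recompute cohort bookkeeping from the bundled published aggregate tables.

The patient-level data of the published pan-cancer cohort are
access-restricted, but its aggregate tables are bundled; re-summarizing
them through the package reproduces the headline percentages.
"""

from tertscape.datasets import (
    expand_cohort_to_samples, load_promoter_assay, load_tf_correlations,
)
from tertscape.pipeline import mutation_bookkeeping
from tertscape.screen import cohort_summary

summary = cohort_summary(expand_cohort_to_samples()).set_index("tumor_type")
total = summary.loc["Total"]
print(f"cohort: {int(total['n_pos'])}/{int(total['n_total'])} marker-positive "
      f"({total['pct_pos']}%)")

tf = load_tf_correlations()
strong = tf[(tf["rho"].abs() >= 0.4) & (tf["p_adj"] < 0.05)]
print(f"strong-tier TF genes (|rho| >= 0.4): {len(strong)} "
      f"({(strong['rho'] > 0).sum()} positive, {(strong['rho'] < 0).sum()} negative)")

book = mutation_bookkeeping(load_promoter_assay())
print(f"promoter assay: {book['n_assayed']} cases, {book['n_mut']} mutant; "
      f"among expressing samples {book['pct_mut_expressing']}% carry a mutation")
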