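"""Bundled reference tables for the published pan-cancer TERT cohort.

These are small aggregate tables of the cohort the pipeline targets (the
underlying patient-level expression data are access-restricted and not
distributed):

* :func:`load_cohort_table` — per-tumor-type counts of TERT+/TERT- samples
  and promoter-mutation assay outcomes (27 tumor types, 1039 samples).
* :func:`load_tf_correlations` — the 19 transcription-factor genes most
  strongly correlated with TERT expression (|rho| >= 0.4).
* :func:`load_promoter_assay` — a per-sample expansion of the promoter
  mutation assay (114 assayed samples).  The per-type mutation and assay
  margins are real; the assignment of expression status to individual
  wild-type cases is NOT identifiable from the published aggregates, so
  this table is a synthetic expansion constrained to reproduce the
  published margins (81 expressing wild-type, 12 expressing mutant cases).
* :data:`PUBLISHED_COUNTS` — cohort-level discovery counts as published,
  used purely as bookkeeping inputs (they are not recomputable without the
  restricted data).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Published cohort-level discovery counts (bookkeeping inputs).
PUBLISHED_COUNTS = {
    "corr_genes_pos": 817,
    "corr_genes_neg": 626,
    "corr_tf_pos": 48,
    "corr_tf_neg": 55,
    "corr_pathways_pos": 241,
    "corr_pathways_neg": 24,
    "diff_genes_up_pos": 262,
    "diff_genes_up_neg": 234,
    "diff_pathways_up_pos": 1077,
    "diff_pathways_up_neg": 898,
    "dna_repair_up_pos": 32,
    "dna_repair_total": 38,
}


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", **kwargs)


def load_cohort_table() -> pd.DataFrame:
    """Aggregated cohort table: one row per tumor type.

    Columns: n_pos / n_neg (TERT expression strata), n_no_data (promoter
    mutation status unavailable), n_mut_C250 / n_mut_C228 / n_wt (assay
    outcomes; NA for the hematologic malignancies that were not assayed),
    n_total.
    """
    return _read("cohort_table.tsv", na_values=["NA"])


def load_tf_correlations() -> pd.DataFrame:
    """Strongly TERT-correlated transcription-factor genes (|rho| >= 0.4)."""
    return _read("tf_correlations.tsv", index_col=0)


def expand_cohort_to_samples(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Expand the aggregated cohort table into a per-sample annotation table.

    Each tumor type contributes n_pos samples with stratum ``pos`` and n_neg
    with ``neg``; promoter mutation labels (C250T, C228T, wt) are assigned to
    samples in order, the remainder being ``unknown``.  Which individual
    sample carries which label is arbitrary — every per-type aggregate count
    is preserved, which is all downstream bookkeeping consumes.
    """
    table = load_cohort_table() if table is None else table
    rows = []
    for rec in table.itertuples(index=False):
        strata = ["pos"] * int(rec.n_pos) + ["neg"] * int(rec.n_neg)
        labels = []
        if not pd.isna(rec.n_wt):
            labels += ["C250T"] * int(rec.n_mut_C250)
            labels += ["C228T"] * int(rec.n_mut_C228)
            labels += ["wt"] * int(rec.n_wt)
        labels += ["unknown"] * (len(strata) - len(labels))
        for i, (stratum, status) in enumerate(zip(strata, labels), start=1):
            rows.append(
                {
                    "sample_id": f"{rec.tumor_type.replace(' ', '_')}_{i:03d}",
                    "tumor_type": rec.tumor_type,
                    "role": "tumor",
                    "tert_stratum": stratum,
                    "mutation_status": status,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def load_promoter_assay() -> pd.DataFrame:
    """Per-sample table of the 114 promoter-mutation assayed cases.

    Synthetic expansion: the per-type assay counts and mutation labels match
    the published aggregates exactly (101 wild-type + 13 mutant = 114; one
    urothelial mutation is C228A, the rest C228T/C250T), and expression
    strata are distributed so that 81 wild-type and 12 mutant cases are
    TERT-expressing.  The identity of the single non-expressing mutant case
    and of the 20 non-expressing wild-type cases is not published; they are
    assigned arbitrarily (the non-expressing mutant is a glioblastoma).
    """
    table = load_cohort_table()
    assayed = table[table["n_wt"].notna()]
    rows = []
    for rec in assayed.itertuples(index=False):
        labels = ["C250T"] * int(rec.n_mut_C250) + ["C228T"] * int(rec.n_mut_C228)
        if rec.tumor_type == "Urothelial carcinoma" and labels:
            labels[-1] = "C228A"  # the one C228A case detected in the assay
        labels += ["wt"] * int(rec.n_wt)
        for i, status in enumerate(labels, start=1):
            rows.append(
                {
                    "sample_id": f"assay_{rec.tumor_type.replace(' ', '_')}_{i:03d}",
                    "tumor_type": rec.tumor_type,
                    "role": "tumor",
                    "mutation_status": status,
                }
            )
    df = pd.DataFrame(rows).set_index("sample_id")
    is_mut = df["mutation_status"] != "wt"
    df["tert_stratum"] = "pos"
    # one non-expressing mutant (assigned to a glioblastoma case)
    gbm_mut = df.index[is_mut & (df["tumor_type"] == "Glioblastoma")]
    df.loc[gbm_mut[0], "tert_stratum"] = "neg"
    # 20 non-expressing wild-type cases, assigned from the end of the table
    wt_ids = df.index[~is_mut]
    df.loc[wt_ids[-20:], "tert_stratum"] = "neg"
    return df[["tumor_type", "role", "tert_stratum", "mutation_status"]]
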