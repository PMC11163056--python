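"""L1 retrotransposon subfamily expression analysis.

Transposable-element instance counts (e.g. from TEcount) are aggregated into
subfamily features — the retrotransposition-competent LINE-1 subfamilies
L1HS and L1PA2 are the expected labels — and compared between sample groups
after normalization with size factors derived from the *gene* count matrix,
so that the handful of TE features cannot distort the library-size estimate.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .differential import DiffConfig, _up_in
from .errors import DataContractError
from .preprocess import size_factors
from .stats import bh_adjust, mann_whitney_u

EXPECTED_SUBFAMILIES = ("L1HS", "L1PA2")


def aggregate_subfamilies(
    te_counts: pd.DataFrame, subfamily: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Sum TE instance counts into per-subfamily totals.

    Returns ``(subfamily_counts, n_instances)``; warns when an expected
    subfamily (L1HS, L1PA2) has no instances.
    """
    labels = subfamily.reindex(te_counts.index)
    if labels.isna().any() or (labels.astype(str).str.strip() == "").any():
        missing = te_counts.index[labels.isna() | (labels.astype(str).str.strip() == "")]
        raise DataContractError(
            f"aggregate_subfamilies: unlabeled instance(s) {list(missing[:5])}"
        )
    totals = te_counts.groupby(labels).sum()
    totals.index.name = "subfamily"
    n_instances = te_counts.groupby(labels).size()
    n_instances.name = "n_instances"
    for expected in EXPECTED_SUBFAMILIES:
        if expected not in totals.index:
            warnings.warn(f"aggregate_subfamilies: no instances of {expected}")
    return totals.loc[sorted(totals.index)], n_instances.loc[sorted(n_instances.index)]


def te_group_compare(
    sub: pd.DataFrame,
    gene_cm: pd.DataFrame,
    ref_ids: Sequence[str],
    alt_ids: Sequence[str],
    cfg: DiffConfig | None = None,
) -> pd.DataFrame:
    """Mann-Whitney comparison of subfamily expression between two groups.

    Size factors are estimated from the gene count matrix only, then applied
    to the TE subfamily counts; p-values are BH-adjusted across the TE
    features (the identity when a single subfamily is tested).
    """
    cfg = cfg or DiffConfig()
    ref_ids, alt_ids = list(ref_ids), list(alt_ids)
    if len(ref_ids) < 2 or len(alt_ids) < 2:
        raise DataContractError("te_group_compare: both groups need >= 2 samples")
    missing = [s for s in ref_ids + alt_ids if s not in sub.columns or s not in gene_cm.columns]
    if missing:
        raise DataContractError(
            f"te_group_compare: sample(s) missing from TE or gene matrix: {missing[:5]}"
        )
    s = size_factors(gene_cm[ref_ids + alt_ids], fallback=True)
    norm = sub[ref_ids + alt_ids].div(s, axis=1)
    records = []
    for sid, row in norm.iterrows():
        a = row[ref_ids].to_numpy(dtype=float)
        b = row[alt_ids].to_numpy(dtype=float)
        tr = mann_whitney_u(a, b)
        records.append((sid, float(a.mean()), float(b.mean()), tr.p_raw))
    res = pd.DataFrame(
        records, columns=["feature_id", "mean_ref", "mean_alt", "p_raw"]
    ).set_index("feature_id")
    res["log2fc"] = np.log2((res["mean_alt"] + 1.0) / (res["mean_ref"] + 1.0))
    res["p_adj"] = bh_adjust(res["p_raw"].to_numpy())
    res["significant"] = res["p_adj"] < cfg.alpha
    res["up_in"] = [
        _up_in(r.mean_ref, r.mean_alt, r.significant) for r in res.itertuples()
    ]
    return res
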