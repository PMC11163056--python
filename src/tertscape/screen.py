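"""Marker-gene stratification and Spearman correlation screens.

Tumor cohorts show a bimodal distribution of telomerase (TERT) expression: a
zero-expression mode and a bell-shaped positive mode.  Samples are classified
TERT+ / TERT- accordingly, the cohort is summarized per tumor type, and the
marker's expression is screened for monotone association against every gene
(or every pathway activation level) with BH-FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataContractError
from .stats import bh_adjust, spearman


@dataclass
class ScreenConfig:
    """Thresholds of the correlation screen.

    ``passes`` requires |rho| strictly greater than ``rho_threshold`` and
    BH-adjusted p below ``alpha``; the ``strong`` tier additionally requires
    |rho| >= ``tf_rho_tier`` (inclusive).
    """

    rho_threshold: float = 0.3
    alpha: float = 0.05
    tf_rho_tier: float = 0.4
    marker_gene: str = "TERT"

    def __post_init__(self) -> None:
        if not (0 < self.rho_threshold <= self.tf_rho_tier <= 1):
            raise ConfigError(
                "require 0 < rho_threshold <= tf_rho_tier <= 1, got "
                f"{self.rho_threshold} and {self.tf_rho_tier}"
            )
        if not (0 < self.alpha <= 1):
            raise ConfigError(f"alpha must be in (0, 1], got {self.alpha}")


def classify_tert(
    cm: pd.DataFrame,
    marker: str = "TERT",
    mode: str = "raw_zero",
    tau: float = 0.0,
    size_factors: pd.Series | None = None,
) -> pd.Series:
    """Assign each sample to the pos/neg marker stratum.

    ``raw_zero`` (default): positive iff the raw marker count exceeds zero.
    ``norm_threshold``: positive iff the size-factor-normalized marker value
    exceeds ``tau``.
    """
    if marker not in cm.index:
        raise DataContractError(f"marker gene {marker!r} absent from count matrix")
    values = cm.loc[marker]
    if mode == "raw_zero":
        pos = values > 0
    elif mode == "norm_threshold":
        if size_factors is None:
            raise ConfigError("norm_threshold mode requires size_factors")
        pos = values / size_factors.reindex(cm.columns) > tau
    else:
        raise ConfigError(f"unknown classify mode {mode!r}")
    out = pd.Series(np.where(pos, "pos", "neg"), index=cm.columns, name="tert_stratum")
    return out


def marker_expression_transform(cm: pd.DataFrame, marker: str = "TERT") -> pd.Series:
    """ln(x + 1) of the marker's per-sample expression, for reporting/plots."""
    if marker not in cm.index:
        raise DataContractError(f"marker gene {marker!r} absent from matrix")
    return np.log1p(cm.loc[marker].astype(float))


def cohort_summary(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-tumor-type stratum and promoter-mutation counts, plus a Total row.

    Columns: n_pos, n_neg, pct_pos, n_mut_C250, n_mut_C228, n_wt, n_total.
    Percentages are rounded to one decimal.  Mutation columns count only
    samples whose mutation status is known (not ``unknown``).
    """
    tumors = samples[samples["role"] == "tumor"] if "role" in samples.columns else samples
    rows = []
    for ttype, grp in sorted(tumors.groupby("tumor_type")) if len(tumors) else []:
        n_pos = int((grp["tert_stratum"] == "pos").sum())
        n_neg = int((grp["tert_stratum"] == "neg").sum())
        n_total = len(grp)
        status = grp["mutation_status"]
        rows.append(
            {
                "tumor_type": ttype,
                "n_pos": n_pos,
                "n_neg": n_neg,
                "pct_pos": round(100.0 * n_pos / n_total, 1) if n_total else 0.0,
                "n_mut_C250": int(status.isin(["C250T", "C250A"]).sum()),
                "n_mut_C228": int(status.isin(["C228T", "C228A"]).sum()),
                "n_wt": int((status == "wt").sum()),
                "n_total": n_total,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "tumor_type", "n_pos", "n_neg", "pct_pos",
            "n_mut_C250", "n_mut_C228", "n_wt", "n_total",
        ],
    )
    total_n = int(out["n_total"].sum())
    total = {
        "tumor_type": "Total",
        "n_pos": int(out["n_pos"].sum()),
        "n_neg": int(out["n_neg"].sum()),
        "pct_pos": round(100.0 * out["n_pos"].sum() / total_n, 1) if total_n else 0.0,
        "n_mut_C250": int(out["n_mut_C250"].sum()),
        "n_mut_C228": int(out["n_mut_C228"].sum()),
        "n_wt": int(out["n_wt"].sum()),
        "n_total": total_n,
    }
    if out.empty:
        return pd.DataFrame([total])
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)


def correlation_screen(
    target: pd.Series,
    features: pd.DataFrame,
    cfg: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Spearman screen of every feature against the target across samples.

    ``features`` is features x samples (genes or pathway activation levels);
    undefined cells (NaN) are handled per feature with pairwise-complete
    samples and the per-feature n is recorded.  BH adjustment runs across
    all *testable* features of the screen; untestable features (fewer than 3
    complete pairs, or constant) are flagged and excluded from the BH family.
    A feature identical in id to the screen's marker gene is excluded
    (no self-correlation).
    """
    cfg = cfg or ScreenConfig()
    shared = [s for s in features.columns if s in target.index]
    if len(shared) < 3:
        raise DataContractError("correlation_screen: fewer than 3 shared samples")
    target = target.loc[shared].astype(float)
    features = features.loc[features.index != cfg.marker_gene, shared]

    records = []
    for fid, row in features.iterrows():
        vals = row.to_numpy(dtype=float)
        mask = np.isfinite(vals) & np.isfinite(target.to_numpy())
        n = int(mask.sum())
        if n < 3 or len(np.unique(vals[mask])) < 2 or len(np.unique(target.to_numpy()[mask])) < 2:
            records.append({"feature_id": fid, "rho": np.nan, "p_raw": np.nan,
                            "n": n, "testable": False})
            continue
        rho, p = spearman(vals[mask], target.to_numpy()[mask])
        records.append({"feature_id": fid, "rho": rho, "p_raw": p, "n": n, "testable": True})
    res = pd.DataFrame(records, columns=["feature_id", "rho", "p_raw", "n", "testable"])
    res["p_adj"] = np.nan
    testable = res["testable"].to_numpy()
    if testable.any():
        res.loc[testable, "p_adj"] = bh_adjust(res.loc[testable, "p_raw"].to_numpy())
    res["direction"] = np.where(res["rho"] >= 0, "pos", "neg")
    res["passes"] = (
        testable
        & (res["rho"].abs() > cfg.rho_threshold)
        & (res["p_adj"] < cfg.alpha)
    )
    res["tier"] = np.where(
        res["passes"] & (res["rho"].abs() >= cfg.tf_rho_tier), "strong", "standard"
    )
    return res.set_index("feature_id")


def annotate_tf(results: pd.DataFrame, tf_list) -> pd.DataFrame:
    """Split screen results into transcription-factor and non-TF partitions.

    Adds an ``is_tf`` column; counts of passing features by direction within
    the TF partition are available via :func:`tf_counts`.
    """
    tf_set = set(tf_list)
    if not tf_set:
        raise DataContractError("annotate_tf: empty TF list")
    out = results.copy()
    out["is_tf"] = out.index.isin(tf_set)
    return out


def tf_counts(annotated: pd.DataFrame) -> dict[str, int]:
    """Counts of passing TF features by correlation direction."""
    tf_pass = annotated[annotated["is_tf"] & annotated["passes"]]
    return {
        "n_tf_pass": int(len(tf_pass)),
        "n_tf_pos": int((tf_pass["direction"] == "pos").sum()),
        "n_tf_neg": int((tf_pass["direction"] == "neg").sum()),
        "n_tf_strong": int((tf_pass["tier"] == "strong").sum()),
    }
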