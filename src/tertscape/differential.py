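"""Differential genes and pathways between sample groups, plus gene-set
over-representation of the resulting lists.

Group comparisons use the two-sided Mann-Whitney U test per feature with
BH-FDR across the tested family.  For genes, significance additionally
requires an absolute log2 fold change above ``lfc_threshold`` (default 1,
i.e. fold change 2); pathway activation levels are compared on their own
scale with no fold-change rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataContractError
from .io import PathwayLibrary
from .stats import bh_adjust, hypergeom_enrich, mann_whitney_u


@dataclass
class DiffConfig:
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    reference_group: str = "neg"

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ConfigError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.lfc_threshold <= 0:
            raise ConfigError("lfc_threshold must be > 0")


def log2fc(mean_ref: float, mean_alt: float, pseudocount: float = 1.0) -> float:
    """log2 fold change of alt over ref with a pseudocount guarding zeros."""
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be > 0")
    return float(np.log2((mean_alt + pseudocount) / (mean_ref + pseudocount)))


DIFF_COLUMNS = [
    "mean_ref", "mean_alt", "log2fc", "p_raw", "p_adj", "significant", "up_in",
]


def _up_in(mean_ref: float, mean_alt: float, significant: bool) -> str:
    if not significant:
        return "none"
    return "alt" if mean_alt > mean_ref else "ref"


def differential_genes(
    nm: pd.DataFrame,
    ref_ids: Sequence[str],
    alt_ids: Sequence[str],
    cfg: DiffConfig | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene Mann-Whitney comparison of two sample groups.

    ``nm`` is a genes x samples matrix of normalized expression.  A gene is
    significant when its BH-adjusted p is below ``cfg.alpha`` *and*
    |log2fc| exceeds ``cfg.lfc_threshold``.
    """
    cfg = cfg or DiffConfig()
    ref_ids, alt_ids = list(ref_ids), list(alt_ids)
    if len(ref_ids) < 2 or len(alt_ids) < 2:
        raise DataContractError("differential_genes: both groups need >= 2 samples")
    ref = nm[ref_ids].to_numpy(dtype=float)
    alt = nm[alt_ids].to_numpy(dtype=float)
    records = []
    for i, gene in enumerate(nm.index):
        tr = mann_whitney_u(ref[i], alt[i])
        m_ref, m_alt = float(ref[i].mean()), float(alt[i].mean())
        records.append((gene, m_ref, m_alt, log2fc(m_ref, m_alt, pseudocount), tr.p_raw))
    res = pd.DataFrame(
        records, columns=["feature_id", "mean_ref", "mean_alt", "log2fc", "p_raw"]
    ).set_index("feature_id")
    res["p_adj"] = bh_adjust(res["p_raw"].to_numpy())
    res["significant"] = (res["p_adj"] < cfg.alpha) & (res["log2fc"].abs() > cfg.lfc_threshold)
    res["up_in"] = [
        _up_in(r.mean_ref, r.mean_alt, r.significant) for r in res.itertuples()
    ]
    return res[DIFF_COLUMNS]


def differential_pal(
    pal: pd.DataFrame,
    ref_ids: Sequence[str],
    alt_ids: Sequence[str],
    cfg: DiffConfig | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-pathway Mann-Whitney comparison of PAL between two groups.

    Undefined PAL cells (NaN) are dropped per pathway; a pathway whose
    defined cells leave either group below 2 samples is untestable — it is
    excluded from the BH family and returned in the second element.
    Significance is ``p_adj < alpha`` (no fold-change rule); ``delta_pal``
    is mean(alt) - mean(ref) and ``up_in`` is the group with the larger
    mean PAL.
    """
    cfg = cfg or DiffConfig()
    ref_ids, alt_ids = list(ref_ids), list(alt_ids)
    if len(ref_ids) < 2 or len(alt_ids) < 2:
        raise DataContractError("differential_pal: both groups need >= 2 samples")
    records, untestable = [], []
    for pid, row in pal.iterrows():
        a = row[ref_ids].dropna().to_numpy(dtype=float)
        b = row[alt_ids].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            untestable.append(pid)
            continue
        tr = mann_whitney_u(a, b)
        records.append((pid, float(a.mean()), float(b.mean()), tr.p_raw, len(a), len(b)))
    res = pd.DataFrame(
        records,
        columns=["feature_id", "mean_ref", "mean_alt", "p_raw", "n_ref", "n_alt"],
    ).set_index("feature_id")
    if len(res):
        res["p_adj"] = bh_adjust(res["p_raw"].to_numpy())
    else:
        res["p_adj"] = pd.Series(dtype=float)
    res["delta_pal"] = res["mean_alt"] - res["mean_ref"]
    res["significant"] = res["p_adj"] < cfg.alpha
    res["up_in"] = [
        _up_in(r.mean_ref, r.mean_alt, r.significant) for r in res.itertuples()
    ]
    return res, untestable


def enrich_list(
    gene_list: Iterable[str],
    library: PathwayLibrary | Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list against a library.

    ``library`` may be a signed pathway library (roles are ignored here) or
    a plain mapping term -> gene collection.  Terms are BH-adjusted as one
    family and ranked by adjusted p.
    """
    universe = set(universe)
    gene_list = set(gene_list)
    if not gene_list:
        return pd.DataFrame(
            columns=["term_id", "overlap", "term_size", "p_raw", "p_adj", "flagged"]
        ).set_index("term_id")
    if not gene_list <= universe:
        raise DataContractError("enrich_list: gene list not a subset of universe")
    terms = library.pathways if isinstance(library, PathwayLibrary) else library
    records = []
    for term_id, members in terms.items():
        term_genes = set(members) & universe
        tr = hypergeom_enrich(gene_list, term_genes, universe)
        records.append((term_id, int(tr.statistic), len(term_genes), tr.p_raw))
    res = pd.DataFrame(
        records, columns=["term_id", "overlap", "term_size", "p_raw"]
    ).set_index("term_id")
    res["p_adj"] = bh_adjust(res["p_raw"].to_numpy())
    res["flagged"] = res["p_adj"] < alpha
    return res.sort_values(["p_adj", "p_raw"])


def group_report(diff_genes: pd.DataFrame | None, diff_pal: pd.DataFrame | None) -> dict[str, int]:
    """Counts of significant features by direction across both analyses."""

    def _counts(df: pd.DataFrame | None, prefix: str) -> dict[str, int]:
        if df is None or df.empty:
            return {f"{prefix}_up_alt": 0, f"{prefix}_up_ref": 0, f"{prefix}_total": 0}
        sig = df[df["significant"]]
        up_alt = int((sig["up_in"] == "alt").sum())
        up_ref = int((sig["up_in"] == "ref").sum())
        return {
            f"{prefix}_up_alt": up_alt,
            f"{prefix}_up_ref": up_ref,
            f"{prefix}_total": up_alt + up_ref,
        }

    report = {}
    report.update(_counts(diff_genes, "genes"))
    report.update(_counts(diff_pal, "pathways"))
    return report
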