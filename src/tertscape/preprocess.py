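"""Sample QC, gene-id aggregation, library-size normalization and CNR.

The case-to-normal ratio (CNR) of a gene is its (normalized) expression in a
tumor sample divided by the average expression of the same gene across the
tissue-matched control group.  CNRs are the input of pathway activation
scoring: CNR > 1 means the gene is elevated relative to normal tissue.

Normalization uses the DESeq2-style median-of-ratios method: each sample's
size factor is the median, over genes with all-positive counts, of the ratio
of that sample's count to the gene's geometric mean across samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataContractError
from . import io as tio


def qc_filter_samples(
    cm: pd.DataFrame, min_gene_mapped_reads: int = 3_500_000
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop samples whose total gene-mapped reads fall below the threshold.

    The boundary is inclusive: a sample with exactly ``min_gene_mapped_reads``
    is retained.  Returns the filtered matrix and a per-sample report with
    columns ``gene_mapped_reads`` and ``retained``.
    """
    if min_gene_mapped_reads < 0:
        raise DataContractError("min_gene_mapped_reads must be >= 0")
    totals = cm.sum(axis=0)
    retained = totals >= min_gene_mapped_reads
    report = pd.DataFrame(
        {"gene_mapped_reads": totals, "retained": retained}
    )
    report.index.name = "sample_id"
    return cm.loc[:, retained[retained].index], report


def aggregate_gene_ids(
    cm: pd.DataFrame, id_map: pd.Series, unmapped: str = "drop"
) -> pd.DataFrame:
    """Convert source gene ids (e.g. Ensembl) to target symbols (e.g. HGNC).

    Counts of all source ids sharing a target symbol are summed, preserving
    the total of gene-mapped reads.  With ``unmapped='drop'`` sources absent
    from the map are removed; with ``'keep'`` they keep their original id.
    """
    if unmapped not in ("drop", "keep"):
        raise DataContractError(f"unmapped must be 'drop' or 'keep', got {unmapped!r}")
    target = cm.index.to_series().map(id_map)
    if unmapped == "keep":
        target = target.fillna(cm.index.to_series())
    keep = target.notna()
    out = cm.loc[keep].groupby(target[keep]).sum()
    out.index.name = "gene_id"
    return out.loc[sorted(out.index)]


def size_factors(cm: pd.DataFrame, fallback: bool = False) -> pd.Series:
    """Median-of-ratios size factors (the DESeq2 normalization method).

    For each sample j, ``s_j = median_g( c_gj / geomean_g )`` over genes g
    with strictly positive counts in every sample, where ``geomean_g`` is the
    gene's geometric mean across samples.

    When no gene is positive in all samples the default is to raise with a
    hint; with ``fallback=True`` the reference set becomes genes positive in
    at least half of the samples, with the geometric mean taken over the
    positive entries only and per-sample medians over that sample's positive
    members of the reference set.
    """
    if cm.shape[1] == 0:
        raise DataContractError("size_factors: empty matrix")
    counts = cm.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if all_positive.any():
        sub = counts[all_positive]
        log_geomean = np.log(sub).mean(axis=1)
        ratios = np.log(sub) - log_geomean[:, None]
        s = np.exp(np.median(ratios, axis=0))
    else:
        if not fallback:
            raise DataContractError(
                "size_factors: no gene has positive counts in every sample; "
                "re-run with fallback=True to use the pseudo-reference over "
                "genes positive in >=50% of samples"
            )
        positive = counts > 0
        ref_set = positive.mean(axis=1) >= 0.5
        if not ref_set.any():
            raise DataContractError(
                "size_factors: fallback failed, no gene positive in >=50% of samples"
            )
        sub = counts[ref_set]
        pos = sub > 0
        with np.errstate(divide="ignore"):
            logs = np.where(pos, np.log(np.where(pos, sub, 1.0)), np.nan)
        log_geomean = np.nanmean(logs, axis=1)
        ratios = logs - log_geomean[:, None]
        s = np.exp(np.nanmedian(ratios, axis=0))
    if not np.all(np.isfinite(s)) or (s <= 0).any():
        raise DataContractError("size_factors: non-positive or non-finite factor")
    return pd.Series(s, index=cm.columns, name="size_factor")


def normalize(cm: pd.DataFrame, s: pd.Series | None = None, fallback: bool = False) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    if s is None:
        s = size_factors(cm, fallback=fallback)
    return cm.div(s, axis=1)


def cnr(
    nm: pd.DataFrame,
    samples: pd.DataFrame,
    pseudocount: float = 1.0,
    control_average: str = "arithmetic",
) -> pd.DataFrame:
    """Case-to-normal ratios of every gene for every tumor sample.

    ``CNR_nj = (x_nj + a) / (avg over same-tumor-type controls of x_n + a)``
    with pseudocount ``a`` (default 1) guarding zeros on both sides.  The
    control average is the arithmetic mean by default; ``'geometric'`` is
    available.  Every tumor sample's tumor type must have at least one
    control sample in the matrix.
    """
    tio.validate_sample_table(samples)
    if control_average not in ("arithmetic", "geometric"):
        raise DataContractError(f"unknown control_average {control_average!r}")
    common = [s for s in samples.index if s in nm.columns]
    samples = samples.loc[common]
    tumors = samples[samples["role"] == "tumor"]
    controls = samples[samples["role"] == "control"]

    columns = {}
    for ttype, group in tumors.groupby("tumor_type", sort=False):
        ctrl_ids = controls[controls["tumor_type"] == ttype].index
        if len(ctrl_ids) == 0:
            raise DataContractError(
                f"cnr: tumor type {ttype!r} has no control samples"
            )
        ctrl = nm[list(ctrl_ids)]
        if control_average == "arithmetic":
            ref = ctrl.mean(axis=1)
        else:
            ref = np.exp(np.log(ctrl.clip(lower=np.nextafter(0, 1))).mean(axis=1))
        denom = ref + pseudocount
        if (denom <= 0).any():
            raise DataContractError(
                "cnr: zero control average with zero pseudocount; "
                "set pseudocount > 0"
            )
        for sid in group.index:
            columns[sid] = (nm[sid] + pseudocount) / denom
    out = pd.DataFrame(columns)
    out = out.loc[:, [s for s in tumors.index if s in out.columns]]
    out.index.name = "gene_id"
    values = out.to_numpy()
    if values.size and (not np.all(np.isfinite(values)) or (values <= 0).any()):
        raise DataContractError("cnr: non-positive or non-finite ratio produced")
    return out
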