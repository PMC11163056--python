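"""Pathway activation level (PAL) scoring.

PAL summarizes the coordinated up/down-regulation of a pathway's member
genes in one tumor sample relative to normal tissue:

    PAL_p = 100 * sum_n ARR_np * log10(CNR_n) / sum_n |ARR_np|

where CNR_n is the case-to-normal ratio of member gene n and ARR_np is the
gene's activator/repressor role in pathway p (+1 activator, -1 inhibitor,
0 ambiguous).  Positive PAL means the pathway is upregulated versus normal
tissue, negative means downregulated, and the magnitude reflects the extent.

The denominator uses the sum of |ARR| so that PAL is a weighted mean of
signed log-ratios; genes with ARR = 0 contribute to neither sum.  A literal
"as-printed" denominator (sum of ARR without modulus) is available for
comparison but is ill-posed for repressor-rich pathways and is not the
default.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataContractError
from .io import PathwayLibrary


def pal_score(
    cnr_vec: Mapping[str, float],
    pathway: Mapping[str, int],
    as_printed: bool = False,
) -> float:
    """PAL of one pathway in one sample; NaN when undefined.

    The sums run over the member genes present in ``cnr_vec``.  The score is
    undefined (NaN, with a warning) when no member gene with a non-zero role
    is present — i.e. when the denominator is zero.
    """
    num = 0.0
    denom = 0.0
    for gene, role in pathway.items():
        if role == 0 or gene not in cnr_vec:
            continue
        value = cnr_vec[gene]
        if not np.isfinite(value) or value <= 0:
            raise DataContractError(f"pal_score: CNR for {gene!r} must be finite and > 0")
        num += role * np.log10(value)
        denom += role if as_printed else abs(role)
    if denom == 0:
        warnings.warn("pal_score: zero denominator (no non-neutral member genes present)")
        return float("nan")
    return 100.0 * num / denom


def pal_matrix(
    cnr: pd.DataFrame,
    lib: PathwayLibrary,
    min_coverage: int = 1,
    as_printed: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PAL of every pathway in every sample, plus a coverage sidecar.

    Coverage counts the pathway's member genes found in the CNR matrix
    (regardless of role).  Cells whose coverage falls below ``min_coverage``
    — or whose denominator is zero — are undefined and reported as NaN,
    never silently 0.

    Returns ``(pal, coverage)``, both pathways x samples.
    """
    if min_coverage < 1:
        raise DataContractError("min_coverage must be >= 1")
    if len(lib) == 0:
        raise DataContractError("pal_matrix: empty pathway library")
    log_cnr = np.log10(cnr.to_numpy(dtype=float))
    gene_pos = {g: i for i, g in enumerate(cnr.index)}
    n_samples = cnr.shape[1]

    pal_rows = np.full((len(lib), n_samples), np.nan)
    cov_rows = np.zeros((len(lib), n_samples), dtype=np.int64)
    pathway_ids = list(lib.pathways)
    for r, pid in enumerate(pathway_ids):
        members = lib.pathways[pid]
        present = [(gene_pos[g], role) for g, role in members.items() if g in gene_pos]
        cov_rows[r, :] = len(present)
        if len(present) < min_coverage:
            continue
        idx = np.array([i for i, _ in present], dtype=np.intp)
        roles = np.array([role for _, role in present], dtype=float)
        denom = roles.sum() if as_printed else np.abs(roles).sum()
        if denom == 0:
            continue
        pal_rows[r, :] = 100.0 * (roles @ log_cnr[idx, :]) / denom

    pal = pd.DataFrame(pal_rows, index=pathway_ids, columns=cnr.columns)
    pal.index.name = "pathway_id"
    coverage = pd.DataFrame(cov_rows, index=pathway_ids, columns=cnr.columns)
    coverage.index.name = "pathway_id"
    return pal, coverage
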