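"""Statistical primitives shared by the screening and differential stages.

Thin, contract-checked wrappers around scipy.stats and statsmodels:
Spearman rank correlation with a t-approximation p-value, the two-sided
Mann-Whitney U test (exact by enumeration for small tie-free groups, normal
approximation with tie and continuity corrections otherwise),
Benjamini-Hochberg step-up FDR adjustment, and the one-sided hypergeometric
over-representation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DataContractError

EXACT_MWU_MAX_N = 8


@dataclass
class TestResult:
    statistic: float
    p_raw: float
    method: str
    n_per_group: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0):
            raise DataContractError(f"p-value {self.p_raw} outside [0, 1]")


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with a two-sided t-approximation p-value.

    Ties receive average ranks.  Requires n >= 3 and at least two distinct
    values in each vector; |rho| = 1 yields p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataContractError("spearman: x and y must be 1-d of equal length")
    n = len(x)
    if n < 3:
        raise DataContractError("spearman: need n >= 3")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise DataContractError("spearman: constant vector")
    rho, p = sps.spearmanr(x, y)
    rho = float(rho)
    if abs(rho) >= 1.0 - 1e-12:  # perfect monotone up to float noise
        return float(np.sign(rho)), 0.0
    return rho, float(p)


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    The p-value is exact (full enumeration of labelings) when both groups
    have at most 8 observations and the pooled data are tie-free; otherwise
    the normal approximation with tie correction and continuity correction
    is used.  Identical constant groups give the null-expectation U with
    p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DataContractError("mann_whitney_u: empty group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:  # zero variance: U at its null expectation
        return TestResult(len(a) * len(b) / 2.0, 1.0, "degenerate", (len(a), len(b)))
    no_ties = len(np.unique(pooled)) == len(pooled)
    if no_ties and len(a) <= EXACT_MWU_MAX_N and len(b) <= EXACT_MWU_MAX_N:
        method = "exact"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    p = min(1.0, float(res.pvalue))
    return TestResult(float(res.statistic), p, method, (len(a), len(b)))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise DataContractError("bh_adjust: expected a 1-d vector")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataContractError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(query: set, term: set, universe: set) -> TestResult:
    """One-sided (upper-tail) hypergeometric over-representation test.

    Probability of observing at least the actual overlap between ``query``
    and ``term`` when drawing |query| genes without replacement from
    ``universe``.
    """
    query, term, universe = set(query), set(term), set(universe)
    if not query <= universe:
        raise DataContractError("hypergeom_enrich: query not a subset of universe")
    if not term <= universe:
        raise DataContractError("hypergeom_enrich: term not a subset of universe")
    k = len(query & term)
    p = float(sps.hypergeom.sf(k - 1, len(universe), len(term), len(query)))
    p = min(1.0, max(0.0, p))
    return TestResult(float(k), p, "hypergeometric", (len(query), len(term)))
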