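"""Cohort-level statistics: paired tests, group tests and the V40 regression.

The behaviour contracts (exact small-sample signed-rank distribution,
tie-corrected Kruskal-Wallis, OLS with a two-sided t-test on the slope)
are delegated to scipy; independent oracles live in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = ["RegressionResult", "wilcoxon_paired", "kruskal_wallis", "regress_v40_benefit"]

EXACT_WILCOXON_MAX_N = 25


def wilcoxon_paired(differences: Sequence[float]) -> Tuple[float, Dict[str, float]]:
    """Two-sided Wilcoxon signed-rank test of median zero.

    Zero differences are dropped; exact null distribution for n <= 25 after
    zero removal (when untied), normal approximation with continuity
    correction otherwise.  Returns (p, summary).
    """
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("need at least one non-missing difference")
    nz = d[d != 0]
    summary: Dict[str, float] = {
        "n": int(d.size),
        "n_nonzero": int(nz.size),
        "median_difference": float(np.median(d)),
    }
    if nz.size == 0:
        summary["note"] = "all differences zero"
        return 1.0, summary
    has_ties = np.unique(np.abs(nz)).size < nz.size
    if nz.size <= EXACT_WILCOXON_MAX_N and not has_ties:
        res = sps.wilcoxon(nz, alternative="two-sided", method="exact")
    else:
        res = sps.wilcoxon(nz, alternative="two-sided", method="approx", correction=True)
    summary["statistic"] = float(res.statistic)
    return float(res.pvalue), summary


def kruskal_wallis(*groups: Sequence[float]) -> Tuple[float, float]:
    """Kruskal-Wallis H test across plan sets; returns (p, H).

    Standard tie-corrected H with a chi-square p-value.  Identical groups
    yield H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group must be nonempty")
    if all(np.array_equal(a, arrs[0]) for a in arrs[1:]) and np.ptp(arrs[0]) == 0:
        return 1.0, 0.0
    try:
        h, p = sps.kruskal(*arrs)
    except ValueError:  # all values identical across groups
        return 1.0, 0.0
    return float(p), float(h)


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of the bowel-bag V40 benefit against the library-strategy V40.

    ``orientation`` records the sign convention of the dependent variable:
    online minus library, so a negative slope means the online benefit grows
    with the library-strategy bowel dose.
    """

    slope: float
    intercept: float
    p_value: float
    r_squared: float
    n: int
    orientation: str = "difference = V40(online) - V40(LOP)"

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("R^2 must lie in [0, 1]")


def regress_v40_benefit(
    v40_lop: Sequence[float],
    v40_online: Sequence[float],
) -> RegressionResult:
    """Per-fraction OLS of (V40 online - V40 LOP) on V40 LOP (cm^3).

    Two-sided t-test on the slope; R^2 from the Pearson correlation.
    """
    x = np.asarray(v40_lop, dtype=float)
    y_online = np.asarray(v40_online, dtype=float)
    if x.shape != y_online.shape:
        raise ValueError("paired inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor: slope undefined")
    y = y_online - x
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        r_squared=float(fit.rvalue**2),
        n=int(x.size),
    )
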