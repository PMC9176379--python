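"""Cohort-level screening statistics.

Candidate optical parameters are screened against a target (e.g. ultrasound
SATT) with rank or product-moment correlations under a Bonferroni-corrected
significance threshold (alpha/n_tests), and a parameter is *retained* for
downstream modelling only if it is both significant and explains more than
half the target's variance (r^2 > 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "screen_parameters",
    "ttest_two_sample",
]

R2_RETENTION_THRESHOLD = 0.5


@dataclass(frozen=True)
class CorrelationResult:
    """Screening outcome for one candidate parameter."""

    parameter: str
    method: str  # "spearman" | "pearson"
    r: float
    r_squared: float
    p_value: float
    n: int
    alpha_adjusted: float
    significant: bool
    retained: bool
    defined: bool = True  # False for constant columns


def _permutation_p(x: np.ndarray, y: np.ndarray, method: str, n_perm: int, seed: int):
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    observed = abs(corr(x, y).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if abs(corr(x, rng.permutation(y)).statistic) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def screen_parameters(
    cohort: pd.DataFrame,
    parameters: Sequence[str],
    target: str,
    method: str = "spearman",
    n_tests: int | None = None,
    alpha: float = 0.05,
    permutation: bool = False,
    n_perm: int = 999,
    seed: int = 0,
) -> list[CorrelationResult]:
    """Correlate each parameter column against ``target`` with retention flags.

    p-values use the t-approximation (adequate at cohort-scale n); set
    ``permutation=True`` for an exact-style permutation p at small n.
    ``n_tests`` defaults to the number of parameters screened.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    n_tests = len(parameters) if n_tests is None else int(n_tests)
    alpha_adj = alpha / n_tests

    results = []
    for name in parameters:
        pair = cohort[[name, target]].dropna()
        x = pair[name].to_numpy(float)
        y = pair[target].to_numpy(float)
        n = x.size
        if n < 5:
            raise ValueError(f"parameter {name!r}: need >= 5 complete pairs")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            results.append(
                CorrelationResult(
                    parameter=name, method=method, r=float("nan"),
                    r_squared=float("nan"), p_value=float("nan"), n=n,
                    alpha_adjusted=alpha_adj, significant=False, retained=False,
                    defined=False,
                )
            )
            continue
        if method == "spearman":
            res = stats.spearmanr(x, y)  # average ranks on ties
        else:
            res = stats.pearsonr(x, y)
        r = float(res.statistic)
        p = float(res.pvalue)
        if permutation:
            p = _permutation_p(x, y, method, n_perm, seed)
        significant = p < alpha_adj
        retained = significant and r * r > R2_RETENTION_THRESHOLD
        results.append(
            CorrelationResult(
                parameter=name, method=method, r=r, r_squared=r * r,
                p_value=p, n=n, alpha_adjusted=alpha_adj,
                significant=significant, retained=retained,
            )
        )
    return results


def ttest_two_sample(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Pooled-variance two-sample t-test; returns (t, two-sided p).

    Two identical-mean groups with zero pooled variance return (0, 1) by
    convention rather than an undefined statistic.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf if a.mean() > b.mean() else -np.inf), 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)
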