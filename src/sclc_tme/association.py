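"""Rank correlations and non-parametric group comparisons.

The cohort's density variables are far from normal (heavy right tails,
compartment-specific dropout), so every comparison here is rank-based:
Spearman's r_s / Kendall's tau-b for marker-marker association, the
Mann-Whitney U test for unpaired two-group density or expression contrasts,
and the Wilcoxon matched-pairs signed-rank test for core A vs core B
replicate agreement.  Missing values are removed pairwise per comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: correlation-strength bands (|r| upper bounds) used only for reporting
STRENGTH_BANDS = ((0.4, "weak"), (0.7, "moderate"), (np.inf, "strong"))


@dataclass(frozen=True)
class CorrelationResult:
    variable_a: str
    variable_b: str
    method: str
    coefficient: float
    p_value: float
    n: int

    @property
    def strength(self) -> str:
        if not np.isfinite(self.coefficient):
            return "undefined"
        for bound, label in STRENGTH_BANDS:
            if abs(self.coefficient) < bound or bound is np.inf:
                return label
        return "strong"


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def rank_correlation(
    x,
    y,
    method: str = "spearman",
    name_a: str = "x",
    name_b: str = "y",
) -> CorrelationResult:
    """Spearman (midrank ties) or Kendall tau-b correlation with two-sided p.

    Missing values are removed pairwise; a constant input vector yields an
    undefined (NaN) coefficient with a warning rather than an error.
    """
    if method not in ("spearman", "kendall_tau_b"):
        raise ValueError(f"unknown method: {method!r}")
    xv, yv = _pairwise_complete(x, y)
    n = len(xv)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        warnings.warn("constant input vector; correlation undefined", stacklevel=2)
        return CorrelationResult(name_a, name_b, method, np.nan, np.nan, n)
    if method == "spearman":
        res = stats.spearmanr(xv, yv)
    else:
        res = stats.kendalltau(xv, yv, variant="b")
    return CorrelationResult(
        name_a, name_b, method, float(res.statistic), float(res.pvalue), n
    )


def correlation_matrix(
    wide: pd.DataFrame, method: str = "spearman"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs correlation grid over the columns of a samples x variables
    table; returns (coefficients, p_values) DataFrames.

    The grid mirrors the marker x compartment correlation tables: unadjusted
    p-values, pairwise-complete observations.
    """
    cols = list(wide.columns)
    k = len(cols)
    coef = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    for i in range(k):
        coef[i, i] = 1.0
        pval[i, i] = 0.0
        for j in range(i + 1, k):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r = rank_correlation(
                        wide[cols[i]], wide[cols[j]], method, cols[i], cols[j]
                    )
                coef[i, j] = coef[j, i] = r.coefficient
                pval[i, j] = pval[j, i] = r.p_value
            except ValueError:
                pass
    return (
        pd.DataFrame(coef, index=cols, columns=cols),
        pd.DataFrame(pval, index=cols, columns=cols),
    )


def two_group_test(a, b, method: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U test; returns (U statistic of group a, two-sided p).

    ``method``: ``exact`` enumerates the permutation distribution (only valid
    without ties), ``asymptotic`` uses the normal approximation with tie
    correction and continuity correction, ``auto`` (default) picks exact when
    both groups have at most 8 observations and there are no ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else (
            "asymptotic"
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def paired_replicate_test(core_a, core_b) -> tuple[float, float]:
    """Wilcoxon matched-pairs signed-rank test between replicate cores.

    Zero differences are dropped.  If every pair is tied the
    statistic is 0 and p = 1 with a warning (no evidence of a replicate
    effect, but also no information).
    Returns (W = sum of ranks of positive differences, two-sided p).
    """
    a = np.asarray(core_a, dtype=float)
    b = np.asarray(core_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided")
    w_pos, _ = signed_rank_sums(d)
    return w_pos, float(res.pvalue)


def signed_rank_sums(diffs) -> tuple[float, float]:
    """(W+, W-) rank sums of the nonzero paired differences.

    scipy reports only min-tailed variants depending on version; this helper
    makes both tails explicit for reporting.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d) & (d != 0)]
    if len(d) == 0:
        return 0.0, 0.0
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), float(ranks[d < 0].sum())
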