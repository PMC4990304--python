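"""Trend tests across ordered dose groups and association descriptives.

The trend statistic is the Cochran-Armitage-type chi-square (1 df) for a
linear trend in proportions across scored dose groups,

    T = sum_i y_i (s_i - s_bar),
    chi2 = T^2 / [ pbar (1 - pbar) * sum_i n_i (s_i - s_bar)^2 ] * c,

where s_bar is the n-weighted mean score, pbar the pooled proportion, and
c = (N-1)/N for the linear-by-linear normalization (default) or 1 for the
classical Cochran-Armitage form.  Scores default to integer group ranks;
geometric-mean doses are an option — the choice is explicit because printed
trend statistics depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TrendResult",
    "AssociationResult",
    "linear_trend_test",
    "pearson_correlation",
    "stepwise_regression",
]


@dataclass(frozen=True)
class TrendResult:
    chi2: float
    p: float
    score_convention: str
    normalization: str

    def __post_init__(self):
        if self.chi2 < 0 or not 0.0 <= self.p <= 1.0:
            raise ValueError("invalid trend-test result")


@dataclass(frozen=True)
class AssociationResult:
    """Pearson correlation and, for regressions, retained coefficients."""

    r: float
    p: float
    n: int
    coefficients: dict | None = None
    coefficient_p: dict | None = None

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of range: {self.r}")


def linear_trend_test(table, scores: str = "rank",
                      normalization: str = "n-1") -> TrendResult:
    """Chi-square test (1 df) for a linear trend in group prevalences.

    Parameters
    ----------
    table
        DoseGroupTable or (n, positives) arrays; groups with n = 0 drop out.
    scores
        "rank" (1..k, default), "dose" (the group GM doses), or an explicit
        sequence of scores.  The statistic is invariant to affine rescaling.
    normalization
        "n-1" for the linear-by-linear form (default) or "n" for the
        classical Cochran-Armitage scaling.
    """
    if hasattr(table, "n"):
        n = np.asarray(table.n, float)
        y = np.asarray(table.positives, float)
        doses = np.asarray(table.doses, float)
    else:
        n, y = (np.asarray(v, float) for v in table)
        doses = None
    if isinstance(scores, str):
        if scores == "rank":
            s = np.arange(1.0, len(n) + 1.0)
        elif scores == "dose":
            if doses is None:
                raise ValueError("dose scores need a table with doses")
            s = doses.copy()
        else:
            raise ValueError(f"unknown score convention {scores!r}")
        convention = scores
    else:
        s = np.asarray(scores, float)
        convention = "custom"
    if normalization not in ("n-1", "n"):
        raise ValueError(f"unknown normalization {normalization!r}")

    keep = n > 0
    n, y, s = n[keep], y[keep], s[keep]
    if len(n) < 2:
        raise ValueError("need at least 2 non-empty groups")
    N, Y = n.sum(), y.sum()
    pbar = Y / N
    if pbar in (0.0, 1.0):
        # no outcome variance: no evidence of trend
        return TrendResult(0.0, 1.0, convention, normalization)
    sbar = np.sum(n * s) / N
    t = np.sum(y * (s - sbar))
    var = pbar * (1.0 - pbar) * np.sum(n * (s - sbar) ** 2)
    if var == 0:
        return TrendResult(0.0, 1.0, convention, normalization)
    chi2 = t * t / var
    if normalization == "n-1":
        chi2 *= (N - 1.0) / N
    p = float(stats.chi2.sf(chi2, 1))
    return TrendResult(float(chi2), p, convention, normalization)


def pearson_correlation(x, y) -> AssociationResult:
    """Pearson r with its t-distribution two-sided p-value.

    Pairs with a missing member are excluded; constant input is an error
    (the correlation is undefined).
    """
    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if xa.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(xa, ya)
    return AssociationResult(r=float(r), p=float(p), n=int(xa.size))


def stepwise_regression(records: pd.DataFrame, response: str,
                        predictors=("age", "ucd"), entry_p: float = 0.05,
                        removal_p: float = 0.10) -> AssociationResult:
    """Forward-stepwise OLS with backward removal.

    At each step the candidate with the smallest coefficient p-value enters
    if p <= ``entry_p``; included predictors with p > ``removal_p`` are then
    removed.  If nothing enters, the coefficient set is empty (reported
    explicitly, not an error).  Complete cases only.
    """
    cols = [response, *predictors]
    data = records.loc[:, cols].dropna()
    if len(data) < 30:
        raise ValueError(f"need at least 30 complete records, got {len(data)}")
    yv = data[response].to_numpy(float)

    def design(included):
        return sm.add_constant(data.loc[:, included].to_numpy(float)) \
            if included else np.ones((len(data), 1))

    def fit(included):
        return sm.OLS(yv, design(included)).fit()

    included: list[str] = []
    while True:
        changed = False
        candidates = [p for p in predictors if p not in included]
        best = None
        base_rank = np.linalg.matrix_rank(design(included))
        for cand in candidates:
            X = design(included + [cand])
            if np.linalg.matrix_rank(X) <= base_rank:
                continue  # adds no variance (collinear with what is in)
            res = fit(included + [cand])
            p_val = res.pvalues[-1]
            if p_val <= entry_p and (best is None or p_val < best[0]):
                best = (p_val, cand)
        if best is not None:
            included.append(best[1])
            changed = True
        if included:
            res = fit(included)
            worst = max(range(len(included)), key=lambda i: res.pvalues[i + 1])
            if res.pvalues[worst + 1] > removal_p:
                del included[worst]
                changed = True
        if not changed:
            break

    if not included:
        return AssociationResult(r=0.0, p=1.0, n=len(data),
                                 coefficients={}, coefficient_p={})
    res = fit(included)
    coefs = {"intercept": float(res.params[0])}
    pvals = {"intercept": float(res.pvalues[0])}
    for i, name in enumerate(included):
        coefs[name] = float(res.params[i + 1])
        pvals[name] = float(res.pvalues[i + 1])
    return AssociationResult(r=float(np.sqrt(res.rsquared)),
                             p=float(res.f_pvalue), n=len(data),
                             coefficients=coefs, coefficient_p=pvals)
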