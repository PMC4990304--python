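"""Quantal log-logistic dose-response fitting and benchmark-dose estimation.

The dichotomous log-logistic model is

    P(d) = g + (1 - g) / (1 + exp(-a - b * ln d)),        P(0) = g,

with background response ``g``, intercept ``a`` and slope ``b`` (per unit of
natural-log dose).  Group counts (n subjects, y positives) at each dose are
treated as independent binomials, and the model is fit by maximum likelihood.

The benchmark dose at benchmark response (BMR) level ``q`` is defined on the
*extra-risk* scale, (P(BMD) - g) / (1 - g) = q, which inverts in closed form:

    BMD = exp((logit(q) - a) / b)

and is independent of the background.  The BMDL is the one-sided lower
confidence limit obtained by profiling the likelihood over the BMD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "FitError",
    "ProfileError",
    "LogLogisticFit",
    "BMDEstimate",
    "loglogistic_prob",
    "quantal_neg_loglik",
    "fit_loglogistic",
    "bmd_from_fit",
    "bmdl_profile",
    "goodness_of_fit",
    "estimate_bmd",
]

_P_CLIP = 1e-12
_BOUND_TOL = 1e-6
_B_MAX = 25.0


class FitError(RuntimeError):
    """Raised when the quantal MLE cannot be computed."""


class ProfileError(FitError):
    """Raised when the profile likelihood never crosses the confidence cut.

    Carries the inspected (bmd, profile negative log-likelihood) pairs in
    ``trace`` for diagnosis.
    """

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []


def loglogistic_prob(dose, g: float, a: float, b: float):
    """Response probability of the log-logistic model at the given dose(s).

    ``P(0) = g`` by the continuous limit (the logistic term vanishes as
    ``ln d -> -inf`` for b > 0); no log of zero is ever taken.
    """
    if not 0.0 <= g <= 1.0:
        raise ValueError(f"background must lie in [0, 1], got {g}")
    if b <= 0:
        raise ValueError(f"slope must be positive, got {b}")
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be nonnegative")
    pos = d > 0
    with np.errstate(divide="ignore", over="ignore"):
        eta = np.where(pos, a + b * np.log(np.where(pos, d, 1.0)), -np.inf)
        frac = np.where(pos, 1.0 / (1.0 + np.exp(-eta)), 0.0)
    p = g + (1.0 - g) * frac
    return p if p.ndim else float(p)


def quantal_neg_loglik(params, doses, n, y) -> float:
    """Negative binomial log-likelihood of (g, a, b) for grouped quantal data."""
    nll, _ = _nll_grad(np.asarray(params, float), np.asarray(doses, float),
                       np.asarray(n, float), np.asarray(y, float))
    return float(nll)


def _nll_grad(params, d, n, y):
    # likelihood and analytic gradient; clipping acts as the optimizer barrier
    g, a, b = params
    g = min(max(g, 0.0), 1.0)
    pos = d > 0
    with np.errstate(over="ignore"):
        eta = np.where(pos, a + b * np.log(np.where(pos, d, 1.0)), 0.0)
        frac = np.where(pos, 1.0 / (1.0 + np.exp(-eta)), 0.0)
    p = np.clip(g + (1.0 - g) * frac, _P_CLIP, 1.0 - _P_CLIP)
    nll = -np.sum(y * np.log(p) + (n - y) * np.log(1.0 - p))
    w = y / p - (n - y) / (1.0 - p)
    dfrac = frac * (1.0 - frac)
    logd = np.where(pos, np.log(np.where(pos, d, 1.0)), 0.0)
    grad = -np.array([
        np.sum(w * (1.0 - frac)),
        np.sum(w * (1.0 - g) * dfrac),
        np.sum(w * (1.0 - g) * dfrac * logd),
    ])
    return nll, grad


@dataclass(frozen=True)
class LogLogisticFit:
    """Maximum-likelihood fit of the quantal log-logistic model."""

    g: float
    a: float
    b: float
    loglik: float
    aic: float
    n_params: int
    gof_stat: float
    gof_df: int
    gof_p: float
    converged: bool
    slope_at_bound: bool
    restrict_slope: bool
    doses: tuple = field(repr=False, default=())
    n: tuple = field(repr=False, default=())
    positives: tuple = field(repr=False, default=())

    @property
    def negloglik(self) -> float:
        return -self.loglik


@dataclass(frozen=True)
class BMDEstimate:
    """Benchmark dose with its one-sided lower confidence limit."""

    bmr: float
    bmd: float
    bmdl: float
    confidence: float = 0.95
    risk_type: str = "extra"


def _as_arrays(table):
    """Accept a DoseGroupTable-like object or a (doses, n, y) triple."""
    if hasattr(table, "doses"):
        d = np.asarray(table.doses, float)
        n = np.asarray(table.n, float)
        y = np.asarray(table.positives, float)
    else:
        d, n, y = (np.asarray(v, float) for v in table)
    keep = n > 0
    return d[keep], n[keep], y[keep]


def fit_loglogistic(table, restrict_slope: bool = True,
                    count_boundary_params: bool = False) -> LogLogisticFit:
    """Fit the log-logistic model to grouped quantal data by MLE.

    Parameters
    ----------
    table
        A :class:`~cadbmd.grouping.DoseGroupTable` or ``(doses, n, positives)``.
    restrict_slope
        Constrain the slope to b >= 1 (the usual regulatory restriction for
        this model); otherwise b > 0.
    count_boundary_params
        If True, AIC and goodness-of-fit degrees of freedom always count
        k = 3 parameters.  The default follows the BMDS convention: a
        parameter pinned at a constraint bound is not counted as estimated.

    Uses deterministic multi-start bounded quasi-Newton (analytic gradient)
    followed by a Nelder-Mead polish; convergence tolerance 1e-8 in the
    negative log-likelihood.
    """
    d, n, y = _as_arrays(table)
    if len(d) < 3:
        raise FitError(f"need at least 3 non-empty dose groups, got {len(d)}")
    if y.sum() == 0 or (n - y).sum() == 0:
        raise FitError("need at least one positive and one negative response overall")

    b_min = 1.0 if restrict_slope else 1e-8
    bounds = [(_P_CLIP, 1.0 - _P_CLIP), (-25.0, 10.0), (b_min, _B_MAX)]
    # fixed start lattice (8 deterministic multi-starts)
    starts = [(g0, a0, b0)
              for g0 in (0.02, 0.08)
              for a0 in (-5.0, -2.5)
              for b0 in (max(b_min, 1.0), max(b_min, 1.0) + 1.0)]
    best = None
    for s in starts:
        res = minimize(_nll_grad, s, args=(d, n, y), jac=True, method="L-BFGS-B",
                       bounds=bounds, options=dict(ftol=1e-14, gtol=1e-10, maxiter=5000))
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    polish = minimize(lambda p: _nll_grad(np.clip(p, [b[0] for b in bounds],
                                                  [b[1] for b in bounds]), d, n, y)[0],
                      best.x, method="Nelder-Mead",
                      options=dict(xatol=1e-10, fatol=1e-12, maxiter=10000))
    x = np.clip(polish.x, [b[0] for b in bounds], [b[1] for b in bounds])
    fun = _nll_grad(x, d, n, y)[0]
    if fun > best.fun:
        x, fun = best.x, best.fun
    converged = bool(best.success or polish.success)
    if not converged:
        raise FitError(f"optimizer failed to converge: {best.message!r} / {polish.message!r}")

    g, a, b = (float(v) for v in x)
    slope_at_bound = restrict_slope and abs(b - 1.0) < _BOUND_TOL
    pinned = int(slope_at_bound) + int(g < 10 * _P_CLIP or g > 1 - 10 * _P_CLIP)
    k = 3 if count_boundary_params else 3 - pinned
    loglik = -float(fun)
    aic = 2.0 * k - 2.0 * loglik
    gof_stat, gof_df, gof_p = _pearson_gof(g, a, b, d, n, y, k)
    return LogLogisticFit(g=g, a=a, b=b, loglik=loglik, aic=aic, n_params=k,
                          gof_stat=gof_stat, gof_df=gof_df, gof_p=gof_p,
                          converged=converged, slope_at_bound=slope_at_bound,
                          restrict_slope=restrict_slope,
                          doses=tuple(d), n=tuple(n), positives=tuple(y))


def _pearson_gof(g, a, b, d, n, y, k):
    p = np.clip(loglogistic_prob(d, g, a, b), _P_CLIP, 1 - _P_CLIP)
    stat = float(np.sum((y - n * p) ** 2 / (n * p * (1.0 - p))))
    df = len(d) - k
    pval = float(chi2_dist.sf(stat, df)) if df > 0 else float("nan")
    return stat, df, pval


def goodness_of_fit(fit: LogLogisticFit, table=None):
    """Pearson chi-square test of the fitted model against the group counts.

    df = number of groups minus the number of estimated parameters; the
    p-value is undefined (NaN) when df <= 0.
    """
    if table is None:
        d, n, y = np.array(fit.doses), np.array(fit.n), np.array(fit.positives)
    else:
        d, n, y = _as_arrays(table)
    _, _, p = _pearson_gof(fit.g, fit.a, fit.b, d, n, y, fit.n_params)
    return p


def bmd_from_fit(fit, bmr: float) -> float:
    """Closed-form extra-risk benchmark dose, exp((logit(bmr) - a) / b).

    Independent of the background g — a property of the extra-risk
    definition under this model.  Accepts a fit object or an (a, b) pair.
    """
    if not 0.0 < bmr < 1.0:
        raise ValueError(f"benchmark response must lie in (0, 1), got {bmr}")
    if hasattr(fit, "a"):
        a, b = fit.a, fit.b
    else:
        a, b = fit
    if b <= 0:
        raise ValueError("slope must be positive to invert the dose-response")
    return float(np.exp((np.log(bmr / (1.0 - bmr)) - a) / b))


def _profile_nll(bmd_star, bmr, d, n, y, b_min, warm):
    """Min negative log-likelihood subject to bmd(a, b) = bmd_star.

    Under extra risk the constraint is linear: a = logit(bmr) - b * ln(BMD*),
    so the inner problem is a 2-parameter bounded optimization over (g, b).
    """
    logit_q = np.log(bmr / (1.0 - bmr))
    log_bmd = np.log(bmd_star)

    def obj(p):
        g, b = p
        a = logit_q - b * log_bmd
        nll, grad = _nll_grad(np.array([g, a, b]), d, n, y)
        return nll, np.array([grad[0], grad[2] - grad[1] * log_bmd])

    starts = [warm[0]] if warm else []
    starts += [(0.05, max(b_min, 1.0)), (0.02, max(b_min, 1.0) + 1.5)]
    best = None
    for s in starts:
        res = minimize(obj, s, jac=True, method="L-BFGS-B",
                       bounds=[(_P_CLIP, 1 - _P_CLIP), (b_min, _B_MAX)],
                       options=dict(ftol=1e-14, gtol=1e-10, maxiter=5000))
        if best is None or res.fun < best.fun:
            best = res
    if warm is not None:
        warm[:] = [tuple(best.x)]
    return float(best.fun)


def bmdl_profile(fit: LogLogisticFit, table=None, bmr: float = 0.10,
                 confidence: float = 0.95) -> float:
    """One-sided profile-likelihood lower confidence limit on the BMD.

    The BMDL is the smallest dose D such that the log-likelihood maximized
    under the constraint BMD = D stays within chi2_{1,2*confidence-1}/2
    (about 1.3528 units at 95%) of the unconstrained maximum — the BMDS
    convention for a one-sided limit.  Found by bracketing and Brent root
    finding on the profile, with warm-started inner optimizations.
    """
    if not 0.0 < bmr < 1.0:
        raise ValueError(f"benchmark response must lie in (0, 1), got {bmr}")
    if not 0.5 < confidence < 1.0:
        raise ValueError(f"confidence must lie in (0.5, 1), got {confidence}")
    if table is None:
        d, n, y = np.array(fit.doses), np.array(fit.n), np.array(fit.positives)
    else:
        d, n, y = _as_arrays(table)
    b_min = 1.0 if fit.restrict_slope else 1e-8
    bmd_hat = bmd_from_fit(fit, bmr)
    crit = fit.negloglik + chi2_dist.ppf(2.0 * confidence - 1.0, 1) / 2.0

    warm = [(fit.g, max(fit.b, b_min))]
    trace = []

    def height(bmd_star):
        h = _profile_nll(bmd_star, bmr, d, n, y, b_min, warm) - crit
        trace.append((bmd_star, h + crit))
        return h

    lo = bmd_hat
    for _ in range(200):
        lo *= 0.7
        if height(lo) > 0:
            break
    else:
        raise ProfileError(
            f"profile likelihood never crossed the {confidence:.0%} threshold "
            f"below the BMD estimate {bmd_hat:.4g}", trace)
    warm[:] = [(fit.g, max(fit.b, b_min))]
    bmdl = brentq(height, lo, bmd_hat, xtol=1e-9, rtol=1e-10)
    return float(bmdl)


def estimate_bmd(fit: LogLogisticFit, table=None, bmr: float = 0.10,
                 confidence: float = 0.95) -> BMDEstimate:
    """Convenience wrapper: closed-form BMD plus profile BMDL as one record."""
    return BMDEstimate(bmr=bmr,
                       bmd=bmd_from_fit(fit, bmr),
                       bmdl=bmdl_profile(fit, table, bmr, confidence),
                       confidence=confidence)
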