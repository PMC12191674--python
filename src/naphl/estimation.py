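"""Classical estimation of the NAP-HL parameters.

Seven frequentist criteria are provided, each as an explicit objective on a
sorted sample plus a common numerical driver:

=======  =======================================================
MLE      maximum likelihood
CVME     minimum Cramer-von Mises distance
MPSE     maximum product of spacings
OLSE     ordinary least squares on the probability plot
WLSE     weighted least squares on the probability plot
ADE      minimum Anderson-Darling distance
RTADE    minimum right-tailed Anderson-Darling distance
=======  =======================================================

All objectives are written in terms of the fitted CDF at the order
statistics, so they are invariant to the input ordering (samples are
sorted internally).  Optimisation runs over (log alpha, log theta) with a
Nelder-Mead simplex and a small multi-start grid on alpha; the log
reparametrisation enforces positivity without explicit box constraints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .distribution import NapHL

__all__ = [
    "METHODS",
    "FitResult",
    "spacings",
    "neg_loglik",
    "cvm_objective",
    "mps_objective",
    "ols_objective",
    "wls_objective",
    "ad_objective",
    "rtad_objective",
    "fit",
    "minimize_multistart",
]

METHODS = ("MLE", "CVME", "MPSE", "OLSE", "WLSE", "ADE", "RTADE")

_BIG = 1e12  # objective value signalling an infeasible parameter point
_UEPS = 1e-12  # probability clamp for EDF objectives


@dataclass
class FitResult:
    """Outcome of a single model fit."""

    params: tuple[float, ...]
    method: str
    objective_value: float
    loglik: float
    converged: bool
    n: int
    start: tuple[float, ...]
    message: str = ""
    param_names: tuple[str, ...] = ("alpha", "theta")

    @property
    def alpha(self) -> float:
        return self.params[0]

    @property
    def theta(self) -> float:
        return self.params[-1]

    def model(self) -> NapHL:
        if self.param_names != ("alpha", "theta"):
            raise ValueError("not a NAP-HL fit")
        return NapHL(*self.params)


def _prepare(sample) -> np.ndarray:
    x = np.sort(np.asarray(sample, dtype=float))
    if x.size == 0:
        raise ValueError("sample is empty")
    if np.any(x <= 0) or np.any(~np.isfinite(x)):
        raise ValueError("sample values must be positive and finite")
    return x


def _dejitter_ties(x: np.ndarray) -> np.ndarray:
    """Break exact ties by a relative 1e-9 jitter (spacings need strict order)."""
    if np.unique(x).size == x.size:
        return x
    warnings.warn("tied observations jittered for spacings-based objective")
    scale = x[-1] - x[0] or x[0]
    return np.sort(x + np.arange(x.size) * 1e-9 * scale)


def _fitted_u(x: np.ndarray, params) -> np.ndarray:
    dist = params if isinstance(params, NapHL) else NapHL(*params)
    return np.clip(np.asarray(dist.cdf(x), dtype=float), _UEPS, 1.0 - _UEPS)


def spacings(u: np.ndarray) -> np.ndarray:
    """CDF increments D_k between consecutive order statistics.

    Uses the conventions F(x_(0)) = 0 and F(x_(n+1)) = 1, so the n+1
    spacings are nonnegative and sum to one.
    """
    return np.diff(np.concatenate(([0.0], np.sort(u), [1.0])))


# ---------------------------------------------------------------------------
# objectives


def neg_loglik(sample, params) -> float:
    """Negative log-likelihood -sum log f(x_i)."""
    x = _prepare(sample)
    dist = params if isinstance(params, NapHL) else NapHL(*params)
    f = np.asarray(dist.pdf(x), dtype=float)
    if np.any(f <= 0) or np.any(~np.isfinite(f)):
        return np.inf
    return float(-np.sum(np.log(f)))


def cvm_objective(sample, params) -> float:
    """Cramer-von Mises criterion 1/(12n) + sum (F(x_(k)) - (2k-1)/(2n))**2."""
    x = _prepare(sample)
    n = x.size
    k = np.arange(1, n + 1)
    u = _fitted_u(x, params)
    return float(1.0 / (12 * n) + np.sum((u - (2 * k - 1) / (2 * n)) ** 2))


def mps_objective(sample, params) -> float:
    """Mean log-spacing (to be maximised); -inf if any spacing vanishes."""
    x = _dejitter_ties(_prepare(sample))
    u = _fitted_u(x, params)
    D = spacings(u)
    if np.any(D <= 0):
        return -np.inf
    return float(np.mean(np.log(D)))


def ols_objective(sample, params) -> float:
    """Sum of squared probability-plot residuals (F(x_(k)) - k/(n+1))**2."""
    x = _prepare(sample)
    n = x.size
    k = np.arange(1, n + 1)
    u = _fitted_u(x, params)
    return float(np.sum((u - k / (n + 1)) ** 2))


def wls_objective(sample, params) -> float:
    """Probability-plot residuals weighted by inverse plotting-position variance."""
    x = _prepare(sample)
    n = x.size
    k = np.arange(1, n + 1)
    w = (n + 1) ** 2 * (n + 2) / (k * (n - k + 1))
    u = _fitted_u(x, params)
    return float(np.sum(w * (u - k / (n + 1)) ** 2))


def ad_objective(sample, params) -> float:
    """Anderson-Darling statistic -n - (1/n) sum (2k-1)[ln F(x_(k)) + ln S(x_(n+1-k))]."""
    x = _prepare(sample)
    n = x.size
    k = np.arange(1, n + 1)
    u = _fitted_u(x, params)
    return float(-n - np.mean((2 * k - 1) * (np.log(u) + np.log(1.0 - u[::-1]))))


def rtad_objective(sample, params) -> float:
    """Right-tailed Anderson-Darling statistic, up-weighting the upper tail.

    n/2 - 2 sum F(x_(k)) - (1/n) sum (2k-1) ln S(x_(n+1-k)).
    """
    x = _prepare(sample)
    n = x.size
    k = np.arange(1, n + 1)
    u = _fitted_u(x, params)
    return float(n / 2 - 2 * np.sum(u) - np.mean((2 * k - 1) * np.log(1.0 - u[::-1])))


_OBJECTIVES: dict[str, tuple[Callable, int]] = {
    # name -> (objective, sign): sign +1 minimised, -1 maximised
    "MLE": (neg_loglik, +1),
    "CVME": (cvm_objective, +1),
    "MPSE": (mps_objective, -1),
    "OLSE": (ols_objective, +1),
    "WLSE": (wls_objective, +1),
    "ADE": (ad_objective, +1),
    "RTADE": (rtad_objective, +1),
}


# ---------------------------------------------------------------------------
# driver


def minimize_multistart(
    fun: Callable[[np.ndarray], float],
    starts: Sequence[np.ndarray],
    xatol: float = 1e-9,
    fatol: float = 1e-12,
    maxiter: int = 4000,
) -> optimize.OptimizeResult:
    """Nelder-Mead from several starting points; returns the best result."""
    best = None
    for s in starts:
        res = optimize.minimize(
            fun,
            np.asarray(s, dtype=float),
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def default_starts(sample, alpha_grid=(0.5, 1.2, 3.0)) -> list[np.ndarray]:
    """Multi-start grid in (log alpha, log theta).

    theta is seeded from the half-logistic median relation
    theta0 = log(3) / median(sample).
    """
    x = np.asarray(sample, dtype=float)
    th0 = np.log(3.0) / np.median(x)
    return [np.array([np.log(a0), np.log(th0)]) for a0 in alpha_grid]


def fit(
    sample,
    method: str = "MLE",
    start: tuple[float, float] | None = None,
    multistart: bool = True,
) -> FitResult:
    """Fit the NAP-HL model to a positive sample by the chosen criterion.

    Parameters
    ----------
    sample : array-like of positive reals (any order; sorted internally).
    method : one of :data:`METHODS`.
    start : optional (alpha0, theta0) overriding the default start grid.
    multistart : when True (default) a small alpha grid of starts guards
        against local optima; False runs a single start (fast path for
        Monte Carlo replicates).
    """
    method = method.upper()
    if method not in _OBJECTIVES:
        raise ValueError(f"unknown method {method!r}; valid: {', '.join(METHODS)}")
    x = _prepare(sample)
    if x.size < (1 if method == "MLE" else 2):
        raise ValueError(f"sample too small for {method}")
    objective, sign = _OBJECTIVES[method]

    def wrapped(logp: np.ndarray) -> float:
        a, th = np.exp(logp)
        if not (np.isfinite(a) and np.isfinite(th)):
            return _BIG
        try:
            v = sign * objective(x, (a, th))
        except (ValueError, FloatingPointError):
            return _BIG
        return v if np.isfinite(v) else _BIG

    if start is not None:
        starts = [np.log(np.asarray(start, dtype=float))]
    else:
        starts = default_starts(x)
        if not multistart:
            starts = starts[1:2]  # the alpha0 = 1.2 start
    res = minimize_multistart(wrapped, starts)
    a_hat, th_hat = np.exp(res.x)
    converged = bool(res.success) and res.fun < _BIG
    return FitResult(
        params=(float(a_hat), float(th_hat)),
        method=method,
        objective_value=float(sign * res.fun),
        loglik=-neg_loglik(x, (a_hat, th_hat)),
        converged=converged,
        n=int(x.size),
        start=tuple(np.exp(starts[0])),
        message="" if converged else str(res.message),
    )
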