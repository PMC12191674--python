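"""Half-logistic-based comparison models.

Six published generalisations of the half-logistic (HL) law used as
benchmarks when assessing the alpha-power half-logistic fit:

=====  =================================  ==============================
OFHL   odd Frechet half-logistic          F = exp(-((1-G)/G)**alpha)
KHL    Kumaraswamy half-logistic          F = 1 - (1 - G**alpha)**beta
EHL    exponentiated half-logistic        F = G**alpha
MoHL   Marshall-Olkin half-logistic       S = alpha (1-G) / (1 - (1-alpha)(1-G))
HL     half-logistic                      F = G
PoHL   power half-logistic                F = G(x**alpha)
=====  =================================  ==============================

with G the HL CDF at rate ``gamma``.  Only the densities are usually
printed in the literature; the closed-form CDFs above are each the known
G-family composition and are cross-validated numerically in the test
suite.  Fitting is by maximum likelihood through the same multi-start
Nelder-Mead driver used for the NAP-HL model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .distribution import hl_cdf, hl_pdf, hl_ppf
from .estimation import FitResult, minimize_multistart
from .gof import GofReport, gof_report

__all__ = ["COMPETITORS", "CompetitorSpec", "competitor_pdf", "competitor_cdf", "fit_competitor"]


@dataclass(frozen=True)
class CompetitorSpec:
    """One comparison model: named positive parameters plus pdf/cdf/ppf."""

    name: str
    param_names: tuple[str, ...]
    pdf: Callable
    cdf: Callable
    ppf: Callable


def _pos(x):
    x = np.asarray(x, dtype=float)
    return x, np.exp(-x)  # convenience; callers guard x > 0


# -- odd Frechet half-logistic ------------------------------------------------


def _ofhl_cdf(x, a, g):
    x = np.asarray(x, dtype=float)
    e = np.exp(-g * np.maximum(x, 1e-300))
    with np.errstate(divide="ignore"):
        w = 2.0 * e / (1.0 - e)
    return np.where(x > 0, np.exp(-(w**a)), 0.0)


def _ofhl_pdf(x, a, g):
    x = np.asarray(x, dtype=float)
    e = np.exp(-g * np.maximum(x, 1e-300))
    w = 2.0 * e / (1.0 - e)
    pdf = a * g * 2.0**a * np.exp(-a * g * x) / (1.0 - e) ** (a + 1.0) * np.exp(-(w**a))
    return np.where(x > 0, pdf, 0.0)


def _ofhl_ppf(u, a, g):
    u = np.asarray(u, dtype=float)
    w = (-np.log(u)) ** (1.0 / a)
    return -np.log(w / (2.0 + w)) / g


# -- Kumaraswamy half-logistic ------------------------------------------------


def _khl_parts(x, a, g):
    """log G and the stably-computed 1 - G**a for the Kumaraswamy factor.

    1 - G**a cancels catastrophically once G**a rounds to 1, well before
    the density underflows, so it is formed as -expm1(a log G) with
    log G = log1p(-2 e^{-g x} / (1 + e^{-g x})).
    """
    x = np.asarray(x, dtype=float)
    e = np.exp(-g * np.maximum(x, 0.0))
    with np.errstate(divide="ignore"):
        logG = np.log1p(-2.0 * e / (1.0 + e))
    return logG, -np.expm1(a * logG)


def _khl_cdf(x, a, b, g):
    x = np.asarray(x, dtype=float)
    _, one_minus_Ga = _khl_parts(x, a, g)
    return np.where(x > 0, -np.expm1(b * np.log(np.maximum(one_minus_Ga, 1e-300))), 0.0)


def _khl_pdf(x, a, b, g):
    x = np.asarray(x, dtype=float)
    logG, one_minus_Ga = _khl_parts(x, a, g)
    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        out = (
            a * b * np.asarray(hl_pdf(x, g), float)
            * np.exp((a - 1.0) * logG)
            * one_minus_Ga ** (b - 1.0)
        )
    # density vanishes wherever the survival factor has fully underflowed
    return np.where((x > 0) & (one_minus_Ga > 0.0), out, 0.0)


def _khl_ppf(u, a, b, g):
    u = np.asarray(u, dtype=float)
    G = (1.0 - (1.0 - u) ** (1.0 / b)) ** (1.0 / a)
    return hl_ppf(G, g)


# -- exponentiated half-logistic ----------------------------------------------


def _ehl_cdf(x, a, g):
    return np.asarray(hl_cdf(x, g), dtype=float) ** a


def _ehl_pdf(x, a, g):
    G = np.asarray(hl_cdf(x, g), dtype=float)
    return a * np.asarray(hl_pdf(x, g), float) * G ** (a - 1.0)


def _ehl_ppf(u, a, g):
    return hl_ppf(np.asarray(u, float) ** (1.0 / a), g)


# -- Marshall-Olkin half-logistic ---------------------------------------------


def _mohl_cdf(x, a, g):
    x = np.asarray(x, dtype=float)
    e = np.exp(-g * np.maximum(x, 0.0))
    return np.where(x > 0, 1.0 - 2.0 * a * e / (1.0 + (2.0 * a - 1.0) * e), 0.0)


def _mohl_pdf(x, a, g):
    x = np.asarray(x, dtype=float)
    e = np.exp(-g * np.maximum(x, 0.0))
    return np.where(x > 0, 2.0 * a * g * e / (1.0 + (2.0 * a - 1.0) * e) ** 2, 0.0)


def _mohl_ppf(u, a, g):
    u = np.asarray(u, dtype=float)
    s = 1.0 - u
    e = s / (2.0 * a - (2.0 * a - 1.0) * s)
    return -np.log(e) / g


# -- power half-logistic ------------------------------------------------------


def _pohl_cdf(x, a, g):
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, hl_cdf(np.maximum(x, 0.0) ** a, g), 0.0)


def _pohl_pdf(x, a, g):
    x = np.asarray(x, dtype=float)
    xs = np.maximum(x, 1e-300)
    e = np.exp(-g * xs**a)
    return np.where(x > 0, 2.0 * a * g * xs ** (a - 1.0) * e / (1.0 + e) ** 2, 0.0)


def _pohl_ppf(u, a, g):
    return np.asarray(hl_ppf(u, g), dtype=float) ** (1.0 / a)


COMPETITORS: dict[str, CompetitorSpec] = {
    "OFHL": CompetitorSpec("OFHL", ("alpha", "gamma"), _ofhl_pdf, _ofhl_cdf, _ofhl_ppf),
    "KHL": CompetitorSpec("KHL", ("alpha", "beta", "gamma"), _khl_pdf, _khl_cdf, _khl_ppf),
    "EHL": CompetitorSpec("EHL", ("alpha", "gamma"), _ehl_pdf, _ehl_cdf, _ehl_ppf),
    "MoHL": CompetitorSpec("MoHL", ("alpha", "gamma"), _mohl_pdf, _mohl_cdf, _mohl_ppf),
    "HL": CompetitorSpec("HL", ("gamma",), lambda x, g: hl_pdf(x, g), lambda x, g: hl_cdf(x, g), lambda u, g: hl_ppf(u, g)),
    "PoHL": CompetitorSpec("PoHL", ("alpha", "gamma"), _pohl_pdf, _pohl_cdf, _pohl_ppf),
}


def _spec(name: str) -> CompetitorSpec:
    key = {k.upper(): k for k in COMPETITORS}.get(name.upper(), name)
    if key not in COMPETITORS:
        raise ValueError(
            f"unknown model {name!r}; valid: {', '.join(COMPETITORS)}"
        )
    return COMPETITORS[key]


def competitor_pdf(name: str, x, params):
    """Density of the named comparison model at ``x``."""
    return _spec(name).pdf(x, *params)


def competitor_cdf(name: str, x, params):
    """CDF of the named comparison model at ``x``."""
    return _spec(name).cdf(x, *params)


def fit_competitor(name: str, sample) -> tuple[FitResult, GofReport]:
    """Maximum-likelihood fit of a comparison model plus its GoF report."""
    spec = _spec(name)
    x = np.sort(np.asarray(sample, dtype=float))
    if np.any(x <= 0):
        raise ValueError("sample values must be positive")
    d = len(spec.param_names)

    def nll(logp):
        p = np.exp(logp)
        if not np.all(np.isfinite(p)):
            return 1e12
        with np.errstate(all="ignore"):
            f = np.asarray(spec.pdf(x, *p), dtype=float)
        if np.any(~np.isfinite(f)) or np.any(f <= 0):
            return 1e12
        return -float(np.sum(np.log(f)))

    th0 = np.log(np.log(3.0) / np.median(x))
    starts = [np.full(d, s) for s in (0.0, 0.5, -0.5)]
    starts.append(np.concatenate([np.zeros(d - 1), [th0]]))
    res = minimize_multistart(nll, starts)
    p_hat = tuple(float(v) for v in np.exp(res.x))
    ll = -nll(res.x)
    result = FitResult(
        params=p_hat,
        method="MLE",
        objective_value=float(res.fun),
        loglik=ll,
        converged=bool(res.success) and res.fun < 1e12,
        n=int(x.size),
        start=tuple(np.exp(starts[0])),
        param_names=spec.param_names,
    )
    report = gof_report(x, lambda t: spec.cdf(t, *p_hat), ll, d)
    return result, report
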