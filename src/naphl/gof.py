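"""Goodness-of-fit and model-selection metrics for fitted lifetime models.

Computes, for a fitted CDF evaluated on a sample: the maximised
log-likelihood, AIC, BIC, the classical (uncorrected) Anderson-Darling
``A*`` and Cramer-von Mises ``W*`` EDF statistics, and the two-sided
Kolmogorov-Smirnov distance with its exact one-sample p-value (the same
small-sample distribution R's ``ks.test`` uses for n < 100).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GofReport", "gof_report"]


@dataclass(frozen=True)
class GofReport:
    """Model-selection metrics for one fitted model on one sample."""

    loglik: float
    aic: float
    bic: float
    a_star: float
    w_star: float
    ks: float
    ks_pvalue: float
    n: int
    k_params: int

    def row(self) -> dict:
        """Flat dict in report-table column order."""
        return {
            "negloglik": -self.loglik,
            "AIC": self.aic,
            "BIC": self.bic,
            "A*": self.a_star,
            "W*": self.w_star,
            "K-S": self.ks,
            "p-value": self.ks_pvalue,
        }


def gof_report(sample, cdf, loglik: float, k_params: int) -> GofReport:
    """Evaluate EDF statistics and information criteria for a fitted CDF.

    Parameters
    ----------
    sample : array-like, positive observations (sorted internally).
    cdf : callable mapping x to the fitted model CDF.
    loglik : maximised log-likelihood of the model on this sample.
    k_params : number of free parameters (for AIC/BIC).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("goodness-of-fit metrics need n >= 2")
    u = np.asarray(cdf(x), dtype=float)
    if np.any(~np.isfinite(u)):
        raise ValueError("fitted CDF returned non-finite values")
    u = np.clip(u, 1e-300, 1.0 - 1e-16)
    k = np.arange(1, n + 1)

    ks = float(max(np.max(k / n - u), np.max(u - (k - 1) / n)))
    w_star = float(1.0 / (12 * n) + np.sum((u - (2 * k - 1) / (2 * n)) ** 2))
    a_star = float(-n - np.mean((2 * k - 1) * (np.log(u) + np.log(1.0 - u[::-1]))))
    pval = float(stats.kstwo.sf(ks, n))

    return GofReport(
        loglik=float(loglik),
        aic=2.0 * k_params - 2.0 * loglik,
        bic=k_params * np.log(n) - 2.0 * loglik,
        a_star=a_star,
        w_star=w_star,
        ks=ks,
        ks_pvalue=min(pval, 1.0),
        n=int(n),
        k_params=int(k_params),
    )
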