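"""Benchmark datasets and descriptive statistics.

Two classic positive-valued reliability datasets ship with the package as
CSV fixtures:

``metrology``
    20 component failure times (the SDS failure-time data), right-skewed
    with a bathtub-suggestive total-time-on-test profile.
``engineering``
    76 fatigue-fracture lives of Kevlar 373/epoxy specimens held at the
    90% stress level until failure.

:func:`describe` reports the summary statistics conventionally tabulated
for such data; sample skewness and kurtosis default to the bias-corrected
(adjusted Fisher-Pearson) estimators with kurtosis on the excess scale —
the convention used by common spreadsheet and R summaries — and the plain
moment-ratio variants are reported alongside.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import stats

__all__ = ["Dataset", "load_dataset", "load_csv", "describe"]

_SOURCES = {
    "metrology": "SDS component failure times (n=20)",
    "engineering": "Kevlar 373/epoxy fatigue fracture lives at 90% stress (n=76)",
}


@dataclass(frozen=True)
class Dataset:
    name: str
    values: np.ndarray
    source: str


def load_dataset(name: str) -> Dataset:
    """Load a bundled dataset by name (``metrology`` or ``engineering``)."""
    key = name.lower()
    if key not in _SOURCES:
        raise ValueError(f"unknown dataset {name!r}; valid: {', '.join(_SOURCES)}")
    ref = resources.files("naphl.data").joinpath(f"{key}.csv")
    with ref.open("r") as fh:
        values = _read_column(fh)
    return Dataset(name=key, values=values, source=_SOURCES[key])


def load_csv(path) -> np.ndarray:
    """Read a single-column CSV of positive reals; a header row is optional."""
    with open(path, "r", newline="") as fh:
        return _read_column(fh)


def _read_column(fh) -> np.ndarray:
    rows = [r for r in csv.reader(fh) if r and r[0].strip()]
    start = 0
    try:
        float(rows[0][0])
    except (ValueError, IndexError):
        start = 1
    vals = np.array([float(r[0]) for r in rows[start:]], dtype=float)
    if vals.size == 0:
        raise ValueError("no numeric values found")
    return vals


def describe(sample) -> dict:
    """Descriptive summary of a univariate sample.

    Returns count, min, max, mean, median, sd, variance (n-1 denominator),
    range, skewness and excess kurtosis (both bias-corrected), plus the
    uncorrected moment-ratio variants under ``skewness_moment`` /
    ``kurtosis_moment`` (the latter non-excess).  A constant sample has
    sd 0 and undefined shape measures, signalled as NaN with a warning.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("describe needs at least two observations")
    sd = float(x.std(ddof=1))
    out = {
        "count": int(x.size),
        "min": float(x.min()),
        "max": float(x.max()),
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "sd": sd,
        "variance": sd**2,
        "range": float(x.max() - x.min()),
    }
    if sd == 0.0:
        warnings.warn("constant sample: skewness and kurtosis undefined")
        out.update(
            skewness=np.nan, kurtosis=np.nan,
            skewness_moment=np.nan, kurtosis_moment=np.nan,
        )
        return out
    m2 = x.var(ddof=0)
    m3 = float(((x - x.mean()) ** 3).mean())
    m4 = float(((x - x.mean()) ** 4).mean())
    out["skewness"] = float(stats.skew(x, bias=False))
    out["kurtosis"] = float(stats.kurtosis(x, bias=False))  # excess
    out["skewness_moment"] = m3 / m2**1.5
    out["kurtosis_moment"] = m4 / m2**2  # non-excess
    return out
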