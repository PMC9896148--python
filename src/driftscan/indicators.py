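"""Classical rolling-window early-warning statistics.

All estimators deliberately use the *biased* (divisor ``n``) moment
conventions: lag-1 autocorrelation with the full-window variance in the
denominator, standard deviation with divisor ``n``, the not-adjusted
Fisher--Pearson skewness ``g1 = m3 / m2**1.5`` and the Pearson kurtosis
``m4 / m2**2`` (equal to 3 for a Gaussian).  For windows of hundreds of
samples the bias is negligible and these are the conventions the
early-warning literature reports.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
import pandas as pd

from driftscan.preprocess import WindowSpec, rolling_windows

__all__ = [
    "ar1",
    "std_biased",
    "skewness",
    "kurtosis_pearson",
    "rolling_indicator",
    "indicator_table",
    "INDICATORS",
    "UndefinedIndicatorError",
]


class UndefinedIndicatorError(ValueError):
    """Raised when an estimator is undefined (e.g. zero variance)."""


def _centered(window) -> np.ndarray:
    x = np.asarray(window, dtype=float)
    return x - x.mean()


def ar1(window) -> float:
    """Biased lag-1 autocorrelation.

    ``sum_{t<n}(x_t - xbar)(x_{t+1} - xbar) / sum_t (x_t - xbar)**2``
    with the mean and variance taken over the whole window.
    """
    c = _centered(window)
    denom = np.dot(c, c)
    if denom == 0:
        raise UndefinedIndicatorError("zero-variance window")
    return float(np.dot(c[:-1], c[1:]) / denom)


def std_biased(window) -> float:
    """Standard deviation with divisor ``n``."""
    c = _centered(window)
    return float(np.sqrt(np.mean(c ** 2)))


def skewness(window) -> float:
    """Not-adjusted Fisher--Pearson skewness ``m3 / m2**1.5``."""
    c = _centered(window)
    m2 = np.mean(c ** 2)
    if m2 == 0:
        raise UndefinedIndicatorError("zero-variance window")
    return float(np.mean(c ** 3) / m2 ** 1.5)


def kurtosis_pearson(window) -> float:
    """Pearson kurtosis ``m4 / m2**2`` (3 for a Gaussian; no excess)."""
    c = _centered(window)
    m2 = np.mean(c ** 2)
    if m2 == 0:
        raise UndefinedIndicatorError("zero-variance window")
    return float(np.mean(c ** 4) / m2 ** 2)


INDICATORS: dict[str, Callable] = {
    "ar1": ar1,
    "std": std_biased,
    "skewness": skewness,
    "kurtosis": kurtosis_pearson,
}


def rolling_indicator(series, spec: WindowSpec, which: str,
                      times=None) -> pd.DataFrame:
    """One indicator value per rolling window, right-aligned timestamps.

    Windows on which the estimator is undefined are recorded as missing
    (NaN) rather than dropped, so indicator series stay aligned across
    statistics.
    """
    if which not in INDICATORS:
        raise KeyError(f"unknown indicator {which!r}; choose from {sorted(INDICATORS)}")
    fn = INDICATORS[which]
    out_t, out_v = [], []
    for view in rolling_windows(series, spec, times=times):
        out_t.append(view.time)
        try:
            out_v.append(fn(view.data))
        except UndefinedIndicatorError:
            out_v.append(np.nan)
    return pd.DataFrame({"time": out_t, which: out_v})


def indicator_table(series, spec: WindowSpec, times=None) -> pd.DataFrame:
    """All classical indicators in one table keyed by window end time."""
    frames = [rolling_indicator(series, spec, name, times=times)
              for name in INDICATORS]
    out = frames[0]
    for f in frames[1:]:
        out = out.merge(f, on="time")
    return out
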