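"""Deseasonalization and rolling-window segmentation.

The simulated series carry a strong annual cycle from the maturation map.
Two deseasonalizers are provided:

* year-over-year differencing (:func:`deseasonalize_yoy`), which subtracts
  from every sample the same calendar sample of the previous year --
  appropriate when the residual forcing is white;
* Gaussian-kernel residuals (:func:`deseasonalize_smooth`), which subtract
  a kernel-smoothed version of the series and thereby remove seasonality
  and slow trend at the same time -- appropriate under correlated forcing.

Windows are right-aligned: each window carries the timestamp of its last
sample so that indicator trends are causal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "WindowSpec",
    "WindowView",
    "deseasonalize_yoy",
    "deseasonalize_smooth",
    "rolling_windows",
    "n_windows",
]


@dataclass(frozen=True)
class WindowSpec:
    """Rolling-window geometry in samples."""

    size: int = 750
    shift: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.shift <= self.size:
            raise ValueError("require 0 < shift <= size")


@dataclass
class WindowView:
    """One rolling window with the timestamp of its last sample."""

    data: np.ndarray
    time: float
    start: int
    stop: int


def deseasonalize_yoy(series, samples_per_year: int = 50,
                      times=None):
    """Year-over-year differencing: ``out[t] = x[t] - x[t - 1 year]``.

    The output is shorter by one year; with ``times`` given, the matching
    (shifted) timestamps are returned as a second array.
    """
    x = np.asarray(series, dtype=float)
    if len(x) <= samples_per_year:
        raise ValueError("series shorter than one year")
    out = x[samples_per_year:] - x[:-samples_per_year]
    if times is not None:
        return out, np.asarray(times)[samples_per_year:]
    return out


def deseasonalize_smooth(series, kernel_sd: float = 2.5):
    """Residual after Gaussian kernel smoothing (reflect-padded).

    ``kernel_sd`` is the standard deviation of the Gaussian kernel in
    sample units.  The residual is a high-pass version of the input that
    removes both the annual cycle and slow trend.
    """
    x = np.asarray(series, dtype=float)
    return x - gaussian_filter1d(x, sigma=kernel_sd, mode="reflect")


def n_windows(n: int, spec: WindowSpec) -> int:
    """Number of windows: ``floor((n - size) / shift) + 1``."""
    if spec.size > n:
        raise ValueError(f"window size {spec.size} exceeds series length {n}")
    return (n - spec.size) // spec.shift + 1


def rolling_windows(series, spec: WindowSpec, times=None) -> list[WindowView]:
    """Ordered window views ``[k*shift, k*shift + size)``.

    Each view carries the timestamp of its last sample (sample index if no
    ``times`` are given).
    """
    x = np.asarray(series, dtype=float)
    k = n_windows(len(x), spec)
    if times is None:
        times = np.arange(len(x), dtype=float)
    else:
        times = np.asarray(times, dtype=float)
    views = []
    for i in range(k):
        start = i * spec.shift
        stop = start + spec.size
        views.append(WindowView(data=x[start:stop], time=float(times[stop - 1]),
                                start=start, stop=stop))
    return views
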