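"""White, pink and red stochastic forcing with calibrated spectra.

Three forcing processes drive the planktivore equation of the food-web
model:

* *white*: plain Wiener increments, ``Z = dW`` with ``Var(dW) = dt``;
* *pink*: a white Gaussian sequence whose power spectrum is reshaped to a
  ``f**(-beta)`` power law (amplitude scaling ``f**(-beta/2)``) by forward
  FFT, spectral scaling and inverse FFT, with the zero-frequency bin set to
  zero so the forcing is mean-free;
* *red*: the stationary Ornstein--Uhlenbeck process
  ``dZ = -phi Z dt + sqrt(2 phi) dW``, integrated by Euler--Maruyama.

For white noise the stored values are the Wiener increments themselves;
for colored noise they are samples of the process ``Z`` and the forcing
increment of a step is ``Z * dt`` (state-like forcing).

The *total power* convention used throughout is the sum of the one-sided
periodogram, which by Parseval's theorem equals the time-domain mean
square.  Pink and red series intended for the same experiment are
normalized to a common target power so that only the correlation
structure differs between them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NoiseSeries",
    "white_noise",
    "pink_noise",
    "red_noise",
    "total_power",
    "normalize_power",
    "estimate_spectral_exponent",
    "write_noise",
    "read_noise",
]

#: Default total power (mean square) the colored forcings are calibrated to.
#: Only the ratio between the pink and red powers matters for the analyses;
#: the absolute value is a configuration knob.
DEFAULT_COLORED_POWER = 15.4

#: Relaxation rate of the red (Ornstein--Uhlenbeck) forcing, per year.
DEFAULT_PHI = 0.53

#: Spectral exponent of the pink forcing.
DEFAULT_PINK_BETA = 0.8


@dataclass
class NoiseSeries:
    """A calibrated stochastic forcing sequence.

    ``values`` are Wiener increments for ``kind == "white"`` and samples of
    the process ``Z`` otherwise; :attr:`increments` converts either into
    the additive forcing increment of one Euler--Maruyama step.
    """

    values: np.ndarray
    dt: float
    kind: str                      # "white" | "pink" | "red"
    beta: float                    # nominal spectral exponent
    power: float                   # total power (time-domain mean square)
    phi: Optional[float] = None    # OU relaxation rate, red only
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("noise series must be non-empty")
        if not np.isfinite(self.values).all():
            raise ValueError("noise series must be finite")
        if self.kind not in ("white", "pink", "red"):
            raise ValueError(f"unknown noise kind {self.kind!r}")

    @property
    def increments(self) -> np.ndarray:
        """Per-step forcing increments at spacing ``dt``."""
        if self.kind == "white":
            return self.values
        return self.values * self.dt

    def __len__(self) -> int:
        return len(self.values)


def white_noise(n: int, dt: float, rng: np.random.Generator) -> NoiseSeries:
    """``n`` independent Wiener increments, mean 0 and variance ``dt``."""
    vals = rng.standard_normal(n) * np.sqrt(dt)
    return NoiseSeries(vals, dt, "white", beta=0.0, power=total_power(vals))


def pink_noise(n: int, dt: float, beta: float = DEFAULT_PINK_BETA,
               rng: Optional[np.random.Generator] = None,
               power: Optional[float] = None) -> NoiseSeries:
    """Spectrally shaped 1/f^beta noise via the FFT recipe.

    A white Gaussian sequence is Fourier transformed, the amplitude at
    frequency ``f`` is scaled by ``f**(-beta/2)`` (so the power spectrum
    scales as ``f**(-beta)``), the zero-frequency component is set to zero
    and the result is transformed back.  With ``power`` given, the series
    is rescaled to that total power; otherwise it is left at unit mean
    square.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if n < 4:
        raise ValueError("need at least 4 samples for spectral shaping")
    if rng is None:
        rng = np.random.default_rng()
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=dt)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-beta / 2.0)
    vals = np.fft.irfft(spec * scale, n=n)     # conjugate-symmetric, real
    vals /= np.sqrt(np.mean(vals ** 2))
    series = NoiseSeries(vals, dt, "pink", beta=beta, power=total_power(vals))
    if power is not None:
        series = normalize_power(series, power)
    return series


def red_noise(n: int, dt: float, phi: float = DEFAULT_PHI,
              rng: Optional[np.random.Generator] = None,
              power: Optional[float] = None) -> NoiseSeries:
    """Stationary Ornstein--Uhlenbeck forcing by Euler--Maruyama.

    ``dZ = -phi Z dt + sqrt(2 phi) dW`` has stationary variance 1; the
    initial value is drawn from the stationary distribution to avoid
    transients.  ``beta`` records the effective spectral exponent the
    process exhibits over the sampled band (its asymptotic exponent is 2).
    """
    if phi <= 0:
        raise ValueError("phi must be > 0")
    if rng is None:
        rng = np.random.default_rng()
    vals = np.empty(n)
    vals[0] = rng.standard_normal()
    xi = rng.standard_normal(n - 1)
    decay = 1.0 - phi * dt
    amp = np.sqrt(2.0 * phi * dt)
    for i in range(1, n):
        vals[i] = decay * vals[i - 1] + amp * xi[i - 1]
    series = NoiseSeries(vals, dt, "red", beta=1.6, phi=phi,
                         power=total_power(vals))
    if power is not None:
        series = normalize_power(series, power)
    return series


def total_power(series, dt: Optional[float] = None) -> float:
    """Total power as the one-sided periodogram sum.

    Computed through the real FFT with conjugate-symmetry weights, which
    makes it exactly Parseval-consistent with the time-domain mean square.
    ``dt`` is accepted for interface symmetry; the convention is
    sampling-rate free.
    """
    x = series.values if isinstance(series, NoiseSeries) else np.asarray(series, float)
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) ** 2
    weights = np.full(len(spec), 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0   # Nyquist bin is not duplicated
    return float((weights * spec).sum() / n ** 2)


def normalize_power(series: NoiseSeries, target: float) -> NoiseSeries:
    """Rescale to the target total power; idempotent at the target."""
    if target < 0:
        raise ValueError("target power must be >= 0")
    current = total_power(series)
    if current == 0:
        raise ValueError("cannot rescale an all-zero series")
    vals = series.values * np.sqrt(target / current)
    return replace(series, values=vals, power=total_power(vals))


def estimate_spectral_exponent(series, dt: Optional[float] = None,
                               skip_low_bins: int = 3) -> float:
    """Spectral exponent from an (ensemble-averaged) periodogram.

    ``series`` is one series or a sequence of equal-length realizations;
    periodograms are averaged across realizations, the ``skip_low_bins``
    lowest positive-frequency bins are excluded, and the least-squares
    slope of log power versus log frequency is fitted.  Returns the
    negated slope (so a ``f**(-beta)`` spectrum yields ``beta``).
    """
    if isinstance(series, NoiseSeries):
        arrs = [series.values]
        dt = series.dt
    elif isinstance(series, Sequence) and isinstance(series[0], NoiseSeries):
        arrs = [s.values for s in series]
        dt = series[0].dt
    elif isinstance(series, np.ndarray) and series.ndim == 2:
        arrs = list(series)
    else:
        arrs = [np.asarray(a, float) for a in np.atleast_2d(series)]
    if dt is None:
        dt = 1.0
    n = len(arrs[0])
    freqs = np.fft.rfftfreq(n, d=dt)[1:]
    pxx = np.mean([np.abs(np.fft.rfft(a))[1:] ** 2 for a in arrs], axis=0)
    f, P = freqs[skip_low_bins:], pxx[skip_low_bins:]
    mask = P > 0
    slope = np.polyfit(np.log(f[mask]), np.log(P[mask]), 1)[0]
    return float(-slope)


def write_noise(series: NoiseSeries, path: str | Path) -> None:
    """CSV (time, value) plus JSON metadata sidecar."""
    path = Path(path)
    t = np.arange(len(series)) * series.dt
    pd.DataFrame({"time": t, "value": series.values}).to_csv(path, index=False)
    meta = {"kind": series.kind, "beta": series.beta, "phi": series.phi,
            "power": series.power, "dt": series.dt, "seed": series.seed}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_noise(path: str | Path) -> NoiseSeries:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return NoiseSeries(df["value"].to_numpy(), meta["dt"], meta["kind"],
                       beta=meta["beta"], power=meta["power"],
                       phi=meta.get("phi"), seed=meta.get("seed"))
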