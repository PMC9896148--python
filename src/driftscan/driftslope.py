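"""Bayesian drift-slope estimation from scalar time-series windows.

A window is modelled as a realization of the Langevin equation
``dx = h(x) dt + sigma dW`` with a third-order polynomial drift

.. math::

    h(x) = \\theta_0 + \\theta_1 x + \\theta_2 x^2 + \\theta_3 x^3

and constant diffusion.  The resilience measure is the *drift slope*

.. math::

    \\zeta = \\left. \\frac{dh}{dx} \\right|_{x = x^*}
           = \\theta_1 + 2 \\theta_2 x^* + 3 \\theta_3 x^{*2},

the derivative of the drift at the fixed point ``x*`` (estimated as the
window mean).  ``zeta`` is negative while the state is stable and crosses
zero when stability is lost, which makes its rolling-window trend an
early-warning signal with an absolute threshold.

The posterior of ``(theta, sigma)`` is sampled with the affine-invariant
ensemble sampler of :mod:`emcee` under a Jeffreys straight-line prior on
``(theta_0, theta_1)``, a ``1/sigma`` scale prior, and zero-mean Gaussian
priors on the curvature parameters.  The likelihood is the product of
short-time Euler--Maruyama Gaussian transition densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import emcee
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "DriftDiffusionParams",
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSample",
    "SlopeEstimate",
    "polynomial_drift",
    "log_likelihood",
    "log_prior",
    "fit_window",
    "slope_from_params",
    "slope_posterior_summary",
    "rolling_drift_slope",
    "slope_table",
    "EstimationError",
]


class EstimationError(RuntimeError):
    """Raised when a window admits no finite posterior (e.g. constant data)."""


@dataclass(frozen=True)
class DriftDiffusionParams:
    """Cubic drift coefficients plus constant diffusion amplitude."""

    theta0: float
    theta1: float
    theta2: float
    theta3: float
    sigma_diff: float

    def __post_init__(self) -> None:
        vec = (self.theta0, self.theta1, self.theta2, self.theta3, self.sigma_diff)
        if not np.all(np.isfinite(vec)):
            raise ValueError("parameters must be finite")
        if self.sigma_diff <= 0:
            raise ValueError("sigma_diff must be > 0")

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.theta0, self.theta1, self.theta2, self.theta3])

    @classmethod
    def from_vector(cls, vec) -> "DriftDiffusionParams":
        return cls(*np.asarray(vec, dtype=float))


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters for one window fit.

    The default box and scale range suit raw and year-over-year
    deseasonalized series; :meth:`wide` gives the broader ranges used for
    smoothing-deseasonalized correlated-noise series, where the posterior
    would otherwise be pinched by the support.
    """

    theta01_box: tuple[float, float] = (-50.0, 50.0)
    sigma_range: tuple[float, float] = (0.0, 50.0)
    theta2_sd: float = 4.0
    theta3_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.theta01_box[0] >= self.theta01_box[1]:
            raise ValueError("empty theta01 box")
        if self.sigma_range[0] >= self.sigma_range[1]:
            raise ValueError("empty sigma range")
        if self.theta2_sd <= 0 or self.theta3_sd <= 0:
            raise ValueError("Gaussian prior scales must be > 0")

    @classmethod
    def wide(cls) -> "PriorSpec":
        return cls(theta01_box=(-70.0, 70.0), sigma_range=(0.0, 70.0))


@dataclass(frozen=True)
class MCMCConfig:
    """Ensemble-sampler settings."""

    walkers: int = 50
    steps: int = 1500
    burn: int = 500
    thin: int = 5

    def __post_init__(self) -> None:
        if self.walkers < 12:
            raise ValueError("need at least 12 walkers for 5 parameters")
        if not 0 <= self.burn < self.steps:
            raise ValueError("require 0 <= burn < steps")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorSample:
    """Retained MCMC draws (columns theta0..theta3, sigma_diff)."""

    draws: np.ndarray
    acceptance_fraction: float
    seed: int
    x_star: float


@dataclass
class SlopeEstimate:
    """Posterior summary of the drift slope for one window."""

    time: float
    zeta_map: float
    band_68: tuple[float, float]    # 16th / 84th percentiles
    band_98: tuple[float, float]    # 1st / 99th percentiles
    x_star: float

    def __post_init__(self) -> None:
        q16, q84 = self.band_68
        q01, q99 = self.band_98
        if not (q01 <= q16 <= q84 <= q99):
            raise ValueError("credibility bands must be nested and ordered")


def polynomial_drift(x, params: DriftDiffusionParams):
    """Evaluate the cubic drift ``theta0 + theta1 x + theta2 x^2 + theta3 x^3``."""
    t = params.theta
    x = np.asarray(x, dtype=float)
    out = t[0] + x * (t[1] + x * (t[2] + x * t[3]))
    return float(out) if out.ndim == 0 else out


def log_likelihood(window, params: DriftDiffusionParams, dt: float) -> float:
    """Euler--Maruyama transition log-likelihood of a window.

    Sum over consecutive pairs of
    ``log N(x_{i+1}; x_i + h(x_i) dt, sigma_diff**2 dt)``.
    """
    x = np.asarray(window, dtype=float)
    if len(x) < 2:
        raise ValueError("window must contain at least two samples")
    if params.sigma_diff <= 0:
        return -np.inf
    resid = x[1:] - x[:-1] - polynomial_drift(x[:-1], params) * dt
    var = params.sigma_diff ** 2 * dt
    n = len(resid)
    return float(-0.5 * np.sum(resid ** 2) / var - 0.5 * n * np.log(2 * np.pi * var))


def log_prior(params: DriftDiffusionParams, spec: PriorSpec) -> float:
    """Joint log prior density.

    Jeffreys straight-line prior ``1 / (2 pi (1 + theta1^2)^{3/2})`` on
    ``(theta0, theta1)`` inside the box, scale prior ``1/sigma`` on the
    sigma range, and zero-mean Gaussians on ``theta2``, ``theta3``.
    """
    lo, hi = spec.theta01_box
    s_lo, s_hi = spec.sigma_range
    if not (lo < params.theta0 < hi and lo < params.theta1 < hi):
        return -np.inf
    if not (s_lo < params.sigma_diff < s_hi):
        return -np.inf
    lp = -np.log(2 * np.pi) - 1.5 * np.log1p(params.theta1 ** 2)
    lp -= np.log(params.sigma_diff)
    for val, sd in ((params.theta2, spec.theta2_sd), (params.theta3, spec.theta3_sd)):
        lp += -0.5 * (val / sd) ** 2 - 0.5 * np.log(2 * np.pi * sd ** 2)
    return float(lp)


def _log_posterior_batch(theta: np.ndarray, x0: np.ndarray, dx: np.ndarray,
                         dt: float, spec: PriorSpec) -> np.ndarray:
    """Vectorized unnormalized log posterior for a batch of walkers.

    ``theta`` has shape (k, 5); returns shape (k,).  The evidence term of
    Bayes' theorem is not needed for MCMC and is not computed.
    """
    theta = np.atleast_2d(theta)
    k = theta.shape[0]
    out = np.full(k, -np.inf)
    lo, hi = spec.theta01_box
    s_lo, s_hi = spec.sigma_range
    ok = ((theta[:, 0] > lo) & (theta[:, 0] < hi)
          & (theta[:, 1] > lo) & (theta[:, 1] < hi)
          & (theta[:, 4] > s_lo) & (theta[:, 4] < s_hi))
    if not ok.any():
        return out
    t = theta[ok]
    sig = t[:, 4]
    # prior
    lp = (-np.log(2 * np.pi) - 1.5 * np.log1p(t[:, 1] ** 2) - np.log(sig)
          - 0.5 * (t[:, 2] / spec.theta2_sd) ** 2
          - 0.5 * np.log(2 * np.pi * spec.theta2_sd ** 2)
          - 0.5 * (t[:, 3] / spec.theta3_sd) ** 2
          - 0.5 * np.log(2 * np.pi * spec.theta3_sd ** 2))
    # likelihood: residuals for all walkers at once, (n, k_ok)
    drift = (t[:, 0][None, :]
             + np.multiply.outer(x0, t[:, 1])
             + np.multiply.outer(x0 ** 2, t[:, 2])
             + np.multiply.outer(x0 ** 3, t[:, 3]))
    resid = dx[:, None] - drift * dt
    var = sig ** 2 * dt
    n = len(x0)
    ll = -0.5 * (resid ** 2).sum(axis=0) / var - 0.5 * n * np.log(2 * np.pi * var)
    out[ok] = lp + ll
    return out


def _init_walkers(x0: np.ndarray, dx: np.ndarray, dt: float, spec: PriorSpec,
                  n_walkers: int, rng: np.random.Generator) -> np.ndarray:
    """Initialize walkers around a least-squares fit of the increment field."""
    X = np.column_stack([np.ones_like(x0), x0, x0 ** 2, x0 ** 3])
    theta_hat, *_ = np.linalg.lstsq(X, dx / dt, rcond=None)
    resid = dx - X @ theta_hat * dt
    sigma_hat = float(np.std(resid) / np.sqrt(dt))
    lo, hi = spec.theta01_box
    s_lo, s_hi = spec.sigma_range
    margin = 1e-3 * (hi - lo)
    center = np.append(np.clip(theta_hat, lo + margin, hi - margin),
                       np.clip(sigma_hat, s_lo + 1e-3 * (s_hi - s_lo), s_hi * 0.9))
    scale = np.maximum(1e-2 * np.abs(center), 1e-4)
    p0 = center[None, :] + scale[None, :] * rng.standard_normal((n_walkers, 5))
    p0[:, 0] = np.clip(p0[:, 0], lo + margin, hi - margin)
    p0[:, 1] = np.clip(p0[:, 1], lo + margin, hi - margin)
    p0[:, 4] = np.clip(p0[:, 4], s_lo + 1e-3 * (s_hi - s_lo), s_hi - 1e-3 * (s_hi - s_lo))
    return p0


def fit_window(window, dt: float, spec: Optional[PriorSpec] = None,
               config: Optional[MCMCConfig] = None, seed: int = 0) -> PosteriorSample:
    """Sample the drift-diffusion posterior of one window.

    Affine-invariant ensemble sampling of ``log_prior + log_likelihood``;
    the burn-in is discarded and the remaining chain thinned.  Reproducible
    under ``seed``.  Raises :class:`EstimationError` on degenerate windows
    (constant data leaves the diffusion amplitude unidentified at 0).
    """
    spec = spec or PriorSpec()
    config = config or MCMCConfig()
    x = np.asarray(window, dtype=float)
    if len(x) < 50:
        raise ValueError("window must contain at least 50 samples")
    if np.ptp(x) == 0:
        raise EstimationError("constant window: posterior is degenerate")
    x0, dx = x[:-1], np.diff(x)

    rng = np.random.default_rng(seed)
    p0 = _init_walkers(x0, dx, dt, spec, config.walkers, rng)
    lp0 = _log_posterior_batch(p0, x0, dx, dt, spec)
    for _ in range(20):
        bad = ~np.isfinite(lp0)
        if not bad.any():
            break
        jitter = p0[~bad].mean(axis=0) if (~bad).any() else p0.mean(axis=0)
        p0[bad] = jitter[None, :] * (1 + 1e-3 * rng.standard_normal((bad.sum(), 5)))
        lp0 = _log_posterior_batch(p0, x0, dx, dt, spec)
    if not np.isfinite(lp0).all():
        raise EstimationError("could not find finite-posterior starting points")

    sampler = emcee.EnsembleSampler(
        config.walkers, 5,
        lambda th: _log_posterior_batch(th, x0, dx, dt, spec),
        vectorize=True,
    )
    sampler._random = np.random.RandomState(seed % (2 ** 32))
    sampler.run_mcmc(p0, config.steps, progress=False)
    draws = sampler.get_chain(discard=config.burn, thin=config.thin, flat=True)
    return PosteriorSample(
        draws=draws,
        acceptance_fraction=float(np.mean(sampler.acceptance_fraction)),
        seed=seed,
        x_star=float(x.mean()),
    )


def slope_from_params(params, x_star: float):
    """Drift slope ``zeta = theta1 + 2 theta2 x* + 3 theta3 x*^2``.

    ``params`` may be a :class:`DriftDiffusionParams` or an array of draws
    with theta in the first four columns.
    """
    if isinstance(params, DriftDiffusionParams):
        t1, t2, t3 = params.theta1, params.theta2, params.theta3
    else:
        arr = np.atleast_2d(np.asarray(params, dtype=float))
        t1, t2, t3 = arr[:, 1], arr[:, 2], arr[:, 3]
    zeta = t1 + 2.0 * t2 * x_star + 3.0 * t3 * x_star ** 2
    return float(zeta) if np.ndim(zeta) == 0 else zeta


def slope_posterior_summary(sample: PosteriorSample,
                            x_star: Optional[float] = None,
                            time: float = np.nan) -> SlopeEstimate:
    """Map draws to drift slopes and summarize the slope posterior.

    The point estimate is the mode of a Gaussian kernel density estimate
    (Scott bandwidth, 512-point grid over the draw range); the bands are
    the empirical 16/84 and 1/99 percentiles.
    """
    x_star = sample.x_star if x_star is None else x_star
    zetas = slope_from_params(sample.draws, x_star)
    q01, q16, q84, q99 = np.percentile(zetas, [1, 16, 84, 99])
    if np.ptp(zetas) == 0:
        zmap = float(zetas[0])
    else:
        grid = np.linspace(zetas.min(), zetas.max(), 512)
        dens = gaussian_kde(zetas, bw_method="scott")(grid)
        zmap = float(grid[np.argmax(dens)])
    return SlopeEstimate(time=time, zeta_map=zmap,
                         band_68=(float(q16), float(q84)),
                         band_98=(float(q01), float(q99)),
                         x_star=float(x_star))


def rolling_drift_slope(series, dt: float, spec=None,
                        prior_spec: Optional[PriorSpec] = None,
                        mcmc_config: Optional[MCMCConfig] = None,
                        seed: int = 0, times=None) -> list[Optional[SlopeEstimate]]:
    """Drift-slope scan over rolling windows.

    Each window is fitted independently with ``x*`` set to that window's
    mean; windows where sampling fails are recorded as ``None`` so the
    scan stays aligned with the other indicators.
    """
    from driftscan.preprocess import WindowSpec, rolling_windows

    spec = spec or WindowSpec()
    estimates: list[Optional[SlopeEstimate]] = []
    for k, view in enumerate(rolling_windows(series, spec, times=times)):
        try:
            sample = fit_window(view.data, dt, spec=prior_spec,
                                config=mcmc_config, seed=seed + k)
            estimates.append(slope_posterior_summary(sample, time=view.time))
        except EstimationError:
            estimates.append(None)
    return estimates


def slope_table(estimates: Sequence[Optional[SlopeEstimate]],
                times=None) -> pd.DataFrame:
    """Tabulate a drift-slope scan (missing windows become NaN rows)."""
    rows = []
    for k, est in enumerate(estimates):
        if est is None:
            t = np.nan if times is None else times[k]
            rows.append({"window_end_time": t, "zeta_map": np.nan,
                         "q16": np.nan, "q84": np.nan,
                         "q01": np.nan, "q99": np.nan, "x_star": np.nan})
        else:
            rows.append({"window_end_time": est.time, "zeta_map": est.zeta_map,
                         "q16": est.band_68[0], "q84": est.band_68[1],
                         "q01": est.band_98[0], "q99": est.band_98[1],
                         "x_star": est.x_star})
    return pd.DataFrame(rows)
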