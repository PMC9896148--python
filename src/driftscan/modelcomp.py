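"""Bayes-factor trend test for indicator time series.

Each indicator series (drift slope, AR1, standard deviation, skewness,
kurtosis), truncated at the point of no return, is explained by one of two
models:

* M1, a linear trend ``y = a t + b`` with the slope constrained to the
  direction of interest (positive for rising indicators);
* M2, a constant ``y = b``.

Evidences ``p(data | M)`` are estimated by plain Monte Carlo over the
prior: parameters are drawn from data-adapted priors (intercept Gaussian
centred on the first indicator value, slope uniform on an interval scaled
to the series range and duration, noise scale log-uniform on
``[log 0.5, log 5]``), the Gaussian data likelihood of each draw is
evaluated, and the evidence is the prior-draw average, computed in log
space.  The Bayes factor ``BF12 = p(data|M1) / p(data|M2)`` is declared
significant above 100.  When every draw of a model underflows to numerical
zero the evidence is reported as 0, which produces the infinite/zero
Bayes-factor pairs and the "inadequate" label when both models underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "TrendPriorSpec",
    "EvidenceResult",
    "build_prior",
    "evidence",
    "evidence_pair",
    "bayes_factor",
    "classify",
    "truncate_at_landmark",
    "compare_models",
    "SIGNIFICANCE_THRESHOLD",
]

SIGNIFICANCE_THRESHOLD = 100.0

#: All draw log-likelihoods below this value count as numerical zero.
_LOG_ZERO = math.log(np.finfo(float).tiny)


@dataclass(frozen=True)
class TrendPriorSpec:
    """Data-adapted prior ranges for the trend/constant model pair."""

    intercept_mean: float
    intercept_sd: float = 1.0
    slope_lo: float = 0.0
    slope_hi: float = 0.0
    log_noise_lo: float = math.log(0.5)
    log_noise_hi: float = math.log(5.0)
    n_draws: int = 100_000

    def __post_init__(self) -> None:
        if self.n_draws < 1_000:
            raise ValueError("need at least 1000 Monte-Carlo draws")
        if self.slope_lo > self.slope_hi:
            raise ValueError("slope interval reversed")


@dataclass
class EvidenceResult:
    """Evidences, Bayes factors and significance label for one series."""

    evidence_linear: float
    evidence_constant: float
    log_evidence_linear: float
    log_evidence_constant: float
    bf12: float
    bf21: float
    label: str    # significant_linear | significant_constant | undecided | inadequate


def build_prior(indicator_series, times, direction: str = "positive",
                n_draws: int = 100_000) -> TrendPriorSpec:
    """Adapt the prior ranges to one indicator series.

    The intercept prior is centred on the series' initial value (unit
    standard deviation); the slope interval is
    ``[0, 1.5 * range / duration]``, mirrored to negative values for
    indicators expected to fall.  Times are in years.
    """
    y = np.asarray(indicator_series, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(y) < 2 or len(t) < 2:
        raise ValueError("need at least two indicator samples")
    finite = np.isfinite(y)
    if finite.sum() < 2:
        raise ValueError("need at least two finite indicator samples")
    y0 = y[finite][0]
    span = float(y[finite].max() - y[finite].min())
    duration = float(t[-1] - t[0])
    if duration <= 0:
        raise ValueError("times must span a positive duration")
    smax = 1.5 * span / duration
    if direction == "positive":
        lo, hi = 0.0, smax
    elif direction == "negative":
        lo, hi = -smax, 0.0
    else:
        raise ValueError("direction must be 'positive' or 'negative'")
    return TrendPriorSpec(intercept_mean=float(y0), slope_lo=lo, slope_hi=hi,
                          n_draws=n_draws)


def _draw_params(spec: TrendPriorSpec, rng: np.random.Generator):
    b = spec.intercept_mean + spec.intercept_sd * rng.standard_normal(spec.n_draws)
    a = rng.uniform(spec.slope_lo, spec.slope_hi, spec.n_draws)
    s = np.exp(rng.uniform(spec.log_noise_lo, spec.log_noise_hi, spec.n_draws))
    return b, a, s


def _log_evidence_from_draws(y: np.ndarray, t: np.ndarray,
                             b: np.ndarray, a: Optional[np.ndarray],
                             s: np.ndarray) -> float:
    """Log of the prior-draw average of the Gaussian data likelihood."""
    n = len(y)
    mean = b[None, :] if a is None else b[None, :] + np.outer(t, a)
    resid = y[:, None] - mean
    loglik = (-0.5 * (resid ** 2).sum(axis=0) / s ** 2
              - n * np.log(s) - 0.5 * n * math.log(2 * math.pi))
    if loglik.max() < _LOG_ZERO:
        return -np.inf
    return float(logsumexp(loglik) - math.log(len(loglik)))


def _finite_series(indicator_series, times):
    y = np.asarray(indicator_series, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.size == 0:
        raise ValueError("empty indicator series")
    keep = np.isfinite(y)
    return y[keep], t[keep]


def evidence(indicator_series, times, model: str, spec: TrendPriorSpec,
             rng: np.random.Generator) -> float:
    """Monte-Carlo marginal likelihood of one model (0 on total underflow)."""
    y, t = _finite_series(indicator_series, times)
    b, a, s = _draw_params(spec, rng)
    if model == "linear":
        le = _log_evidence_from_draws(y, t, b, a, s)
    elif model == "constant":
        le = _log_evidence_from_draws(y, t, b, None, s)
    else:
        raise ValueError("model must be 'linear' or 'constant'")
    return float(np.exp(le)) if np.isfinite(le) else 0.0


def evidence_pair(indicator_series, times, spec: TrendPriorSpec,
                  rng: np.random.Generator) -> tuple[float, float]:
    """Log evidences of (linear, constant) from a shared draw stream.

    The drawn constant of M2 is reused as the intercept of M1 and the
    noise draws are shared, so the models are compared on matched
    parameter realizations.  Returns ``-inf`` for a model whose draws all
    underflow to numerical zero.
    """
    y, t = _finite_series(indicator_series, times)
    b, a, s = _draw_params(spec, rng)
    le1 = _log_evidence_from_draws(y, t, b, a, s)
    le2 = _log_evidence_from_draws(y, t, b, None, s)
    return le1, le2


def bayes_factor(e1: float, e2: float) -> tuple[float, float]:
    """Bayes-factor pair ``(BF12, BF21)`` with degenerate conventions.

    A model with evidence zero loses with ``BF = inf`` for its rival; two
    zero evidences yield ``(nan, nan)`` and are flagged "inadequate" by
    :func:`classify`.  Accepts linear or log evidences (log values are
    marked by passing ``-inf`` for underflow instead of 0).
    """
    if e1 < 0 or e2 < 0:
        raise ValueError("evidences must be >= 0")
    if e1 == 0 and e2 == 0:
        return (float("nan"), float("nan"))
    if e2 == 0:
        return (float("inf"), 0.0)
    if e1 == 0:
        return (0.0, float("inf"))
    return (e1 / e2, e2 / e1)


def _bayes_factor_log(le1: float, le2: float) -> tuple[float, float]:
    if le1 == -np.inf and le2 == -np.inf:
        return (float("nan"), float("nan"))
    if le2 == -np.inf:
        return (float("inf"), 0.0)
    if le1 == -np.inf:
        return (0.0, float("inf"))
    d = le1 - le2
    with np.errstate(over="ignore"):
        return (float(np.exp(d)), float(np.exp(-d)))


def classify(bf12: float, bf21: float,
             threshold: float = SIGNIFICANCE_THRESHOLD) -> str:
    """Significance label from a Bayes-factor pair.

    Both factors NaN (both evidences zero) marks the comparison
    "inadequate"; a factor above the threshold is significant for its
    model; anything else is undecided.
    """
    if math.isnan(bf12) and math.isnan(bf21):
        return "inadequate"
    if bf12 > threshold:
        return "significant_linear"
    if bf21 > threshold:
        return "significant_constant"
    return "undecided"


def truncate_at_landmark(indicator_series, times, landmark_time: float):
    """Keep indicator samples with ``time <= landmark_time``."""
    y = np.asarray(indicator_series, dtype=float)
    t = np.asarray(times, dtype=float)
    keep = t <= landmark_time
    return y[keep], t[keep]


def compare_models(indicator_series, times, direction: str = "positive",
                   n_draws: int = 100_000,
                   rng: Optional[np.random.Generator] = None) -> EvidenceResult:
    """Full trend-versus-constant comparison for one indicator series."""
    if rng is None:
        rng = np.random.default_rng()
    spec = build_prior(indicator_series, times, direction=direction,
                       n_draws=n_draws)
    le1, le2 = evidence_pair(indicator_series, times, spec, rng)
    bf12, bf21 = _bayes_factor_log(le1, le2)
    e1 = float(np.exp(le1)) if np.isfinite(le1) else 0.0
    e2 = float(np.exp(le2)) if np.isfinite(le2) else 0.0
    return EvidenceResult(
        evidence_linear=e1, evidence_constant=e2,
        log_evidence_linear=le1, log_evidence_constant=le2,
        bf12=bf12, bf21=bf21, label=classify(bf12, bf21),
    )
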