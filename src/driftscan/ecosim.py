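"""Seasonal piscivore/planktivore food-web model under a harvest ramp.

The model couples a continuous within-year ("monitoring") interval

.. math::

    dA/dt = -qE \\, A, \\qquad
    dF/dt = D_F (F_R - F) - c_{FA} F A + \\sigma Z, \\qquad
    dJ/dt = -c_{JA} J A - \\frac{c_{JF} \\nu F J}{h + \\nu + c_{JF} F},

with an annual discrete maturation map

.. math::

    A_{y+1} = s (A_{y;t=1} + J_{y;t=1}), \\qquad
    F_{y+1} = F_y, \\qquad
    J_{y+1} = f A_{y+1}.

``A`` are adult piscivores, ``J`` juvenile piscivores and ``F``
planktivores.  Harvesting removes adults at rate ``qE`` which increases
linearly year by year; stochastic forcing (white, pink or red) enters the
planktivore equation only.  Increasing harvest destroys the
piscivore-dominated annual cycle and the system shifts to a
planktivore-dominated state with ``F`` near the refuge reservoir ``F_R``.

Three destabilization landmarks are located here:

* the *attractor switch*: the smallest harvest rate at which the annual
  cycle no longer persists when the harvest rate is held fixed
  (:func:`find_attractor_switch`);
* the *point of no return*: the smallest ramp harvest rate from which an
  immediate reduction of harvesting to a small rescue value no longer
  prevents the planktivore transition (:func:`find_point_of_no_return`);
* the *transition*: the first time the planktivore abundance exceeds a
  threshold (:func:`detect_transition`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from driftscan.noisegen import NoiseSeries

__all__ = [
    "ModelParams",
    "EcoState",
    "Trajectory",
    "drift_field",
    "step_euler_maruyama",
    "maturation",
    "equilibrate",
    "simulate",
    "find_attractor_switch",
    "find_point_of_no_return",
    "detect_transition",
    "analytic_drift_slope",
    "write_trajectory",
    "read_trajectory",
]


class InvalidStateError(ValueError):
    """Raised when a state contains non-finite abundances."""


class SequencingError(RuntimeError):
    """Raised when the annual maturation map is applied mid-year."""


class NoTransitionError(RuntimeError):
    """Raised when a landmark scan requires a transition that never occurs."""


@dataclass(frozen=True)
class ModelParams:
    """Ecological rate constants, harvest ramp and integration step.

    All rates are per year; abundances are in individuals (arbitrary
    absolute scale).  ``sigma`` is the noise level on the per-sqrt(year)
    scale; the per-step forcing added to ``F`` is ``sigma * z`` with ``z``
    the precomputed forcing increment of the step.
    """

    qE_init: float = 1.0      # initial harvest rate (catchability x effort)
    dqE: float = 0.013        # harvest-rate increase per year
    F_R: float = 100.0        # planktivore refuge reservoir
    D_F: float = 0.1          # foraging-arena exchange rate
    c_FA: float = 0.3         # consumption of planktivores by adults
    c_JA: float = 0.001       # control of juveniles by adults
    c_JF: float = 0.5         # consumption of juveniles by planktivores
    nu: float = 1.0           # vulnerability rate of juveniles
    h_ref: float = 8.0        # refuge-entry rate of juveniles
    f_fec: float = 2.0        # fecundity of adults
    s_surv: float = 0.5       # overwinter survival
    dt: float = 1.0 / 50.0    # integration step in years
    sigma: float = 0.0        # noise level (0 for deterministic runs)

    def __post_init__(self) -> None:
        for name in ("qE_init", "dqE", "F_R", "D_F", "c_FA", "c_JA",
                     "c_JF", "nu", "h_ref", "f_fec", "sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.s_surv <= 1.0:
            raise ValueError("s_surv must lie in [0, 1]")
        if not 0.0 < self.dt <= 1.0:
            raise ValueError("dt must lie in (0, 1]")
        if abs(round(1.0 / self.dt) - 1.0 / self.dt) > 1e-9:
            raise ValueError("1/dt must be an integer (samples per year)")

    @property
    def samples_per_year(self) -> int:
        return round(1.0 / self.dt)


@dataclass
class EcoState:
    """Instantaneous state of the food web."""

    A: float
    J: float
    F: float
    year: int = 0
    tau: float = 0.0   # within-year time in [0, 1]
    qE: float = 1.0

    def validate(self) -> None:
        if not (np.isfinite(self.A) and np.isfinite(self.J) and np.isfinite(self.F)):
            raise InvalidStateError(f"non-finite abundances: {self}")


@dataclass
class Trajectory:
    """Uniformly sampled model trajectory.

    ``times`` run from 0 (start of the harvest ramp) in steps of ``dt``.
    The sample at an integer year is the post-maturation state (the first
    record of the new year); ``year_end_A`` keeps the pre-maturation
    adult abundance at the end of each monitoring interval, which is the
    quantity the annual cycle is diagnosed on.
    """

    times: np.ndarray
    A_series: np.ndarray
    J_series: np.ndarray
    F_series: np.ndarray
    qE_series: np.ndarray
    year_end_A: np.ndarray = field(default_factory=lambda: np.empty(0))
    params: Optional[ModelParams] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        n = len(self.times)
        for arr in (self.A_series, self.J_series, self.F_series, self.qE_series):
            if len(arr) != n:
                raise ValueError("all trajectory series must have equal length")
        d = np.diff(self.times)
        if n > 1 and not (d > 0).all():
            raise ValueError("times must be strictly increasing")


def drift_field(state: EcoState, p: ModelParams) -> tuple[float, float, float]:
    """Deterministic right-hand sides ``(dA/dt, dF/dt, dJ/dt)``."""
    state.validate()
    if state.A < 0 or state.J < 0 or state.F < 0:
        raise InvalidStateError("abundances must be >= 0")
    dA = -state.qE * state.A
    dF = p.D_F * (p.F_R - state.F) - p.c_FA * state.F * state.A
    dJ = (-p.c_JA * state.J * state.A
          - p.c_JF * p.nu * state.F * state.J
          / (p.h_ref + p.nu + p.c_JF * state.F))
    return dA, dF, dJ


def step_euler_maruyama(state: EcoState, p: ModelParams, z: float = 0.0) -> EcoState:
    """One Euler--Maruyama step of length ``dt``.

    ``z`` is the forcing increment for this step (a Wiener increment for
    white noise, ``Z * dt`` for colored noise); it enters the planktivore
    equation only, scaled by ``sigma``.  Abundances are clipped at zero.
    """
    if p.dt <= 0:
        raise ValueError("dt must be positive")
    dA, dF, dJ = drift_field(state, p)
    return EcoState(
        A=max(state.A + dA * p.dt, 0.0),
        F=max(state.F + dF * p.dt + p.sigma * z, 0.0),
        J=max(state.J + dJ * p.dt, 0.0),
        year=state.year,
        tau=state.tau + p.dt,
        qE=state.qE,
    )


def maturation(state: EcoState, p: ModelParams) -> EcoState:
    """Annual maturation map, applied at the end of the monitoring interval.

    Surviving adults and juveniles form the new adult class, the new
    juvenile class is the adults' offspring, planktivores carry over
    unchanged.  Advances the year and updates the harvest ramp.
    """
    if abs(state.tau - 1.0) > 1e-9:
        raise SequencingError(f"maturation requires tau = 1, got tau = {state.tau}")
    A_new = p.s_surv * (state.A + state.J)
    year = state.year + 1
    return EcoState(
        A=A_new,
        F=state.F,
        J=p.f_fec * A_new,
        year=year,
        tau=0.0,
        qE=p.qE_init + p.dqE * year,
    )


# -- deterministic core loops (plain floats; these dominate the landmark
#    scans, so they avoid per-step object construction) --------------------

def _year_det(A: float, F: float, J: float, qE: float, p: ModelParams
              ) -> tuple[float, float, float]:
    """Integrate one deterministic monitoring interval."""
    dt = p.dt
    D_F, F_R, c_FA = p.D_F, p.F_R, p.c_FA
    c_JA, c_JF, nu, h = p.c_JA, p.c_JF, p.nu, p.h_ref
    for _ in range(p.samples_per_year):
        dA = -qE * A
        dF = D_F * (F_R - F) - c_FA * F * A
        dJ = -c_JA * J * A - c_JF * nu * F * J / (h + nu + c_JF * F)
        A = max(A + dA * dt, 0.0)
        F = max(F + dF * dt, 0.0)
        J = max(J + dJ * dt, 0.0)
    return A, F, J


def _map(A: float, F: float, J: float, p: ModelParams) -> tuple[float, float, float]:
    A_new = p.s_surv * (A + J)
    return A_new, F, p.f_fec * A_new


# Burn-in convention: the ramp starts on the deterministic attractor at
# qE_init, found by iterating the annual map from a piscivore-dominated
# guess for a fixed number of discarded years.
_BURNIN_STATE = (300.0, 1.0, 600.0)   # (A, F, J)
_BURNIN_YEARS = 20


def equilibrate(p: ModelParams, years: int = _BURNIN_YEARS) -> tuple[float, float, float]:
    """Relax onto the deterministic annual cycle at ``qE_init``."""
    A, F, J = _BURNIN_STATE
    for _ in range(years):
        A, F, J = _year_det(A, F, J, p.qE_init, p)
        A, F, J = _map(A, F, J, p)
    return A, F, J


def simulate(p: ModelParams, years: int, noise: Optional[NoiseSeries] = None,
             seed: Optional[int] = None, burn_in: int = _BURNIN_YEARS) -> Trajectory:
    """Simulate ``years`` of the harvest ramp after a discarded burn-in.

    Alternates ``1/dt`` Euler--Maruyama steps with one maturation map per
    year.  With ``sigma > 0`` a forcing series must be supplied (or a seed
    from which white forcing is drawn).  The run is deterministic given
    ``(p, noise, seed)``.
    """
    spy = p.samples_per_year
    n_steps = years * spy
    if p.sigma > 0:
        if noise is None:
            if seed is None:
                raise ValueError("stochastic run needs a noise series or a seed")
            from driftscan import noisegen
            noise = noisegen.white_noise(n_steps, p.dt, np.random.default_rng(seed))
        z = noise.increments
        if len(z) < n_steps:
            raise ValueError(
                f"noise series too short: {len(z)} increments < {n_steps} steps")
    else:
        z = np.zeros(n_steps)

    A, F, J = equilibrate(p, burn_in)

    n = n_steps + 1
    times = np.arange(n) * p.dt
    A_s = np.empty(n); J_s = np.empty(n); F_s = np.empty(n); qE_s = np.empty(n)
    year_end_A = np.empty(years)

    A_s[0], F_s[0], J_s[0] = A, F, J
    qE = p.qE_init
    qE_s[0] = qE
    sigma, dt = p.sigma, p.dt
    D_F, F_R, c_FA = p.D_F, p.F_R, p.c_FA
    c_JA, c_JF, nu, h = p.c_JA, p.c_JF, p.nu, p.h_ref

    i = 1
    for y in range(years):
        qE = p.qE_init + p.dqE * y
        base = y * spy
        for k in range(spy):
            dA = -qE * A
            dF = D_F * (F_R - F) - c_FA * F * A
            dJ = -c_JA * J * A - c_JF * nu * F * J / (h + nu + c_JF * F)
            A = max(A + dA * dt, 0.0)
            F = max(F + dF * dt + sigma * z[base + k], 0.0)
            J = max(J + dJ * dt, 0.0)
            if k < spy - 1:
                A_s[i], F_s[i], J_s[i], qE_s[i] = A, F, J, qE
                i += 1
        year_end_A[y] = A
        A, F, J = _map(A, F, J, p)
        # post-maturation state is the first record of the new year
        A_s[i], F_s[i], J_s[i] = A, F, J
        qE_s[i] = p.qE_init + p.dqE * (y + 1)
        i += 1

    return Trajectory(times=times, A_series=A_s, J_series=J_s, F_series=F_s,
                      qE_series=qE_s, year_end_A=year_end_A, params=p, seed=seed)


def find_attractor_switch(p: ModelParams, qE_max: float = 3.0,
                          max_settle_years: int = 20000,
                          rel_tol: float = 1e-10,
                          extinct_below: float = 1e-6) -> Optional[float]:
    """Harvest rate at which the piscivore annual cycle stops persisting.

    Scans harvest rates from ``qE_init`` upward in steps of ``dqE`` (one
    ramp year).  At each candidate the harvest rate is held fixed and the
    annual map is iterated from the previous attractor: if the year-end
    adult abundance settles, the cycle still exists; if it declines in
    every subsequent year down to extinction, the cycle has opened up.
    Returns the first such harvest rate, or ``None`` if the cycle persists
    over the whole scanned range.

    Requires a deterministic parameterization (``sigma == 0``).
    """
    if p.sigma != 0:
        raise ValueError("attractor-switch scan requires sigma = 0")
    A, F, J = equilibrate(p)
    qE = p.qE_init
    while qE <= qE_max + 1e-12:
        prev = None
        opened = True
        for _ in range(max_settle_years):
            A, F, J = _year_det(A, F, J, qE, p)
            A_end = A
            A, F, J = _map(A, F, J, p)
            if A_end < extinct_below:
                break
            if prev is not None and abs(A_end - prev) <= rel_tol * max(A_end, 1.0):
                opened = False
                break
            prev = A_end
        if opened:
            return qE
        qE += p.dqE
    return None


def detect_transition(traj: Trajectory, threshold: float = 21.0) -> Optional[float]:
    """Time (years) at which planktivores first exceed ``threshold``."""
    above = traj.F_series > threshold
    if not above.any():
        return None
    return float(traj.times[int(np.argmax(above))])


def _rescue_fails(A: float, F: float, J: float, p: ModelParams,
                  rescue_qE: float, horizon: int, threshold: float) -> bool:
    """Does the planktivore transition still occur after cutting harvest?"""
    for _ in range(horizon):
        A, F, J = _year_det(A, F, J, rescue_qE, p)
        if F > threshold:
            return True
        A, F, J = _map(A, F, J, p)
    return F > threshold


def find_point_of_no_return(p: ModelParams, rescue_qE: float = 0.1,
                            horizon: int = 200, scan_years: int = 140,
                            threshold: float = 21.0) -> float:
    """Smallest ramp harvest rate from which rescue no longer works.

    Runs the deterministic harvest ramp, and for each ramp year clones the
    start-of-year state, fixes the harvest rate at ``rescue_qE`` and
    integrates ``horizon`` further years.  Returns the ramp harvest rate of
    the first year whose rescue still ends in the planktivore transition
    (monotonicity of rescue failure along the ramp is exploited by
    bisection; it is verified empirically in the test suite).
    """
    if p.sigma != 0:
        raise ValueError("point-of-no-return scan requires sigma = 0")
    A, F, J = equilibrate(p)
    states = []
    for y in range(scan_years):
        states.append((A, F, J))
        A, F, J = _year_det(A, F, J, p.qE_init + p.dqE * y, p)
        A, F, J = _map(A, F, J, p)

    def fails(y: int) -> bool:
        return _rescue_fails(*states[y], p, rescue_qE, horizon, threshold)

    if not fails(scan_years - 1):
        raise NoTransitionError(
            "no rescue failure within the scanned ramp; transition never locks in")
    lo, hi = 0, scan_years - 1
    if fails(lo):
        return p.qE_init
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if fails(mid):
            hi = mid
        else:
            lo = mid
    return p.qE_init + p.dqE * hi


def analytic_drift_slope(traj: Trajectory, p: ModelParams, window) -> pd.DataFrame:
    """Window-averaged analytic planktivore drift slope.

    The partial derivative of the planktivore drift in the planktivore
    direction is ``d(dF/dt)/dF = -(D_F + c_FA * A(t))``; it is evaluated
    along the realized adult abundance and averaged over the same rolling
    windows as the drift-slope estimator.  ``window`` is a
    :class:`driftscan.preprocess.WindowSpec` or an integer window size
    (then with shift equal to the size).
    """
    from driftscan.preprocess import WindowSpec, rolling_windows

    if isinstance(window, int):
        window = WindowSpec(size=window, shift=window)
    local = -(p.D_F + p.c_FA * traj.A_series)
    views = rolling_windows(local, window, times=traj.times)
    return pd.DataFrame({
        "time": [v.time for v in views],
        "zeta_analytic": [float(np.mean(v.data)) for v in views],
    })


# -- interchange -----------------------------------------------------------

def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """CSV with time_years, A, J, F, qE plus a JSON sidecar with params/seed."""
    path = Path(path)
    pd.DataFrame({
        "time_years": traj.times,
        "A": traj.A_series,
        "J": traj.J_series,
        "F": traj.F_series,
        "qE": traj.qE_series,
    }).to_csv(path, index=False)
    meta = {"seed": traj.seed,
            "params": asdict(traj.params) if traj.params else None,
            "year_end_A": traj.year_end_A.tolist()}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    params = seed = None
    year_end_A = np.empty(0)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        seed = meta.get("seed")
        if meta.get("params"):
            params = ModelParams(**meta["params"])
        year_end_A = np.asarray(meta.get("year_end_A", []))
    return Trajectory(
        times=df["time_years"].to_numpy(),
        A_series=df["A"].to_numpy(),
        J_series=df["J"].to_numpy(),
        F_series=df["F"].to_numpy(),
        qE_series=df["qE"].to_numpy(),
        year_end_A=year_end_A,
        params=params, seed=seed,
    )
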