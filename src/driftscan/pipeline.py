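"""End-to-end orchestration of the resilience study design.

A *case* is one combination of noise type (white, pink, red), noise level
``sigma`` and preprocessing choice.  :func:`run_case` carries a case
through the full chain:

1. simulate the harvested food web under the configured forcing;
2. deseasonalize the planktivore series (year-over-year differencing for
   white noise, Gaussian-kernel residuals for correlated noise, by
   default);
3. scan rolling windows with the Bayesian drift slope and the four
   classical indicators;
4. truncate every indicator series at the deterministic point of no
   return;
5. run the Bayes-factor trend test on each indicator and classify the
   result.

Two execution profiles are provided: ``desk`` (window shift 150 samples,
1e5 evidence draws) for quick runs, and ``paper`` (shift 30, 1e7 draws)
for full-resolution scans.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from driftscan import ecosim, noisegen, preprocess, indicators, driftslope, modelcomp

__all__ = ["CaseConfig", "PROFILES", "run_case", "window_size_study", "make_figures"]

#: Noise levels of the study design (per sqrt(year) scale).
STUDY_SIGMAS = (0.1, 2.2, 4.5)

PROFILES = {
    "desk": {"shift": 150, "n_draws": 100_000},
    "paper": {"shift": 30, "n_draws": 10_000_000},
}

#: Indicators expected to rise toward the transition; the trend test for
#: all of them uses a positive-slope prior by default.
_INDICATOR_DIRECTIONS = {
    "zeta": "positive",
    "ar1": "positive",
    "std": "positive",
    "skewness": "positive",
    "kurtosis": "positive",
}


@dataclass(frozen=True)
class CaseConfig:
    """One study case: forcing, preprocessing and analysis geometry."""

    noise: str = "white"            # white | pink | red
    sigma: float = 2.2
    deseason: str = "auto"          # auto | none | yoy | smooth
    years: int = 120
    seed: int = 0
    profile: str = "desk"
    window_size: int = 750
    shift: Optional[int] = None     # None: taken from the profile
    n_draws: Optional[int] = None   # None: taken from the profile
    colored_power: float = noisegen.DEFAULT_COLORED_POWER
    phi: float = noisegen.DEFAULT_PHI
    pink_beta: float = noisegen.DEFAULT_PINK_BETA
    directions: dict = field(default_factory=lambda: dict(_INDICATOR_DIRECTIONS))
    mcmc: driftslope.MCMCConfig = field(default_factory=driftslope.MCMCConfig)

    def resolved_shift(self) -> int:
        return self.shift if self.shift is not None else PROFILES[self.profile]["shift"]

    def resolved_draws(self) -> int:
        return self.n_draws if self.n_draws is not None else PROFILES[self.profile]["n_draws"]

    def resolved_deseason(self) -> str:
        if self.deseason != "auto":
            return self.deseason
        return "yoy" if self.noise == "white" else "smooth"

    def window_spec(self) -> preprocess.WindowSpec:
        return preprocess.WindowSpec(size=self.window_size, shift=self.resolved_shift())

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _make_noise(cfg: CaseConfig, n_steps: int, dt: float) -> Optional[noisegen.NoiseSeries]:
    rng = np.random.default_rng(cfg.seed)
    if cfg.sigma == 0:
        return None
    if cfg.noise == "white":
        return noisegen.white_noise(n_steps, dt, rng)
    if cfg.noise == "pink":
        return noisegen.pink_noise(n_steps, dt, beta=cfg.pink_beta, rng=rng,
                                   power=cfg.colored_power)
    if cfg.noise == "red":
        return noisegen.red_noise(n_steps, dt, phi=cfg.phi, rng=rng,
                                  power=cfg.colored_power)
    raise ValueError(f"unknown noise kind {cfg.noise!r}")


def _prior_for_case(cfg: CaseConfig) -> driftslope.PriorSpec:
    # broader support for smoothing-deseasonalized correlated-noise series
    if cfg.noise != "white" and cfg.resolved_deseason() == "smooth":
        return driftslope.PriorSpec.wide()
    return driftslope.PriorSpec()


def deseasonalized_series(cfg: CaseConfig, traj: ecosim.Trajectory
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Planktivore series after the case's preprocessing, with times."""
    mode = cfg.resolved_deseason()
    if mode == "none":
        return traj.F_series, traj.times
    if mode == "yoy":
        spy = traj.params.samples_per_year if traj.params else 50
        return preprocess.deseasonalize_yoy(traj.F_series, spy, times=traj.times)
    if mode == "smooth":
        return preprocess.deseasonalize_smooth(traj.F_series), traj.times
    raise ValueError(f"unknown deseasonalization {mode!r}")


def compute_landmarks(params: ecosim.ModelParams) -> dict:
    """Deterministic destabilization landmarks for the parameter set."""
    det = dataclasses.replace(params, sigma=0.0)
    switch_qE = ecosim.find_attractor_switch(det)
    ponr_qE = ecosim.find_point_of_no_return(det)
    to_years = lambda q: (q - det.qE_init) / det.dqE if q is not None else None
    return {
        "attractor_switch_qE": switch_qE,
        "attractor_switch_year": to_years(switch_qE),
        "point_of_no_return_qE": ponr_qE,
        "point_of_no_return_year": to_years(ponr_qE),
    }


def run_case(cfg: CaseConfig, out_dir: Optional[str | Path] = None,
             with_indicators: bool = True,
             landmarks: Optional[dict] = None) -> dict:
    """Run one case end to end and return the case report.

    The report contains the landmarks, the drift-slope table, the
    classical-indicator table, and one evidence/Bayes-factor row per
    indicator (drift slope plus the four classical statistics), all
    truncated at the point of no return.  With ``out_dir`` set, the
    tables and the report are also written to disk with full provenance
    (config hash and seeds).
    """
    t0 = _time.time()
    timings = {}
    params = ecosim.ModelParams(sigma=cfg.sigma)
    if landmarks is None:
        landmarks = compute_landmarks(params)
        timings["landmarks_s"] = round(_time.time() - t0, 2)

    t1 = _time.time()
    n_steps = cfg.years * params.samples_per_year
    noise = _make_noise(cfg, n_steps, params.dt)
    traj = ecosim.simulate(params, cfg.years, noise=noise, seed=cfg.seed)
    series, times = deseasonalized_series(cfg, traj)
    timings["simulate_s"] = round(_time.time() - t1, 2)

    wspec = cfg.window_spec()
    ponr_time = landmarks["point_of_no_return_year"]

    t2 = _time.time()
    estimates = driftslope.rolling_drift_slope(
        series, params.dt, spec=wspec, prior_spec=_prior_for_case(cfg),
        mcmc_config=cfg.mcmc, seed=cfg.seed * 1000 + 1, times=times)
    slope_df = driftslope.slope_table(estimates)
    timings["drift_slope_s"] = round(_time.time() - t2, 2)

    t3 = _time.time()
    indicator_df = (indicators.indicator_table(series, wspec, times=times)
                    if with_indicators else None)
    timings["indicators_s"] = round(_time.time() - t3, 2)

    t4 = _time.time()
    rng = np.random.default_rng(cfg.seed * 1000 + 7)
    comparisons = {}
    indicator_series = {"zeta": (slope_df["window_end_time"].to_numpy(),
                                 slope_df["zeta_map"].to_numpy())}
    if with_indicators:
        for name in indicators.INDICATORS:
            indicator_series[name] = (indicator_df["time"].to_numpy(),
                                      indicator_df[name].to_numpy())
    for name, (t_arr, y_arr) in indicator_series.items():
        y_cut, t_cut = modelcomp.truncate_at_landmark(y_arr, t_arr, ponr_time)
        res = modelcomp.compare_models(
            y_cut, t_cut, direction=cfg.directions.get(name, "positive"),
            n_draws=cfg.resolved_draws(), rng=rng)
        comparisons[name] = res
    timings["evidence_s"] = round(_time.time() - t4, 2)

    report = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "landmarks": landmarks,
        "transition_time": ecosim.detect_transition(traj),
        "slope": slope_df,
        "indicators": indicator_df,
        "comparisons": comparisons,
        "labels": {k: v.label for k, v in comparisons.items()},
        "timings": timings,
        "trajectory": traj,
    }
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _json_safe(x):
    if isinstance(x, float):
        return x
    if isinstance(x, dict):
        return {k: _json_safe(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_json_safe(v) for v in x]
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return _json_safe(asdict(x))
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return x


def _write_report(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report["slope"].to_csv(out_dir / "drift_slope.csv", index=False)
    if report["indicators"] is not None:
        report["indicators"].to_csv(out_dir / "indicators.csv", index=False)
    ecosim.write_trajectory(report["trajectory"], out_dir / "trajectory.csv")
    summary = {
        "config": _json_safe(report["config"]),
        "config_hash": report["config_hash"],
        "landmarks": report["landmarks"],
        "transition_time": report["transition_time"],
        "comparisons": {k: _json_safe(v) for k, v in report["comparisons"].items()},
        "labels": report["labels"],
        "timings": report["timings"],
    }
    (out_dir / "report.json").write_text(json.dumps(summary, indent=1))
    log = [f"{k}: {v}s" for k, v in report["timings"].items()]
    (out_dir / "run.log").write_text("\n".join(log) + "\n")


def window_size_study(cfg: CaseConfig, sizes=(150, 100, 50, 25),
                      landmarks: Optional[dict] = None) -> dict:
    """Drift-slope significance as a function of window size.

    Repeats the drift-slope part of :func:`run_case` for each window size
    in decreasing order and reports the label per size plus the smallest
    size whose trend test is still significant.
    """
    sizes = sorted(sizes, reverse=True)
    per_size = {}
    smallest = None
    params = ecosim.ModelParams(sigma=cfg.sigma)
    if landmarks is None:
        landmarks = compute_landmarks(params)
    for size in sizes:
        # small study windows need the shift capped at the window size
        sub = dataclasses.replace(cfg, window_size=size,
                                  shift=min(cfg.resolved_shift(), size))
        rep = run_case(sub, with_indicators=False, landmarks=landmarks)
        label = rep["labels"]["zeta"]
        per_size[size] = {"label": label, "bf12": rep["comparisons"]["zeta"].bf12}
        if label == "significant_linear":
            smallest = size
    return {
        "config": asdict(cfg),
        "sizes": list(sizes),
        "per_size": per_size,
        "smallest_significant": smallest,
        "landmarks": landmarks,
    }


def make_figures(report: dict, out_dir: str | Path) -> list[Path]:
    """Drift-slope and indicator panels with landmark annotations."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    slope = report["slope"]
    lm = report["landmarks"]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(slope["window_end_time"], slope["zeta_map"], color="C3", lw=1.5,
            label="drift slope (KDE mode)")
    ax.fill_between(slope["window_end_time"], slope["q16"], slope["q84"],
                    color="C2", alpha=0.4, label="68% band")
    ax.fill_between(slope["window_end_time"], slope["q01"], slope["q99"],
                    color="C2", alpha=0.2, label="98% band")
    ax.axhline(0.0, color="red", ls=":", lw=1)
    if lm["attractor_switch_year"] is not None:
        ax.axvline(lm["attractor_switch_year"], color="green", ls=":",
                   label="attractor switch")
    if lm["point_of_no_return_year"] is not None:
        ax.axvline(lm["point_of_no_return_year"], color="orange",
                   label="point of no return")
    if report.get("transition_time") is not None:
        ax.axvspan(report["transition_time"], float(slope["window_end_time"].max()),
                   color="gray", alpha=0.25)
    ax.set_xlabel("time (years)")
    ax.set_ylabel(r"drift slope $\zeta$")
    ax.legend(loc="lower right", fontsize=8)
    p = out_dir / "drift_slope.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    if report.get("indicators") is not None:
        ind = report["indicators"]
        fig, axes = plt.subplots(2, 2, figsize=(8, 5), sharex=True)
        for ax, name in zip(axes.ravel(), ["ar1", "std", "skewness", "kurtosis"]):
            ax.plot(ind["time"], ind[name], lw=1)
            ax.set_ylabel(name)
            if lm["point_of_no_return_year"] is not None:
                ax.axvline(lm["point_of_no_return_year"], color="orange", lw=1)
        for ax in axes[-1]:
            ax.set_xlabel("time (years)")
        p = out_dir / "indicators.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths
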