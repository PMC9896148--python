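import dataclasses

import numpy as np
import pytest

from driftscan import ecosim, noisegen
from driftscan.ecosim import (EcoState, InvalidStateError, ModelParams,
                              NoTransitionError, SequencingError, Trajectory)


def state(A=0.0, J=0.0, F=0.0, tau=0.0, qE=1.0, year=0):
    return EcoState(A=A, J=J, F=F, tau=tau, qE=qE, year=year)


class TestDriftField:
    def test_adult_harvest(self, default_params):
        dA, _, _ = ecosim.drift_field(state(A=10.0, qE=1.0), default_params)
        assert dA == -10.0

    def test_refuge_equilibrium(self, default_params):
        _, dF, _ = ecosim.drift_field(state(F=100.0, A=0.0), default_params)
        assert dF == 0.0

    def test_juvenile_rate(self, default_params):
        _, _, dJ = ecosim.drift_field(state(A=1.0, F=8.0, J=1.0), default_params)
        assert dJ == pytest.approx(-0.001 - 4.0 / 13.0, rel=1e-12)

    def test_nonfinite_state_rejected(self, default_params):
        with pytest.raises(InvalidStateError):
            ecosim.drift_field(state(A=np.nan), default_params)

    def test_negative_state_rejected(self, default_params):
        with pytest.raises(InvalidStateError):
            ecosim.drift_field(state(A=-1.0), default_params)


class TestStep:
    def test_explicit_euler_adult(self, default_params):
        s1 = ecosim.step_euler_maruyama(state(A=10.0, qE=1.0), default_params)
        assert s1.A == pytest.approx(10.0 * (1 - 1 / 50), rel=1e-12)

    def test_fixed_point_invariant(self, default_params):
        s0 = state(A=0.0, J=0.0, F=100.0)
        s1 = ecosim.step_euler_maruyama(s0, default_params)
        assert (s1.A, s1.J, s1.F) == (0.0, 0.0, 100.0)

    def test_negative_clipped(self, default_params):
        p = dataclasses.replace(default_params, sigma=1.0)
        s1 = ecosim.step_euler_maruyama(state(F=1.0), p, z=-1000.0)
        assert s1.F == 0.0

    def test_tau_advances(self, default_params):
        s1 = ecosim.step_euler_maruyama(state(), default_params)
        assert s1.tau == pytest.approx(default_params.dt)


class TestMaturation:
    def test_map_values(self, default_params):
        s1 = ecosim.maturation(state(A=10.0, J=6.0, F=3.0, tau=1.0), default_params)
        assert s1.A == 8.0 and s1.J == 16.0 and s1.F == 3.0

    def test_year_and_ramp(self, default_params):
        s1 = ecosim.maturation(state(tau=1.0, year=4), default_params)
        assert s1.year == 5 and s1.tau == 0.0
        assert s1.qE == pytest.approx(1.0 + 0.013 * 5)

    def test_extinction_at_zero_survival(self, default_params):
        p = dataclasses.replace(default_params, s_surv=0.0)
        s1 = ecosim.maturation(state(A=10.0, J=6.0, tau=1.0), p)
        assert s1.A == 0.0 and s1.J == 0.0

    def test_midyear_call_rejected(self, default_params):
        with pytest.raises(SequencingError):
            ecosim.maturation(state(tau=0.5), default_params)


class TestSimulate:
    def test_deterministic_cycle_keeps_planktivores_low(self, default_params):
        traj = ecosim.simulate(default_params, 30)
        assert np.all(traj.F_series < 1.0)
        # the explicit Euler step overshoots the fast planktivore relaxation
        # when adults are abundant, so single samples may clip to the 0 floor
        assert np.all(traj.F_series >= 0.0)
        assert traj.F_series.mean() > 0.0

    def test_determinism(self):
        p = ModelParams(sigma=2.2)
        t1 = ecosim.simulate(p, 10, seed=7)
        t2 = ecosim.simulate(p, 10, seed=7)
        assert np.array_equal(t1.F_series, t2.F_series)
        assert np.array_equal(t1.A_series, t2.A_series)

    def test_noise_too_short(self):
        p = ModelParams(sigma=2.2)
        rng = np.random.default_rng(0)
        short = noisegen.white_noise(10, p.dt, rng)
        with pytest.raises(ValueError, match="too short"):
            ecosim.simulate(p, 10, noise=short)

    def test_nonnegative_under_strong_noise(self):
        p = ModelParams(sigma=20.0)
        traj = ecosim.simulate(p, 20, seed=3)
        for arr in (traj.A_series, traj.J_series, traj.F_series):
            assert np.all(arr >= 0.0)

    def test_shapes_and_times(self, default_params):
        traj = ecosim.simulate(default_params, 5)
        assert len(traj.times) == 5 * 50 + 1
        assert np.allclose(np.diff(traj.times), default_params.dt)
        assert len(traj.year_end_A) == 5

    def test_refuge_convergence_without_piscivores(self, default_params):
        A, F, J = 0.0, 1.0, 0.0
        prev = F
        for _ in range(200):
            A, F, J = ecosim._year_det(A, F, J, 5.0, default_params)
            assert F >= prev  # monotone approach to the refuge level
            prev = F
        assert F == pytest.approx(100.0, abs=1e-6)

    def test_euler_convergence(self, default_params):
        fine = dataclasses.replace(default_params, dt=1.0 / 100.0)
        t1 = ecosim.simulate(default_params, 30)
        t2 = ecosim.simulate(fine, 30)
        a1, a2 = t1.year_end_A[-1], t2.year_end_A[-1]
        assert a1 == pytest.approx(a2, rel=0.05)


class TestLandmarks:
    def test_attractor_switch_range(self, landmarks):
        q = landmarks["attractor_switch_qE"]
        assert q is not None and 1.0 < q < 2.5

    def test_no_switch_when_harvest_stays_low(self, default_params):
        p = dataclasses.replace(default_params, qE_init=0.1)
        assert ecosim.find_attractor_switch(p, qE_max=0.3) is None

    def test_switch_requires_deterministic(self):
        with pytest.raises(ValueError):
            ecosim.find_attractor_switch(ModelParams(sigma=2.2))

    def test_ponr_after_switch(self, landmarks):
        assert landmarks["point_of_no_return_qE"] > landmarks["attractor_switch_qE"]

    def test_rescue_succeeds_before_switch(self, default_params, landmarks):
        A, F, J = ecosim.equilibrate(default_params)
        # state on the attractor, well before the switch: rescue must work
        assert not ecosim._rescue_fails(A, F, J, default_params,
                                        rescue_qE=0.1, horizon=200, threshold=21.0)

    def test_rescue_monotone_along_ramp(self, default_params, landmarks):
        ponr_year = round(landmarks["point_of_no_return_year"])
        A, F, J = ecosim.equilibrate(default_params)
        states = []
        for y in range(min(ponr_year + 5, 140)):
            states.append((A, F, J))
            A, F, J = ecosim._year_det(A, F, J, 1.0 + 0.013 * y, default_params)
            A, F, J = ecosim._map(A, F, J, default_params)
        flags = [ecosim._rescue_fails(*s, default_params, 0.1, 200, 21.0)
                 for s in states[max(0, ponr_year - 3):]]
        # once rescue fails it fails for every later ramp year
        first_fail = flags.index(True)
        assert all(flags[first_fail:])

    def test_ponr_error_without_transition(self, default_params):
        with pytest.raises(NoTransitionError):
            ecosim.find_point_of_no_return(default_params, scan_years=5)


class TestDetectTransition:
    def _traj(self, F):
        n = len(F)
        t = np.arange(n, dtype=float)
        z = np.zeros(n)
        return Trajectory(times=t, A_series=z, J_series=z,
                          F_series=np.asarray(F, float), qE_series=z)

    def test_constant_below(self):
        assert ecosim.detect_transition(self._traj(np.full(50, 5.0))) is None

    def test_linear_ramp(self):
        tr = ecosim.detect_transition(self._traj(np.arange(50, dtype=float)))
        assert tr == 22.0  # first sample with F > 21

    def test_on_simulation(self, default_params):
        traj = ecosim.simulate(default_params, 125)
        tr = ecosim.detect_transition(traj)
        assert tr is not None and tr > 0


class TestAnalyticDriftSlope:
    def _traj(self, A):
        n = len(A)
        z = np.zeros(n)
        return Trajectory(times=np.arange(n, dtype=float), A_series=np.asarray(A, float),
                          J_series=z, F_series=z, qE_series=z)

    def test_no_adults(self, default_params):
        df = ecosim.analytic_drift_slope(self._traj(np.zeros(100)), default_params, 10)
        assert np.allclose(df["zeta_analytic"], -0.1)

    def test_constant_adults(self, default_params):
        df = ecosim.analytic_drift_slope(self._traj(np.full(100, 10.0)),
                                         default_params, 10)
        assert np.allclose(df["zeta_analytic"], -3.1)


class TestIO:
    def test_roundtrip(self, tmp_path, default_params):
        traj = ecosim.simulate(default_params, 3)
        path = tmp_path / "traj.csv"
        ecosim.write_trajectory(traj, path)
        back = ecosim.read_trajectory(path)
        assert np.allclose(back.F_series, traj.F_series)
        assert np.allclose(back.year_end_A, traj.year_end_A)
        assert back.params == traj.params


class TestParams:
    def test_defaults_match_model_table(self, default_params):
        p = default_params
        assert (p.qE_init, p.dqE, p.F_R, p.D_F) == (1.0, 0.013, 100.0, 0.1)
        assert (p.c_FA, p.c_JA, p.c_JF, p.nu) == (0.3, 0.001, 0.5, 1.0)
        assert (p.h_ref, p.f_fec, p.s_surv, p.dt) == (8.0, 2.0, 0.5, 1.0 / 50.0)
        assert p.samples_per_year == 50

    @pytest.mark.parametrize("kwargs", [
        {"dqE": -0.1}, {"s_surv": 1.5}, {"dt": 0.0}, {"dt": 0.03},
    ])
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)
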