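"""Bicycle vehicle model, prediction primitives and road disturbance."""

import numpy as np
import pytest

from intermit.core import PrimitiveShape
from intermit.perception import StraightRoad, TwoPointLaw
from intermit.plants import (BicycleSpec, DisturbanceSpec, SteeringTask,
                             VehicleState, bicycle_step, build_H_steering,
                             build_H_steering_from_spec, build_H_tracking,
                             fit_bicycle_matrices, road_disturbance,
                             steady_state_yaw_gain, yaw_response_to_G)
from intermit.series import UniformSeries

DT60 = 1.0 / 60.0


class TestBicycleStep:
    def test_rest_stays_at_rest(self):
        spec = BicycleSpec.lane_keeping()
        st = VehicleState()
        for _ in range(100):
            st = bicycle_step(st, 0.0, 0.0, DT60, spec)
        assert st.v_y == 0.0 and st.omega == 0.0 and st.y == 0.0

    def test_constant_steering_converges_to_steady_state_gain(self):
        spec = BicycleSpec.lane_keeping()
        S = steady_state_yaw_gain(spec)
        st = VehicleState()
        for _ in range(600):  # 10 s
            st = bicycle_step(st, 2.0, 0.0, DT60, spec)
        assert st.omega == pytest.approx(2.0 * S, rel=1e-6)

    def test_zoh_matches_fine_euler(self):
        spec = BicycleSpec.lane_keeping()
        dt = 0.01
        st = VehicleState()
        for _ in range(100):  # 1 s, ZOH
            st = bicycle_step(st, 3.0, 0.0, dt, spec)
        x = np.zeros(2)
        fine = dt / 1000
        A, b = spec.A, spec.b * 3.0
        for _ in range(100_000):  # same second, fine Euler
            x = x + fine * (A @ x + b)
        assert abs(st.v_y - x[0]) < 1e-6
        assert abs(st.omega - x[1]) < 1e-6

    def test_default_specs_are_stable(self):
        for spec in (BicycleSpec.lane_keeping(), BicycleSpec.circle_task()):
            assert np.all(np.real(np.linalg.eigvals(spec.A)) < 0)


class TestSteadyStateYawGain:
    def test_zero_input_vector_gives_zero_gain(self):
        spec = BicycleSpec.lane_keeping()
        zero = BicycleSpec(A=spec.A, b=np.zeros(2), v_x=spec.v_x)
        assert steady_state_yaw_gain(zero) == 0.0

    def test_matches_long_time_primitive_response(self):
        spec = BicycleSpec.lane_keeping()
        wg = yaw_response_to_G(spec, PrimitiveShape(), horizon=6.0)
        assert wg.values[-1] == pytest.approx(steady_state_yaw_gain(spec),
                                              rel=1e-3)

    def test_linear_in_input_vector(self):
        spec = BicycleSpec.lane_keeping()
        scaled = BicycleSpec(A=spec.A, b=3.0 * spec.b, v_x=spec.v_x)
        assert steady_state_yaw_gain(scaled) == pytest.approx(
            3.0 * steady_state_yaw_gain(spec))


class TestYawResponse:
    def test_zero_before_motor_delay(self):
        spec = BicycleSpec.lane_keeping()
        sh = PrimitiveShape()
        wg = yaw_response_to_G(spec, sh, horizon=2.0)
        assert np.all(np.abs(wg.values[wg.times <= sh.tau_m]) < 1e-12)

    def test_monotone_approach_to_steady_state(self):
        spec = BicycleSpec.lane_keeping()
        wg = yaw_response_to_G(spec, PrimitiveShape(), horizon=4.0)
        S = steady_state_yaw_gain(spec)
        assert np.max(wg.values) <= S * (1.0 + 1e-6)  # overdamped: no overshoot
        assert np.all(np.diff(wg.values) >= -1e-9 * S)
        tail = wg.values[wg.times > 2.0]
        assert np.all(np.abs(tail - S) < 0.01 * S)

    def test_linearity_in_amplitude(self):
        spec = BicycleSpec.lane_keeping()
        sh = PrimitiveShape()
        wg = yaw_response_to_G(spec, sh, horizon=2.0)
        big = BicycleSpec(A=spec.A, b=2 * spec.b, v_x=spec.v_x)
        wg2 = yaw_response_to_G(big, sh, horizon=2.0)
        np.testing.assert_allclose(wg2.values, 2 * wg.values, atol=1e-9)

    def test_horizon_must_cover_primitive(self):
        with pytest.raises(ValueError):
            yaw_response_to_G(BicycleSpec.lane_keeping(), PrimitiveShape(),
                              horizon=0.3)


class TestPredictionPrimitives:
    def test_steering_H_constraints(self):
        spec = BicycleSpec.lane_keeping()
        sh = PrimitiveShape()
        H = build_H_steering_from_spec(spec, sh, tau_p=0.05)
        assert H(0.0) == 0.0 and H(-1.0) == 0.0
        assert H(1e-6) == pytest.approx(1.0, abs=1e-6)
        # still one while the yaw response has not begun
        assert H(0.05 + sh.tau_m / 2) == pytest.approx(1.0, abs=1e-9)
        assert H(H.T_p + 1e-9) == 0.0
        assert H(10.0) == 0.0

    def test_steering_H_is_definition_sample_wise(self):
        spec = BicycleSpec.lane_keeping()
        sh = PrimitiveShape()
        tau_p = 0.05
        wg = yaw_response_to_G(spec, sh, horizon=6.0)
        S = steady_state_yaw_gain(spec)
        H = build_H_steering(wg, S, tau_p)
        t = 0.3
        expected = 1.0 - float(wg.at(t - tau_p)) / S
        assert H(t) == pytest.approx(expected, abs=1e-9)

    def test_steering_H_rejects_zero_gain_and_short_horizon(self):
        spec = BicycleSpec.lane_keeping()
        wg = yaw_response_to_G(spec, PrimitiveShape(), horizon=2.0)
        with pytest.raises(ValueError):
            build_H_steering(wg, 0.0, 0.05)
        short = UniformSeries(0.0, wg.dt, wg.values[:30])
        with pytest.raises(ValueError, match="horizon"):
            build_H_steering(short, steady_state_yaw_gain(spec), 0.05)

    def test_tracking_H_shape(self):
        sh = PrimitiveShape()
        H = build_H_tracking(sh, tau_p=0.05)
        assert H.T_p == pytest.approx(0.05 + sh.t_end)
        assert H(1e-9) == pytest.approx(1.0)
        assert H(H.T_p) == 0.0
        assert H(0.05 + sh.tau_m + sh.duration / 2) == pytest.approx(0.5)


class TestRoadDisturbance:
    def test_zero_sigma_gives_zeros(self):
        d = road_disturbance(DisturbanceSpec(sigma_R=0.0), 1000, DT60, seed=0)
        assert np.all(d.values == 0.0)

    def test_sample_sd_matches_sigma_R(self):
        d = road_disturbance(DisturbanceSpec(sigma_R=0.02), 200_000, DT60,
                             seed=1)
        assert np.std(d.values) == pytest.approx(0.02, rel=1e-9)

    def test_band_limited_below_half_hertz(self):
        d = road_disturbance(DisturbanceSpec(sigma_R=0.02), 120_000, DT60,
                             seed=2)
        f = np.fft.rfftfreq(len(d.values), DT60)
        p = np.abs(np.fft.rfft(d.values)) ** 2
        assert p[f > 1.0].sum() / p.sum() < 0.05

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            road_disturbance(DisturbanceSpec(sigma_R=0.02, cutoff_hz=40.0),
                             100, DT60, seed=0)


class TestFitBicycleMatrices:
    def _synth(self, spec, seed=0, n=6000, noise=0.0):
        rng = np.random.default_rng(seed)
        dt = DT60
        delta = np.cumsum(rng.normal(0, 0.5, n))  # persistent excitation
        x = np.zeros(2)
        vy = np.zeros(n)
        om = np.zeros(n)
        Ad, bd, _ = spec.discretise(dt)
        for j in range(n):
            x = Ad @ x + bd * delta[j]
            vy[j], om[j] = x
        if noise:
            vy = vy + rng.normal(0, noise, n)
            om = om + rng.normal(0, noise, n)
        mk = lambda v: UniformSeries(0.0, dt, v)
        return mk(delta), mk(vy), mk(om)

    def test_noise_free_recovery(self):
        spec = BicycleSpec.lane_keeping()
        delta, vy, om = self._synth(spec)
        fit = fit_bicycle_matrices(delta, vy, om, v_x=spec.v_x)
        # finite differencing limits accuracy; matrices recovered closely
        assert np.linalg.norm(fit.A - spec.A) / np.linalg.norm(spec.A) < 0.05
        assert np.linalg.norm(fit.b - spec.b) / np.linalg.norm(spec.b) < 0.05

    def test_free_decay_gives_zero_input_vector(self):
        spec = BicycleSpec.lane_keeping()
        dt = DT60
        x = np.array([1.0, 0.2])
        vy, om = [], []
        Ad, _, _ = spec.discretise(dt)
        for _ in range(600):
            x = Ad @ x
            vy.append(x[0])
            om.append(x[1])
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_bicycle_matrices(
                UniformSeries(0, dt, np.zeros(600)),
                UniformSeries(0, dt, np.array(vy)),
                UniformSeries(0, dt, np.array(om)))
        assert np.linalg.norm(fit.b) == 0.0

    def test_error_grows_with_measurement_noise(self):
        spec = BicycleSpec.lane_keeping()
        errs = []
        for noise in (1e-4, 1e-3, 1e-2):
            delta, vy, om = self._synth(spec, noise=noise)
            fit = fit_bicycle_matrices(delta, vy, om)
            errs.append(np.linalg.norm(fit.A - spec.A))
        assert errs[0] < errs[1] < errs[2]

    def test_mismatched_grids_rejected(self):
        s1 = UniformSeries(0, DT60, np.zeros(100))
        s2 = UniformSeries(0, DT60, np.zeros(99))
        with pytest.raises(ValueError):
            fit_bicycle_matrices(s1, s2, s1)


def test_lane_keeping_stays_on_road_five_minutes():
    """Closed loop with default parameters keeps lateral deviation small."""
    from intermit.core import AccumulatorSpec, ControllerSpec, simulate

    plant = BicycleSpec.lane_keeping()
    ctl = ControllerSpec(sigma_m=0.8,
                         accumulator=AccumulatorSpec(k=200.0, sigma_a=0.8))
    ctl.H = build_H_steering_from_spec(plant, ctl.shape, ctl.tau_p)
    task = SteeringTask(StraightRoad(), TwoPointLaw(), plant,
                        DisturbanceSpec(sigma_R=0.02))
    trace = simulate(ctl, task, 300.0, dt=DT60, seed=42)
    assert np.max(np.abs(trace.task_records["y"])) < 2.0
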