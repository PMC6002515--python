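"""Motor primitives, accumulator dynamics, superposition and the stepping
engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intermit import ControllerSpec, PrimitiveShape, TrackingTask, simulate
from intermit.core import (AccumulatorSpec, accumulator_step, check_trigger,
                           control_rate, control_signal, first_rate_departure,
                           make_adjustment, prediction_signal)
from intermit.plants import build_H_tracking
from intermit.synth import step_target

from conftest import DT60, tracking_controller


class TestPrimitiveShape:
    def test_boundary_values_exact(self, shape):
        assert shape.step(0.0) == 0.0
        assert shape.step(shape.tau_m) == 0.0
        assert shape.step(shape.t_end) == 1.0
        assert shape.step(shape.t_end + 5.0) == 1.0

    def test_symmetric_bell_midpoint(self, shape):
        assert shape.step(shape.tau_m + shape.duration / 2) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(duration=st.floats(0.05, 2.0), tau_m=st.floats(0.0, 0.5))
    def test_rate_integrates_to_one_and_G_monotone(self, duration, tau_m):
        from scipy.integrate import quad

        sh = PrimitiveShape(duration=duration, tau_m=tau_m)
        integral, _ = quad(lambda x: float(sh.rate(x)), sh.tau_m, sh.t_end,
                           limit=200)
        assert integral == pytest.approx(1.0, abs=1e-6)
        t = np.linspace(tau_m - 0.1, sh.t_end + 0.1, 20001)
        g = sh.step(t)
        assert np.all(np.diff(g) >= -1e-12)
        assert np.all(sh.rate(t[t <= tau_m]) == 0.0)
        assert np.all(sh.rate(t[t >= sh.t_end]) == 0.0)

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            PrimitiveShape(duration=0.0)
        with pytest.raises(ValueError):
            PrimitiveShape(tau_m=-0.1)


class TestAccumulator:
    def test_simplified_euler_update(self):
        spec = AccumulatorSpec(k=20.0, sigma_a=0.0)
        assert accumulator_step(0.0, 1.0, 1e-3, spec) == pytest.approx(0.02)

    def test_zero_error_leaves_activation(self):
        spec = AccumulatorSpec(k=20.0, sigma_a=0.0)
        assert accumulator_step(0.3, 0.0, 0.01, spec) == 0.3

    def test_gating_blocks_subthreshold_drive(self):
        spec = AccumulatorSpec(k=1.0, eta0=0.5, sigma_a=0.0)
        assert accumulator_step(0.1, 0.4, 0.01, spec) == 0.1
        # above the gate only the excess drives
        assert accumulator_step(0.0, 0.8, 1.0, spec) == pytest.approx(0.3)

    def test_leakage_decays_activation(self):
        spec = AccumulatorSpec(k=1.0, lam=2.0, sigma_a=0.0)
        assert accumulator_step(1.0, 0.0, 0.1, spec) == pytest.approx(0.8)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            accumulator_step(0.0, 1.0, 0.0, AccumulatorSpec())

    @pytest.mark.parametrize("A,expected", [(0.99, 0), (1.0, 1), (-1.2, -1),
                                            (0.0, 0), (-1.0, -1)])
    def test_threshold_is_boundary_inclusive(self, A, expected):
        assert check_trigger(A, AccumulatorSpec()) == expected


class TestAdjustment:
    def test_noise_free_amplitude(self):
        ev = make_adjustment(0.5, 1.0, 0.0)
        assert ev.amplitude == 0.5 and ev.eps_tilde == 0.5 and ev.m == 0.0

    def test_full_negative_draw_gives_zero_amplitude_event(self):
        class FakeRng:
            def normal(self, mu, sd):
                return -1.0

        ev = make_adjustment(0.5, 1.0, 0.8, FakeRng())
        assert ev.amplitude == 0.0  # still emitted

    def test_motor_noise_scales_as_sigma_m(self):
        rng = np.random.default_rng(12345)
        sigma_m, eps, n = 0.8, 0.7, 100_000
        amps = np.array([make_adjustment(eps, 1.0, sigma_m, rng).amplitude
                         for _ in range(n)])
        assert np.std(amps / eps) == pytest.approx(sigma_m, abs=0.01)

    def test_amplitude_sign_follows_error(self):
        assert make_adjustment(-0.3, 2.0, 0.0).amplitude == pytest.approx(-0.6)


class TestSuperposition:
    def test_no_events_returns_initial_control(self, shape):
        assert control_signal([], 1.23, C0=4.0, shape=shape) == 4.0
        assert prediction_signal([], 1.23, build_H_tracking(shape, 0.05)) == 0.0

    def test_completed_event_contributes_full_amplitude(self, shape):
        ev = make_adjustment(1.0, 1.0, 0.0, t=0.0)
        assert control_signal([ev], shape.t_end + 0.1, 0.0, shape) == 1.0

    def test_overlapping_events_match_brute_force_sum(self, shape):
        # two adjustments offset by a quarter duration
        evs = [make_adjustment(1.0, 1.0, 0.0, t=0.0),
               make_adjustment(-0.5, 1.0, 0.0, t=shape.duration / 4)]
        t = np.linspace(-0.1, 1.5, 500)
        expected = (evs[0].amplitude * shape.step(t - evs[0].t)
                    + evs[1].amplitude * shape.step(t - evs[1].t))
        np.testing.assert_allclose(control_signal(evs, t, 0.0, shape),
                                   expected, atol=1e-12)
        expected_rate = (evs[0].amplitude * shape.rate(t - evs[0].t)
                         + evs[1].amplitude * shape.rate(t - evs[1].t))
        np.testing.assert_allclose(control_rate(evs, t, shape),
                                   expected_rate, atol=1e-12)

    def test_prediction_vanishes_beyond_horizon(self, shape):
        H = build_H_tracking(shape, 0.05)
        ev = make_adjustment(1.0, 1.0, 0.0, t=0.0)
        assert prediction_signal([ev], H.T_p + 1e-9, H) == 0.0


class TestSimulate:
    def test_step_response_onset_chain(self, step_trace):
        # tau_p + 1/k + tau_m = 0.05 + 0.05 + 0.1 delays the first motor
        # output to 0.2 s, like the continuous model's tau_d
        trace, ctl = step_trace
        assert trace.events[0].t == pytest.approx(0.1, abs=1e-9)
        t_on = first_rate_departure(trace.times, trace.Cdot)
        assert 0.2 < t_on <= 0.2 + 2 * DT60
        assert trace.C[-1] == pytest.approx(1.0, abs=1e-6)

    def test_zero_target_zero_noise_never_triggers(self):
        ctl = tracking_controller()
        tgt = step_target(0.0, 2.0, DT60)
        trace = simulate(ctl, TrackingTask(tgt), 2.0, dt=DT60, seed=0)
        assert trace.events == []
        np.testing.assert_array_equal(trace.C, np.full(len(trace.C), ctl.C0))

    def test_trace_reproducible_from_events(self, sines_trace):
        trace, ctl, _ = sines_trace
        rebuilt = control_signal(trace.events, trace.times, ctl.C0, ctl.shape)
        np.testing.assert_allclose(rebuilt, trace.C, atol=1e-9)

    def test_identical_seed_bit_identical_trace(self):
        ctl = tracking_controller(sigma_a=0.5, sigma_m=0.5)
        tgt = step_target(1.0, 5.0, DT60)
        a = simulate(ctl, TrackingTask(tgt), 5.0, dt=DT60, seed=7)
        b = simulate(ctl, TrackingTask(tgt), 5.0, dt=DT60, seed=7)
        np.testing.assert_array_equal(a.C, b.C)
        np.testing.assert_array_equal(a.A, b.A)
        assert [e.t for e in a.events] == [e.t for e in b.events]
        assert [e.amplitude for e in a.events] == [e.amplitude for e in b.events]

    def test_missing_prediction_primitive_rejected(self):
        ctl = ControllerSpec(H=None)
        with pytest.raises(ValueError, match="H"):
            simulate(ctl, TrackingTask(step_target(1.0, 1.0, DT60)), 1.0,
                     dt=DT60)

    def test_dense_trigger_limit_matches_continuous_law(self, shape):
        # with high accumulator gain and no noise, the window-averaged
        # intermittent rate approaches K*P with K = K'/duration
        from intermit.synth import sum_of_sines_target

        ctl = tracking_controller(k=2000.0)
        tgt = sum_of_sines_target(60.0, DT60, seed=11)
        tr = simulate(ctl, TrackingTask(tgt), 60.0, dt=DT60, seed=0)
        w = int(round(shape.duration / DT60))
        ma = np.convolve(tr.Cdot, np.ones(w) / w, mode="same")
        K = ctl.Kprime / shape.duration
        sl = slice(3 * w, len(ma) - 3 * w)
        # alignment freedom: the bell's rate mass sits tau_p + tau_m after
        # the triggering error sample, give or take trigger quantisation
        best = min(
            np.linalg.norm(ma[sl] - K * np.roll(tr.P, s)[sl])
            / np.linalg.norm(K * np.roll(tr.P, s)[sl])
            for s in range(6, 15))
        assert best < 0.10


class TestControllerSpecConfig:
    def test_round_trip_flat_dict(self):
        spec = ControllerSpec(tau_p=0.06, Kprime=2.0, sigma_m=0.3,
                              shape=PrimitiveShape(duration=0.5, tau_m=0.12),
                              accumulator=AccumulatorSpec(k=123.0, sigma_a=0.4))
        d = spec.to_dict()
        back = ControllerSpec.from_dict(d)
        assert back.to_dict() == d

    def test_unknown_keys_rejected(self):
        with pytest.raises(KeyError):
            ControllerSpec.from_dict({"tau_p": 0.05, "bogus": 1.0})
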