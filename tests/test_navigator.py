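"""Dual-detector agent model: sensory transforms, confidence dynamics,
motor mapping, turning kernel, stepping, and cohort behaviour."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from antagonav.navigator import (
    ModelParams,
    SensorSample,
    StartRegion,
    WormState,
    draw_tumble_angle,
    motor_state,
    run_cohort,
    sensory_inputs,
    step_worm,
    update_confidence,
    wrap_angle,
)
from antagonav.synthetic_data import gen_toy_field


class TestSensoryInputs:
    def test_reference_concentration_zero_rate(self):
        p = ModelParams(C0=2.0, Cdot0=1.0)
        f_H, f_T = sensory_inputs(SensorSample(C=2.0, Cdot=0.0), p)
        assert f_H == 0.0
        assert f_T == pytest.approx(1.0)

    def test_high_concentration_tail_floored_at_minus_one(self):
        # C = C0 e^2: raw tail input 1 - 4 = -3, floored at -1
        p = ModelParams(C0=1.0, Cdot0=1.0)
        _, f_T = sensory_inputs(SensorSample(C=np.e**2, Cdot=0.3), p)
        assert f_T == -1.0

    def test_head_input_saturates_at_rate_ratio(self):
        p = ModelParams(C0=1.0, Cdot0=0.5)
        f_H, _ = sensory_inputs(SensorSample(C=1e6, Cdot=0.5), p)
        assert f_H == pytest.approx(1.0, abs=1e-9)

    def test_zero_concentration_guarded(self):
        p = ModelParams(C0=1.0, Cdot0=1.0)
        f_H, f_T = sensory_inputs(SensorSample(C=0.0, Cdot=1.0), p)
        assert f_H == 0.0 and f_T == 0.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            SensorSample(C=-1.0, Cdot=0.0)


class TestConfidenceDynamics:
    def test_zero_input_zero_state_is_fixed_point(self):
        assert update_confidence(0.0, 0.0, 1 / 60, 1.0, 0.5) == 0.0

    def test_free_decay_matches_exponential(self):
        # Q(0)=1, f=0, k1=1/60: after 60 s Q = e^{-1} up to O(dt)
        Q, dt = 1.0, 0.05
        for _ in range(int(60 / dt)):
            Q = update_confidence(Q, 0.0, 1 / 60, 1.0, dt)
        assert Q == pytest.approx(np.exp(-1), abs=1e-3)

    def test_constant_drive_matches_closed_form_relaxation(self):
        k1, k2, f, dt = 1 / 60, 1.0, 0.005, 0.05
        Q = 0.0
        traj = []
        for n in range(1, int(120 / dt) + 1):
            Q = update_confidence(Q, f, k1, k2, dt)
            traj.append((n * dt, Q))
        for t, q in traj[::200]:
            assert q == pytest.approx((k2 * f / k1) * (1 - np.exp(-k1 * t)),
                                      abs=2e-3)

    @given(st.floats(-5, 5), st.floats(-5, 5))
    def test_clamp_always_respected(self, Q, f):
        out = update_confidence(Q, f, 1 / 60, 1.0, 0.1, clamp=(-1, 1))
        assert -1.0 <= out <= 1.0

    def test_unstable_step_rejected(self):
        with pytest.raises(ValueError):
            update_confidence(0.0, 0.0, k1=1.0, k2=1.0, dt=2.0)


class TestMotorState:
    def test_baseline_state_at_zero_confidence(self):
        U, gamma = motor_state(0.0, 0.0, 0.0, ModelParams())
        assert U == pytest.approx(0.064)
        assert gamma == pytest.approx(0.067)

    def test_klinokinesis_plugin(self):
        p = ModelParams(lambda_K=2.0)
        _, gamma = motor_state(1.0, 0.0, 0.0, p)
        assert gamma == pytest.approx(0.067 * np.exp(-2), rel=1e-9)

    @given(st.floats(-1, 1), st.floats(-1, 1))
    def test_tumble_rate_decreases_with_confidence_contrast(self, q1, q2):
        p = ModelParams(lambda_K=1.5)
        _, g1 = motor_state(q1, q2, 0.0, p)
        _, g2 = motor_state(q1 + 0.1, q2, 0.0, p)
        assert g2 < g1

    def test_speed_floored_at_zero(self):
        U, _ = motor_state(-1.0, 1.0, -5.0, ModelParams())
        assert U == 0.0


class TestTumbleKernel:
    def test_pure_uniform_branch(self, rng):
        draws = draw_tumble_angle(rng, alpha=1.0, sigma=0.5, size=100_000)
        assert stats.kstest(draws, stats.uniform(-np.pi, 2 * np.pi).cdf).pvalue > 0.01

    def test_degenerate_gaussian_concentrates_at_pi(self, rng):
        draws = draw_tumble_angle(rng, alpha=0.0, sigma=1e-6, size=1000)
        assert np.all(np.minimum(np.abs(draws - np.pi),
                                 np.abs(draws + np.pi)) < 1e-4)

    def test_mixture_histogram_matches_analytic_density(self, rng):
        alpha, sigma, n = 0.5, 0.5, 200_000
        draws = draw_tumble_angle(rng, alpha, sigma, size=n)
        edges = np.linspace(-np.pi, np.pi, 37)
        centers = (edges[:-1] + edges[1:]) / 2
        emp, _ = np.histogram(draws, bins=edges, density=True)
        # analytic mixture: uniform + wrapped normal centred at pi
        wrapped = sum(stats.norm.pdf(centers, np.pi + 2 * np.pi * k, sigma)
                      for k in (-2, -1, 0, 1))
        expected = alpha / (2 * np.pi) + (1 - alpha) * wrapped
        se = np.sqrt(expected / (n * np.diff(edges)))
        assert np.all(np.abs(emp - expected) < 5 * se + 1e-3)


class TestStepWorm:
    def test_frozen_dynamics_leave_state_unchanged(self, rng):
        field = gen_toy_field("uniform", {"level": 0.0}, radius=20.0)
        p = ModelParams(gamma0=0.0, U0=0.0, U1=0.0, D_R=0.0,
                        confidence_noise=0.0)
        s = WormState(r=(1.0, 2.0), theta=0.5)
        out = step_worm(s, field, 0.0, 0.1, p, rng)
        assert np.allclose(out.r, s.r)
        assert out.theta == pytest.approx(s.theta)
        assert out.Q_H == 0.0 and out.Q_T == 0.0

    def test_deterministic_straight_run(self, rng):
        field = gen_toy_field("uniform", {"level": 0.0}, radius=20.0)
        p = ModelParams(gamma0=0.0, U1=0.0, D_R=0.0, confidence_noise=0.0)
        s = WormState(r=(0.0, 0.0), theta=0.0, head_enabled=False,
                      tail_enabled=False)
        out = step_worm(s, field, 0.0, 0.1, p, rng)
        assert out.r[0] == pytest.approx(0.064 * 0.1)
        assert out.r[1] == pytest.approx(0.0)

    def test_taxis_turn_points_exactly_at_source(self, rng):
        field = gen_toy_field("linear", {"offset": 5.0, "slope_x": 0.1},
                              radius=20.0, source_xy=(-10.0, 3.0))
        p = ModelParams(C0=1.0, Cdot0=1.0, D_R=0.0, gamma0=0.0,
                        confidence_noise=0.0, taxis_threshold=0.1)
        # worm moving down-gradient: last_C above current C triggers taxis
        s = WormState(r=(5.0, 0.0), theta=0.0, last_C=10.0)
        out = step_worm(s, field, 0.0, 0.1, p, rng, source_xy=(-10.0, 3.0))
        expected = np.arctan2(3.0 - 0.0, -10.0 - 5.0)
        assert out.theta == pytest.approx(expected, abs=1e-12)

    def test_wall_reflection_keeps_worm_inside(self, rng):
        field = gen_toy_field("uniform", {"level": 0.0}, radius=5.0)
        p = ModelParams(U0=2.0, U1=0.0, gamma0=0.0, D_R=0.0,
                        confidence_noise=0.0)
        s = WormState(r=(4.9, 0.0), theta=0.0, head_enabled=False,
                      tail_enabled=False)
        out = step_worm(s, field, 0.0, 1.0, p, rng)
        assert np.hypot(*out.r) <= 5.0


class TestCohort:
    def test_condition_semantics(self, rng):
        field = gen_toy_field("gaussian_hill",
                              {"peak": 1.0, "width": 10.0, "center": (0, 0)},
                              radius=20.0, source_xy=(0.0, 0.0))
        p = ModelParams(C0=0.5, Cdot0=0.01)
        tail = run_cohort(20, "tail_only", field, 60.0, dt=0.1, params=p,
                          init=StartRegion((5.0, 0.0), 2.0), seed=5)
        assert np.all(tail.Q_H == 0.0)
        assert np.all(tail.taxis_counts == 0)
        head = run_cohort(20, "head_only", field, 60.0, dt=0.1, params=p,
                          init=StartRegion((5.0, 0.0), 2.0), seed=5)
        assert np.all(head.Q_T == 0.0)

    def test_confidences_respect_clamp(self):
        field = gen_toy_field("gaussian_hill", {"peak": 100.0, "width": 5.0},
                              radius=20.0)
        p = ModelParams(C0=0.01, Cdot0=1e-4)
        res = run_cohort(20, "both", field, 120.0, dt=0.1, params=p,
                         init=StartRegion((5.0, 0.0), 2.0), seed=6)
        assert res.Q_H.min() >= -1.0 and res.Q_H.max() <= 1.0
        assert res.Q_T.min() >= -1.0 and res.Q_T.max() <= 1.0

    def test_identical_seed_bitwise_reproducible(self):
        field = gen_toy_field("uniform", {"level": 0.0}, radius=20.0)
        a = run_cohort(15, "none", field, 60.0, dt=0.1, seed=9,
                       init=StartRegion((0.0, 0.0), 3.0))
        b = run_cohort(15, "none", field, 60.0, dt=0.1, seed=9,
                       init=StartRegion((0.0, 0.0), 3.0))
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.headings, b.headings)

    def test_null_condition_is_unbiased_active_walk(self):
        field = gen_toy_field("uniform", {"level": 0.0}, radius=60.0)
        res = run_cohort(400, "none", field, 600.0, dt=0.1, seed=10,
                         init=StartRegion((0.0, 0.0), 1.0),
                         source_xy=(-50.0, 0.0), capture_radius=1.0)
        final = res.positions[:, -1, :]
        disp = final.mean(axis=0)
        sem = final.std(axis=0) / np.sqrt(len(final))
        assert np.all(np.abs(disp) < 4 * sem + 0.2)
        msd = ((res.positions - res.positions[:, :1, :]) ** 2).sum(-1).mean(0)
        assert msd[-1] > msd[len(msd) // 2] > msd[1]

    def test_sprint_emerges_at_high_concentration(self):
        # constant C >> C0 with rising history: Q_T -> -1, Q_H > 0 => U > U0
        p = ModelParams(C0=1.0, Cdot0=0.05, confidence_noise=0.0)
        Q_H, Q_T = 0.0, 0.0
        f_H, f_T = sensory_inputs(SensorSample(C=20.0, Cdot=0.05), p)
        for _ in range(3000):
            Q_H = update_confidence(Q_H, f_H, p.k1, p.k2_H, 0.1)
            Q_T = update_confidence(Q_T, f_T, p.k1, p.k2_T, 0.1)
        U, gamma = motor_state(Q_H, Q_T, 0.0, p)
        assert Q_T == -1.0 and Q_H > 0.0
        assert U > p.U0
        assert gamma < p.gamma0

    def test_invalid_condition_and_geometry_rejected(self):
        field = gen_toy_field("uniform", {"level": 0.0}, radius=10.0)
        with pytest.raises(ValueError):
            run_cohort(5, "head", field, 10.0)
        with pytest.raises(ValueError):
            run_cohort(5, "none", field, 10.0,
                       init=StartRegion((9.0, 0.0), 5.0))


@given(st.floats(-50, 50))
def test_wrap_angle_range(theta):
    w = wrap_angle(theta)
    assert -np.pi < w <= np.pi
    assert np.cos(w) == pytest.approx(np.cos(theta), abs=1e-9)
    assert np.sin(w) == pytest.approx(np.sin(theta), abs=1e-9)
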