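"""Surrogate integrators: reductions, mixing algebra, schedules, stability."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from timeskip.model import NetworkParams, init_network, simulate_base
from timeskip.surrogates import (
    AnnealSchedule,
    SurrogateSpec,
    cd_macro_step,
    dasc_mix,
    schedule_value,
    sctt_mix,
    segment_list,
    simulate_with_surrogate,
    strategic_skip_positions,
)

DT = 5.0


def _vec(n=5):
    return hnp.arrays(np.float64, n, elements=st.floats(-5, 5))


class TestCdMacroStep:
    def test_theta_one_equals_euler(self, leak_net):
        r = np.array([1.0, 2.0, -0.5])
        out = cd_macro_step(leak_net, r, np.zeros(2), np.zeros(3), 1, DT)
        np.testing.assert_array_equal(out, r * (1 - DT / 100.0))

    def test_effective_step_equal_tau_zeroes_state(self, leak_net):
        # theta * dt = tau: leak multiplier 1 - theta dt / tau = 0
        r = np.array([3.0, -1.0, 0.2])
        out = cd_macro_step(leak_net, r, np.zeros(2), np.zeros(3), 20, DT)
        np.testing.assert_array_equal(out, np.zeros(3))

    def test_effective_step_twice_tau_flips_sign(self, leak_net):
        # the instability seed: 1 - theta dt / tau = -1
        r = np.array([3.0, -1.0, 0.2])
        out = cd_macro_step(leak_net, r, np.zeros(2), np.zeros(3), 40, DT)
        np.testing.assert_array_equal(out, -r)


class TestMixes:
    def test_sctt_beta_one_returns_base_state(self):
        a, b = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        np.testing.assert_array_equal(sctt_mix(a, b, 1.0), b)

    def test_sctt_midpoint(self):
        out = sctt_mix(np.array([2.0, 0.0]), np.array([0.0, 2.0]), 0.5)
        np.testing.assert_array_equal(out, [1.0, 1.0])

    def test_dasc_boundary_values(self):
        a, b = np.array([1.0, -2.0]), np.array([0.5, 8.0])
        np.testing.assert_array_equal(dasc_mix(a, b, 1.0), b)
        np.testing.assert_array_equal(dasc_mix(a, b, 0.0), a)

    @pytest.mark.parametrize("beta", [0.2, 0.5, 0.8])
    @given(r_t=_vec(), r_end=_vec())
    @settings(max_examples=30, deadline=None)
    def test_sctt_deviation_identity(self, beta, r_t, r_end):
        # || mix - r_base_end || = (1 - beta) || r_t - r_base_end ||
        out = sctt_mix(r_t, r_end, beta)
        lhs = np.linalg.norm(out - r_end)
        rhs = (1 - beta) * np.linalg.norm(r_t - r_end)
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("beta", [0.2, 0.5, 0.8])
    @given(r_cd=_vec(), r_end=_vec())
    @settings(max_examples=30, deadline=None)
    def test_dasc_deviation_identity(self, beta, r_cd, r_end):
        out = dasc_mix(r_cd, r_end, beta)
        lhs = np.linalg.norm(out - r_end)
        rhs = (1 - beta) * np.linalg.norm(r_cd - r_end)
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-12)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            sctt_mix(np.zeros(2), np.zeros(2), 0.0)
        with pytest.raises(ValueError):
            sctt_mix(np.zeros(2), np.zeros(2), 1.5)
        with pytest.raises(ValueError):
            dasc_mix(np.zeros(2), np.zeros(2), -0.1)


class TestSchedule:
    def test_worked_example_plateaus(self):
        # DASC, step count 5, beta0 0.5: 0.5, 0.6, 0.7, 0.8, 0.9, 1.0
        sched = AnnealSchedule(step_count=5, initial_value=0.5,
                               horizon=20_000)
        assert sched.plateaus() == pytest.approx(
            [0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        )
        # equal intervals over the horizon: probe each interval's midpoint
        seen = [schedule_value(sched, int((k + 0.5) * 20_000 / 6))
                for k in range(6)]
        assert seen == pytest.approx([0.5, 0.6, 0.7, 0.8, 0.9, 1.0])

    @pytest.mark.parametrize("sc,v0,kind", [
        (1, 0.2, "beta"), (5, 0.5, "beta"), (10, 0.8, "beta"),
        (1, 10, "theta"), (5, 10, "theta"), (10, 10, "theta"),
    ])
    def test_terminal_contract(self, sc, v0, kind):
        sched = AnnealSchedule(sc, v0, horizon=1000, kind=kind)
        for t in (1000, 1001, 50_000):
            assert schedule_value(sched, t) == 1

    def test_single_step_two_plateaus(self):
        sched = AnnealSchedule(step_count=1, initial_value=0.2, horizon=100)
        vals = {schedule_value(sched, t) for t in range(100)}
        assert vals == {0.2, 1.0}

    def test_monotone_toward_one(self):
        for kind, v0 in (("beta", 0.2), ("theta", 10)):
            sched = AnnealSchedule(10, v0, horizon=5000, kind=kind)
            seq = [schedule_value(sched, t) for t in range(0, 6000, 7)]
            if kind == "beta":
                assert all(b >= a for a, b in zip(seq, seq[1:]))
            else:
                assert all(b <= a for a, b in zip(seq, seq[1:]))

    def test_theta_plateaus_are_integers_at_least_one(self):
        sched = AnnealSchedule(5, 10, horizon=100, kind="theta")
        for v in sched.plateaus():
            assert isinstance(v, int) and v >= 1


class TestSkipGeometry:
    def test_equal_trials_give_consecutive_spans(self):
        segs = strategic_skip_positions([0, 100, 200, 300, 400])
        assert segs == [(0, 100), (100, 200), (200, 300), (300, 400)]

    def test_single_trial_empty(self):
        assert strategic_skip_positions([0]) == []

    def test_irregular_lengths_allowed(self):
        assert strategic_skip_positions([0, 10, 25]) == [(0, 10), (10, 25)]

    def test_trailing_partial_segment_dropped(self):
        spec = SurrogateSpec("sctt", theta=40, beta=0.5)
        segs = segment_list(spec, 100)
        assert segs == [(0, 40), (40, 80)]

    def test_strategic_merged_and_deduplicated(self):
        spec = SurrogateSpec("sctt", theta=50, beta=0.5,
                             strategic_segments=[(0, 50), (0, 100), (100, 200)])
        segs = segment_list(spec, 200)
        assert (0, 50) in segs
        assert segs.count((0, 50)) == 1
        assert (0, 100) in segs and (100, 200) in segs


class TestSimulateWithSurrogate:
    @pytest.mark.parametrize("spec", [
        SurrogateSpec("sctt", theta=4, beta=1.0),
        SurrogateSpec("dasc", theta=4, beta=1.0),
        SurrogateSpec("cd", theta=1),
    ])
    def test_reduction_bitwise_with_shared_noise(self, spec, desk_go_trial):
        p = init_network(6, 65, 33, seed=3, sigma_noise=0.05)
        base = simulate_base(p, desk_go_trial.inputs, DT, seed=11)
        mod = simulate_with_surrogate(
            p, desk_go_trial.inputs, DT, spec, seed=11
        )
        np.testing.assert_array_equal(mod.rates, base.rates)

    def test_cd_grid_has_coarse_resolution(self, small_net, desk_go_trial):
        spec = SurrogateSpec("cd", theta=8)
        traj = simulate_with_surrogate(
            small_net, desk_go_trial.inputs, DT, spec
        )
        n = desk_go_trial.inputs.shape[0]
        assert traj.rates.shape[0] == -(-n // 8) + 1
        assert traj.dt_effective == 8 * DT
        assert traj.time_index[1] == 8 and traj.time_index[-1] == n

    def test_sctt_grid_matches_fine_grid(self, small_net, desk_go_trial):
        spec = SurrogateSpec("sctt", theta=8, beta=0.5)
        traj = simulate_with_surrogate(
            small_net, desk_go_trial.inputs, DT, spec
        )
        assert traj.rates.shape[0] == desk_go_trial.inputs.shape[0] + 1

    def test_single_segment_dasc_norm_identity(self):
        # n_steps = theta: ||dasc_end - base_end|| = (1-b)||cd_end - base_end||
        theta, beta = 10, 0.3
        p = init_network(6, 4, 2, seed=8, sigma_noise=0.0)
        inp = np.random.default_rng(2).random((theta, 4))
        base = simulate_base(p, inp, DT, r0=np.ones(6) * 0.2)
        cd = simulate_with_surrogate(
            p, inp, DT, SurrogateSpec("cd", theta=theta),
            r0=np.ones(6) * 0.2,
        )
        dasc = simulate_with_surrogate(
            p, inp, DT, SurrogateSpec("dasc", theta=theta, beta=beta),
            r0=np.ones(6) * 0.2,
        )
        lhs = np.linalg.norm(dasc.rates[-1] - base.rates[-1])
        rhs = (1 - beta) * np.linalg.norm(cd.rates[-1] - base.rates[-1])
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_golden_fixture_reductions(self, bundle):
        # SCTT/DASC at beta=0.5 differ from base; CD grid is coarse
        assert not np.array_equal(
            bundle.golden["sctt"].rates, bundle.golden["base"].rates
        )
        assert bundle.golden["cd"].rates.shape[0] < \
            bundle.golden["base"].rates.shape[0]


class TestGradientShortcut:
    def test_sctt_bounds_gradient_below_while_base_decays(self):
        """In a contractive linear system the base end-to-start gradient
        decays as lambda^n; the SCTT bypass keeps it >= (1-beta)^(n/theta)."""
        from timeskip.training import _chain_backward, _chain_forward

        lam, alpha = 0.9, 0.05
        n_units, T, theta, beta = 2, 60, 10, 0.5
        # W chosen so the per-step Jacobian is exactly lambda * I on the
        # positive orthant (large bias keeps every ReLU active -> linear)
        w = (lam - (1 - alpha)) / alpha
        stack = {
            "W_rec": np.array([[np.eye(n_units) * w]])[0],
            "W_inp": np.zeros((1, n_units, 1)),
            "W_out": np.zeros((1, 1, n_units)),
            "b": np.full((1, n_units), 5.0),
        }
        proj = np.full((1, 1, T, n_units), 5.0)
        noise = np.zeros_like(proj)

        def grad_norm(segments, beta_):
            states, fprime, btapes = _chain_forward(
                stack, alpha, proj, noise, segments, beta_,
                "sctt" if segments else "base", np.ones(T),
            )
            assert np.all(fprime == 1.0)  # genuinely in the linear regime
            delta = np.zeros((1, 1, T, n_units))
            delta[0, 0, -1, 0] = 1.0
            _dW, _dp, dr0 = _chain_backward(
                stack, alpha, delta, fprime, states, segments, beta_,
                "sctt" if segments else "base", btapes, np.ones(T),
            )
            return np.linalg.norm(dr0)

        g_base = grad_norm([], 1.0)
        assert g_base == pytest.approx(lam ** T, rel=1e-9)
        segs = [(s, s + theta) for s in range(0, T, theta)]
        g_sctt = grad_norm(segs, beta)
        assert g_sctt >= (1 - beta) ** (T / theta)
        assert g_sctt > g_base


class TestCdStabilityBoundary:
    def test_cd_unstable_beyond_time_constant_sctt_dasc_finite(self):
        """theta dt > tau turns the CD leak multiplier negative; over many
        macro steps a random contractive network's trajectory blows up,
        while SCTT/DASC mixes of bounded base states stay finite."""
        from timeskip.analysis import trajectory_unstable
        from timeskip.model import DivergenceError
        from timeskip.tasks import generate_trial
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trial = generate_trial(
                "go", 0,
                timing_overrides={"fix": 200, "stim": 800, "resp": 200},
            )
        n_unstable = 0
        for seed in range(5):
            p = init_network(32, 65, 33, seed=seed, sigma_noise=0.0)
            try:
                traj = simulate_with_surrogate(
                    p, trial.inputs, DT, SurrogateSpec("cd", theta=40)
                )
                unstable = trajectory_unstable(traj)
            except DivergenceError:
                unstable = True
            n_unstable += unstable
            for method in ("sctt", "dasc"):
                traj = simulate_with_surrogate(
                    p, trial.inputs, DT,
                    SurrogateSpec(method, theta=40, beta=0.5),
                )
                assert not trajectory_unstable(traj)
        assert n_unstable >= 3
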