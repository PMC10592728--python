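"""Task battery: ring codes, trial structure, decoding, rule episodes."""

import warnings

import numpy as np
import pytest

from timeskip.tasks import (
    DESK_TIMING,
    FIX_THRESHOLD,
    N_INPUTS,
    N_OUTPUTS,
    N_RING,
    RING_PREFS,
    TASK_IDS,
    decode_response,
    generate_rule_episode,
    generate_trial,
    population_masks,
    ring_encode,
    ring_target,
    rule_correct_response,
    score_batch,
)


def _trial(task_id, seed=0, **timing):
    t = dict(DESK_TIMING)
    t.update(timing)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_trial(task_id, seed, timing_overrides=t)


class TestRingCode:
    def test_input_peak_is_08_gamma(self):
        for gamma in (0.5, 1.0, 1.7):
            assert ring_encode(1.3, 1.3, gamma) == pytest.approx(0.8 * gamma)

    def test_zero_gamma_zero_activation(self):
        assert ring_encode(0.2, 2.0, 0.0) == 0.0

    def test_even_symmetry_around_preferred_direction(self):
        psi0 = 0.7
        for delta in (0.1, 0.9, 2.5):
            assert ring_encode(psi0 + delta, psi0, 1.0) == pytest.approx(
                ring_encode(psi0 - delta, psi0, 1.0)
            )

    def test_target_peak_and_baseline(self):
        assert ring_target(0.4, 0.4) == pytest.approx(0.85)
        # maximal angular distance: Gaussian term below 1e-10 of baseline
        assert ring_target(0.0, np.pi) == pytest.approx(0.05, abs=1e-10)

    def test_target_floor_over_whole_ring(self):
        for psi in np.linspace(0, 2 * np.pi, 17):
            assert np.min(ring_target(psi, RING_PREFS)) >= 0.05

    def test_wrapped_distance(self):
        # distance is taken on the circle: 2 pi - eps is close to 0
        assert ring_encode(2 * np.pi - 0.01, 0.0, 1.0) == pytest.approx(
            ring_encode(0.01, 0.0, 1.0)
        )


class TestTrialStructure:
    def test_channel_counts(self):
        assert N_INPUTS == 1 + 2 * 32
        assert N_OUTPUTS == 1 + 32
        t = _trial("go")
        assert t.inputs.shape[1] == 65
        assert t.targets.shape[1] == 33
        assert t.loss_mask.shape == t.targets.shape

    @pytest.mark.parametrize("task_id", TASK_IDS)
    def test_targets_within_bounds_and_fixation_margin(self, task_id):
        t = _trial(task_id, seed=3)
        assert np.all(t.targets >= 0.05 - 1e-12)
        assert np.all(t.targets <= 0.85 + 1e-12)
        # fixation target keeps >= 0.3 margin on both sides of 0.5
        fix = t.targets[:, 0]
        assert np.all((fix >= FIX_THRESHOLD + 0.3) | (fix <= FIX_THRESHOLD - 0.3))

    @pytest.mark.parametrize("task_id", TASK_IDS)
    def test_epochs_tile_trial_without_overlap(self, task_id):
        t = _trial(task_id, seed=1)
        spans = sorted(t.meta.epoch_times.values())
        assert spans[0][0] == 0
        assert spans[-1][1] == t.meta.n_steps
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert b == c  # contiguous, non-overlapping

    def test_go_target_peaks_at_stimulus_direction(self):
        t = _trial("go", seed=5)
        psi = t.meta.stim_directions[0]
        r0, r1 = t.meta.response_epoch
        peak_unit = np.argmax(t.targets[r0, 1:])
        assert abs((RING_PREFS[peak_unit] - psi + np.pi) % (2 * np.pi)
                   - np.pi) <= np.pi / N_RING

    @pytest.mark.parametrize("task_id", ["anti", "rtanti", "danti"])
    def test_anti_family_target_is_antipodal(self, task_id):
        for seed in range(4):
            t = _trial(task_id, seed=seed)
            psi = t.meta.stim_directions[0]
            d = abs((t.meta.target_direction - psi - np.pi + np.pi)
                    % (2 * np.pi) - np.pi)
            assert d < 1e-9

    def test_match_rule_truth_table(self):
        # dms responds on match, dnms on non-match; categories for dmc/dnmc
        for seed in range(12):
            for task, respond_on_match in (("dms", True), ("dnms", False)):
                t = _trial(task, seed=seed)
                s, te = t.meta.stim_directions
                is_match = abs((s - te + np.pi) % (2 * np.pi) - np.pi) < 1e-9
                wants = is_match if respond_on_match else not is_match
                assert (t.meta.target_direction is not None) == wants
            for task, respond_on_match in (("dmc", True), ("dnmc", False)):
                t = _trial(task, seed=seed)
                s, te = t.meta.stim_directions
                same_cat = (s < np.pi) == (te < np.pi)
                wants = same_cat if respond_on_match else not same_cat
                assert (t.meta.target_direction is not None) == wants

    def test_decision_tasks_pick_stronger_stimulus(self):
        for seed in range(6):
            t = _trial("dm1", seed=seed)
            g = t.meta.stim_magnitudes
            d = t.meta.stim_directions
            assert t.meta.target_direction == d[int(np.argmax(g))]

    def test_full_scale_lengths_in_printed_range(self):
        for task in ("go", "dgo", "dms"):
            t = generate_trial(task, 0)
            assert 1500 <= t.meta.n_steps <= 2500

    def test_desk_length_warns(self):
        with pytest.warns(UserWarning, match="trial length"):
            generate_trial("go", 0, timing_overrides=DESK_TIMING)

    def test_loss_mask_grace_after_transitions(self):
        t = _trial("dgo", seed=2)
        for name, (e0, _e1) in t.meta.epoch_times.items():
            if e0 == 0:
                continue
            assert np.all(t.loss_mask[e0:e0 + 5] == 0.0)


class TestDecode:
    @pytest.mark.parametrize("task_id", TASK_IDS)
    def test_round_trip_on_exact_targets(self, task_id):
        # decoding the target tensor itself recovers the generating
        # direction within 1e-6 rad whenever a saccade is required
        for seed in range(3):
            t = _trial(task_id, seed=seed)
            if t.meta.target_direction is None:
                continue
            direction, broken = decode_response(
                t.targets, t.meta.response_epoch
            )
            assert not broken
            err = abs((direction - t.meta.target_direction + np.pi)
                      % (2 * np.pi) - np.pi)
            assert err < 1e-6

    def test_uniform_outputs_give_no_direction(self):
        y = np.full((100, 33), 0.3)
        direction, _ = decode_response(y, (50, 100))
        assert direction is None

    def test_constant_high_fixation_not_broken(self):
        t = _trial("go")
        y = t.targets.copy()
        y[:, 0] = 0.85
        _, broken = decode_response(y, t.meta.response_epoch)
        assert not broken

    def test_score_batch_on_exact_targets_is_one(self):
        t = _trial("dgo", seed=4)
        td = (np.nan if t.meta.target_direction is None
              else t.meta.target_direction)
        score = score_batch(t.targets, np.array(td), t.meta.response_epoch)
        assert score == 1.0

    def test_score_batch_flat_outputs_is_zero_for_saccade(self):
        t = _trial("go", seed=4)
        y = np.full_like(t.targets, 0.5)
        score = score_batch(y, np.array(t.meta.target_direction),
                            t.meta.response_epoch)
        assert score == 0.0


class TestPopulationMasks:
    def test_example_partition(self):
        pm = population_masks(256, 64, 64)
        assert pm.auxiliary.size == 128
        assert pm.input_pop.size == 64 and pm.output_pop.size == 64

    def test_disjoint_and_covering(self):
        pm = population_masks(40, 12, 8)
        all_units = np.concatenate([pm.input_pop, pm.output_pop, pm.auxiliary])
        assert np.array_equal(np.sort(all_units), np.arange(40))
        assert not set(pm.input_pop) & set(pm.output_pop)

    def test_masks_zero_the_right_rows_and_columns(self):
        pm = population_masks(10, 3, 4)
        W_inp = np.ones((10, 65)) * pm.inp_mask
        assert np.all(W_inp[3:] == 0.0) and np.all(W_inp[:3] == 1.0)
        W_out = np.ones((33, 10)) * pm.out_mask
        assert np.all(W_out[:, :3] == 0.0) and np.all(W_out[:, 7:] == 0.0)

    def test_over_allocation_rejected(self):
        with pytest.raises(ValueError):
            population_masks(10, 6, 6)


class TestRuleEpisode:
    def test_rule_one_identity_mapping(self):
        ep = generate_rule_episode(3, switch_trials=[], rng_seed=0)
        if ep.rule_sequence[0] == 1:
            np.testing.assert_array_equal(ep.correct_responses, ep.stimuli)
        else:
            np.testing.assert_array_equal(ep.correct_responses,
                                          1 - ep.stimuli)

    def test_switch_reverses_association(self):
        for seed in range(8):
            ep = generate_rule_episode(5, switch_trials=[2], rng_seed=seed)
            assert np.all(ep.rule_sequence[:2] == ep.rule_sequence[0])
            assert np.all(ep.rule_sequence[2:] == 3 - ep.rule_sequence[0])
            for r, s, c in zip(ep.rule_sequence, ep.stimuli,
                               ep.correct_responses):
                assert c == rule_correct_response(r, s)

    def test_boundaries_and_spans(self):
        ep = generate_rule_episode(5, switch_trials=[3], rng_seed=1)
        assert len(ep.trial_boundaries) == 5
        spans = np.diff(ep.trial_boundaries)
        assert len(spans) == 4
        assert np.all(spans == ep.n_steps // 5)

    def test_reference_agent_feedback_marks_switch(self):
        # the rule-following agent errs exactly on the first trial after
        # each uncued switch
        ep = generate_rule_episode(5, switch_trials=[2], rng_seed=3)
        np.testing.assert_array_equal(ep.feedback, [1, 1, 0, 1, 1])

    def test_feedback_inputs_follow_response_epochs(self):
        ep = generate_rule_episode(2, switch_trials=[], rng_seed=0)
        for i, (f0, f1) in enumerate(ep.feedback_epochs):
            ch = 2 + (1 - ep.feedback[i])
            assert np.all(ep.inputs[f0:f1, ch] == 1.0)
            assert np.all(ep.inputs[f0:f1, 2 + ep.feedback[i]] == 0.0)

    def test_invalid_switch_trials_rejected(self):
        with pytest.raises(ValueError):
            generate_rule_episode(3, switch_trials=[0], rng_seed=0)
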