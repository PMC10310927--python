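"""Stimulus/reward scheduling and trial orchestration contracts."""

import dataclasses

import numpy as np
import pytest

from colseq.config import NetworkConfig, RewardParams, TraceParams
from colseq.protocol import (
    StimulusSequence,
    make_stimulus,
    randomize_learning_params,
    run_recall,
    run_training,
    schedule_rewards,
)


class TestStimulusSequence:
    def test_onsets_and_offsets_are_contiguous(self):
        seq = StimulusSequence.of([500.0, 1000.0, 700.0, 1800.0])
        np.testing.assert_allclose(seq.onsets, [0.0, 500.0, 1500.0, 2200.0])
        np.testing.assert_allclose(seq.offsets, [500.0, 1500.0, 2200.0, 4000.0])
        assert seq.total == 4000.0

    def test_duplicate_columns_rejected(self):
        with pytest.raises(ValueError):
            StimulusSequence.of([700.0, 700.0], columns=[1, 1])

    def test_too_short_element_rejected(self, small_model):
        seq = StimulusSequence.of([40.0, 700.0])
        with pytest.raises(ValueError):
            seq.validate(small_model)


class TestMakeStimulus:
    def test_expected_spike_count_per_afferent(self, small_model, rng):
        # 30 spks/sec for 50 ms -> 1.5 expected spikes per afferent train
        n_rep = 200
        counts = []
        for _ in range(n_rep):
            times, tgt = make_stimulus(small_model, 1, 0.0, rng)
            n_aff = (small_model.input_mask & (small_model.column == 1)).sum()
            counts.append(len(times) / n_aff)
        mean = np.mean(counts)
        assert mean == pytest.approx(1.5, abs=0.05)

    def test_targets_are_stimulated_populations_of_that_column(self, small_model, rng):
        _, tgt = make_stimulus(small_model, 2, 0.0, rng)
        assert set(small_model.column[tgt]) == {2}
        assert set(small_model.role[tgt]) <= {0, 2}  # T and I_T

    def test_spike_times_inside_pulse(self, small_model, rng):
        times, _ = make_stimulus(small_model, 1, 300.0, rng)
        assert times.min() >= 300.0 and times.max() < 350.0


class TestScheduleRewards:
    reward = RewardParams()

    def test_empty_sequence_empty_schedule(self):
        seq = StimulusSequence(())
        assert len(schedule_rewards(seq, self.reward)) == 0

    def test_single_element_window(self):
        seq = StimulusSequence.of([700.0])
        win = schedule_rewards(seq, self.reward, include_onset=False)
        np.testing.assert_allclose(win, [[725.0, 750.0]])

    def test_four_element_offset_windows(self):
        seq = StimulusSequence.of([700.0] * 4)
        win = schedule_rewards(seq, self.reward, include_onset=False)
        np.testing.assert_allclose(win[:, 0], [725.0, 1425.0, 2125.0, 2825.0])
        np.testing.assert_allclose(win[:, 1] - win[:, 0], 25.0)

    def test_onset_window_prepended_by_default(self):
        seq = StimulusSequence.of([700.0] * 4)
        win = schedule_rewards(seq, self.reward)
        assert len(win) == 5
        np.testing.assert_allclose(win[0], [25.0, 50.0])

    def test_windows_never_overlap(self):
        seq = StimulusSequence.of([500.0, 1000.0, 700.0, 1800.0])
        win = schedule_rewards(seq, self.reward)
        assert np.all(win[1:, 0] >= win[:-1, 1])


class TestRandomizeLearningParams:
    def test_zero_spread_identity(self, rng):
        base = TraceParams()
        out = randomize_learning_params(base, rng, spread=0.0)
        assert out == base

    def test_draws_stay_within_band_and_vary(self, rng):
        base = TraceParams()
        outs = [randomize_learning_params(base, rng, spread=0.2) for _ in range(50)]
        ratios = np.array([o.tau_p / base.tau_p for o in outs])
        assert np.all((ratios >= 0.8) & (ratios <= 1.2))
        assert len(np.unique(ratios)) == 50  # fresh draw each call

    def test_only_learning_parameters_touched(self, rng):
        base = TraceParams()
        out = randomize_learning_params(base, rng, spread=0.2)
        for name in ("tmax_p", "tmax_d", "r_th", "r_th_ff", "tau_rate"):
            assert getattr(out, name) == getattr(base, name)


@pytest.fixture(scope="module")
def micro_setup():
    """Two-column network and a short sequence for fast protocol checks."""
    cfg = NetworkConfig(n_columns=2)
    model_seed = 3
    from colseq import build_network

    return build_network(cfg, model_seed), StimulusSequence.of([300.0, 300.0])


class TestTrialOrchestration:
    def test_zero_training_trials_leave_weights(self, micro_setup):
        model, seq = micro_setup
        w0 = model.pl_w.copy()
        run_training(model.copy(), seq, n_trials=0, seed=1)
        np.testing.assert_array_equal(model.pl_w, w0)

    def test_training_is_deterministic_in_seed(self, micro_setup):
        model, seq = micro_setup
        a, b = model.copy(), model.copy()
        ra = run_training(a, seq, n_trials=2, seed=9)
        rb = run_training(b, seq, n_trials=2, seed=9)
        np.testing.assert_array_equal(a.pl_w, b.pl_w)
        for ta, tb in zip(ra.trials, rb.trials):
            assert ta.class_means == tb.class_means

    def test_training_modifies_only_plastic_weights(self, micro_setup):
        model, seq = micro_setup
        m = model.copy()
        st0 = m.st_w.copy()
        res = run_training(m, seq, n_trials=3, seed=4)
        np.testing.assert_array_equal(m.st_w, st0)
        assert not np.allclose(m.pl_w, model.pl_w)
        assert len(res.trials) == 3

    def test_recall_never_changes_weights(self, micro_setup):
        model, seq = micro_setup
        m = model.copy()
        run_training(m, seq, n_trials=2, seed=4)
        w_trained = m.pl_w.copy()
        rr = run_recall(m, seq, n_trials=2, seed=5)
        np.testing.assert_array_equal(m.pl_w, w_trained)
        assert all(t.spikes is not None for t in rr.trials)

    def test_untrained_recall_activates_only_cued_column(self, micro_setup):
        model, seq = micro_setup
        rr = run_recall(model.copy(), seq, n_trials=2, seed=6, record_spikes=False)
        from colseq.analysis import activation_onset

        for tr in rr.trials:
            assert np.isfinite(activation_onset(tr.rate_times, tr.rate(model, "T", 1)))
            assert np.isnan(activation_onset(tr.rate_times, tr.rate(model, "T", 2)))

    def test_invalid_randomize_mode_rejected(self, micro_setup):
        model, seq = micro_setup
        with pytest.raises(ValueError):
            run_training(model.copy(), seq, n_trials=1, seed=1, randomize="sometimes")

    def test_per_trial_randomization_restores_base_config(self, micro_setup):
        model, seq = micro_setup
        m = model.copy()
        base = m.config
        run_training(m, seq, n_trials=2, seed=4, randomize="per_trial")
        assert m.config == base


class TestOffsetDecayOrdering:
    def test_inhibitory_cells_decay_faster_under_identical_drive(self):
        """With the same afferent drive, the higher inhibitory threshold
        (-50 vs -55 mV) and missing recurrence make I_T's response outlast
        the stimulus by less than the Timer's."""
        import dataclasses

        from colseq import build_network
        from colseq.analysis import recall_time

        cfg = NetworkConfig(n_columns=1)
        cfg = cfg.replace(weights=dataclasses.replace(cfg.weights, t_to_it=0.0))
        model = build_network(cfg, seed=8)
        seq = StimulusSequence.of([300.0])
        rr = run_recall(model, seq, n_trials=3, seed=4, record_spikes=False)
        t_offsets, it_offsets = [], []
        for tr in rr.trials:
            t_offsets.append(recall_time(tr.rate_times, tr.rate(model, "T", 1)))
            it_offsets.append(recall_time(tr.rate_times, tr.rate(model, "IT", 1)))
        assert np.nanmean(it_offsets) < np.nanmean(t_offsets)
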