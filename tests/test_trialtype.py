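"""Binary population vectors, reference probabilities, trial-type prediction."""

from __future__ import annotations

import numpy as np
import pytest

from replaykit.trialtype import (TrialTypeReference, binarize,
                                 build_reference, predict_window)


class TestBinarize:
    def test_above_mean_is_high(self):
        spikes = {0: np.array([0.0, 0.05, 0.1, 0.15])}   # 4 spikes in 200 ms
        high = binarize(spikes, [0], np.array([0.0]), 0.2, {0: 5.0})
        assert high[0, 0]                                 # 20 Hz > 5 Hz

    def test_zero_spike_window_is_low(self):
        spikes = {0: np.array([10.0])}
        high = binarize(spikes, [0], np.array([0.0]), 0.2, {0: 0.5})
        assert not high[0, 0]

    def test_exactly_equal_rate_is_low(self):
        spikes = {0: np.array([0.01])}                    # 5 Hz in 200 ms
        high = binarize(spikes, [0], np.array([0.0]), 0.2, {0: 5.0})
        assert not high[0, 0]


class TestReference:
    def _ref(self, n_high, n_obs, alpha=1.0):
        T, P, C = n_high.shape
        return TrialTypeReference(
            trial_types=[("VD", "LR")] * T, cells=list(range(C)),
            bin_width_cm=20.0, n_bins=P, alpha=alpha, n_high=n_high,
            n_obs=n_obs, trial_counts={})

    def test_pseudocount_arithmetic(self):
        # 3 high of 4 windows with alpha=1 -> 4/6
        ref = self._ref(np.full((1, 1, 1), 3.0), np.full((1, 1), 4.0))
        assert ref.p_high[0, 0, 0] == pytest.approx(4 / 6)

    def test_no_data_gives_half(self):
        ref = self._ref(np.zeros((1, 1, 1)), np.zeros((1, 1)))
        assert ref.p_high[0, 0, 0] == pytest.approx(0.5)

    def test_alpha_zero_limit_is_empirical_fraction(self):
        ref = self._ref(np.full((1, 1, 1), 4.0), np.full((1, 1), 4.0),
                        alpha=1e-12)
        assert ref.p_high[0, 0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_probabilities_strictly_inside_unit_interval(self, full_sim,
                                                         full_session):
        ref = build_reference(full_session, full_sim.templates,
                              full_session.cells)
        p = ref.p_high
        assert np.all(p > 0) and np.all(p < 1)
        assert len(ref.trial_types) == 8

    def test_loo_removes_exactly_one_trial(self, full_sim, full_session):
        ref = build_reference(full_session, full_sim.templates,
                              full_session.cells)
        tr_idx = next(iter(ref.trial_counts))
        ti, nh_tr, nn_tr = ref.trial_counts[tr_idx]
        p_loo = ref.p_high_loo(tr_idx)
        a = ref.alpha
        expect = (ref.n_high[ti] - nh_tr + a) / (
            (ref.n_obs[ti] - nn_tr)[:, None] + 2 * a)
        assert np.allclose(p_loo[ti], expect)


class TestPredictWindow:
    def test_hand_product_example(self):
        # two cells, two types: R=(0.9,0.2) vs (0.3,0.8); C=(high,low)
        p_high = np.array([[[0.9, 0.2]], [[0.3, 0.8]]])   # (T=2, P=1, C=2)
        c_vec = np.array([True, False])
        logp, arg = predict_window(c_vec, p_high, 0)
        assert np.exp(logp) == pytest.approx([0.72, 0.06])
        assert arg == 0

    def test_identical_references_tie_break_to_first(self):
        p_high = np.full((3, 1, 4), 0.5)
        logp, arg = predict_window(np.array([True, False, True, False]),
                                   p_high, 0)
        assert arg == 0
        assert np.allclose(logp, logp[0])

    def test_separating_cell_decides(self):
        p_high = np.array([[[0.99, 0.5]], [[0.01, 0.5]]])
        _, arg = predict_window(np.array([True, False]), p_high, 0)
        assert arg == 0
        _, arg = predict_window(np.array([False, False]), p_high, 0)
        assert arg == 1

    def test_invariant_to_cell_ordering(self):
        rng = np.random.default_rng(0)
        p_high = rng.uniform(0.1, 0.9, (4, 1, 30))
        c_vec = rng.random(30) > 0.5
        logp, _ = predict_window(c_vec, p_high, 0)
        perm = rng.permutation(30)
        logp_p, _ = predict_window(c_vec[perm], p_high[:, :, perm], 0)
        assert np.allclose(logp, logp_p)

    def test_no_underflow_with_thousand_cells(self):
        rng = np.random.default_rng(1)
        p_high = rng.uniform(0.01, 0.99, (8, 1, 1000))
        logp, arg = predict_window(rng.random(1000) > 0.5, p_high, 0)
        assert np.all(np.isfinite(logp))
        assert 0 <= arg < 8


class TestEpisodic:
    def test_uniform_predictions_are_not_episodic(self, full_session,
                                                  full_sim, full_maps):
        """A replay decoded against a flat reference cannot be certified."""
        from replaykit.decoding import BayesianDecoder
        from replaykit.events import detect_candidates
        from replaykit.replay import assemble_path
        from replaykit.trialtype import classify_episodic

        cands = detect_candidates(full_session)
        decoder = BayesianDecoder(full_maps)
        gt = full_session.ground_truth[0]
        tts = [(gt.subtask, j) for j in ("LL", "LR", "RL", "RR")
               if (gt.subtask, j) in full_maps.rates]
        path = assemble_path(cands[0], decoder, full_session.spikes, tts)
        ref = build_reference(full_session, full_sim.templates,
                              full_session.cells)
        flat = TrialTypeReference(
            trial_types=ref.trial_types, cells=ref.cells,
            bin_width_cm=ref.bin_width_cm, n_bins=ref.n_bins, alpha=1.0,
            n_high=np.zeros_like(ref.n_high),
            n_obs=np.zeros_like(ref.n_obs), trial_counts={})
        pred = classify_episodic(path, full_session, flat, n_shuffles=100,
                                 seed=0)
        assert pred is None or not pred.episodic

    def test_confident_consistent_replay_is_episodic(self, full_session,
                                                     full_sim, full_maps,
                                                     ground_truth_matcher):
        from replaykit.decoding import BayesianDecoder
        from replaykit.events import detect_candidates
        from replaykit.replay import assemble_path
        from replaykit.trialtype import classify_episodic

        cands = detect_candidates(full_session)
        decoder = BayesianDecoder(full_maps)
        ref = build_reference(full_session, full_sim.templates,
                              full_session.cells)
        gt = ground_truth_matcher(full_session, cands[2])
        tts = [(gt.subtask, j) for j in ("LL", "LR", "RL", "RR")
               if (gt.subtask, j) in full_maps.rates]
        path = assemble_path(cands[2], decoder, full_session.spikes, tts)
        pred = classify_episodic(path, full_session, ref, n_shuffles=200,
                                 seed=5)
        assert pred is not None
        assert pred.episodic
        assert pred.modal_type == (gt.subtask, gt.journey)

    def test_too_few_windows_not_classifiable(self, full_session, full_sim,
                                              full_maps):
        from replaykit.decoding import BayesianDecoder, PosteriorMatrix
        from replaykit.events import CandidateEvent
        from replaykit.replay import PathReplay
        from replaykit.trialtype import classify_episodic

        ref = build_reference(full_session, full_sim.templates,
                              full_session.cells)
        cand = CandidateEvent(t_start=1.0, t_end=1.02, cells=(), n_spikes=0,
                              peak_sd=0.0)
        post = PosteriorMatrix(t0s=np.array([1.0]), tau=0.02,
                               nprob=np.ones((1, 10)) / 10,
                               blocks=[(("VD", "LR"), 0, 10)],
                               bin_width_cm=2.0,
                               uniform=np.array([False]))
        path = PathReplay(cand, post, np.full((1, 2), np.nan), [], 0.0,
                          False, [("VD", "LR")])
        assert classify_episodic(path, full_session, ref) is None


def test_running_confusion_beats_chance_strongly(full_session, full_sim,
                                                 full_maps):
    from replaykit.trialtype import running_confusion

    ref = build_reference(full_session, full_sim.templates,
                          full_session.cells)
    confusion, acc = running_confusion(full_session, full_maps,
                                       full_sim.templates, ref)
    assert acc > 3 * 0.125              # far above the 1/8 chance level
    # journeys are essentially never confused
    tts = ref.trial_types
    cm = confusion.values
    journey_err = sum(cm[i, j] for i in range(8) for j in range(8)
                      if tts[i][1] != tts[j][1])
    assert journey_err / cm.sum() < 0.02
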