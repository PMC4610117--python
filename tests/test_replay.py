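"""Path assembly, dual-shuffle certification, and compression estimation."""

from __future__ import annotations

import numpy as np
import pytest

from replaykit.decoding import BayesianDecoder
from replaykit.events import CandidateEvent, detect_candidates
from replaykit.replay import (assemble_path, compression_rate,
                              shuffle_test)
from replaykit.session import JOURNEYS


@pytest.fixture(scope="module")
def decoder(full_maps):
    return BayesianDecoder(full_maps)


@pytest.fixture(scope="module")
def candidates(full_session):
    return detect_candidates(full_session)


def _trial_types(maps, subtask):
    return [(subtask, j) for j in JOURNEYS if (subtask, j) in maps.rates]


class TestAssemblePath:
    def test_injected_replay_yields_monotone_forward_path(
            self, full_session, full_maps, decoder, candidates,
            ground_truth_matcher):
        cand = candidates[0]
        gt = ground_truth_matcher(full_session, cand)
        path = assemble_path(cand, decoder, full_session.spikes,
                             _trial_types(full_maps, gt.subtask))
        assert path.is_path
        est = path.map_path
        have = ~np.isnan(est[:, 0])
        arcs = est[have, 1]
        # forward path: positions increase along the journey overall
        assert arcs[-1] > arcs[0]
        steps = np.diff(arcs)
        assert np.mean(steps > -5) > 0.9
        # begins near where the rat paused (the journey start zone)
        assert arcs[0] < 40.0
        assert path.total_distance_cm > 100.0

    def test_single_window_event_is_rejected(self, full_session, full_maps,
                                             decoder):
        cand = CandidateEvent(t_start=10.0, t_end=10.021, cells=(0, 1),
                              n_spikes=4, peak_sd=4.0)
        path = assemble_path(cand, decoder, full_session.spikes,
                             _trial_types(full_maps, "VD"))
        assert not path.is_path

    def test_most_injected_replays_become_paths(self, full_session, full_maps,
                                                decoder, candidates,
                                                ground_truth_matcher):
        n_path = 0
        subset = candidates[:60]
        for cand in subset:
            gt = ground_truth_matcher(full_session, cand)
            if gt is None:
                continue
            path = assemble_path(cand, decoder, full_session.spikes,
                                 _trial_types(full_maps, gt.subtask))
            n_path += path.is_path
        assert n_path / len(subset) >= 0.8


class TestShuffleTest:
    def test_injected_replay_certified(self, full_session, full_maps, decoder,
                                       candidates, ground_truth_matcher):
        cand = candidates[0]
        gt = ground_truth_matcher(full_session, cand)
        path = assemble_path(cand, decoder, full_session.spikes,
                             _trial_types(full_maps, gt.subtask))
        p_cell, p_field = shuffle_test(path, decoder, full_session.spikes,
                                       n_shuffles=200, seed=3)
        assert p_cell <= 0.01 and p_field <= 0.01

    def test_fixed_seed_reproduces_pvalues(self, full_session, full_maps,
                                           decoder, candidates,
                                           ground_truth_matcher):
        cand = candidates[1]
        gt = ground_truth_matcher(full_session, cand)
        path = assemble_path(cand, decoder, full_session.spikes,
                             _trial_types(full_maps, gt.subtask))
        a = shuffle_test(path, decoder, full_session.spikes, n_shuffles=100,
                         seed=11)
        b = shuffle_test(path, decoder, full_session.spikes, n_shuffles=100,
                         seed=11)
        assert a == b

    def test_degenerate_path_gives_p_one(self, full_session, full_maps,
                                         decoder):
        # a nearly empty stretch decodes to too few informative windows
        cand = CandidateEvent(t_start=0.5, t_end=0.56, cells=(0, 1),
                              n_spikes=0, peak_sd=0.0)
        path = assemble_path(cand, decoder, full_session.spikes,
                             _trial_types(full_maps, "VD"))
        if not np.isfinite(path.total_distance_cm) or path.n_windows < 3:
            p = shuffle_test(path, decoder, full_session.spikes,
                             n_shuffles=100, seed=0)
            assert p == (1.0, 1.0)

    def test_pvalues_super_uniform_under_own_null(self, full_session,
                                                  full_maps, decoder):
        """Applying the certification to null bursts rejects at most ~alpha."""
        from replaykit import SessionSimulator, SimulationConfig

        cfg = SimulationConfig(seed=31, replay_per_pause=0,
                               null_burst_per_pause=1, include_lfp=False,
                               protocol_blocks=(("VD", 8), ("NA", 8)))
        sim = SessionSimulator(cfg)
        bundle = sim.generate()
        from replaykit.placemaps import build_place_maps
        maps = build_place_maps(bundle, sim.templates)
        dec = BayesianDecoder(maps)
        cands = detect_candidates(bundle)
        assert len(cands) >= 10
        rng = np.random.default_rng(0)
        certified = 0
        for cand in cands:
            sub = "VD" if any(tt[0] == "VD" for tt in maps.trial_types) else "NA"
            path = assemble_path(cand, dec, bundle.spikes,
                                 _trial_types(maps, sub))
            if not path.is_path:
                continue
            pc, pf = shuffle_test(path, dec, bundle.spikes, n_shuffles=100,
                                  seed=int(rng.integers(2**31)))
            certified += (pc < 0.05) and (pf < 0.05)
        assert certified / len(cands) <= 0.1


class TestCompressionRate:
    def test_identity_when_distributions_match(self):
        """Candidate windows cut from a homogeneous train give ratio ~1."""
        import replaykit.session as sess
        rng = np.random.default_rng(5)
        dur = 600.0
        t = np.arange(0, dur, 0.02)
        behavior = __import__("pandas").DataFrame({
            "t": t, "x": 50.0, "y": 10.0, "speed": 10.0,
            "head_direction": 0.0})
        spikes = {c: np.sort(rng.uniform(0, dur, rng.poisson(5 * dur)))
                  for c in range(5)}
        bundle = sess.SessionBundle(behavior=behavior, trials=[],
                                    spikes=spikes, lfp=None)
        # long windows keep the both-spikes-inside censoring negligible
        cands = [CandidateEvent(t_start=s, t_end=s + 10.0, cells=(0,),
                                n_spikes=0, peak_sd=0.0)
                 for s in np.arange(10, 400, 20.0)]
        comp = compression_rate(bundle, cands)
        assert comp["compression"].median() == pytest.approx(1.0, rel=0.1)

    def test_exact_tenfold_scaling(self):
        """Event ISIs exactly one tenth of rest ISIs give ratio 10."""
        import replaykit.session as sess
        import pandas as pd
        rest = np.arange(0.0, 500.0, 0.5)                  # 0.5-s ISIs
        ev_start = 501.0
        event = ev_start + np.arange(0, 40) * 0.05         # 0.05-s ISIs
        st = np.concatenate([rest, event])
        t = np.arange(0, 510, 0.02)
        behavior = pd.DataFrame({"t": t, "x": 0.0, "y": 0.0, "speed": 10.0,
                                 "head_direction": 0.0})
        bundle = sess.SessionBundle(behavior=behavior, trials=[],
                                    spikes={0: st, 1: np.array([0.1, 509.0])},
                                    lfp=None)
        cands = [CandidateEvent(t_start=ev_start - 0.01,
                                t_end=event[-1] + 0.01, cells=(0,),
                                n_spikes=40, peak_sd=5.0)]
        comp = compression_rate(bundle, cands)
        assert comp["compression"].iloc[0] == pytest.approx(10.0, rel=1e-6)

    def test_simulator_recovers_injected_factor(self, full_session,
                                                candidates):
        comp = compression_rate(full_session, candidates)
        assert len(comp) >= 100
        assert 8.0 <= comp["compression"].median() <= 12.0

    def test_no_candidates_raises(self, full_session):
        with pytest.raises(ValueError):
            compression_rate(full_session, [])
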