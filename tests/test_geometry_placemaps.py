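"""Maze geometry, linearization, place maps, spatial information, screening."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from replaykit import SessionSimulator, SimulationConfig
from replaykit.maze import (JOURNEY_LENGTH_CM, linearize,
                            make_journey_templates, zone_of)
from replaykit.placemaps import (build_place_maps, journey_maps,
                                 screen_place_cells, spatial_information)


@pytest.fixture(scope="module")
def templates():
    return make_journey_templates()


class TestTemplates:
    def test_arc_strictly_increasing_and_length(self, templates):
        for tpl in templates.values():
            assert np.all(np.diff(tpl.arc) > 0)
            assert tpl.length == pytest.approx(JOURNEY_LENGTH_CM)

    def test_zones_disjoint(self, templates):
        tpl = templates["LR"]
        names = list(tpl.zones)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                lo_a, hi_a = tpl.zones[a]
                lo_b, hi_b = tpl.zones[b]
                assert min(hi_a, hi_b) <= max(lo_a, lo_b)

    def test_zone_lookup(self, templates):
        tpl = templates["LR"]
        assert zone_of(tpl, 5.0) == "start"
        assert zone_of(tpl, 100.0) == "stem"
        assert zone_of(tpl, 150.0) == "junction"
        assert zone_of(tpl, 195.0) == "goal"


class TestLinearize:
    def test_point_on_template_maps_to_own_arc(self, templates):
        tpl = templates["LR"]
        idx = [0, 50, 120, len(tpl.arc) - 1]
        arcs = linearize(tpl.points[idx], tpl)
        assert np.allclose(arcs, tpl.arc[idx])

    def test_equidistant_tie_breaks_to_smaller_arc(self):
        from replaykit.maze import JourneyTemplate
        tpl = JourneyTemplate(
            journey="XX",
            points=np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),
            arc=np.array([0.0, 1.0, 2.0]),
            zones={})
        # equidistant from the first two template points
        assert linearize(np.array([[0.5, 1.0]]), tpl)[0] == 0.0

    def test_empty_input(self, templates):
        assert linearize(np.empty((0, 2)), templates["LR"]).size == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_agrees_with_exhaustive_nearest_neighbor(self, seed):
        tpl = make_journey_templates()["RL"]
        rng = np.random.default_rng(seed)
        s = rng.uniform(0, tpl.length, 5)
        pts = tpl.position_at(s) + rng.uniform(-10, 10, (5, 2))
        arcs = linearize(pts, tpl)
        for p, a in zip(pts, arcs):
            d = np.hypot(tpl.points[:, 0] - p[0], tpl.points[:, 1] - p[1])
            assert a == tpl.arc[np.argmin(d)]


class TestPlaceMaps:
    def test_no_spikes_gives_zero_map(self, small_sim, small_session):
        bundle = small_session
        silent = dict(bundle.spikes)
        silent[0] = np.empty(0)
        import replaykit.session as sess
        b2 = sess.SessionBundle(behavior=bundle.behavior, trials=bundle.trials,
                                spikes=silent, lfp=None)
        maps = build_place_maps(b2, small_sim.templates, cells=[0])
        for tt in maps.trial_types:
            assert np.all(maps.rates[tt] == 0)

    def test_flat_poisson_cell_recovers_constant_rate(self):
        """A 5-Hz homogeneous cell maps to ~5 Hz in every visited bin."""
        cfg = SimulationConfig(seed=3, n_cells=2, include_lfp=False,
                               replay_per_pause=0,
                               protocol_blocks=(("VD", 30),))
        sim = SessionSimulator(cfg)
        bundle = sim.generate()
        rng = np.random.default_rng(0)
        dur = bundle.duration
        flat = np.sort(rng.uniform(0, dur, rng.poisson(5.0 * dur)))
        bundle.spikes[0] = flat
        maps = build_place_maps(bundle, sim.templates, cells=[0])
        pooled = []
        for tt in maps.trial_types:
            occ = maps.occupancy[tt]
            good = occ > 0.2       # reasonably sampled bins only
            pooled.extend(maps.rates[tt][0][good])
        pooled = np.asarray(pooled)
        assert pooled.size > 50
        # Poisson sampling error around the true 5-Hz rate
        assert abs(pooled.mean() - 5.0) < 1.0

    def test_peak_recovery_on_pooled_laps(self):
        """Gaussian tuning peaks are recovered within one bin when one
        trial type holds the whole session's laps."""
        cfg = SimulationConfig(seed=5, n_cells=30, include_lfp=False,
                               replay_per_pause=0,
                               protocol_blocks=(("VD", 70),))
        sim = SessionSimulator(cfg)
        bundle = sim.generate()
        maps = build_place_maps(bundle, sim.templates)
        errs = []
        for tt in maps.trial_types:
            centers = sim.ensemble.centers[tt[1]]
            peaks = (np.argmax(maps.rates[tt], axis=1) + 0.5) * maps.bin_width_cm
            errs.extend(np.abs(peaks - centers))
        assert np.median(errs) <= 1.5 * maps.bin_width_cm

    def test_smoothing_conserves_spike_mass(self, small_sim, small_session):
        """Rate x smoothed occupancy integrates back to the spikes that
        entered the map (normalized kernel, reflective edges).

        The oracle recounts the mapped spikes by brute force: a spike enters
        the map when its nearest retained (running, in-trial) behavior
        sample lies within 1.5 sampling steps.
        """
        maps = build_place_maps(small_session, small_sim.templates)
        tt = maps.trial_types[0]
        recovered = (maps.rates[tt] * maps.occupancy[tt][None, :]).sum(axis=1)
        from replaykit.placemaps import _trial_samples
        samples = _trial_samples(small_session, 5.0)
        grp = samples[(samples.subtask == tt[0]) & (samples.journey == tt[1])]
        dt = float(np.median(np.diff(small_session.behavior["t"].to_numpy())))
        for ci, cell in enumerate(maps.cells[:5]):
            st = small_session.spikes[cell]
            n_raw = 0
            for _, g in grp.groupby("trial_index"):
                tt_tr = g["t"].to_numpy()
                sel = st[(st >= tt_tr[0]) & (st <= tt_tr[-1])]
                for s in sel:
                    if np.min(np.abs(tt_tr - s)) <= 1.5 * dt:
                        n_raw += 1
            if n_raw:
                assert recovered[ci] == pytest.approx(n_raw, rel=0.05)

    def test_maps_invariant_to_trial_order(self, small_sim, small_session):
        maps_a = build_place_maps(small_session, small_sim.templates)
        import replaykit.session as sess
        shuffled = sess.SessionBundle(
            behavior=small_session.behavior,
            trials=list(reversed(small_session.trials)),
            spikes=dict(small_session.spikes), lfp=None)
        maps_b = build_place_maps(shuffled, small_sim.templates)
        for tt in maps_a.trial_types:
            assert np.allclose(maps_a.rates[tt], maps_b.rates[tt])

    def test_journey_pooling_is_occupancy_weighted(self, small_sim, small_session):
        maps = build_place_maps(small_session, small_sim.templates)
        jm = journey_maps(maps)
        for key in jm.trial_types:
            j = key[1]
            tts = [tt for tt in maps.trial_types if tt[1] == j]
            occ = np.sum([maps.occupancy[tt] for tt in tts], axis=0)
            num = np.sum([maps.rates[tt] * maps.occupancy[tt] for tt in tts],
                         axis=0)
            good = occ > 1e-9
            assert np.allclose(jm.rates[key][:, good], num[:, good] / occ[good])


class TestSpatialInformation:
    def test_flat_map_is_zero(self):
        assert spatial_information(np.full(10, 3.0), np.ones(10)) == pytest.approx(0.0)

    @pytest.mark.parametrize("k,expected", [(2, 1.0), (4, 2.0), (8, 3.0)])
    def test_one_of_k_bins_gives_log2_k(self, k, expected):
        rate = np.zeros(k)
        rate[0] = 1.0
        assert spatial_information(rate, np.ones(k)) == pytest.approx(expected)

    def test_zero_mean_rate_raises(self):
        with pytest.raises(ValueError, match="insufficient activity"):
            spatial_information(np.zeros(5), np.ones(5))


class TestScreening:
    def test_screen_keeps_remapping_cells(self, full_sim, full_session, full_maps):
        """Cells with subtask rate gains and Gaussian tuning pass at 140 laps."""
        selected = screen_place_cells(full_session, full_maps,
                                      full_sim.templates)
        assert len(selected) >= 0.95 * full_session.n_cells

    def test_flat_and_silent_cells_are_excluded(self, full_sim, full_session,
                                                full_maps):
        import replaykit.session as sess
        rng = np.random.default_rng(0)
        dur = full_session.duration
        spikes = dict(full_session.spikes)
        n0 = full_session.n_cells
        # flat 1-Hz cell (no spatial information), and a near-silent cell
        spikes[n0] = np.sort(rng.uniform(0, dur, int(1.0 * dur)))
        spikes[n0 + 1] = np.sort(rng.uniform(0, dur, 5))
        b2 = sess.SessionBundle(behavior=full_session.behavior,
                                trials=full_session.trials, spikes=spikes,
                                lfp=None)
        maps = build_place_maps(b2, full_sim.templates)
        selected = screen_place_cells(b2, maps, full_sim.templates)
        assert n0 not in selected          # fails the information criterion
        assert n0 + 1 not in selected      # fails the mean-rate floor
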