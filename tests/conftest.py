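"""Shared fixtures: synthetic sessions at two scales.

``full_session`` is the study-scale session (100 cells, 140 laps, one
injected replay per pause) reused across the expensive integration and
acceptance tests; ``small_session`` is a 20-cell, 8-lap session for fast
unit tests.  Both are deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from replaykit import SessionSimulator, SimulationConfig
from replaykit.placemaps import build_place_maps


@pytest.fixture(scope="session")
def full_sim():
    return SessionSimulator(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def full_session(full_sim):
    return full_sim.generate()


@pytest.fixture(scope="session")
def full_maps(full_sim, full_session):
    return build_place_maps(full_session, full_sim.templates)


@pytest.fixture(scope="session")
def small_sim():
    cfg = SimulationConfig(
        seed=7, n_cells=20,
        protocol_blocks=(("VD", 3), ("NA", 3), ("DA", 2)),
    )
    return SessionSimulator(cfg)


@pytest.fixture(scope="session")
def small_session(small_sim):
    return small_sim.generate()


@pytest.fixture(scope="session")
def small_maps(small_sim, small_session):
    return build_place_maps(small_session, small_sim.templates)


def overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


@pytest.fixture(scope="session")
def ground_truth_matcher():
    def match(bundle, event, kind="replay", min_frac=0.0):
        best, best_o = None, 0.0
        for gt in bundle.ground_truth:
            if gt.kind != kind:
                continue
            o = overlap(gt.t_start, gt.t_end, event.t_start, event.t_end)
            if o > best_o:
                best, best_o = gt, o
        if best is not None and best_o >= min_frac * (best.t_end - best.t_start):
            return best
        return None
    return match
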