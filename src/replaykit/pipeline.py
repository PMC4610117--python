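"""End-to-end pipeline: simulate/load -> maps -> screen -> events -> path
replays -> trial types -> episodic replays -> session statistics.

Each stage writes its table into the artifact directory and logs the seeds
and counts it used, so a run is reproducible from the config alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .decoding import BayesianDecoder
from .events import detect_candidates, detect_swr, events_frame, flag_swr_coincidence
from .io import read_session, write_session
from .maze import make_journey_templates
from .placemaps import build_place_maps, screen_place_cells
from .replay import (assemble_path, compression_rate, replay_table,
                     shuffle_test)
from .sessionstats import (goal_vicinity_region, path_representation,
                           match_score, subtask_preference)
from .session import JOURNEYS, SessionBundle
from .simulate import SessionSimulator
from .trialtype import build_reference, classify_episodic, running_confusion

log = logging.getLogger("replaykit")


def relevant_trial_types(maps, subtask: str) -> list[tuple[str, str]]:
    """Journey maps searched when decoding a replay under one subtask."""
    return [(subtask, j) for j in JOURNEYS if (subtask, j) in maps.rates]


def subtask_at(bundle: SessionBundle, t: float) -> str:
    """Subtask context of a time point: the surrounding or next trial."""
    for tr in bundle.trials:
        if t <= tr.t_end:
            return tr.subtask
    return bundle.trials[-1].subtask if bundle.trials else "VD"


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 session_dir: str | Path | None = None) -> dict:
    """Run the full analysis; returns the summary dict written to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    templates = make_journey_templates()

    if session_dir is None:
        log.info("simulating session (seed=%d)", config.seed)
        sim = SessionSimulator(config.simulation_config())
        bundle = sim.generate()
        write_session(bundle, out / "session")
    else:
        log.info("loading session from %s", session_dir)
        bundle = read_session(session_dir)

    if not bundle.spikes or bundle.duration <= 0:
        (out / "summary.json").write_text(json.dumps({"empty": True}))
        log.warning("empty session; wrote empty report")
        return {"empty": True}

    # place maps and screening
    maps = build_place_maps(bundle, templates,
                            bin_width_cm=config.bin_width_cm,
                            kernel_sd_cm=config.kernel_sd_cm,
                            speed_min=config.speed_min_cm_s)
    maps.to_frame().to_csv(out / "place_maps.csv", index=False)
    cells = screen_place_cells(bundle, maps, templates,
                               si_threshold=config.si_threshold_bits,
                               alpha=config.screen_alpha,
                               min_mean_rate=config.min_mean_rate_hz,
                               max_mean_rate=config.max_mean_rate_hz)
    log.info("screened %d/%d cells", len(cells), bundle.n_cells)

    # events
    swrs = []
    if bundle.lfp is not None:
        swrs = detect_swr(bundle.lfp, bundle.behavior["t"].to_numpy(),
                          bundle.behavior["speed"].to_numpy(),
                          threshold_sd=config.ripple_threshold_sd,
                          immobility_speed=config.immobility_speed_cm_s)
    candidates = detect_candidates(bundle,
                                   threshold_sd=config.burst_threshold_sd,
                                   immobility_speed=config.immobility_speed_cm_s)
    flag_swr_coincidence(candidates, swrs)
    events_frame(candidates).to_csv(out / "candidates.csv", index=False)
    log.info("detected %d SWRs, %d candidates", len(swrs), len(candidates))

    # path replays
    decoder = BayesianDecoder(maps, cells=cells,
                              rate_floor_hz=config.rate_floor_hz)
    paths = []
    for cand in candidates:
        tts = relevant_trial_types(maps, subtask_at(bundle, cand.t_start))
        path = assemble_path(cand, decoder, bundle.spikes, tts,
                             compression=config.compression_factor,
                             window_s=config.replay_window_s,
                             step_s=config.replay_step_s,
                             continuity_cm=config.continuity_cm,
                             distance_criterion_cm=config.distance_criterion_cm)
        if path.is_path:
            path.p_cell_identity, path.p_place_field = shuffle_test(
                path, decoder, bundle.spikes, n_shuffles=config.n_shuffles,
                seed=int(rng.integers(2**31)),
                continuity_cm=config.continuity_cm,
                compression=config.compression_factor)
        paths.append(path)
    replay_table(paths).to_csv(out / "path_replays.csv", index=False)
    significant = [p for p in paths if p.significant]
    log.info("%d candidates -> %d paths -> %d significant",
             len(paths), sum(p.is_path for p in paths), len(significant))

    # trial types
    reference = build_reference(bundle, templates, cells,
                                window_s=config.ref_window_s,
                                step_s=config.ref_step_s,
                                bin_width_cm=config.ref_bin_cm,
                                alpha=config.pseudocount,
                                speed_min=config.speed_min_cm_s)
    confusion, accuracy = running_confusion(bundle, maps, templates, reference)
    confusion.to_csv(out / "running_confusion.csv")
    log.info("running LOO accuracy %.3f", accuracy)

    episodic = []
    predictions = []
    for path in significant:
        pred = classify_episodic(path, bundle, reference,
                                 n_shuffles=config.n_shuffles,
                                 seed=int(rng.integers(2**31)))
        predictions.append(pred)
        if pred is not None and pred.episodic:
            episodic.append((path, pred))
    log.info("%d episodic replays", len(episodic))

    # statistics
    region = goal_vicinity_region(extent_cm=config.goal_vicinity_cm)
    goal_mass = [path_representation(p.posterior, region) for p in significant]
    counts = {}
    for path, pred in episodic:
        counts[pred.modal_type[0]] = counts.get(pred.modal_type[0], 0) + 1
    summary = {
        "n_cells_screened": len(cells),
        "n_swr": len(swrs),
        "n_candidates": len(candidates),
        "n_paths": int(sum(p.is_path for p in paths)),
        "n_significant": len(significant),
        "n_episodic": len(episodic),
        "running_loo_accuracy": float(accuracy),
        "goal_vicinity_mass": goal_mass,
    }
    if len(counts) == 3:
        summary["subtask_preference"] = subtask_preference(
            counts, experience_ratio=tuple(config.experience_ratio))
    if bundle.ground_truth and episodic:
        actual, predicted = [], []
        for path, pred in episodic:
            for ev in bundle.ground_truth:
                if (ev.kind == "replay"
                        and min(ev.t_end, path.candidate.t_end)
                        - max(ev.t_start, path.candidate.t_start) > 0):
                    actual.append(f"{ev.subtask}_{ev.journey}")
                    predicted.append(f"{pred.modal_type[0]}_{pred.modal_type[1]}")
                    break
        if len(set(actual)) >= 2:
            summary["episodic_match"] = match_score(np.array(actual),
                                                    np.array(predicted))
    if candidates:
        comp = compression_rate(bundle, candidates)
        comp.to_csv(out / "compression.csv", index=False)
        if len(comp):
            summary["compression_median"] = float(comp["compression"].median())

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary
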