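"""Session readers and writers.

A session is a directory of plain tables: ``behavior.csv`` (t, x, y, speed,
head_direction), ``trials.csv``, ``spikes.csv`` (cell_id, time_s),
``ground_truth.json`` (synthetic sessions only) and, when an LFP trace is
present, ``lfp.npy`` with a ``lfp.json`` sidecar carrying the sampling rate.
Readers validate schemas and monotonicity and name the offending table in
errors.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .session import GroundTruthEvent, LfpTrace, SessionBundle, TrialRecord


class SchemaError(ValueError):
    """A session table is missing or malformed."""


def write_session(bundle: SessionBundle, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bundle.behavior.to_csv(path / "behavior.csv", index=False)
    bundle.trials_frame().to_csv(path / "trials.csv", index=False)
    bundle.spikes_frame().to_csv(path / "spikes.csv", index=False)
    if bundle.lfp is not None:
        np.save(path / "lfp.npy", bundle.lfp.samples)
        (path / "lfp.json").write_text(json.dumps({"fs_hz": bundle.lfp.fs}))
    gt = [
        {"kind": e.kind, "t_start": e.t_start, "t_end": e.t_end,
         "subtask": e.subtask, "journey": e.journey,
         "cells": list(e.cells), "n_spikes": e.n_spikes}
        for e in bundle.ground_truth
    ]
    (path / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    return path


def _require(frame: pd.DataFrame, columns: set[str], table: str) -> None:
    missing = columns - set(frame.columns)
    if missing:
        raise SchemaError(f"{table}: missing columns {sorted(missing)}")


def read_session(path: str | Path) -> SessionBundle:
    path = Path(path)
    beh_file = path / "behavior.csv"
    if not beh_file.exists():
        raise SchemaError("behavior.csv: file not found")
    behavior = pd.read_csv(beh_file)
    _require(behavior, {"t", "x", "y", "speed", "head_direction"}, "behavior.csv")
    t = behavior["t"].to_numpy()
    if np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise SchemaError(f"behavior.csv: non-increasing time at row {bad}")

    trials_frame = pd.read_csv(path / "trials.csv")
    _require(trials_frame, {"index", "subtask", "journey", "correct",
                            "t_start", "t_end"}, "trials.csv")
    trials = [
        TrialRecord(index=int(r["index"]), subtask=str(r["subtask"]),
                    journey=str(r["journey"]), correct=bool(r["correct"]),
                    t_start=float(r["t_start"]), t_end=float(r["t_end"]))
        for _, r in trials_frame.iterrows()
    ]

    spikes_frame = pd.read_csv(path / "spikes.csv")
    _require(spikes_frame, {"cell_id", "time_s"}, "spikes.csv")
    spikes: dict[int, np.ndarray] = {}
    for cell, grp in spikes_frame.groupby("cell_id"):
        st = np.sort(grp["time_s"].to_numpy(dtype=float))
        spikes[int(cell)] = st

    lfp = None
    if (path / "lfp.npy").exists():
        sidecar = path / "lfp.json"
        if not sidecar.exists():
            raise SchemaError("lfp.json: sidecar with fs_hz required")
        meta = json.loads(sidecar.read_text())
        if "fs_hz" not in meta:
            raise SchemaError("lfp.json: missing fs_hz")
        lfp = LfpTrace(samples=np.load(path / "lfp.npy"), fs=float(meta["fs_hz"]))

    ground_truth = []
    gt_file = path / "ground_truth.json"
    if gt_file.exists():
        for e in json.loads(gt_file.read_text()):
            ground_truth.append(GroundTruthEvent(
                kind=e["kind"], t_start=e["t_start"], t_end=e["t_end"],
                subtask=e["subtask"], journey=e["journey"],
                cells=tuple(e["cells"]), n_spikes=e["n_spikes"]))

    try:
        return SessionBundle(behavior=behavior, trials=trials, spikes=spikes,
                             lfp=lfp, ground_truth=ground_truth)
    except ValueError as err:
        raise SchemaError(str(err)) from err
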