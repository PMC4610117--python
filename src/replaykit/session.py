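"""Core session containers.

A recording session is represented by a :class:`SessionBundle`: a uniformly
sampled behavior trace, a list of trial records, per-cell spike-time arrays,
and (optionally) a wideband LFP trace.  Synthetic sessions additionally carry
a ground-truth inventory of injected events so that detection stages can be
scored against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

SUBTASKS = ("VD", "NA", "DA")
JOURNEYS = ("LL", "LR", "RL", "RR")
#: The eight trial types, in canonical enumeration order (used for
#: tie-breaks).  The alternation subtasks (NA, DA) can only produce the
#: crossing journeys LR and RL on correct trials.
TRIAL_TYPES = (
    ("VD", "LL"), ("VD", "LR"), ("VD", "RL"), ("VD", "RR"),
    ("NA", "LR"), ("NA", "RL"),
    ("DA", "LR"), ("DA", "RL"),
)


@dataclass(frozen=True)
class TrialRecord:
    """One lap: a journey through the maze under one subtask rule."""

    index: int
    subtask: str          # VD, NA or DA
    journey: str          # LL, LR, RL or RR (start side -> goal side)
    correct: bool
    t_start: float        # run onset at the start zone (s)
    t_end: float          # arrival at the goal (s)

    @property
    def trial_type(self) -> tuple[str, str]:
        return (self.subtask, self.journey)


@dataclass(frozen=True)
class GroundTruthEvent:
    """Inventory record for an injected synthetic event."""

    kind: str             # "replay" or "null_burst"
    t_start: float
    t_end: float
    subtask: str
    journey: str
    cells: tuple[int, ...]
    n_spikes: int


@dataclass
class LfpTrace:
    """A sampled local-field-potential trace (arbitrary units)."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("LFP sampling rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class SessionBundle:
    """Synchronized container for one recording session.

    Attributes
    ----------
    behavior : pandas.DataFrame
        Uniformly sampled columns ``t`` (s), ``x``, ``y`` (cm), ``speed``
        (cm/s) and ``head_direction`` (rad).
    trials : list of TrialRecord
    spikes : dict
        ``cell_id -> strictly increasing array of spike times (s)``.
    lfp : LfpTrace, optional
    ground_truth : list of GroundTruthEvent
        Present only for synthetic sessions.
    """

    behavior: pd.DataFrame
    trials: list[TrialRecord]
    spikes: dict[int, np.ndarray]
    lfp: Optional[LfpTrace] = None
    ground_truth: list[GroundTruthEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"t", "x", "y", "speed", "head_direction"}
        missing = required - set(self.behavior.columns)
        if missing:
            raise ValueError(f"behavior table missing columns: {sorted(missing)}")
        t = self.behavior["t"].to_numpy()
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("behavior timestamps must be strictly increasing")
        for cell, st in self.spikes.items():
            st = np.asarray(st, dtype=float)
            if st.size > 1 and np.any(np.diff(st) <= 0):
                raise ValueError(f"spike times of cell {cell} not strictly increasing")
            self.spikes[cell] = st
        span = self.span
        for tr in self.trials:
            if not (span[0] - 1e-9 <= tr.t_start < tr.t_end <= span[1] + 1e-9):
                raise ValueError(f"trial {tr.index} lies outside the session span")

    @property
    def cells(self) -> list[int]:
        return sorted(self.spikes)

    @property
    def n_cells(self) -> int:
        return len(self.spikes)

    @property
    def span(self) -> tuple[float, float]:
        t = self.behavior["t"].to_numpy()
        return (float(t[0]), float(t[-1])) if t.size else (0.0, 0.0)

    @property
    def duration(self) -> float:
        lo, hi = self.span
        return hi - lo

    def trials_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [tr.index for tr in self.trials],
                "subtask": [tr.subtask for tr in self.trials],
                "journey": [tr.journey for tr in self.trials],
                "correct": [tr.correct for tr in self.trials],
                "t_start": [tr.t_start for tr in self.trials],
                "t_end": [tr.t_end for tr in self.trials],
            }
        )

    def spikes_frame(self) -> pd.DataFrame:
        cells = np.concatenate(
            [np.full(self.spikes[c].size, c, dtype=int) for c in self.cells]
        ) if self.spikes else np.empty(0, dtype=int)
        times = np.concatenate([self.spikes[c] for c in self.cells]) if self.spikes else np.empty(0)
        frame = pd.DataFrame({"cell_id": cells, "time_s": times})
        return frame.sort_values(["time_s", "cell_id"], kind="mergesort").reset_index(drop=True)

    def session_mean_rates(self) -> dict[int, float]:
        """Whole-session mean firing rate (Hz) per cell."""
        dur = self.duration
        if dur <= 0:
            raise ValueError("session has zero duration")
        return {c: self.spikes[c].size / dur for c in self.cells}

    def speed_at(self, t: np.ndarray) -> np.ndarray:
        """Running speed interpolated at arbitrary times."""
        b = self.behavior
        return np.interp(np.asarray(t, dtype=float), b["t"].to_numpy(), b["speed"].to_numpy())

    def position_at(self, t: np.ndarray) -> np.ndarray:
        """(x, y) interpolated at arbitrary times, shape (n, 2)."""
        b = self.behavior
        tt = np.asarray(t, dtype=float)
        return np.column_stack(
            [
                np.interp(tt, b["t"].to_numpy(), b["x"].to_numpy()),
                np.interp(tt, b["t"].to_numpy(), b["y"].to_numpy()),
            ]
        )

    def trial_at(self, t: float) -> Optional[TrialRecord]:
        for tr in self.trials:
            if tr.t_start <= t <= tr.t_end:
                return tr
        return None
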