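"""Synthetic session generator.

Emulates the statistical structure of a figure-eight maze recording: place
cells with journey-specific Gaussian tuning on the linearized coordinate
(global remapping between journeys) and multiplicative subtask-specific rate
gains (rate remapping); inhomogeneous-Poisson spiking while the animal runs;
immobility pauses in the start zones (and during the DA waiting period in the
stem) into which time-compressed replay sequences and matched non-sequential
null bursts are injected; and an LFP trace of pink noise plus ripple-band
bursts coincident with each injected replay and theta during running.

The trial sequence follows the subtask protocol VD(20) NA(20) VD(10) DA(20),
repeated twice: 140 laps, a 60:40:40 VD:NA:DA experience ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .maze import JourneyTemplate, make_journey_templates, return_rail
from .session import (
    SUBTASKS,
    GroundTruthEvent,
    LfpTrace,
    SessionBundle,
    TrialRecord,
)

#: Subtask blocks of the training protocol, run twice per session.
PROTOCOL_BLOCKS = (("VD", 20), ("NA", 20), ("VD", 10), ("DA", 20))

#: Rate-remapping gain set: each cell gets a random permutation of these
#: multipliers across the three subtasks.
DEFAULT_SUBTASK_GAINS = (1.0, 1.5, 2.25)

#: Nominal duration (s) of a 10x-compressed full-journey replay
#: (200 cm / (50 cm/s * 10)), used to size injection slots within pauses.
JOURNEY_SLOT_S = 0.5


@dataclass
class SimulationConfig:
    """Parameters of the synthetic session.

    ``subtask_gain`` maps each subtask to either a scalar (shared by all
    cells) or a per-cell array of nonnegative multiplicative gains.  When
    left ``None``, each cell receives an independent random permutation of
    :data:`DEFAULT_SUBTASK_GAINS` across the three subtasks, i.e. pure rate
    remapping with a population-balanced gain budget.
    """

    seed: int = 0
    n_cells: int = 100
    field_width_cm: float = 10.0          # Gaussian tuning SD
    peak_rate_hz: float = 8.0
    baseline_rate_hz: float = 0.1
    subtask_gain: Optional[dict[str, np.ndarray | float]] = None
    compression_factor: float = 10.0
    protocol_blocks: Sequence[tuple[str, int]] = field(
        default_factory=lambda: PROTOCOL_BLOCKS * 2
    )
    replay_per_pause: int = 1
    null_burst_per_pause: int = 0
    lfp_fs_hz: float = 1250.0
    behavior_fs_hz: float = 50.0
    run_speed_cm_s: float = 50.0
    pause_range_s: tuple[float, float] = (1.0, 5.0)
    delay_s: float = 5.0                  # DA waiting period at the barrier
    error_rate: float = 0.0
    include_lfp: bool = True
    theta_hz: float = 8.0
    ripple_hz: float = 180.0

    def validate(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be at least 2")
        if self.peak_rate_hz < 0 or self.baseline_rate_hz < 0:
            raise ValueError("firing rates must be nonnegative")
        if self.field_width_cm <= 0:
            raise ValueError("field width must be positive")
        if self.compression_factor < 1:
            raise ValueError("compression_factor must be >= 1")
        if self.behavior_fs_hz <= 0 or self.lfp_fs_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if self.run_speed_cm_s <= 0:
            raise ValueError("run speed must be positive")
        if self.subtask_gain is not None:
            for s in SUBTASKS:
                if s not in self.subtask_gain:
                    raise ValueError(f"subtask_gain missing entry for {s}")
                if np.any(np.asarray(self.subtask_gain[s]) < 0):
                    raise ValueError("subtask gains must be nonnegative")


@dataclass
class CellEnsemble:
    """Ground-truth tuning of the simulated population."""

    centers: dict[str, np.ndarray]        # journey -> (n_cells,) field centers (cm)
    gains: dict[str, np.ndarray]          # subtask -> (n_cells,) gains
    field_width_cm: float
    peak_rate_hz: float
    baseline_rate_hz: float

    def rate(self, subtask: str, journey: str, s: np.ndarray) -> np.ndarray:
        """Firing rate (Hz) of every cell at linearized position(s) ``s``.

        Returns shape (len(s), n_cells).
        """
        s = np.atleast_1d(np.asarray(s, dtype=float))
        c = self.centers[journey]
        bump = np.exp(-((s[:, None] - c[None, :]) ** 2) / (2 * self.field_width_cm**2))
        return self.gains[subtask][None, :] * (
            self.baseline_rate_hz + self.peak_rate_hz * bump
        )


def _make_ensemble(config: SimulationConfig, rng: np.random.Generator,
                   templates: dict[str, JourneyTemplate]) -> CellEnsemble:
    n = config.n_cells
    centers = {}
    for j in sorted(templates):
        # even tiling with jitter so fields cover the whole journey
        base = (np.arange(n) + 0.5) / n * templates[j].length
        jitter = rng.uniform(-0.5, 0.5, n) * templates[j].length / n
        centers[j] = rng.permutation(base + jitter)   # global remapping
    if config.subtask_gain is None:
        gains = {s: np.empty(n) for s in SUBTASKS}
        for i in range(n):
            perm = rng.permutation(len(DEFAULT_SUBTASK_GAINS))
            for k, s in enumerate(SUBTASKS):
                gains[s][i] = DEFAULT_SUBTASK_GAINS[perm[k]]
    else:
        gains = {
            s: np.broadcast_to(np.asarray(config.subtask_gain[s], dtype=float), (n,)).copy()
            for s in SUBTASKS
        }
    return CellEnsemble(
        centers=centers,
        gains=gains,
        field_width_cm=config.field_width_cm,
        peak_rate_hz=config.peak_rate_hz,
        baseline_rate_hz=config.baseline_rate_hz,
    )


# ---------------------------------------------------------------------------
# behavior assembly


def _journey_sequence(config: SimulationConfig, rng: np.random.Generator) -> list[tuple[str, str, bool]]:
    """(subtask, journey, correct) per lap following the protocol."""
    laps: list[tuple[str, str, bool]] = []
    prev_goal = rng.choice(["L", "R"])
    for subtask, n_laps in config.protocol_blocks:
        for _ in range(n_laps):
            start = prev_goal
            err = rng.random() < config.error_rate
            if subtask == "VD":
                # cue side random; an error trial turns the wrong way
                cued = rng.choice(["L", "R"])
                goal = cued if not err else ("L" if cued == "R" else "R")
                correct = not err
            else:
                # alternation: memory-guided goal is opposite the previous
                memory_goal = "L" if prev_goal == "R" else "R"
                goal = memory_goal if not err else prev_goal
                correct = not err
            laps.append((subtask, start + goal, correct))
            prev_goal = goal
    return laps


@dataclass
class _Pause:
    t_start: float
    t_end: float
    subtask: str
    journey: str          # trial type of the *upcoming* run
    arc: float            # rat's linearized position during the pause
    zone: str             # "start" or "stem"


class _BehaviorBuilder:
    """Accumulates uniformly sampled behavior segments."""

    def __init__(self, fs: float):
        self.dt = 1.0 / fs
        self.t: list[np.ndarray] = []
        self.xy: list[np.ndarray] = []
        self.speed: list[np.ndarray] = []
        self.hd: list[np.ndarray] = []
        self.clock = 0.0

    def add(self, xy: np.ndarray, speed: np.ndarray, hd: np.ndarray) -> tuple[float, float]:
        n = len(xy)
        t = self.clock + np.arange(n) * self.dt
        self.t.append(t)
        self.xy.append(xy)
        self.speed.append(speed)
        self.hd.append(hd)
        t0 = self.clock
        self.clock += n * self.dt
        return t0, self.clock

    def frame(self) -> pd.DataFrame:
        xy = np.concatenate(self.xy)
        return pd.DataFrame(
            {
                "t": np.concatenate(self.t),
                "x": xy[:, 0],
                "y": xy[:, 1],
                "speed": np.concatenate(self.speed),
                "head_direction": np.concatenate(self.hd),
            }
        )


def _pause_samples(point: np.ndarray, heading: float, duration: float, dt: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = max(int(round(duration / dt)), 1)
    xy = point[None, :] + rng.normal(0, 0.3, (n, 2))
    speed = np.abs(rng.normal(0.3, 0.25, n)).clip(0.0, 1.9)
    hd = heading + rng.normal(0, 0.2, n)
    return xy, speed, hd


def _run_samples(template: JourneyTemplate, s0: float, s1: float, speed_mean: float,
                 dt: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate a run along a template between arc coordinates s0 < s1."""
    arcs = [s0]
    speeds = []
    v = speed_mean
    while arcs[-1] < s1:
        # AR(1) speed fluctuation around the mean, never below the 5 cm/s
        # place-map speed criterion
        v = speed_mean + 0.8 * (v - speed_mean) + rng.normal(0, 0.15 * speed_mean)
        v = float(np.clip(v, 8.0, 2.0 * speed_mean))
        speeds.append(v)
        arcs.append(arcs[-1] + v * dt)
    s = np.array(arcs[:-1])
    speed = np.array(speeds)
    xy = template.position_at(s)
    hd = template.heading_at(s) + rng.normal(0, 0.15, len(s))
    return s, xy, speed, hd


def _rail_samples(vertices: np.ndarray, speed_mean: float, dt: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run along the outer return rail (not part of any journey template)."""
    seg = vertices[1] - vertices[0]
    length = float(np.hypot(*seg))
    n = max(int(round(length / speed_mean / dt)), 1)
    frac = (np.arange(n) + 0.5) / n
    xy = vertices[0][None, :] + frac[:, None] * seg[None, :]
    speed = np.full(n, speed_mean) + rng.normal(0, 2.0, n)
    hd = np.full(n, np.arctan2(seg[1], seg[0])) + rng.normal(0, 0.15, n)
    return xy, speed.clip(8.0, None), hd


# ---------------------------------------------------------------------------
# spike generation


def _poisson_spikes(rates: np.ndarray, t0: float, dt: float,
                    rng: np.random.Generator) -> list[np.ndarray]:
    """Inhomogeneous-Poisson spike times per cell from a (n_samples, n_cells)
    rate array sampled at ``dt`` starting at ``t0``."""
    n_samples, n_cells = rates.shape
    counts = rng.poisson(rates * dt)
    out = []
    for i in range(n_cells):
        c = counts[:, i]
        idx = np.repeat(np.nonzero(c)[0], c[c > 0])
        times = t0 + (idx + rng.random(idx.size)) * dt
        out.append(np.sort(times))
    return out


def _virtual_traversal(ensemble: CellEnsemble, template: JourneyTemplate,
                       subtask: str, run_speed: float, compression: float,
                       rng: np.random.Generator, s0: float = 0.0,
                       s1: Optional[float] = None,
                       dt: float = 1e-3) -> tuple[np.ndarray, np.ndarray, float]:
    """Spikes of a time-compressed virtual run along a journey.

    The event is the running spike process time-scaled by ``compression``:
    the virtual position advances at ``run_speed * compression`` and every
    rate is multiplied by ``compression`` (on top of the subtask gain already
    inside the tuning).  Returns (cell_ids, times-relative-to-onset, duration).
    """
    s1 = template.length if s1 is None else s1
    v = run_speed * compression
    duration = (s1 - s0) / v
    n = max(int(np.ceil(duration / dt)), 1)
    tt = (np.arange(n) + 0.5) * dt
    s = s0 + v * tt
    rates = compression * ensemble.rate(subtask, template.journey, s)
    per_cell = _poisson_spikes(rates, 0.0, dt, rng)
    cells = np.concatenate(
        [np.full(st.size, i, dtype=int) for i, st in enumerate(per_cell)]
    ) if per_cell else np.empty(0, dtype=int)
    times = np.concatenate(per_cell) if per_cell else np.empty(0)
    order = np.argsort(times, kind="mergesort")
    return cells[order], times[order], duration


def _merge_spikes(spikes: dict[int, np.ndarray], cells: np.ndarray,
                  times: np.ndarray) -> None:
    for i in np.unique(cells):
        st = times[cells == i]
        spikes[i] = np.sort(np.concatenate([spikes.get(i, np.empty(0)), st]))


def _dedupe(spikes: dict[int, np.ndarray]) -> None:
    """Enforce strictly increasing spike times (collisions get 0.1 ms nudges)."""
    for c, st in spikes.items():
        if st.size < 2:
            continue
        for _ in range(10):
            d = np.diff(st)
            if np.all(d > 0):
                break
            st[1:][d <= 0] += 1e-4
            st = np.sort(st)
        spikes[c] = st


# ---------------------------------------------------------------------------
# generator


class SessionSimulator:
    """Generates synthetic sessions; holds the ground-truth ensemble."""

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.config = config
        self.templates = make_journey_templates()
        self.rng = np.random.default_rng(config.seed)
        self.ensemble = _make_ensemble(config, self.rng, self.templates)

    # -- public API ---------------------------------------------------------

    def generate(self) -> SessionBundle:
        cfg = self.config
        rng = self.rng
        dt = 1.0 / cfg.behavior_fs_hz

        laps = _journey_sequence(cfg, rng)
        builder = _BehaviorBuilder(cfg.behavior_fs_hz)
        trials: list[TrialRecord] = []
        pauses: list[_Pause] = []
        run_segments: list[tuple[float, float, str, str, np.ndarray]] = []
        # (t0, dt, subtask, journey, arc positions) for rate evaluation
        rail_segments: list[tuple[float, int]] = []

        for lap_idx, (subtask, journey, correct) in enumerate(laps):
            template = self.templates[journey]
            # 1) pause in the start zone before the run
            p_dur = rng.uniform(*cfg.pause_range_s)
            xy, speed, hd = _pause_samples(
                template.points[0], float(template.heading_at(np.array([0.0]))[0]),
                p_dur, dt, rng)
            p0, p1 = builder.add(xy, speed, hd)
            pauses.append(_Pause(p0, p1, subtask, journey, 0.0, "start"))

            # 2) the journey run (DA trials wait at the barrier mid-stem)
            t_start = builder.clock
            if subtask == "DA":
                s_barrier = 60.0  # 20 cm past the stem entrance
                s, xy, speed, hd = _run_samples(template, 0.0, s_barrier,
                                                cfg.run_speed_cm_s, dt, rng)
                t0, _ = builder.add(xy, speed, hd)
                run_segments.append((t0, dt, subtask, journey, s))
                bxy, bspeed, bhd = _pause_samples(
                    template.position_at(np.array([s_barrier - 5.0]))[0],
                    float(template.heading_at(np.array([s_barrier]))[0]),
                    cfg.delay_s, dt, rng)
                d0, d1 = builder.add(bxy, bspeed, bhd)
                pauses.append(_Pause(d0, d1, subtask, journey, s_barrier - 5.0, "stem"))
                s, xy, speed, hd = _run_samples(template, s_barrier, template.length,
                                                cfg.run_speed_cm_s, dt, rng)
                t0, _ = builder.add(xy, speed, hd)
                run_segments.append((t0, dt, subtask, journey, s))
            else:
                s, xy, speed, hd = _run_samples(template, 0.0, template.length,
                                                cfg.run_speed_cm_s, dt, rng)
                t0, _ = builder.add(xy, speed, hd)
                run_segments.append((t0, dt, subtask, journey, s))
            t_end = builder.clock - dt
            trials.append(TrialRecord(lap_idx, subtask, journey, correct,
                                      t_start, t_end))

            # 3) return along the outer rail to the next start zone
            xy, speed, hd = _rail_samples(return_rail(journey[1]),
                                          cfg.run_speed_cm_s, dt, rng)
            r0, _ = builder.add(xy, speed, hd)
            rail_segments.append((r0, len(xy)))

        behavior = builder.frame()

        # -- spikes: running (tuned) + everything else (baseline) ------------
        spikes: dict[int, np.ndarray] = {i: np.empty(0) for i in range(cfg.n_cells)}
        for t0, seg_dt, subtask, journey, s in run_segments:
            rates = self.ensemble.rate(subtask, journey, s)
            per_cell = _poisson_spikes(rates, t0, seg_dt, rng)
            for i, st in enumerate(per_cell):
                if st.size:
                    spikes[i] = np.concatenate([spikes[i], st])
        # baseline firing everywhere outside the tuned run segments
        total = behavior["t"].iloc[-1] + dt
        run_mask = np.zeros(len(behavior), dtype=bool)
        t_all = behavior["t"].to_numpy()
        for t0, seg_dt, *_rest, s in run_segments:
            i0 = int(round(t0 / dt))
            run_mask[i0:i0 + len(s)] = True
        off_idx = np.nonzero(~run_mask)[0]
        if off_idx.size:
            gains_mean = np.mean([self.ensemble.gains[s] for s in SUBTASKS], axis=0)
            base = cfg.baseline_rate_hz * gains_mean
            counts = rng.poisson(np.broadcast_to(base * dt, (off_idx.size, cfg.n_cells)))
            for i in range(cfg.n_cells):
                c = counts[:, i]
                nz = np.nonzero(c)[0]
                if nz.size:
                    idx = np.repeat(off_idx[nz], c[nz])
                    st = t_all[idx] + rng.random(idx.size) * dt
                    spikes[i] = np.concatenate([spikes[i], st])
        for i in range(cfg.n_cells):
            spikes[i] = np.sort(spikes[i])
        _dedupe(spikes)

        bundle = SessionBundle(behavior=behavior, trials=trials, spikes=spikes,
                               lfp=None, ground_truth=[])

        # -- injected replays and null bursts --------------------------------
        # slot length comfortably exceeds the compressed event duration so
        # injected events never spill out of the pause
        slot_len = 0.05 + 10.0 * JOURNEY_SLOT_S / cfg.compression_factor
        for pause in pauses:
            slots = cfg.replay_per_pause + cfg.null_burst_per_pause
            if slots == 0:
                continue
            usable = pause.t_end - pause.t_start - 0.1
            n_fit = min(slots, int(usable / slot_len))
            kinds = (["replay"] * cfg.replay_per_pause
                     + ["null"] * cfg.null_burst_per_pause)[:n_fit]
            for k, kind in enumerate(kinds):
                t0 = pause.t_start + 0.05 + k * slot_len
                if kind == "replay":
                    self.inject_replay(bundle, t0, (pause.subtask, pause.journey),
                                       compression_factor=cfg.compression_factor,
                                       start_arc=pause.arc)
                else:
                    self.make_null_burst(bundle, t0,
                                         trial_type=(pause.subtask, pause.journey),
                                         start_arc=pause.arc)

        if cfg.include_lfp and cfg.peak_rate_hz > 0:
            bundle.lfp = self._synthesize_lfp(bundle, total)
        return bundle

    # -- event injection ----------------------------------------------------

    def _check_injection_site(self, bundle: SessionBundle, t0: float,
                              duration: float) -> None:
        if bundle.speed_at(np.array([t0]))[0] >= 2.0:
            raise ValueError("injection time is not inside an immobility pause")
        for ev in bundle.ground_truth:
            if t0 < ev.t_end and t0 + duration > ev.t_start:
                raise ValueError("injected event overlaps an existing event")

    def inject_replay(self, bundle: SessionBundle, t0: float,
                      trial_type: tuple[str, str], direction: str = "forward",
                      compression_factor: Optional[float] = None,
                      start_arc: float = 0.0) -> SessionBundle:
        """Append a time-compressed forward traversal of one trial type.

        Spike timing is compressed by ``compression_factor`` and rates are
        scaled by ``compression_factor x subtask gain``; the virtual path runs
        forward from ``start_arc`` to the goal.
        """
        if direction != "forward":
            raise ValueError("only forward replays are simulated")
        subtask, journey = trial_type
        cf = self.config.compression_factor if compression_factor is None else float(compression_factor)
        if cf < 1:
            raise ValueError("compression_factor must be >= 1")
        template = self.templates[journey]
        cells, rel_times, duration = _virtual_traversal(
            self.ensemble, template, subtask, self.config.run_speed_cm_s, cf,
            self.rng, s0=start_arc)
        self._check_injection_site(bundle, t0, duration)
        _merge_spikes(bundle.spikes, cells, t0 + rel_times)
        _dedupe(bundle.spikes)
        bundle.ground_truth.append(GroundTruthEvent(
            kind="replay", t_start=t0, t_end=t0 + duration, subtask=subtask,
            journey=journey, cells=tuple(int(c) for c in sorted(np.unique(cells))),
            n_spikes=int(cells.size)))
        return bundle

    def make_null_burst(self, bundle: SessionBundle, t0: float,
                        n_spikes: Optional[int] = None,
                        trial_type: Optional[tuple[str, str]] = None,
                        start_arc: float = 0.0) -> SessionBundle:
        """Append a population burst with the count profile of a replay but no
        sequential structure: cell identities are permuted against times."""
        subtask, journey = trial_type if trial_type is not None else ("VD", "LR")
        template = self.templates[journey]
        cells, rel_times, duration = _virtual_traversal(
            self.ensemble, template, subtask, self.config.run_speed_cm_s,
            self.config.compression_factor, self.rng, s0=start_arc)
        if n_spikes is not None:
            if cells.size == 0:
                raise ValueError("cannot build a null burst with no spikes")
            pick = self.rng.choice(cells.size, size=n_spikes,
                                   replace=n_spikes > cells.size)
            cells, rel_times = cells[pick], rel_times[pick]
            order = np.argsort(rel_times, kind="mergesort")
            cells, rel_times = cells[order], rel_times[order]
        self._check_injection_site(bundle, t0, duration)
        # permute identities against times; forbid the identity permutation
        if len(np.unique(cells)) > 1:
            while True:
                perm = self.rng.permutation(cells.size)
                if not np.array_equal(perm, np.arange(cells.size)):
                    break
            cells = cells[perm]
        _merge_spikes(bundle.spikes, cells, t0 + rel_times)
        _dedupe(bundle.spikes)
        bundle.ground_truth.append(GroundTruthEvent(
            kind="null_burst", t_start=t0, t_end=t0 + duration, subtask=subtask,
            journey=journey, cells=tuple(int(c) for c in sorted(np.unique(cells))),
            n_spikes=int(cells.size)))
        return bundle

    # -- LFP ----------------------------------------------------------------

    def _synthesize_lfp(self, bundle: SessionBundle, duration: float) -> LfpTrace:
        cfg = self.config
        rng = self.rng
        fs = cfg.lfp_fs_hz
        n = int(np.ceil(duration * fs))
        # pink (1/f) background noise, unit variance
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, 1.0 / fs)
        shaping = np.ones_like(freqs)
        shaping[1:] = 1.0 / np.sqrt(freqs[1:])
        spec *= shaping
        x = np.fft.irfft(spec, n)
        x /= x.std()
        t = np.arange(n) / fs
        # theta during running
        speed = bundle.speed_at(t)
        theta = 2.0 * np.sin(2 * np.pi * cfg.theta_hz * t) * (speed > 5.0)
        x = x + theta
        # ripple burst at each injected replay
        for ev in bundle.ground_truth:
            if ev.kind != "replay":
                continue
            mid = 0.5 * (ev.t_start + ev.t_end)
            sd = max((ev.t_end - ev.t_start) / 4.0, 0.01)
            sel = (t > ev.t_start - 2 * sd) & (t < ev.t_end + 2 * sd)
            env = np.exp(-((t[sel] - mid) ** 2) / (2 * sd**2))
            x[sel] += 5.0 * env * np.sin(2 * np.pi * cfg.ripple_hz * t[sel])
        return LfpTrace(samples=x, fs=fs)


def generate_session(config: SimulationConfig) -> SessionBundle:
    """Generate a fully synthetic session (see :class:`SessionSimulator`)."""
    return SessionSimulator(config).generate()
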