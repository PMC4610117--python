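"""Path-replay assembly and dual Monte-Carlo shuffle certification.

Each candidate event is decoded in 20-ms windows advanced in 5-ms steps at
the compressed scale (rates x compression, applied as tau scaling).  The
per-window MAP locations (unimodality-gated) are concatenated into periods
wherever neighboring decoded locations are less than 25 cm apart; an event
whose best period covers more than the distance criterion (default 4 x 25 cm)
is a candidate path.

Certification uses a Monte-Carlo test with two shuffle modes -- cell
identity (permute the cell-to-place-map assignment) and cell place field
(independent circular shift of each cell's map) -- applied to the test
statistic

    S = |weighted corr(window index, decoded location)| x (fraction of
        steps < 25 cm),

with window weights equal to the posterior peak.  Events with p < 0.05 in
both modes are path replays.  Inside the shuffle machinery the per-window
location is the plain posterior argmax for the observed and every shuffled
event alike (the dip gate would multiply the cost a thousandfold and the
comparison remains exchangeable); the gate still applies to path assembly.

The firing compression rate of an event is the ratio of per-cell-pooled
inter-spike intervals outside candidates to those inside (values > 1 mean
compressed firing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoding import BayesianDecoder, PosteriorMatrix, spike_count_matrix
from .events import CandidateEvent
from .placemaps import TrialType
from .session import SessionBundle

REPLAY_WINDOW_S = 0.020
REPLAY_STEP_S = 0.005
CONTINUITY_CM = 25.0
MIN_WINDOWS = 4
DISTANCE_CRITERION_CM = MIN_WINDOWS * CONTINUITY_CM
ALPHA = 0.05
N_SHUFFLES = 5000
#: virtual separation between journey blocks so that a step across blocks
#: can never satisfy the continuity criterion
_BLOCK_GAP = 10.0


@dataclass
class PathReplay:
    """A candidate decoded in sliding windows, with certification state."""

    candidate: CandidateEvent
    posterior: PosteriorMatrix
    map_path: np.ndarray             # (W, 2): block index, arc cm (NaN gated)
    segments: list[tuple[int, int]]  # concatenated window runs [i0, i1)
    total_distance_cm: float         # distance covered by the best period
    is_path: bool
    trial_types: list[TrialType]
    p_cell_identity: float = np.nan
    p_place_field: float = np.nan

    @property
    def n_windows(self) -> int:
        return self.posterior.n_windows

    @property
    def significant(self) -> bool:
        return (self.p_cell_identity < ALPHA) and (self.p_place_field < ALPHA)


def assemble_path(candidate: CandidateEvent, decoder: BayesianDecoder,
                  spikes: dict[int, np.ndarray],
                  trial_types: list[TrialType],
                  compression: float = 10.0,
                  window_s: float = REPLAY_WINDOW_S,
                  step_s: float = REPLAY_STEP_S,
                  continuity_cm: float = CONTINUITY_CM,
                  distance_criterion_cm: float = DISTANCE_CRITERION_CM,
                  gate: bool = True) -> PathReplay:
    """Decode a candidate and assemble its continuous decoded path."""
    t0s = np.arange(candidate.t_start, candidate.t_end - window_s + 1e-9, step_s)
    posterior = decoder.decode(spikes, t0s, window_s, trial_types,
                               compression=compression)
    if t0s.size < MIN_WINDOWS:
        return PathReplay(candidate, posterior,
                          np.full((t0s.size, 2), np.nan), [], 0.0, False,
                          trial_types)
    est = posterior.map_estimates(gate=gate)
    segments, best_dist = _concatenate(est, continuity_cm)
    is_path = best_dist > distance_criterion_cm
    return PathReplay(candidate, posterior, est, segments, best_dist, is_path,
                      trial_types)


def _concatenate(est: np.ndarray, continuity_cm: float
                 ) -> tuple[list[tuple[int, int]], float]:
    """Merge consecutive valid MAP windows into continuous periods.

    Neighboring decoded locations closer than ``continuity_cm`` (and in the
    same journey block) belong to the same period; the covered distance of a
    period is the summed step length.  Returns (periods as [i0, i1) window
    ranges, best period distance).
    """
    valid = np.flatnonzero(~np.isnan(est[:, 0]))
    if valid.size < 2:
        return [], 0.0
    segments = []
    best = 0.0
    run = [valid[0]]
    run_dist = 0.0
    for prev, cur in zip(valid[:-1], valid[1:]):
        same_block = est[prev, 0] == est[cur, 0]
        step = abs(est[cur, 1] - est[prev, 1]) if same_block else np.inf
        if step < continuity_cm:
            run.append(cur)
            run_dist += step
        else:
            segments.append((int(run[0]), int(run[-1]) + 1))
            best = max(best, run_dist)
            run = [cur]
            run_dist = 0.0
    segments.append((int(run[0]), int(run[-1]) + 1))
    best = max(best, run_dist)
    return segments, best


# ---------------------------------------------------------------------------
# shuffle certification


def _flat_positions(argmax_flat: np.ndarray, block_starts: np.ndarray,
                    n_bins: int, bin_width: float) -> np.ndarray:
    """Concatenated-bin argmax -> scalar coordinate with block separation."""
    block = np.searchsorted(block_starts, argmax_flat, side="right") - 1
    arc = (argmax_flat - block_starts[block] + 0.5) * bin_width
    span = n_bins * bin_width
    return block * _BLOCK_GAP * span + arc


def _weighted_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    sw = w.sum()
    if sw <= 0:
        return np.nan
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    cov = (w * (x - mx) * (y - my)).sum()
    vx = (w * (x - mx) ** 2).sum()
    vy = (w * (y - my) ** 2).sum()
    if vx <= 0 or vy <= 0:
        return np.nan
    return float(cov / np.sqrt(vx * vy))


def _path_statistic(loglik: np.ndarray, valid: np.ndarray,
                    block_starts: np.ndarray, n_bins: int, bin_width: float,
                    continuity_cm: float) -> float:
    """S = |weighted time-position correlation| x continuity fraction."""
    if valid.sum() < 3:
        return np.nan
    ll = loglik[valid]
    flat = np.argmax(ll, axis=1)
    # posterior peak weight per window (softmax max)
    mx = ll.max(axis=1)
    w = 1.0 / np.sum(np.exp(ll - mx[:, None]), axis=1)   # posterior peak
    pos = _flat_positions(flat, block_starts, n_bins, bin_width)
    x = np.flatnonzero(valid).astype(float)
    r = _weighted_corr(x, pos, w)
    if not np.isfinite(r):
        return np.nan
    steps = np.abs(np.diff(pos))
    frac = float(np.mean(steps < continuity_cm)) if steps.size else 0.0
    return abs(r) * frac


def shuffle_test(path: PathReplay, decoder: BayesianDecoder,
                 spikes: dict[int, np.ndarray],
                 n_shuffles: int = N_SHUFFLES,
                 seed: int = 0,
                 continuity_cm: float = CONTINUITY_CM,
                 compression: float = 10.0,
                 chunk: int = 64) -> tuple[float, float]:
    """Dual Monte-Carlo shuffle p-values for an assembled path.

    Mode A permutes the cell-to-place-map assignment; mode B circularly
    shifts each cell's map by an independent uniform offset within every
    journey block.  Add-one p-values: p = (1 + #{S_shuffle >= S_obs}) /
    (1 + n_shuffles).  Returns (p_cell_identity, p_place_field); a degenerate
    statistic yields p = 1 for both.
    """
    if n_shuffles < 100:
        import warnings
        warnings.warn("fewer than 100 shuffles; p-values are coarse")
    rng = np.random.default_rng(seed)
    rates, cols, blocks = decoder.block_matrix(path.trial_types)
    f = rates + decoder.rate_floor_hz
    logf = np.log(f)
    tau_eff = path.posterior.tau * compression
    expterm = tau_eff * f.sum(axis=0)
    t0s = path.posterior.t0s
    counts = spike_count_matrix(spikes, decoder.cells, t0s,
                                path.posterior.tau)
    valid = counts.sum(axis=1) > 0
    block_starts = np.array([b[1] for b in blocks])
    n_bins = decoder.maps.n_bins
    bw = decoder.maps.bin_width_cm

    loglik_obs = counts @ logf - expterm[None, :]
    s_obs = _path_statistic(loglik_obs, valid, block_starts, n_bins, bw,
                            continuity_cm)
    if not np.isfinite(s_obs):
        return 1.0, 1.0

    C = counts.shape[1]
    M = logf.shape[1]

    # mode A: cell identity -- permute count columns (sum_i f_i unchanged)
    exceed_a = 0
    for start in range(0, n_shuffles, chunk):
        size = min(chunk, n_shuffles - start)
        perms = np.array([rng.permutation(C) for _ in range(size)])
        cc = counts[:, perms]                      # (W, size, C)
        ll = np.einsum("wsc,cm->swm", cc, logf) - expterm[None, None, :]
        for s in range(size):
            s_sh = _path_statistic(ll[s], valid, block_starts, n_bins, bw,
                                   continuity_cm)
            if np.isfinite(s_sh) and s_sh >= s_obs - 1e-12:
                exceed_a += 1
    p_cell = (1 + exceed_a) / (1 + n_shuffles)

    # mode B: place field -- circular shift of each cell's map per block
    exceed_b = 0
    col_idx = np.arange(M)
    block_bounds = [(b[1], b[2]) for b in blocks]
    for start in range(0, n_shuffles, chunk):
        size = min(chunk, n_shuffles - start)
        for _ in range(size):
            gather = np.empty((C, M), dtype=int)
            for lo, hi in block_bounds:
                nb = hi - lo
                shifts = rng.integers(0, nb, C)
                gather[:, lo:hi] = lo + (col_idx[lo:hi][None, :] - lo
                                         - shifts[:, None]) % nb
            f_sh = np.take_along_axis(f, gather, axis=1)
            ll = counts @ np.log(f_sh) - tau_eff * f_sh.sum(axis=0)[None, :]
            s_sh = _path_statistic(ll, valid, block_starts, n_bins, bw,
                                   continuity_cm)
            if np.isfinite(s_sh) and s_sh >= s_obs - 1e-12:
                exceed_b += 1
    p_field = (1 + exceed_b) / (1 + n_shuffles)
    return float(p_cell), float(p_field)


def certify_paths(candidates: list[CandidateEvent], decoder: BayesianDecoder,
                  bundle: SessionBundle, trial_type_map,
                  n_shuffles: int = N_SHUFFLES, seed: int = 0,
                  compression: float = 10.0,
                  **assemble_kwargs) -> list[PathReplay]:
    """Assemble and shuffle-test every candidate.

    ``trial_type_map`` maps a candidate to the list of trial types whose
    journey maps the decoder should search (e.g. the four journeys under the
    subtask of the surrounding trial).
    """
    rng = np.random.default_rng(seed)
    out = []
    for cand in candidates:
        tts = trial_type_map(cand)
        path = assemble_path(cand, decoder, bundle.spikes, tts,
                             compression=compression, **assemble_kwargs)
        if path.is_path:
            path.p_cell_identity, path.p_place_field = shuffle_test(
                path, decoder, bundle.spikes, n_shuffles=n_shuffles,
                seed=int(rng.integers(2**31)), compression=compression)
        out.append(path)
    return out


# ---------------------------------------------------------------------------
# compression rate


def compression_rate(bundle: SessionBundle,
                     candidates: list[CandidateEvent],
                     statistic: str = "median",
                     min_spikes: int = 2,
                     reference_speed_min: float | None = 5.0) -> pd.DataFrame:
    """Per-event firing compression estimate and session summary.

    For every candidate the per-cell inter-spike intervals whose both spikes
    fall inside the event are pooled; the reference pool holds per-cell ISIs
    with both spikes outside every candidate.  Because a replay is a
    compressed *running* firing pattern, the reference is restricted by
    default to intervals whose spikes both occur above
    ``reference_speed_min`` cm/s (pass None to use the whole rest of the
    session, which mixes in immobility baseline intervals and biases the
    ratio upward).  The event's compression rate is (reference ISI statistic)
    / (event ISI statistic), oriented so that values > 1 indicate temporally
    compressed firing.  ``statistic`` is ``median`` (default; insensitive to
    the long between-pass intervals that dominate a mean) or ``mean``.
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    agg = np.median if statistic == "median" else np.mean
    if not candidates:
        raise ValueError("no candidate events")
    iv = np.array([[c.t_start, c.t_end] for c in candidates])
    iv = iv[np.argsort(iv[:, 0])]

    rest_pool = []
    per_event: list[list[float]] = [[] for _ in candidates]
    starts = iv[:, 0]
    for c in bundle.cells:
        st = bundle.spikes[c]
        if st.size < min_spikes:
            continue
        # event membership of each spike (-1 = outside)
        pos = np.searchsorted(starts, st, side="right") - 1
        inside = np.where((pos >= 0) & (st <= iv[np.clip(pos, 0, None), 1]),
                          pos, -1)
        isi = np.diff(st)
        same = inside[:-1] == inside[1:]
        rest = (inside[:-1] == -1) & (inside[1:] == -1)
        if reference_speed_min is not None:
            v = bundle.speed_at(st)
            rest &= (v[:-1] > reference_speed_min) & (v[1:] > reference_speed_min)
        rest_pool.append(isi[rest])
        ev = same & (inside[:-1] >= 0)
        for e, d in zip(inside[:-1][ev], isi[ev]):
            per_event[int(e)].append(float(d))
    rest_isi = np.concatenate(rest_pool) if rest_pool else np.empty(0)
    if rest_isi.size == 0:
        raise ValueError("no reference inter-spike intervals")
    ref = float(agg(rest_isi))

    rows = []
    order = np.argsort([c.t_start for c in candidates])
    for rank, k in enumerate(order):
        isis = per_event[rank]
        if len(isis) < 1:
            continue
        rows.append({
            "t_start": candidates[k].t_start,
            "t_end": candidates[k].t_end,
            "n_isi": len(isis),
            "event_isi_s": float(agg(isis)),
            "compression": ref / float(agg(isis)),
        })
    return pd.DataFrame(rows)


def replay_table(paths: list[PathReplay]) -> pd.DataFrame:
    return pd.DataFrame({
        "t_start": [p.candidate.t_start for p in paths],
        "t_end": [p.candidate.t_end for p in paths],
        "n_windows": [p.n_windows for p in paths],
        "distance_cm": [p.total_distance_cm for p in paths],
        "is_path": [p.is_path for p in paths],
        "p_cell": [p.p_cell_identity for p in paths],
        "p_field": [p.p_place_field for p in paths],
        "significant": [p.significant for p in paths],
    })
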