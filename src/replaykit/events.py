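"""LFP and population-burst event detection.

Sharp-wave/ripple (SWR) events are local peaks of the 150-250 Hz Hilbert
envelope exceeding mean + 3 SD, extended to the surrounding mean crossings,
and kept only while the animal is immobile (< 2 cm/s).  Theta power is the
z-scored 4-12 Hz band power.  Candidate replay events are periods where the
Gaussian-smoothed (SD 10 ms) population spike rate stays above its mean and
peaks above mean + 3 SD during immobility, trimmed to the tightest window
still satisfying the participation constraints: at least 10% of all cells
with at least two spikes each, and a duration of at least 30 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, hilbert

from .session import LfpTrace, SessionBundle

RIPPLE_BAND_HZ = (150.0, 250.0)
THETA_BAND_HZ = (4.0, 12.0)
IMMOBILITY_SPEED = 2.0
POP_KERNEL_SD_S = 0.010
MIN_EVENT_DURATION_S = 0.030
MIN_CELL_FRACTION = 0.10
MIN_SPIKES_PER_CELL = 2


@dataclass(frozen=True)
class SwrEvent:
    t_start: float
    t_end: float
    t_peak: float
    peak_sd: float          # envelope peak in SD units above the mean


@dataclass
class CandidateEvent:
    """A population-burst candidate replay."""

    t_start: float
    t_end: float
    cells: tuple[int, ...]          # members with >= 2 spikes
    n_spikes: int
    peak_sd: float                  # smoothed population activity peak (SD)
    swr_coincident: bool = False

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def bandpass(samples: np.ndarray, fs: float, band: tuple[float, float],
             order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    nyq = fs / 2.0
    lo, hi = band
    if hi >= nyq:
        raise ValueError(f"band {band} exceeds Nyquist {nyq}")
    b, a = butter(order, [lo / nyq, hi / nyq], btype="band")
    return filtfilt(b, a, samples)


def ripple_envelope(lfp: LfpTrace) -> np.ndarray:
    """Analytic amplitude of the ripple-band (150-250 Hz) signal."""
    if lfp.fs <= 500:
        raise ValueError("sampling rate too low for ripple detection")
    filt = bandpass(lfp.samples, lfp.fs, RIPPLE_BAND_HZ)
    return np.abs(hilbert(filt))


def detect_swr(lfp: LfpTrace, speed_t: np.ndarray, speed: np.ndarray,
               threshold_sd: float = 3.0,
               immobility_speed: float = IMMOBILITY_SPEED) -> list[SwrEvent]:
    """Detect SWRs on the ripple envelope, gated to immobility.

    Peaks above ``mean + threshold_sd * SD`` of the envelope are extended to
    the nearest mean crossings; an event is kept only if the running speed at
    its peak is below ``immobility_speed``.
    """
    env = ripple_envelope(lfp)
    if np.ptp(env) == 0:
        return []
    mu, sd = env.mean(), env.std()
    if sd == 0:
        return []
    thr = mu + threshold_sd * sd
    above = env > thr
    if not above.any():
        return []
    t = lfp.times
    # contiguous supra-threshold runs -> one event each, extended to the mean
    runs = _runs(above)
    below_mean = env <= mu
    events: list[SwrEvent] = []
    last_end = -1
    for i0, i1 in runs:
        ipk = i0 + int(np.argmax(env[i0:i1]))
        # extend to mean crossings
        left = np.flatnonzero(below_mean[:i0 + 1])
        j0 = int(left[-1]) + 1 if left.size else 0
        right = np.flatnonzero(below_mean[i1:])
        j1 = i1 + int(right[0]) if right.size else env.size
        if j0 <= last_end:        # merged with the previous event
            continue
        v = np.interp(t[ipk], speed_t, speed)
        if v >= immobility_speed:
            continue
        events.append(SwrEvent(t_start=float(t[j0]), t_end=float(t[min(j1, env.size - 1)]),
                               t_peak=float(t[ipk]),
                               peak_sd=float((env[ipk] - mu) / sd)))
        last_end = j1
    return events


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of contiguous True runs."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def theta_power(lfp: LfpTrace, intervals: list[tuple[float, float]]
                ) -> np.ndarray:
    """Z-scored theta-band (4-12 Hz) power averaged per interval.

    The band power (squared Hilbert envelope) is z-scored against the whole
    trace before averaging within each interval.
    """
    filt = bandpass(lfp.samples, lfp.fs, THETA_BAND_HZ)
    power = np.abs(hilbert(filt)) ** 2
    z = (power - power.mean()) / power.std()
    t = lfp.times
    out = np.empty(len(intervals))
    for k, (a, b) in enumerate(intervals):
        i0, i1 = np.searchsorted(t, [a, b])
        if i1 <= i0:
            raise ValueError(f"interval ({a}, {b}) outside the LFP trace")
        out[k] = z[i0:i1].mean()
    return out


def population_activity(bundle: SessionBundle, dt: float = 0.001,
                        kernel_sd_s: float = POP_KERNEL_SD_S,
                        cells: list[int] | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-smoothed population spike rate on a uniform grid.

    Returns (grid times, smoothed rate in spikes/s summed over cells).
    """
    from scipy.ndimage import gaussian_filter1d

    cells = bundle.cells if cells is None else list(cells)
    lo, hi = bundle.span
    n = int(np.ceil((hi - lo) / dt)) + 1
    counts = np.zeros(n)
    for c in cells:
        st = bundle.spikes[c]
        idx = ((st - lo) / dt).astype(int)
        idx = idx[(idx >= 0) & (idx < n)]
        np.add.at(counts, idx, 1.0)
    rate = gaussian_filter1d(counts / dt, kernel_sd_s / dt, mode="constant")
    return lo + np.arange(n) * dt, rate


def detect_candidates(bundle: SessionBundle,
                      cells: list[int] | None = None,
                      threshold_sd: float = 3.0,
                      immobility_speed: float = IMMOBILITY_SPEED,
                      min_duration: float = MIN_EVENT_DURATION_S,
                      min_cell_fraction: float = MIN_CELL_FRACTION,
                      min_spikes: int = MIN_SPIKES_PER_CELL,
                      dt: float = 0.001) -> list[CandidateEvent]:
    """Detect candidate replay events from population spiking.

    The mean and SD of the smoothed population activity are computed over
    immobility periods only, so running-rate elevation does not contaminate
    the burst threshold.  Supra-mean periods containing a > mean + 3 SD peak
    are trimmed inward to the tightest window still satisfying the
    participation, per-cell spike count and duration constraints.
    """
    cells = bundle.cells if cells is None else list(cells)
    if len(cells) < 2:
        raise ValueError("need at least two cells")
    t, rate = population_activity(bundle, dt=dt, cells=cells)
    speed = bundle.speed_at(t)
    immobile = speed < immobility_speed
    if not immobile.any():
        return []
    mu = rate[immobile].mean()
    sd = rate[immobile].std()
    if sd == 0:
        return []
    thr = mu + threshold_sd * sd
    min_cells = max(int(np.ceil(min_cell_fraction * len(cells))), 1)

    events: list[CandidateEvent] = []
    for i0, i1 in _runs((rate > mu) & immobile):
        if rate[i0:i1].max() <= thr:
            continue
        window = (float(t[i0]), float(t[min(i1, t.size - 1)]))
        trimmed = _trim_candidate(bundle, cells, window, min_cells,
                                  min_spikes, min_duration)
        if trimmed is None:
            continue
        t_start, t_end, members, n_spk = trimmed
        peak_sd = float((rate[i0:i1].max() - mu) / sd)
        events.append(CandidateEvent(t_start=t_start, t_end=t_end,
                                     cells=members, n_spikes=n_spk,
                                     peak_sd=peak_sd))
    return events


def _trim_candidate(bundle: SessionBundle, cells: list[int],
                    window: tuple[float, float], min_cells: int,
                    min_spikes: int, min_duration: float
                    ) -> tuple[float, float, tuple[int, ...], int] | None:
    """Reduce a supra-mean period to the span of its participating cells.

    Member cells are those with at least ``min_spikes`` spikes inside the
    period; the event boundaries shrink to the first and last member spike,
    dropping the low-activity flanks of the smoothed-rate excursion.  The
    event is rejected when fewer than ``min_cells`` members remain or the
    reduced duration falls below ``min_duration``.  (Shrinking further to the
    literally smallest window still meeting the constraints would cut most
    of a burst away and defeat the downstream path-distance criterion.)
    """
    a, b = window
    times, owners = [], []
    for c in cells:
        st = bundle.spikes[c]
        sel = st[(st >= a) & (st <= b)]
        times.append(sel)
        owners.append(np.full(sel.size, c))
    if not times:
        return None
    tt = np.concatenate(times)
    oo = np.concatenate(owners)
    order = np.argsort(tt, kind="mergesort")
    tt, oo = tt[order], oo[order]
    if tt.size < 2:
        return None
    uniq, counts = np.unique(oo, return_counts=True)
    members = uniq[counts >= min_spikes]
    if members.size < min_cells:
        return None
    member_mask = np.isin(oo, members)
    tt_m = tt[member_mask]
    t_start, t_end = float(tt_m[0]), float(tt_m[-1])
    if t_end - t_start < min_duration:
        return None
    inside = (tt >= t_start) & (tt <= t_end)
    pad = 1e-4               # keep the boundary spikes inside the window
    return (t_start - pad, t_end + pad,
            tuple(int(c) for c in members), int(inside.sum()))


def flag_swr_coincidence(candidates: list[CandidateEvent],
                         swrs: list[SwrEvent]) -> None:
    """Mark candidates that overlap any SWR event (in place)."""
    for ev in candidates:
        ev.swr_coincident = any(
            ev.t_start < s.t_end and ev.t_end > s.t_start for s in swrs)


def events_frame(candidates: list[CandidateEvent]) -> pd.DataFrame:
    return pd.DataFrame({
        "start_s": [e.t_start for e in candidates],
        "end_s": [e.t_end for e in candidates],
        "n_cells": [len(e.cells) for e in candidates],
        "n_spikes": [e.n_spikes for e in candidates],
        "peak_sd": [e.peak_sd for e in candidates],
        "swr_flag": [e.swr_coincident for e in candidates],
    })
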