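"""Linearized place maps, spatial information, and place-cell screening.

For every trial type (subtask x journey), each cell's one-dimensional firing
rate map is built on 2-cm bins of the linearized journey coordinate: spike
counts and occupancy are accumulated from running samples (speed > 5 cm/s,
which also removes the DA barrier waiting period), both are smoothed with a
3-cm-SD Gaussian kernel, and the smoothed counts are divided by the smoothed
occupancy.  Trials of the same type are pooled across blocks.

Screening keeps putative principal cells (session mean rate in
[0.1, 5) Hz) that carry spatial information above 0.3 bits/spike
(Skaggs-McNaughton per-spike information) and whose windowed firing rate
differs between trial types after adjusting for running speed, head
direction and x/y position (ANCOVA-style F-test, p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .maze import JourneyTemplate, linearize
from .session import SessionBundle

TrialType = tuple[str, str]

DEFAULT_BIN_CM = 2.0
DEFAULT_KERNEL_SD_CM = 3.0
DEFAULT_SPEED_MIN = 5.0


@dataclass
class PlaceMapSet:
    """Per-cell, per-trial-type linearized rate maps with occupancy.

    ``rates[tt]`` is an (n_cells, n_bins) array of firing rates (Hz) on
    half-open bins [k*w, (k+1)*w) cm; ``occupancy[tt]`` holds smoothed
    occupancy seconds per bin and ``visited[tt]`` flags bins with nonzero raw
    occupancy (unvisited bins carry rate 0 and are masked from decoding).
    """

    bin_width_cm: float
    kernel_sd_cm: float
    n_bins: int
    cells: list[int]
    rates: dict[TrialType, np.ndarray]
    occupancy: dict[TrialType, np.ndarray]
    visited: dict[TrialType, np.ndarray]
    mean_rates: dict[int, float] = field(default_factory=dict)

    @property
    def trial_types(self) -> list[TrialType]:
        return sorted(self.rates)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_index(self, cells: list[int] | None = None) -> np.ndarray:
        sel = self.cells if cells is None else cells
        lookup = {c: i for i, c in enumerate(self.cells)}
        return np.array([lookup[c] for c in sel], dtype=int)

    def rate_matrix(self, trial_type: TrialType,
                    cells: list[int] | None = None) -> np.ndarray:
        """(n_selected_cells, n_bins) rate matrix for one trial type."""
        return self.rates[trial_type][self.cell_index(cells)]

    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_cm

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tt in self.trial_types:
            sub, jour = tt
            occ = self.occupancy[tt]
            for ci, cell in enumerate(self.cells):
                rows.append(pd.DataFrame({
                    "cell": cell,
                    "subtask": sub,
                    "journey": jour,
                    "bin": np.arange(self.n_bins),
                    "rate_hz": self.rates[tt][ci],
                    "occupancy_s": occ,
                }))
        return pd.concat(rows, ignore_index=True)


def _trial_samples(bundle: SessionBundle, speed_min: float) -> pd.DataFrame:
    """Behavior samples inside trials with speed above threshold, labeled."""
    b = bundle.behavior
    t = b["t"].to_numpy()
    frames = []
    for tr in bundle.trials:
        sel = (t >= tr.t_start) & (t <= tr.t_end) & (b["speed"].to_numpy() > speed_min)
        if not sel.any():
            continue
        f = b.loc[sel, ["t", "x", "y", "speed", "head_direction"]].copy()
        f["trial_index"] = tr.index
        f["subtask"] = tr.subtask
        f["journey"] = tr.journey
        frames.append(f)
    if not frames:
        return pd.DataFrame(columns=["t", "x", "y", "speed", "head_direction",
                                     "trial_index", "subtask", "journey"])
    return pd.concat(frames, ignore_index=True)


def build_place_maps(bundle: SessionBundle,
                     templates: dict[str, JourneyTemplate],
                     bin_width_cm: float = DEFAULT_BIN_CM,
                     kernel_sd_cm: float = DEFAULT_KERNEL_SD_CM,
                     speed_min: float = DEFAULT_SPEED_MIN,
                     cells: list[int] | None = None) -> PlaceMapSet:
    """Build the full set of trial-type place maps for a session."""
    cells = bundle.cells if cells is None else list(cells)
    length = max(tpl.length for tpl in templates.values())
    n_bins = int(np.ceil(length / bin_width_cm))
    sigma_bins = kernel_sd_cm / bin_width_cm
    dt = float(np.median(np.diff(bundle.behavior["t"].to_numpy())))

    samples = _trial_samples(bundle, speed_min)
    rates: dict[TrialType, np.ndarray] = {}
    occupancy: dict[TrialType, np.ndarray] = {}
    visited: dict[TrialType, np.ndarray] = {}

    for (sub, jour), grp in samples.groupby(["subtask", "journey"], sort=True):
        template = templates[jour]
        arc = linearize(grp[["x", "y"]].to_numpy(), template)
        bins = np.clip((arc / bin_width_cm).astype(int), 0, n_bins - 1)
        occ_raw = np.bincount(bins, minlength=n_bins) * dt
        occ = gaussian_filter1d(occ_raw.astype(float), sigma_bins, mode="reflect")
        counts = np.zeros((len(cells), n_bins))
        grp_t = grp["t"].to_numpy()
        trial_ids = grp["trial_index"].to_numpy()
        # spikes are kept when the nearest retained (running, in-trial)
        # behavior sample is within one sampling step
        for ci, cell in enumerate(cells):
            st = bundle.spikes[cell]
            for tr_idx in np.unique(trial_ids):
                m = trial_ids == tr_idx
                tt_tr = grp_t[m]
                sel = st[(st >= tt_tr[0]) & (st <= tt_tr[-1])]
                if sel.size == 0:
                    continue
                nearest = np.searchsorted(tt_tr, sel)
                nearest = np.clip(nearest, 0, tt_tr.size - 1)
                prev = np.clip(nearest - 1, 0, tt_tr.size - 1)
                use_prev = np.abs(sel - tt_tr[prev]) < np.abs(sel - tt_tr[nearest])
                nearest[use_prev] = prev[use_prev]
                ok = np.abs(sel - tt_tr[nearest]) <= 1.5 * dt
                sb = bins[np.nonzero(m)[0][nearest[ok]]]
                np.add.at(counts[ci], sb, 1.0)
        smoothed = gaussian_filter1d(counts, sigma_bins, axis=1, mode="reflect")
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(occ > 1e-12, smoothed / occ, 0.0)
        vis = occ_raw > 0
        r[:, ~vis] = 0.0
        rates[(sub, jour)] = r
        occupancy[(sub, jour)] = occ
        visited[(sub, jour)] = vis

    return PlaceMapSet(
        bin_width_cm=bin_width_cm,
        kernel_sd_cm=kernel_sd_cm,
        n_bins=n_bins,
        cells=cells,
        rates=rates,
        occupancy=occupancy,
        visited=visited,
        mean_rates=bundle.session_mean_rates(),
    )


def journey_maps(maps: PlaceMapSet) -> PlaceMapSet:
    """Pool trial-type maps of the same journey across subtasks.

    Occupancy-weighted pooling reproduces the map that would be built from
    the union of the subtasks' trials.  Keys of the result are
    ``("ALL", journey)``.  Used for location decoding when the subtask should
    not split the posterior into duplicate journey blocks.
    """
    journeys = sorted({tt[1] for tt in maps.trial_types})
    rates, occupancy, visited = {}, {}, {}
    for j in journeys:
        tts = [tt for tt in maps.trial_types if tt[1] == j]
        occ = np.sum([maps.occupancy[tt] for tt in tts], axis=0)
        num = np.sum([maps.rates[tt] * maps.occupancy[tt][None, :]
                      for tt in tts], axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(occ > 1e-12, num / occ, 0.0)
        rates[("ALL", j)] = r
        occupancy[("ALL", j)] = occ
        visited[("ALL", j)] = np.any([maps.visited[tt] for tt in tts], axis=0)
    return PlaceMapSet(bin_width_cm=maps.bin_width_cm,
                       kernel_sd_cm=maps.kernel_sd_cm, n_bins=maps.n_bins,
                       cells=maps.cells, rates=rates, occupancy=occupancy,
                       visited=visited, mean_rates=dict(maps.mean_rates))


def spatial_information(rate_map: np.ndarray, occupancy: np.ndarray) -> float:
    """Skaggs-McNaughton per-spike spatial information (bits/spike).

    ``sum_k p_k (f_k / F) log2(f_k / F)`` with ``p_k`` the occupancy share
    and ``F`` the occupancy-weighted mean rate.  Raises on zero mean rate.
    """
    f = np.asarray(rate_map, dtype=float)
    occ = np.asarray(occupancy, dtype=float)
    tot = occ.sum()
    if tot <= 0:
        raise ValueError("occupancy is empty")
    p = occ / tot
    F = float(np.dot(p, f))
    if F <= 0:
        raise ValueError("insufficient activity: zero mean rate")
    ratio = f / F
    terms = np.where(ratio > 0, p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return float(terms.sum())


def windowed_rates(bundle: SessionBundle,
                   templates: dict[str, JourneyTemplate],
                   window_s: float = 0.25,
                   speed_min: float = DEFAULT_SPEED_MIN,
                   cells: list[int] | None = None
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Non-overlapping running windows within trials.

    Returns a window table (t0, trial_index, subtask, journey, arc, speed,
    head_direction, x, y at the window center) and an (n_windows, n_cells)
    matrix of firing rates (Hz).  Windows are half-open [t, t + window_s) and
    kept only when the center sample is running.
    """
    cells = bundle.cells if cells is None else list(cells)
    rows = []
    starts = []
    for tr in bundle.trials:
        t0s = np.arange(tr.t_start, tr.t_end - window_s + 1e-9, window_s)
        if t0s.size == 0:
            continue
        centers = t0s + window_s / 2
        speed = bundle.speed_at(centers)
        keep = speed > speed_min
        if not keep.any():
            continue
        xy = bundle.position_at(centers[keep])
        arc = linearize(xy, templates[tr.journey])
        hd = np.interp(centers[keep], bundle.behavior["t"].to_numpy(),
                       bundle.behavior["head_direction"].to_numpy())
        for k, (t0, a) in enumerate(zip(t0s[keep], arc)):
            rows.append((t0, tr.index, tr.subtask, tr.journey, a,
                         speed[keep][k], hd[k], xy[k, 0], xy[k, 1]))
        starts.extend(t0s[keep])
    table = pd.DataFrame(rows, columns=["t0", "trial_index", "subtask", "journey",
                                        "arc", "speed", "head_direction", "x", "y"])
    starts = np.asarray(starts)
    counts = np.zeros((len(starts), len(cells)))
    for ci, cell in enumerate(cells):
        st = bundle.spikes[cell]
        counts[:, ci] = np.searchsorted(st, starts + window_s) - np.searchsorted(st, starts)
    return table, counts / window_s


def screen_place_cells(bundle: SessionBundle,
                       maps: PlaceMapSet,
                       templates: dict[str, JourneyTemplate],
                       si_threshold: float = 0.3,
                       alpha: float = 0.05,
                       min_mean_rate: float = 0.1,
                       max_mean_rate: float = 5.0,
                       window_s: float = 0.25) -> list[int]:
    """Select place cells for the decoding analyses.

    A cell is kept when (a) its session mean rate lies in
    ``[min_mean_rate, max_mean_rate)`` Hz (putative principal cell), (b) its
    best trial-type map carries more than ``si_threshold`` bits/spike of
    spatial information, and (c) its windowed firing rate shows a trial-type
    effect (F-test, p < ``alpha``) after adjusting for speed, head direction
    (sine/cosine) and x/y position.
    """
    table, rate_mat = windowed_rates(bundle, templates, window_s=window_s)
    if len(table) == 0:
        import warnings
        warnings.warn("no running windows; screening returns no cells")
        return []
    # covariate design (shared across cells)
    tt_labels = (table["subtask"] + "_" + table["journey"]).to_numpy()
    tt_codes, _ = pd.factorize(tt_labels)
    n_types = tt_codes.max() + 1
    dummies = np.eye(n_types)[tt_codes][:, 1:]       # reference-coded factor
    covars = np.column_stack([
        table["speed"].to_numpy(),
        np.sin(table["head_direction"].to_numpy()),
        np.cos(table["head_direction"].to_numpy()),
        table["x"].to_numpy(),
        table["y"].to_numpy(),
    ])
    ones = np.ones((len(table), 1))
    X_full = np.column_stack([ones, dummies, covars])
    X_red = np.column_stack([ones, covars])
    df1 = dummies.shape[1]
    df2 = len(table) - X_full.shape[1]

    selected = []
    cell_lookup = {c: i for i, c in enumerate(bundle.cells)}
    for cell in maps.cells:
        mean_rate = maps.mean_rates[cell]
        if not (min_mean_rate <= mean_rate < max_mean_rate):
            continue
        ci = maps.cell_index([cell])[0]
        si = 0.0
        for tt in maps.trial_types:
            try:
                si = max(si, spatial_information(maps.rates[tt][ci],
                                                 maps.occupancy[tt]))
            except ValueError:
                continue
        if si <= si_threshold:
            continue
        y = rate_mat[:, cell_lookup[cell]]
        rss_full = _rss(X_full, y)
        rss_red = _rss(X_red, y)
        if rss_full <= 0 or df2 <= 0:
            continue
        F = ((rss_red - rss_full) / df1) / (rss_full / df2)
        p = stats.f.sf(F, df1, df2)
        if p < alpha:
            selected.append(cell)
    if not selected:
        import warnings
        warnings.warn("no cells passed place-cell screening")
    return selected


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)
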