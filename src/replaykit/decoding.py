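"""Memoryless Bayesian position decoding and simple spatial reconstruction.

For a time window of duration tau with spike counts ``n_i`` and place maps
``f_i`` (Hz per linearized bin), the posterior over location bins is

    Prob(Pos | spikes) = (prod_i f_i(Pos)^{n_i}) * exp(-tau * sum_i f_i(Pos))

normalized over all bins (``nProb``).  Candidate journeys are concatenated as
disjoint bin blocks, so a decoded location is a (trial type, arc position)
pair.  During replay decoding the rates are effectively scaled by the
compression factor; since the product term only changes by a bin-independent
constant, the scaling is applied to tau inside the exponential, which is
mathematically identical after normalization.

A point estimate (MAP) is issued only when the posterior row passes the
unimodality gate (Hartigan's dip test, Monte-Carlo calibrated); ties break
toward the smallest bin index.  The simple spatial reconstruction algorithm
is the linear alternative: ``Rp = sum_i n_i f_i``, with the location estimate
at the argmax of Rp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from ._dip import dip_pvalue
from .placemaps import PlaceMapSet, TrialType

DEFAULT_RATE_FLOOR_HZ = 0.01
DIP_ALPHA = 0.05
DIP_SAMPLE = 32


def spike_count_matrix(spikes: dict[int, np.ndarray], cells: list[int],
                       t0s: np.ndarray, tau: float) -> np.ndarray:
    """Spike counts per half-open window [t0, t0 + tau), shape (W, C)."""
    t0s = np.asarray(t0s, dtype=float)
    counts = np.empty((t0s.size, len(cells)))
    for ci, cell in enumerate(cells):
        st = spikes[cell]
        counts[:, ci] = (np.searchsorted(st, t0s + tau, side="left")
                         - np.searchsorted(st, t0s, side="left"))
    return counts


@dataclass
class PosteriorMatrix:
    """Normalized posterior rows over concatenated journey bin blocks."""

    t0s: np.ndarray                      # window starts (s)
    tau: float                           # window duration (s)
    nprob: np.ndarray                    # (W, M), each row sums to 1
    blocks: list[tuple[TrialType, int, int]]  # (trial type, start, stop) bins
    bin_width_cm: float
    uniform: np.ndarray                  # rows flagged all-zero-likelihood

    @property
    def n_windows(self) -> int:
        return self.nprob.shape[0]

    @property
    def n_bins(self) -> int:
        return self.nprob.shape[1]

    def block_of(self, flat_bin: int) -> tuple[TrialType, int]:
        """(trial type, within-block bin) of a concatenated bin index."""
        for tt, start, stop in self.blocks:
            if start <= flat_bin < stop:
                return tt, flat_bin - start
        raise IndexError(flat_bin)

    def map_estimates(self, alpha: float = DIP_ALPHA,
                      gate: bool = True,
                      dip_m: int = DIP_SAMPLE) -> np.ndarray:
        """Per-window MAP as (block index, arc cm) pairs; NaN when gated out.

        Returns an (W, 2) array: column 0 the block index, column 1 the arc
        position (bin center, cm).  Windows failing the unimodality gate or
        flagged uniform carry NaN.
        """
        out = np.full((self.n_windows, 2), np.nan)
        starts = np.array([b[1] for b in self.blocks])
        for w in range(self.n_windows):
            if self.uniform[w]:
                continue
            row = self.nprob[w]
            if gate and dip_pvalue(row, m=dip_m) < alpha:
                continue
            flat = int(np.argmax(row))
            b = int(np.searchsorted(starts, flat, side="right") - 1)
            out[w, 0] = b
            out[w, 1] = (flat - self.blocks[b][1] + 0.5) * self.bin_width_cm
        return out


class BayesianDecoder:
    """Memoryless Bayesian decoder over a set of trial-type place maps."""

    def __init__(self, maps: PlaceMapSet, cells: list[int] | None = None,
                 rate_floor_hz: float = DEFAULT_RATE_FLOOR_HZ):
        self.maps = maps
        self.cells = maps.cells if cells is None else list(cells)
        self.rate_floor_hz = rate_floor_hz

    def block_matrix(self, trial_types: list[TrialType]
                     ) -> tuple[np.ndarray, np.ndarray, list[tuple[TrialType, int, int]]]:
        """Concatenate visited bins of the requested trial types.

        Returns (rates (C, M), flat visited mask per concatenated bin index
        into the original per-type bins, blocks).  Unvisited bins are dropped
        from the decode and never appear in the posterior.
        """
        mats, blocks, cols = [], [], []
        offset = 0
        for tt in trial_types:
            r = self.maps.rate_matrix(tt, self.cells)
            vis = self.maps.visited[tt]
            mats.append(r[:, vis])
            cols.append(np.nonzero(vis)[0])
            n_vis = int(vis.sum())
            blocks.append((tt, offset, offset + n_vis))
            offset += n_vis
        return np.concatenate(mats, axis=1), cols, blocks

    def decode(self, spikes: dict[int, np.ndarray], t0s: np.ndarray,
               tau: float, trial_types: list[TrialType],
               compression: float = 1.0) -> PosteriorMatrix:
        counts = spike_count_matrix(spikes, self.cells, np.asarray(t0s), tau)
        return self.decode_counts(counts, np.asarray(t0s, dtype=float), tau,
                                  trial_types, compression)

    def decode_counts(self, counts: np.ndarray, t0s: np.ndarray, tau: float,
                      trial_types: list[TrialType],
                      compression: float = 1.0) -> PosteriorMatrix:
        rates, cols, blocks = self.block_matrix(trial_types)
        nprob, uniform = decode_posterior(counts, rates, tau * compression,
                                          self.rate_floor_hz)
        # re-expand dropped (unvisited) bins as zero-probability columns so
        # bin indices align with the map grid
        full_blocks, mats = [], []
        offset = 0
        for (tt, start, stop), c in zip(blocks, cols):
            block = np.zeros((nprob.shape[0], self.maps.n_bins))
            block[:, c] = nprob[:, start:stop]
            mats.append(block)
            full_blocks.append((tt, offset, offset + self.maps.n_bins))
            offset += self.maps.n_bins
        return PosteriorMatrix(t0s=t0s, tau=tau,
                               nprob=np.concatenate(mats, axis=1),
                               blocks=full_blocks,
                               bin_width_cm=self.maps.bin_width_cm,
                               uniform=uniform)


def decode_posterior(counts: np.ndarray, rates: np.ndarray, tau: float,
                     rate_floor_hz: float = DEFAULT_RATE_FLOOR_HZ
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized posterior rows for count windows against a rate matrix.

    ``counts`` is (W, C), ``rates`` (C, M).  Returns (nprob (W, M), uniform
    flags).  A rate floor is added inside the likelihood to avoid
    zero-probability annihilation; rows with no finite likelihood fall back
    to uniform and are flagged.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    f = np.asarray(rates, dtype=float) + rate_floor_hz
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = np.log(f)        # -inf for truly zero rates (no floor)
        loglik = counts @ logf - tau * f.sum(axis=0)[None, :]
    bad = ~np.isfinite(loglik).any(axis=1)
    norm = logsumexp(loglik, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        nprob = np.exp(loglik - norm)
    M = nprob.shape[1]
    uniform = bad | ~np.isfinite(nprob).all(axis=1)
    nprob[uniform] = 1.0 / M
    return nprob, uniform


def map_estimate(row: np.ndarray, alpha: float = DIP_ALPHA,
                 dip_m: int = DIP_SAMPLE) -> int | None:
    """Unimodality-gated MAP bin of a single normalized posterior row.

    Returns the argmax bin (ties to the smallest index) when the dip test
    does not reject unimodality at ``alpha``; otherwise None.
    """
    row = np.asarray(row, dtype=float)
    if row.sum() <= 0 or not np.isfinite(row).all():
        return None
    if dip_pvalue(row, m=dip_m) < alpha:
        return None
    return int(np.argmax(row))


@dataclass
class PlacePreference:
    """Spike-weighted sum of place maps (simple spatial reconstruction)."""

    rp: np.ndarray                       # (M,) Hz * spikes
    blocks: list[tuple[TrialType, int, int]]
    bin_width_cm: float

    @property
    def estimate(self) -> int | None:
        if not np.any(self.rp > 0):
            return None
        return int(np.argmax(self.rp))


def reconstruct_place_preference(counts: np.ndarray, maps: PlaceMapSet,
                                 trial_types: list[TrialType],
                                 cells: list[int] | None = None) -> PlacePreference:
    """``Rp = sum_i n_i f_i`` over the concatenated journey blocks."""
    cells = maps.cells if cells is None else list(cells)
    counts = np.asarray(counts, dtype=float).ravel()
    mats, blocks = [], []
    offset = 0
    for tt in trial_types:
        r = maps.rate_matrix(tt, cells)
        mats.append(counts @ r)
        blocks.append((tt, offset, offset + maps.n_bins))
        offset += maps.n_bins
    return PlacePreference(rp=np.concatenate(mats), blocks=blocks,
                           bin_width_cm=maps.bin_width_cm)
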