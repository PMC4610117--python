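"""Firing-rate-based trial-type prediction and episodic replay detection.

Trial type (journey x subtask) is predicted from a binary population vector
C: a cell is "high" in a time window when its firing rate there exceeds its
whole-session mean rate, "low" otherwise (strictly; a tie is low).  Eight
reference vectors R -- one per trial type -- store, for every linearized
location bin, each cell's probability of being high, estimated from 200-ms
running windows with a pseudocount:  R = (n_high + alpha) / (n + 2 alpha).
A window at decoded location p is assigned the trial type maximizing

    Prob(C | t) = prod_i Prob_i(c_i | t, p)

evaluated in log space; ties break in canonical trial-type order.

A significant path replay is *episodic* when the summed probability of its
modal predicted trial type beats both Monte-Carlo nulls: cell-identity
permutation and permutation of decoded locations across windows (p < 0.05
each).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoding import BayesianDecoder, spike_count_matrix
from .maze import JourneyTemplate
from .placemaps import PlaceMapSet, TrialType, journey_maps
from .replay import PathReplay
from .session import TRIAL_TYPES, SessionBundle

REF_WINDOW_S = 0.200
#: step between successive reference windows; overlapping windows densify
#: the per-location Bernoulli estimates without biasing them (leave-one-
#: trial-out removes whole trials, so no window predicts itself)
REF_STEP_S = 0.100
#: running prediction windows match the 200-ms binarization basis; location
#: is decoded in the 250-ms task windows centered on each prediction window
RUN_PREDICT_WINDOW_S = 0.200
RUN_DECODE_WINDOW_S = 0.250
#: location resolution of the reference vectors (cm); about the spatial
#: footprint of a 200-ms window at running speed, much coarser than the 2-cm
#: map bins so the per-(type, bin, cell) Bernoulli estimates stay dense
REF_BIN_CM = 20.0
PSEUDOCOUNT = 1.0
ALPHA = 0.05
N_SHUFFLES = 5000


def binarize(spikes: dict[int, np.ndarray], cells: list[int],
             t0s: np.ndarray, window_s: float,
             mean_rates: dict[int, float]) -> np.ndarray:
    """High/low state per (window, cell): rate strictly above session mean."""
    counts = spike_count_matrix(spikes, cells, np.asarray(t0s), window_s)
    means = np.array([mean_rates[c] for c in cells])
    return (counts / window_s) > means[None, :]


@dataclass
class TrialTypeReference:
    """Per (trial type, location bin, cell) probability of the high state."""

    trial_types: list[TrialType]
    cells: list[int]
    bin_width_cm: float
    n_bins: int
    alpha: float
    n_high: np.ndarray           # (T, P, C) high-state window counts
    n_obs: np.ndarray            # (T, P) window counts
    trial_counts: dict[int, tuple[int, np.ndarray, np.ndarray]]
    # trial index -> (type index, per-bin n_high (P, C), per-bin n (P,))

    @property
    def p_high(self) -> np.ndarray:
        """(T, P, C) smoothed probabilities in (0, 1)."""
        a = self.alpha
        return (self.n_high + a) / (self.n_obs[..., None] + 2 * a)

    def p_high_loo(self, trial_index: int) -> np.ndarray:
        """Reference with one trial's windows removed (leave-one-trial-out)."""
        a = self.alpha
        nh = self.n_high.copy()
        nn = self.n_obs.copy()
        ti, nh_tr, nn_tr = self.trial_counts[trial_index]
        nh[ti] = nh[ti] - nh_tr
        nn[ti] = nn[ti] - nn_tr
        return (nh + a) / (nn[..., None] + 2 * a)


def build_reference(bundle: SessionBundle,
                    templates: dict[str, JourneyTemplate],
                    cells: list[int],
                    window_s: float = REF_WINDOW_S,
                    step_s: float = REF_STEP_S,
                    bin_width_cm: float = REF_BIN_CM,
                    alpha: float = PSEUDOCOUNT,
                    speed_min: float = 5.0) -> TrialTypeReference:
    """Estimate the eight population reference vectors from running windows."""
    from .maze import linearize

    trial_types = [tt for tt in TRIAL_TYPES
                   if any((tr.subtask, tr.journey) == tt for tr in bundle.trials)]
    t_index = {tt: i for i, tt in enumerate(trial_types)}
    length = max(tpl.length for tpl in templates.values())
    n_bins = int(np.ceil(length / bin_width_cm))
    mean_rates = bundle.session_mean_rates()

    T, P, C = len(trial_types), n_bins, len(cells)
    n_high = np.zeros((T, P, C))
    n_obs = np.zeros((T, P))
    trial_counts: dict[int, tuple[int, np.ndarray, np.ndarray]] = {}

    for tr in bundle.trials:
        tt = (tr.subtask, tr.journey)
        if tt not in t_index:
            continue
        t0s = np.arange(tr.t_start, tr.t_end - window_s + 1e-9, step_s)
        if t0s.size == 0:
            continue
        centers = t0s + window_s / 2
        keep = bundle.speed_at(centers) > speed_min
        t0s, centers = t0s[keep], centers[keep]
        if t0s.size == 0:
            continue
        arc = linearize(bundle.position_at(centers), templates[tr.journey])
        bins = np.clip((arc / bin_width_cm).astype(int), 0, n_bins - 1)
        high = binarize(bundle.spikes, cells, t0s, window_s, mean_rates)
        nh_tr = np.zeros((P, C))
        nn_tr = np.zeros(P)
        np.add.at(nh_tr, bins, high.astype(float))
        np.add.at(nn_tr, bins, 1.0)
        ti = t_index[tt]
        n_high[ti] += nh_tr
        n_obs[ti] += nn_tr
        trial_counts[tr.index] = (ti, nh_tr, nn_tr)

    return TrialTypeReference(trial_types=trial_types, cells=list(cells),
                              bin_width_cm=bin_width_cm, n_bins=n_bins,
                              alpha=alpha, n_high=n_high, n_obs=n_obs,
                              trial_counts=trial_counts)


def predict_window(c_vec: np.ndarray, p_high: np.ndarray,
                   location_bin: int) -> tuple[np.ndarray, int]:
    """Log Prob(C|t) for every trial type at one location, and the argmax.

    ``c_vec`` is the boolean high/low state per cell; ``p_high`` the (T, P, C)
    reference.  Ties break to the first (canonical-order) type.
    """
    r = p_high[:, location_bin, :]           # (T, C)
    logp = np.where(c_vec[None, :], np.log(r), np.log1p(-r)).sum(axis=1)
    return logp, int(np.argmax(logp))


def _predict_many(high: np.ndarray, bins: np.ndarray,
                  p_high: np.ndarray) -> np.ndarray:
    """(W, T) log Prob(C|t) for many windows at their location bins."""
    r = p_high[:, bins, :]                   # (T, W, C)
    logp = np.where(high[None, :, :], np.log(r), np.log1p(-r)).sum(axis=2)
    return logp.T


@dataclass
class TrialTypePrediction:
    """Per-window and event-level trial-type prediction for one replay."""

    trial_types: list[TrialType]
    window_logp: np.ndarray          # (W, T)
    window_argmax: np.ndarray        # (W,)
    modal_type: TrialType
    probability_sum: float           # summed Prob(C|t*) across windows
    p_cell_identity: float = np.nan
    p_decoded_location: float = np.nan

    @property
    def episodic(self) -> bool:
        return (self.p_cell_identity < ALPHA) and (self.p_decoded_location < ALPHA)


def classify_episodic(path: PathReplay, bundle: SessionBundle,
                      reference: TrialTypeReference,
                      n_shuffles: int = N_SHUFFLES,
                      seed: int = 0) -> TrialTypePrediction | None:
    """Predict the trial type of a path replay and test it against shuffles.

    Uses the replay's 20-ms decoding windows that carry a MAP location.
    The statistic is the summed probability of the modal predicted type;
    nulls are (A) permutation of cell identities within C and (B)
    permutation of decoded locations across windows.
    """
    est = path.map_path
    have = ~np.isnan(est[:, 0])
    if have.sum() < 2:
        return None
    t0s = path.posterior.t0s[have]
    arcs = est[have, 1]
    bins = np.clip((arcs / reference.bin_width_cm).astype(int),
                   0, reference.n_bins - 1)
    mean_rates = bundle.session_mean_rates()
    high = binarize(bundle.spikes, reference.cells, t0s,
                    path.posterior.tau, mean_rates)
    p_high = reference.p_high

    def statistic(high_m: np.ndarray, bins_m: np.ndarray
                  ) -> tuple[float, np.ndarray, np.ndarray]:
        logp = _predict_many(high_m, bins_m, p_high)
        arg = np.argmax(logp, axis=1)
        modal = int(np.bincount(arg, minlength=logp.shape[1]).argmax())
        # summed probability of the modal type (normalized across types to
        # keep the sum comparable between events)
        mx = logp.max(axis=1, keepdims=True)
        prob = np.exp(logp - mx)
        prob /= prob.sum(axis=1, keepdims=True)
        return float(prob[:, modal].sum()), arg, logp

    s_obs, arg_obs, logp_obs = statistic(high, bins)
    modal_idx = int(np.bincount(arg_obs, minlength=len(reference.trial_types)).argmax())

    rng = np.random.default_rng(seed)
    C = high.shape[1]
    exceed_a = exceed_b = 0
    for _ in range(n_shuffles):
        s_a, _, _ = statistic(high[:, rng.permutation(C)], bins)
        if s_a >= s_obs - 1e-12:
            exceed_a += 1
        s_b, _, _ = statistic(high, bins[rng.permutation(bins.size)])
        if s_b >= s_obs - 1e-12:
            exceed_b += 1
    p_a = (1 + exceed_a) / (1 + n_shuffles)
    p_b = (1 + exceed_b) / (1 + n_shuffles)
    return TrialTypePrediction(trial_types=reference.trial_types,
                               window_logp=logp_obs, window_argmax=arg_obs,
                               modal_type=reference.trial_types[modal_idx],
                               probability_sum=s_obs,
                               p_cell_identity=float(p_a),
                               p_decoded_location=float(p_b))


def running_confusion(bundle: SessionBundle, maps: PlaceMapSet,
                      templates: dict[str, JourneyTemplate],
                      reference: TrialTypeReference,
                      window_s: float = RUN_PREDICT_WINDOW_S,
                      decode_window_s: float = RUN_DECODE_WINDOW_S,
                      speed_min: float = 5.0,
                      leave_one_out: bool = True,
                      gate: bool = True) -> tuple[pd.DataFrame, float]:
    """Confusion matrix of per-window trial-type predictions while running.

    Location is decoded per window with the Bayesian decoder over
    journey-pooled maps (MAP with the unimodality gate).  With
    ``leave_one_out`` the reference excludes the window's own trial.
    Returns (confusion table actual x predicted, overall accuracy).
    """
    jmaps = journey_maps(maps)
    decoder = BayesianDecoder(jmaps, cells=reference.cells)
    jset = jmaps.trial_types
    mean_rates = bundle.session_mean_rates()
    tts = reference.trial_types
    confusion = pd.DataFrame(0.0, index=[f"{s}_{j}" for s, j in tts],
                             columns=[f"{s}_{j}" for s, j in tts])
    n_correct = 0
    n_total = 0
    for tr in bundle.trials:
        tt = (tr.subtask, tr.journey)
        if tt not in tts or tr.index not in reference.trial_counts:
            continue
        if leave_one_out and reference.n_obs[tts.index(tt)].sum() <= \
                reference.trial_counts[tr.index][2].sum():
            continue                     # degenerate single-trial type
        t0s = np.arange(tr.t_start, tr.t_end - window_s + 1e-9, window_s)
        centers = t0s + window_s / 2
        keep = bundle.speed_at(centers) > speed_min
        t0s, centers = t0s[keep], centers[keep]
        if t0s.size == 0:
            continue
        posterior = decoder.decode(bundle.spikes, centers - decode_window_s / 2,
                                   decode_window_s, jset)
        est = posterior.map_estimates(gate=gate)
        have = ~np.isnan(est[:, 0])
        if not have.any():
            continue
        bins = np.clip((est[have, 1] / reference.bin_width_cm).astype(int),
                       0, reference.n_bins - 1)
        high = binarize(bundle.spikes, reference.cells, t0s[have], window_s,
                        mean_rates)
        p_high = (reference.p_high_loo(tr.index) if leave_one_out
                  else reference.p_high)
        logp = _predict_many(high, bins, p_high)
        arg = np.argmax(logp, axis=1)
        ai = tts.index(tt)
        for pi in arg:
            confusion.iloc[ai, int(pi)] += 1
        n_correct += int((arg == ai).sum())
        n_total += arg.size
    accuracy = n_correct / n_total if n_total else np.nan
    return confusion, accuracy
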