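"""Session-level replay statistics.

Path-representation strength is the summed posterior probability of decoded
locations over a named region of the maze; the future region runs from the
start position to the memory-guided goal (always opposite the previous
goal under the alternation rule), the past region to the previous goal.
Event posteriors can be aligned to a common frame (centered on the start
position or the animal's location, reflected toward the memory-guided goal,
optionally scaled by the distance to that goal) before stacking.

Subtask preference of replay counts is tested with a chi-square
goodness-of-fit against the 60:40:40 VD:NA:DA experience ratio, followed by
pairwise binomial tests with Benjamini-Hochberg correction.  Agreement
between actual and predicted trial types is scored with Cohen's kappa and
its large-sample z-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decoding import PosteriorMatrix

#: goal vicinity: final stretch of each journey (cm)
GOAL_VICINITY_CM = 20.0


@dataclass(frozen=True)
class RegionSpec:
    """Named arc-length intervals (cm) on a journey, half-open [lo, hi)."""

    intervals: tuple[tuple[float, float], ...]
    journey_length_cm: float = 200.0

    def __post_init__(self):
        for lo, hi in self.intervals:
            if not (0 <= lo < hi <= self.journey_length_cm + 1e-9):
                raise ValueError(f"region ({lo}, {hi}) outside the journey")

    def mask(self, n_bins: int, bin_width_cm: float) -> np.ndarray:
        centers = (np.arange(n_bins) + 0.5) * bin_width_cm
        m = np.zeros(n_bins, dtype=bool)
        for lo, hi in self.intervals:
            m |= (centers >= lo) & (centers < hi)
        return m


def goal_vicinity_region(journey_length_cm: float = 200.0,
                         extent_cm: float = GOAL_VICINITY_CM) -> RegionSpec:
    return RegionSpec(((journey_length_cm - extent_cm, journey_length_cm),),
                      journey_length_cm)


def path_representation(posterior: PosteriorMatrix, region: RegionSpec,
                        block: int | None = None) -> float:
    """Sum of posterior probability over a region, across all windows.

    ``block`` restricts the sum to one journey block; None sums the region
    mask applied within every block.
    """
    n_bins_block = posterior.blocks[0][2] - posterior.blocks[0][1]
    mask_block = region.mask(n_bins_block, posterior.bin_width_cm)
    if not mask_block.any():
        raise ValueError("empty region")
    total = 0.0
    for bi, (tt, start, stop) in enumerate(posterior.blocks):
        if block is not None and bi != block:
            continue
        total += float(posterior.nprob[:, start:stop][:, mask_block].sum())
    return total


def align_events(event_profiles: list[np.ndarray],
                 centers: np.ndarray,
                 toward_goal: np.ndarray,
                 scale_to: np.ndarray | None = None,
                 bin_width_cm: float = 2.0,
                 grid: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Align per-event linear posterior profiles to a common frame.

    Each profile (probability per arc bin) is translated so that
    ``centers[k]`` maps to zero, reflected so that the memory-guided goal
    lies in the positive direction (``toward_goal[k]`` is +1 when the goal is
    at larger arc values, -1 otherwise), and optionally scaled so that the
    distance ``scale_to[k]`` maps to one.  Probability mass is accumulated
    onto the common grid by nearest-bin assignment (mass conserving).

    Returns (grid centers, stacked array (n_events, len(grid))).
    """
    if grid is None:
        if scale_to is None:
            grid = np.arange(-200.0, 200.0 + bin_width_cm, bin_width_cm)
        else:
            grid = np.arange(-2.0, 2.0 + 0.02, 0.02)
    lo = grid[0]
    step = grid[1] - grid[0]
    out = np.zeros((len(event_profiles), grid.size))
    for k, prof in enumerate(event_profiles):
        n = prof.size
        arc = (np.arange(n) + 0.5) * bin_width_cm
        coord = (arc - centers[k]) * toward_goal[k]
        if scale_to is not None:
            if scale_to[k] == 0:
                raise ValueError("zero scaling distance")
            coord = coord / scale_to[k]
        idx = np.clip(np.round((coord - lo) / step).astype(int), 0, grid.size - 1)
        np.add.at(out[k], idx, prof)
    return grid, out


def subtask_preference(counts: dict[str, int],
                       experience_ratio: tuple[float, float, float] = (60, 40, 40),
                       order: tuple[str, str, str] = ("VD", "NA", "DA")
                       ) -> dict:
    """Chi-square GOF of replay counts against the experience ratio, with
    BH-corrected post hoc pairwise binomial tests.

    The null is that replays occur in proportion to subtask exposure
    (60 VD : 40 NA : 40 DA laps).  Pairwise tests compare each subtask pair's
    split against the corresponding conditional expected proportion.
    """
    obs = np.array([counts.get(s, 0) for s in order], dtype=float)
    if obs.sum() == 0:
        raise ValueError("all-zero counts")
    ratio = np.asarray(experience_ratio, dtype=float)
    expected = obs.sum() * ratio / ratio.sum()
    chi2, p = stats.chisquare(obs, expected)

    pairs, raw_p = [], []
    for i in range(3):
        for j in range(i + 1, 3):
            n_pair = obs[i] + obs[j]
            if n_pair == 0:
                continue
            p0 = ratio[i] / (ratio[i] + ratio[j])
            res = stats.binomtest(int(obs[i]), int(n_pair), p0)
            pairs.append(f"{order[i]} vs {order[j]}")
            raw_p.append(res.pvalue)
    if raw_p:
        adj = multipletests(raw_p, method="fdr_bh")[1]
    else:
        adj = []
    return {
        "counts": dict(zip(order, obs.astype(int))),
        "expected": dict(zip(order, expected)),
        "chi2": float(chi2),
        "p": float(p),
        "pairwise": [
            {"pair": name, "p_raw": float(pr), "p_bh": float(pa)}
            for name, pr, pa in zip(pairs, raw_p, adj)
        ],
    }


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (delegates to statsmodels)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def cohen_kappa(actual: np.ndarray, predicted: np.ndarray
                ) -> tuple[float, float, float]:
    """Cohen's kappa with its large-sample z-test against kappa = 0.

    Returns (kappa, z, two-sided p).  The null standard error uses the
    Fleiss-Cohen-Everitt formula under independence.
    """
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.size != predicted.size or actual.size == 0:
        raise ValueError("label vectors must be equal-length and nonempty")
    labels = np.unique(np.concatenate([actual, predicted]))
    if labels.size < 2:
        raise ValueError("need at least two observed categories")
    n = actual.size
    k = labels.size
    idx = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((k, k))
    for a, p in zip(actual, predicted):
        table[idx[a], idx[p]] += 1
    table /= n
    po = float(np.trace(table))
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    pe = float(rows @ cols)
    if pe >= 1.0:
        raise ValueError("degenerate marginals")
    kappa = (po - pe) / (1 - pe)
    # variance of kappa under H0: kappa = 0 (independence)
    var0 = (pe + pe**2 - float(np.sum(rows * cols * (rows + cols)))) / (n * (1 - pe) ** 2)
    if var0 <= 0:
        raise ValueError("null variance not positive")
    z = kappa / np.sqrt(var0)
    p = 2 * stats.norm.sf(abs(z))
    return float(kappa), float(z), float(p)


def match_score(actual: np.ndarray, predicted: np.ndarray) -> dict:
    """Trial-type match between actual and predicted labels."""
    kappa, z, p = cohen_kappa(actual, predicted)
    return {"kappa": kappa, "z": z, "p": p, "n": int(np.asarray(actual).size)}


def rank_compare(x: np.ndarray, y: np.ndarray, paired: bool = False,
                 alternative: str = "two-sided") -> dict:
    """Nonparametric comparison glue (Wilcoxon signed-rank / rank-sum)."""
    if paired:
        res = stats.wilcoxon(x, y, alternative=alternative)
        test = "wilcoxon-signed-rank"
    else:
        res = stats.mannwhitneyu(x, y, alternative=alternative)
        test = "rank-sum"
    return {"test": test, "statistic": float(res.statistic),
            "p": float(res.pvalue)}
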