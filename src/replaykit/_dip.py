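"""Hartigan's dip statistic and a Monte-Carlo calibrated unimodality test.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and the class of unimodal CDFs (convex below the mode, concave above).
It is computed here from that definition: for every candidate mode the
minimal band half-width admitting a unimodal crossing of the ECDF band is
found from chord conditions within the convex and concave regions (closed
form) plus a coupled condition through the shared modal value (solved by
bisection), and the dip is the minimum over modes.  The statistic is affine
invariant and bounded below by ``1/(2n)``.

P-values are calibrated by Monte Carlo against the uniform null: the null
table of dips of sorted uniform samples of matching size is drawn once per
process from a fixed seed and cached.
"""

from __future__ import annotations

import numpy as np

_NULL_TABLE_SEED = 190_321_557
_NULL_TABLE_SIZE = 1000
_null_cache: dict[int, np.ndarray] = {}


def dip_statistic(x: np.ndarray) -> float:
    """Dip of a one-dimensional sample (need not be sorted).

    Returns 0 for degenerate samples (n < 2 or all values equal).

    For a candidate mode at sample point k, a unimodal CDF G within a band
    of half-width eps around the ECDF must satisfy three groups of chord
    conditions: convexity among points left of k, concavity among points
    right of k, and a coupled condition through the shared modal value
    ``g = G(x_k)`` (chords from the left band into ``g`` must clear the lower
    band while chords from ``g`` into the right band stay below the upper
    band).  The first two groups give closed-form lower bounds on eps; the
    coupled group is monotone in eps and is solved by bisection.  The dip is
    the minimum over modes.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 2 or x[-1] == x[0]:
        return 0.0
    # scale to [0, 1]; the dip is affine invariant
    x = (x - x[0]) / (x[-1] - x[0])

    # ECDF band at sample point i (0-based): F jumps from i/n to (i+1)/n,
    # so  (i+1)/n - eps <= G(x_i) <= i/n + eps.
    idx = np.arange(n)
    ub = idx / n               # upper band minus eps
    lb = (idx + 1) / n         # lower band plus eps
    floor = 1.0 / (2 * n)

    # closed-form internal constraints: chords of the upper band must clear
    # the lower band among points strictly left of the mode (convexity), and
    # chords of the lower band must stay below the upper band strictly right
    # of the mode (concavity); both are cumulative in the region size.
    ceps = _prefix_eps(x, ub, lb)                  # prefixes ending at t
    xr = (1.0 - x)[::-1]
    seps = _prefix_eps(xr, (1.0 - lb)[::-1], (1.0 - ub)[::-1])[::-1]

    lower_bounds = np.full(n, floor)
    lower_bounds[1:] = np.maximum(lower_bounds[1:], ceps[:-1])
    lower_bounds[:-1] = np.maximum(lower_bounds[:-1], seps[1:])

    best = np.inf
    for k in np.argsort(lower_bounds):
        if lower_bounds[k] >= best:
            break
        eps = _coupled_eps(x, ub, lb, int(k), lower_bounds[k], floor, cap=best)
        best = min(best, eps)
    return float(best)


def _coupled_eps(x: np.ndarray, ub: np.ndarray, lb: np.ndarray, k: int,
                 lower_bound: float, floor: float,
                 cap: float = np.inf) -> float:
    """Minimal eps admitting a unimodal band crossing with mode at x[k]."""
    n = x.size
    # left chords (i < l < k): g >= (lo_l - (1-lam) u_i) / lam
    if k >= 2:
        xi = x[:k - 1][:, None]
        xl = x[1:k][None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(xl > xi, (xl - xi) / (x[k] - xi), np.nan)
        valid_L = (xl > xi) & (lam > 1e-12)
        aL0 = np.where(valid_L, (lb[1:k][None, :] - (1 - lam) * ub[:k - 1][:, None]) / lam, -np.inf)
        aL1 = np.where(valid_L, (1 + (1 - lam)) / lam, 0.0)   # decreasing in eps
    else:
        aL0 = aL1 = None
    # right chords (k < b < c): g <= (u_b - mu*lo_c) / (1 - mu)
    if k <= n - 3:
        xb = x[k + 1:n - 1][:, None]
        xc = x[k + 2:n][None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            mu = np.where(xc > xb, (xb - x[k]) / (xc - x[k]), np.nan)
        valid_R = (xc > xb) & (mu < 1 - 1e-12) & (mu >= 0)
        bR0 = np.where(valid_R, (ub[k + 1:n - 1][:, None] - mu * lb[k + 2:n][None, :]) / (1 - mu), np.inf)
        bR1 = np.where(valid_R, (1 + mu) / (1 - mu), 0.0)     # increasing in eps
    else:
        bR0 = bR1 = None

    def feasible(eps: float) -> bool:
        g_min = lb[k] - eps
        g_max = ub[k] + eps
        if aL0 is not None:
            g_min = max(g_min, float(np.max(aL0 - aL1 * eps)))
        if bR0 is not None:
            g_max = min(g_max, float(np.min(bR0 + bR1 * eps)))
        return g_min <= g_max + 1e-12

    lo_e = max(lower_bound, floor)
    if feasible(lo_e):
        return lo_e
    hi_e = min(cap, 0.5)
    if hi_e <= lo_e or not feasible(hi_e):
        # the minimum for this mode cannot beat the current best
        if np.isfinite(cap):
            return max(cap, lo_e)
        hi_e = 0.5
        while not feasible(hi_e):
            hi_e *= 2.0
    while hi_e - lo_e > 1e-10:
        mid = 0.5 * (lo_e + hi_e)
        if feasible(mid):
            hi_e = mid
        else:
            lo_e = mid
    return hi_e


def _prefix_eps(x: np.ndarray, up: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Minimal band half-width for a convex crossing of every prefix.

    ``up``/``lo`` are the eps-free parts of the upper/lower band (the bands
    are ``up + eps`` and ``lo - eps``).  Returns an array ``eps[t]`` =
    minimal eps for the prefix ending at index t (0-based, cumulative max).
    """
    n = x.size
    eps = np.zeros(n)
    running = 0.0
    for t in range(n):
        if t >= 2:
            xi = x[:t - 1]                        # i < k < t
            xk = x[1:t]
            denom = x[t] - xi
            # chord from (x_i, up_i) to (x_t, up_t) evaluated at every x_k
            with np.errstate(divide="ignore", invalid="ignore"):
                lam = (xk[None, :] - xi[:, None]) / np.where(
                    denom[:, None] == 0, np.inf, denom[:, None])
            valid = (xk[None, :] > xi[:, None]) & (x[t] > xk[None, :])
            chord = (1 - lam) * up[:t - 1, None] + lam * up[t]
            viol = np.where(valid, (lo[1:t][None, :] - chord) / 2.0, -np.inf)
            m = viol.max(initial=-np.inf)
            if m > running:
                running = float(m)
        eps[t] = running
    return eps


def _null_dips(m: int) -> np.ndarray:
    if m not in _null_cache:
        rng = np.random.default_rng(_NULL_TABLE_SEED + m)
        _null_cache[m] = np.array(
            [dip_statistic(rng.random(m)) for _ in range(_NULL_TABLE_SIZE)]
        )
    return _null_cache[m]


def pseudo_sample(pmf: np.ndarray, m: int = 32) -> np.ndarray:
    """Deterministic quantile sample of a discrete pmf over bins.

    The pmf is treated as a piecewise-constant density over unit-width bins;
    the inverse CDF is evaluated at the m mid-quantiles (i - 1/2)/m, giving a
    continuous, reproducible sample suitable for the dip statistic.
    """
    p = np.asarray(pmf, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("pmf has no mass")
    p = p / total
    cdf = np.concatenate([[0.0], np.cumsum(p)])
    q = (np.arange(m) + 0.5) / m
    # invert exactly: locate the bin, then interpolate linearly within it
    bins = np.clip(np.searchsorted(cdf, q, side="right") - 1, 0, p.size - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(p[bins] > 0, (q - cdf[bins]) / p[bins], 0.5)
    return bins + np.clip(frac, 0.0, 1.0)


def dip_pvalue(pmf: np.ndarray, m: int = 32) -> float:
    """Monte-Carlo dip-test p-value for unimodality of a probability row.

    Small p rejects unimodality (the row is multimodal).
    """
    obs = dip_statistic(pseudo_sample(pmf, m=m))
    null = _null_dips(m)
    return float((1 + np.sum(null >= obs)) / (1 + null.size))
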