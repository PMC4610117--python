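"""Figure-eight maze geometry: journey templates and trajectory linearization.

The maze is a 100 x 140 cm figure-eight: a central stem flanked by two loops.
Every rewarded lap is one of four *journeys* -- LL, LR, RL, RR, named by
(start side, goal side): the rat leaves a bottom start zone, runs along the
bottom rail to the stem, climbs the stem to the junction (decision point) and
turns toward the left or right goal.  Each journey is an idealized polyline;
2D trajectories are linearized by nearest-neighbor projection onto the
polyline's sample points, yielding an arc-length coordinate measured from the
journey start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import JOURNEYS

# Maze landmark coordinates (cm).  Overall footprint 100 x 140 cm with a
# 20-cm-wide path; landmarks sit on the path midline.
_X_LEFT, _X_STEM, _X_RIGHT = 10.0, 50.0, 90.0
_Y_BOTTOM, _Y_TOP = 10.0, 130.0

#: Arc length of every journey (cm): 40 (bottom rail) + 120 (stem) + 40 (top rail).
JOURNEY_LENGTH_CM = 200.0


@dataclass(frozen=True)
class JourneyTemplate:
    """One idealized journey: polyline samples with arc-length coordinates."""

    journey: str
    points: np.ndarray        # (n, 2) cm, sampled along the polyline
    arc: np.ndarray           # (n,) strictly increasing arc length (cm)
    zones: dict[str, tuple[float, float]]  # named half-open arc intervals

    @property
    def length(self) -> float:
        return float(self.arc[-1])

    def position_at(self, s: np.ndarray) -> np.ndarray:
        """2D point at arc-length coordinate(s) ``s`` (clipped to the path)."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        x = np.interp(s, self.arc, self.points[:, 0])
        y = np.interp(s, self.arc, self.points[:, 1])
        return np.column_stack([x, y])

    def heading_at(self, s: np.ndarray) -> np.ndarray:
        """Tangent direction (rad) of travel at arc-length coordinate(s)."""
        s = np.asarray(s, dtype=float)
        p0 = self.position_at(s - 0.5)
        p1 = self.position_at(s + 0.5)
        return np.arctan2(p1[:, 1] - p0[:, 1], p1[:, 0] - p0[:, 0])


def _resample_polyline(vertices: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample a polyline at uniform arc-length intervals (endpoint kept)."""
    seg = np.diff(vertices, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    arc = np.arange(0.0, total + step / 2, step)
    arc[-1] = min(arc[-1], total)
    x = np.interp(arc, cum, vertices[:, 0])
    y = np.interp(arc, cum, vertices[:, 1])
    return np.column_stack([x, y]), arc


def make_journey_templates(step_cm: float = 1.0) -> dict[str, JourneyTemplate]:
    """Build the four journey templates of the figure-eight maze.

    Zones (arc-length intervals, cm from the journey start):
    ``start`` [0, 20), ``stem`` [40, 140), ``junction`` [140, 160) (the
    decision point at the top of the stem), ``goal`` [180, 200] (goal
    vicinity, final 20 cm).
    """
    side_x = {"L": _X_LEFT, "R": _X_RIGHT}
    zones = {
        "start": (0.0, 20.0),
        "stem": (40.0, 140.0),
        "junction": (140.0, 160.0),
        "goal": (180.0, 200.0),
    }
    templates = {}
    for j in JOURNEYS:
        start, goal = j[0], j[1]
        vertices = np.array(
            [
                [side_x[start], _Y_BOTTOM],
                [_X_STEM, _Y_BOTTOM],
                [_X_STEM, _Y_TOP],
                [side_x[goal], _Y_TOP],
            ]
        )
        points, arc = _resample_polyline(vertices, step_cm)
        templates[j] = JourneyTemplate(journey=j, points=points, arc=arc, zones=zones)
    return templates


def return_rail(goal_side: str) -> np.ndarray:
    """Vertices of the outer return rail from a goal down to its start zone."""
    x = {"L": _X_LEFT, "R": _X_RIGHT}[goal_side]
    return np.array([[x, _Y_TOP], [x, _Y_BOTTOM]])


def linearize(points: np.ndarray, template: JourneyTemplate) -> np.ndarray:
    """Project 2D points onto a journey template.

    Each point maps to the arc-length coordinate of the nearest template
    sample point; ties break toward the smaller arc length.  Empty input
    yields an empty array.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        return np.empty(0)
    if template.points.size == 0:
        raise ValueError("empty journey template")
    # pairwise squared distances, (n_points, n_template)
    d2 = (
        (points[:, 0:1] - template.points[None, :, 0]) ** 2
        + (points[:, 1:2] - template.points[None, :, 1]) ** 2
    )
    # argmin returns the first (smallest-arc) index on exact ties; guard
    # against float noise by snapping near-ties to the earliest index
    idx = np.argmin(d2, axis=1)
    best = d2[np.arange(len(points)), idx]
    for i in range(len(points)):
        tied = np.nonzero(d2[i] <= best[i] + 1e-9)[0]
        idx[i] = tied[0]
    return template.arc[idx]


def zone_of(template: JourneyTemplate, s: float) -> str | None:
    """Name of the zone containing arc coordinate ``s``, or None."""
    for name, (lo, hi) in template.zones.items():
        if lo <= s < hi or (name == "goal" and s == hi):
            return name
    return None
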