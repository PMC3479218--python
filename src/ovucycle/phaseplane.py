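"""Phase-plane trajectories for hormone pairs and their shape descriptors.

Plotting one hormone against another with the cycle day as curve parameter
turns the familiar time profiles into closed orbits whose geometry is
diagnostic: the FSH-estradiol orbit of a normal cycle crosses itself (a
"leaning &"), while the LH-progesterone orbit is a simple open loop (a
"boomerang").  The descriptors below operationalize those two patterns as
a self-intersection count and a signed (shoelace) loop area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import HormoneLookupError
from .reference_data import HormoneSeries

__all__ = [
    "PhaseTrajectory",
    "ShapeDescriptors",
    "build_trajectory",
    "count_self_intersections",
    "signed_loop_area",
    "classify_shape",
]

#: Relative tolerance of the orientation predicate (hormone data are in
#: general position; exact rational arithmetic is deliberately not used).
ORIENT_RTOL = 1e-9

#: Collinearity tolerance: max perpendicular deviation below this fraction
#: of the coordinate range makes a trajectory degenerate.
COLLINEAR_RTOL = 1e-9

ShapeClass = Literal["crossed_loop", "open_loop", "degenerate"]


@dataclass(frozen=True)
class PhaseTrajectory:
    """Ordered, day-labeled 2-D points for one hormone pair."""

    points: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,) strictly increasing day labels
    x_name: str
    y_name: str
    closed: bool = True

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "labels", labels)
        if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 2:
            raise ValueError("points must be an (n >= 2, 2) array")
        if labels.shape != (points.shape[0],):
            raise ValueError("labels must match the number of points")
        if labels.size > 1 and not np.all(np.diff(labels) > 0):
            raise ValueError("labels must be strictly increasing")
        if not np.all(np.isfinite(points)) or np.any(points < 0):
            raise ValueError("coordinates must be finite and >= 0")

    def __len__(self) -> int:
        return int(self.points.shape[0])

    def segments(self) -> np.ndarray:
        """Polyline segments as an (m, 2, 2) array; includes the closing
        segment when the trajectory is closed."""
        pts = self.points
        segs = np.stack([pts[:-1], pts[1:]], axis=1)
        if self.closed:
            closing = np.stack([pts[-1:], pts[:1]], axis=1)
            segs = np.concatenate([segs, closing], axis=0)
        return segs


@dataclass(frozen=True)
class ShapeDescriptors:
    """Shape summary of one phase-plane orbit."""

    n_self_intersections: int
    signed_loop_area: float
    shape_class: ShapeClass

    def to_frame(self, x_name: str, y_name: str) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "x_name": x_name,
                    "y_name": y_name,
                    "n_self_intersections": self.n_self_intersections,
                    "signed_loop_area": self.signed_loop_area,
                    "shape_class": self.shape_class,
                }
            ]
        )


def build_trajectory(
    series: HormoneSeries, x_name: str, y_name: str, closed: bool = True
) -> PhaseTrajectory:
    """Pair two hormones of a series into a day-labeled trajectory."""
    if x_name == y_name:
        raise HormoneLookupError(f"x and y hormones must be distinct, got {x_name!r} twice")
    x = series.hormone(x_name)
    y = series.hormone(y_name)
    return PhaseTrajectory(
        points=np.column_stack([x, y]),
        labels=series.days,
        x_name=x_name,
        y_name=y_name,
        closed=closed,
    )


def _orient(a: np.ndarray, b: np.ndarray, c: np.ndarray, scale: float) -> int:
    """Sign of the turn a->b->c with a relative tolerance on the cross product."""
    cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    if abs(cross) <= ORIENT_RTOL * scale * scale:
        return 0
    return 1 if cross > 0 else -1


def _segments_cross(p: np.ndarray, q: np.ndarray, scale: float) -> bool:
    """True if segments p and q intersect transversally or overlap collinearly.

    Transverse means each segment strictly straddles the other's supporting
    line; collinear overlapping pairs count as a single crossing.  A mere
    endpoint touch between non-adjacent segments is not counted.
    """
    a, b = p
    c, d = q
    o1 = _orient(a, b, c, scale)
    o2 = _orient(a, b, d, scale)
    o3 = _orient(c, d, a, scale)
    o4 = _orient(c, d, b, scale)
    if o1 * o2 < 0 and o3 * o4 < 0:
        return True
    if o1 == 0 and o2 == 0 and o3 == 0 and o4 == 0:
        # collinear: check 1-D overlap of more than a single point
        axis = 0 if abs(b[0] - a[0]) + abs(d[0] - c[0]) >= abs(b[1] - a[1]) + abs(d[1] - c[1]) else 1
        lo = max(min(a[axis], b[axis]), min(c[axis], d[axis]))
        hi = min(max(a[axis], b[axis]), max(c[axis], d[axis]))
        return hi - lo > ORIENT_RTOL * scale
    return False


def count_self_intersections(traj: PhaseTrajectory) -> int:
    """Number of interior crossings between non-adjacent polyline segments.

    Adjacent segments share an endpoint by construction and never count;
    for a closed trajectory the closing segment is adjacent to both the
    first and the last segment.  Coincident crossing points are counted
    once per crossing segment pair.
    """
    if len(traj) < 4:
        return 0
    segs = traj.segments()
    m = segs.shape[0]
    span = traj.points.max(axis=0) - traj.points.min(axis=0)
    scale = float(max(span.max(), 1e-300))
    count = 0
    for i in range(m):
        for j in range(i + 2, m):
            if traj.closed and i == 0 and j == m - 1:
                continue  # closing segment is adjacent to the first
            if _segments_cross(segs[i], segs[j], scale):
                count += 1
    return count


def signed_loop_area(traj: PhaseTrajectory) -> float:
    """Shoelace area of a closed trajectory; positive when counter-clockwise."""
    if not traj.closed:
        raise ValueError("signed_loop_area requires a closed trajectory")
    x = traj.points[:, 0]
    y = traj.points[:, 1]
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _is_collinear(points: np.ndarray) -> bool:
    span = points.max(axis=0) - points.min(axis=0)
    scale = float(max(span.max(), 1e-300))
    a = points[0]
    b = points[np.argmax(np.hypot(*(points - a).T))]
    direction = b - a
    norm = float(np.hypot(*direction))
    if norm == 0.0:
        return True
    perp = np.abs((points[:, 0] - a[0]) * direction[1] - (points[:, 1] - a[1]) * direction[0]) / norm
    return bool(np.max(perp) < COLLINEAR_RTOL * scale)


def classify_shape(traj: PhaseTrajectory) -> ShapeDescriptors:
    """Classify an orbit as crossed_loop, open_loop, or degenerate.

    ``crossed_loop`` iff the polyline self-intersects at least once (the
    "&" pattern); ``degenerate`` iff all points are collinear within
    tolerance; otherwise ``open_loop`` (the "boomerang").
    """
    if _is_collinear(traj.points):
        return ShapeDescriptors(0, 0.0 if not traj.closed else signed_loop_area(traj), "degenerate")
    n = count_self_intersections(traj)
    area = signed_loop_area(traj) if traj.closed else 0.0
    shape: ShapeClass = "crossed_loop" if n >= 1 else "open_loop"
    return ShapeDescriptors(n, area, shape)
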