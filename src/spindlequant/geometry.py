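"""Planar geometry shared by the measurement modules.

Points in the coronal plane are ``(y, x)`` in micrometres, *y* increasing
from the apical (ventricular) surface toward the pial side.  Angles follow
the convention of the orientation analysis: 0 deg is the apico-basal axis
(perpendicular to the local apical surface), +/-90 deg is parallel to the
surface, and the sign is positive for a clockwise tilt viewed in the
coronal plane with the apical side up and *x* to the right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import GeometryError


@dataclass
class ApicalSurface:
    """Polyline tracing the local ventricular surface, points ``(y, x)`` um."""

    points: np.ndarray  # (N, 2)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise GeometryError("surface needs >= 2 (y, x) points")
        if _self_intersects(self.points):
            raise GeometryError("surface polyline self-intersects")

    @classmethod
    def horizontal(cls, y: float, x_min: float, x_max: float) -> "ApicalSurface":
        return cls(np.array([[y, x_min], [y, x_max]]))

    def nearest_segment(self, point) -> int:
        """Index of the segment closest to ``point``."""
        p = np.asarray(point, dtype=float)
        a = self.points[:-1]
        b = self.points[1:]
        ab = b - a
        t = np.clip(
            np.einsum("ij,ij->i", p - a, ab) / np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-300),
            0.0,
            1.0,
        )
        proj = a + t[:, None] * ab
        return int(np.argmin(np.linalg.norm(proj - p, axis=1)))

    def inward_normal(self, point) -> np.ndarray:
        """Unit normal of the nearest segment pointing toward ``point``'s side.

        For a cell sitting basally of (below) the surface this is the
        apico-basal direction.
        """
        i = self.nearest_segment(point)
        d = self.points[i + 1] - self.points[i]
        n = np.array([-d[1], d[0]])  # 90 deg rotation in (y, x)
        n = n / np.linalg.norm(n)
        mid = 0.5 * (self.points[i] + self.points[i + 1])
        if np.dot(np.asarray(point, float) - mid, n) < 0:
            n = -n
        return n

    def arc_position(self, point) -> float:
        """Arc length (um) from the start of the polyline to the projection
        of ``point`` onto its nearest segment."""
        i = self.nearest_segment(point)
        seg_lengths = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        a, b = self.points[i], self.points[i + 1]
        ab = b - a
        t = float(
            np.clip(np.dot(np.asarray(point, float) - a, ab) / max(np.dot(ab, ab), 1e-300), 0, 1)
        )
        return float(seg_lengths[:i].sum() + t * seg_lengths[i])

    @property
    def total_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def signed_axis_angle_deg(axis_yx, normal_yx) -> float:
    """Signed deviation (deg, in (-90, 90]) of an *unoriented* axis from a
    reference direction.

    Positive for a clockwise tilt in the coronal view (apical up, x right).
    """
    v = np.asarray(axis_yx, dtype=float)
    n = np.asarray(normal_yx, dtype=float)
    if np.linalg.norm(v) == 0 or np.linalg.norm(n) == 0:
        raise GeometryError("zero-length axis or reference")
    v = v / np.linalg.norm(v)
    n = n / np.linalg.norm(n)
    if np.dot(v, n) < 0:  # unoriented axis: take the representative along n
        v = -v
    # cross z-component in (x, y-down) screen coordinates
    cross = n[1] * v[0] - n[0] * v[1]
    ang = float(np.degrees(np.arctan2(cross, np.dot(v, n))))
    if ang <= -90.0:
        ang += 180.0
    return ang


def plate_axis_direction(angle_deg: float) -> np.ndarray:
    """Unit ``(y, x)`` direction of a plate main axis at a signed deviation
    ``angle_deg`` from a vertical (apico-basal, +y) reference.  Inverse of
    :func:`signed_axis_angle_deg` with normal ``(1, 0)``."""
    t = np.radians(angle_deg)
    return np.array([np.cos(t), -np.sin(t)])


def segments_intersect(p1, p2, q1, q2) -> bool:
    """Whether the closed segments ``p1p2`` and ``q1q2`` intersect (2D)."""

    def orient(a, b, c):
        return (b[1] - a[1]) * (c[0] - a[0]) - (b[0] - a[0]) * (c[1] - a[1])

    def on_seg(a, b, c):
        return (
            min(a[0], b[0]) - 1e-12 <= c[0] <= max(a[0], b[0]) + 1e-12
            and min(a[1], b[1]) - 1e-12 <= c[1] <= max(a[1], b[1]) + 1e-12
        )

    d1 = orient(q1, q2, p1)
    d2 = orient(q1, q2, p2)
    d3 = orient(p1, p2, q1)
    d4 = orient(p1, p2, q2)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return True
    for d, a, b, c in ((d1, q1, q2, p1), (d2, q1, q2, p2), (d3, p1, p2, q1), (d4, p1, p2, q2)):
        if abs(d) < 1e-12 and on_seg(a, b, c):
            return True
    return False


def _self_intersects(points: np.ndarray) -> bool:
    n = len(points) - 1
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1 and np.allclose(points[0], points[-1]):
                continue
            if segments_intersect(points[i], points[i + 1], points[j], points[j + 1]):
                return True
    return False


def ellipsoid_chord_length(semi_axes_zyx, direction_zyx) -> float:
    """Analytic chord length of an ellipsoid along a line through its centre."""
    a = np.asarray(semi_axes_zyx, dtype=float)
    u = np.asarray(direction_zyx, dtype=float)
    u = u / np.linalg.norm(u)
    return float(2.0 / np.sqrt(np.sum((u / a) ** 2)))
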