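"""Division-symmetry classification: bisecting vs bypassing the apical domain.

At late anaphase the cleavage plane of an apical progenitor either bisects
the cadherin-negative apical membrane domain — distributing it to both
daughters (a symmetric division) — or bypasses it, so that only one
daughter inherits the apical domain (an asymmetric division).  At anaphase
onset the chromosome-plate angle is practically identical to the cleavage
angle of the soma, so cleavage geometry can be read from plate geometry.
Analysis is 2D, in the coronal plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString

from .exceptions import GeometryError
from .geometry import ApicalSurface


@dataclass
class ApicalDomain:
    """Arc-length interval (um) on the apical surface polyline marking the
    cadherin-negative apical membrane stretch."""

    start_um: float
    end_um: float

    def __post_init__(self) -> None:
        if not self.start_um < self.end_um:
            raise GeometryError("apical domain must have positive length")


@dataclass
class CleavageGeometry:
    """Cleavage-plane line in the coronal view: a point and a direction.

    The cleavage plane is perpendicular to the anaphase plate-separation
    axis; a cleavage at 0 deg from the apico-basal axis is the canonical
    vertical cleavage.
    """

    point_yx_um: np.ndarray
    direction_yx: np.ndarray

    def __post_init__(self) -> None:
        self.point_yx_um = np.asarray(self.point_yx_um, dtype=float)
        d = np.asarray(self.direction_yx, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise GeometryError("cleavage direction must be non-zero")
        self.direction_yx = d / n

    @classmethod
    def from_angle(cls, point_yx_um, angle_deg: float) -> "CleavageGeometry":
        """Cleavage line tilted ``angle_deg`` from the apico-basal (+y) axis."""
        t = np.radians(angle_deg)
        return cls(point_yx_um, np.array([np.cos(t), -np.sin(t)]))


def surface_intersection_arc(
    cleavage: CleavageGeometry, surface: ApicalSurface, reach_um: float = 1e4
) -> float:
    """Arc-length position (um) where the cleavage line meets the surface.

    The line is extended ``reach_um`` in both directions.  No intersection
    (e.g. cleavage parallel to the surface) is an error.
    """
    p = cleavage.point_yx_um
    d = cleavage.direction_yx
    # shapely works in (x, y)
    line = LineString(
        [(p[1] - reach_um * d[1], p[0] - reach_um * d[0]),
         (p[1] + reach_um * d[1], p[0] + reach_um * d[0])]
    )
    poly = LineString([(pt[1], pt[0]) for pt in surface.points])
    hit = line.intersection(poly)
    if hit.is_empty:
        raise GeometryError("cleavage line does not reach the apical surface")
    if hit.geom_type == "Point":
        pts = [hit]
    elif hit.geom_type == "MultiPoint":
        pts = list(hit.geoms)
    else:  # collinear overlap
        raise GeometryError("cleavage line runs along the apical surface")
    # nearest intersection to the cell
    best = min(pts, key=lambda q: (q.x - p[1]) ** 2 + (q.y - p[0]) ** 2)
    return surface.arc_position((best.y, best.x))


def classify_division(
    domain: ApicalDomain, cleavage: CleavageGeometry, surface: ApicalSurface
) -> str:
    """``"bisect"`` if the cleavage line meets the surface strictly inside
    the apical-domain interval, else ``"bypass"``.

    An intersection exactly on a domain endpoint is a bypass: bisection
    requires splitting the domain into two non-empty parts.
    """
    arc = surface_intersection_arc(cleavage, surface)
    if domain.start_um < arc < domain.end_um:
        return "bisect"
    return "bypass"


def percent_asymmetric(classifications) -> float:
    """Percentage of divisions classified as bypass (asymmetric)."""
    classifications = list(classifications)
    if len(classifications) == 0:
        raise GeometryError("no classifications")
    bad = [c for c in classifications if c not in ("bisect", "bypass")]
    if bad:
        raise GeometryError(f"unknown classification {bad[0]!r}")
    return 100.0 * sum(c == "bypass" for c in classifications) / len(classifications)


def simulate_divisions(
    n: int,
    angle_sd_deg: float,
    domain_half_width_um: float = 0.75,
    soma_height_um: float = 5.0,
    surface_halfspan_um: float = 50.0,
    seed: int = 0,
) -> list[str]:
    """Monte-Carlo division assay: cleavage angles drawn from a centred
    normal distribution, a flat apical surface, and a centred apical domain.

    The geometric core of the anchoring model: wider cleavage-angle spread
    sends more cleavage planes outside the apical domain, i.e. more
    asymmetric divisions.
    """
    rng = np.random.default_rng(seed)
    surface = ApicalSurface.horizontal(0.0, -surface_halfspan_um, surface_halfspan_um)
    mid = surface_halfspan_um  # arc position of x = 0
    domain = ApicalDomain(mid - domain_half_width_um, mid + domain_half_width_um)
    out = []
    for angle in rng.normal(0.0, angle_sd_deg, size=n):
        cleavage = CleavageGeometry.from_angle((soma_height_um, 0.0), float(angle))
        try:
            out.append(classify_division(domain, cleavage, surface))
        except GeometryError:
            # cleavage so oblique it misses the annotated surface stretch:
            # it certainly misses the apical domain
            out.append("bypass")
    return out
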