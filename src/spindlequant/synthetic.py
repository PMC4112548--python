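"""Ground-truthed synthetic microscopy of mitotic neural progenitors.

No raw image data exist for the quantifications this package implements, so
this module generates inputs with the geometric and statistical structure
the measurements assume, together with a complete generative record (the
ground truth) against which every detector can be scored:

* single mitotic cells — an ellipsoidal soma, a metaphase chromosome plate
  carrying bright peri/centromeric heterochromatin foci, two spindle poles
  joined by a dense central spindle, sparse astral rods reaching (or
  stopping short of) the cell cortex, and a cortical marker band with a
  prescribed angular intensity profile over diffuse cytoplasm;
* plate-angle trajectories — a mean-reverting (Ornstein-Uhlenbeck) angle
  series whose restoring stiffness is proportional to the number of polar
  cortical anchors, the phenomenological "guy rope" picture of astral
  microtubules anchoring the spindle;
* tissue scenes — nuclei with zone (VZ/SVZ/CP) and marker labels along an
  apical and a pial surface, for the tissue-level censuses.

Photon-level realism is not claimed: rods are single-voxel lines under a
Gaussian PSF, noise is Poisson-then-Gaussian and off by default.  What is
guaranteed is that the rendered structures, and only they, are present, and
that the ground truth records every generative parameter exactly.

Axis order is ``(z, y, x)``; *y* runs from the apical (ventricular) surface
toward the pial side; physical units are micrometres throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cortical_profile import Contour, apical_boundary_point, extract_contour
from .exceptions import GeometryError
from .geometry import plate_axis_direction
from .plate_orientation import PlateTrack
from .stacks import ImageStack

REGIONS = ("apical", "basal", "central")

# rendered intensity levels (arbitrary units); foci add their amplitude on
# top of the plate so focus peaks are twice the plate level by construction
LEVELS = {"plate": 100.0, "focus": 100.0, "spindle": 60.0, "astral": 120.0, "pole": 500.0}


# ======================================================================= cells
@dataclass
class AstralSpec:
    """One astral microtubule: a rod from a spindle pole toward the cortex."""

    origin_pole: int  # 0 or 1
    direction: np.ndarray  # unit (z, y, x)
    reaches_cortex: bool
    region_label: str  # apical | basal | central

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if n == 0:
            raise GeometryError("astral direction must be non-zero")
        self.direction = self.direction / n
        if self.region_label not in REGIONS:
            raise GeometryError(f"unknown region label {self.region_label!r}")


@dataclass
class CellSpec:
    """Generative description of one synthetic mitotic cell.

    ``soma_axes`` are ellipsoid semi-axes ``(az, ay, ax)`` in um (a 2-tuple
    is promoted to ``(ay, ay, ax)``); ``pole_positions`` are the two
    centrosome positions in um; foci must lie within the plate envelope.
    ``noise`` is ``(gaussian_sd, poisson_gain_or_None)``.
    """

    soma_axes: tuple
    pole_positions: np.ndarray  # (2, 3) um
    plate_angle_deg: float
    n_foci: int
    foci_positions: np.ndarray  # (n, 3) um
    astral_spec: list[AstralSpec] = field(default_factory=list)
    cortical_profile_fn: object = None
    cytoplasm_level: float = 30.0
    noise: tuple = (0.0, None)
    voxel_spacing: tuple = (0.75, 0.09, 0.09)
    psf_sigma: float = 0.09
    apical_surface_y: float = 0.0
    shape: tuple = (9, 200, 200)
    center: tuple | None = None
    plate_radius_um: float = 2.6
    plate_thickness_um: float = 0.45
    spindle_radius_um: float = 2.2  # bicone max radius, < plate radius
    reach_inset_um: float = 0.35  # cortex-reaching rods stop this far inside
    stop_fraction: float = 0.7  # non-reaching rods stop at this pole->cortex fraction
    view: str = "front"

    def __post_init__(self) -> None:
        if len(self.soma_axes) == 2:
            self.soma_axes = (self.soma_axes[0], self.soma_axes[0], self.soma_axes[1])
        self.soma_axes = tuple(float(a) for a in self.soma_axes)
        if any(a <= 0 for a in self.soma_axes):
            raise GeometryError("soma axes must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise GeometryError("voxel spacing must be positive")
        self.pole_positions = np.asarray(self.pole_positions, dtype=float).reshape(2, 3)
        self.foci_positions = np.asarray(self.foci_positions, dtype=float).reshape(-1, 3)
        if self.n_foci < 1 or len(self.foci_positions) != self.n_foci:
            raise GeometryError("need n_foci >= 1 matching foci_positions")
        if self.center is None:
            self.center = tuple(
                0.5 * n * s for n, s in zip(self.shape, self.voxel_spacing)
            )
        self.center = tuple(float(c) for c in self.center)
        if self.cortical_profile_fn is None:
            self.cortical_profile_fn = cosine_profile(40.0, 0.0)
        for f in self.foci_positions:
            ax_d, rad_d = self._plate_coords(f)
            if ax_d > self.plate_thickness_um + 1e-6 or rad_d > self.plate_radius_um + 1e-6:
                raise GeometryError("focus outside the plate envelope")

    # plate frame: thickness axis = spindle (pole-pole) axis
    def spindle_axis(self) -> np.ndarray:
        d = self.pole_positions[1] - self.pole_positions[0]
        n = np.linalg.norm(d)
        if n == 0:
            raise GeometryError("coincident pole positions")
        return d / n

    def _plate_coords(self, point) -> tuple[float, float]:
        d = np.asarray(point, float) - np.asarray(self.center)
        s = self.spindle_axis()
        axial = float(np.dot(d, s))
        radial = float(np.sqrt(max(np.dot(d, d) - axial**2, 0.0)))
        return abs(axial), radial

    def in_plate(self, point, pad: float = 0.0) -> bool:
        ax_d, rad_d = self._plate_coords(point)
        return ax_d <= self.plate_thickness_um + pad and rad_d <= self.plate_radius_um + pad

    def any_in_plate(self, points, pad: float = 0.0) -> bool:
        """Vectorized plate-envelope test over an (n, 3) point array."""
        d = np.asarray(points, float) - np.asarray(self.center)
        sax = self.spindle_axis()
        axial = d @ sax
        radial2 = np.einsum("ij,ij->i", d, d) - axial**2
        return bool(
            np.any(
                (np.abs(axial) <= self.plate_thickness_um + pad)
                & (radial2 <= (self.plate_radius_um + pad) ** 2)
            )
        )

    def boundary_distance(self, origin, direction) -> float:
        """Distance from ``origin`` along unit ``direction`` to the soma surface."""
        a = np.asarray(self.soma_axes)
        p = (np.asarray(origin, float) - np.asarray(self.center)) / a
        u = np.asarray(direction, float) / a
        A = float(np.dot(u, u))
        B = 2.0 * float(np.dot(p, u))
        C = float(np.dot(p, p)) - 1.0
        disc = B * B - 4 * A * C
        if disc <= 0:
            raise GeometryError("ray does not exit through the soma surface")
        s = (-B + math.sqrt(disc)) / (2 * A)
        if s <= 0:
            raise GeometryError("ray origin outside the soma")
        return s

    def astral_endpoint(self, astral: AstralSpec) -> np.ndarray:
        pole = self.pole_positions[astral.origin_pole]
        s_b = self.boundary_distance(pole, astral.direction)
        s = s_b - self.reach_inset_um if astral.reaches_cortex else self.stop_fraction * s_b
        return pole + s * astral.direction


@dataclass
class GroundTruthAstral:
    origin_pole: int
    endpoint_um: np.ndarray
    reaches_cortex: bool
    region: str


@dataclass
class CellGroundTruth:
    """Complete generative record of one synthetic cell."""

    spec: CellSpec
    soma_mask: np.ndarray
    plate_mask: np.ndarray
    spindle_mask: np.ndarray
    pole_positions_um: np.ndarray
    foci_um: np.ndarray
    partition_y_um: tuple  # (apical_bound, basal_bound)
    astrals: list[GroundTruthAstral]
    census: dict
    plate_angle_deg: float
    view: str
    contour: Contour
    contour_s: np.ndarray
    contour_true_values: np.ndarray
    cytoplasm_level: float

    def to_json(self) -> dict:
        return {
            "plate_angle_deg": self.plate_angle_deg,
            "view": self.view,
            "pole_positions_um": self.pole_positions_um.tolist(),
            "foci_um": self.foci_um.tolist(),
            "partition_y_um": list(self.partition_y_um),
            "census": self.census,
            "cytoplasm_level": self.cytoplasm_level,
            "astrals": [
                {
                    "origin_pole": a.origin_pole,
                    "endpoint_um": a.endpoint_um.tolist(),
                    "reaches_cortex": bool(a.reaches_cortex),
                    "region": a.region,
                }
                for a in self.astrals
            ],
        }


def cosine_profile(base: float, amplitude: float, phase: float = 0.5):
    """Smooth cortical profile ``base + amplitude * cos(2*pi*(s - phase))``.

    With the default ``phase=0.5`` the maximum sits at the basal pole of the
    perimeter (s = 0.5), the configuration of a proliferating apical
    progenitor with basally enriched cortical LGN.
    """

    def fn(s):
        return base + amplitude * np.cos(2 * np.pi * (np.asarray(s, float) - phase))

    fn.params = {"kind": "cosine", "base": base, "amplitude": amplitude, "phase": phase}
    return fn


def _region_of_y(y: float, y_ap: float, y_ba: float, tol: float = 0.0) -> str:
    """Region label induced by the partition planes (planes belong to central)."""
    if y < y_ap - tol:
        return "apical"
    if y > y_ba + tol:
        return "basal"
    return "central"


def make_mitotic_cell(spec: CellSpec, seed: int = 0) -> tuple[ImageStack, CellGroundTruth]:
    """Render one synthetic mitotic cell and its ground truth.

    Channels: ``dna`` (plate + foci, foci peaks 2x plate level), ``tubulin``
    (bicone central spindle, astral rods, bright pole spots; PSF-blurred),
    ``cortical_marker`` (one-pixel cortical band with the prescribed profile
    on the central section, over uniform cytoplasm).  Identical spec and
    seed give voxel-identical stacks.
    """
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.voxel_spacing
    cz, cy, cx = spec.center
    Z = (np.arange(nz) + 0.5)[:, None, None] * dz
    Y = (np.arange(ny) + 0.5)[None, :, None] * dy
    X = (np.arange(nx) + 0.5)[None, None, :] * dx
    az, ay, ax = spec.soma_axes

    soma = ((Z - cz) / az) ** 2 + ((Y - cy) / ay) ** 2 + ((X - cx) / ax) ** 2 <= 1.0
    if not soma.any():
        raise GeometryError("soma does not intersect the volume")

    # --- DNA: plate ellipsoid (disc) + foci spots -------------------------
    s_axis = spec.spindle_axis()
    D = np.stack(np.broadcast_arrays(Z - cz, Y - cy, X - cx), axis=-1)
    axial = D @ s_axis
    radial2 = np.einsum("...i,...i->...", D, D) - axial**2
    plate = (np.abs(axial) <= spec.plate_thickness_um) & (
        radial2 <= spec.plate_radius_um**2
    )
    plate &= soma
    dna = np.where(plate, LEVELS["plate"], 0.0)
    sigma_focus = 0.18
    for f in spec.foci_positions:
        r2 = (Z - f[0]) ** 2 + (Y - f[1]) ** 2 + (X - f[2]) ** 2
        dna += LEVELS["focus"] * np.exp(-r2 / (2 * sigma_focus**2))

    # --- tubulin: bicone + rods + poles -----------------------------------
    p0, p1 = spec.pole_positions
    L = np.linalg.norm(p1 - p0)
    t = np.clip(((D + np.asarray(spec.center) - p0) @ s_axis) / L, 0.0, 1.0)
    closest = p0 + t[..., None] * (p1 - p0)
    P = np.stack(np.broadcast_arrays(Z, Y, X), axis=-1)
    seg_dist2 = np.einsum("...i,...i->...", P - closest, P - closest)
    r_core = 0.4
    cone_r = r_core + (spec.spindle_radius_um - r_core) * (1.0 - np.abs(2 * t - 1))
    spindle = (seg_dist2 <= cone_r**2) & soma
    tubulin = np.where(spindle, LEVELS["spindle"], 0.0)

    astrals_gt: list[GroundTruthAstral] = []
    y_ap = float(spec.foci_positions[:, 1].min())
    y_ba = float(spec.foci_positions[:, 1].max())
    step = 0.25 * min(dy, dx)
    for astral in spec.astral_spec:
        pole = spec.pole_positions[astral.origin_pole]
        s_end = float(
            np.linalg.norm(spec.astral_endpoint(astral) - pole)
        )
        n_steps = max(int(s_end / step), 2)
        s_samples = np.linspace(0.0, s_end, n_steps)
        pts = pole[None, :] + s_samples[:, None] * astral.direction[None, :]
        # reject rods exiting through the plate envelope
        d_pts = pts - np.asarray(spec.center)
        ax_pts = np.abs(d_pts @ s_axis)
        rad_pts = np.sqrt(np.maximum(np.einsum("ij,ij->i", d_pts, d_pts) - ax_pts**2, 0))
        inside_plate = (ax_pts <= spec.plate_thickness_um) & (rad_pts <= spec.plate_radius_um)
        if inside_plate.any():
            raise GeometryError("astral direction exits through the plate envelope")
        idx = np.floor(pts / np.asarray(spec.voxel_spacing)).astype(int)
        # deposit into the two nearest sections: a rod crossing a section
        # boundary then stays seamless in the coronal (z-max) projection
        zfrac = pts[:, 0] / dz - idx[:, 0]
        idx2 = idx.copy()
        idx2[:, 0] = np.clip(idx[:, 0] + np.where(zfrac > 0.5, 1, -1), 0, nz - 1)
        for ii in (idx, idx2):
            keep = (
                (ii[:, 0] >= 0) & (ii[:, 0] < nz)
                & (ii[:, 1] >= 0) & (ii[:, 1] < ny)
                & (ii[:, 2] >= 0) & (ii[:, 2] < nx)
            )
            jj = ii[keep]
            tubulin[jj[:, 0], jj[:, 1], jj[:, 2]] = np.maximum(
                tubulin[jj[:, 0], jj[:, 1], jj[:, 2]], LEVELS["astral"]
            )
        endpoint = pts[-1]
        region = _region_of_y(float(endpoint[1]), y_ap, y_ba)
        if region != astral.region_label:
            raise GeometryError(
                f"astral region label {astral.region_label!r} disagrees with the "
                f"foci-induced partition ({region!r})"
            )
        astrals_gt.append(
            GroundTruthAstral(astral.origin_pole, endpoint, astral.reaches_cortex, region)
        )

    # PSF blur on the optical channels, then sharp pole spots on top so the
    # poles remain the global tubulin maxima by construction
    if spec.psf_sigma > 0:
        sig = tuple(spec.psf_sigma / s for s in spec.voxel_spacing)
        dna = ndimage.gaussian_filter(dna, sig)
        tubulin = ndimage.gaussian_filter(tubulin, sig)
    for p in spec.pole_positions:
        r2 = (Z - p[0]) ** 2 + (Y - p[1]) ** 2 + (X - p[2]) ** 2
        tubulin += LEVELS["pole"] * np.exp(-r2 / (2 * 0.25**2))

    # --- cortical marker: cytoplasm + one-pixel cortical band -------------
    marker = np.where(soma, spec.cytoplasm_level, 0.0)
    zc = int(np.clip(round(cz / dz - 0.5), 0, nz - 1))
    central = soma[zc]
    contour = extract_contour(central, apical_boundary_point(central))
    s_pos, _ = contour.arc_positions()
    true_vals = np.asarray(spec.cortical_profile_fn(s_pos), dtype=float)
    marker[zc][contour.points[:, 0], contour.points[:, 1]] = (
        spec.cytoplasm_level + true_vals
    )

    # --- noise ------------------------------------------------------------
    gaussian_sd, poisson_gain = spec.noise
    rng = np.random.default_rng(seed)
    channels = {"dna": dna, "tubulin": tubulin, "cortical_marker": marker}
    for name, img in channels.items():
        if poisson_gain:
            img = rng.poisson(np.clip(img, 0, None) / poisson_gain) * float(poisson_gain)
        if gaussian_sd:
            img = img + rng.normal(0.0, gaussian_sd, img.shape)
        channels[name] = img

    stack = ImageStack(
        channels=channels,
        spacing=spec.voxel_spacing,
        meta={
            "apical_surface_y": spec.apical_surface_y,
            "view": spec.view,
            "seed": int(seed),
        },
    )
    reaching = [a for a in astrals_gt if a.reaches_cortex]
    census = {r: sum(a.region == r for a in reaching) for r in REGIONS}
    gt = CellGroundTruth(
        spec=spec,
        soma_mask=soma,
        plate_mask=plate,
        spindle_mask=spindle,
        pole_positions_um=spec.pole_positions.copy(),
        foci_um=spec.foci_positions.copy(),
        partition_y_um=(y_ap, y_ba),
        astrals=astrals_gt,
        census=census,
        plate_angle_deg=spec.plate_angle_deg,
        view=spec.view,
        contour=contour,
        contour_s=s_pos,
        contour_true_values=true_vals,
        cytoplasm_level=spec.cytoplasm_level,
    )
    return stack, gt


# -------------------------------------------------------------- cell builders
def _snap_to_voxel(points, spacing):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    spacing = np.asarray(spacing)
    return (np.floor(points / spacing) + 0.5) * spacing


def _sample_foci(rng, n_foci, center, axis_a, axis_b, radius, spacing, min_sep=0.7,
                 b_extent=0.45):
    """Foci inside the plate disc spanned by unit vectors ``axis_a/axis_b``;
    the first two sit at +/-0.92 radius along ``axis_a`` so the partition
    band has a reproducible extent, the rest fill the middle.  ``b_extent``
    scales the spread along ``axis_b`` (0 collapses foci onto ``axis_a``).
    Sequential placement can dead-end at tight packing, so the whole draw
    is restarted a few times before giving up."""
    for _restart in range(25):
        offsets = [-0.92 * radius, 0.92 * radius]
        coords_b = [0.0, 0.0]
        ok = True
        for _ in range(n_foci - 2):
            for _attempt in range(200):
                a = rng.uniform(-0.78 * radius, 0.78 * radius)
                b = rng.uniform(-b_extent * radius, b_extent * radius)
                if all(
                    math.hypot(a - oa, b - ob) >= min_sep
                    for oa, ob in zip(offsets, coords_b)
                ):
                    offsets.append(a)
                    coords_b.append(b)
                    break
            else:
                ok = False
                break
        if ok:
            break
    else:
        raise GeometryError("could not place foci with the requested separation")
    pts = (
        np.asarray(center)[None, :]
        + np.asarray(offsets)[:, None] * axis_a[None, :]
        + np.asarray(coords_b)[:, None] * axis_b[None, :]
    )
    return _snap_to_voxel(pts, spacing)


def _boundary_point(center, ay, ax, phi, z=None):
    """Central-section soma boundary point at parameter ``phi`` (0 = apical top)."""
    cz, cy, cx = center
    return np.array(
        [cz if z is None else z, cy - ay * math.cos(phi), cx + ax * math.sin(phi)]
    )


def _visible_segment(pole_yx, endpoint_yx, pole_clearance_um: float = 2.6):
    """Projected rod part beyond the pole neighbourhood, or None if the rod
    never emerges (shapely LineString in (y, x) um)."""
    from shapely.geometry import LineString

    p = np.asarray(pole_yx, float)
    e = np.asarray(endpoint_yx, float)
    length = float(np.linalg.norm(e - p))
    if length <= pole_clearance_um:
        return None
    start = p + (pole_clearance_um / length) * (e - p)
    return LineString([tuple(start), tuple(e)])


def _min_angular_separation(phi, used, min_sep_deg):
    return all(
        min(abs(phi - u), 2 * math.pi - abs(phi - u)) >= math.radians(min_sep_deg)
        for u in used
    )


def _place_astrals(rng, spec_kwargs, center, soma_axes, poles, foci, counts,
                   side_view, n_nonreaching=0, min_sep_deg=10.0, n_restarts=12):
    """Rejection-sample astral directions honouring region margins and the
    angular separation needed for rods to stay resolvable.  Greedy packing
    can dead-end, so the whole placement is restarted a few times before
    giving up."""
    last_err = None
    for _restart in range(n_restarts):
        try:
            return _place_astrals_once(
                rng, spec_kwargs, center, soma_axes, poles, foci, counts,
                side_view, n_nonreaching, min_sep_deg,
            )
        except GeometryError as exc:
            last_err = exc
    raise last_err


def _place_astrals_once(rng, spec_kwargs, center, soma_axes, poles, foci, counts,
                        side_view, n_nonreaching=0, min_sep_deg=10.0):
    az, ay, ax = soma_axes
    cz, cy, cx = center
    y_ap, y_ba = float(foci[:, 1].min()), float(foci[:, 1].max())
    dy = spec_kwargs["voxel_spacing"][1]
    margin = 4.0 * dy + spec_kwargs.get("reach_inset_um", 0.35)
    probe = CellSpec(
        soma_axes=soma_axes,
        pole_positions=poles,
        plate_angle_deg=0.0,
        n_foci=len(foci),
        foci_positions=foci,
        **{k: v for k, v in spec_kwargs.items() if k in
           ("voxel_spacing", "shape", "center", "plate_radius_um",
            "plate_thickness_um", "reach_inset_um", "stop_fraction")},
    )
    s2d = poles[1][1:] - poles[0][1:]
    s2d_norm = np.linalg.norm(s2d)
    astrals: list[AstralSpec] = []
    used_phi: list[float] = []
    used_segments: list = []  # visible projected rod parts (shapely)
    order = (
        [("apical", True)] * counts.get("apical", 0)
        + [("basal", True)] * counts.get("basal", 0)
        + [("central", True)] * counts.get("central", 0)
        + [("apical", False)] * n_nonreaching
    )
    # inward regions (apical/basal) need clearance from the partition planes
    # both for the label and for endpoint-localization error; the central
    # region only needs the latter
    margin_outer = margin
    margin_central = 3.0 * dy

    def candidate_phis(lo_deg, hi_deg, mirror=False):
        grid = np.arange(lo_deg, hi_deg, 2.0)
        if mirror:
            grid = np.concatenate([grid, -grid])
        grid = grid + rng.uniform(-1.0, 1.0, size=grid.shape)
        rng.shuffle(grid)
        return [math.radians(g) for g in grid]

    for region, reaches in order:
        placed = False
        # disjoint angular bands (buffer zones between them) so apical and
        # basal rods never crowd the central sector of a Side-view cell
        if region == "apical":
            phis = candidate_phis(-48, 48) if side_view else candidate_phis(-70, 70)
        elif region == "basal":
            phis = candidate_phis(132, 228) if side_view else candidate_phis(110, 250)
        elif side_view:
            phis = candidate_phis(64, 116, mirror=True)
        else:
            phis = [None] * 50
        candidates = []  # feasible (min-used-distance, phi, astral, visible)
        for phi in phis:
            if phi is None:
                # Front view: central astrals run mostly along the optical
                # axis toward the cortex facing the viewer
                sgn = rng.choice([-1.0, 1.0])
                pole_idx = int(rng.integers(2))
                direction = np.array([sgn, rng.normal(0, 0.06), rng.normal(0, 0.06)])
                astral = AstralSpec(pole_idx, direction, reaches, "central")
                endpoint = probe.astral_endpoint(astral)
                if _region_of_y(endpoint[1], y_ap, y_ba) != "central":
                    continue
                astrals.append(astral)
                placed = True
                break
            bp = _boundary_point(center, ay, ax, phi)
            if side_view:
                pole_idx = int(rng.integers(2))
            else:
                pole_idx = int(
                    np.argmin(np.linalg.norm(poles[:, 1:] - bp[1:], axis=1))
                )
            pole = poles[pole_idx]
            direction = bp - pole
            astral = AstralSpec(pole_idx, direction, reaches, region)
            endpoint = probe.astral_endpoint(astral)
            want = region if reaches else _region_of_y(endpoint[1], y_ap, y_ba)
            label = _region_of_y(endpoint[1], y_ap, y_ba)
            if label != want:
                continue
            if reaches:
                if label == "apical" and endpoint[1] > y_ap - margin_outer:
                    continue
                if label == "basal" and endpoint[1] < y_ba + margin_outer:
                    continue
                if label == "central" and not (
                    y_ap + margin_central <= endpoint[1] <= y_ba - margin_central
                ):
                    continue
            # any rod must emerge well beyond the pole neighbourhood in
            # projection to be a detectable structure at all
            if np.linalg.norm(endpoint[1:] - pole[1:]) < 3.0:
                continue
            # a non-reaching rod must stop clearly outside the cortex
            # contact distance, or it would not exemplify the rule
            if not reaches:
                gap = np.linalg.norm(endpoint - pole) * (1.0 / probe.stop_fraction - 1.0)
                if gap < 1.4:
                    continue
            if not _min_angular_separation(phi, used_phi, min_sep_deg):
                continue
            # no exit through the plate envelope
            s_end = np.linalg.norm(endpoint - pole)
            samples = pole[None, :] + np.linspace(0, s_end, 60)[:, None] * astral.direction
            if probe.any_in_plate(samples):
                continue
            # the visible (beyond pole neighbourhood) projected parts of
            # any two rods must keep clear of each other
            vis = _visible_segment(pole[1:], endpoint[1:])
            if vis is not None and any(
                vis.distance(v) < 0.40 for v in used_segments
            ):
                continue
            astral.region_label = label
            score = min(
                (min(abs(phi - u), 2 * math.pi - abs(phi - u)) for u in used_phi),
                default=math.pi,
            )
            candidates.append((score, phi, astral, vis))
        if candidates and not placed:
            # farthest-point packing: take the feasible candidate with the
            # largest clearance so later rods still fit
            _, phi, astral, vis = max(candidates, key=lambda c: c[0])
            astrals.append(astral)
            used_phi.append(phi)
            if vis is not None:
                used_segments.append(vis)
            placed = True
        if not placed:
            raise GeometryError(
                f"could not place a {region} astral with the requested separation"
            )
    return astrals


def front_view_cell(
    rng=None,
    *,
    plate_angle_deg: float = 0.0,
    n_apical: int = 5,
    n_basal: int = 6,
    n_central: int = 0,
    n_nonreaching: int = 0,
    n_foci: int = 8,
    soma_axes=(2.9, 5.4, 5.0),
    profile_fn=None,
    cytoplasm_level: float = 30.0,
    noise=(0.0, None),
    **overrides,
) -> CellSpec:
    """A Front-view cell: spindle axis in the coronal plane, plate seen
    edge-on, its main axis at ``plate_angle_deg`` from apico-basal."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    shape = overrides.pop("shape", (9, 200, 200))
    spacing = overrides.pop("voxel_spacing", (0.75, 0.09, 0.09))
    az, ay, ax = soma_axes
    center = overrides.pop(
        "center", (0.5 * shape[0] * spacing[0], ay + 0.4, 0.5 * shape[2] * spacing[2])
    )
    u2d = plate_axis_direction(plate_angle_deg)  # (y, x), plate main axis
    u3d = np.array([0.0, u2d[0], u2d[1]])
    s2d = np.array([-u2d[1], u2d[0]])  # spindle axis, in-plane, perpendicular
    s3d = np.array([0.0, s2d[0], s2d[1]])
    pole_dist = overrides.pop("pole_dist_um", 2.8)
    poles = np.stack([np.asarray(center) - pole_dist * s3d, np.asarray(center) + pole_dist * s3d])
    plate_radius = overrides.pop("plate_radius_um", 2.6)
    # plate disc spans the in-plane main axis and the optical (z) axis;
    # foci stay in the central section (b_extent 0) so each is individually
    # resolvable in a coronal slice; collinear puncta tolerate a slightly
    # smaller spacing than the 2D default
    foci = _sample_foci(
        rng, n_foci, center, u3d, np.array([1.0, 0.0, 0.0]), plate_radius, spacing,
        min_sep=0.55, b_extent=0.0,
    )
    spec_kwargs = dict(
        voxel_spacing=spacing,
        shape=shape,
        center=center,
        plate_radius_um=plate_radius,
        plate_thickness_um=overrides.pop("plate_thickness_um", 0.45),
        reach_inset_um=overrides.pop("reach_inset_um", 0.35),
        stop_fraction=overrides.pop("stop_fraction", 0.7),
    )
    astrals = _place_astrals(
        rng,
        spec_kwargs,
        center,
        soma_axes,
        poles,
        foci,
        {"apical": n_apical, "basal": n_basal, "central": n_central},
        side_view=False,
        n_nonreaching=n_nonreaching,
        min_sep_deg=overrides.pop("min_sep_deg", 10.0),
    )
    return CellSpec(
        soma_axes=soma_axes,
        pole_positions=poles,
        plate_angle_deg=plate_angle_deg,
        n_foci=n_foci,
        foci_positions=foci,
        astral_spec=astrals,
        cortical_profile_fn=profile_fn or cosine_profile(40.0, 0.0),
        cytoplasm_level=cytoplasm_level,
        noise=noise,
        view="front",
        **spec_kwargs,
        **overrides,
    )


def side_view_cell(
    rng=None,
    *,
    n_apical: int = 5,
    n_basal: int = 6,
    n_central: int = 9,
    n_foci: int = 8,
    soma_axes=(2.9, 5.4, 5.0),
    profile_fn=None,
    cytoplasm_level: float = 30.0,
    noise=(0.0, None),
    **overrides,
) -> CellSpec:
    """A Side-view cell: spindle axis along the optical (z) axis, plate seen
    face-on; all three census regions are countable."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    shape = overrides.pop("shape", (9, 200, 200))
    spacing = overrides.pop("voxel_spacing", (0.75, 0.09, 0.09))
    az, ay, ax = soma_axes
    center = overrides.pop(
        "center",
        (0.5 * shape[0] * spacing[0], ay + 0.4, 0.5 * shape[2] * spacing[2]),
    )
    pole_dist = overrides.pop("pole_dist_um", 2.25)
    s3d = np.array([1.0, 0.0, 0.0])
    poles = np.stack([np.asarray(center) - pole_dist * s3d, np.asarray(center) + pole_dist * s3d])
    plate_radius = overrides.pop("plate_radius_um", 2.6)
    # plate disc spans (y, x); foci extremes along y anchor the partition
    foci = _sample_foci(
        rng, n_foci, center, np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0]),
        plate_radius, spacing,
    )
    spec_kwargs = dict(
        voxel_spacing=spacing,
        shape=shape,
        center=center,
        plate_radius_um=plate_radius,
        plate_thickness_um=overrides.pop("plate_thickness_um", 0.45),
        reach_inset_um=overrides.pop("reach_inset_um", 0.35),
        stop_fraction=overrides.pop("stop_fraction", 0.7),
    )
    astrals = _place_astrals(
        rng,
        spec_kwargs,
        center,
        soma_axes,
        poles,
        foci,
        {"apical": n_apical, "basal": n_basal, "central": n_central},
        side_view=True,
        min_sep_deg=overrides.pop("min_sep_deg", 10.0),
    )
    return CellSpec(
        soma_axes=soma_axes,
        pole_positions=poles,
        plate_angle_deg=0.0,
        n_foci=n_foci,
        foci_positions=foci,
        astral_spec=astrals,
        cortical_profile_fn=profile_fn or cosine_profile(40.0, 0.0),
        cytoplasm_level=cytoplasm_level,
        noise=noise,
        view="side",
        **spec_kwargs,
        **overrides,
    )


# ================================================================ trajectories
@dataclass
class TrajectoryParams:
    """Parameters of the guy-rope (mean-reverting) plate-angle model.

    The restoring stiffness is ``stiffness_per_anchor * (n_anchors_polar +
    central_fraction * n_anchors_central)``: polar astrals anchor the
    spindle like guy ropes, central ones contribute only weakly.
    """

    n_anchors_polar: int = 12
    n_anchors_central: int = 9
    stiffness_per_anchor: float = 0.05  # per anchor per min
    central_fraction: float = 0.1
    noise_sd: float = 6.0  # deg per sqrt(min)
    dt: float = 3.0  # min (live-imaging frame interval)
    duration: float = 30.0  # min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_anchors_polar < 0 or self.n_anchors_central < 0:
            raise GeometryError("anchor counts must be >= 0")
        if self.dt <= 0 or self.duration < self.dt:
            raise GeometryError("need dt > 0 and duration >= dt")

    @property
    def stiffness(self) -> float:
        return self.stiffness_per_anchor * (
            self.n_anchors_polar + self.central_fraction * self.n_anchors_central
        )


def simulate_plate_trajectory(params: TrajectoryParams) -> PlateTrack:
    """Euler-Maruyama simulation of the mean-reverting angle series
    ``d(theta) = -k * theta * dt + noise_sd * dW`` with theta(0) = 0.

    Samples are labeled metaphase, the final one anaphase onset, and times
    are shifted so anaphase onset is at t = 0.
    """
    n = int(round(params.duration / params.dt)) + 1
    rng = np.random.default_rng(params.seed)
    theta = np.zeros(n)
    k = params.stiffness
    # exact OU transition over one frame interval: stable for any k * dt
    if k > 0:
        decay = math.exp(-k * params.dt)
        step_sd = params.noise_sd * math.sqrt((1.0 - decay**2) / (2.0 * k))
    else:
        decay = 1.0
        step_sd = params.noise_sd * math.sqrt(params.dt)
    for i in range(1, n):
        theta[i] = decay * theta[i - 1] + step_sd * rng.standard_normal()
    theta = np.clip(theta, -90.0, 90.0)
    times = np.arange(n) * params.dt - (n - 1) * params.dt
    phase = ["metaphase"] * (n - 1) + ["anaphase_onset"]
    return PlateTrack(times=times, angles_deg=theta, phase=phase, anaphase_onset_time=0.0)


# ================================================================ tissue scenes
MARKERS = ("Pax6", "Tbr2", "Tbr1", "Tis21", "PH3", "pVim", "Casp3")
ZONES = ("VZ", "SVZ", "CP")


@dataclass
class Nucleus:
    id: int
    y_um: float
    x_um: float
    zone: str
    markers: frozenset
    radius_um: float = 3.0


@dataclass
class TissueSpec:
    """A synthetic cortical-wall scene: nuclei between an apical (y = 0)
    and a pial (y = tissue_height) surface, zoned VZ / SVZ / CP."""

    apical_surface_length: float
    pial_surface_length: float
    vz_svz_boundary_y: float
    svz_cp_boundary_y: float
    tissue_height_um: float
    nuclei: list
    seed: int = 0

    def __post_init__(self) -> None:
        if self.apical_surface_length <= 0 or self.pial_surface_length <= 0:
            raise GeometryError("surface lengths must be positive")
        if not (0 < self.vz_svz_boundary_y < self.svz_cp_boundary_y < self.tissue_height_um):
            raise GeometryError("zone boundaries must be ordered apical -> pial")
        for nuc in self.nuclei:
            if nuc.zone != self.zone_of(nuc.y_um):
                raise GeometryError(
                    f"nucleus {nuc.id} zone {nuc.zone!r} inconsistent with y={nuc.y_um}"
                )
            if not set(nuc.markers) <= set(MARKERS):
                raise GeometryError(f"unknown markers on nucleus {nuc.id}")

    def zone_of(self, y: float) -> str:
        # half-open bands toward basal: a nucleus on a boundary is in the
        # more basal zone
        if y < self.vz_svz_boundary_y:
            return "VZ"
        if y < self.svz_cp_boundary_y:
            return "SVZ"
        return "CP"

    @property
    def area_um2(self) -> float:
        return self.apical_surface_length * self.tissue_height_um


@dataclass
class TissueGroundTruth:
    """Expected census values, exact by construction."""

    n_per_zone: dict
    marker_counts: dict  # zone -> marker -> count
    ap_fraction_vz_pct: float  # Pax6+ Tbr2- among VZ nuclei
    newborn_bp_fraction_vz_pct: float  # Tbr2+ among VZ nuclei
    mitoses_per_100um: dict  # VZ / SVZ / all, per apical surface
    neurons_per_100um_pial: float
    apoptotic_per_10000um2: float


def make_tissue_scene(
    spec: TissueSpec, pixel_um: float = 0.5, max_overlap_fraction: float = 0.05
):
    """Render a labeled nuclei image, the nuclei table, and the ground truth.

    Scenes denser than ``max_overlap_fraction`` (fraction of nuclei whose
    discs overlap another) are rejected.
    """
    import pandas as pd

    n = len(spec.nuclei)
    if n > 1:
        pos = np.array([[nu.y_um, nu.x_um] for nu in spec.nuclei])
        rad = np.array([nu.radius_um for nu in spec.nuclei])
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        overlapping = (d < rad[:, None] + rad[None, :]).any(axis=1)
        if overlapping.sum() / n > max_overlap_fraction:
            raise GeometryError(
                f"{overlapping.sum()} of {n} nuclei overlap: density cap exceeded"
            )
    ny = int(np.ceil(spec.tissue_height_um / pixel_um))
    nx = int(np.ceil(spec.apical_surface_length / pixel_um))
    labels = np.zeros((ny, nx), dtype=np.int32)
    Y = (np.arange(ny) + 0.5)[:, None] * pixel_um
    X = (np.arange(nx) + 0.5)[None, :] * pixel_um
    for nu in spec.nuclei:
        disc = (Y - nu.y_um) ** 2 + (X - nu.x_um) ** 2 <= nu.radius_um**2
        labels[disc] = nu.id
    table = pd.DataFrame(
        {
            "id": [nu.id for nu in spec.nuclei],
            "x_um": [nu.x_um for nu in spec.nuclei],
            "y_um": [nu.y_um for nu in spec.nuclei],
            "zone": [nu.zone for nu in spec.nuclei],
            "markers": [";".join(sorted(nu.markers)) for nu in spec.nuclei],
        }
    )

    zones = {z: [nu for nu in spec.nuclei if nu.zone == z] for z in ZONES}
    n_per_zone = {z: len(v) for z, v in zones.items()}
    marker_counts = {
        z: {m: sum(m in nu.markers for nu in v) for m in MARKERS} for z, v in zones.items()
    }
    n_vz = n_per_zone["VZ"]
    ap_frac = (
        100.0
        * sum("Pax6" in nu.markers and "Tbr2" not in nu.markers for nu in zones["VZ"])
        / n_vz
        if n_vz
        else 0.0
    )
    bp_frac = (
        100.0 * sum("Tbr2" in nu.markers for nu in zones["VZ"]) / n_vz if n_vz else 0.0
    )
    mitotic = {
        z: sum(("PH3" in nu.markers) or ("pVim" in nu.markers) for nu in zones[z])
        for z in ("VZ", "SVZ")
    }
    per100 = {
        z: 100.0 * mitotic[z] / spec.apical_surface_length for z in ("VZ", "SVZ")
    }
    per100["all"] = per100["VZ"] + per100["SVZ"]
    neurons = sum("Tbr1" in nu.markers for nu in spec.nuclei)
    apoptotic = sum("Casp3" in nu.markers for nu in spec.nuclei)
    gt = TissueGroundTruth(
        n_per_zone=n_per_zone,
        marker_counts=marker_counts,
        ap_fraction_vz_pct=ap_frac,
        newborn_bp_fraction_vz_pct=bp_frac,
        mitoses_per_100um=per100,
        neurons_per_100um_pial=100.0 * neurons / spec.pial_surface_length,
        apoptotic_per_10000um2=10000.0 * apoptotic / spec.area_um2,
    )
    return labels, table, gt


#: marker probabilities and event densities for the two culture conditions
#: (control vs minimal-nocodazole), matching the reported tissue censuses
TISSUE_CONDITIONS = {
    "control": {
        "vz_pax6_only": 0.625,
        "vz_tbr2": 0.343,
        "vz_tis21": 0.588,
        "mitoses_per_100um_vz": 6.0,
        "mitoses_per_100um_svz": 1.5,
        "neurons_per_100um_pial": 40.0,
        "apoptotic_per_10000um2": 1.49,
    },
    "nocodazole": {
        "vz_pax6_only": 0.538,
        "vz_tbr2": 0.431,
        "vz_tis21": 0.682,
        "mitoses_per_100um_vz": 6.0,
        "mitoses_per_100um_svz": 3.0,
        "neurons_per_100um_pial": 55.0,
        "apoptotic_per_10000um2": 1.59,
    },
}


def sample_tissue_spec(
    rng=None,
    condition: str = "control",
    width_um: float = 200.0,
    height_um: float = 120.0,
    vz_svz_y: float = 60.0,
    svz_cp_y: float = 90.0,
    nuclei_per_zone=(120, 50, 45),
    seed: int = 0,
) -> TissueSpec:
    """Draw a tissue scene for one of the two culture conditions.

    Nuclei are placed with a minimum centre distance (no overlapping discs);
    marker flags are Bernoulli draws at the condition's rates; mitoses sit
    near the apical surface (VZ) or in the SVZ, neurons in the CP.
    """
    rng = np.random.default_rng(rng if rng is not None else seed)
    rates = TISSUE_CONDITIONS[condition]
    radius = 2.6
    min_dist = 2 * radius + 0.3
    bands = {"VZ": (radius, vz_svz_y), "SVZ": (vz_svz_y + radius * 0, svz_cp_y), "CP": (svz_cp_y, height_um - radius)}
    placed: list[tuple[float, float]] = []
    nuclei: list[Nucleus] = []
    nid = 1

    def place(y_lo, y_hi):
        for _ in range(4000):
            y = rng.uniform(y_lo, y_hi)
            x = rng.uniform(radius, width_um - radius)
            if all((y - py) ** 2 + (x - px) ** 2 >= min_dist**2 for py, px in placed):
                placed.append((y, x))
                return y, x
        raise GeometryError("could not place nucleus: scene too dense")

    spec_tmp_boundaries = (vz_svz_y, svz_cp_y)

    def zone_of(y):
        if y < spec_tmp_boundaries[0]:
            return "VZ"
        if y < spec_tmp_boundaries[1]:
            return "SVZ"
        return "CP"

    for zone, n_target in zip(ZONES, nuclei_per_zone):
        lo, hi = bands[zone]
        # keep away from boundaries so the zone label is unambiguous
        lo, hi = lo + 0.5, hi - 0.5
        for _ in range(n_target):
            y, x = place(lo, hi)
            markers = set()
            if zone == "VZ":
                u = rng.uniform()
                if u < rates["vz_pax6_only"]:
                    markers.add("Pax6")
                elif u < rates["vz_pax6_only"] + rates["vz_tbr2"]:
                    markers.add("Tbr2")
                if rng.uniform() < rates["vz_tis21"]:
                    markers.add("Tis21")
            elif zone == "SVZ":
                if rng.uniform() < 0.8:
                    markers.add("Tbr2")
                else:
                    markers.add("Pax6")
            else:
                markers.add("Tbr1")
            if rng.uniform() < rates["apoptotic_per_10000um2"] * (width_um * height_um / 10000.0) / sum(nuclei_per_zone):
                markers.add("Casp3")
            nuclei.append(Nucleus(nid, y, x, zone_of(y), frozenset(markers), radius_um=radius))
            nid += 1
    # mitotic figures at the densities of the condition
    n_mit_vz = int(round(rates["mitoses_per_100um_vz"] * width_um / 100.0))
    n_mit_svz = int(round(rates["mitoses_per_100um_svz"] * width_um / 100.0))
    for n_mit, (lo, hi) in (
        (n_mit_vz, (radius + 0.5, min(12.0, vz_svz_y - 0.5))),
        (n_mit_svz, (vz_svz_y + 0.5, svz_cp_y - 0.5)),
    ):
        for _ in range(n_mit):
            y, x = place(lo, hi)
            nuclei.append(
                Nucleus(nid, y, x, zone_of(y), frozenset({"PH3", "pVim"}), radius_um=radius)
            )
            nid += 1
    # neurons: Tbr1-positive cells counted per pial surface; most sit in the
    # CP band already, extra ones are added to reach the target density
    n_neurons_target = int(round(rates["neurons_per_100um_pial"] * width_um / 100.0))
    n_have = sum("Tbr1" in nu.markers for nu in nuclei)
    for _ in range(max(n_neurons_target - n_have, 0)):
        y, x = place(svz_cp_y + 0.5, height_um - radius - 0.5)
        nuclei.append(Nucleus(nid, y, x, "CP", frozenset({"Tbr1"}), radius_um=radius))
        nid += 1
    return TissueSpec(
        apical_surface_length=width_um,
        pial_surface_length=width_um,
        vz_svz_boundary_y=vz_svz_y,
        svz_cp_boundary_y=svz_cp_y,
        tissue_height_um=height_um,
        nuclei=nuclei,
        seed=seed,
    )
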