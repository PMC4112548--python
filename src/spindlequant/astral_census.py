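"""Regional census of cortex-reaching astral microtubules.

The mitotic soma is partitioned into an apical, a central and a basal
region by the two horizontal planes through the apical-most and basal-most
peri/centromeric heterochromatin foci — the brightest puncta of the DNA
stain on the metaphase plate.  Astral microtubules emanating from the two
spindle poles that reach the cell periphery are detected and counted per
region.  Apical and basal astrals are countable in any viewing geometry;
central astrals are only countable when the spindle is seen in "Side" view
(pole-pole axis mostly along the optical axis), because in "Front" view the
dense central spindle hides them — Front-view censuses therefore report the
central count as not assessed.

Basal progenitors lack apical surface contact, so their astrals are instead
binned by the cortical sector their endpoint faces: apically oriented
(toward the ventricle), basally oriented (toward the pia), or centrally
oriented (the remainder).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.morphology import convex_hull_image, disk

from .exceptions import DetectionError, GeometryError
from .geometry import ApicalSurface
from .stacks import ImageStack

NOT_ASSESSED = "not_assessed"


@dataclass
class RegionPartition:
    """Apical/central/basal partition anchored on the heterochromatin foci.

    ``apical_bound`` / ``basal_bound`` are the y coordinates (um) of the
    planes through the apical-most and basal-most focus.  The planes
    themselves belong to the central region, which is defined to contain
    all foci.
    """

    apical_bound: float
    basal_bound: float
    orientation: str = "apical_up"  # ventricular side at low y

    def __post_init__(self) -> None:
        if self.apical_bound > self.basal_bound:
            raise GeometryError("apical bound must be apical of the basal bound")

    def region_of_y(self, y: float, tol: float = 0.0) -> str:
        if y < self.apical_bound - tol:
            return "apical"
        if y > self.basal_bound + tol:
            return "basal"
        return "central"


@dataclass
class AstralSegment:
    """One detected astral: pole origin, far endpoint, cortex contact, region."""

    origin_pole: int
    endpoint_um: np.ndarray  # (y, x) in the coronal projection
    reaches_cortex: bool
    region: str


@dataclass
class AstralCensusResult:
    apical: int
    basal: int
    central: object  # int, or NOT_ASSESSED in Front view
    view: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.view == "front" and self.central != NOT_ASSESSED:
            raise GeometryError("central astrals are not assessed in Front view")


# ----------------------------------------------------------------------- foci
def detect_centromeric_foci(
    dna, plate_mask: np.ndarray, min_prominence: float = 30.0, min_distance: int = 3,
    spacing=None, smooth_px: float = 1.0,
) -> np.ndarray:
    """Peri/centromeric foci: local DNA maxima inside the plate mask with
    prominence over the plate's median intensity of at least
    ``min_prominence``, sorted along the apico-basal (y) axis.

    Returns points in um if ``spacing`` is given (taken from the stack when
    one is passed), else in voxel coordinates.
    """
    if isinstance(dna, ImageStack):
        spacing = dna.spacing if spacing is None else spacing
        dna = dna["dna"]
    raw = np.asarray(dna, dtype=float)
    plate_mask = np.asarray(plate_mask, dtype=bool)
    if raw.shape != plate_mask.shape:
        raise GeometryError("DNA image and plate mask shapes differ")
    img = raw
    if smooth_px > 0:
        sigma = (0, smooth_px, smooth_px) if raw.ndim == 3 else smooth_px
        img = ndimage.gaussian_filter(raw, sigma)
    baseline = float(np.median(img[plate_mask]))
    peaks = peak_local_max(
        img,
        min_distance=min_distance,
        labels=plate_mask.astype(int),
        threshold_abs=baseline + min_prominence,
        exclude_border=False,
    )
    if len(peaks) == 0:
        raise DetectionError("no centromeric foci detected: partition undefined")
    # smoothing biases peaks on intensity gradients (e.g. near the plate
    # rim); refine each to the raw-image argmax in a small neighbourhood
    refined = []
    half = (1, 2, 2) if raw.ndim == 3 else (2, 2)
    for p in peaks:
        lo = np.maximum(p - half, 0)
        hi = np.minimum(p + np.asarray(half) + 1, raw.shape)
        window = raw[tuple(slice(a, b) for a, b in zip(lo, hi))]
        refined.append(lo + np.unravel_index(np.argmax(window), window.shape))
    peaks = np.asarray(refined)
    y_axis = 0 if img.ndim == 2 else 1
    peaks = peaks[np.argsort(peaks[:, y_axis])]
    if spacing is not None:
        return (peaks + 0.5) * np.asarray(spacing)[-img.ndim:]
    return peaks


def partition_regions(
    foci_um: np.ndarray, surface: ApicalSurface, soma_mask: np.ndarray, spacing=None
) -> RegionPartition:
    """Partition planes through the apical-most and basal-most focus.

    The apical region runs from the ventricular surface to just before the
    apical-most focus, the basal region from just after the basal-most
    focus to the basal end of the soma, the central region (which owns both
    planes) lies between.  A focus outside the soma mask is an error.
    """
    foci_um = np.atleast_2d(np.asarray(foci_um, dtype=float))
    if len(foci_um) < 1:
        raise DetectionError("no foci: partition undefined")
    soma_mask = np.asarray(soma_mask, dtype=bool)
    if spacing is not None:
        idx = np.floor(foci_um / np.asarray(spacing)[-foci_um.shape[1]:]).astype(int)
        for i in idx:
            inside = soma_mask[tuple(np.clip(i, 0, np.array(soma_mask.shape) - 1))]
            if not inside or np.any(i < 0) or np.any(i >= soma_mask.shape):
                raise GeometryError("focus outside the soma mask")
    y = foci_um[:, -2]
    return RegionPartition(apical_bound=float(y.min()), basal_bound=float(y.max()))


# -------------------------------------------------------------------- astrals
def detect_poles(tubulin, plate_mask: np.ndarray, spacing=None) -> np.ndarray:
    """The two spindle poles: brightest tubulin maxima outside the plate."""
    if isinstance(tubulin, ImageStack):
        spacing = tubulin.spacing if spacing is None else spacing
        tubulin = tubulin["tubulin"]
    img = np.asarray(tubulin, dtype=float)
    plate_mask = np.asarray(plate_mask, bool)
    # dilate in-plane only: in a Side view the poles sit a few sections
    # above/below the plate disc at the same (y, x)
    structure = np.ones((1, 3, 3), bool) if plate_mask.ndim == 3 else np.ones((3, 3), bool)
    outside = ~ndimage.binary_dilation(plate_mask, structure=structure, iterations=3)
    peaks = peak_local_max(
        np.where(outside, img, 0.0), min_distance=2, num_peaks=2, exclude_border=False
    )
    if len(peaks) < 2:
        raise DetectionError("spindle poles not found")
    if spacing is not None:
        return (peaks + 0.5) * np.asarray(spacing)[-img.ndim:]
    return peaks.astype(float)


def _exclusion_core(plate2d, poles_px_yx, pole_radius_px: int) -> np.ndarray:
    """Central-spindle exclusion mask in the coronal projection: convex hull
    of plate and poles, plus pole discs, dilated a little for blur tails."""
    seed = np.asarray(plate2d, bool).copy()
    for p in poles_px_yx:
        y, x = int(round(p[0])), int(round(p[1]))
        if 0 <= y < seed.shape[0] and 0 <= x < seed.shape[1]:
            seed[y, x] = True
    core = convex_hull_image(seed)
    pole_disc = np.zeros_like(core)
    for p in poles_px_yx:
        y, x = int(round(p[0])), int(round(p[1]))
        yy, xx = np.ogrid[: core.shape[0], : core.shape[1]]
        pole_disc |= (yy - y) ** 2 + (xx - x) ** 2 <= pole_radius_px**2
    return ndimage.binary_dilation(core | pole_disc, structure=disk(1), iterations=4)


def detect_astrals(
    tubulin,
    poles_um: np.ndarray,
    soma_mask: np.ndarray,
    partition: RegionPartition,
    plate_mask: np.ndarray,
    spacing=None,
    delta_cortex_um: float = 1.0,
    threshold_fraction: float = 0.03,
    pole_exclusion_um: float = 2.0,
    min_rod_px: int = 4,
) -> list[AstralSegment]:
    """Detect astral rods in the coronal (z-maximum) projection.

    Above-threshold tubulin structures outside the central-spindle exclusion
    mask (convex hull of plate and poles plus pole neighbourhoods) are taken
    as astral rods; each connected component contributes one segment whose
    far endpoint is the component pixel farthest from the exclusion mask.
    A segment reaches the cortex when that endpoint lies within
    ``delta_cortex_um`` of the soma boundary; its region is the partition
    region of the endpoint's y coordinate (endpoints exactly on a partition
    plane count as central).
    """
    if isinstance(tubulin, ImageStack):
        spacing = tubulin.spacing if spacing is None else spacing
        tubulin = tubulin["tubulin"]
    if spacing is None:
        raise GeometryError("voxel spacing required")
    img = np.asarray(tubulin, dtype=float)
    soma_mask = np.asarray(soma_mask, bool)
    # light per-section smoothing before projection suppresses pixel noise
    if img.ndim == 3:
        img = ndimage.gaussian_filter(img, (0, 1.0, 1.0))
        proj = img.max(axis=0)
    else:
        proj = ndimage.gaussian_filter(img, 1.0)
    soma2d = soma_mask.any(axis=0) if soma_mask.ndim == 3 else soma_mask
    dy, dx = spacing[-2], spacing[-1]
    if abs(dy - dx) > 1e-9:
        raise GeometryError("anisotropic in-plane spacing is not supported")
    poles_um = np.atleast_2d(np.asarray(poles_um, dtype=float))
    if len(poles_um) != 2:
        raise DetectionError("poles not found")
    poles_px = poles_um[:, -2:] / dy - 0.5

    # baseline-aware threshold: the projection of a noisy stack sits on a
    # positive pedestal (max over sections of the noise)
    baseline = float(np.median(proj))
    thr = baseline + threshold_fraction * (proj.max() - baseline)
    fg = (proj > thr) & soma2d
    plate_mask = np.asarray(plate_mask, bool)
    plate2d = plate_mask.any(axis=0) if plate_mask.ndim == 3 else plate_mask
    core = _exclusion_core(plate2d, poles_px, int(round(pole_exclusion_um / dy)))

    rods = fg & ~core
    labels, n = ndimage.label(rods, structure=np.ones((3, 3), dtype=int))
    dist_to_core = ndimage.distance_transform_edt(~core)
    dist_to_outside = ndimage.distance_transform_edt(soma2d)
    segments: list[AstralSegment] = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        if len(ys) < min_rod_px:
            continue
        d_core = dist_to_core[ys, xs]
        if d_core.min() > 3.0:  # debris not attached to the spindle region
            continue
        tip = int(np.argmax(d_core))
        ty, tx = int(ys[tip]), int(xs[tip])
        endpoint_um = np.array([(ty + 0.5) * dy, (tx + 0.5) * dx])
        reach = float(dist_to_outside[ty, tx]) * dy <= delta_cortex_um
        origin = int(np.argmin(np.linalg.norm(poles_px - np.array([ys[np.argmin(d_core)], xs[np.argmin(d_core)]]), axis=1)))
        segments.append(
            AstralSegment(
                origin_pole=origin,
                endpoint_um=endpoint_um,
                reaches_cortex=bool(reach),
                region=partition.region_of_y(float(endpoint_um[0]), tol=0.5 * dy),
            )
        )
    return segments


# ---------------------------------------------------------------------- views
def classify_view(
    pole_positions_um: np.ndarray,
    section_spacing_um: float,
    theta_view_deg: float = 45.0,
    max_front_sections: int = 3,
) -> str:
    """Front if the pole-pole axis makes less than ``theta_view_deg`` with
    the sectioning plane AND spans at most ``max_front_sections`` confocal
    sections; otherwise Side.  An axis at exactly the threshold angle is
    Side (strict inequality)."""
    p = np.asarray(pole_positions_um, dtype=float).reshape(2, 3)
    dz = abs(p[1, 0] - p[0, 0])
    dxy = float(np.linalg.norm(p[1, 1:] - p[0, 1:]))
    angle = np.degrees(np.arctan2(dz, dxy))
    n_sections = int(np.floor(dz / section_spacing_um + 1e-9)) + 1
    if angle < theta_view_deg and n_sections <= max_front_sections:
        return "front"
    return "side"


# --------------------------------------------------------------------- census
def count_census(
    segments: list[AstralSegment], partition: RegionPartition, view: str
) -> AstralCensusResult:
    """Count cortex-reaching astrals per region.  Central counts are only
    reported from Side-view cells; Front views return ``not_assessed``."""
    reaching = [s for s in segments if s.reaches_cortex]
    counts = {r: sum(s.region == r for s in reaching) for r in ("apical", "basal", "central")}
    central = counts["central"] if view == "side" else NOT_ASSESSED
    return AstralCensusResult(
        apical=counts["apical"], basal=counts["basal"], central=central, view=view
    )


def bp_orient_census(
    segments: list[AstralSegment],
    soma_centroid_um,
    ventricle_direction=(-1.0, 0.0),
    sector_half_angle_deg: float = 45.0,
) -> dict[str, int]:
    """Orientation classes for basal progenitors (no surface contact).

    The endpoint direction from the soma centroid is binned into three
    sectors: apically oriented (within the half-angle of the ventricle
    direction), basally oriented (within the half-angle of the pial
    direction), centrally oriented otherwise.
    """
    v = np.asarray(ventricle_direction, dtype=float)
    v = v / np.linalg.norm(v)
    c = np.asarray(soma_centroid_um, dtype=float)
    out = {"apically_oriented": 0, "basally_oriented": 0, "centrally_oriented": 0}
    for s in segments:
        if not s.reaches_cortex:
            continue
        d = np.asarray(s.endpoint_um, float) - c
        nd = np.linalg.norm(d)
        if nd == 0:
            raise GeometryError("astral endpoint coincides with the centroid")
        cosang = float(np.clip(np.dot(d / nd, v), -1, 1))
        ang = np.degrees(np.arccos(cosang))
        if ang <= sector_half_angle_deg:
            out["apically_oriented"] += 1
        elif ang >= 180.0 - sector_half_angle_deg:
            out["basally_oriented"] += 1
        else:
            out["centrally_oriented"] += 1
    return out
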