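"""Cortical marker intensity profiling (the cortical-polarity assay).

The cortical level of a polarity factor such as LGN is quantified on a
single central optical section: intensities are read along the one-pixel
boundary chain of the cell soma, the diffuse cytoplasmic signal is
subtracted, and the corrected values are resampled by linear interpolation
to 100 equidistant positions on the normalized perimeter, starting at the
middle of the apical region and proceeding clockwise.  Profiles from cells
of different sizes are thereby directly comparable position by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import DetectionError, GeometryError

#: normalized arc positions of the 100 resampled profile values
PROFILE_POSITIONS = 0.005 + 0.01 * np.arange(100)

# clockwise Moore neighbourhood in (dy, dx), screen convention (y down)
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


@dataclass
class Contour:
    """Closed, one-pixel-wide, clockwise boundary chain of a soma mask.

    ``points`` are integer ``(y, x)`` voxel coordinates; the chain starts at
    the boundary point nearest the apical-domain midpoint and is implicitly
    closed (the last point connects back to the first).
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 3:
            raise GeometryError("contour needs >= 3 (y, x) points")

    def __len__(self) -> int:
        return len(self.points)

    def arc_positions(self) -> tuple[np.ndarray, float]:
        """Normalized arc position of each chain point and total length (px)."""
        pts = self.points.astype(float)
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        closing = np.linalg.norm(pts[0] - pts[-1])
        total = float(steps.sum() + closing)
        s = np.concatenate([[0.0], np.cumsum(steps)]) / total
        return s, total

    def sample(self, image: np.ndarray) -> np.ndarray:
        """Per-chain-point intensity values from a 2D image."""
        return np.asarray(image, dtype=float)[self.points[:, 0], self.points[:, 1]]


@dataclass
class CorticalProfile:
    """100 background-corrected intensities on the normalized perimeter."""

    positions: np.ndarray
    intensities: np.ndarray
    region_windows: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.positions) != 100 or len(self.intensities) != 100:
            raise GeometryError("a cortical profile has exactly 100 values")


def _is_clockwise(points: np.ndarray) -> bool:
    # screen convention (y down): visually clockwise <=> positive shoelace sum
    x, y = points[:, 1].astype(float), points[:, 0].astype(float)
    return float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)) > 0


def extract_contour(mask: np.ndarray, apical_midpoint) -> Contour:
    """Moore-neighbour boundary trace of a simply connected mask.

    The chain is oriented clockwise (coronal view, apical up) and rotated to
    start at the boundary point nearest ``apical_midpoint`` (``(y, x)``).
    Masks with holes or without interior are rejected.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise GeometryError("contour extraction expects a 2D mask")
    if not mask.any():
        raise DetectionError("empty mask")
    if ndimage.binary_fill_holes(mask).sum() != mask.sum():
        raise GeometryError("mask has holes")
    _, n = ndimage.label(mask)
    if n != 1:
        raise GeometryError("mask is not simply connected")
    if not ndimage.binary_erosion(mask).any():
        raise GeometryError("mask has no interior")

    padded = np.pad(mask, 1)
    ys, xs = np.nonzero(padded)
    start = (int(ys[0]), int(xs[0]))  # topmost, then leftmost
    chain = [start]
    # backtrack: the pixel we came from; for the scan start that is its left
    backtrack = (start[0], start[1] - 1)
    current = start
    first_move = None
    while True:
        idx = _MOORE.index((backtrack[0] - current[0], backtrack[1] - current[1]))
        nxt = None
        for k in range(1, 9):
            d = _MOORE[(idx + k) % 8]
            cand = (current[0] + d[0], current[1] + d[1])
            if padded[cand]:
                nxt = cand
                break
            backtrack = cand
        if nxt is None:  # isolated pixel; excluded earlier by interior check
            raise GeometryError("mask has no interior")
        move = (nxt[0] - current[0], nxt[1] - current[1])
        if nxt == start and first_move is not None and move == first_move:
            break
        if current == start and first_move is None:
            first_move = move
        current = nxt
        if current != chain[0]:
            chain.append(current)
        else:
            break
        if len(chain) > 8 * mask.size:
            raise GeometryError("boundary trace failed to close")

    points = np.asarray(chain, dtype=int) - 1  # undo padding
    # deduplicate revisited pixels (8-connected traces can touch twice)
    _, keep = np.unique(points, axis=0, return_index=True)
    points = points[np.sort(keep)]
    if not _is_clockwise(points):
        points = points[::-1]
    target = np.asarray(apical_midpoint, dtype=float)
    start_idx = int(np.argmin(np.linalg.norm(points - target, axis=1)))
    points = np.roll(points, -start_idx, axis=0)
    return Contour(points)


def apical_boundary_point(mask: np.ndarray, surface_y: float = 0.0) -> tuple[int, int]:
    """Boundary point of ``mask`` nearest the apical surface: minimal y,
    ties broken toward the mask's x centroid (the apical-domain midpoint)."""
    mask = np.asarray(mask, dtype=bool)
    boundary = mask & ~ndimage.binary_erosion(mask)
    ys, xs = np.nonzero(boundary)
    if len(ys) == 0:
        raise DetectionError("empty mask")
    cx = np.nonzero(mask)[1].mean()
    order = np.lexsort((np.abs(xs - cx), np.abs(ys - surface_y)))
    return int(ys[order[0]]), int(xs[order[0]])


def interior_mask(mask: np.ndarray, band_width: int = 3) -> np.ndarray:
    """Soma interior: the mask eroded by the expected cortical-band width."""
    interior = ndimage.binary_erosion(np.asarray(mask, bool), iterations=band_width)
    if not interior.any():
        raise GeometryError("eroded interior is empty")
    return interior


def subtract_cytoplasm(raw_values, image, interior) -> np.ndarray:
    """Background-correct cortical intensities.

    The diffuse cytoplasmic signal is estimated as the median intensity over
    the eroded soma interior (robust to the bright cortical band) and
    subtracted from the raw contour values; negatives are clipped to 0.
    """
    interior = np.asarray(interior, bool)
    if not interior.any():
        raise GeometryError("empty interior mask")
    background = float(np.median(np.asarray(image, float)[interior]))
    return np.clip(np.asarray(raw_values, dtype=float) - background, 0.0, None)


def resample_profile(values, contour: Contour, region_windows: dict | None = None,
                     meta: dict | None = None) -> CorticalProfile:
    """Linear interpolation of contour values at 100 equidistant normalized
    arc positions (s = 0.005, 0.015, ..., 0.995)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise GeometryError("need >= 2 contour values")
    if len(values) != len(contour):
        raise GeometryError("values and contour length mismatch")
    s, _ = contour.arc_positions()
    s_closed = np.concatenate([s, [1.0]])
    v_closed = np.concatenate([values, [values[0]]])
    intensities = np.interp(PROFILE_POSITIONS, s_closed, v_closed)
    if region_windows is None:
        region_windows = default_region_windows()
    return CorticalProfile(
        positions=PROFILE_POSITIONS.copy(),
        intensities=intensities,
        region_windows=region_windows,
        meta={"region_windows_source": "package defaults (boundaries not standardized)",
              **(meta or {})},
    )


def default_region_windows() -> dict[str, np.ndarray]:
    """Index windows on the 100-point profile.

    Apical is centred on s = 0 (the start), basal on s = 0.5 (the opposite
    cortex), the two central windows cover the flanks; the exact fractions
    are a package default and fully configurable.
    """
    idx = np.arange(100)
    return {
        "apical": idx[(idx < 10) | (idx >= 90)],
        "central_1": idx[(idx >= 10) & (idx < 40)],
        "basal": idx[(idx >= 40) & (idx < 60)],
        "central_2": idx[(idx >= 60) & (idx < 90)],
    }


def region_means(profile: CorticalProfile, windows: dict | None = None) -> dict[str, float]:
    """Mean corrected intensity per region window; the two central windows
    are reported separately and pooled.  Windows must partition 0..99."""
    windows = {k: np.asarray(v, dtype=int) for k, v in (windows or profile.region_windows).items()}
    flat = np.concatenate(list(windows.values()))
    if len(flat) != 100 or len(np.unique(flat)) != 100 or flat.min() != 0 or flat.max() != 99:
        raise GeometryError("region windows must partition indices 0..99")
    means = {name: float(profile.intensities[ix].mean()) for name, ix in windows.items()}
    central = [n for n in windows if n.startswith("central")]
    if central:
        pooled = np.concatenate([windows[n] for n in central])
        means["central_pooled"] = float(profile.intensities[pooled].mean())
    return means


def segment_soma(marker: np.ndarray) -> np.ndarray:
    """Soma mask from the cortical-marker channel.

    Otsu threshold (background vs cytoplasm), largest connected component,
    light closing against noise speckle, holes filled per section.
    """
    from skimage.filters import threshold_otsu

    img = np.asarray(marker, dtype=float)
    if img.max() <= 0:
        raise DetectionError("marker channel is empty")
    mask = img > threshold_otsu(img)
    if not mask.any():
        raise DetectionError("marker channel is empty")
    labels, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    # close and fill per section: z neighbours must not erode end sections
    structure = np.ones((3, 3), bool)
    if mask.ndim == 3:
        return np.stack(
            [
                ndimage.binary_fill_holes(
                    ndimage.binary_closing(m, structure=structure, iterations=2)
                )
                for m in mask
            ]
        )
    return ndimage.binary_fill_holes(
        ndimage.binary_closing(mask, structure=structure, iterations=2)
    )
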