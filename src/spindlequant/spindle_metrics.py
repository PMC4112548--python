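"""Spindle-integrity controls: region, area, intensity, texture, diameter.

These metrics verify that an experimental perturbation left the main
spindle itself untouched: the main spindle region (soma clipped to the band
between the extreme heterochromatin foci, extended to the two centrosome
neighbourhoods), its area averaged over the two central-most optical
sections, its mean fluorescence normalized to the whole image, the per-pixel
intensity SD normalized to the region mean, and the soma diameter along the
pole-pole axis (which also reports total spindle length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DetectionError, GeometryError


@dataclass
class MainSpindleRegion:
    """Voxel mask of the main spindle region plus its defining landmarks."""

    mask: np.ndarray  # (nz, ny, nx) bool
    pole_positions_um: np.ndarray
    foci_band_y_um: tuple
    spacing: tuple

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise GeometryError("empty main spindle region")


def main_spindle_region(
    soma_mask: np.ndarray,
    poles_um: np.ndarray,
    foci_um: np.ndarray,
    spacing,
    r_pole_um: float = 1.5,
) -> MainSpindleRegion:
    """Soma clipped to the y band between the apical- and basal-most focus
    (band inclusive of the foci planes), laterally extended by discs of
    radius ``r_pole_um`` around the two poles; always within the soma."""
    soma_mask = np.asarray(soma_mask, bool)
    poles_um = np.asarray(poles_um, dtype=float).reshape(2, 3)
    foci_um = np.atleast_2d(np.asarray(foci_um, dtype=float))
    if len(foci_um) < 1:
        raise DetectionError("need at least one focus")
    dz, dy, dx = spacing
    nz, ny, nx = soma_mask.shape
    for p in poles_um:
        idx = tuple(np.floor(p / np.asarray(spacing)).astype(int))
        if not (0 <= idx[0] < nz and 0 <= idx[1] < ny and 0 <= idx[2] < nx) or not soma_mask[idx]:
            raise GeometryError("pole outside the soma mask")
    y_lo, y_hi = float(foci_um[:, 1].min()), float(foci_um[:, 1].max())
    Y = (np.arange(ny) + 0.5) * dy
    band = (Y >= y_lo - 0.5 * dy) & (Y <= y_hi + 0.5 * dy)
    region = soma_mask & band[None, :, None]
    Z = (np.arange(nz) + 0.5)[:, None, None] * dz
    Yg = Y[None, :, None]
    X = (np.arange(nx) + 0.5)[None, None, :] * dx
    for p in poles_um:
        disc = (Z - p[0]) ** 2 + (Yg - p[1]) ** 2 + (X - p[2]) ** 2 <= r_pole_um**2
        region |= disc & soma_mask
    return MainSpindleRegion(
        mask=region,
        pole_positions_um=poles_um,
        foci_band_y_um=(y_lo, y_hi),
        spacing=tuple(spacing),
    )


def central_sections(region: MainSpindleRegion, n: int = 2) -> np.ndarray:
    """Indices of the ``n`` sections straddling the mask's z centroid."""
    per_z = region.mask.sum(axis=(1, 2)).astype(float)
    if per_z.sum() == 0:
        raise GeometryError("empty region")
    zc = float(np.average(np.arange(len(per_z)), weights=per_z))
    order = np.argsort(np.abs(np.arange(len(per_z)) - zc), kind="stable")
    chosen = [i for i in order if per_z[i] > 0][:n]
    return np.sort(np.asarray(chosen, dtype=int))


def spindle_area(region: MainSpindleRegion) -> float:
    """Region area (um^2): pixel count x pixel area, mean over the two
    central-most sections."""
    if not region.mask.any():
        return 0.0
    _, dy, dx = region.spacing
    secs = central_sections(region, n=2)
    return float(np.mean([region.mask[z].sum() for z in secs]) * dy * dx)


def normalized_mean_intensity(region: MainSpindleRegion, image: np.ndarray) -> float:
    """Mean intensity inside the region / mean intensity of the whole image."""
    image = np.asarray(image, dtype=float)
    whole = float(image.mean())
    if whole == 0:
        raise GeometryError("zero whole-image mean")
    return float(image[region.mask].mean()) / whole


def normalized_sd(region: MainSpindleRegion, image: np.ndarray) -> float:
    """Population SD of per-voxel intensities in the region, normalized to
    the region mean."""
    values = np.asarray(image, dtype=float)[region.mask]
    if values.size < 2:
        raise GeometryError("region needs >= 2 voxels")
    mean = float(values.mean())
    if mean == 0:
        raise GeometryError("zero region mean")
    return float(values.std(ddof=0)) / mean


def diameter_at_spindle_plane(
    soma_mask: np.ndarray, poles_um: np.ndarray, spacing, step_fraction: float = 0.25
) -> float:
    """Chord length (um) of the soma along the line through the two poles.

    The line is marched at sub-voxel steps; the chord is the contiguous
    inside run containing the pole-axis midpoint.  A line that misses the
    mask is an error.
    """
    soma_mask = np.asarray(soma_mask, bool)
    poles_um = np.asarray(poles_um, dtype=float).reshape(2, 3)
    spacing = np.asarray(spacing, dtype=float)
    direction = poles_um[1] - poles_um[0]
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise GeometryError("pole axis undefined")
    direction = direction / norm
    mid = poles_um.mean(axis=0)
    step = step_fraction * spacing.min()
    extent = float(np.linalg.norm(np.asarray(soma_mask.shape) * spacing))
    s = np.arange(-extent, extent, step)
    pts = mid[None, :] + s[:, None] * direction[None, :]
    idx = np.floor(pts / spacing).astype(int)
    valid = np.all((idx >= 0) & (idx < np.array(soma_mask.shape)), axis=1)
    inside = np.zeros(len(s), dtype=bool)
    inside[valid] = soma_mask[idx[valid, 0], idx[valid, 1], idx[valid, 2]]
    i_mid = int(np.searchsorted(s, 0.0))
    if not inside[i_mid]:
        raise GeometryError("pole axis misses the soma mask")
    lo = i_mid
    while lo > 0 and inside[lo - 1]:
        lo -= 1
    hi = i_mid
    while hi < len(s) - 1 and inside[hi + 1]:
        hi += 1
    return float(s[hi] - s[lo] + step)
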