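"""Chromosome-plate orientation: segmentation, signed angle, amplitude, bins.

The plate's orientation is measured per time point as the signed deviation of
its main axis from the local apico-basal axis (the normal to the nearest
apical-surface segment): 0 deg means the plate lies along the apico-basal
axis ("vertical", the canonical orientation of an apical progenitor in
metaphase), +/-90 deg means parallel to the ventricular surface.  The
per-cell summary statistic is the maximal amplitude of deviations — the
range (max - min) of the signed angle from metaphase to anaphase onset.

Tracks are additionally binned into the six colour categories used to
display orientation time courses: blue (beyond 30), cyan (30..15),
green (15..0), yellow (0..-15), red (-15..-30), dark_red (beyond -30).
Angles exactly on a bin edge belong to the bin closer to 0 deg; 0 deg
itself is assigned to green.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .exceptions import DetectionError, GeometryError
from .geometry import ApicalSurface, signed_axis_angle_deg
from .stacks import ImageStack

PHASES = ("prometaphase", "metaphase", "anaphase_onset")

TRACK_BINS = ("blue", "cyan", "green", "yellow", "red", "dark_red")


@dataclass
class PlateTrack:
    """Time series of signed plate-angle deviations for one mitosis.

    Times are in minutes with anaphase onset at t = 0 (the last sample).
    """

    times: np.ndarray
    angles_deg: np.ndarray
    phase: list[str] = field(default=None)
    anaphase_onset_time: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.phase is None:
            self.phase = ["metaphase"] * (len(self.times) - 1) + ["anaphase_onset"]
        if len(self.times) != len(self.angles_deg) or len(self.times) != len(self.phase):
            raise GeometryError("times, angles and phase labels must align")
        if np.any(np.diff(self.times) <= 0):
            raise GeometryError("times must be strictly increasing")
        if np.any(np.abs(self.angles_deg) > 90.0 + 1e-9):
            raise GeometryError("|angle| must be <= 90 deg")
        if self.phase.count("anaphase_onset") != 1 or self.phase[-1] != "anaphase_onset":
            raise GeometryError("exactly one anaphase_onset sample, the last")
        if any(p not in PHASES for p in self.phase):
            raise GeometryError(f"phase labels must be in {PHASES}")

    def metaphase_window(self) -> np.ndarray:
        """Angles of the samples labeled metaphase through anaphase onset."""
        sel = [p in ("metaphase", "anaphase_onset") for p in self.phase]
        return self.angles_deg[np.asarray(sel)]


# ----------------------------------------------------------------- segmentation
def segment_chromatin(dna, threshold_policy: str = "otsu", smooth_px: float = 1.0) -> np.ndarray:
    """Binary plate mask: the largest above-threshold connected component.

    Parameters
    ----------
    dna
        DNA-channel array (2D or 3D) or an :class:`ImageStack`.
    threshold_policy
        ``"otsu"`` (default) or ``"fraction:<f>"`` for a threshold at a
        fraction ``f`` of the image maximum.
    smooth_px
        In-plane Gaussian presmoothing (pixels) applied before
        thresholding, for robustness against pixel noise.
    """
    if isinstance(dna, ImageStack):
        dna = dna["dna"]
    img = np.asarray(dna, dtype=float)
    if img.max() <= 0:
        raise DetectionError("no chromatin detected: image is empty")
    if smooth_px > 0:
        sigma = (0, smooth_px, smooth_px) if img.ndim == 3 else smooth_px
        img = ndimage.gaussian_filter(img, sigma)
    if threshold_policy == "otsu":
        thr = threshold_otsu(img)
    elif threshold_policy.startswith("fraction:"):
        thr = float(threshold_policy.split(":", 1)[1]) * img.max()
    else:
        raise ValueError(f"unknown threshold policy {threshold_policy!r}")
    binary = img > thr
    labels, n = ndimage.label(binary)
    if n == 0:
        raise DetectionError("no chromatin detected: empty mask after threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def plate_axis_angle(mask: np.ndarray, surface: ApicalSurface, spacing_yx=(1.0, 1.0)) -> float:
    """Signed deviation (deg) of the plate's main axis from the apico-basal axis.

    The main axis is the principal axis of the second-order central moments
    of a maximum-intensity projection of the mask (2D analysis in the
    coronal plane, as orientation is assessed in coronal view).  The
    apico-basal reference is the inward normal of the nearest surface
    segment.  Raises on an empty or isotropic mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 3:
        mask = mask.any(axis=0)
    if not mask.any():
        raise DetectionError("empty plate mask")
    ys, xs = np.nonzero(mask)
    pts = np.stack([ys * spacing_yx[0], xs * spacing_yx[1]], axis=1)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or (evals[-1] - evals[0]) / evals[-1] < 1e-6:
        raise GeometryError("axis undefined: isotropic plate mask")
    main_axis = evecs[:, -1]  # (y, x), largest eigenvalue
    normal = surface.inward_normal(centroid)
    return signed_axis_angle_deg(main_axis, normal)


# ------------------------------------------------------------------- statistics
def track_amplitude(track: PlateTrack) -> float:
    """Maximal amplitude of deviations: max - min of the signed angle over
    the metaphase-to-anaphase-onset window."""
    window = track.metaphase_window()
    if len(window) < 2:
        raise GeometryError("metaphase window shorter than 2 samples")
    return float(window.max() - window.min())


def _bin_angle(angle: float) -> str:
    # edges owned by the bin closer to 0; 0 itself is green
    if angle > 30.0:
        return "blue"
    if angle > 15.0:
        return "cyan"
    if angle >= 0.0:
        return "green"
    if angle >= -15.0:
        return "yellow"
    if angle >= -30.0:
        return "red"
    return "dark_red"


def classify_track(track: PlateTrack) -> str:
    """Colour category of a track: the bin holding most samples; ties are
    broken toward the bin containing the metaphase-window median angle."""
    if len(track.angles_deg) == 0:
        raise GeometryError("empty track")
    bins = [_bin_angle(a) for a in track.angles_deg]
    counts = {b: bins.count(b) for b in set(bins)}
    best = max(counts.values())
    tied = [b for b, c in counts.items() if c == best]
    if len(tied) == 1:
        return tied[0]
    window = track.metaphase_window()
    if len(window) == 0:
        window = track.angles_deg
    median_bin = _bin_angle(float(np.median(window)))
    if median_bin in tied:
        return median_bin
    # median bin not among the tied bins: pick the tied bin nearest it
    order = list(TRACK_BINS)
    return min(tied, key=lambda b: abs(order.index(b) - order.index(median_bin)))
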