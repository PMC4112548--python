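"""Plate segmentation, the signed-angle measurement, amplitude and binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from spindlequant.exceptions import DetectionError, GeometryError
from spindlequant.geometry import ApicalSurface
from spindlequant.plate_orientation import (
    PlateTrack,
    classify_track,
    plate_axis_angle,
    segment_chromatin,
    track_amplitude,
)


def _elongated_mask(angle_deg, shape=(201, 201), length=60, width=10):
    """Binary bar rotated to a given signed deviation from vertical."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    cy, cx = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    t = np.radians(angle_deg)
    # round away float residue so axis-aligned bars are exact rectangles
    u = np.round(np.array([np.cos(t), -np.sin(t)]), 12)  # (y, x) axis direction
    v = np.array([u[1], -u[0]])
    d = np.stack([yy - cy, xx - cx], axis=-1)
    along = d @ u
    across = d @ v
    return (np.abs(along) <= length / 2) & (np.abs(across) <= width / 2)


class TestSegmentation:
    def test_largest_component_is_returned(self):
        img = np.zeros((40, 40))
        img[5:8, 5:8] = 10.0  # 9 px
        img[20:32, 20:32] = 10.0  # 144 px
        mask = segment_chromatin(img, threshold_policy="fraction:0.5")
        assert mask[25, 25] and not mask[6, 6]

    def test_empty_image_raises(self):
        with pytest.raises(DetectionError, match="no chromatin"):
            segment_chromatin(np.zeros((10, 10)))

    def test_noise_free_plate_mask_matches_rendered_support(self, front_cell):
        stack, gt = front_cell
        mask = segment_chromatin(stack)
        truth = gt.plate_mask
        dilated = np.stack([ndimage.binary_dilation(m) for m in truth])
        # mask within one dilation of the rendered plate, and covers most of it
        assert not (mask & ~dilated).any()
        assert (mask & truth).sum() / truth.sum() > 0.7


class TestAngle:
    surface = ApicalSurface.horizontal(0.0, 0.0, 201.0)

    def test_mask_along_surface_normal_reads_zero(self):
        assert plate_axis_angle(_elongated_mask(0.0), self.surface) == pytest.approx(
            0.0, abs=0.5
        )

    def test_mask_parallel_to_surface_reads_ninety(self):
        assert abs(plate_axis_angle(_elongated_mask(90.0), self.surface)) == pytest.approx(
            90.0, abs=0.5
        )

    @pytest.mark.parametrize("angle", [-60, -40, -17, 17, 40, 60])
    def test_signed_recovery_of_rotated_bars(self, angle):
        assert plate_axis_angle(_elongated_mask(angle), self.surface) == pytest.approx(
            angle, abs=0.5
        )

    @pytest.mark.parametrize("phi", [-35.0, 20.0, 50.0])
    def test_rotation_equivariance_of_mask_and_surface(self, phi):
        # rotate bar and surface jointly: the reported deviation is unchanged
        base = plate_axis_angle(_elongated_mask(10.0), self.surface)
        c = np.array([100.0, 100.0])
        t = np.radians(phi)
        rot = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
        surf_pts = (np.array([[-40.0, 0.0], [-40.0, 200.0]]) - c) @ rot.T + c
        rotated = plate_axis_angle(
            _elongated_mask(10.0 + phi), ApicalSurface(surf_pts)
        )
        assert rotated == pytest.approx(base, abs=0.5)

    def test_isotropic_mask_is_rejected(self):
        yy, xx = np.mgrid[:41, :41]
        disc = (yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2
        with pytest.raises(GeometryError, match="axis undefined"):
            plate_axis_angle(disc, self.surface)

    def test_synthetic_cell_angle_recovered_within_one_degree(self, front_cell):
        stack, gt = front_cell
        mask = segment_chromatin(stack)
        surface = ApicalSurface.horizontal(0.0, 0.0, 18.0)
        angle = plate_axis_angle(mask, surface, stack.spacing[1:])
        assert angle == pytest.approx(gt.plate_angle_deg, abs=1.0)


class TestAmplitude:
    def _track(self, angles, dt=3.0):
        n = len(angles)
        return PlateTrack(times=np.arange(n) * dt - (n - 1) * dt, angles_deg=angles)

    def test_constant_track_has_zero_amplitude(self):
        assert track_amplitude(self._track([12.0] * 5)) == 0.0

    def test_amplitude_is_range_of_the_window(self):
        assert track_amplitude(self._track([-5.0, 3.0, 10.0])) == 15.0

    def test_amplitude_equals_brute_force_max_minus_min(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            angles = rng.uniform(-90, 90, size=rng.integers(2, 40))
            track = self._track(angles)
            assert track_amplitude(track) == angles.max() - angles.min()

    @given(
        st.lists(st.floats(-80, 80), min_size=2, max_size=30),
        st.floats(-10, 10),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_amplitude_invariant_to_offset_and_time_reversal(self, angles, offset):
        angles = np.asarray(angles)
        if np.any(np.abs(angles + offset) > 90):
            return
        base = track_amplitude(self._track(angles))
        assert track_amplitude(self._track(angles + offset)) == pytest.approx(base)
        assert track_amplitude(self._track(angles[::-1])) == pytest.approx(base)

    def test_single_sample_window_raises(self):
        track = PlateTrack(
            times=[0.0, 3.0],
            angles_deg=[1.0, 2.0],
            phase=["prometaphase", "anaphase_onset"],
        )
        with pytest.raises(GeometryError):
            track_amplitude(track)

    def test_prometaphase_samples_are_excluded_from_the_window(self):
        track = PlateTrack(
            times=[0, 3, 6, 9],
            angles_deg=[80.0, 1.0, 3.0, 2.0],
            phase=["prometaphase", "metaphase", "metaphase", "anaphase_onset"],
        )
        assert track_amplitude(track) == 2.0


class TestTrackCategories:
    def _track(self, angles):
        n = len(angles)
        return PlateTrack(times=np.arange(n, dtype=float), angles_deg=angles)

    @pytest.mark.parametrize(
        "level, category",
        [(20.0, "cyan"), (-40.0, "dark_red"), (35.0, "blue"), (-20.0, "red"), (5.0, "green"), (-5.0, "yellow")],
    )
    def test_constant_tracks_land_in_their_range(self, level, category):
        assert classify_track(self._track([level] * 4)) == category

    def test_majority_bin_wins(self):
        assert classify_track(self._track([2.0, 4.0, 20.0])) == "green"

    @pytest.mark.parametrize(
        "edge, category",
        [(15.0, "green"), (30.0, "cyan"), (-15.0, "yellow"), (-30.0, "red"), (0.0, "green")],
    )
    def test_bin_edges_belong_to_the_bin_closer_to_zero(self, edge, category):
        assert classify_track(self._track([edge] * 3)) == category

    def test_tie_broken_toward_the_median_bin(self):
        # two green, two cyan; window median 12 lies in green
        assert classify_track(self._track([2.0, 4.0, 20.0, 25.0])) == "green"


def test_track_invariants_enforced():
    with pytest.raises(GeometryError):
        PlateTrack(times=[0.0, 0.0], angles_deg=[0.0, 1.0])
    with pytest.raises(GeometryError):
        PlateTrack(times=[0.0, 1.0], angles_deg=[0.0, 95.0])
    with pytest.raises(GeometryError):
        PlateTrack(
            times=[0.0, 1.0], angles_deg=[0.0, 1.0], phase=["metaphase", "metaphase"]
        )
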