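"""Foci detection, region partition, astral detection, views and censuses."""

import numpy as np
import pytest
from scipy import ndimage

from spindlequant.astral_census import (
    NOT_ASSESSED,
    AstralSegment,
    RegionPartition,
    bp_orient_census,
    classify_view,
    count_census,
    detect_astrals,
    detect_centromeric_foci,
    detect_poles,
    partition_regions,
)
from spindlequant.cortical_profile import segment_soma
from spindlequant.exceptions import DetectionError, GeometryError
from spindlequant.geometry import ApicalSurface
from spindlequant.plate_orientation import segment_chromatin
from spindlequant.synthetic import make_mitotic_cell, side_view_cell

SURFACE = ApicalSurface.horizontal(0.0, 0.0, 18.0)


def _measure(stack):
    plate = segment_chromatin(stack)
    soma = segment_soma(stack["cortical_marker"])
    foci = detect_centromeric_foci(stack, plate)
    partition = partition_regions(foci, SURFACE, soma, spacing=stack.spacing)
    poles = detect_poles(stack, plate)
    segments = detect_astrals(stack, poles, soma, partition, plate)
    return plate, soma, foci, partition, poles, segments


class TestFoci:
    def test_all_rendered_foci_found_within_one_voxel(self, side_cell):
        stack, gt = side_cell
        plate = segment_chromatin(stack)
        foci = detect_centromeric_foci(stack, plate)
        assert len(foci) == len(gt.foci_um)
        truth = gt.foci_um[np.argsort(gt.foci_um[:, 1])]
        np.testing.assert_allclose(foci[:, 1:], truth[:, 1:], atol=0.1)

    def test_uniform_plate_has_no_foci(self):
        img = np.zeros((3, 30, 30))
        img[1, 5:25, 5:25] = 100.0
        mask = img > 50
        with pytest.raises(DetectionError, match="no centromeric foci"):
            detect_centromeric_foci(img, mask)

    def test_heavy_blur_never_overdetects(self):
        rng = np.random.default_rng(9)
        spec = side_view_cell(rng, n_apical=2, n_basal=2, n_central=2, psf_sigma=0.2)
        stack, gt = make_mitotic_cell(spec, seed=9)
        plate = segment_chromatin(stack)
        foci = detect_centromeric_foci(stack, plate)
        assert 1 <= len(foci) <= len(gt.foci_um)


class TestPartition:
    def test_bounds_are_the_extreme_foci_planes(self, side_cell):
        stack, gt = side_cell
        _, _, foci, partition, _, _ = _measure(stack)
        assert partition.apical_bound == pytest.approx(gt.partition_y_um[0], abs=0.1)
        assert partition.basal_bound == pytest.approx(gt.partition_y_um[1], abs=0.1)

    def test_partition_plane_points_are_central(self):
        p = RegionPartition(apical_bound=3.0, basal_bound=8.0)
        assert p.region_of_y(3.0) == "central"
        assert p.region_of_y(8.0) == "central"
        assert p.region_of_y(2.99) == "apical"
        assert p.region_of_y(8.01) == "basal"

    def test_single_focus_gives_one_plane_thick_central_region(self):
        p = RegionPartition(apical_bound=5.0, basal_bound=5.0)
        assert p.region_of_y(5.0) == "central"
        assert p.region_of_y(4.9) == "apical"
        assert p.region_of_y(5.1) == "basal"

    def test_focus_outside_soma_is_rejected(self):
        soma = np.zeros((3, 20, 20), bool)
        soma[1, 5:15, 5:15] = True
        with pytest.raises(GeometryError, match="outside"):
            partition_regions(
                np.array([[1.0, 1.0, 1.0]]), SURFACE, soma, spacing=(1, 1, 1)
            )

    def test_region_oracle_matches_brute_force_voxel_labels(self):
        # voxel-wise labeling by the two planes vs RegionPartition.region_of_y
        rng = np.random.default_rng(4)
        for _ in range(100):
            y_ap, span = rng.uniform(2, 6), rng.uniform(0.5, 5)
            p = RegionPartition(apical_bound=y_ap, basal_bound=y_ap + span)
            ys = rng.uniform(0, 14, size=200)
            brute = np.where(
                ys < y_ap, "apical", np.where(ys > y_ap + span, "basal", "central")
            )
            ours = np.array([p.region_of_y(float(y)) for y in ys])
            assert (brute == ours).all()


class TestDetection:
    def test_noise_free_recovery_is_exact(self, side_cell):
        stack, gt = side_cell
        *_, partition, poles, segments = _measure(stack)
        reaching = [s for s in segments if s.reaches_cortex]
        counts = {
            r: sum(s.region == r for s in reaching)
            for r in ("apical", "basal", "central")
        }
        assert counts == gt.census

    def test_short_astral_is_excluded_by_the_cortex_rule(self):
        rng = np.random.default_rng(21)
        spec = side_view_cell(rng, n_apical=2, n_basal=2, n_central=2)
        # one extra rod stopping at 70% of the pole-cortex distance
        from spindlequant.synthetic import front_view_cell

        spec_f = front_view_cell(
            rng, n_apical=2, n_basal=2, n_central=0, n_nonreaching=1
        )
        stack, gt = make_mitotic_cell(spec_f, seed=21)
        *_, segments = _measure(stack)
        reaching = [s for s in segments if s.reaches_cortex]
        stopped = [s for s in segments if not s.reaches_cortex]
        assert len(reaching) == 4
        assert len(stopped) >= 1

    def test_poles_recovered_at_rendered_positions(self, side_cell):
        stack, gt = side_cell
        plate = segment_chromatin(stack)
        poles = detect_poles(stack, plate)
        truth = gt.pole_positions_um
        d = min(
            np.abs(poles - truth).max(), np.abs(poles[::-1] - truth).max()
        )
        assert d < 0.5

    def test_noisy_recovery_within_one_per_region(self, noisy_side_cell):
        stack, gt = noisy_side_cell
        *_, segments = _measure(stack)
        reaching = [s for s in segments if s.reaches_cortex]
        for region in ("apical", "basal", "central"):
            got = sum(s.region == region for s in reaching)
            assert abs(got - gt.census[region]) <= 1


class TestView:
    def test_in_plane_axis_single_section_is_front(self):
        poles = np.array([[1.0, 5.0, 2.0], [1.0, 5.0, 8.0]])
        assert classify_view(poles, 0.75) == "front"

    def test_axis_along_optical_axis_is_side(self):
        poles = np.array([[0.5, 5.0, 5.0], [5.0, 5.0, 5.0]])
        assert classify_view(poles, 0.75) == "side"

    def test_exactly_forty_five_degrees_is_side(self):
        poles = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 2.0]])
        assert classify_view(poles, 10.0) == "side"  # angle == threshold

    def test_shallow_axis_spanning_many_sections_is_side(self):
        poles = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 8.0]])
        assert classify_view(poles, 0.75) == "side"  # 21 deg but 5 sections


class TestCensus:
    def _segments(self):
        segs = []
        for region, n in (("apical", 5), ("basal", 6), ("central", 9)):
            y = {"apical": 1.0, "basal": 10.0, "central": 5.0}[region]
            segs += [
                AstralSegment(0, np.array([y, float(i)]), True, region)
                for i in range(n)
            ]
        return segs

    def test_side_view_reports_all_three_regions(self):
        partition = RegionPartition(3.0, 8.0)
        res = count_census(self._segments(), partition, "side")
        assert (res.apical, res.basal, res.central) == (5, 6, 9)

    def test_front_view_suppresses_central(self):
        res = count_census(self._segments(), RegionPartition(3.0, 8.0), "front")
        assert (res.apical, res.basal) == (5, 6)
        assert res.central == NOT_ASSESSED

    def test_empty_segment_list(self):
        res = count_census([], RegionPartition(3.0, 8.0), "side")
        assert (res.apical, res.basal, res.central) == (0, 0, 0)

    def test_census_conservation(self, side_cell):
        stack, _ = side_cell
        *_, partition, _, segments = _measure(stack)
        res = count_census(segments, partition, "side")
        n_reaching = sum(s.reaches_cortex for s in segments)
        assert res.apical + res.basal + res.central == n_reaching


class TestBPOrientation:
    def test_endpoint_toward_ventricle_is_apically_oriented(self):
        seg = AstralSegment(0, np.array([0.0, 5.0]), True, "central")
        out = bp_orient_census([seg], soma_centroid_um=(5.0, 5.0))
        assert out["apically_oriented"] == 1

    def test_endpoint_perpendicular_is_centrally_oriented(self):
        seg = AstralSegment(0, np.array([5.0, 10.0]), True, "central")
        out = bp_orient_census([seg], soma_centroid_um=(5.0, 5.0))
        assert out["centrally_oriented"] == 1

    def test_sector_counts_match_brute_force_assignment(self):
        rng = np.random.default_rng(11)
        c = np.array([6.0, 6.0])
        segs = []
        expected = {"apically_oriented": 0, "basally_oriented": 0, "centrally_oriented": 0}
        for _ in range(400):
            phi = rng.uniform(0, 2 * np.pi)
            end = c + 5.0 * np.array([-np.cos(phi), np.sin(phi)])
            segs.append(AstralSegment(0, end, True, "central"))
            ang = np.degrees(
                np.arccos(np.clip(np.dot((end - c) / 5.0, [-1.0, 0.0]), -1, 1))
            )
            if ang <= 45:
                expected["apically_oriented"] += 1
            elif ang >= 135:
                expected["basally_oriented"] += 1
            else:
                expected["centrally_oriented"] += 1
        assert bp_orient_census(segs, c) == expected
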