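"""Generator contracts: determinism, ground-truth consistency, trajectories,
tissue scenes."""

import numpy as np
import pytest

from spindlequant.exceptions import GeometryError
from spindlequant.plate_orientation import track_amplitude
from spindlequant.synthetic import (
    AstralSpec,
    CellSpec,
    Nucleus,
    TissueSpec,
    TrajectoryParams,
    front_view_cell,
    make_mitotic_cell,
    make_tissue_scene,
    sample_tissue_spec,
    side_view_cell,
    simulate_plate_trajectory,
)


def _bare_spec(**kw):
    rng = np.random.default_rng(0)
    return front_view_cell(rng, n_apical=0, n_basal=0, n_central=0, **kw)


class TestMitoticCell:
    def test_same_spec_and_seed_give_voxel_identical_stacks(self):
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        s1 = side_view_cell(rng1, noise=(8.0, 10.0))
        s2 = side_view_cell(rng2, noise=(8.0, 10.0))
        a, _ = make_mitotic_cell(s1, seed=7)
        b, _ = make_mitotic_cell(s2, seed=7)
        for role in a.channels:
            np.testing.assert_array_equal(a[role], b[role])

    def test_zero_astrals_zero_noise_leaves_background_empty(self):
        stack, gt = make_mitotic_cell(_bare_spec(), seed=0)
        tub = stack["tubulin"]
        # outside a comfortable margin around spindle + poles, nothing is lit
        from scipy import ndimage

        near = ndimage.binary_dilation(gt.spindle_mask, iterations=12)
        for p in gt.pole_positions_um:
            idx = np.floor(p / np.asarray(stack.spacing)).astype(int)
            near[
                max(idx[0] - 2, 0) : idx[0] + 3,
                max(idx[1] - 12, 0) : idx[1] + 13,
                max(idx[2] - 12, 0) : idx[2] + 13,
            ] = True
        # tails of the PSF / pole spots are below 0.01% of any structure level
        assert tub[~near].max() < 1e-2

    def test_ground_truth_census_echoes_the_requested_counts(self):
        rng = np.random.default_rng(1)
        spec = side_view_cell(rng, n_apical=5, n_basal=6, n_central=9)
        _, gt = make_mitotic_cell(spec, seed=1)
        assert gt.census == {"apical": 5, "basal": 6, "central": 9}

    def test_foci_peaks_are_brighter_than_any_other_dna_voxel(self):
        stack, gt = make_mitotic_cell(_bare_spec(), seed=0)
        dna = stack["dna"]
        foci_idx = np.floor(gt.foci_um / np.asarray(stack.spacing)).astype(int)
        foci_vals = dna[foci_idx[:, 0], foci_idx[:, 1], foci_idx[:, 2]]
        plate_only = dna.copy()
        for i in foci_idx:  # blank small neighbourhoods around each focus
            plate_only[i[0] - 1 : i[0] + 2, i[1] - 6 : i[1] + 7, i[2] - 6 : i[2] + 7] = 0
        assert foci_vals.min() > plate_only.max()

    def test_astral_through_plate_envelope_is_rejected(self):
        spec = _bare_spec()
        # aim an astral from one pole straight through the plate centre
        pole = spec.pole_positions[0]
        through = np.asarray(spec.center) - pole
        spec.astral_spec = [AstralSpec(0, through, True, "central")]
        with pytest.raises(GeometryError, match="plate envelope"):
            make_mitotic_cell(spec, seed=0)

    def test_inconsistent_region_label_is_rejected(self):
        rng = np.random.default_rng(3)
        spec = side_view_cell(rng, n_apical=1, n_basal=0, n_central=0)
        spec.astral_spec[0].region_label = "basal"  # truth says apical
        with pytest.raises(GeometryError, match="partition"):
            make_mitotic_cell(spec, seed=0)

    def test_foci_outside_plate_envelope_rejected(self):
        spec = _bare_spec()
        with pytest.raises(GeometryError, match="plate envelope"):
            CellSpec(
                soma_axes=spec.soma_axes,
                pole_positions=spec.pole_positions,
                plate_angle_deg=0.0,
                n_foci=1,
                foci_positions=np.asarray(spec.center) + np.array([0, 0, 5.0]),
                shape=spec.shape,
                center=spec.center,
            )


class TestTrajectory:
    def test_zero_noise_keeps_the_plate_at_zero(self):
        track = simulate_plate_trajectory(TrajectoryParams(noise_sd=0.0, seed=1))
        assert np.all(track.angles_deg == 0.0)
        assert track_amplitude(track) == 0.0

    def test_phase_labels_and_time_convention(self):
        track = simulate_plate_trajectory(TrajectoryParams(dt=3.0, duration=30.0, seed=0))
        assert track.phase[-1] == "anaphase_onset"
        assert track.phase[:-1] == ["metaphase"] * (len(track.phase) - 1)
        assert track.times[-1] == 0.0
        assert track.times[0] == -30.0

    def test_more_polar_anchors_give_lower_mean_amplitude(self):
        amps = {}
        for n_anchors in (7, 12):
            amps[n_anchors] = np.mean(
                [
                    track_amplitude(
                        simulate_plate_trajectory(
                            TrajectoryParams(n_anchors_polar=n_anchors, seed=s)
                        )
                    )
                    for s in range(500)
                ]
            )
        assert amps[12] < amps[7]

    def test_zero_anchors_diffuse_with_variance_proportional_to_time(self):
        # pure diffusion: Var[theta(t)] = noise_sd^2 * t
        finals = {}
        for duration in (12.0, 48.0):
            vals = [
                simulate_plate_trajectory(
                    TrajectoryParams(
                        n_anchors_polar=0,
                        n_anchors_central=0,
                        noise_sd=2.0,
                        dt=3.0,
                        duration=duration,
                        seed=s,
                    )
                ).angles_deg[-1]
                for s in range(800)
            ]
            finals[duration] = np.var(vals)
        assert finals[48.0] / finals[12.0] == pytest.approx(4.0, rel=0.25)

    def test_invalid_params_raise(self):
        with pytest.raises(GeometryError):
            TrajectoryParams(n_anchors_polar=-1)
        with pytest.raises(GeometryError):
            TrajectoryParams(dt=0.0)


class TestTissueScene:
    def test_ground_truth_rates_are_exact_by_construction(self):
        nuclei = [
            Nucleus(i + 1, 5.0, 10.0 + 12.0 * i, "VZ", frozenset({"PH3"}))
            for i in range(8)
        ]
        spec = TissueSpec(
            apical_surface_length=100.0,
            pial_surface_length=100.0,
            vz_svz_boundary_y=60.0,
            svz_cp_boundary_y=90.0,
            tissue_height_um=120.0,
            nuclei=nuclei,
        )
        _, table, gt = make_tissue_scene(spec)
        assert gt.mitoses_per_100um["VZ"] == 8.0
        assert gt.mitoses_per_100um["all"] == 8.0
        assert len(table) == 8

    def test_empty_scene_has_all_zero_censuses(self):
        spec = TissueSpec(100.0, 100.0, 60.0, 90.0, 120.0, nuclei=[])
        _, table, gt = make_tissue_scene(spec)
        assert len(table) == 0
        assert gt.mitoses_per_100um["all"] == 0.0
        assert gt.neurons_per_100um_pial == 0.0
        assert gt.apoptotic_per_10000um2 == 0.0

    def test_tbr2_fraction_matches_construction(self):
        nuclei = [
            Nucleus(
                i + 1,
                5.0 + 3.0 * i,
                10.0 + 10.0 * i,
                "VZ",
                frozenset({"Tbr2"}) if i < 4 else frozenset({"Pax6"}),
            )
            for i in range(10)
        ]
        spec = TissueSpec(120.0, 120.0, 60.0, 90.0, 120.0, nuclei=nuclei)
        _, _, gt = make_tissue_scene(spec)
        assert gt.newborn_bp_fraction_vz_pct == 40.0
        assert gt.ap_fraction_vz_pct == 60.0

    def test_zone_position_mismatch_is_rejected(self):
        bad = [Nucleus(1, 70.0, 10.0, "VZ", frozenset())]  # y=70 is SVZ
        with pytest.raises(GeometryError, match="inconsistent"):
            TissueSpec(100.0, 100.0, 60.0, 90.0, 120.0, nuclei=bad)

    def test_overcrowded_scene_is_rejected(self):
        nuclei = [
            Nucleus(i + 1, 5.0, 10.0 + 0.5 * i, "VZ", frozenset()) for i in range(10)
        ]
        spec = TissueSpec(100.0, 100.0, 60.0, 90.0, 120.0, nuclei=nuclei)
        with pytest.raises(GeometryError, match="density"):
            make_tissue_scene(spec)

    def test_sampled_conditions_shift_the_progenitor_balance(self):
        rng = np.random.default_rng(0)
        ctrl = sample_tissue_spec(rng, "control", seed=1)
        noc = sample_tissue_spec(rng, "nocodazole", seed=2)
        _, _, gt_c = make_tissue_scene(ctrl)
        _, _, gt_n = make_tissue_scene(noc)
        assert gt_n.newborn_bp_fraction_vz_pct > gt_c.ap_fraction_vz_pct - 60
        assert gt_n.mitoses_per_100um["SVZ"] > gt_c.mitoses_per_100um["SVZ"]
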