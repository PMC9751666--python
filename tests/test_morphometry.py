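import numpy as np
import pytest
from skimage import measure

from osteorad import morphometry as morph
from osteorad import synthetic_data as synth
from osteorad.morphometry import (
    BinaryVolume,
    DensityCalibration,
    GrayVolume,
    MorphometryError,
    VoiSpec,
)

from conftest import betti_numbers_oracle, euler_characteristic_oracle


class TestPreprocessing:
    def test_median_filter_constant_volume_unchanged(self):
        vol = GrayVolume(np.full((8, 8, 8), 7.0), 10.0)
        assert np.array_equal(morph.median_filter_3d(vol).voxels, vol.voxels)

    def test_median_filter_removes_impulse(self):
        data = np.zeros((11, 11, 11))
        data[5, 5, 5] = 100.0
        out = morph.median_filter_3d(GrayVolume(data, 10.0))
        assert out.voxels[5, 5, 5] == 0.0

    def test_median_filter_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(9, 9, 9))
        out = morph.median_filter_3d(GrayVolume(data, 10.0)).voxels
        padded = np.pad(data, 2, mode="symmetric")  # scipy's "reflect"
        for idx in [(2, 3, 4), (4, 4, 4), (0, 0, 0), (8, 8, 8)]:
            z, y, x = idx
            hood = padded[z : z + 5, y : y + 5, x : x + 5]
            assert out[idx] == pytest.approx(np.median(hood))

    def test_threshold_calibration_mapping(self):
        # phantoms: gray 100 -> 0 mg/cm^3, gray 1100 -> 1000 mg/cm^3,
        # so gray 434 maps exactly to the 334 threshold
        cal = DensityCalibration.from_pairs([(100.0, 0.0), (1100.0, 1000.0)])
        vol = GrayVolume(np.array([[[433.9, 434.0, 500.0]]]), 10.0)
        mask = morph.threshold_density(vol, cal)
        assert mask.mask.tolist() == [[[False, True, True]]]

    def test_threshold_all_air(self):
        cal = DensityCalibration(1.0, 0.0)
        vol = GrayVolume(np.zeros((4, 4, 4)), 10.0)
        assert not morph.threshold_density(vol, cal).mask.any()

    def test_inclusive_boundary(self):
        cal = DensityCalibration(1.0, 0.0)
        vol = GrayVolume(np.full((2, 2, 2), 334.0), 10.0)
        assert morph.threshold_density(vol, cal).mask.all()

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(MorphometryError):
            DensityCalibration(0.0, 0.0)


class TestVoiSelection:
    def test_trabecular_slab_arithmetic(self):
        # 10 um voxels: offset 0.5 mm -> 50 slices, height 1.0 mm -> 100
        mask = BinaryVolume(np.zeros((400, 4, 4), bool), 10.0)
        spec = VoiSpec("trabecular_metaphysis", growth_plate_slice=210)
        voi = morph.select_voi(mask, spec)
        assert voi.mask.shape[0] == 100

    def test_identity_crop(self):
        mask = BinaryVolume(np.ones((100, 4, 4), bool), 10.0)
        spec = VoiSpec(
            "trabecular_metaphysis", growth_plate_slice=0, offset_mm=0.0, height_mm=1.0
        )
        assert morph.select_voi(mask, spec).mask.shape[0] == 100

    def test_cortical_slab_is_half_millimetre(self):
        mask = BinaryVolume(np.zeros((200, 4, 4), bool), 10.0)
        spec = VoiSpec("cortical_midshaft", midshaft_center_slice=100, n_slices=50)
        voi = morph.select_voi(mask, spec)
        assert voi.mask.shape[0] * voi.voxel_size_mm == pytest.approx(0.5)

    def test_voi_overrun_reports_bounds(self):
        mask = BinaryVolume(np.zeros((60, 4, 4), bool), 10.0)
        spec = VoiSpec("trabecular_metaphysis", growth_plate_slice=30)
        with pytest.raises(MorphometryError, match="exceed"):
            morph.select_voi(mask, spec)


class TestBvTv:
    def test_all_bone(self):
        assert morph.bv_tv(BinaryVolume(np.ones((4, 4, 4), bool), 10.0)) == 100.0

    def test_plate_stack_volume_fraction(self, plate_stack_20um):
        vol, truth = plate_stack_20um
        assert morph.bv_tv(vol) == pytest.approx(truth["bv_tv"])

    def test_empty_mask_is_zero_percent(self):
        assert morph.bv_tv(BinaryVolume(np.zeros((4, 4, 4), bool), 10.0)) == 0.0


class TestLocalThickness:
    def test_plate_thickness_within_one_voxel(self):
        mask = np.zeros((20, 50, 50), bool)
        mask[6:14] = True  # 80 um plate at 10 um voxels
        th = morph.local_thickness(BinaryVolume(mask, 10.0), "bone")
        assert th == pytest.approx(0.080, abs=0.010)

    def test_ball_diameter_within_one_voxel(self, ball_10um):
        vol, truth = ball_10um
        th = morph.local_thickness(vol, "bone")
        assert th == pytest.approx(truth["tb_th"], abs=1.01 * vol.voxel_size_mm)

    def test_rod_diameter_within_one_voxel(self, rod_10um):
        vol, truth = rod_10um
        th = morph.local_thickness(vol, "bone")
        assert th == pytest.approx(truth["tb_th"], abs=1.01 * vol.voxel_size_mm)

    def test_single_voxel_is_one_voxel_thick(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[4, 4, 4] = True
        assert morph.local_thickness(BinaryVolume(mask, 10.0), "bone") == pytest.approx(
            0.010
        )

    @pytest.mark.parametrize("width", [4, 7, 12, 20])
    def test_slab_widths_recovered(self, width):
        mask = np.zeros((width + 12, 40, 40), bool)
        mask[6 : 6 + width] = True
        th = morph.local_thickness(BinaryVolume(mask, 10.0), "bone")
        assert th == pytest.approx(width * 0.010, abs=0.010)

    def test_separation_on_plate_stack(self, plate_stack_20um):
        vol, truth = plate_stack_20um
        sp = morph.local_thickness(vol, "background")
        assert sp == pytest.approx(truth["tb_sp"], abs=vol.voxel_size_mm)

    def test_empty_phase_rejected(self):
        with pytest.raises(MorphometryError):
            morph.local_thickness(BinaryVolume(np.zeros((4, 4, 4), bool), 10.0), "bone")


class TestTbN:
    def test_inverse_of_mean_spacing(self):
        assert morph.tb_n(0.1, 0.4) == pytest.approx(2.0)
        assert morph.tb_n(0.25, 0.25) == pytest.approx(2.0)

    def test_plate_stack_pitch(self, plate_stack_20um):
        vol, truth = plate_stack_20um
        th = morph.local_thickness(vol, "bone")
        sp = morph.local_thickness(vol, "background")
        assert morph.tb_n(th, sp) == pytest.approx(truth["tb_n"], rel=0.05)

    def test_zero_denominator(self):
        with pytest.raises(MorphometryError):
            morph.tb_n(0.0, 0.0)


class TestSmi:
    def test_plate_is_near_zero(self, plate_10um):
        vol, truth = plate_10um
        assert abs(morph.smi(vol) - truth["smi"]) <= 0.5

    def test_rod_is_near_three(self, rod_10um):
        vol, truth = rod_10um
        assert abs(morph.smi(vol) - truth["smi"]) <= 0.5

    def test_ball_is_near_four(self, ball_10um):
        vol, truth = ball_10um
        assert abs(morph.smi(vol) - truth["smi"]) <= 0.5

    def test_monotone_along_plate_to_rod_morph(self):
        # widen a rod cross-section from square-ish toward a wide ribbon:
        # SMI should fall monotonically from rod-like toward plate-like
        values = []
        for half_width in (4, 8, 16, 32, 64):
            mask = np.zeros((120, 20, 2 * half_width + 12), bool)
            mask[4:116, 6:14, 6 : 6 + 2 * half_width] = True
            values.append(morph.smi(BinaryVolume(mask, 10.0)))
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_full_mask_rejected(self):
        with pytest.raises(MorphometryError):
            morph.smi(BinaryVolume(np.ones((4, 4, 4), bool), 10.0))


class TestConnD:
    def test_torus_has_unit_connectivity(self, torus_10um):
        vol, truth = torus_10um
        tv = vol.mask.size * vol.voxel_volume_mm3
        assert morph.conn_d(vol) * tv == pytest.approx(truth["n_loops"])

    def test_ball_has_zero_connectivity(self, ball_10um):
        vol, _ = ball_10um
        assert morph.conn_d(vol) == 0.0

    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_loop_lattice_counts_loops(self, k):
        vol, truth = synth.make_phantom(
            synth.PhantomSpec("loop_lattice", 10.0, {"n_loops": k})
        )
        tv = vol.mask.size * vol.voxel_volume_mm3
        assert morph.conn_d(vol) * tv == pytest.approx(k)
        assert truth["euler"] == 1 - k

    def test_euler_number_matches_cubical_oracle_on_random_grids(self):
        rng = np.random.default_rng(42)
        for density in (0.2, 0.5, 0.8):
            for _ in range(10):
                mask = rng.random((12, 12, 12)) < density
                chi = measure.euler_number(mask, connectivity=3)
                assert chi == euler_characteristic_oracle(mask)

    @pytest.mark.parametrize("seed", range(5))
    def test_conn_d_equals_betti_one_for_connected_cavity_free(self, seed):
        # construct a connected, cavity-free random structure: largest
        # 26-connected component with enclosed pockets filled
        from scipy import ndimage as ndi

        rng = np.random.default_rng(seed)
        raw = rng.random((12, 12, 12)) < 0.5
        labels, n = ndi.label(raw, structure=np.ones((3, 3, 3)))
        assert n >= 1
        largest = labels == np.argmax(np.bincount(labels.ravel())[1:]) + 1
        mask = ndi.binary_fill_holes(largest)
        b0, b1, b2 = betti_numbers_oracle(mask)
        assert (b0, b2) == (1, 0)
        vol = BinaryVolume(mask, 100.0)
        tv = mask.size * vol.voxel_volume_mm3
        assert morph.conn_d(vol) * tv == pytest.approx(b1)


@pytest.fixture(scope="module")
def random_mask():
    rng = np.random.default_rng(3)
    from scipy import ndimage as ndi

    return ndi.binary_closing(rng.random((18, 18, 18)) < 0.4, np.ones((3, 3, 3)))


class TestSymmetryInvariance:
    @pytest.mark.parametrize("op", ["transpose", "flip"])
    def test_metrics_invariant_under_axis_symmetry(self, random_mask, op):
        vol = BinaryVolume(random_mask, 10.0)
        moved = (
            np.transpose(random_mask, (2, 0, 1)) if op == "transpose"
            else np.flip(random_mask, axis=1)
        )
        vol2 = BinaryVolume(moved.copy(), 10.0)
        assert morph.bv_tv(vol) == morph.bv_tv(vol2)
        assert morph.conn_d(vol) == morph.conn_d(vol2)
        assert morph.local_thickness(vol, "bone") == pytest.approx(
            morph.local_thickness(vol2, "bone")
        )
        assert morph.smi(vol) == pytest.approx(morph.smi(vol2), abs=0.05)


class TestCorticalMetrics:
    def test_annulus_closed_forms(self, annulus_metrics_10um):
        metrics, truth = annulus_metrics_10um
        vox = 0.010
        assert metrics.tt_ar == pytest.approx(truth["tt_ar"], rel=0.01)
        assert metrics.ct_ar == pytest.approx(truth["ct_ar"], rel=0.01)
        assert metrics.ct_ar_tt_ar == pytest.approx(truth["ct_ar_tt_ar"], abs=0.5)
        assert metrics.ct_th == pytest.approx(truth["ct_th"], abs=vox)

    def test_solid_cylinder_fraction_is_100(self):
        vol, _ = synth.make_phantom(
            synth.PhantomSpec(
                "hollow_cylinder", 10.0,
                {"outer_radius_um": 500.0, "inner_radius_um": 0.0, "n_slices": 10},
            )
        )
        m = morph.cortical_metrics(vol)
        assert m.ct_ar == pytest.approx(m.tt_ar)
        assert m.ct_ar_tt_ar == pytest.approx(100.0)

    def test_marrow_cavity_included_in_total_area(self, annulus_10um):
        vol, truth = annulus_10um
        m = morph.cortical_metrics(vol)
        assert m.ct_ar < m.tt_ar

    def test_resolution_convergence(self):
        errors = []
        for vox in (40.0, 20.0, 10.0):
            vol, truth = synth.make_phantom(
                synth.PhantomSpec("hollow_cylinder", vox, {"n_slices": 6})
            )
            m = morph.cortical_metrics(vol)
            errors.append(
                abs(m.tt_ar - truth["tt_ar"]) / truth["tt_ar"]
                + abs(m.ct_ar - truth["ct_ar"]) / truth["ct_ar"]
            )
        assert errors[-1] < errors[0]
        # area error scales roughly with voxel size
        assert errors[-1] < 0.02

    def test_empty_slice_identified(self):
        mask = np.ones((5, 8, 8), bool)
        mask[2] = False
        with pytest.raises(MorphometryError, match="slice 2"):
            morph.cortical_metrics(BinaryVolume(mask, 10.0))


class TestRelativeRatio:
    def test_identical_groups(self):
        assert morph.relative_metric_ratio([1.0, 2.0], [2.0, 1.0]) == 100.0

    def test_reported_format(self):
        assert morph.relative_metric_ratio([2.47], [1.0]) == pytest.approx(247.0)

    def test_zero_numerator(self):
        assert morph.relative_metric_ratio([0.0], [1.0]) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(MorphometryError):
            morph.relative_metric_ratio([1.0], [0.0])


class TestFullPipeline:
    def test_grayscale_femur_phantom_recovers_truth(self, femur_like_20um):
        vol, truth = femur_like_20um
        gray, cal = synth.make_gray_phantom(
            vol, bone_density_mg_cm3=800.0, background_density_mg_cm3=100.0,
            noise_sd_mg_cm3=50.0, seed=11,
        )
        filtered = morph.median_filter_3d(gray)
        mask = morph.threshold_density(filtered, cal)
        spec = VoiSpec(
            "trabecular_metaphysis", growth_plate_slice=truth["growth_plate_slice"]
        )
        voi = morph.select_voi(mask, spec)
        assert morph.bv_tv(voi) == pytest.approx(truth["trabecular"]["bv_tv"], rel=0.05)
        th = morph.local_thickness(voi, "bone")
        assert th == pytest.approx(truth["trabecular"]["tb_th"], abs=voi.voxel_size_mm)

        cort_spec = VoiSpec(
            "cortical_midshaft",
            midshaft_center_slice=truth["midshaft_center_slice"],
            n_slices=50,
        )
        cort = morph.cortical_metrics(morph.select_voi(mask, cort_spec))
        assert cort.tt_ar == pytest.approx(truth["cortical"]["tt_ar"], rel=0.02)
        assert cort.ct_ar == pytest.approx(truth["cortical"]["ct_ar"], rel=0.02)
        assert cort.ct_th == pytest.approx(
            truth["cortical"]["ct_th"], abs=2 * voi.voxel_size_mm
        )
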