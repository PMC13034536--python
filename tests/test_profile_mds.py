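import numpy as np
import pytest

from mdslope.io_core import ScalarVolume, SegmentationVolume, affine_from_spacing
from mdslope.profile_mds import (
    MDSParams,
    apply_validity_filter,
    compute_mds,
    fit_slope,
    profile_correlation_map,
    sample_profile,
)
from mdslope.surface_vectors import EmptyROIError, estimate_normals

from conftest import make_slab_profile, random_full_run_profile


class TestSampleProfile:
    def test_standard_window_yields_17_samples(self):
        vol = ScalarVolume(np.zeros((30, 30, 30)), affine_from_spacing((1, 1, 1)))
        p = sample_profile(vol, [15, 15, 15], [1, 0, 0])
        assert len(p.arc_mm) == 17
        np.testing.assert_allclose(np.diff(p.arc_mm), 0.5)
        assert p.arc_mm[0] == -2.0 and p.arc_mm[-1] == 6.0

    def test_constant_volume_samples_constant(self):
        vol = ScalarVolume(np.full((30, 30, 30), 7e-4), affine_from_spacing((1, 1, 1)))
        p = sample_profile(vol, [15.0, 14.2, 15.7], [0.6, 0.8, 0.0])
        np.testing.assert_allclose(p.values, 7e-4)

    def test_trilinear_interpolation_exact_on_linear_field(self):
        a, b = 5e-4, 3e-5
        x = np.arange(40)[:, None, None] * np.ones((40, 20, 20))
        vol = ScalarVolume(a + b * x, affine_from_spacing((1, 1, 1)))
        p = sample_profile(vol, [20.0, 10.0, 10.0], [1.0, 0.0, 0.0])
        np.testing.assert_allclose(p.values, a + b * (20.0 + p.arc_mm), rtol=1e-12)

    def test_out_of_volume_samples_marked_missing_not_zero(self):
        vol = ScalarVolume(np.ones((10, 10, 10)), affine_from_spacing((1, 1, 1)))
        p = sample_profile(vol, [8.0, 5.0, 5.0], [1.0, 0.0, 0.0])
        assert p.missing.any()
        assert np.isnan(p.values[p.missing]).all()
        np.testing.assert_allclose(p.values[~p.missing], 1.0)


class TestValidityFilter:
    def test_full_window_in_abnormality_gives_8mm_run(self):
        profile, _ = make_slab_profile(abnormality_out_mm=6.0)
        assert profile.valid
        assert profile.n_contiguous_mm == pytest.approx(8.0)

    def test_run_of_4p5_mm_is_valid(self):
        profile, _ = make_slab_profile(abnormality_out_mm=2.5)
        assert profile.n_contiguous_mm == pytest.approx(4.5)
        assert profile.valid

    def test_run_of_3p5_mm_is_invalid(self):
        profile, _ = make_slab_profile(abnormality_out_mm=1.5)
        assert profile.n_contiguous_mm == pytest.approx(3.5)
        assert not profile.valid

    def test_run_of_exactly_4_mm_fails_strict_rule(self):
        profile, _ = make_slab_profile(abnormality_out_mm=2.0)
        assert profile.n_contiguous_mm == pytest.approx(4.0)
        assert not profile.valid

    def test_flair_truncation_at_3mm_leaves_valid_5mm_run(self):
        profile, _ = make_slab_profile(abnormality_out_mm=3.0)
        assert profile.n_contiguous_mm == pytest.approx(5.0)
        assert profile.valid

    def test_run_anchored_at_boundary_crossing(self):
        profile, _ = make_slab_profile(abnormality_out_mm=6.0)
        i0, i1 = profile.run
        assert profile.arc_mm[i0] <= 0.0 <= profile.arc_mm[i1]

    def test_missing_samples_break_contiguity(self):
        profile, seg = make_slab_profile(abnormality_out_mm=6.0)
        profile.missing[profile.arc_mm == 2.0] = True
        apply_validity_filter(profile, seg)
        assert profile.n_contiguous_mm == pytest.approx(3.5)
        assert not profile.valid


class TestFitSlope:
    def test_constant_values_give_zero_slope(self):
        p = random_full_run_profile(np.random.default_rng(0))
        p.values[:] = 4e-4
        assert fit_slope(p)["slope"] == pytest.approx(0.0, abs=1e-18)

    def test_exact_line_recovered(self):
        p = random_full_run_profile(np.random.default_rng(0))
        p.values = 1e-3 + 5e-5 * p.arc_mm
        fit = fit_slope(p)
        assert fit["slope"] == pytest.approx(5e-5, rel=1e-12)
        assert fit["intercept"] == pytest.approx(1e-3, rel=1e-12)
        assert fit["r_squared"] == pytest.approx(1.0, abs=1e-12)

    def test_index_slope_times_rate_equals_per_mm_regression(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = random_full_run_profile(rng)
            slope = fit_slope(p)["slope"]
            ref = np.polyfit(p.arc_mm, p.values, 1)[0]
            assert abs(slope - ref) <= 1e-12 * abs(ref)

    def test_per_index_slope_doubles_under_rate_2(self):
        # slope of 0.05 per sample at 2 samples/mm is 0.1 per mm
        p = random_full_run_profile(np.random.default_rng(1), rate=2.0)
        p.values = 0.05 * np.arange(len(p.arc_mm))
        assert fit_slope(p)["slope"] == pytest.approx(0.1, rel=1e-12)

    def test_fewer_than_3_samples_rejected(self):
        p = random_full_run_profile(np.random.default_rng(2))
        p.run = (0, 1)
        with pytest.raises(ValueError, match="fewer than 3"):
            fit_slope(p)


class TestComputeMDS:
    def test_ground_truth_recovery_on_synthetic_patient(self, default_patient, default_patient_mds):
        truth = default_patient.true_slope
        assert default_patient_mds.n_valid == default_patient_mds.n_total
        assert default_patient_mds.mean_mds == pytest.approx(truth, rel=0.05)

    def test_adc_scaling_doubles_mean_mds(self, default_patient, default_patient_mds):
        scaled = ScalarVolume(
            default_patient.adc.data * 2.0, default_patient.adc.affine, units="mm2_per_s"
        )
        res2 = compute_mds(scaled, default_patient.seg)
        assert res2.mean_mds == pytest.approx(2.0 * default_patient_mds.mean_mds, rel=1e-12)

    def test_no_surrounding_abnormality_yields_zero_valid(self):
        labels = np.zeros((24, 24, 24), dtype=np.int16)
        grids = np.meshgrid(*[np.arange(24)] * 3, indexing="ij")
        r2 = sum((g - 11.5) ** 2 for g in grids)
        labels[r2 <= 36] = 1  # enhancing ball, nothing around it
        seg = SegmentationVolume(labels, affine_from_spacing((1, 1, 1)))
        adc = ScalarVolume(np.full((24, 24, 24), 8e-4), seg.affine, units="mm2_per_s")
        res = compute_mds(adc, seg)
        assert res.n_valid == 0
        assert np.isnan(res.mean_mds)

    def test_empty_enhancing_roi_raises(self):
        labels = np.zeros((10, 10, 10), dtype=np.int16)
        labels[2:8, 2:8, 2:8] = 3
        seg = SegmentationVolume(labels, affine_from_spacing((1, 1, 1)))
        adc = ScalarVolume(np.zeros((10, 10, 10)), seg.affine)
        with pytest.raises(EmptyROIError, match="empty ROI"):
            compute_mds(adc, seg)

    def test_integer_translation_leaves_slopes_unchanged(self, default_patient, default_patient_mds):
        shift = (2, -3, 1)
        adc_t = ScalarVolume(
            np.roll(default_patient.adc.data, shift, axis=(0, 1, 2)),
            default_patient.adc.affine,
            units="mm2_per_s",
        )
        seg_t = SegmentationVolume(
            np.roll(default_patient.seg.labels, shift, axis=(0, 1, 2)),
            default_patient.seg.affine,
        )
        res_t = compute_mds(adc_t, seg_t)
        a = np.sort(res_t.per_profile["slope"].to_numpy())
        b = np.sort(default_patient_mds.per_profile["slope"].to_numpy())
        np.testing.assert_allclose(a, b, rtol=1e-12)


@pytest.fixture(scope="module")
def disc_setup():
    shape = (60, 60)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r = np.sqrt(sum((g - 29.5) ** 2 for g in grids))
    mask = r <= 15
    aff = affine_from_spacing((1.0, 1.0))
    field = estimate_normals(mask, aff)
    vol_a = ScalarVolume(1e-3 - 2e-5 * r, aff)
    return vol_a, field, aff


class TestProfileCorrelationMap:
    def test_perfect_monotone_inversion_gives_rho_minus_one(self, disc_setup):
        vol_a, field, aff = disc_setup
        vol_b = ScalarVolume(-vol_a.data + 5e-3, aff)
        table = profile_correlation_map(vol_a, vol_b, field, window_mm=(-2, 6), rate_per_mm=2)
        defined = table[table.defined]
        assert len(defined) == len(field)
        np.testing.assert_allclose(defined["rho"], -1.0, atol=1e-12)

    def test_independent_noise_gives_null_correlations(self, disc_setup):
        # one sample per voxel so interpolated noise samples are independent
        # (finer sampling would serially correlate them and inflate rho)
        vol_a, field, aff = disc_setup
        rng = np.random.default_rng(7)
        vol_b = ScalarVolume(rng.normal(size=vol_a.data.shape), aff)
        table = profile_correlation_map(vol_a, vol_b, field, window_mm=(-2, 6), rate_per_mm=1)
        defined = table[table.defined]
        # null mean |rho| for n=9 ranks is ~0.28; significance near nominal 5%
        assert defined["rho"].abs().mean() < 0.4
        assert (defined["p"] < 0.05).mean() < 0.15

    def test_short_usable_run_flagged_undefined(self, disc_setup):
        vol_a, field, aff = disc_setup
        # volume valid only in a thin shell: nearly all samples missing
        small = ScalarVolume(np.ones((4, 4)), affine_from_spacing((1.0, 1.0)))
        small_b = ScalarVolume(np.ones((4, 4)), affine_from_spacing((1.0, 1.0)))
        from mdslope.surface_vectors import SurfaceVectorField

        f = SurfaceVectorField(
            base_points=np.array([[1.5, 1.5]]),
            directions=np.array([[1.0, 0.0]]),
            ids=np.array([0]),
            component_ids=np.array([1]),
            grid_shape=(4, 4),
            affine=small.affine,
        )
        table = profile_correlation_map(small, small_b, f, window_mm=(-2, 6), rate_per_mm=0.5)
        assert not table.iloc[0]["defined"]
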