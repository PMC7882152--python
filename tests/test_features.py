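import numpy as np
import pytest

from che_radiomics import features as F
from che_radiomics.imaging_io import ImageVolume, ROIMask

from conftest import roi_from_values


def strip(values, n_bins):
    """1D strip as a (n,1,1) ROI, discretized."""
    arr = np.asarray(values, float).reshape(-1, 1, 1)
    return F.discretize(roi_from_values(arr), n_bins=n_bins)


class TestDiscretize:
    def test_identity_binning(self):
        roi = roi_from_values(np.arange(32, dtype=float).reshape(32, 1, 1))
        disc = F.discretize(roi, n_bins=32)
        np.testing.assert_array_equal(disc.levels.ravel(), np.arange(1, 33))

    def test_constant_roi_maps_to_level_one(self):
        disc = F.discretize(roi_from_values(np.full((3, 3, 3), 9.0)), 32)
        assert set(disc.levels.ravel()) == {1}

    def test_two_bin_edge_at_midpoint(self):
        disc = strip([0.0, 10.0, 20.0, 30.0], n_bins=2)
        np.testing.assert_array_equal(disc.levels.ravel(), [1, 1, 2, 2])

    def test_levels_cover_full_range(self, rng):
        roi = roi_from_values(rng.normal(size=(6, 6, 6)))
        disc = F.discretize(roi, 32)
        assert disc.levels.min() == 1 and disc.levels.max() == 32
        assert np.all(np.diff(disc.bin_edges) > 0)


class TestIntensityFeatures:
    def test_constant_roi(self):
        f = F.intensity_features(roi_from_values(np.full((3, 3, 3), 4.2)))
        assert f["Median"] == 4.2
        assert f["Variance"] == pytest.approx(0.0, abs=1e-24)
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0

    def test_hand_computed_values(self):
        f = F.intensity_features(
            roi_from_values(np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)))
        assert f["Mean"] == 2.5
        assert f["Variance"] == 1.25  # population form
        assert f["Range"] == 3.0
        assert f["RootMeanSquare"] == pytest.approx(np.sqrt(7.5))
        assert f["Energy"] == 30.0

    def test_shift_equivariance(self, small_roi):
        base = F.intensity_features(small_roi)
        shifted = roi_from_values(small_roi.grid + 17.0, small_roi.mask)
        f = F.intensity_features(shifted)
        assert f["Median"] == pytest.approx(base["Median"] + 17.0)
        assert f["Mean"] == pytest.approx(base["Mean"] + 17.0)
        assert f["Variance"] == pytest.approx(base["Variance"])


class TestGLCM:
    def test_constant_roi_single_level_matrix(self):
        disc = F.discretize(roi_from_values(np.full((2, 2, 2), 1.0)), 32)
        m = F.glcm(disc, (1, 0, 0))
        assert m.matrix[0, 0] == 1.0
        assert m.matrix.sum() == 1.0

    def test_alternating_strip_matrix(self):
        disc = strip([0, 10, 0, 10], n_bins=2)
        m = F.glcm(disc, (1, 0, 0)).matrix
        assert m[0, 1] == 0.5 and m[1, 0] == 0.5
        assert m[0, 0] == 0.0 and m[1, 1] == 0.0

    @pytest.mark.parametrize("direction", F.DIRECTIONS_13)
    def test_symmetry_every_direction(self, rng, direction):
        roi = roi_from_values(rng.normal(size=(5, 5, 5)))
        m = F.glcm(F.discretize(roi, 8), direction).matrix
        np.testing.assert_array_equal(m, m.T)

    def test_normalization_sums_to_one(self, rng, small_roi):
        disc = F.discretize(small_roi, 16)
        for d in F.DIRECTIONS_13:
            m = F.glcm(disc, d)
            if not m.empty:
                assert m.matrix.sum() == pytest.approx(1.0)


class TestGLCMFeatures:
    def test_constant_roi_degenerate_conventions(self):
        disc = F.discretize(roi_from_values(np.full((3, 3, 3), 2.0)), 32)
        f = F.glcm_features(disc)
        assert f["Contrast"] == 0.0
        assert f["JointEnergy"] == 1.0
        assert f["JointEntropy"] == 0.0
        assert f["MaximumProbability"] == 1.0
        assert f["Correlation"] == 0.0
        assert f["InformationalMeasureOfCorrelation1"] == 0.0
        assert f["InformationalMeasureOfCorrelation2"] == 0.0

    def test_alternating_strip_contrast(self):
        disc = strip([0, 10, 0, 10], n_bins=2)
        f = F.glcm_features(disc, directions=((1, 0, 0),))
        assert f["Contrast"] == pytest.approx(1.0)

    def test_imc1_zero_for_independent_matrix(self):
        # p(i,j) = p(i) p(j)  =>  HXY == HXY1  =>  IMC1 = 0
        px = np.array([0.1, 0.2, 0.3, 0.4])
        p = np.outer(px, px)
        f = F._glcm_features_single(p)
        assert f["InformationalMeasureOfCorrelation1"] == pytest.approx(0.0, abs=1e-12)


class TestGLRLM:
    def test_single_run_closed_form(self):
        disc = strip([5.0, 5.0, 5.0, 5.0], n_bins=4)
        f = F.glrlm_features(disc, directions=((1, 0, 0),))
        assert f["ShortRunEmphasis"] == pytest.approx(1 / 16)
        assert f["LongRunEmphasis"] == pytest.approx(16.0)
        assert f["RunPercentage"] == pytest.approx(0.25)
        assert f["GrayLevelNonuniformity"] == pytest.approx(1.0)

    def test_two_runs_of_length_two(self):
        disc = strip([0.0, 0.0, 10.0, 10.0], n_bins=2)
        f = F.glrlm_features(disc, directions=((1, 0, 0),))
        assert f["ShortRunEmphasis"] == pytest.approx(0.25)
        assert f["LongRunEmphasis"] == pytest.approx(4.0)
        assert f["GrayLevelNonuniformity"] == pytest.approx(1.0)

    def test_mask_hole_breaks_run(self):
        arr = np.full((5, 1, 1), 7.0)
        mask = np.ones((5, 1, 1), bool)
        mask[2] = False  # constant line of 5 with the middle voxel removed
        disc = F.discretize(roi_from_values(arr, mask), 4)
        m = F.glrlm(disc, (1, 0, 0)).matrix
        assert m[0, 1] == 2.0       # two runs of length 2
        assert m[0, 3] == 0.0       # not one run of length 4
        assert m.sum() == 2.0

    def test_run_mass_equals_in_mask_voxels(self, small_roi):
        disc = F.discretize(small_roi, 8)
        n_voxels = int(disc.mask.sum())
        for d in F.DIRECTIONS_13:
            m = F.glrlm(disc, d).matrix
            lengths = np.arange(1, m.shape[1] + 1)
            assert (m * lengths).sum() == n_voxels


class TestWavelet:
    def test_constant_volume_details_vanish(self):
        bands = F.wavelet_subbands(np.full((8, 8, 8), 3.0))
        assert set(bands) == set(F.SUBBANDS)
        for b in F.SUBBANDS[1:]:
            assert np.abs(bands[b]).max() == 0.0
        assert np.ptp(bands["LLL"]) == pytest.approx(0.0)

    def test_impulse_lll_is_product_of_lowpass_taps(self):
        data = np.zeros((8, 8, 8))
        data[4, 4, 4] = 1.0
        bands = F.wavelet_subbands(data)
        assert bands["LLL"][4, 4, 4] == pytest.approx((1 / np.sqrt(2)) ** 3)

    def test_subbands_on_original_grid_with_odd_axes(self, rng):
        data = rng.normal(size=(9, 8, 11))
        bands = F.wavelet_subbands(data)
        assert all(bands[b].shape == data.shape for b in F.SUBBANDS)

    def test_axis_shorter_than_filter_raises(self):
        with pytest.raises(ValueError, match="filter"):
            F.wavelet_subbands(np.ones((1, 8, 8)))


class TestExtraction:
    def test_counts_per_roi(self, small_volume, small_mask):
        f = F.extract_roi_features(small_volume, small_mask)
        assert len(f) == 423
        assert F.FEATURES_PER_ROI == 47
        assert 47 * (1 + len(F.SUBBANDS)) == 423
        families = {"intensity": 0, "glcm": 0, "glrlm": 0}
        wavelet_count = 0
        for name in f:
            fam = name.split("_")[1]
            if name.split("_")[-1] in F.SUBBANDS:
                wavelet_count += 1
            else:
                families[fam] += 1
        assert families == {"intensity": 14, "glcm": 22, "glrlm": 11}
        assert wavelet_count == 376

    def test_ten_rois_give_4230_columns(self, small_volume):
        masks = [ROIMask(f"roi{i}", np.ones((12, 12, 12))) for i in range(10)]
        f = F.extract_all(small_volume, masks)
        assert len(f) == 4230

    def test_deterministic_and_finite(self, small_volume, small_mask):
        f1 = F.extract_roi_features(small_volume, small_mask)
        f2 = F.extract_roi_features(small_volume, small_mask)
        assert f1 == f2
        assert all(np.isfinite(v) for v in f1.values())

    def test_affine_rescaling_invariance_of_texture(self, small_volume,
                                                    small_mask):
        from che_radiomics.imaging_io import apply_mask
        roi = apply_mask(small_volume, small_mask)
        disc_a = F.discretize(roi, 16)
        rescaled = roi_from_values(3.0 * roi.grid + 100.0, roi.mask)
        disc_b = F.discretize(rescaled, 16)
        fa, fb = F.glcm_features(disc_a), F.glcm_features(disc_b)
        for k in fa:
            assert fa[k] == pytest.approx(fb[k], abs=1e-12)
        ga, gb = F.glrlm_features(disc_a), F.glrlm_features(disc_b)
        for k in ga:
            assert ga[k] == pytest.approx(gb[k], abs=1e-12)
        ia = F.intensity_features(roi)
        ib = F.intensity_features(rescaled)
        assert ib["Median"] == pytest.approx(3 * ia["Median"] + 100)
        assert ib["Variance"] == pytest.approx(9 * ia["Variance"])
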