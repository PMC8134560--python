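"""Activation mapping: HRF regressor, voxel statistics, filters, clustering."""

import numpy as np
import pytest
from scipy import ndimage

from flnet.activation import (
    FWHM_TO_SD,
    SubjectScan,
    activation_statistics,
    cluster_components,
    cluster_threshold,
    hrf_kernel,
    hrf_regressor,
    sd_filter,
    smooth_volume,
)
from flnet.config import AnalysisConfig, RegionSpec, SyntheticConfig, TaskParadigm, ValidationError
from flnet.scenarios import null_config
from flnet.simulate import simulate_subject

from conftest import flood_fill_components, neighbourhood_offsets


def _noise_scan(shape, paradigm, seed, baseline=100.0):
    rng = np.random.default_rng(seed)
    data = baseline + rng.standard_normal((*shape, paradigm.n_timepoints))
    return SubjectScan(data, 4.0, paradigm)


class TestHrfRegressor:
    def test_kernel_integrates_to_one(self):
        k = hrf_kernel(2.5, 5.0, 2.5)
        assert abs(k.sum() - 1.0) < 1e-9

    def test_regressor_peaks_after_block_onset(self, paradigm):
        reg = hrf_regressor(paradigm)
        assert len(reg) == paradigm.n_timepoints
        epoch_tr = int(paradigm.epoch_s / paradigm.tr_s)
        for onset in range(0, paradigm.n_timepoints, epoch_tr):
            block = reg[onset : onset + epoch_tr]
            # the convolved response lags the onset by at least one TR
            assert np.argmax(block) >= 1

    def test_regressor_is_nonnegative_and_bounded_by_boxcar_height(self, paradigm):
        reg = hrf_regressor(paradigm)
        assert np.all(reg >= 0) and np.all(reg <= 1 + 1e-12)

    def test_invalid_kernel_parameters_rejected(self):
        with pytest.raises(ValidationError):
            hrf_kernel(2.5, peak_s=0.0)


class TestActivationStatistics:
    def test_voxel_equal_to_regressor_has_perfect_correlation(self, paradigm):
        reg = hrf_regressor(paradigm)
        data = np.stack([reg, -reg, np.full_like(reg, 5.0)]).reshape(3, 1, 1, -1)
        r, p, const = activation_statistics(data, reg)
        assert r[0, 0, 0] == pytest.approx(1.0)
        assert p[0, 0, 0] < 1e-30
        assert r[1, 0, 0] == pytest.approx(-1.0)
        # constant series: flagged, r = 0, p = 1
        assert const[2, 0, 0] and r[2, 0, 0] == 0.0 and p[2, 0, 0] == 1.0

    def test_constant_regressor_rejected(self, paradigm):
        data = np.random.default_rng(0).standard_normal((2, 2, 2, 160))
        with pytest.raises(ValidationError):
            activation_statistics(data, np.ones(160))

    def test_null_type_one_error_rate_matches_p_voxel(self, paradigm):
        # pure noise: suprathreshold fraction within 3 binomial SDs of 0.001
        scan = _noise_scan((25, 20, 20), paradigm, seed=5)
        r, p, _ = activation_statistics(scan, hrf_regressor(paradigm))
        frac = (p <= 0.001).mean()
        tol = 3 * np.sqrt(0.001 * 0.999 / p.size)
        assert abs(frac - 0.001) <= tol


class TestSdFilter:
    @pytest.mark.parametrize("ratio,kept", [(0.10, False), (0.05, True)])
    def test_eight_percent_rule(self, paradigm, ratio, kept):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(paradigm.n_timepoints)
        series = 100.0 + 100.0 * ratio * base / base.std()
        series = series - series.mean() + 100.0  # exact mean 100
        data = series.reshape(1, 1, 1, -1)
        scan = SubjectScan(data, 4.0, paradigm)
        assert sd_filter(scan, 0.08)[0, 0, 0] == kept

    def test_nonpositive_mean_voxel_excluded(self, paradigm):
        data = np.zeros((1, 1, 1, paradigm.n_timepoints))
        scan = SubjectScan(data, 4.0, paradigm)
        assert not sd_filter(scan, 0.08)[0, 0, 0]


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, paradigm):
        scan = _noise_scan((6, 6, 4), paradigm, seed=1)
        assert smooth_volume(scan, 0.0) is scan

    def test_kernel_sd_follows_fwhm_conversion(self):
        # 4 mm FWHM on 4 mm voxels -> sd 4/(2 sqrt(2 ln 2))/4 ~ 0.4247 voxels
        assert 4.0 * FWHM_TO_SD / 4.0 == pytest.approx(0.42466, abs=1e-4)

    def test_constant_volume_unchanged(self, paradigm):
        data = np.full((6, 6, 4, paradigm.n_timepoints), 7.0)
        scan = SubjectScan(data, 4.0, paradigm)
        out = smooth_volume(scan, 4.0)
        assert np.allclose(out.data, 7.0)

    def test_smoothing_commutes_with_translation_in_the_interior(self, paradigm):
        scan = _noise_scan((12, 10, 8), paradigm, seed=2)
        shifted = SubjectScan(np.roll(scan.data, 2, axis=0), 4.0, paradigm)
        a = smooth_volume(scan, 4.0).data
        b = smooth_volume(shifted, 4.0).data
        # compare away from the rolled boundary
        assert np.allclose(np.roll(a, 2, axis=0)[4:10], b[4:10])


class TestClusterComponents:
    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle_on_random_masks(self, connectivity, rng):
        offsets = neighbourhood_offsets(connectivity)
        for _ in range(10):
            mask = rng.random((8, 8, 6)) < 0.25
            ours = {frozenset(map(tuple, c)) for c in cluster_components(mask, connectivity)}
            oracle = set(flood_fill_components(mask, offsets))
            assert ours == oracle

    def test_corner_touching_blobs_split_by_connectivity(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        mask[1, 1, 1] = True  # touches only at a corner
        assert len(cluster_components(mask, 6)) == 2
        assert len(cluster_components(mask, 26)) == 1

    def test_empty_mask_yields_no_components(self):
        assert cluster_components(np.zeros((3, 3, 3), bool), 6) == []


class TestClusterThreshold:
    def test_planted_cluster_recovered_with_dice_overlap(self):
        cfg = SyntheticConfig(
            grid_shape=(16, 16, 8),
            regions=(RegionSpec("blob", 1, "cuboid", (6, 6, 3), (4, 4, 2), beta=5.0),),
            noise_sd=1.0,
            subject_jitter_sd=0.0,
            voxel_jitter_sd=0.0,
            seed=0,
        )
        sd = simulate_subject(cfg, 1)
        amap = cluster_threshold(sd.scan, None, AnalysisConfig(n_null=200, seed=0))
        planted = set(map(tuple, cfg.regions[0].voxel_indices(cfg.grid_shape)))
        recovered = set(map(tuple, np.argwhere(amap.active)))
        dice = 2 * len(planted & recovered) / (len(planted) + len(recovered))
        assert dice >= 0.5

    def test_single_suprathreshold_voxel_removed_by_extent_rule(self, paradigm):
        scan = _noise_scan((12, 12, 8), paradigm, seed=3)
        reg = hrf_regressor(paradigm)
        data = scan.data.copy()
        data[6, 6, 4] += 10.0 * (reg - reg.mean())  # one perfectly driven voxel
        spiked = SubjectScan(data, 4.0, paradigm)
        amap = cluster_threshold(spiked, reg, AnalysisConfig(n_null=200, smooth_fwhm_mm=0.0, seed=1))
        assert amap.extent_threshold >= 1
        assert not amap.active[6, 6, 4]

    def test_lowering_p_voxel_never_adds_suprathreshold_voxels(self, paradigm):
        scan = _noise_scan((10, 10, 6), paradigm, seed=4)
        r, p, _ = activation_statistics(scan, hrf_regressor(paradigm))
        loose = p <= 0.01
        tight = p <= 0.001
        assert np.all(loose[tight])

    def test_all_excluded_scan_yields_empty_map(self, paradigm):
        data = np.zeros((4, 4, 4, paradigm.n_timepoints))  # mean 0 everywhere
        scan = SubjectScan(data, 4.0, paradigm)
        amap = cluster_threshold(scan, None, AnalysisConfig(n_null=100, seed=0))
        assert not amap.active.any()
        assert amap.clusters == []
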