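"""Movie preprocessing chain and PCA/ICA source extraction."""

import numpy as np
import pytest
from scipy import ndimage

from socialscope.movieproc import (
    CalciumMovie,
    SpatialFootprint,
    bandpass_spatial,
    compute_dff,
    downsample_temporal,
    fix_defective_pixels,
    motion_correct,
    n_ica_components,
    pca_ica_extract,
    qc_filter_rois,
)


def _movie(data, fr=15.0):
    return CalciumMovie(np.asarray(data, dtype=float), fr)


class TestDefectRepair:
    def test_constant_movie_unchanged(self):
        m = _movie(np.full((4, 8, 8), 7.0))
        assert np.array_equal(fix_defective_pixels(m).data, m.data)

    def test_stuck_pixel_restored(self):
        data = np.full((3, 8, 8), 10.0)
        data[:, 4, 4] = 0.0
        out = fix_defective_pixels(_movie(data))
        assert np.all(out.data[:, 4, 4] == 10.0)

    def test_matches_bruteforce_median_on_random_frames(self):
        rng = np.random.default_rng(0)
        data = rng.random((2, 16, 16))
        out = fix_defective_pixels(_movie(data)).data
        # scipy's 'reflect' repeats the edge sample (numpy calls it 'symmetric')
        padded = np.pad(data, ((0, 0), (1, 1), (1, 1)), mode="symmetric")
        for t in range(2):
            for i in range(16):
                for j in range(16):
                    med = np.median(padded[t, i : i + 3, j : j + 3])
                    assert out[t, i, j] == pytest.approx(med)


class TestDownsample:
    def test_block_mean_of_triples(self):
        data = np.zeros((6, 4, 4))
        data[0::3], data[1::3], data[2::3] = 1.0, 2.0, 3.0
        out = downsample_temporal(_movie(data, 15.0), 5.0)
        assert out.frame_rate == 5.0
        assert np.all(out.data == 2.0)

    def test_remainder_frames_dropped(self):
        out = downsample_temporal(_movie(np.zeros((10, 4, 4)), 15.0), 5.0)
        assert out.n_frames == 3

    def test_matches_bruteforce_blocks_on_random_movie(self):
        rng = np.random.default_rng(1)
        data = rng.random((9, 16, 16))
        out = downsample_temporal(_movie(data, 15.0), 5.0).data
        for b in range(3):
            assert np.allclose(out[b], data[3 * b : 3 * b + 3].mean(axis=0))

    def test_non_integer_ratio_fails(self):
        with pytest.raises(ValueError, match="integer multiple"):
            downsample_temporal(_movie(np.zeros((10, 4, 4)), 12.0), 5.0)


class TestBandpass:
    def test_constant_frame_maps_to_zero(self):
        out = bandpass_spatial(_movie(np.full((2, 32, 32), 5.0)), 8.0, 1.0)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_impulse_response_is_difference_of_gaussians(self):
        data = np.zeros((1, 33, 33))
        data[0, 16, 16] = 1.0
        out = bandpass_spatial(_movie(data), sigma_low_px=6.0, sigma_high_px=1.5)
        expected = ndimage.gaussian_filter(data[0], 1.5) - ndimage.gaussian_filter(
            data[0], 6.0
        )
        assert np.allclose(out.data[0], expected, atol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        data = rng.random((2, 16, 16))
        a = bandpass_spatial(_movie(3.0 * data), 5.0, 1.0).data
        b = 3.0 * bandpass_spatial(_movie(data), 5.0, 1.0).data
        assert np.allclose(a, b)

    def test_sigma_ordering_enforced(self):
        with pytest.raises(ValueError):
            bandpass_spatial(_movie(np.zeros((2, 8, 8))), 1.0, 5.0)


class TestMotionCorrect:
    def test_recovers_planted_shifts(self, small_movie):
        _, _, movie, gt = small_movie
        _, shifts = motion_correct(movie)
        rel_est = shifts - shifts.mean(axis=0)
        rel_true = -(gt.planted_shifts - gt.planted_shifts.mean(axis=0))
        assert np.abs(rel_est - rel_true).max() < 0.5

    def test_aligned_movie_needs_no_shift(self, small_movie):
        _, _, movie, _ = small_movie
        corrected, _ = motion_correct(movie)
        _, again = motion_correct(corrected)
        assert np.abs(again - again.mean(axis=0)).max() < 0.5

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            motion_correct(_movie(np.zeros((4, 8, 8))))


class TestComputeDff:
    def test_hand_series(self):
        data = np.array([10.0, 15.0, 10.0]).reshape(3, 1, 1)
        out = compute_dff(_movie(data))
        assert np.allclose(out.data.ravel(), [0.0, 0.5, 0.0])

    def test_constant_movie_is_zero(self):
        out = compute_dff(_movie(np.full((5, 4, 4), 9.0)))
        assert np.allclose(out.data, 0.0)

    def test_per_pixel_minimum_is_zero(self):
        rng = np.random.default_rng(3)
        out = compute_dff(_movie(1.0 + rng.random((20, 8, 8))))
        assert np.allclose(out.data.min(axis=0), 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        data = 1.0 + rng.random((10, 6, 6))
        a = compute_dff(_movie(data)).data
        b = compute_dff(_movie(4.0 * data)).data
        assert np.allclose(a, b)

    def test_zero_baseline_pixels_masked(self):
        data = 1.0 + np.zeros((4, 4, 4))
        data[:, 0, 0] = 0.0
        with pytest.warns(UserWarning, match="masked"):
            out = compute_dff(_movie(data))
        assert np.all(out.data[:, 0, 0] == 0.0)
        assert (0, 0) in {tuple(p) for p in out.masked_pixels}


class TestPcaIca:
    def test_component_count_is_fifteen_percent_over(self):
        assert n_ica_components(20) == 23
        assert n_ica_components(100) == 115

    def test_recovers_planted_footprints(self):
        import socialscope as ss

        cfg = ss.SimulationConfig(
            duration_s=120.0, frame_rate=5.0, n_neurons=30, baseline_rate=6.0,
            loading_w={"M1": 0.0, "O": 0.0, "M2": 0.0}, noise_sd=0.0,
            movie_noise_sd=2.0, seed=7, fov=(80, 80),
        )
        track, bouts = ss.generate_behavior(cfg)
        traces, gt = ss.generate_traces(track, bouts, cfg)
        movie, gt = ss.generate_movie(traces, cfg, gt)
        footprints = pca_ica_extract(compute_dff(movie), 30, seed=0)
        assert len(footprints) == 35  # ceil(1.15 x 30)
        accepted, _ = qc_filter_rois(footprints)
        yy, xx = np.mgrid[0:80, 0:80]
        true_c = np.array(
            [((yy * f).sum() / f.sum(), (xx * f).sum() / f.sum()) for f in gt.footprints]
        )
        est_c = np.array([f.centroid for f in accepted])
        used, matched = set(), 0
        for t in range(30):
            d = np.linalg.norm(est_c - true_c[t], axis=1)
            for j in np.argsort(d):
                if d[j] <= 2.0 and j not in used:
                    matched += 1
                    used.add(j)
                    break
        assert matched >= 27

    def test_noise_movie_yields_nothing_after_qc(self):
        rng = np.random.default_rng(0)
        movie = _movie(100 + rng.normal(0, 1, (200, 32, 32)), 5.0)
        footprints = pca_ica_extract(compute_dff(movie), 8, seed=0)
        accepted, log = qc_filter_rois(footprints)
        assert accepted == []
        assert len(log) == len(footprints)

    def test_too_short_movie_rejected(self):
        movie = _movie(1 + np.random.default_rng(0).random((5, 8, 8)), 5.0)
        with pytest.raises(ValueError, match="components"):
            pca_ica_extract(compute_dff(movie), 20)


def _fp(area=10, snr=10.0, centroid=(10.0, 10.0), n_components=1, ecc=0.5):
    mask = np.zeros((32, 32), dtype=bool)
    mask[:1, :area] = True
    return SpatialFootprint(
        map=mask.astype(float), mask=mask, trace=np.zeros(10), area=area,
        centroid=centroid, snr=snr, n_components=n_components, eccentricity=ecc,
    )


class TestQcRules:
    def test_small_area_rejected_rule1(self):
        _, log = qc_filter_rois([_fp(area=3)])
        assert log == [(0, "rule1_area_or_shape")]

    def test_low_snr_rejected_rule2(self):
        _, log = qc_filter_rois([_fp(snr=2.9)])
        assert log == [(0, "rule2_snr_or_components")]

    def test_fragmented_map_rejected_rule2(self):
        _, log = qc_filter_rois([_fp(n_components=3)])
        assert log == [(0, "rule2_snr_or_components")]

    def test_near_neighbors_keep_higher_snr(self):
        a = _fp(snr=6.0, centroid=(10.0, 10.0))
        b = _fp(snr=4.0, centroid=(10.0, 14.0))  # 4 px apart
        accepted, log = qc_filter_rois([a, b])
        assert accepted == [a]
        assert log == [(1, "rule3_neighbor")]

    def test_distant_neighbors_both_kept(self):
        a = _fp(centroid=(10.0, 10.0))
        b = _fp(centroid=(10.0, 16.0))
        accepted, _ = qc_filter_rois([a, b])
        assert len(accepted) == 2
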