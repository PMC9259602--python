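"""Synthetic-session generator: determinism, planted structure, statistics."""

import numpy as np
import pytest

import socialscope as ss
from socialscope.behavior import SessionLabeling, detect_bouts, interaction_times
from socialscope.simdata import (
    SimulationConfig,
    gcamp_kernel,
    generate_behavior,
    generate_movie,
    generate_traces,
    rett_like_config,
    wt_like_config,
)

FLAT_GAINS = {z: 1.0 for z in ("SNIFF_A", "ZONE_A", "TZ", "ZONE_B", "SNIFF_B")}
NO_COACTIVATION = {"M1": 0.0, "O": 0.0, "M2": 0.0}


class TestConfig:
    def test_invalid_loading_rejected(self):
        cfg = SimulationConfig(loading_w={"M1": 1.5})
        with pytest.raises(ValueError, match="loading_w"):
            cfg.validate()

    def test_preference_over_unity_rejected(self):
        cfg = SimulationConfig(preference={"M1": 0.7, "O": 0.6})
        with pytest.raises(ValueError, match="preference"):
            cfg.validate()

    def test_kernel_decay_must_be_positive(self):
        with pytest.raises(ValueError, match="decay"):
            gcamp_kernel(5.0, decay_s=0.0)


class TestGenerateBehavior:
    def test_planted_interaction_time_is_exact(self):
        cfg = wt_like_config(duration_s=600.0, n_neurons=5, seed=1)
        track, bouts = generate_behavior(cfg)
        times = interaction_times(bouts)
        assert times["M1"] == pytest.approx(120.0)
        assert times["O"] == pytest.approx(60.0)

    def test_detector_recovers_planted_bouts_exactly(self):
        for seed in range(3):
            cfg = wt_like_config(duration_s=600.0, n_neurons=5, seed=seed)
            track, bouts = generate_behavior(cfg)
            detected = detect_bouts(track, labeling=SessionLabeling.default("S1"))
            assert [(b.stimulus, b.start, b.end) for b in detected] == [
                (b.stimulus, b.start, b.end) for b in bouts
            ]

    def test_zero_preference_gives_no_bouts(self):
        cfg = SimulationConfig(duration_s=120.0, n_neurons=5, preference={}, seed=0)
        track, bouts = generate_behavior(cfg)
        assert bouts == []
        assert set(track.data["zone"]) <= {"TZ", "ZONE_A", "ZONE_B"}

    def test_same_seed_is_byte_identical(self):
        cfg = wt_like_config(duration_s=300.0, n_neurons=5, seed=9)
        t1, b1 = generate_behavior(cfg)
        t2, b2 = generate_behavior(cfg)
        assert t1.data.equals(t2.data)
        assert b1 == b2

    def test_too_short_session_fails_loudly(self):
        cfg = wt_like_config(duration_s=4.0, n_neurons=5, seed=0)
        with pytest.raises(ValueError, match="duration too short"):
            generate_behavior(cfg)

    def test_bouts_disjoint_and_in_range(self):
        cfg = rett_like_config(duration_s=600.0, n_neurons=5, seed=2)
        track, bouts = generate_behavior(cfg)
        spans = sorted((b.start, b.end) for b in bouts)
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            assert e0 <= s1
        assert all(0 <= b.start < b.end <= track.n_frames for b in bouts)


class TestGenerateTraces:
    def test_event_counts_match_poisson_expectation(self):
        cfg = SimulationConfig(
            duration_s=600.0, n_neurons=200, baseline_rate=2.0,
            zone_gain=FLAT_GAINS, loading_w=NO_COACTIVATION, noise_sd=0.0, seed=3,
        )
        track, bouts = generate_behavior(cfg)
        _, gt = generate_traces(track, bouts, cfg)
        counts = np.array([len(t) for t in gt.event_times])
        se = np.sqrt(20.0 / 200)
        assert abs(counts.mean() - 20.0) < 3 * se

    def test_independent_neurons_are_uncorrelated(self):
        cfg = SimulationConfig(
            duration_s=600.0, n_neurons=50, zone_gain=FLAT_GAINS,
            loading_w=NO_COACTIVATION, noise_sd=0.0, seed=4,
        )
        track, bouts = generate_behavior(cfg)
        traces, _ = generate_traces(track, bouts, cfg)
        R = np.corrcoef(traces.values)
        iu = np.triu_indices_from(R, k=1)
        assert abs(R[iu].mean()) < 0.02

    def test_full_loading_single_train_gives_identical_traces(self):
        cfg = SimulationConfig(
            duration_s=600.0, n_neurons=10, baseline_rate=0.0,
            zone_gain=FLAT_GAINS, shared_trains={"M1": (1, 30.0)},
            loading_w={"M1": 1.0}, noise_sd=0.0, preference={"M1": 0.3}, seed=5,
        )
        track, bouts = generate_behavior(cfg)
        traces, gt = generate_traces(track, bouts, cfg)
        assert any(len(t) for t in gt.event_times)
        R = np.corrcoef(traces.values)
        assert np.allclose(R, 1.0)

    def test_correlation_width_monotone_in_loading(self):
        """Median |pairwise r| during bouts is non-decreasing in w.

        A single run's median is noisy at 20 neurons, so the check averages
        over a fixed seed family.
        """
        medians = []
        for w in (0.0, 0.2, 0.5, 0.8):
            per_seed = []
            for seed in range(5):
                cfg = SimulationConfig(
                    duration_s=600.0, n_neurons=20, zone_gain=FLAT_GAINS,
                    loading_w={"M1": w, "O": 0.0}, noise_sd=0.05,
                    preference={"M1": 0.3}, seed=seed,
                )
                track, bouts = generate_behavior(cfg)
                traces, _ = generate_traces(track, bouts, cfg)
                frames = np.concatenate([np.arange(b.start, b.end) for b in bouts])
                R = np.corrcoef(traces.values[:, frames])
                iu = np.triu_indices_from(R, k=1)
                per_seed.append(np.median(np.abs(R[iu])))
            medians.append(np.mean(per_seed))
        assert all(a <= b + 1e-9 for a, b in zip(medians, medians[1:]))

    def test_event_frames_within_recording(self, wt_session):
        _, track, _, _, gt = wt_session
        for t in gt.event_times:
            assert np.all((t >= 0) & (t < track.n_frames))

    def test_determinism(self):
        cfg = wt_like_config(duration_s=120.0, n_neurons=8, seed=11)
        track, bouts = generate_behavior(cfg)
        a, _ = generate_traces(track, bouts, cfg)
        b, _ = generate_traces(track, bouts, cfg)
        assert np.array_equal(a.values, b.values)


class TestGenerateMovie:
    def test_two_disjoint_footprints_two_components(self):
        from skimage import measure

        cfg = SimulationConfig(
            duration_s=30.0, n_neurons=2, baseline_rate=6.0, noise_sd=0.0,
            movie_noise_sd=0.0, background_texture_sd=0.0, seed=1, fov=(32, 32),
        )
        track, bouts = generate_behavior(cfg)
        traces, gt = generate_traces(track, bouts, cfg)
        movie, gt = generate_movie(traces, cfg, gt)
        mip = movie.data.max(axis=0)
        labels = measure.label(mip > cfg.background + 1.0)
        assert labels.max() == 2

    def test_planted_shifts_recorded_exactly(self, small_movie):
        _, _, movie, gt = small_movie
        assert gt.planted_shifts.shape == (movie.n_frames, 2)
        assert np.abs(gt.planted_shifts).max() <= 2

    def test_defective_pixels_stuck_at_zero(self):
        cfg = SimulationConfig(
            duration_s=30.0, n_neurons=4, n_defective_pixels=3, seed=2, fov=(32, 32)
        )
        track, bouts = generate_behavior(cfg)
        traces, gt = generate_traces(track, bouts, cfg)
        movie, gt = generate_movie(traces, cfg, gt)
        for y, x in gt.defective_pixels:
            assert np.all(movie.data[:, y, x] == 0.0)

    def test_fov_too_small_fails(self):
        cfg = SimulationConfig(duration_s=30.0, n_neurons=100, seed=0, fov=(16, 16))
        track, bouts = generate_behavior(cfg)
        traces, gt = generate_traces(track, bouts, cfg)
        with pytest.raises(ValueError, match="too small"):
            generate_movie(traces, cfg, gt)
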