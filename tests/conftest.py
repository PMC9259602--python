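import numpy as np
import pytest

import socialscope as ss


@pytest.fixture(scope="session")
def wt_session():
    """One WT-like synthetic session shared by read-only tests."""
    cfg = ss.simdata.wt_like_config(duration_s=600.0, n_neurons=40, seed=5)
    track, bouts = ss.generate_behavior(cfg)
    traces, gt = ss.generate_traces(track, bouts, cfg)
    return cfg, track, bouts, traces, gt


@pytest.fixture(scope="session")
def small_movie():
    """A small rendered movie with ground-truth footprints and jitter."""
    cfg = ss.SimulationConfig(
        duration_s=60.0,
        frame_rate=5.0,
        n_neurons=10,
        baseline_rate=6.0,
        noise_sd=0.0,
        movie_noise_sd=1.0,
        jitter_px=2,
        seed=3,
        fov=(64, 64),
    )
    track, bouts = ss.generate_behavior(cfg)
    traces, gt = ss.generate_traces(track, bouts, cfg)
    movie, gt = ss.generate_movie(traces, cfg, gt)
    return cfg, traces, movie, gt
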