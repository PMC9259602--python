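"""Synthetic three-chamber sessions with ground-truthed calcium activity.

The generator emulates the statistical structure the downstream analyses
assume: zone-structured occupancy with planted interaction bouts, zone- and
stimulus-dependent Poisson transient events convolved with a GCaMP-like
double-exponential kernel, co-activation through per-stimulus shared event
trains (a neuron copies a shared event with probability ``w``, which sets
the width of the pairwise-correlation distribution during that stimulus's
bouts), and an optional rendered movie with planted footprints, defective
pixels, and rigid jitter.

Two preset regimes mirror the study conditions: a socially-preferring
"WT-like" animal with weak social / strong object co-activation, and a
"Rett-like" animal with equal co-activation and no preference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .behavior import (
    BehaviorTrack,
    ChamberGeometry,
    InteractionBout,
    SessionLabeling,
    assign_zones,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "wt_like_config",
    "rett_like_config",
    "generate_behavior",
    "generate_traces",
    "generate_movie",
    "generate_session",
    "gcamp_kernel",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic session generator.

    Rates are in events/min; ``loading_w`` maps a stimulus id to the
    probability w in [0, 1] that a neuron copies an event of that
    stimulus's shared trains; ``preference`` maps a stimulus id to the
    target fraction of session time spent interacting with it.
    """

    duration_s: float = 600.0
    frame_rate: float = 5.0
    n_neurons: int = 120
    baseline_rate: float = 2.0
    zone_gain: Mapping[str, float] = field(
        default_factory=lambda: {
            "SNIFF_A": 1.5,
            "ZONE_A": 1.2,
            "TZ": 1.0,
            "ZONE_B": 1.2,
            "SNIFF_B": 1.5,
        }
    )
    shared_trains: Mapping[str, tuple[int, float]] = field(
        default_factory=lambda: {"M1": (3, 30.0), "O": (3, 30.0), "M2": (3, 30.0)}
    )
    loading_w: Mapping[str, float] = field(
        default_factory=lambda: {"M1": 0.1, "O": 0.4, "M2": 0.1}
    )
    kernel_rise_s: float = 0.2
    kernel_decay_s: float = 0.75
    noise_sd: float = 0.05
    event_amplitude: float = 1.0
    preference: Mapping[str, float] = field(
        default_factory=lambda: {"M1": 0.20, "O": 0.10}
    )
    session_id: str = "S1"
    seed: int = 0
    # movie rendering
    fov: tuple[int, int] = (80, 80)
    footprint_radius_px: float = 3.0
    background: float = 100.0
    background_texture_sd: float = 5.0  # static spatial structure (counts)
    resting_fluor: float = 0.3  # baseline cell brightness, dF/F units
    movie_noise_sd: float = 1.0
    jitter_px: int = 0
    n_defective_pixels: int = 0

    def validate(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.baseline_rate < 0 or any(g < 0 for g in self.zone_gain.values()):
            raise ValueError("rates and gains must be >= 0")
        for s, w in self.loading_w.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"loading_w[{s!r}] = {w} outside [0, 1]")
        for s, (m, rate) in self.shared_trains.items():
            if m < 0 or rate < 0:
                raise ValueError(f"shared_trains[{s!r}] must be non-negative")
        if sum(self.preference.values()) > 1.0 + 1e-9:
            raise ValueError("preference fractions must sum to <= 1")
        if any(f < 0 for f in self.preference.values()):
            raise ValueError("preference fractions must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))


def wt_like_config(**overrides) -> SimulationConfig:
    """Socially-preferring regime: strong object, weak social co-activation."""
    cfg = SimulationConfig(
        loading_w={"M1": 0.1, "O": 0.4, "M2": 0.1},
        preference={"M1": 0.20, "O": 0.10},
    )
    return replace(cfg, **overrides)


def rett_like_config(**overrides) -> SimulationConfig:
    """No-preference regime: equal co-activation and equal interaction time."""
    cfg = SimulationConfig(
        loading_w={"M1": 0.25, "O": 0.25, "M2": 0.25},
        preference={"M1": 0.13, "O": 0.13},
    )
    return replace(cfg, **overrides)


@dataclass
class GroundTruth:
    """Planted quantities the analyses are later scored against."""

    event_times: list[np.ndarray]
    bout_table: pd.DataFrame
    footprints: np.ndarray | None = None
    planted_shifts: np.ndarray | None = None
    defective_pixels: np.ndarray | None = None


def _rngs(seed: int, *streams: str) -> list[np.random.Generator]:
    """Deterministic per-component generators derived from one master seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(streams))
    return [np.random.default_rng(c) for c in children]


# ---------------------------------------------------------------------------
# behavior


def _split_into_episodes(
    total_frames: int, rng: np.random.Generator, frame_rate: float
) -> list[int]:
    """Split a frame budget into bout episodes of roughly 3-15 s."""
    lo = max(1, int(round(3 * frame_rate)))
    hi = max(lo + 1, int(round(15 * frame_rate)))
    out: list[int] = []
    remaining = total_frames
    while remaining > 0:
        n = int(rng.integers(lo, hi + 1))
        if remaining - n < lo:  # avoid a trailing sliver shorter than lo
            n = remaining
        out.append(min(n, remaining))
        remaining -= out[-1]
    return out


def _smooth_bridge(
    n: int, x0: float, x1: float, rng: np.random.Generator, lo: float, hi: float
) -> np.ndarray:
    """Continuous noisy path from x0 to x1 in n steps, clipped to [lo, hi]."""
    if n <= 1:
        return np.full(max(n, 1), x1)
    base = np.linspace(x0, x1, n)
    noise = np.cumsum(rng.normal(0.0, 0.6, n))
    noise -= np.linspace(noise[0], noise[-1], n)  # pin both ends
    noise = ndimage.uniform_filter1d(noise, size=max(3, n // 10))
    return np.clip(base + noise, lo, hi)


def generate_behavior(
    config: SimulationConfig, geometry: ChamberGeometry | None = None
) -> tuple[BehaviorTrack, list[InteractionBout]]:
    """Synthesize a continuous track with planted interaction bouts.

    The animal wanders the central chamber between bouts; during a bout
    its nose sits inside the queried sniffing strip with heading toward
    the barrier, so :func:`socialscope.behavior.detect_bouts` recovers the
    planted episodes exactly.  Realized interaction time per stimulus
    equals the configured ``preference`` fraction to within one frame.
    """
    config.validate()
    geometry = geometry or ChamberGeometry()
    labeling = SessionLabeling.default(config.session_id)
    stim_to_side = {v: k for k, v in labeling.side_to_stimulus.items()}
    rng_sched, rng_path = _rngs(config.seed, "behavior-schedule", "behavior-path")

    n_frames = config.n_frames
    L = geometry.central_length_cm
    sniff = geometry.sniff_zone_cm

    # --- schedule: alternate wander gaps and bout episodes -----------------
    episodes: list[tuple[str, int]] = []  # (stimulus, n_frames)
    for stimulus, frac in config.preference.items():
        if stimulus not in stim_to_side:
            raise ValueError(
                f"preference stimulus {stimulus!r} absent from session "
                f"{config.session_id} labeling {labeling.side_to_stimulus}"
            )
        target = int(round(frac * n_frames))
        for n in _split_into_episodes(target, rng_sched, config.frame_rate):
            episodes.append((stimulus, n))
    order = rng_sched.permutation(len(episodes))
    episodes = [episodes[i] for i in order]

    total_bout = sum(n for _, n in episodes)
    min_gap = max(2, int(round(1.0 * config.frame_rate)))
    n_gaps = len(episodes) + 1
    free = n_frames - total_bout
    if free < n_gaps * min_gap:
        raise ValueError(
            f"duration too short: {n_frames} frames cannot hold {total_bout} bout "
            f"frames plus {n_gaps} wander gaps of >= {min_gap} frames"
        )
    # distribute free frames over gaps (each >= min_gap), deterministic
    weights = rng_sched.dirichlet(np.ones(n_gaps))
    gaps = np.maximum(min_gap, np.floor(weights * free).astype(int))
    while gaps.sum() > free:
        gaps[np.argmax(gaps)] -= 1
    gaps[-1] += free - gaps.sum()

    # --- path synthesis ----------------------------------------------------
    body_x = np.empty(n_frames)
    body_y = np.empty(n_frames)
    nose_x = np.empty(n_frames)
    nose_y = np.empty(n_frames)
    heading = np.empty(n_frames)

    wander_lo, wander_hi = sniff + 1.5, L - sniff - 1.5
    y_mid = geometry.central_width_cm / 2
    cursor = 0
    cur_x = L / 2
    bouts: list[InteractionBout] = []

    def fill_wander(n: int, x_target: float) -> None:
        nonlocal cursor, cur_x
        if n == 0:
            return
        seg = _smooth_bridge(n, cur_x, x_target, rng_path, wander_lo, wander_hi)
        ys = np.clip(
            y_mid + ndimage.uniform_filter1d(np.cumsum(rng_path.normal(0, 0.3, n)), 5),
            1.0,
            geometry.central_width_cm - 1.0,
        )
        dx = np.gradient(seg) if n > 1 else np.array([0.0])
        hd = np.degrees(np.arctan2(np.zeros_like(dx), np.where(dx == 0, 1e-9, dx)))
        body_x[cursor : cursor + n] = seg
        body_y[cursor : cursor + n] = ys
        # keep the wandering nose out of both sniffing strips
        nose_x[cursor : cursor + n] = np.clip(
            seg + 2.0 * np.cos(np.radians(hd)), sniff + 0.2, L - sniff - 0.2
        )
        nose_y[cursor : cursor + n] = ys
        # heading along instantaneous motion, perturbed away from the cones
        heading[cursor : cursor + n] = (hd + rng_path.normal(90.0, 10.0, n)) % 360.0
        cursor += n
        cur_x = seg[-1]

    for (stimulus, n_bout), gap in zip(episodes, gaps[:-1]):
        side = stim_to_side[stimulus]
        at_a = side == "A"
        barrier_x = 0.0 if at_a else L
        approach_x = sniff + 2.0 if at_a else L - sniff - 2.0
        fill_wander(int(gap), approach_x)
        # bout frames: nose inside the strip, heading toward the barrier
        jitter = rng_path.uniform(0.3, sniff - 0.3, n_bout)
        nx = jitter if at_a else L - jitter
        cone = geometry.orientation_cone_deg
        hd = (180.0 if at_a else 0.0) + np.clip(
            rng_path.normal(0.0, 10.0, n_bout), -(cone - 5.0), cone - 5.0
        )
        body_off = 3.0
        bx = np.clip(nx + (body_off if at_a else -body_off), 0.0, L)
        ys = np.clip(y_mid + rng_path.normal(0, 0.5, n_bout), 1.0, geometry.central_width_cm - 1.0)
        sl = slice(cursor, cursor + n_bout)
        body_x[sl], body_y[sl] = bx, ys
        nose_x[sl], nose_y[sl] = nx, ys
        heading[sl] = hd % 360.0
        bouts.append(
            InteractionBout(
                stimulus=stimulus,
                start=cursor,
                end=cursor + n_bout,
                duration_s=n_bout / config.frame_rate,
            )
        )
        cursor += n_bout
        cur_x = approach_x
    fill_wander(int(gaps[-1]), L / 2)
    assert cursor == n_frames

    frames = np.arange(n_frames)
    data = pd.DataFrame(
        {
            "frame": frames,
            "t_s": frames / config.frame_rate,
            "body_x": body_x,
            "body_y": body_y,
            "nose_x": nose_x,
            "nose_y": nose_y,
            "heading_deg": heading,
        }
    )
    track = BehaviorTrack(data, config.frame_rate)
    assign_zones(track, geometry)
    track.speed()
    return track, bouts


def bout_table(bouts: Sequence[InteractionBout]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stimulus": b.stimulus,
                "start_frame": b.start,
                "end_frame": b.end,
                "duration_s": b.duration_s,
            }
            for b in bouts
        ],
        columns=["stimulus", "start_frame", "end_frame", "duration_s"],
    )


# ---------------------------------------------------------------------------
# traces


def gcamp_kernel(frame_rate: float, rise_s: float = 0.2, decay_s: float = 0.75) -> np.ndarray:
    """Double-exponential calcium-indicator kernel, peak-normalized to 1."""
    if decay_s <= 0:
        raise ValueError("kernel decay must be > 0")
    if rise_s < 0:
        raise ValueError("kernel rise must be >= 0")
    t = np.arange(0, 6 * decay_s + rise_s, 1.0 / frame_rate)
    k = np.exp(-t / decay_s)
    if rise_s > 0:
        k = k - np.exp(-t / rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel (rise >= decay?)")
    return k / peak


def _active_stimulus(n_frames: int, bouts: Sequence[InteractionBout]) -> np.ndarray:
    active = np.full(n_frames, "", dtype=object)
    for b in bouts:
        active[b.start : b.end] = b.stimulus
    return active


def generate_traces(
    track: BehaviorTrack,
    bouts: Sequence[InteractionBout],
    config: SimulationConfig,
) -> tuple["TraceMatrix", GroundTruth]:
    """Draw per-neuron transient events and render noisy dF/F traces.

    Private events follow an inhomogeneous Poisson process with rate
    ``baseline_rate x zone_gain(zone(t))``.  During a stimulus's bouts each
    of that stimulus's shared trains emits events at its configured rate and
    every neuron copies each shared event independently with probability
    ``loading_w[stimulus]`` — identical copied events are what correlate
    neuron pairs.  Events are convolved with the GCaMP-like kernel and
    Gaussian noise is added.
    """
    from .events import TraceMatrix  # local import to avoid a cycle

    config.validate()
    kernel = gcamp_kernel(config.frame_rate, config.kernel_rise_s, config.kernel_decay_s)
    n_frames = track.n_frames
    if abs(track.frame_rate - config.frame_rate) > 1e-9:
        raise ValueError(
            f"track frame rate {track.frame_rate} != config frame rate {config.frame_rate}"
        )
    rng_priv, rng_shared, rng_noise = _rngs(
        config.seed, "traces-private", "traces-shared", "traces-noise"
    )

    if "zone" in track.data.columns:
        zones = track.data["zone"].to_numpy()
    else:
        zones = assign_zones(track)
    gain = np.array([config.zone_gain.get(z, 1.0) for z in zones])
    p_frame = 1.0 - np.exp(-config.baseline_rate / 60.0 / config.frame_rate * gain)

    events = rng_priv.random((config.n_neurons, n_frames)) < p_frame[None, :]

    # Each neuron listens to exactly one of the stimulus's shared trains
    # (assigned at random) and copies that train's events with probability
    # w.  Pairs on the same train correlate (~w^2); pairs on different
    # trains stay near zero, so the pooled pairwise-correlation
    # distribution remains centered near zero with a width governed by w —
    # per-event copying from *all* trains would instead shift every pair's
    # correlation upward without widening the distribution.
    active = _active_stimulus(n_frames, bouts)
    for stimulus, (m, rate) in config.shared_trains.items():
        w = config.loading_w.get(stimulus, 0.0)
        mask = active == stimulus
        if m == 0 or rate == 0 or w == 0 or not mask.any():
            continue
        p_train = 1.0 - np.exp(-rate / 60.0 / config.frame_rate)
        membership = rng_shared.integers(0, m, size=config.n_neurons)
        for train_id in range(m):
            train = mask & (rng_shared.random(n_frames) < p_train)
            idx = np.flatnonzero(train)
            members = np.flatnonzero(membership == train_id)
            if idx.size == 0 or members.size == 0:
                continue
            copies = rng_shared.random((members.size, idx.size)) < w
            events[np.ix_(members, idx)] |= copies

    amplitudes = events.astype(float) * config.event_amplitude
    traces = signal.fftconvolve(amplitudes, kernel[None, :], axes=1)[:, :n_frames]
    if config.noise_sd > 0:
        traces = traces + rng_noise.normal(0.0, config.noise_sd, traces.shape)

    event_times = [np.flatnonzero(row) for row in events]
    gt = GroundTruth(event_times=event_times, bout_table=bout_table(bouts))
    tm = TraceMatrix(
        values=traces,
        frame_rate=config.frame_rate,
        neuron_ids=[f"n{i:03d}" for i in range(config.n_neurons)],
    )
    return tm, gt


# ---------------------------------------------------------------------------
# movie


def _place_footprints(
    n: int, fov: tuple[int, int], radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Disjoint soma-like Gaussian-profile disks on a jittered grid."""
    H, W = fov
    cell = int(math.ceil(2 * radius + 4))
    rows, cols = (H - 2) // cell, (W - 2) // cell
    if rows * cols < n:
        raise ValueError(
            f"FOV {fov} too small for {n} non-overlapping footprints of radius {radius}"
        )
    slots = [(r, c) for r in range(rows) for c in range(cols)]
    chosen = [slots[i] for i in rng.permutation(len(slots))[:n]]
    yy, xx = np.mgrid[0:H, 0:W]
    footprints = np.zeros((n, H, W))
    for i, (r, c) in enumerate(chosen):
        cy = 1 + r * cell + cell / 2 + rng.uniform(-1, 1)
        cx = 1 + c * cell + cell / 2 + rng.uniform(-1, 1)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        fp = np.exp(-d2 / (2 * (radius / 1.5) ** 2))
        fp[d2 > radius**2] = 0.0
        footprints[i] = fp
    return footprints


def generate_movie(
    traces: "TraceMatrix",
    config: SimulationConfig,
    ground_truth: GroundTruth | None = None,
) -> tuple["CalciumMovie", GroundTruth]:
    """Render a movie: sum of footprint x trace, background, noise, jitter.

    Optional planted rigid shifts (alternating +/- ``jitter_px``) and
    stuck-at-zero defective pixels are recorded in the returned
    :class:`GroundTruth` for oracle-based testing of the preprocessing
    chain.
    """
    from .movieproc import CalciumMovie  # local import to avoid a cycle

    config.validate()
    rng_fp, rng_mnoise, rng_defect = _rngs(
        config.seed, "movie-footprints", "movie-noise", "movie-defects"
    )
    n_neurons, n_frames = traces.values.shape
    footprints = _place_footprints(
        n_neurons, config.fov, config.footprint_radius_px, rng_fp
    )
    H, W = config.fov
    scale = 50.0  # fluorescence counts per unit dF/F
    # resting fluorescence keeps every soma visible in every frame and the
    # smooth static texture mimics out-of-focus neuropil/vasculature; both
    # give rigid registration stable landmarks
    movie = np.tensordot(
        traces.values.T + config.resting_fluor, footprints, axes=(1, 0)
    ) * scale
    movie += config.background
    if config.background_texture_sd > 0:
        texture = ndimage.gaussian_filter(
            rng_fp.normal(0.0, 1.0, (H, W)), sigma=6.0
        )
        texture *= config.background_texture_sd / max(texture.std(), 1e-12)
        movie += texture[None, :, :]
    if config.movie_noise_sd > 0:
        movie += rng_mnoise.normal(0.0, config.movie_noise_sd, movie.shape)

    # intermittent rigid twitches: a minority of frames displaced by up to
    # +/- jitter_px; the mean projection then stays a sharp reference
    shifts = np.zeros((n_frames, 2))
    if config.jitter_px > 0:
        jittered = rng_mnoise.random(n_frames) < 0.25
        jittered[0] = False
        amp = rng_mnoise.integers(-config.jitter_px, config.jitter_px + 1, (n_frames, 2))
        shifts[jittered] = amp[jittered]
        for t in range(n_frames):
            if shifts[t].any():
                movie[t] = ndimage.shift(movie[t], shifts[t], order=1, mode="nearest")

    defective = np.zeros((0, 2), dtype=int)
    if config.n_defective_pixels > 0:
        ys = rng_defect.integers(0, H, config.n_defective_pixels)
        xs = rng_defect.integers(0, W, config.n_defective_pixels)
        defective = np.stack([ys, xs], axis=1)
        movie[:, ys, xs] = 0.0

    movie = np.clip(movie, 0.0, None)
    gt = ground_truth or GroundTruth(event_times=[], bout_table=pd.DataFrame())
    gt.footprints = footprints
    gt.planted_shifts = shifts
    gt.defective_pixels = defective
    return CalciumMovie(movie, frame_rate=traces.frame_rate), gt


def generate_session(
    config: SimulationConfig,
    geometry: ChamberGeometry | None = None,
    render_movie: bool = False,
):
    """Convenience wrapper: behavior + traces (+ movie) for one session."""
    track, bouts = generate_behavior(config, geometry)
    traces, gt = generate_traces(track, bouts, config)
    movie = None
    if render_movie:
        movie, gt = generate_movie(traces, config, gt)
    return track, bouts, traces, gt, movie
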