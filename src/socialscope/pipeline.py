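"""End-to-end orchestration: stream alignment, the full run, and the report.

``run_pipeline`` executes simulate -> behavior -> events -> responsiveness
-> decorrelation (-> VAE) for the three sessions of one synthetic subject
and serializes every stage's artifact under one run directory, so every
number in the report is traceable to a file.  All randomness derives from
one master seed.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np

from . import io as sio
from .behavior import (
    PREFERRED_STIMULUS,
    SessionLabeling,
    interaction_times,
    occupancy_raster,
    session_discrimination_index,
)
from .decorrelation import delta_fwhm, epoch_correlations
from .events import detect_transients_matrix, rate_by_zone
from .responsiveness import behavior_vector, responsive_fraction, shuffle_test_population
from .simdata import SimulationConfig, generate_behavior, generate_traces
from .vaefeatures import VaeConfig, embed, radius, relative_radius, train_vae

logger = logging.getLogger("socialscope")

DEFAULT_CONFIG: dict = {
    "sessions": ["S1", "S2", "S3"],
    "simulation": {},  # overrides for SimulationConfig fields
    "preference_by_session": {
        "S1": {"M1": 0.20, "O": 0.10},
        "S2": {"M1": 0.18, "O": 0.10},
        "S3": {"M2": 0.20, "M1": 0.12},
    },
    "n_shuffles": 1000,
    "cutoff_pct": 99.95,
    "min_epoch_frames": 50,
    "raster_bin_s": 20.0,
    "run_vae": False,
    "vae": {"epochs": 20, "frames_per_session": 128},
}


def align_streams(
    imaging_rate: float,
    behavior_rate: float,
    n_imaging: int,
    n_behavior: int,
    offset_frames: int = 0,
) -> np.ndarray:
    """Map each imaging frame to its nearest behavior sample.

    Both streams start at the shared trigger; with equal rates and zero
    offset the mapping is the identity.  The mapping is total (clipped to
    the behavior stream) and non-decreasing.
    """
    if imaging_rate <= 0 or behavior_rate <= 0:
        raise ValueError("rates must be > 0")
    if offset_frames < 0 and -offset_frames >= n_behavior:
        raise ValueError(
            f"offset {offset_frames} beyond behavior stream length {n_behavior}"
        )
    k = np.arange(n_imaging)
    mapping = np.rint(k * behavior_rate / imaging_rate).astype(int) + offset_frames
    return np.clip(mapping, 0, n_behavior - 1)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def run_pipeline(config: dict | None = None, out_dir=None, seed: int = 0) -> dict:
    """Run the full synthetic-subject analysis; returns the summary dict.

    Artifacts per session: behavior/bout/trace/event CSVs, zone-rate CSV,
    responsiveness CSV, correlation values and FWHM, and (optionally) the
    VAE embedding CSV.  The summary JSON collects DI, responsive fraction,
    FWHM per stimulus, delta-FWHM, and radii.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    for key in ("sessions", "n_shuffles", "cutoff_pct"):
        if cfg.get(key) is None:
            raise KeyError(f"config missing required key {key!r}")
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    summary: dict = {"seed": seed, "sessions": {}}
    frames_by_session: dict[str, np.ndarray] = {}
    vae_frame_labels: list[str] = []

    for i, session_id in enumerate(cfg["sessions"]):
        sim_kwargs = dict(cfg["simulation"])
        sim_kwargs.setdefault("preference", cfg["preference_by_session"].get(session_id, {}))
        sim = SimulationConfig(session_id=session_id, seed=seed + 1000 * i, **sim_kwargs)
        logger.info("session %s: simulating (%d neurons, %d frames)",
                    session_id, sim.n_neurons, sim.n_frames)
        track, bouts = generate_behavior(sim)
        traces, gt = generate_traces(track, bouts, sim)
        labeling = SessionLabeling.default(session_id)

        di = session_discrimination_index(bouts, labeling)
        raster = occupancy_raster(bouts, sim.duration_s, sim.frame_rate, cfg["raster_bin_s"])

        events = detect_transients_matrix(traces)
        zones = track.data["zone"].to_numpy()
        zone_rates = rate_by_zone(events, zones, sim.frame_rate)

        pref = PREFERRED_STIMULUS[session_id]
        b = behavior_vector(traces.n_frames, bouts, pref)
        results = shuffle_test_population(
            b, traces.values, traces.neuron_ids,
            n_shuffles=cfg["n_shuffles"], cutoff_pct=cfg["cutoff_pct"], seed=seed + 77 + i,
        )
        frac = responsive_fraction(results)

        fwhm_by_stim: dict[str, float | None] = {}
        corr_notes = {}
        for stimulus in labeling.stimuli:
            dist = epoch_correlations(
                traces, bouts, stimulus, session_id, min_frames=cfg["min_epoch_frames"]
            )
            fwhm_by_stim[stimulus] = dist.fwhm if dist.ok else None
            corr_notes[stimulus] = dist.note
            if out_dir is not None and dist.ok:
                np.savetxt(out_dir / f"{session_id}_corr_{stimulus}.csv",
                           dist.values, header="pearson_r", comments="")
        dfwhm = (
            delta_fwhm(session_id, fwhm_by_stim)
            if all(v is not None for v in fwhm_by_stim.values())
            else float("nan")
        )

        summary["sessions"][session_id] = {
            "discrimination_index": di,
            "interaction_times_s": interaction_times(bouts),
            "responsive_fraction_pct": frac,
            "fwhm": {k: (v if v is not None else "undefined") for k, v in fwhm_by_stim.items()},
            "delta_fwhm": dfwhm if math.isfinite(dfwhm) else "undefined",
            "n_neurons": traces.n_neurons,
            "n_bouts": len(bouts),
            "correlation_notes": corr_notes,
        }

        if out_dir is not None:
            sio.write_behavior_csv(track, out_dir / f"{session_id}_behavior.csv")
            sio.write_bouts_csv(bouts, out_dir / f"{session_id}_bouts.csv")
            sio.write_traces_csv(traces, out_dir / f"{session_id}_traces.csv")
            sio.write_events_csv(events, out_dir / f"{session_id}_events.csv")
            zone_rates.to_csv(out_dir / f"{session_id}_zone_rates.csv", index=False)
            sio.write_responsiveness_csv(results, out_dir / f"{session_id}_responsiveness.csv")
            raster.to_csv(out_dir / f"{session_id}_raster.csv")

        if cfg["run_vae"]:
            # population-activity frames: neurons tiled into a square image
            side = 64
            n_keep = cfg["vae"]["frames_per_session"]
            idx = np.flatnonzero(b > 0)[:n_keep]
            imgs = _activity_frames(traces.values[:, idx], side)
            frames_by_session[session_id] = imgs
            vae_frame_labels.extend([session_id] * len(idx))

    if cfg["run_vae"] and frames_by_session:
        all_frames = np.concatenate(list(frames_by_session.values()), axis=0)
        labels = np.array(vae_frame_labels)
        vcfg = VaeConfig(seed=seed)
        model, history = train_vae(all_frames, vcfg, epochs=cfg["vae"]["epochs"])
        emb = embed(all_frames, model, labels)
        coords_by_session = {s: emb.subset(s) for s in frames_by_session}
        rel = relative_radius(coords_by_session, reference=cfg["sessions"][0])
        summary["vae"] = {
            "radius": {s: radius(c) for s, c in coords_by_session.items()},
            "relative_radius": rel,
            "final_loss": history[-1]["total"],
        }
        if out_dir is not None:
            sio.write_embedding_csv(emb.coords, labels, out_dir / "embedding.csv")

    if out_dir is not None:
        sio.write_summary_json(summary, out_dir / "summary.json")
    return summary


def _activity_frames(trace_block: np.ndarray, side: int) -> np.ndarray:
    """Tile a (neurons, frames) activity block into square pseudo-frames.

    Stand-in for ROI-masked dF/F movie frames when no movie was rendered:
    each neuron paints a small square patch with its momentary dF/F.
    """
    n_neurons, n_frames = trace_block.shape
    grid = int(math.ceil(math.sqrt(n_neurons)))
    patch = side // grid
    frames = np.zeros((n_frames, side, side))
    for i in range(n_neurons):
        r, c = divmod(i, grid)
        frames[:, r * patch : (r + 1) * patch, c * patch : (c + 1) * patch] = (
            trace_block[i][:, None, None]
        )
    lo, hi = frames.min(), frames.max()
    return (frames - lo) / (hi - lo) if hi > lo else frames


def report(summary: dict, out_path=None) -> str:
    """Render the summary as a markdown report; flagged stats print as 'undefined'."""
    lines = ["# socialscope run report", ""]
    lines.append(f"Master seed: {summary.get('seed', 'n/a')}")
    lines.append("")
    for session_id, s in summary.get("sessions", {}).items():
        lines.append(f"## Session {session_id}")
        di = s["discrimination_index"]
        di_str = f"{di:.3f}" if isinstance(di, float) and math.isfinite(di) else "undefined"
        lines.append(f"- discrimination index: {di_str}")
        times = ", ".join(
            f"{k}: {v:.1f} s" for k, v in sorted(s["interaction_times_s"].items())
        )
        lines.append(f"- interaction time: {times}")
        lines.append(f"- responsive neurons: {s['responsive_fraction_pct']:.2f}%")
        fw = ", ".join(
            f"{k}: {v:.3f}" if isinstance(v, float) else f"{k}: undefined"
            for k, v in sorted(s["fwhm"].items())
        )
        lines.append(f"- correlation FWHM: {fw}")
        d = s["delta_fwhm"]
        lines.append(
            f"- delta FWHM: {d:.3f}" if isinstance(d, float) and math.isfinite(d)
            else "- delta FWHM: undefined"
        )
        lines.append("")
    if "vae" in summary:
        lines.append("## VAE latent features")
        for s, r in summary["vae"]["relative_radius"].items():
            r_str = f"{r:.3f}" if isinstance(r, float) and math.isfinite(r) else "undefined"
            lines.append(f"- relative radius {s}: {r_str}")
        lines.append("")
    text = "\n".join(lines)
    if out_path is not None:
        Path(out_path).write_text(text)
    return text
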