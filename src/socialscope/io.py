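"""Readers and writers for the pipeline's text and TIFF artifacts.

Schemas: behavior CSV (frame, t_s, body_x, body_y, nose_x, nose_y,
heading_deg[, zone, speed_cms]); bout CSV (stimulus, start_frame,
end_frame, duration_s); trace CSV (neurons x frames, one row per neuron,
index = neuron id); events CSV (neuron, peak_frame, amplitude,
onset_frame); responsiveness CSV (neuron, sa, percentile, responsive);
embeddings CSV (frame, z1, z2, condition); movies as multi-page TIFF;
summaries as versioned JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .behavior import BehaviorTrack, InteractionBout
from .events import TraceMatrix, TransientEvent
from .movieproc import CalciumMovie, SpatialFootprint
from .responsiveness import ResponsivenessResult

SCHEMA_VERSION = 1


def write_behavior_csv(track: BehaviorTrack, path) -> None:
    track.data.to_csv(path, index=False)


def read_behavior_csv(path, frame_rate: float) -> BehaviorTrack:
    return BehaviorTrack(pd.read_csv(path), frame_rate)


def write_bouts_csv(bouts: Sequence[InteractionBout], path) -> None:
    from .simdata import bout_table

    bout_table(bouts).to_csv(path, index=False)


def read_bouts_csv(path, frame_rate: float) -> list[InteractionBout]:
    df = pd.read_csv(path)
    return [
        InteractionBout(
            stimulus=row.stimulus,
            start=int(row.start_frame),
            end=int(row.end_frame),
            duration_s=(int(row.end_frame) - int(row.start_frame)) / frame_rate,
        )
        for row in df.itertuples()
    ]


def write_traces_csv(traces: TraceMatrix, path) -> None:
    df = pd.DataFrame(traces.values, index=traces.neuron_ids)
    df.index.name = "neuron"
    df.to_csv(path)


def read_traces_csv(path, frame_rate: float) -> TraceMatrix:
    df = pd.read_csv(path, index_col="neuron")
    return TraceMatrix(df.to_numpy(), frame_rate, [str(i) for i in df.index])


def write_events_csv(events_per_neuron: Sequence[Sequence[TransientEvent]], path) -> None:
    rows = [
        {
            "neuron": e.neuron_id,
            "peak_frame": e.peak_frame,
            "amplitude": e.amplitude,
            "onset_frame": e.onset_frame,
        }
        for events in events_per_neuron
        for e in events
    ]
    pd.DataFrame(rows, columns=["neuron", "peak_frame", "amplitude", "onset_frame"]).to_csv(
        path, index=False
    )


def write_responsiveness_csv(results: Sequence[ResponsivenessResult], path) -> None:
    pd.DataFrame(
        [
            {
                "neuron": r.neuron_id,
                "sa": r.sa,
                "percentile": r.percentile,
                "responsive": r.responsive,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


def write_movie_tiff(movie: CalciumMovie, path) -> None:
    tifffile.imwrite(path, movie.data.astype(np.float32))


def read_movie_tiff(path, frame_rate: float) -> CalciumMovie:
    data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim == 2:
        data = data[None]
    return CalciumMovie(data, frame_rate)


def write_footprints(footprints: Sequence[SpatialFootprint], json_path, tiff_path=None) -> None:
    meta = [
        {
            "index": i,
            "area": fp.area,
            "centroid": list(fp.centroid),
            "snr": fp.snr,
            "n_components": fp.n_components,
            "eccentricity": fp.eccentricity,
        }
        for i, fp in enumerate(footprints)
    ]
    Path(json_path).write_text(json.dumps({"schema_version": SCHEMA_VERSION, "rois": meta}, indent=1))
    if tiff_path is not None and footprints:
        stack = np.stack([fp.map for fp in footprints]).astype(np.float32)
        tifffile.imwrite(tiff_path, stack)


def write_embedding_csv(coords: np.ndarray, conditions, path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(coords)),
            "z1": coords[:, 0],
            "z2": coords[:, 1],
            "condition": conditions if conditions is not None else "",
        }
    )
    df.to_csv(path, index=False)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_summary_json(summary: dict, path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **summary}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=_json_default))


def read_summary_json(path) -> dict:
    return json.loads(Path(path).read_text())
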