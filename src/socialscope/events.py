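"""Calcium-transient detection and per-neuron activity statistics.

Transients are local maxima of the dF/F trace exceeding ``k_sigma`` robust
noise SDs, with minimum separation and prominence.  Downstream statistics:
zone-conditioned rates (events/min over zone occupancy), the five-zone
normalized response field with its smoothing spline, inter-event intervals,
area under the curve per second over an interaction bout, and the
rate-versus-running-speed correlation in 10 s bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.interpolate import make_interp_spline

from ._utils import robust_noise_sd
from .behavior import ZONES, ChamberGeometry, InteractionBout

__all__ = [
    "TraceMatrix",
    "TransientEvent",
    "detect_transients",
    "detect_transients_matrix",
    "rate_by_zone",
    "response_field",
    "inter_event_intervals",
    "auc_per_second",
    "rate_speed_correlation",
]


@dataclass
class TraceMatrix:
    """dF/F traces, one row per accepted ROI, on a common frame clock."""

    values: np.ndarray  # (neurons, frames)
    frame_rate: float
    neuron_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("traces contain non-finite values")
        if len(self.neuron_ids) != self.values.shape[0]:
            raise ValueError("neuron_ids length must match trace rows")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class TransientEvent:
    neuron_id: str
    peak_frame: int
    amplitude: float  # dF/F at the peak
    onset_frame: int


def detect_transients(
    trace: np.ndarray,
    frame_rate: float,
    neuron_id: str = "n000",
    k_sigma: float = 3.0,
    min_separation_s: float = 1.0,
    min_prominence: float | None = None,
    smooth_frames: int = 3,
) -> list[TransientEvent]:
    """Peak-finder transient detection on one dF/F trace.

    The trace is first smoothed with a short boxcar (``smooth_frames``
    samples, a crude matched filter for the indicator kernel: suppresses
    single-sample noise excursions while barely attenuating multi-frame
    transients).  Peaks of the smoothed trace must exceed ``k_sigma`` x its
    robust noise SD, be separated by at least ``min_separation_s`` and have
    prominence of at least ``min_prominence`` (default 2 x noise SD).  The
    amplitude is the raw dF/F at the smoothed peak frame — an unbiased
    estimate of the transient peak (a max over neighboring raw samples
    would bias it upward by a fraction of the noise SD); the onset is the
    peak's left base.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if smooth_frames > 1:
        from scipy.ndimage import uniform_filter1d

        smoothed = uniform_filter1d(trace, size=smooth_frames, mode="nearest")
        # first-difference noise estimation needs the unsmoothed trace
        # (smoothing correlates neighbors); boxcar averaging of white noise
        # divides its SD by sqrt(window)
        noise = robust_noise_sd(trace) / np.sqrt(smooth_frames)
    else:
        smoothed = trace
        noise = robust_noise_sd(trace)
    height = k_sigma * noise
    prominence = 2.0 * noise if min_prominence is None else min_prominence
    distance = max(1, int(round(min_separation_s * frame_rate)))
    peaks, props = signal.find_peaks(
        smoothed, height=height, distance=distance, prominence=max(prominence, 1e-12)
    )
    bases = props.get("left_bases", peaks)
    return [
        TransientEvent(
            neuron_id=neuron_id,
            peak_frame=int(p),
            amplitude=float(trace[p]),
            onset_frame=int(b),
        )
        for p, b in zip(peaks, bases)
    ]


def detect_transients_matrix(traces: TraceMatrix, **kwargs) -> list[list[TransientEvent]]:
    """Per-neuron transient detection over a whole trace matrix."""
    return [
        detect_transients(traces.values[i], traces.frame_rate, traces.neuron_ids[i], **kwargs)
        for i in range(traces.n_neurons)
    ]


def rate_by_zone(
    events_per_neuron: Sequence[Sequence[TransientEvent]],
    zone_labels: np.ndarray,
    frame_rate: float,
) -> pd.DataFrame:
    """Event count, occupancy and rate (events/min) per neuron per zone.

    An event is attributed to the zone occupied at its peak frame.  Zones
    the animal never visited get NaN rates and ``defined = False`` rather
    than a spurious 0.
    """
    zone_labels = np.asarray(zone_labels)
    occupancy_s = {z: float((zone_labels == z).sum()) / frame_rate for z in ZONES}
    rows = []
    for i, events in enumerate(events_per_neuron):
        peaks = np.array([e.peak_frame for e in events], dtype=int)
        for z in ZONES:
            count = int((zone_labels[peaks] == z).sum()) if peaks.size else 0
            occ = occupancy_s[z]
            defined = occ > 0
            rows.append(
                {
                    "neuron": i,
                    "zone": z,
                    "count": count,
                    "occupancy_s": occ,
                    "rate_per_min": count / (occ / 60.0) if defined else float("nan"),
                    "defined": defined,
                }
            )
    return pd.DataFrame(rows)


def response_field(
    zone_rates_by_group: Mapping[str, Sequence[Sequence[float]]],
    reference_group: str,
    geometry: ChamberGeometry | None = None,
    n_curve_points: int = 200,
):
    """Normalized five-zone response profile with a smoothing spline.

    ``zone_rates_by_group`` maps a group label to per-subject 5-vectors of
    mean transient rates ordered along the chamber (SNIFF_A, ZONE_A, TZ,
    ZONE_B, SNIFF_B).  Group means are normalized by the maximum of the
    reference group's mean profile (so the reference group's best zone is
    exactly 1.0) and interpolated with a cubic B-spline through the five
    zone centers.

    Returns ``{group: (points, curve_x, curve_y)}``.
    """
    geometry = geometry or ChamberGeometry()
    if reference_group not in zone_rates_by_group:
        raise ValueError(f"reference group {reference_group!r} missing")
    means = {}
    for group, subjects in zone_rates_by_group.items():
        arr = np.asarray(subjects, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(ZONES):
            raise ValueError(f"group {group!r}: expected (subjects, 5) rates")
        means[group] = arr.mean(axis=0)
    ref_max = means[reference_group].max()
    if ref_max <= 0:
        raise ValueError("reference group maximal rate is 0; cannot normalize")
    centers = geometry.zone_centers()
    curve_x = np.linspace(centers[0], centers[-1], n_curve_points)
    out = {}
    for group, mean in means.items():
        points = mean / ref_max
        spline = make_interp_spline(centers, points, k=3)
        out[group] = (points, curve_x, spline(curve_x))
    return out


def inter_event_intervals(
    events: Sequence[TransientEvent], frame_rate: float
) -> np.ndarray:
    """Successive peak-to-peak intervals in seconds (empty for < 2 events)."""
    peaks = np.sort(np.array([e.peak_frame for e in events], dtype=float))
    if peaks.size < 2:
        return np.empty(0)
    return np.diff(peaks) / frame_rate


def auc_per_second(trace: np.ndarray, bout: InteractionBout, frame_rate: float) -> float:
    """Trapezoidal integral of dF/F over a bout divided by the integrated span.

    For a constant trace this returns the constant; for a linear ramp from
    0 to 1 it returns 0.5.  A single-frame bout returns the sample value.
    """
    trace = np.asarray(trace, dtype=float)
    if bout.end > trace.size or bout.start < 0:
        raise ValueError("bout outside recording")
    seg = trace[bout.start : bout.end]
    if seg.size == 0:
        raise ValueError("zero-length bout")
    if seg.size == 1:
        return float(seg[0])
    span = (seg.size - 1) / frame_rate
    return float(np.trapezoid(seg, dx=1.0 / frame_rate) / span)


def rate_speed_correlation(
    events_per_neuron: Sequence[Sequence[TransientEvent]],
    speed: np.ndarray,
    frame_rate: float,
    bin_s: float = 10.0,
) -> dict:
    """Pearson correlation of population transient rate vs speed per 10 s bin.

    Returns ``{"r", "p", "n_bins", "defined"}``; undefined (NaN r) when
    either binned series has zero variance or fewer than 3 bins exist.
    """
    speed = np.asarray(speed, dtype=float)
    frames_per_bin = int(round(bin_s * frame_rate))
    n_bins = speed.size // frames_per_bin
    if n_bins < 3:
        raise ValueError(f"need >= 3 bins, got {n_bins}")
    peaks = np.concatenate(
        [[e.peak_frame for e in ev] for ev in events_per_neuron if ev] or [[]]
    ).astype(int)
    counts = np.zeros(n_bins)
    if peaks.size:
        idx = peaks // frames_per_bin
        idx = idx[idx < n_bins]
        np.add.at(counts, idx, 1.0)
    rate = counts / max(len(events_per_neuron), 1) / (bin_s / 60.0)  # events/min/neuron
    mean_speed = speed[: n_bins * frames_per_bin].reshape(n_bins, frames_per_bin).mean(axis=1)
    if np.std(rate) == 0 or np.std(mean_speed) == 0:
        warnings.warn("rate-speed correlation undefined: zero variance")
        return {"r": float("nan"), "p": float("nan"), "n_bins": n_bins, "defined": False}
    r, p = stats.pearsonr(rate, mean_speed)
    return {"r": float(r), "p": float(p), "n_bins": n_bins, "defined": True}
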