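"""Three-chamber social-preference behavior analysis.

The arena is a 45 x 10 cm central chamber flanked by two 10 x 10 cm end
compartments separated from it by wire barriers.  Along the chamber axis
(x, origin at the side-A barrier) five zones are defined: a 3 cm sniffing
strip at each barrier, a 10 cm end zone on each side, and the transition
zone in between.  An interaction bout requires the nose inside a sniffing
strip with the animal oriented toward the barrier.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ZONES = ("SNIFF_A", "ZONE_A", "TZ", "ZONE_B", "SNIFF_B")
INVALID = "INVALID"

#: stimulus expected to attract more interaction in each session
PREFERRED_STIMULUS = {"S1": "M1", "S2": "M1", "S3": "M2"}


@dataclass(frozen=True)
class ChamberGeometry:
    """Dimensions of the modified three-chamber arena, in cm."""

    central_length_cm: float = 45.0
    central_width_cm: float = 10.0
    end_compartment_cm: float = 10.0
    sniff_zone_cm: float = 3.0
    end_zone_cm: float = 10.0
    orientation_cone_deg: float = 45.0

    def __post_init__(self) -> None:
        if not (0 < self.sniff_zone_cm <= self.end_zone_cm <= self.central_length_cm / 2):
            raise ValueError(
                "require 0 < sniff_zone_cm <= end_zone_cm <= central_length_cm/2, got "
                f"{self.sniff_zone_cm}, {self.end_zone_cm}, {self.central_length_cm / 2}"
            )
        for name in ("central_length_cm", "central_width_cm", "end_compartment_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def zone_centers(self) -> np.ndarray:
        """x coordinate of the center of each of the five zones (cm)."""
        L, s, e = self.central_length_cm, self.sniff_zone_cm, self.end_zone_cm
        return np.array([s / 2, e / 2, L / 2, L - e / 2, L - s / 2])


@dataclass
class BehaviorTrack:
    """Per-frame tracking record on the imaging frame clock.

    ``data`` columns: frame, t_s, body_x, body_y, nose_x, nose_y,
    heading_deg, and (after :func:`assign_zones`) zone and speed_cms.
    Heading is measured in degrees from the +x axis (0 points at barrier
    B, 180 at barrier A).
    """

    data: pd.DataFrame
    frame_rate: float

    REQUIRED = ("frame", "t_s", "body_x", "body_y", "nose_x", "nose_y", "heading_deg")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"behavior track missing columns: {missing}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        t = self.data["t_s"].to_numpy()
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def speed(self) -> np.ndarray:
        """Body speed in cm/s (forward difference, last value repeated)."""
        if "speed_cms" in self.data.columns:
            return self.data["speed_cms"].to_numpy()
        xy = self.data[["body_x", "body_y"]].to_numpy()
        d = np.linalg.norm(np.diff(xy, axis=0), axis=1) * self.frame_rate
        speed = np.concatenate([d, d[-1:]]) if len(d) else np.zeros(1)
        self.data["speed_cms"] = speed
        return speed


@dataclass(frozen=True)
class InteractionBout:
    """A maximal run of qualifying interaction frames, [start, end)."""

    stimulus: str
    start: int
    end: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("bout must satisfy start < end")

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SessionLabeling:
    """Which stimulus occupies which end compartment in a session."""

    session_id: str
    side_to_stimulus: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.side_to_stimulus) != {"A", "B"}:
            raise ValueError("side_to_stimulus must map exactly sides 'A' and 'B'")

    @classmethod
    def default(cls, session_id: str) -> "SessionLabeling":
        """S1: mouse M1 vs object O; S2: positions swapped; S3: novel M2 vs M1."""
        table = {
            "S1": {"A": "M1", "B": "O"},
            "S2": {"A": "O", "B": "M1"},
            "S3": {"A": "M2", "B": "M1"},
        }
        if session_id not in table:
            raise ValueError(f"unknown session id {session_id!r}")
        return cls(session_id, table[session_id])

    @property
    def stimuli(self) -> tuple[str, str]:
        return (self.side_to_stimulus["A"], self.side_to_stimulus["B"])


def assign_zones(track: BehaviorTrack, geometry: ChamberGeometry | None = None) -> np.ndarray:
    """Assign one of the five zone labels to every frame.

    The sniffing strips are decided by the nose position, the end/transition
    zones by the body centroid; the sniff label wins where both apply (the
    3 cm strip lies inside the 10 cm end zone).  Frames with coordinates
    outside the chamber are labeled ``INVALID`` and excluded downstream.
    Intervals are half-open: [0, sniff), [0, end), [end, L-end), ...

    Returns the label array and stores it in ``track.data["zone"]``.
    """
    geometry = geometry or ChamberGeometry()
    L, W = geometry.central_length_cm, geometry.central_width_cm
    body_x = track.data["body_x"].to_numpy()
    body_y = track.data["body_y"].to_numpy()
    nose_x = track.data["nose_x"].to_numpy()

    valid = (body_x >= 0) & (body_x <= L) & (body_y >= 0) & (body_y <= W)
    zones = np.full(track.n_frames, "TZ", dtype=object)
    zones[body_x < geometry.end_zone_cm] = "ZONE_A"
    zones[body_x >= L - geometry.end_zone_cm] = "ZONE_B"
    zones[nose_x < geometry.sniff_zone_cm] = "SNIFF_A"
    zones[nose_x >= L - geometry.sniff_zone_cm] = "SNIFF_B"
    zones[~valid] = INVALID
    n_invalid = int((~valid).sum())
    if n_invalid:
        warnings.warn(f"{n_invalid} frames outside chamber bounds flagged INVALID")
    track.data["zone"] = zones
    return zones


def _angular_difference_deg(a: np.ndarray, b: float) -> np.ndarray:
    return np.abs((a - b + 180.0) % 360.0 - 180.0)


def detect_bouts(
    track: BehaviorTrack,
    geometry: ChamberGeometry | None = None,
    labeling: SessionLabeling | None = None,
    min_duration_s: float = 0.2,
) -> list[InteractionBout]:
    """Find interaction bouts: nose in a sniffing strip, oriented at the barrier.

    A frame qualifies for side A when the nose x lies within the sniff strip
    and the heading is within ``orientation_cone_deg`` of the barrier
    direction (180 deg for side A, 0 deg for side B).  Maximal qualifying
    runs of at least ``min_duration_s`` become bouts; runs on opposite sides
    are never merged and a single disqualified frame splits a run.
    """
    geometry = geometry or ChamberGeometry()
    labeling = labeling or SessionLabeling.default("S1")
    L = geometry.central_length_cm
    nose_x = track.data["nose_x"].to_numpy()
    heading = track.data["heading_deg"].to_numpy()
    cone = geometry.orientation_cone_deg

    qual_a = (nose_x >= 0) & (nose_x < geometry.sniff_zone_cm) & (
        _angular_difference_deg(heading, 180.0) <= cone
    )
    qual_b = (nose_x >= L - geometry.sniff_zone_cm) & (nose_x <= L) & (
        _angular_difference_deg(heading, 0.0) <= cone
    )

    min_frames = max(1, math.ceil(min_duration_s * track.frame_rate - 1e-9))
    bouts: list[InteractionBout] = []
    for side, qual in (("A", qual_a), ("B", qual_b)):
        stimulus = labeling.side_to_stimulus[side]
        padded = np.concatenate([[False], qual, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for start, end in zip(edges[::2], edges[1::2]):
            if end - start >= min_frames:
                bouts.append(
                    InteractionBout(
                        stimulus=stimulus,
                        start=int(start),
                        end=int(end),
                        duration_s=(end - start) / track.frame_rate,
                    )
                )
    bouts.sort(key=lambda b: b.start)
    return bouts


def discrimination_index(t_pref: float, t_other: float) -> float:
    """DI = (t_pref - t_other) / (t_pref + t_other), in [-1, 1].

    Positive values mean more time with the session's preferred-class
    stimulus (M1 vs O in S1/S2; M2 vs M1 in S3).  Undefined (NaN, with a
    warning) when the animal interacted with neither stimulus.
    """
    if t_pref < 0 or t_other < 0:
        raise ValueError("interaction times must be non-negative")
    total = t_pref + t_other
    if total == 0:
        warnings.warn("discrimination index undefined: no interaction time")
        return float("nan")
    return (t_pref - t_other) / total


def interaction_times(bouts: Sequence[InteractionBout]) -> dict[str, float]:
    """Total interaction time (s) per stimulus."""
    out: dict[str, float] = {}
    for b in bouts:
        out[b.stimulus] = out.get(b.stimulus, 0.0) + b.duration_s
    return out


def session_discrimination_index(
    bouts: Sequence[InteractionBout], labeling: SessionLabeling
) -> float:
    """DI of a session using the session's preferred-stimulus convention."""
    pref = PREFERRED_STIMULUS[labeling.session_id]
    others = [s for s in labeling.stimuli if s != pref]
    if len(others) != 1:
        raise ValueError(f"cannot identify non-preferred stimulus in {labeling.stimuli}")
    times = interaction_times(bouts)
    return discrimination_index(times.get(pref, 0.0), times.get(others[0], 0.0))


def occupancy_raster(
    bouts: Sequence[InteractionBout],
    session_length_s: float,
    frame_rate: float,
    bin_s: float = 20.0,
) -> pd.DataFrame:
    """Percent of each time bin spent interacting, per stimulus.

    Returns a DataFrame (index = stimulus, columns = bin start times in s)
    of values in [0, 100]; a 600 s session at the default 20 s bin gives 30
    bins.  Bout overlap with each bin is computed in seconds so partial
    coverage yields partial percentages.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    n_bins = math.ceil(session_length_s / bin_s)
    edges = np.arange(n_bins + 1) * bin_s
    stimuli = sorted({b.stimulus for b in bouts})
    raster = pd.DataFrame(
        np.zeros((len(stimuli), n_bins)), index=stimuli, columns=edges[:-1]
    )
    for b in bouts:
        t0, t1 = b.start / frame_rate, b.end / frame_rate
        lo = np.maximum(edges[:-1], t0)
        hi = np.minimum(edges[1:], t1)
        overlap = np.clip(hi - lo, 0.0, None)
        raster.loc[b.stimulus] += overlap / bin_s * 100.0
    # bouts are pairwise disjoint, so per-bin totals cannot exceed 100
    return raster
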