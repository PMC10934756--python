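"""Eye-aspect-ratio (EAR) blink analysis.

The EAR is a per-frame scalar computed from six eye-contour landmarks:
``EAR = (|p2 - p6| + |p3 - p5|) / (2 |p1 - p4|)``, where p1/p4 are the eye
corners and p2,p3 / p6,p5 the upper / lower lid points.  High values mean the
eye is open; the ratio drops toward zero during a blink or closure.  Because
it is a ratio of Euclidean distances, the EAR is invariant under translation,
rotation and uniform scaling of the landmark set.

This module computes EAR series from landmark trajectories, segments closed
intervals by thresholding, extracts duration-gated blink events, and produces
summary statistics and the unit-interval "EAR channel" score consumed by the
fuzzy fusion stage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Point2D",
    "EyeLandmarks",
    "EarSeries",
    "ClosedInterval",
    "BlinkEvent",
    "BlinkSource",
    "euclidean_distance",
    "compute_ear",
    "compute_ear_series",
    "segment_ear_series",
    "extract_blink_events",
    "blink_statistics",
    "ear_channel_score",
    "read_landmarks_csv",
    "write_ear_series_csv",
    "write_events_json",
    "read_events_json",
]

#: Conventional EAR open/closed threshold; the field's usual default.
DEFAULT_EAR_THRESHOLD = 0.2
#: Blink-duration gate: closures shorter than this are noise, longer are
#: prolonged closures (drowsiness evidence), not blinks.
DEFAULT_MIN_BLINK_S = 0.04
DEFAULT_MAX_BLINK_S = 0.5


class BlinkSource(str, Enum):
    EAR = "EAR"
    EOG = "EOG"


@dataclass(frozen=True)
class Point2D:
    """Pixel coordinate, origin top-left, y increasing downward."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinate: ({self.x}, {self.y})")


@dataclass(frozen=True)
class EyeLandmarks:
    """Six-point eye contour.

    Ordering contract: p1 = outer corner, then counter-clockwise — p2, p3 on
    the upper lid, p4 = inner corner, p5, p6 on the lower lid (p6 below p2,
    p5 below p3).
    """

    p1: Point2D
    p2: Point2D
    p3: Point2D
    p4: Point2D
    p5: Point2D
    p6: Point2D

    def __post_init__(self) -> None:
        if self.p1 == self.p4:
            raise ValueError("degenerate eye: p1 and p4 coincide")

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "EyeLandmarks":
        """Build from a (6, 2) array of (x, y) rows."""
        a = np.asarray(arr, dtype=float)
        if a.shape != (6, 2):
            raise ValueError(f"expected (6, 2) landmark array, got {a.shape}")
        return cls(*(Point2D(x, y) for x, y in a))

    def to_array(self) -> np.ndarray:
        return np.array(
            [[p.x, p.y] for p in (self.p1, self.p2, self.p3, self.p4, self.p5, self.p6)]
        )


@dataclass(frozen=True)
class ClosedInterval:
    """Half-open frame range [start, end) during which the eye is closed."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BlinkEvent:
    """A blink at ``time`` seconds from stream start, lasting ``duration`` s."""

    time: float
    duration: float
    source: BlinkSource = BlinkSource.EAR

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("blink time must be >= 0")
        if self.duration <= 0:
            raise ValueError("blink duration must be > 0")


class EarSeries:
    """Per-frame EAR values at a fixed frame rate."""

    def __init__(self, values: Sequence[float], frame_rate: float):
        if frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        v = np.asarray(values, dtype=float)
        if v.ndim != 1:
            raise ValueError("EAR values must be one-dimensional")
        if v.size and (not np.all(np.isfinite(v)) or np.any(v < 0)):
            raise ValueError("EAR values must be finite and >= 0")
        self.values = v
        self.frame_rate = float(frame_rate)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Series length in seconds."""
        return len(self) / self.frame_rate


def euclidean_distance(a: Point2D, b: Point2D) -> float:
    """Pixel distance sqrt((x_a - x_b)^2 + (y_a - y_b)^2)."""
    return math.hypot(a.x - b.x, a.y - b.y)


def compute_ear(lm: EyeLandmarks) -> float:
    """Eye aspect ratio (|p2-p6| + |p3-p5|) / (2 |p1-p4|)."""
    width = euclidean_distance(lm.p1, lm.p4)
    if width == 0.0:  # unreachable given the EyeLandmarks invariant
        raise ValueError("degenerate eye: zero corner distance")
    return (euclidean_distance(lm.p2, lm.p6) + euclidean_distance(lm.p3, lm.p5)) / (
        2.0 * width
    )


def compute_ear_series(
    landmarks: Iterable[EyeLandmarks], frame_rate: float
) -> EarSeries:
    """EAR value per frame for a landmark trajectory."""
    return EarSeries([compute_ear(lm) for lm in landmarks], frame_rate)


def segment_ear_series(
    s: EarSeries, threshold: float = DEFAULT_EAR_THRESHOLD
) -> list[ClosedInterval]:
    """Maximal runs of frames with EAR below ``threshold``.

    Equality at the threshold counts as open.  Intervals are half-open,
    0-based, sorted and disjoint.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if len(s) == 0:
        raise ValueError("empty EAR series")
    closed = s.values < threshold
    # run-length boundaries of the boolean mask
    padded = np.concatenate(([False], closed, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    return [ClosedInterval(int(a), int(b)) for a, b in zip(starts, ends)]


def extract_blink_events(
    s: EarSeries,
    threshold: float = DEFAULT_EAR_THRESHOLD,
    min_dur: float = DEFAULT_MIN_BLINK_S,
    max_dur: float = DEFAULT_MAX_BLINK_S,
) -> list[BlinkEvent]:
    """Closed intervals with duration in [min_dur, max_dur] as blink events.

    The event time is the interval midpoint (frame centres); longer closures
    are treated as prolonged closure, not blinks, and excluded.
    """
    if not 0 < min_dur < max_dur:
        raise ValueError("require 0 < min_dur < max_dur")
    events = []
    for iv in segment_ear_series(s, threshold):
        dur = iv.n_frames / s.frame_rate
        if min_dur <= dur <= max_dur:
            # midpoint of the covered frames, each frame centred at (i+0.5)/fps
            mid = (iv.start + iv.end) / 2.0 / s.frame_rate
            events.append(BlinkEvent(time=mid, duration=dur, source=BlinkSource.EAR))
    return events


def blink_statistics(events: Sequence[BlinkEvent], window: float) -> dict:
    """Blink rate and inter-blink interval statistics over ``window`` seconds.

    Returns ``{"rate": blinks/min, "mean_interval": s, "interval_sd": s}``;
    the interval fields are NaN when fewer than two events are present
    (and the sd additionally requires three).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    rate = 60.0 * len(events) / window
    if len(events) < 2:
        return {"rate": rate, "mean_interval": math.nan, "interval_sd": math.nan}
    times = np.sort([e.time for e in events])
    gaps = np.diff(times)
    sd = float(np.std(gaps, ddof=1)) if gaps.size >= 2 else math.nan
    return {"rate": rate, "mean_interval": float(np.mean(gaps)), "interval_sd": sd}


def ear_channel_score(
    s: EarSeries, threshold: float = DEFAULT_EAR_THRESHOLD
) -> float:
    """Fraction of frames at-or-above threshold: 1 = fully open (alert), 0 = closed.

    This is the unit-interval "EAR" input of the fuzzy fusion stage.
    """
    if len(s) == 0:
        raise ValueError("empty EAR series")
    return float(np.mean(s.values >= threshold))


# ---------------------------------------------------------------------------
# I/O: landmark CSV / JSON, EAR series CSV, event JSON


def read_landmarks_csv(path) -> list[EyeLandmarks]:
    """Read per-frame landmarks: frame_index,x1,y1,...,x6,y6 (pixels)."""
    df = pd.read_csv(path)
    cols = [f"{ax}{i}" for i in range(1, 7) for ax in ("x", "y")]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"landmark CSV missing columns: {missing}")
    df = df.sort_values("frame_index") if "frame_index" in df.columns else df
    out = []
    for _, row in df.iterrows():
        pts = np.array([[row[f"x{i}"], row[f"y{i}"]] for i in range(1, 7)], dtype=float)
        out.append(EyeLandmarks.from_array(pts))
    return out


def write_landmarks_csv(path, landmarks: Sequence[EyeLandmarks]) -> None:
    rows = []
    for i, lm in enumerate(landmarks):
        a = lm.to_array()
        row = {"frame_index": i}
        for j in range(6):
            row[f"x{j + 1}"] = a[j, 0]
            row[f"y{j + 1}"] = a[j, 1]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ear_series_csv(path, s: EarSeries) -> None:
    pd.DataFrame(
        {"frame_index": np.arange(len(s)), "ear": s.values}
    ).to_csv(path, index=False)


def read_ear_series_csv(path, frame_rate: float) -> EarSeries:
    df = pd.read_csv(path)
    return EarSeries(df["ear"].to_numpy(), frame_rate)


def write_events_json(path, events: Sequence[BlinkEvent]) -> None:
    payload = [
        {"time_s": e.time, "duration_s": e.duration, "source": e.source.value}
        for e in events
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_events_json(path) -> list[BlinkEvent]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        BlinkEvent(r["time_s"], r["duration_s"], BlinkSource(r["source"]))
        for r in payload
    ]
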