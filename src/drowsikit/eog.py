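"""Electrooculography (EOG) pulse detection and blink-signature matching.

Three periocular electrodes (EOG1, EOG2 horizontal; EOG3 vertical) record
pulse waveforms of two characteristic shapes: S1, a biphasic pulse (positive
then negative lobe, modelled as a derivative-of-Gaussian), and S2, a
monophasic bump (Gaussian).  A blink produces the unique channel
configuration EOG1=S2, EOG2=S1, EOG3=S1; other eye movements produce other
configurations, so requiring this exact triple within a small coincidence
tolerance separates blinks from saccades and gaze shifts.

Detection is by matched filtering: each channel is detrended and band-pass
filtered, cross-correlated with the S1 and S2 templates (normalised,
sliding-window), and local correlation maxima above a threshold become typed
pulses.  Per-channel pulse lists are then combined by a greedy earliest-first
triple matcher into blink events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .ear import BlinkEvent, BlinkSource

__all__ = [
    "Channel",
    "PulseKind",
    "Pulse",
    "EogStream",
    "BlinkSignature",
    "s1_template",
    "s2_template",
    "default_templates",
    "preprocess_eog",
    "detect_pulses",
    "detect_blink_signature",
    "eog_channel_score",
]

DEFAULT_SAMPLE_RATE = 250.0  # Hz
DEFAULT_BAND = (0.5, 20.0)  # Hz band-pass for ocular potentials
DEFAULT_TEMPLATE_WIDTH = 0.150  # s, full pulse support
DEFAULT_MIN_CORR = 0.7
DEFAULT_COINCIDENCE_TOL = 0.050  # s
#: Alert-baseline spontaneous blink rate, blinks/min.
DEFAULT_EXPECTED_RATE = 15.0


class Channel(str, Enum):
    EOG1 = "EOG1"
    EOG2 = "EOG2"
    EOG3 = "EOG3"


class PulseKind(str, Enum):
    S1 = "S1"
    S2 = "S2"


@dataclass(frozen=True)
class Pulse:
    channel: Channel
    time: float
    kind: PulseKind
    match_score: float


class EogStream:
    """Three synchronised EOG channels at a common sample rate."""

    def __init__(
        self,
        eog1: Sequence[float],
        eog2: Sequence[float],
        eog3: Sequence[float],
        sample_rate: float = DEFAULT_SAMPLE_RATE,
    ):
        if sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        chans = [np.asarray(c, dtype=float) for c in (eog1, eog2, eog3)]
        if len({c.size for c in chans}) != 1:
            raise ValueError("the three EOG channels must have equal length")
        for c in chans:
            if not np.all(np.isfinite(c)):
                raise ValueError("non-finite EOG samples")
        self.channels = dict(zip(Channel, chans))
        self.sample_rate = float(sample_rate)

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @classmethod
    def from_csv(cls, path) -> "EogStream":
        df = pd.read_csv(path)
        fs = 1.0 / np.median(np.diff(df["time_s"].to_numpy()))
        return cls(df["eog1"], df["eog2"], df["eog3"], fs)

    def to_csv(self, path) -> None:
        t = np.arange(self.n_samples) / self.sample_rate
        pd.DataFrame(
            {
                "time_s": t,
                "eog1": self.channels[Channel.EOG1],
                "eog2": self.channels[Channel.EOG2],
                "eog3": self.channels[Channel.EOG3],
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class BlinkSignature:
    """Per-channel pulse kinds that jointly identify a blink."""

    required: dict[Channel, PulseKind] = field(
        default_factory=lambda: {
            Channel.EOG1: PulseKind.S2,
            Channel.EOG2: PulseKind.S1,
            Channel.EOG3: PulseKind.S1,
        }
    )
    coincidence_tolerance: float = DEFAULT_COINCIDENCE_TOL

    def __post_init__(self) -> None:
        if self.coincidence_tolerance <= 0:
            raise ValueError("coincidence tolerance must be > 0")


# ---------------------------------------------------------------------------
# Templates


def s1_template(
    sample_rate: float = DEFAULT_SAMPLE_RATE, width: float = DEFAULT_TEMPLATE_WIDTH
) -> np.ndarray:
    """Biphasic derivative-of-Gaussian pulse (positive lobe first)."""
    n = max(int(round(width * sample_rate)), 5)
    t = np.linspace(-1.0, 1.0, n)
    sigma = 0.4
    w = -t * np.exp(-(t**2) / (2 * sigma**2))  # positive lobe at t < 0
    return w / np.max(np.abs(w))

def s2_template(
    sample_rate: float = DEFAULT_SAMPLE_RATE, width: float = DEFAULT_TEMPLATE_WIDTH
) -> np.ndarray:
    """Monophasic Gaussian bump."""
    n = max(int(round(width * sample_rate)), 5)
    t = np.linspace(-1.0, 1.0, n)
    sigma = 0.35
    w = np.exp(-(t**2) / (2 * sigma**2))
    # remove DC so noise-only segments do not correlate spuriously
    w = w - w.mean()
    return w / np.max(np.abs(w))


def default_templates(
    sample_rate: float = DEFAULT_SAMPLE_RATE, width: float = DEFAULT_TEMPLATE_WIDTH
) -> dict[PulseKind, np.ndarray]:
    return {
        PulseKind.S1: s1_template(sample_rate, width),
        PulseKind.S2: s2_template(sample_rate, width),
    }


# ---------------------------------------------------------------------------
# Preprocessing and matched-filter detection


def preprocess_eog(
    raw: EogStream, band: tuple[float, float] = DEFAULT_BAND
) -> EogStream:
    """Detrend and zero-phase band-pass filter all three channels."""
    lo, hi = band
    nyq = raw.sample_rate / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} outside (0, Nyquist={nyq}) Hz")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=raw.sample_rate, output="sos")
    filtered = []
    for ch in Channel:
        x = sps.detrend(raw.channels[ch], type="linear")
        filtered.append(sps.sosfiltfilt(sos, x))
    return EogStream(*filtered, sample_rate=raw.sample_rate)


def _normalized_xcorr(x: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Sliding normalised cross-correlation, one value per window start."""
    m = template.size
    tz = template - template.mean()
    tnorm = np.linalg.norm(tz)
    num = sps.correlate(x, tz, mode="valid")
    # sliding mean/energy via cumulative sums
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x**2)))
    win_sum = c1[m:] - c1[:-m]
    win_sq = c2[m:] - c2[:-m]
    var = np.maximum(win_sq - win_sum**2 / m, 0.0)
    denom = np.sqrt(var) * tnorm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 1e-12, num / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


def detect_pulses(
    ch: Sequence[float],
    sample_rate: float,
    templates: dict[PulseKind, np.ndarray] | None = None,
    min_corr: float = DEFAULT_MIN_CORR,
    channel: Channel = Channel.EOG1,
    min_amp_snr: float = 3.0,
) -> list[Pulse]:
    """Typed pulses on one channel by normalised matched filtering.

    Correlation local maxima above ``min_corr`` become candidate pulses;
    within one template length the best score wins, and the pulse kind is the
    template with the larger score at that location (mutually exclusive).

    Normalised correlation is scale-invariant, so shape alone cannot reject
    low-amplitude noise that happens to wiggle like a template.  Candidates
    must therefore also have a least-squares fitted template amplitude of at
    least ``min_amp_snr`` times the channel's robust noise level
    (median-absolute-deviation estimate).
    """
    if templates is None:
        templates = default_templates(sample_rate)
    if not templates:
        raise ValueError("templates must be nonempty")
    if not 0 < min_corr <= 1:
        raise ValueError("min_corr must be in (0, 1]")
    x = np.asarray(ch, dtype=float)
    lengths = {t.size for t in templates.values()}
    m = max(lengths)
    if m > x.size:
        raise ValueError("template longer than channel")
    robust_sd = float(np.median(np.abs(x - np.median(x)))) / 0.6745

    candidates = []  # (score, centre_sample, kind)
    for kind, tpl in templates.items():
        r = _normalized_xcorr(x, tpl)
        peaks, _ = sps.find_peaks(r, height=min_corr)
        tz = tpl - tpl.mean()
        fit = sps.correlate(x, tz, mode="valid") / float(tz @ tz)
        for p in peaks:
            if abs(fit[p]) >= min_amp_snr * robust_sd:
                candidates.append((float(r[p]), p + tpl.size // 2, kind))

    # greedy non-maximum suppression: best score wins within a template length
    candidates.sort(key=lambda c: -c[0])
    kept: list[tuple[float, int, PulseKind]] = []
    for score, centre, kind in candidates:
        if all(abs(centre - kc) >= m for _, kc, _ in kept):
            kept.append((score, centre, kind))
    kept.sort(key=lambda c: c[1])
    return [
        Pulse(channel, centre / sample_rate, kind, score)
        for score, centre, kind in kept
    ]


def detect_stream_pulses(
    stream: EogStream,
    templates: dict[PulseKind, np.ndarray] | None = None,
    min_corr: float = DEFAULT_MIN_CORR,
) -> dict[Channel, list[Pulse]]:
    """detect_pulses applied to each channel of a stream."""
    return {
        ch: detect_pulses(
            stream.channels[ch], stream.sample_rate, templates, min_corr, channel=ch
        )
        for ch in Channel
    }


# ---------------------------------------------------------------------------
# Signature matching


def detect_blink_signature(
    pulses: dict[Channel, list[Pulse]],
    sig: BlinkSignature | None = None,
) -> list[BlinkEvent]:
    """Blink events from per-channel pulses by the S2/S1/S1 signature.

    Greedy earliest-first matching: scanning candidate triples in time order,
    each triple of correctly-typed pulses (one per channel, pairwise within
    the coincidence tolerance) produces one event at the mean pulse time;
    every pulse is used at most once.
    """
    if sig is None:
        sig = BlinkSignature()
    tol = sig.coincidence_tolerance
    pools = {
        ch: sorted(
            (p for p in pulses.get(ch, []) if p.kind is sig.required[ch]),
            key=lambda p: p.time,
        )
        for ch in Channel
    }
    used = {ch: [False] * len(pools[ch]) for ch in Channel}
    events = []
    # anchor on EOG1 pulses in time order
    for i, p1 in enumerate(pools[Channel.EOG1]):
        if used[Channel.EOG1][i]:
            continue
        partners = {}
        for ch in (Channel.EOG2, Channel.EOG3):
            j_match = None
            for j, p in enumerate(pools[ch]):
                if used[ch][j]:
                    continue
                if abs(p.time - p1.time) <= tol:
                    j_match = j
                    break
                if p.time - p1.time > tol:
                    break
            if j_match is None:
                break
            partners[ch] = j_match
        if len(partners) != 2:
            continue
        # pairwise check between the two partners
        t2 = pools[Channel.EOG2][partners[Channel.EOG2]].time
        t3 = pools[Channel.EOG3][partners[Channel.EOG3]].time
        if abs(t2 - t3) > tol:
            continue
        used[Channel.EOG1][i] = True
        for ch, j in partners.items():
            used[ch][j] = True
        mean_t = (p1.time + t2 + t3) / 3.0
        events.append(
            BlinkEvent(time=mean_t, duration=2 * tol, source=BlinkSource.EOG)
        )
    events.sort(key=lambda e: e.time)
    return events


def eog_channel_score(
    events: Sequence[BlinkEvent],
    window: float,
    expected_rate: float = DEFAULT_EXPECTED_RATE,
) -> float:
    """Alertness evidence from the window's blink rate.

    1 when the observed rate equals the alert-baseline ``expected_rate``
    (blinks/min), decreasing linearly to 0 as the rate reaches zero or twice
    the baseline; departures in either direction (absent blinking during
    microsleep, rapid blinking during fatigue) lower the score.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if expected_rate <= 0:
        raise ValueError("expected_rate must be > 0")
    rate = 60.0 * len(events) / window
    return float(np.clip(1.0 - abs(rate - expected_rate) / expected_rate, 0.0, 1.0))
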