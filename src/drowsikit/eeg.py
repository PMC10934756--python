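"""EEG spectral analysis for the drowsy/alert decision.

Drowsiness onset is accompanied by a rise of alpha-band (8–12 Hz) power
relative to the broadband background, while alert wakefulness is dominated by
desynchronised beta (13–30 Hz) activity.  This module estimates the power
spectral density of single-channel EEG epochs with an averaged windowed
periodogram (Welch), integrates the canonical rhythm bands, and classifies an
epoch as DROWSY when a spectral peak inside the 10–12 Hz search window stands
out from the non-alpha background by at least a configurable prominence
ratio.

Band edges follow the conventional definitions: delta [0.5, 4), theta [4, 7),
alpha [8, 12], beta [13, 30] Hz.  The (7, 8) Hz and (12, 13) Hz gaps are left
unassigned deliberately, matching the band definitions as stated rather than
smoothing them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "EegEpoch",
    "EegSpectrum",
    "BANDS",
    "compute_psd",
    "band_powers",
    "alpha_peak",
    "classify_epoch",
]

#: Rhythm bands in Hz; half-open [lo, hi) for delta/theta, closed for alpha/beta.
BANDS: Mapping[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
}

ALPHA_SEARCH = (10.0, 12.0)  # Hz window for the drowsiness peak
DEFAULT_RATIO_THRESHOLD = 3.0


@dataclass(frozen=True)
class EegEpoch:
    """Single-channel EEG samples at a fixed rate; duration >= 2 s."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float).ravel()
        )
        if self.duration < 2.0:
            raise ValueError("epoch must be at least 2 s long")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite EEG samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @classmethod
    def from_csv(cls, path) -> "EegEpoch":
        """Read time_s,amplitude CSV; the rate is inferred from timestamps."""
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        fs = 1.0 / np.median(np.diff(t))
        return cls(df["amplitude"].to_numpy(), fs)

    def to_csv(self, path) -> None:
        t = np.arange(self.samples.size) / self.sample_rate
        pd.DataFrame({"time_s": t, "amplitude": self.samples}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class EegSpectrum:
    """One-sided PSD on an ascending frequency grid."""

    frequencies: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.psd, dtype=float)
        if f.shape != p.shape or f.ndim != 1:
            raise ValueError("frequency grid and PSD must be 1-D and aligned")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly ascending")
        if np.any(p < 0):
            raise ValueError("PSD must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "psd", p)

    @property
    def band_powers(self) -> dict[str, float]:
        return band_powers(self)

    def to_csv(self, path) -> None:
        pd.DataFrame({"freq_hz": self.frequencies, "psd": self.psd}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "EegSpectrum":
        df = pd.read_csv(path)
        return cls(df["freq_hz"].to_numpy(), df["psd"].to_numpy())


def compute_psd(
    ep: EegEpoch, segment_len: float = 1.0, overlap: float = 0.5
) -> EegSpectrum:
    """Averaged-periodogram (Welch, Hann window) PSD of an epoch.

    ``segment_len`` is in seconds; ``overlap`` is the fractional segment
    overlap.  The density is normalised so that its integral approximates the
    time-domain variance.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    if segment_len <= 0 or segment_len > ep.duration:
        raise ValueError("segment_len must be positive and <= epoch duration")
    nperseg = int(round(segment_len * ep.sample_rate))
    freqs, psd = signal.welch(
        ep.samples,
        fs=ep.sample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend="constant",
        scaling="density",
    )
    return EegSpectrum(freqs, psd)


def _band_mask(f: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (f >= lo) & (f <= hi)


def band_powers(spec: EegSpectrum) -> dict[str, float]:
    """Integral of the PSD over each rhythm band (trapezoid rule)."""
    f = spec.frequencies
    if f[-1] < 30.0:
        raise ValueError("spectrum must cover at least 30 Hz")
    out = {}
    for name, (lo, hi) in BANDS.items():
        m = _band_mask(f, lo, hi)
        if m.sum() < 2:
            raise ValueError(f"frequency grid too coarse for {name} band")
        out[name] = float(np.trapezoid(spec.psd[m], f[m]))
    return out


def alpha_peak(spec: EegSpectrum) -> dict[str, float]:
    """Largest PSD bin in the 10–12 Hz window and its prominence.

    ``prominence_ratio`` is the peak amplitude divided by the median PSD over
    [0.5, 30] Hz with the alpha band [8, 12] Hz excluded, so a sharp alpha
    peak scores far above 1 while flat noise scores near 1.
    """
    f, p = spec.frequencies, spec.psd
    m = _band_mask(f, *ALPHA_SEARCH)
    if not m.any():
        raise ValueError("frequency grid has no bin in the 10-12 Hz window")
    bg = _band_mask(f, 0.5, 30.0) & ~_band_mask(f, *BANDS["alpha"])
    if not bg.any():
        raise ValueError("spectrum does not cover the background range")
    i = np.flatnonzero(m)[np.argmax(p[m])]
    background = float(np.median(p[bg]))
    ratio = float("inf") if background == 0 and p[i] > 0 else (
        1.0 if background == 0 else float(p[i] / background)
    )
    return {
        "freq": float(f[i]),
        "amplitude": float(p[i]),
        "prominence_ratio": ratio,
    }


def classify_epoch(
    spec: EegSpectrum, ratio_threshold: float = DEFAULT_RATIO_THRESHOLD
) -> str:
    """DROWSY iff the 10–12 Hz peak prominence reaches ``ratio_threshold``."""
    peak = alpha_peak(spec)
    return "DROWSY" if peak["prominence_ratio"] >= ratio_threshold else "ALERT"


def eeg_channel_score(
    spec: EegSpectrum, ratio_threshold: float = DEFAULT_RATIO_THRESHOLD
) -> float:
    """Unit-interval alertness evidence from one spectrum.

    1 when no alpha prominence is present, falling linearly to 0 as the
    prominence ratio reaches twice the decision threshold; the score passes
    0.5 exactly at the DROWSY/ALERT classification boundary.
    """
    ratio = alpha_peak(spec)["prominence_ratio"]
    return float(np.clip(1.0 - ratio / (2.0 * ratio_threshold), 0.0, 1.0))
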