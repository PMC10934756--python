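"""Seeded synthetic generators for every input modality.

Real recordings from an instrumented vehicle (camera frames, periocular
electrodes, scalp EEG) are not distributable, so each detection stage is
exercised on synthetic inputs with known ground truth:

* schematic 51x51 grayscale eye crops (open: elliptical iris/pupil inside a
  lid aperture; closed: a narrow horizontal lid crease) with additive noise;
* six-point eye-landmark trajectories parametrised by a per-frame openness
  value in [0, 1];
* three-channel EOG streams with S2/S1/S1 blink signatures injected at known
  times, plus optional non-blink distractor configurations;
* single-channel EEG epochs with controllable alpha (drowsy) or beta (alert)
  content over a 1/f background.

Every generator is a pure function of its parameters and a seed.  The
rendering is deliberately schematic rather than photorealistic: after
down-sampling to 51x51 only coarse structure survives in real crops too, so
coarse structure is the honest target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ear import BlinkEvent, BlinkSource, EyeLandmarks
from .eeg import EegEpoch
from .eog import (
    DEFAULT_COINCIDENCE_TOL,
    DEFAULT_SAMPLE_RATE,
    Channel,
    EogStream,
    PulseKind,
    default_templates,
)
from .eye_state import EyeImage, EyeLabel

__all__ = [
    "SessionScenario",
    "gen_eye_image",
    "gen_eye_corpus",
    "gen_landmarks",
    "gen_openness_profile",
    "gen_eog_stream",
    "gen_eeg_epoch",
    "gen_eeg_session",
]

#: Default session frame rate (frames/s) for landmark trajectories.
DEFAULT_FPS = 25.0
#: Spontaneous alert blink rate used by default scenarios, blinks/min.
BASELINE_BLINK_RATE = 15.0


@dataclass(frozen=True)
class SessionScenario:
    """Ground-truth script for one synthetic monitoring session.

    ``blink_times`` are seconds from session start; ``drowsy_windows`` are
    non-overlapping (start, end) spans during which the eyes stay closed,
    blinking stops and the EEG turns alpha-dominant.
    """

    duration: float = 60.0
    blink_times: tuple[float, ...] = ()
    drowsy_windows: tuple[tuple[float, float], ...] = ()
    noise: dict = field(default_factory=dict)  # per-modality SNR / sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        for t in self.blink_times:
            if not 0 <= t < self.duration:
                raise ValueError(f"blink at {t} s outside session")
        spans = sorted(self.drowsy_windows)
        for (a, b) in spans:
            if not 0 <= a < b <= self.duration:
                raise ValueError(f"drowsy window ({a}, {b}) invalid")
        for (_, b), (a2, _) in zip(spans, spans[1:]):
            if a2 < b:
                raise ValueError("drowsy windows overlap")

    def is_drowsy(self, t: float) -> bool:
        return any(a <= t < b for a, b in self.drowsy_windows)

    @classmethod
    def default_drowsy_session(cls, seed: int = 0) -> "SessionScenario":
        """60 s session, one 15 s drowsy segment, baseline blinking elsewhere."""
        duration, window = 60.0, (25.0, 40.0)
        rng = np.random.default_rng(seed)
        gap = 60.0 / BASELINE_BLINK_RATE
        times, t = [], 1.0
        while t < duration - 0.5:
            if not (window[0] - 0.5 <= t < window[1] + 0.5):
                times.append(round(t + rng.uniform(-0.3, 0.3), 3))
            t += gap
        return cls(duration, tuple(times), (window,), seed=seed)


# ---------------------------------------------------------------------------
# Eye images


def gen_eye_image(
    state: EyeLabel, seed: int = 0, noise_sd: float = 0.05, size: int = 51
) -> EyeImage:
    """Render one schematic eye crop with a ground-truth label.

    Open/half-open: a bright almond-shaped lid aperture containing a dark
    iris disc with a darker pupil; closed: a narrow dark horizontal crease
    across mid-image.  Geometry is jittered per seed; additive Gaussian
    noise at ``noise_sd`` is clipped back into [0, 1].
    """
    if not isinstance(state, EyeLabel):
        raise ValueError(f"invalid eye state: {state!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy, cx = (size - 1) / 2.0, (size - 1) / 2.0
    img = np.full((size, size), 0.55)  # skin background
    img += rng.normal(0.0, 0.01, size=(size, size))  # texture

    if state is EyeLabel.OPEN_OR_HALF:
        # lid aperture: almond (ellipse), half-open eyes get a flatter one
        aperture_h = rng.uniform(0.45, 1.0) * size * 0.30
        aperture_w = size * 0.42
        ell = ((xx - cx) / aperture_w) ** 2 + ((yy - cy) / aperture_h) ** 2
        img[ell <= 1.0] = 0.92  # sclera
        # iris + pupil, horizontally jittered
        ix = cx + rng.uniform(-0.08, 0.08) * size
        iris_r = min(aperture_h * 1.1, size * 0.16)
        d2 = (xx - ix) ** 2 + (yy - cy) ** 2
        inside = (d2 <= iris_r**2) & (ell <= 1.0)
        img[inside] = 0.25
        img[(d2 <= (iris_r * 0.45) ** 2) & (ell <= 1.0)] = 0.05
    else:
        # closed lids: dark crease with soft vertical falloff, lash shadow
        crease_y = cy + rng.uniform(-1.5, 1.5)
        half_w = rng.uniform(1.0, 2.0)
        profile = np.exp(-((yy - crease_y) ** 2) / (2 * half_w**2))
        img -= 0.45 * profile
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=(size, size))
    img = np.clip(img, 0.0, 1.0)
    return EyeImage(raster=img, label=state, source_size=(size, size))


def gen_eye_corpus(
    n_per_class: int = 100, seed: int = 0, noise_sd: float = 0.05
) -> list[EyeImage]:
    """Balanced labeled corpus of 2 * n_per_class schematic eye images.

    The default 100 per class gives the 200-image design whose 70 + 70
    training split leaves 60 images for testing.  Class order alternates so
    any prefix split stays roughly balanced; reproducible per seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=2 * n_per_class)
    corpus = []
    for i in range(n_per_class):
        corpus.append(
            gen_eye_image(EyeLabel.OPEN_OR_HALF, int(sub[2 * i]), noise_sd)
        )
        corpus.append(gen_eye_image(EyeLabel.CLOSED, int(sub[2 * i + 1]), noise_sd))
    return corpus


# ---------------------------------------------------------------------------
# Landmarks


def gen_landmarks(
    openness,
    corner_dist: float = 40.0,
    max_lid_gap: float = 20.0,
    origin: tuple[float, float] = (100.0, 100.0),
) -> list[EyeLandmarks]:
    """Six-point landmark frames parametrised by per-frame openness.

    Corners sit ``corner_dist`` pixels apart; the upper/lower lid points at
    horizontal offsets 1/4 and 3/4 of the width are displaced vertically by
    ``openness * max_lid_gap / 2`` each, so the EAR of frame i is
    ``openness_i * max_lid_gap / (2 * corner_dist)`` — strictly increasing
    in openness.
    """
    openness = np.asarray(openness, dtype=float)
    if openness.ndim != 1:
        raise ValueError("openness must be a 1-D sequence")
    if np.any((openness < 0) | (openness > 1)):
        raise ValueError("openness values must lie in [0, 1]")
    x0, y0 = origin
    frames = []
    for o in openness:
        dy = o * max_lid_gap / 2.0
        pts = np.array(
            [
                [x0, y0],  # p1 outer corner
                [x0 + 0.25 * corner_dist, y0 - dy],  # p2 upper lid
                [x0 + 0.75 * corner_dist, y0 - dy],  # p3 upper lid
                [x0 + corner_dist, y0],  # p4 inner corner
                [x0 + 0.75 * corner_dist, y0 + dy],  # p5 lower lid
                [x0 + 0.25 * corner_dist, y0 + dy],  # p6 lower lid
            ]
        )
        frames.append(EyeLandmarks.from_array(pts))
    return frames


def gen_openness_profile(
    scenario: SessionScenario,
    fps: float = DEFAULT_FPS,
    blink_dur: float = 0.16,
    open_level: float = 1.0,
    jitter_sd: float = 0.02,
) -> np.ndarray:
    """Per-frame openness for a session: blinks dip to 0, drowsy spans stay 0."""
    rng = np.random.default_rng(scenario.seed)
    n = int(round(scenario.duration * fps))
    t = np.arange(n) / fps
    o = np.full(n, open_level) + rng.normal(0.0, jitter_sd, size=n)
    for bt in scenario.blink_times:
        o[(t >= bt) & (t < bt + blink_dur)] = 0.0
    for a, b in scenario.drowsy_windows:
        o[(t >= a) & (t < b)] = 0.0
    return np.clip(o, 0.0, 1.0)


# ---------------------------------------------------------------------------
# EOG


def gen_eog_stream(
    scenario: SessionScenario,
    templates=None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    snr: float = 10.0,
    amplitude: float = 100.0,
    distractor_times=(),
    distractor_kinds=(PulseKind.S1, PulseKind.S1, PulseKind.S1),
) -> tuple[EogStream, list[BlinkEvent]]:
    """Three-channel EOG stream with blink signatures at the scenario times.

    At each blink time an S2 pulse is placed on EOG1 and S1 pulses on
    EOG2/EOG3 with per-channel timing jitter below half the coincidence
    tolerance.  ``distractor_times`` insert non-blink pulse configurations
    (default S1/S1/S1, a non-blink eye movement) that must not be reported
    as blinks.  Gaussian noise is added at ``snr`` = pulse amplitude over
    noise sd; ``snr = inf`` (or <= 0 treated as error) disables noise.
    """
    if templates is None:
        templates = default_templates(sample_rate)
    if snr <= 0:
        raise ValueError("snr must be > 0 (use np.inf for noise-free)")
    rng = np.random.default_rng(scenario.seed)
    n = int(round(scenario.duration * sample_rate))
    chans = {ch: np.zeros(n) for ch in Channel}
    blink_kinds = {
        Channel.EOG1: PulseKind.S2,
        Channel.EOG2: PulseKind.S1,
        Channel.EOG3: PulseKind.S1,
    }
    jitter = DEFAULT_COINCIDENCE_TOL / 4.0

    def _insert(t_centre, kinds):
        for ch, kind in kinds.items():
            tpl = templates[kind]
            tc = t_centre + rng.uniform(-jitter, jitter)
            start = int(round(tc * sample_rate)) - tpl.size // 2
            if start < 0 or start + tpl.size > n:
                raise ValueError(f"pulse at {t_centre} s outside stream")
            chans[ch][start : start + tpl.size] += amplitude * tpl

    truth = []
    for bt in scenario.blink_times:
        _insert(bt, blink_kinds)
        truth.append(BlinkEvent(time=bt, duration=0.1, source=BlinkSource.EOG))
    for dt in distractor_times:
        _insert(dt, dict(zip(Channel, distractor_kinds)))
    if np.isfinite(snr):
        sd = amplitude / snr
        for ch in Channel:
            chans[ch] = chans[ch] + rng.normal(0.0, sd, size=n)
    stream = EogStream(
        chans[Channel.EOG1], chans[Channel.EOG2], chans[Channel.EOG3], sample_rate
    )
    return stream, truth


# ---------------------------------------------------------------------------
# EEG


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-weighted Gaussian noise, unit variance."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec = spec / np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def gen_eeg_epoch(
    state: str,
    fs: float = 256.0,
    duration: float = 4.0,
    seed: int = 0,
    snr: float = 5.0,
) -> tuple[EegEpoch, float | None]:
    """One synthetic EEG epoch; returns (epoch, injected alpha frequency).

    DROWSY: a sinusoid at a seeded frequency in [10, 12] Hz over a pink
    background at the given amplitude SNR.  ALERT: beta-weighted broadband
    (13-30 Hz band-filtered noise) over the same background; the alpha
    frequency is None.
    """
    if fs <= 60:
        raise ValueError("fs must exceed 60 Hz to cover the beta band")
    if duration < 2:
        raise ValueError("duration must be >= 2 s")
    if state not in ("DROWSY", "ALERT"):
        raise ValueError(f"invalid state {state!r}")
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    background = _pink_noise(n, rng)
    if state == "DROWSY":
        f_alpha = float(rng.uniform(10.0, 12.0))
        x = snr * np.sin(2 * np.pi * f_alpha * t + rng.uniform(0, 2 * np.pi))
        return EegEpoch(x + background, fs), f_alpha
    # alert: beta emphasis via FFT-domain band weighting of white noise
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    weight = np.where((f >= 13.0) & (f <= 30.0), 1.0, 0.05)
    beta = np.fft.irfft(spec * weight, n)
    beta = beta / beta.std()
    return EegEpoch(0.8 * snr * beta + background, fs), None


def gen_eeg_session(
    scenario: SessionScenario, fs: float = 256.0, snr: float = 5.0
) -> EegEpoch:
    """Continuous EEG for a whole session: alpha inside drowsy windows,
    beta-weighted broadband elsewhere, stitched per second."""
    rng = np.random.default_rng(scenario.seed + 104729)
    pieces = []
    t0 = 0.0
    bounds = sorted({0.0, scenario.duration}
                    | {a for a, _ in scenario.drowsy_windows}
                    | {b for _, b in scenario.drowsy_windows})
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg_dur = b - a
        if seg_dur <= 0:
            continue
        state = "DROWSY" if scenario.is_drowsy(a) else "ALERT"
        # piecewise generation; segments shorter than 2 s are padded and cut
        gen_dur = max(seg_dur, 2.0)
        ep, _ = gen_eeg_epoch(state, fs, gen_dur, int(rng.integers(2**31 - 1)), snr)
        pieces.append(ep.samples[: int(round(seg_dur * fs))])
        t0 = b
    return EegEpoch(np.concatenate(pieces), fs)
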