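"""End-to-end orchestration: windowed channel scores, fusion, warnings.

The pipeline slides a fixed window (default 10 s, hop 5 s) across a session
and computes three unit-interval alertness scores per window:

1. channel 1 — EEG alpha-prominence evidence or EOG blink-rate evidence,
   selected by configuration;
2. channel 2 — "FR": fraction of frames classified open/half-open by a
   trained eye-state network;
3. channel 3 — "EAR": fraction of frames whose eye aspect ratio is at or
   above the open/closed threshold.

Each window's scores are fused by the Mamdani engine into a crisp value and
a DROWSY/ALERT label; a warning event opens when a configurable number of
consecutive windows are DROWSY and closes at the next ALERT window.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ear as ear_mod
from . import eeg as eeg_mod
from . import eog as eog_mod
from . import eye_state
from .fuzzy import MamdaniFuser

__all__ = [
    "PipelineConfig",
    "DecisionTimeline",
    "WindowDecision",
    "run_pipeline",
    "emit_warnings",
    "load_config",
]

logger = logging.getLogger("drowsikit.pipeline")


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.  Paths may stay None when a
    pre-loaded object is passed to run_pipeline directly."""

    channel1_source: str = "EOG"  # "EEG" or "EOG"
    window: float = 10.0
    hop: float = 5.0
    frame_rate: float = 25.0
    ear_threshold: float = ear_mod.DEFAULT_EAR_THRESHOLD
    eog_expected_rate: float = eog_mod.DEFAULT_EXPECTED_RATE
    eeg_ratio_threshold: float = eeg_mod.DEFAULT_RATIO_THRESHOLD
    warning_persistence: int = 2
    landmarks_csv: str | None = None
    eog_csv: str | None = None
    eeg_csv: str | None = None
    frames_manifest: str | None = None  # CSV: frame_index,path
    frame_labels_csv: str | None = None  # CSV: frame_index,label (alternative)
    model_meta: str | None = None
    output_json: str | None = None
    fuser_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.channel1_source not in ("EEG", "EOG"):
            raise ValueError("channel1_source must be 'EEG' or 'EOG'")
        if not 0 < self.hop <= self.window:
            raise ValueError("require 0 < hop <= window")
        if self.warning_persistence < 1:
            raise ValueError("warning_persistence must be >= 1")


@dataclass(frozen=True)
class WindowDecision:
    start: float
    end: float
    scores: tuple[float, float, float]
    crisp: float
    label: str


@dataclass
class DecisionTimeline:
    windows: list[WindowDecision]

    @property
    def labels(self) -> list[str]:
        return [w.label for w in self.windows]

    def to_json(self, path) -> None:
        payload = [
            {
                "start": w.start,
                "end": w.end,
                "scores": list(w.scores),
                "crisp": w.crisp,
                "label": w.label,
            }
            for w in self.windows
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DecisionTimeline":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            [
                WindowDecision(
                    r["start"], r["end"], tuple(r["scores"]), r["crisp"], r["label"]
                )
                for r in payload
            ]
        )


def load_config(path) -> PipelineConfig:
    """Read a YAML/JSON pipeline configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    cfg = PipelineConfig(**data)
    for attr in ("landmarks_csv", "eog_csv", "eeg_csv", "frames_manifest",
                 "frame_labels_csv", "model_meta"):
        p = getattr(cfg, attr)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"config references missing {attr}: {p}")
    return cfg


# ---------------------------------------------------------------------------
# Per-modality window scorers


def _frame_labels(cfg: PipelineConfig) -> list[eye_state.EyeLabel]:
    """Per-frame eye-state labels: from a labels CSV or by classifying images."""
    if cfg.frame_labels_csv is not None:
        df = pd.read_csv(cfg.frame_labels_csv)
        return [eye_state.EyeLabel(l) for l in df.sort_values("frame_index")["label"]]
    if cfg.frames_manifest is None or cfg.model_meta is None:
        raise ValueError(
            "face-recognition channel needs frame_labels_csv or "
            "frames_manifest + model_meta"
        )
    model = eye_state.EyeStateModel.load(cfg.model_meta)
    df = pd.read_csv(cfg.frames_manifest).sort_values("frame_index")
    imgs = [
        eye_state.EyeImage(eye_state.load_image(p).astype(float) / 255.0)
        for p in df["path"]
    ]
    return model.predict(imgs)


def run_pipeline(
    cfg: PipelineConfig,
    landmarks=None,
    eog_stream: eog_mod.EogStream | None = None,
    eeg_session: eeg_mod.EegEpoch | None = None,
    frame_labels=None,
    fuser: MamdaniFuser | None = None,
) -> DecisionTimeline:
    """Compute the windowed decision timeline for one session.

    Inputs may be passed as objects or read from the configured paths.
    Every window's label is exactly the fuzzy decision on that window's
    three scores; no state is carried across windows.
    """
    fuser = fuser or MamdaniFuser(**cfg.fuser_params)

    if landmarks is None:
        if cfg.landmarks_csv is None:
            raise ValueError("missing modality: landmarks (EAR channel)")
        landmarks = ear_mod.read_landmarks_csv(cfg.landmarks_csv)
    series = ear_mod.compute_ear_series(landmarks, cfg.frame_rate)

    if frame_labels is None:
        frame_labels = _frame_labels(cfg)
    if len(frame_labels) != len(series):
        raise ValueError(
            f"frame count mismatch: {len(frame_labels)} labels vs "
            f"{len(series)} landmark frames"
        )

    if cfg.channel1_source == "EOG":
        if eog_stream is None:
            if cfg.eog_csv is None:
                raise ValueError("missing modality: EOG stream (channel 1)")
            eog_stream = eog_mod.EogStream.from_csv(cfg.eog_csv)
        clean = eog_mod.preprocess_eog(eog_stream)
        pulses = eog_mod.detect_stream_pulses(clean)
        blink_events = eog_mod.detect_blink_signature(pulses)
        logger.info("EOG: %d blink events detected", len(blink_events))
    else:
        if eeg_session is None:
            if cfg.eeg_csv is None:
                raise ValueError("missing modality: EEG session (channel 1)")
            eeg_session = eeg_mod.EegEpoch.from_csv(cfg.eeg_csv)
        blink_events = None

    duration = series.duration
    windows = []
    start = 0.0
    while start + cfg.window <= duration + 1e-9:
        end = start + cfg.window
        # channel 1
        if cfg.channel1_source == "EOG":
            in_win = [e for e in blink_events if start <= e.time < end]
            s1 = eog_mod.eog_channel_score(in_win, cfg.window, cfg.eog_expected_rate)
        else:
            i0 = int(round(start * eeg_session.sample_rate))
            i1 = int(round(end * eeg_session.sample_rate))
            epoch = eeg_mod.EegEpoch(
                eeg_session.samples[i0:i1], eeg_session.sample_rate
            )
            spec = eeg_mod.compute_psd(epoch)
            s1 = eeg_mod.eeg_channel_score(spec, cfg.eeg_ratio_threshold)
        # channel 2: FR
        f0 = int(round(start * cfg.frame_rate))
        f1 = int(round(end * cfg.frame_rate))
        s2 = eye_state.fr_channel_score(frame_labels[f0:f1])
        # channel 3: EAR
        win_series = ear_mod.EarSeries(series.values[f0:f1], cfg.frame_rate)
        s3 = ear_mod.ear_channel_score(win_series, cfg.ear_threshold)

        d = fuser.decide((s1, s2, s3))
        logger.debug(
            "window [%.1f, %.1f): scores=(%.3f, %.3f, %.3f) crisp=%.3f %s",
            start, end, s1, s2, s3, d.crisp, d.label,
        )
        windows.append(WindowDecision(start, end, (s1, s2, s3), d.crisp, d.label))
        start += cfg.hop

    tl = DecisionTimeline(windows)
    if cfg.output_json:
        tl.to_json(cfg.output_json)
    return tl


@dataclass(frozen=True)
class WarningEvent:
    """Span of consecutive DROWSY windows that reached the persistence gate."""

    start: float
    end: float
    n_windows: int


def emit_warnings(tl: DecisionTimeline, persistence: int = 2) -> list[WarningEvent]:
    """Warning events from the decision timeline.

    A warning opens when at least ``persistence`` consecutive windows are
    DROWSY and covers the whole drowsy run; it closes at the next ALERT
    window.
    """
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    warnings = []
    run_start = None
    run_n = 0
    for w in tl.windows:
        if w.label == "DROWSY":
            if run_start is None:
                run_start = w.start
            run_n += 1
            run_end = w.end
        else:
            if run_start is not None and run_n >= persistence:
                warnings.append(WarningEvent(run_start, run_end, run_n))
            run_start, run_n = None, 0
    if run_start is not None and run_n >= persistence:
        warnings.append(WarningEvent(run_start, run_end, run_n))
    return warnings
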