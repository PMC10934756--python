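"""EOG preprocessing, matched-filter pulse detection, blink-signature matching."""

import numpy as np
import pytest

from drowsikit.ear import BlinkSource
from drowsikit.eog import (
    BlinkSignature,
    Channel,
    EogStream,
    Pulse,
    PulseKind,
    default_templates,
    detect_blink_signature,
    detect_pulses,
    detect_stream_pulses,
    eog_channel_score,
    preprocess_eog,
    s1_template,
    s2_template,
)
from drowsikit.synth import SessionScenario, gen_eog_stream

FS = 250.0


def inject(template, t_centre, duration=4.0, fs=FS, amplitude=100.0, noise_sd=0.0,
           seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    x = rng.normal(0, noise_sd, n) if noise_sd else np.zeros(n)
    start = int(t_centre * fs) - template.size // 2
    x[start : start + template.size] += amplitude * template
    return x


class TestPreprocess:
    def test_dc_offset_removed(self):
        stream = EogStream(*[np.full(2500, 7.0)] * 3, sample_rate=FS)
        clean = preprocess_eog(stream)
        for ch in Channel:
            assert np.abs(clean.channels[ch]).max() < 1e-6

    def test_in_band_sinusoid_preserved(self):
        t = np.arange(5000) / FS
        x = np.sin(2 * np.pi * 5.0 * t)
        clean = preprocess_eog(EogStream(x, x, x, FS))
        core = clean.channels[Channel.EOG1][1000:-1000]
        assert np.abs(core).max() == pytest.approx(1.0, rel=0.05)

    def test_band_above_nyquist_rejected(self):
        stream = EogStream(*[np.zeros(1000)] * 3, sample_rate=FS)
        with pytest.raises(ValueError):
            preprocess_eog(stream, band=(0.5, 200.0))


class TestDetectPulses:
    def test_injected_s2_recovered(self):
        tpl = s2_template(FS)
        x = inject(tpl, 1.0, noise_sd=10.0, amplitude=100.0)
        pulses = detect_pulses(x, FS)
        assert len(pulses) == 1
        assert pulses[0].kind is PulseKind.S2
        half_width = tpl.size / FS / 2
        assert abs(pulses[0].time - 1.0) <= half_width

    def test_injected_s1_recovered(self):
        x = inject(s1_template(FS), 2.0, noise_sd=10.0, amplitude=100.0)
        pulses = detect_pulses(x, FS)
        assert len(pulses) == 1
        assert pulses[0].kind is PulseKind.S1

    def test_low_amplitude_noise_yields_nothing(self):
        rng = np.random.default_rng(0)
        assert detect_pulses(rng.normal(0, 1.0, 2000), FS) == []

    def test_no_overlapping_detections_on_one_channel(self):
        x = inject(s2_template(FS), 1.0) + inject(s1_template(FS), 1.02)
        pulses = detect_pulses(x, FS)
        tpl_len = max(t.size for t in default_templates(FS).values()) / FS
        times = [p.time for p in pulses]
        assert all(b - a >= tpl_len for a, b in zip(times, times[1:]))

    def test_template_longer_than_channel_rejected(self):
        with pytest.raises(ValueError):
            detect_pulses(np.zeros(10), FS)


class TestBlinkSignature:
    @staticmethod
    def _pulses(spec):
        """spec: {channel: [(time, kind), ...]}"""
        return {
            ch: [Pulse(ch, t, k, 1.0) for t, k in spec.get(ch, [])]
            for ch in Channel
        }

    def test_matching_triple_yields_one_blink(self):
        pulses = self._pulses(
            {
                Channel.EOG1: [(2.00, PulseKind.S2)],
                Channel.EOG2: [(2.01, PulseKind.S1)],
                Channel.EOG3: [(1.99, PulseKind.S1)],
            }
        )
        events = detect_blink_signature(pulses, BlinkSignature())
        assert len(events) == 1
        assert events[0].time == pytest.approx(2.00)
        assert events[0].source is BlinkSource.EOG

    def test_wrong_configuration_is_not_a_blink(self):
        """Coincident S1/S1/S1 is some other eye movement, not a blink."""
        pulses = self._pulses(
            {ch: [(2.0, PulseKind.S1)] for ch in Channel}
        )
        assert detect_blink_signature(pulses, BlinkSignature()) == []

    def test_empty_input(self):
        assert detect_blink_signature({}, BlinkSignature()) == []

    def test_pulse_used_at_most_once(self):
        pulses = self._pulses(
            {
                Channel.EOG1: [(2.00, PulseKind.S2), (2.02, PulseKind.S2)],
                Channel.EOG2: [(2.01, PulseKind.S1)],
                Channel.EOG3: [(2.00, PulseKind.S1)],
            }
        )
        assert len(detect_blink_signature(pulses, BlinkSignature())) == 1

    def test_time_shift_invariance(self):
        base = {
            Channel.EOG1: [(2.0, PulseKind.S2), (5.0, PulseKind.S2)],
            Channel.EOG2: [(2.0, PulseKind.S1), (5.0, PulseKind.S1)],
            Channel.EOG3: [(2.0, PulseKind.S1), (5.0, PulseKind.S1)],
        }
        n0 = len(detect_blink_signature(self._pulses(base), BlinkSignature()))
        shifted = {
            ch: [(t + 11.3, k) for t, k in lst] for ch, lst in base.items()
        }
        n1 = len(detect_blink_signature(self._pulses(shifted), BlinkSignature()))
        assert n0 == n1 == 2


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(5))
    def test_generator_detector_round_trip(self, seed, triple_matching_oracle):
        """All injected blinks recovered, no distractor reported, and the
        greedy matcher count equals the exhaustive maximum matching."""
        blink_times = (2.0, 6.5, 11.0, 15.5)
        sc = SessionScenario(duration=20.0, blink_times=blink_times, seed=seed)
        stream, _ = gen_eog_stream(
            sc, snr=5.0, distractor_times=(4.0, 9.0, 13.0),
        )
        pulses = detect_stream_pulses(preprocess_eog(stream))
        events = detect_blink_signature(pulses, BlinkSignature())
        assert len(events) == len(blink_times)
        for bt in blink_times:
            assert any(abs(e.time - bt) < 0.05 for e in events)
        sig = BlinkSignature()
        per_kind = [
            [p.time for p in pulses[ch] if p.kind is sig.required[ch]]
            for ch in Channel
        ]
        assert triple_matching_oracle(*per_kind, sig.coincidence_tolerance) == len(
            events
        )

    def test_noise_free_silent_stream(self):
        sc = SessionScenario(duration=5.0, blink_times=(), seed=0)
        stream, truth = gen_eog_stream(sc, snr=np.inf)
        assert truth == []
        for ch in Channel:
            assert np.all(stream.channels[ch] == 0.0)


class TestChannelScore:
    def test_baseline_rate_scores_one(self):
        from drowsikit.ear import BlinkEvent

        events = [BlinkEvent(t, 0.1) for t in np.linspace(0, 59, 15)]
        assert eog_channel_score(events, 60.0, expected_rate=15.0) == 1.0

    def test_no_blinks_scores_zero(self):
        assert eog_channel_score([], 60.0, expected_rate=15.0) == 0.0

    def test_elevated_rate_scores_below_one(self):
        from drowsikit.ear import BlinkEvent

        events = [BlinkEvent(t, 0.1) for t in np.linspace(0, 59, 30)]
        assert eog_channel_score(events, 60.0, expected_rate=15.0) < 1.0

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            eog_channel_score([], 0.0)


def test_stream_csv_round_trip(tmp_path):
    sc = SessionScenario(duration=4.0, blink_times=(2.0,), seed=3)
    stream, _ = gen_eog_stream(sc, snr=8.0)
    path = tmp_path / "eog.csv"
    stream.to_csv(path)
    loaded = EogStream.from_csv(path)
    assert loaded.sample_rate == pytest.approx(stream.sample_rate)
    for ch in Channel:
        np.testing.assert_allclose(loaded.channels[ch], stream.channels[ch])
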