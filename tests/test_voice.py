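"""Voice feature extraction: frame statistics, pauses, zero-crossing pitch."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pdscreen as p
from pdscreen import voice as V
from pdscreen.errors import FeatureUndefinedError, InputError

from conftest import brute_force_crossings, brute_force_pause_count, make_tone


def series(values, frame_duration=0.025):
    return V.FrameSeries(np.asarray(values, float), frame_duration, "volume")


class TestFrameVolume:
    def test_constant_signal(self):
        sig = p.AudioSignal(np.full(44100, 200.0))
        vols = V.frame_volume(sig)
        assert len(vols) == 40
        assert np.allclose(vols.values, 200.0)

    def test_silence_is_zero(self):
        vols = V.frame_volume(p.AudioSignal(np.zeros(44100)))
        assert np.allclose(vols.values, 0.0)

    def test_crafted_per_frame_means(self):
        # sr=1000 so a 25 ms frame is exactly 25 samples
        x = np.concatenate([np.full(25, -10.0), np.full(25, 300.0), np.full(25, 10.0)])
        vols = V.frame_volume(p.AudioSignal(x, sample_rate=1000))
        assert vols.values.tolist() == [10.0, 300.0, 10.0]

    def test_trailing_partial_frame_dropped(self):
        vols = V.frame_volume(p.AudioSignal(np.ones(44100 + 500)))
        assert len(vols) == 40

    def test_too_short_signal(self):
        with pytest.raises(InputError):
            V.frame_volume(p.AudioSignal(np.ones(100)))


class TestPauseRules:
    @pytest.mark.parametrize(
        "mean_volume,expected", [(150.0, 30.0), (100.0, 20.0), (5.0, 20.0)]
    )
    def test_threshold_rule(self, mean_volume, expected):
        assert V.pause_threshold(series([mean_volume] * 4)) == expected

    def test_no_pauses_when_loud(self):
        assert V.pause_percentage(series([200.0] * 10)) == 0.0

    def test_half_pause(self):
        # mean 102.5 -> threshold 30; two of four frames below
        assert V.pause_percentage(series([5, 5, 200, 200])) == 50.0

    def test_silence_all_pause(self):
        assert V.pause_percentage(series([0.0] * 8)) == 100.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 500), min_size=1, max_size=60))
    def test_matches_brute_force_count(self, vols):
        s = series(vols)
        expected = 100.0 * brute_force_pause_count(s.values) / len(vols)
        assert V.pause_percentage(s) == pytest.approx(expected, abs=1e-12)


class TestVolumeVariance:
    def test_constant_is_zero(self):
        assert V.volume_variance(series([120.0] * 9)) == 0.0

    def test_hand_computed_value(self):
        # 100 * (mean(100,100) - mean(200,200)) / 150 = -66.67
        assert V.volume_variance(series([100, 100, 200, 200])) == pytest.approx(-200 / 3)

    def test_reversal_negates_even_length(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(10, 300, 20)
        assert V.volume_variance(series(v)) == pytest.approx(
            -V.volume_variance(series(v[::-1].copy()))
        )

    def test_odd_middle_frame_joins_first_half(self):
        # halves: {30, 60} and {90}: 100*(45-90)/60
        assert V.volume_variance(series([30, 60, 90])) == pytest.approx(100 * (45 - 90) / 60)

    def test_silent_signal_undefined(self):
        with pytest.raises(FeatureUndefinedError):
            V.volume_variance(series([0.0, 0.0]))


class TestZeroCrossings:
    def test_constant_positive_no_crossings(self):
        cz = V.zero_crossings(p.AudioSignal(np.full(44100, 5.0)))
        assert np.all(cz.values == 0)

    def test_sine_crossing_rate(self):
        cz = V.zero_crossings(make_tone(100, duration=2.0))
        assert cz.values.mean() == pytest.approx(2.0, abs=0.02)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 10_000), st.integers(30, 400))
    def test_matches_brute_force_scan(self, seed, n):
        rng = np.random.default_rng(seed)
        # small integers so zero samples actually occur
        x = rng.integers(-4, 5, size=n).astype(float)
        if not np.any(x):
            x[0] = 1.0
        sig = p.AudioSignal(x, sample_rate=1000)  # 10 ms -> 10 samples/frame
        cz = V.zero_crossings(sig, frame_duration=0.010)
        assert cz.values.tolist() == brute_force_crossings(x, 10)


class TestPitch:
    @pytest.mark.parametrize("f0", [150, 220])
    def test_sine_recovers_frequency(self, f0):
        cz = V.zero_crossings(make_tone(f0, duration=2.0))
        assert V.average_pitch(cz) == pytest.approx(f0, rel=0.02)

    def test_doubling_frequency_doubles_estimate(self):
        est = [
            V.average_pitch(V.zero_crossings(make_tone(f, duration=2.0)))
            for f in (110, 220)
        ]
        assert est[1] == pytest.approx(2 * est[0], rel=0.03)

    def test_amplitude_scaling_invariance(self):
        a = V.zero_crossings(make_tone(180, amplitude=500))
        b = V.zero_crossings(make_tone(180, amplitude=5000))
        assert np.array_equal(a.values, b.values)

    def test_pure_sine_pitch_variance_zero(self):
        # 150 Hz at 44.1 kHz: exactly 3 crossings every 10 ms frame
        cz = V.zero_crossings(make_tone(150, duration=2.0, phase=0.3))
        assert V.pitch_variance(cz) == 0.0

    def test_hand_computed_pitch_variance(self):
        cz = V.FrameSeries(np.array([2.0, 4.0, 2.0, 4.0]), 0.010, "crossings")
        # mean |diff| = 2 counts -> 2 / (2 * 0.01) = 100 Hz
        assert V.pitch_variance(cz) == pytest.approx(100.0)

    def test_order_matters(self):
        a = V.FrameSeries(np.array([2.0, 4.0, 2.0, 4.0]), 0.010, "crossings")
        b = V.FrameSeries(np.array([2.0, 2.0, 4.0, 4.0]), 0.010, "crossings")
        assert V.pitch_variance(a) != V.pitch_variance(b)

    def test_no_voiced_frames_undefined(self):
        cz = V.FrameSeries(np.array([2.0, 3.0]), 0.010, "crossings")
        with pytest.raises(FeatureUndefinedError):
            V.average_pitch(cz, voiced_mask=np.array([False, False]))
        with pytest.raises(FeatureUndefinedError):
            V.pitch_variance(cz, voiced_mask=np.array([True, False]))


class TestReadingTime:
    def test_speech_span_within_silence(self):
        vols = np.zeros(100)
        vols[10:50] = 200.0  # frames 10..49 active -> 40 frames * 25 ms = 1 s
        assert V.reading_time(series(vols)) == pytest.approx(1.0)

    def test_fully_voiced_is_total_duration(self):
        assert V.reading_time(series([100.0] * 40)) == pytest.approx(1.0)

    def test_padding_invariance(self):
        core = np.full(40, 200.0)
        padded = np.concatenate([np.zeros(17), core, np.zeros(5)])
        assert V.reading_time(series(padded)) == V.reading_time(series(core))

    def test_all_pause_undefined(self):
        with pytest.raises(FeatureUndefinedError):
            V.reading_time(series([1.0] * 10))


class TestExtractVoiceFeatures:
    def test_planted_pause_recovered(self):
        sig, truth = p.simulate_voice(
            p.VoiceParams(duration_s=30, pause_fraction=0.30, f0_mean=160), seed=5
        )
        vf = p.extract_voice_features(sig)
        assert vf.pause_percentage == pytest.approx(100 * truth["pause_fraction"], abs=2.0)

    def test_pure_tone_no_pauses(self):
        vf = p.extract_voice_features(make_tone(150, duration=3.0))
        assert vf.pause_percentage == 0.0
        assert vf.pitch_variance == pytest.approx(0.0, abs=1.0)
        assert vf.average_pitch == pytest.approx(150.0, rel=0.02)

    def test_fading_volume_positive_variance(self):
        sig, _ = p.simulate_voice(
            p.VoiceParams(duration_s=20, pause_fraction=0.0, volume_drift=0.4), seed=2
        )
        assert p.extract_voice_features(sig).volume_variance > 5.0

    def test_sign_flip_invariance(self):
        sig, _ = p.simulate_voice(p.VoiceParams(duration_s=10, pause_fraction=0.2), seed=9)
        a = p.extract_voice_features(sig).to_dict()
        flipped = p.AudioSignal(-sig.samples, sig.sample_rate)
        b = p.extract_voice_features(flipped).to_dict()
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-9), key
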