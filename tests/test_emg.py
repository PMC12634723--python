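"""EMG preprocessing chain, normalizations and window features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

from mmdtkit.emg import (
    CalibrationProfile,
    EmgRecording,
    build_training_samples,
    muscle_contraction_level,
    normalize_vector,
    preprocess_channel,
    window_features,
)
from mmdtkit import synth

FS = 200.0


class TestPreprocessChannel:
    def test_zero_in_zero_out(self):
        assert np.allclose(preprocess_channel(np.zeros(500)), 0.0)

    def test_dc_gain_amplifies_by_ten(self):
        # 20 dB amplitude gain and unity-DC-gain filter: 0.5 mV -> 5.0 mV
        env = preprocess_channel(np.full(4000, 0.5), fs=FS)
        assert env[-1] == pytest.approx(5.0, rel=1e-6)

    def test_rectified_sine_envelope_mean(self):
        # full-wave rectified sine has mean 2A/pi; after x10 gain and the
        # unity-DC-gain low-pass the steady-state envelope mean follows.
        # 47.3 Hz is incommensurate with fs=200 so the sampled phases
        # equidistribute (an exact submultiple like 50 Hz would alias).
        a = 0.3
        t = np.arange(int(20 * FS)) / FS
        env = preprocess_channel(a * np.sin(2 * np.pi * 47.3 * t), fs=FS)
        steady = env[int(5 * FS):]
        assert steady.mean() == pytest.approx(2 / np.pi * 10 * a, rel=0.02)

    def test_filter_dc_gain_is_unity(self):
        b, a = signal.butter(2, 3.0, btype="low", fs=FS)
        assert abs(np.sum(b) / np.sum(a) - 1.0) < 1e-9

    def test_envelope_never_negative(self):
        rng = np.random.default_rng(0)
        env = preprocess_channel(rng.normal(size=2000), fs=FS)
        assert np.all(env >= 0)

    @pytest.mark.parametrize("bad", [np.array([]), None])
    def test_empty_series_rejected(self, bad):
        with pytest.raises((ValueError, TypeError)):
            preprocess_channel(bad if bad is not None else None)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            preprocess_channel(np.ones(100), fs=200, fc=150)


class TestNormalizeVector:
    def test_uniform_activation_gives_equal_shares(self):
        out = normalize_vector(np.full(8, 2.0), np.full(8, 1.0))
        assert np.allclose(out, 0.125)

    def test_known_shares(self):
        out = normalize_vector(np.array([1, 1, 2, 0, 0, 0, 0, 0], float),
                               np.zeros(8))
        assert np.allclose(out, [0.25, 0.25, 0.5, 0, 0, 0, 0, 0])

    def test_rest_input_raises(self):
        rest = np.full(8, 0.3)
        with pytest.raises(ZeroDivisionError, match="zero total activation"):
            normalize_vector(rest.copy(), rest)

    @given(st.lists(st.floats(-5, 5), min_size=8, max_size=8))
    @settings(deadline=None, max_examples=100)
    def test_output_sums_to_one(self, deltas):
        emg = np.asarray(deltas)
        if abs(emg.sum()) < 1e-6:
            return
        out = normalize_vector(emg, np.zeros(8))
        assert abs(out.sum() - 1.0) < 1e-12


class TestMuscleContractionLevel:
    def test_rest_is_zero_and_max_is_one(self, cal):
        assert muscle_contraction_level(cal.rest, cal) == 0.0
        assert muscle_contraction_level(cal.max, cal) == pytest.approx(1.0)

    def test_midpoint_is_half(self, cal):
        mid = (cal.rest + cal.max) / 2
        assert muscle_contraction_level(mid, cal) == pytest.approx(0.5)

    def test_clamped_above(self, cal):
        assert muscle_contraction_level(cal.max * 10, cal) == 1.5

    @given(st.floats(0.1, 10), st.floats(0, 2), st.integers(0, 100))
    @settings(deadline=None, max_examples=50)
    def test_affine_rescaling_invariance(self, scale, shift, seed):
        # per-channel affine map of (emg, rest, max) leaves the MCL unchanged
        rng = np.random.default_rng(seed)
        rest = rng.uniform(0, 1, 8)
        mx = rest + rng.uniform(0.5, 2, 8)
        emg = rest + rng.uniform(0, 1, 8) * (mx - rest)
        base = muscle_contraction_level(emg, CalibrationProfile(rest, mx))
        shifted = muscle_contraction_level(
            emg * scale + shift,
            CalibrationProfile(rest * scale + shift, mx * scale + shift))
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_degenerate_calibration_rejected(self):
        with pytest.raises(ValueError):
            CalibrationProfile(rest=np.ones(8), max=np.ones(8))


class TestWindowFeatures:
    @pytest.mark.parametrize("window,mav,iemg,rms", [
        (np.full(10, 0.7), 0.7, 7.0, 0.7),
        (np.array([1.0, -1.0, 1.0, -1.0]), 1.0, 4.0, 1.0),
    ])
    def test_closed_form_windows(self, window, mav, iemg, rms):
        fs = window_features(window)
        assert fs.mav == pytest.approx(mav)
        assert fs.iemg == pytest.approx(iemg)
        assert fs.rms == pytest.approx(rms)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(42)
        w = rng.normal(size=257)
        fs = window_features(w)
        mav = sum(abs(x) for x in w) / len(w)
        iemg = sum(abs(x) for x in w)
        rms = (sum(x * x for x in w) / len(w)) ** 0.5
        assert abs(fs.mav - mav) < 1e-12
        assert abs(fs.iemg - iemg) < 1e-10
        assert abs(fs.rms - rms) < 1e-12

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            window_features(np.array([]))


class TestBuildTrainingSamples:
    def test_twenty_samples_from_active_window(self, cal):
        rec = synth.gen_training_recording("hold", cal, seed=3)
        samples = build_training_samples(rec, "hold", cal)
        assert len(samples) == 20
        for vec, label in samples:
            assert label == "hold"
            assert abs(vec.sum() - 1.0) < 1e-9

    def test_short_recording_rejected(self, cal):
        rec = EmgRecording(np.random.default_rng(0).normal(size=(1000, 8)))
        with pytest.raises(ValueError, match="active window incomplete"):
            build_training_samples(rec, "hold", cal)

    def test_even_spacing_arithmetic(self, cal):
        # 4 samples over index window [400, 1200) land at 400, 600, 800, 1000
        rec = synth.gen_training_recording("hold", cal, seed=3)
        lo = 400
        idx = lo + (np.arange(4) * 800) // 4
        assert list(idx) == [400, 600, 800, 1000]
        samples = build_training_samples(rec, "hold", cal, n_samples=4)
        assert len(samples) == 4

    def test_random_mode_is_seeded(self, cal):
        rec = synth.gen_training_recording("release", cal, seed=4)
        a = build_training_samples(rec, "release", cal, mode="random", seed=9)
        b = build_training_samples(rec, "release", cal, mode="random", seed=9)
        assert all(np.array_equal(x, y) for (x, _), (y, _) in zip(a, b))


class TestEmgRecordingIO:
    def test_csv_round_trip_infers_fs(self, tmp_path, cal):
        rec = synth.gen_training_recording("hold", cal, seed=5)
        rec.to_csv(tmp_path / "emg.csv")
        back = EmgRecording.from_csv(tmp_path / "emg.csv", expected_fs=200.0)
        assert back.fs == pytest.approx(200.0, rel=1e-6)
        assert np.allclose(back.samples, rec.samples, atol=1e-9)

    def test_fs_mismatch_rejected(self, tmp_path, cal):
        rec = synth.gen_training_recording("hold", cal, seed=5)
        rec.to_csv(tmp_path / "emg.csv")
        with pytest.raises(ValueError, match="disagrees"):
            EmgRecording.from_csv(tmp_path / "emg.csv", expected_fs=100.0)
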