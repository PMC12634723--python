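"""Surface-EMG preprocessing for forearm-band recordings.

The band delivers 8 channels at 200 Hz. The processing chain mirrors a
conventional envelope extractor: amplitude amplification (20 dB), full-wave
rectification, and a 2nd-order low-pass Butterworth at 3 Hz. On top of the
envelopes this module provides the two normalisations used for motion
classification — the per-sample channel-share vector (components sum to 1)
and the scalar muscle contraction level (MCL) referenced to rest/maximal
calibration — plus the classic time-domain window features (MAV, IEMG, RMS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "EmgRecording",
    "CalibrationProfile",
    "FeatureSet",
    "preprocess_channel",
    "preprocess_recording",
    "normalize_vector",
    "muscle_contraction_level",
    "window_features",
    "build_training_samples",
]

DEFAULT_FS = 200.0
N_CHANNELS = 8


@dataclass
class EmgRecording:
    """Multi-channel EMG stream in millivolts.

    ``samples`` has shape (n_samples, n_channels); ``fs`` is the sampling
    rate in Hz; ``t0`` the start time in seconds.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (n_samples, n_channels)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def to_csv(self, path) -> None:
        """Write as tabular text: columns ``t, ch1..ch8``."""
        cols = {"t": self.t}
        for i in range(self.n_channels):
            cols[f"ch{i + 1}"] = self.samples[:, i]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, expected_fs: float | None = None) -> "EmgRecording":
        """Read a ``t, ch1..chN`` CSV; fs is inferred from the timestamps.

        If ``expected_fs`` is given the inferred rate must agree within 1%.
        """
        df = pd.read_csv(path)
        if "t" not in df.columns:
            raise ValueError("EMG CSV must have a 't' column")
        chan_cols = [c for c in df.columns if c.startswith("ch")]
        if not chan_cols:
            raise ValueError("EMG CSV must have ch1..chN columns")
        chan_cols.sort(key=lambda c: int(c[2:]))
        t = df["t"].to_numpy(float)
        if len(t) < 2:
            raise ValueError("EMG CSV must contain at least 2 samples")
        dt = np.diff(t)
        fs = 1.0 / float(np.median(dt))
        if expected_fs is not None and abs(fs - expected_fs) > 0.01 * expected_fs:
            raise ValueError(
                f"inferred fs {fs:.3f} Hz disagrees with configured {expected_fs} Hz"
            )
        return cls(df[chan_cols].to_numpy(float), fs=fs, t0=float(t[0]))


@dataclass
class CalibrationProfile:
    """Per-channel envelope levels at rest and at maximal voluntary contraction."""

    rest: np.ndarray
    max: np.ndarray

    def __post_init__(self) -> None:
        self.rest = np.asarray(self.rest, dtype=float)
        self.max = np.asarray(self.max, dtype=float)
        if self.rest.shape != self.max.shape:
            raise ValueError("rest and max must have the same shape")
        if np.any(self.rest < 0):
            raise ValueError("rest envelope levels must be non-negative")
        if np.any(self.max <= self.rest):
            raise ValueError("max must exceed rest on every channel")

    @property
    def n_channels(self) -> int:
        return self.rest.shape[0]

    @property
    def span(self) -> np.ndarray:
        return self.max - self.rest


@dataclass(frozen=True)
class FeatureSet:
    """Time-domain window features: MAV, IEMG, RMS."""

    mav: float
    iemg: float
    rms: float

    def as_vector(self) -> np.ndarray:
        return np.array([self.mav, self.iemg, self.rms])


def _envelope_filter(fs: float, fc: float, order: int):
    if fc >= fs / 2:
        raise ValueError(f"cutoff {fc} Hz must be below Nyquist {fs / 2} Hz")
    return signal.butter(order, fc, btype="low", fs=fs)


def preprocess_channel(
    raw: np.ndarray,
    fs: float = DEFAULT_FS,
    gain_db: float = 20.0,
    fc: float = 3.0,
    order: int = 2,
) -> np.ndarray:
    """Amplify, rectify and low-pass one raw EMG channel into an envelope.

    Gain is an amplitude gain (20 dB = x10). The filter is a causal
    single-pass digital Butterworth with unity DC gain; small negative
    excursions from filter ringing are clipped at zero because the envelope
    is a magnitude.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty EMG series")
    b, a = _envelope_filter(fs, fc, order)
    rectified = np.abs(raw * 10.0 ** (gain_db / 20.0))
    env = signal.lfilter(b, a, rectified)
    return np.maximum(env, 0.0)


def preprocess_recording(rec: EmgRecording, **kwargs) -> np.ndarray:
    """Envelope of every channel; shape matches ``rec.samples``."""
    return np.column_stack(
        [preprocess_channel(rec.samples[:, i], fs=rec.fs, **kwargs)
         for i in range(rec.n_channels)]
    )


def normalize_vector(emg: np.ndarray, rest: np.ndarray) -> np.ndarray:
    """Rest-subtracted channel shares summing to one.

    out[i] = (emg[i] - rest[i]) / sum_j(emg[j] - rest[j]).  Raises when the
    total activation is zero (arm at rest); callers gate on MCL first.
    """
    emg = np.asarray(emg, dtype=float)
    rest = np.asarray(rest, dtype=float)
    if emg.shape != rest.shape:
        raise ValueError("emg and rest must have equal length")
    centered = emg - rest
    denom = centered.sum()
    if denom == 0:
        raise ZeroDivisionError("zero total activation: signals at rest")
    return centered / denom


def muscle_contraction_level(
    emg: np.ndarray,
    cal: CalibrationProfile,
    clamp: tuple[float, float] | None = (0.0, 1.5),
) -> float:
    """Scalar contraction level: mean over channels of the rest-to-max fraction.

    0 at rest, 1 at the calibrated maximum. Clamped to [0, 1.5] by default to
    tolerate supra-calibration contractions; pass ``clamp=None`` to disable.
    """
    emg = np.asarray(emg, dtype=float)
    mcl = float(np.mean((emg - cal.rest) / cal.span))
    if clamp is not None:
        mcl = min(max(mcl, clamp[0]), clamp[1])
    return mcl


def mcl_series(envelopes: np.ndarray, cal: CalibrationProfile,
               clamp: tuple[float, float] | None = (0.0, 1.5)) -> np.ndarray:
    """Vectorised MCL over an (n_samples, n_channels) envelope array."""
    m = np.mean((envelopes - cal.rest) / cal.span, axis=1)
    if clamp is not None:
        m = np.clip(m, clamp[0], clamp[1])
    return m


def window_features(window: np.ndarray) -> FeatureSet:
    """MAV (mean |x|), IEMG (sum |x|) and RMS of one analysis window."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    absx = np.abs(window)
    return FeatureSet(
        mav=float(absx.mean()),
        iemg=float(absx.sum()),
        rms=float(np.sqrt(np.mean(window ** 2))),
    )


def active_window_indices(fs: float, start_s: float = 2.0, end_s: float = 6.0):
    """Sample-index range of the gesture window inside a training recording."""
    return int(round(start_s * fs)), int(round(end_s * fs))


def build_training_samples(
    recording: EmgRecording,
    label: str,
    cal: CalibrationProfile,
    n_samples: int = 20,
    mode: str = "even",
    seed: int | None = None,
) -> list[tuple[np.ndarray, str]]:
    """Extract labelled classifier inputs from an 8-s gesture recording.

    The gesture is performed between seconds 2 and 6 of the recording;
    ``n_samples`` envelope frames are taken from that window only (evenly
    spaced by default, or a seeded random subsample with ``mode='random'``)
    and converted to the channel-share vectors the classifier consumes.
    """
    lo, hi = active_window_indices(recording.fs)
    if recording.n_samples < hi:
        raise ValueError(
            f"active window incomplete: recording has {recording.n_samples} samples, "
            f"needs {hi} (6 s at {recording.fs:g} Hz)"
        )
    if mode == "even":
        idx = lo + (np.arange(n_samples) * (hi - lo)) // n_samples
    elif mode == "random":
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(np.arange(lo, hi), size=n_samples, replace=False))
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    env = preprocess_recording(recording)
    return [(normalize_vector(env[i], cal.rest), label) for i in idx]
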