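"""Forearm IMU kinematics: unit conversion, per-phase summaries, inactivity.

The armband's 9-axis IMU supplies 3-axis angular velocity (roll/pitch/yaw,
deg/s, range +-2000) and 3-axis linear acceleration (g, range +-16). The
accelerometer is converted to m/s^2 with gravity subtracted from the Z axis
(the sensor Z is assumed near world-vertical; no orientation fusion). Phase
summaries report the peak absolute angular velocity per axis and the mean of
local acceleration peaks per axis; an inactivity detector accumulates the
time during which every kinematic channel stays below its threshold
("thinking time" in the assessment rules).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "ImuTrace",
    "KinSummary",
    "GRAVITY",
    "GYRO_RANGE_DPS",
    "ACCEL_RANGE_G",
    "accel_to_ms2",
    "summarize_phase",
    "inactivity_time",
    "quiet_intervals",
]

GRAVITY = 9.81  # m/s^2
GYRO_RANGE_DPS = 2000.0
ACCEL_RANGE_G = 16.0
DEFAULT_IMU_FS = 50.0

AXES = ("x", "y", "z")
GYRO_AXES = ("roll", "pitch", "yaw")


@dataclass
class ImuTrace:
    """Time-stamped gyro (deg/s) and accelerometer (g) series.

    ``gyro`` and ``accel`` have shape (n_samples, 3); gyro axes are
    roll/pitch/yaw about X/Y/Z, accelerometer axes are X/Y/Z in g.
    """

    t: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    fs: float = DEFAULT_IMU_FS

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.gyro.shape != (self.t.size, 3) or self.accel.shape != (self.t.size, 3):
            raise ValueError("gyro and accel must be (n_samples, 3)")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(np.abs(self.gyro) > GYRO_RANGE_DPS):
            raise ValueError(f"gyro exceeds sensor range +-{GYRO_RANGE_DPS} deg/s")
        if np.any(np.abs(self.accel) > ACCEL_RANGE_G):
            raise ValueError(f"accel exceeds sensor range +-{ACCEL_RANGE_G} g")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) + 1.0 / self.fs

    def accel_ms2(self) -> np.ndarray:
        return accel_to_ms2(self.accel)

    def slice(self, t_start: float, t_end: float) -> "ImuTrace":
        m = (self.t >= t_start) & (self.t < t_end)
        return ImuTrace(self.t[m], self.gyro[m], self.accel[m], self.fs)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "t": self.t,
            "gx": self.gyro[:, 0], "gy": self.gyro[:, 1], "gz": self.gyro[:, 2],
            "ax": self.accel[:, 0], "ay": self.accel[:, 1], "az": self.accel[:, 2],
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float | None = None) -> "ImuTrace":
        df = pd.read_csv(path)
        t = df["t"].to_numpy(float)
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else DEFAULT_IMU_FS
        return cls(t, df[["gx", "gy", "gz"]].to_numpy(float),
                   df[["ax", "ay", "az"]].to_numpy(float), fs)


def accel_to_ms2(accel_g: np.ndarray) -> np.ndarray:
    """g -> m/s^2 with gravity (9.81) subtracted from the Z component."""
    a = np.asarray(accel_g, dtype=float) * GRAVITY
    a = a.copy()
    a[..., 2] -= GRAVITY
    return a


@dataclass
class KinSummary:
    """Per-phase kinematic summary.

    gyro_max_dps: max |angular velocity| per roll/pitch/yaw axis (deg/s).
    accel_peak_mean_ms2: mean of local |acceleration| peaks per X/Y/Z axis
    (m/s^2, gravity-compensated); 0 when an axis has no peaks.
    Plus plain mean/min/max per axis for both sensors.
    """

    gyro_max_dps: dict
    accel_peak_mean_ms2: dict
    gyro_stats: dict
    accel_stats: dict

    def as_dict(self) -> dict:
        return {
            "gyro_max_dps": self.gyro_max_dps,
            "accel_peak_mean_ms2": self.accel_peak_mean_ms2,
            "gyro_stats": self.gyro_stats,
            "accel_stats": self.accel_stats,
        }


def _axis_stats(arr: np.ndarray, names) -> dict:
    return {
        name: {
            "mean": float(arr[:, i].mean()),
            "min": float(arr[:, i].min()),
            "max": float(arr[:, i].max()),
        }
        for i, name in enumerate(names)
    }


def summarize_phase(trace: ImuTrace, peak_prominence: float = 0.3) -> KinSummary:
    """Summarise one test phase: peak angular velocities and mean accel peaks.

    Acceleration peaks are local maxima of |a| with prominence at least
    ``peak_prominence`` (m/s^2); the per-axis summary is their mean amplitude,
    defined as 0 for an axis without peaks.
    """
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    acc = trace.accel_ms2()
    gyro_max = {name: float(np.max(np.abs(trace.gyro[:, i])))
                for i, name in enumerate(GYRO_AXES)}
    peak_means = {}
    for i, name in enumerate(AXES):
        mag = np.abs(acc[:, i])
        idx, _ = find_peaks(mag, prominence=peak_prominence)
        peak_means[name] = float(mag[idx].mean()) if idx.size else 0.0
    return KinSummary(
        gyro_max_dps=gyro_max,
        accel_peak_mean_ms2=peak_means,
        gyro_stats=_axis_stats(trace.gyro, GYRO_AXES),
        accel_stats=_axis_stats(acc, AXES),
    )


def inactivity_time(
    trace: ImuTrace,
    gyro_thresh: float = 10.0,
    accel_thresh: float = 0.3,
) -> float:
    """Seconds during which the arm is (near-)stationary.

    A sample is quiet when every gyro axis satisfies |w| < gyro_thresh
    (deg/s) and every gravity-compensated accel axis satisfies
    |a| < accel_thresh (m/s^2). Quiet time is the quiet-sample count divided
    by the sampling rate.
    """
    if gyro_thresh <= 0 or accel_thresh <= 0:
        raise ValueError("thresholds must be positive")
    if trace.n_samples == 0:
        return 0.0
    quiet = _quiet_mask(trace, gyro_thresh, accel_thresh)
    return float(quiet.sum() / trace.fs)


def _quiet_mask(trace: ImuTrace, gyro_thresh: float, accel_thresh: float):
    return (np.all(np.abs(trace.gyro) < gyro_thresh, axis=1)
            & np.all(np.abs(trace.accel_ms2()) < accel_thresh, axis=1))


def quiet_intervals(
    trace: ImuTrace,
    gyro_thresh: float = 10.0,
    accel_thresh: float = 0.3,
) -> list[tuple[float, float]]:
    """Maximal (start, end) intervals of consecutive quiet samples.

    The end bound is exclusive at one sample past the last quiet sample, so
    an interval's duration is its quiet-sample count divided by fs.
    """
    quiet = _quiet_mask(trace, gyro_thresh, accel_thresh)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], quiet.astype(int), [0]))))
    starts, ends = edges[::2], edges[1::2]
    return [(float(trace.t[a]), float(trace.t[a] + (b - a) / trace.fs))
            for a, b in zip(starts, ends)]
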