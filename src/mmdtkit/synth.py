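"""Synthetic test sessions with ground truth, for validation and examples.

No public dataset exists for this system, so this module emulates all three
sensor streams of a dexterity-test session — board camera frames, 8-channel
EMG, and forearm IMU — from an explicit ``SessionSchedule`` that doubles as
ground truth: disc event times, hold/release gesture windows, arm-movement
bursts, and a lighting condition (normal / shadow / flash / dim).

What it emulates: disc colour states at known hole centres with pixel noise
and gross illumination changes; EMG envelopes with channels 4-5 dominant
during grasping (as observed on the real armband) riding on a rectified
carrier; IMU bursts as half-sine pulses over a gravity baseline. What it
does not: photorealistic hands/occlusion, biophysical EMG statistics, or
sensor drift — see the methods note for what that implies about test scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .emg import CalibrationProfile, EmgRecording
from .imu import ACCEL_RANGE_G, GRAVITY, GYRO_RANGE_DPS, ImuTrace
from .tables import load_fixture  # re-exported: packaged reference tables
from .vision import PLACING, TURNING, BoardLayout

__all__ = [
    "SessionSchedule",
    "LIGHTING_MODES",
    "gen_board_frames",
    "gen_emg",
    "gen_imu",
    "load_fixture",
    "default_calibration",
    "RED_RGB",
    "BLACK_RGB",
    "WHITE_RGB",
]

LIGHTING_MODES = ("normal", "shadow", "flash", "dim")

# Disc/board colours. The red face is deliberately a dark red (V ~ 100 on the
# 0-255 value scale): under a x0.25 shadow its value channel drops below the
# black threshold, reproducing the real system's shadow failure mode where a
# shadowed disc reads "closer to black".
WHITE_RGB = (240, 240, 240)
RED_RGB = (100, 12, 12)
BLACK_RGB = (12, 12, 12)

DISC_RADIUS_PX = 12
PATCH_HALF_PX = 35  # half-side of the shadow/flash patch around a hole
DEFAULT_FPS = 10.0

# Per-channel activation profiles as fractions of the rest-to-max span.
# Channels 4 and 5 dominate both gestures; grasping pushes them slightly past
# the calibrated maximum (squeezes during the test exceed the calibration
# squeeze), which keeps the scalar contraction level clearly above the rest
# gate. Co-activation of the remaining channels stays at <= 30% of the rise.
HOLD_PROFILE = np.array([0.3, 0.3, 0.3, 1.15, 1.15, 0.3, 0.3, 0.3])
RELEASE_PROFILE = np.array([0.6, 0.6, 0.3, 0.8, 0.8, 0.3, 0.6, 0.6])


def default_calibration(n_channels: int = 8) -> CalibrationProfile:
    """A plausible armband calibration: ~0.05 mV rest, ~1.5-2 mV maximal."""
    rest = np.full(n_channels, 0.05)
    mx = np.linspace(1.5, 2.0, n_channels)
    return CalibrationProfile(rest=rest, max=mx)


@dataclass
class SessionSchedule:
    """Ground-truth plan of one synthetic test phase."""

    phase: str = PLACING
    disc_events: list = field(default_factory=list)   # [(hole_id, time_s)]
    upside_down: list = field(default_factory=list)   # hole ids placed black-up
    hold_windows: list = field(default_factory=list)  # [(start_s, end_s)]
    release_windows: list = field(default_factory=list)
    imu_bursts: list = field(default_factory=list)    # [(t, "gyro"|"accel", axis, amp)]
    lighting: str = "normal"
    perturbed_holes: list = field(default_factory=list)
    duration: float = 0.0
    phase_start: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase not in (PLACING, TURNING):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.lighting not in LIGHTING_MODES:
            raise ValueError(f"unknown lighting mode {self.lighting!r}")
        times = [t for _, t in self.disc_events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("disc event times must be strictly increasing")
        hw = sorted(self.hold_windows)
        if any(b[0] < a[1] for a, b in zip(hw, hw[1:])):
            raise ValueError("hold windows must not overlap")
        if not self.duration and times:
            self.duration = times[-1] + 1.0

    @classmethod
    def generate(
        cls,
        phase: str = PLACING,
        n_discs: int = 60,
        seed: int = 0,
        mean_gap: float = 1.0,
        gap_jitter: float = 0.15,
        lighting: str = "normal",
        n_perturbed: int = 1,
        hold_fraction: float = 0.45,
    ) -> "SessionSchedule":
        """Draw a random but reproducible session plan.

        Disc events are spaced ``mean_gap`` +- jitter seconds apart (the
        healthy-cohort per-disc averages are ~1 s); each inter-event interval
        carries one hold window covering ``hold_fraction`` of it, followed by
        a brief release gesture. Shadow/flash modes perturb ``n_perturbed``
        random holes.
        """
        rng = np.random.default_rng(seed)
        gaps = rng.uniform(mean_gap - gap_jitter, mean_gap + gap_jitter, n_discs)
        times = 0.5 + np.cumsum(gaps)
        order = rng.permutation(60)[:n_discs]
        events = list(zip(order.tolist(), np.round(times, 3).tolist()))
        holds = []
        prev = 0.5
        for _, t in events:
            span = t - prev
            h0 = prev + 0.1 * span
            h1 = h0 + hold_fraction * span
            holds.append((round(h0, 3), round(h1, 3)))
            prev = t
        # The open hand persists from one disc's release until the next
        # grasp (the subject reaches for the next disc open-handed), so
        # every hold boundary is a hold<->release crossover for the
        # classifier; the crossover delays on the two sides are symmetric
        # and the accumulated hold time stays unbiased.
        releases = [(h1, nh0) for (_, h1), (nh0, _) in zip(holds, holds[1:])]
        last_h1 = holds[-1][1]
        releases.append((last_h1, round(last_h1 + 0.3 * (times[-1] - last_h1), 3)))
        perturbed = (sorted(rng.permutation(order)[:n_perturbed].tolist())
                     if lighting in ("shadow", "flash") else [])
        # One co-located gyro+accel burst per reach. Gyro amplitudes are kept
        # >= 140 deg/s and accel amplitudes <= 2 m/s^2 so that, at the default
        # inactivity thresholds (10 deg/s, 0.3 m/s^2), the accel
        # above-threshold interval nests strictly inside the gyro one and the
        # quiet-interval boundaries are set by the steep gyro edges alone.
        bursts = []
        for _, t in events:
            axis = int(rng.integers(0, 3))
            bursts.append((round(t - 0.3, 3), "gyro", axis,
                           float(rng.uniform(140, 180))))
            bursts.append((round(t - 0.3, 3), "accel", axis,
                           float(rng.uniform(1.2, 2.0))))
        return cls(
            phase=phase,
            disc_events=events,
            hold_windows=holds,
            release_windows=releases,
            imu_bursts=bursts,
            lighting=lighting,
            perturbed_holes=perturbed,
            duration=float(times[-1] + 1.0),
            seed=seed,
        )

    def total_hold_time(self) -> float:
        return float(sum(b - a for a, b in self.hold_windows))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SessionSchedule":
        with open(path) as fh:
            doc = json.load(fh)
        doc["disc_events"] = [tuple(e) for e in doc["disc_events"]]
        doc["hold_windows"] = [tuple(w) for w in doc["hold_windows"]]
        doc["release_windows"] = [tuple(w) for w in doc["release_windows"]]
        doc["imu_bursts"] = [tuple(b) for b in doc["imu_bursts"]]
        return cls(**doc)


# ---------------------------------------------------------------------------
# board frames


def _disc_mask(radius: int) -> tuple[np.ndarray, np.ndarray]:
    rr = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(rr, rr, indexing="ij")
    m = dx ** 2 + dy ** 2 <= radius ** 2
    return dx[m], dy[m]


def _apply_lighting(frame: np.ndarray, schedule: SessionSchedule,
                    layout: BoardLayout) -> np.ndarray:
    mode = schedule.lighting
    if mode == "normal":
        return frame
    if mode == "dim":
        return (frame * 0.5).astype(np.uint8)
    holes = {h.id: h for h in layout.holes}
    out = frame.copy()
    h_img, w_img = frame.shape[:2]
    for hid in schedule.perturbed_holes:
        hole = holes[hid]
        x0 = max(0, int(hole.x) - PATCH_HALF_PX)
        x1 = min(w_img, int(hole.x) + PATCH_HALF_PX)
        y0 = max(0, int(hole.y) - PATCH_HALF_PX)
        y1 = min(h_img, int(hole.y) + PATCH_HALF_PX)
        if mode == "shadow":
            out[y0:y1, x0:x1] = (out[y0:y1, x0:x1] * 0.25).astype(np.uint8)
        else:  # flash: saturation to 0, value to 255
            out[y0:y1, x0:x1] = 255
    return out


def board_colors_at(schedule: SessionSchedule, t: float) -> dict:
    """Ground-truth hole colour (name) for every occupied hole at time t."""
    upside = set(schedule.upside_down)
    colors = {}
    if schedule.phase == PLACING:
        for hid, et in schedule.disc_events:
            if et <= t:
                colors[hid] = "black" if hid in upside else "red"
    else:
        for hid in range(60):
            colors[hid] = "red"
        for hid, et in schedule.disc_events:
            if et <= t:
                colors[hid] = "black"
    return colors


def gen_board_frames(
    schedule: SessionSchedule,
    layout: BoardLayout | None = None,
    fps: float = DEFAULT_FPS,
    seed: int | None = None,
    noise_counts: int = 3,
):
    """Yield (timestamp, RGB uint8 frame) pairs for the scheduled session.

    White board background with red/black discs rendered at the hole centres
    that the schedule says are occupied at each frame time; seeded uniform
    noise of +-``noise_counts`` per channel; then the lighting perturbation.
    """
    layout = layout or BoardLayout.default_grid()
    hole_ids = {h.id for h in layout.holes}
    for hid, _ in schedule.disc_events:
        if hid not in hole_ids:
            raise ValueError(f"scheduled hole {hid} not present in layout")
    rng = np.random.default_rng(schedule.seed if seed is None else seed)
    w, h = layout.image_size
    dx, dy = _disc_mask(DISC_RADIUS_PX)
    centers = {hole.id: (int(hole.x), int(hole.y)) for hole in layout.holes}
    rgb = {"red": RED_RGB, "black": BLACK_RGB}

    n_frames = int(np.floor(schedule.duration * fps)) + 1
    clean = None
    cached_state = None
    for k in range(n_frames):
        t = k / fps
        state = tuple(sorted(board_colors_at(schedule, t).items()))
        if state != cached_state:
            clean = np.empty((h, w, 3), dtype=np.int16)
            clean[:] = WHITE_RGB
            for hid, color in state:
                cx, cy = centers[hid]
                clean[cy + dy, cx + dx] = rgb[color]
            cached_state = state
        noise = rng.integers(-noise_counts, noise_counts + 1,
                             size=clean.shape, dtype=np.int16)
        frame = np.clip(clean + noise, 0, 255).astype(np.uint8)
        yield t, _apply_lighting(frame, schedule, layout)


# ---------------------------------------------------------------------------
# EMG


def _trapezoid(t: np.ndarray, start: float, end: float, ramp: float = 0.1):
    """Unit trapezoid: ramps 0->1 over [start, start+ramp], 1->0 at the end."""
    up = np.clip((t - start) / ramp, 0.0, 1.0)
    down = np.clip((end - t) / ramp, 0.0, 1.0)
    return np.minimum(up, down) * ((t >= start) & (t <= end))


def gen_emg(
    schedule: SessionSchedule,
    cal: CalibrationProfile | None = None,
    fs: float = 200.0,
    seed: int | None = None,
    noise_frac: float = 0.02,
) -> EmgRecording:
    """Synthesize the raw 8-channel EMG stream for the scheduled gestures.

    Channel envelopes follow rest level plus trapezoidal activations of the
    hold/release profiles inside the scheduled windows, with Gaussian noise
    of sigma = ``noise_frac`` x calibration span (clipped at 0). The raw
    signal is the envelope divided by the 20 dB gain and modulated onto a
    +-1 rectangular carrier, so the preprocessing chain recovers the
    envelope. Deterministic for a fixed seed.
    """
    cal = cal or default_calibration()
    rng = np.random.default_rng(schedule.seed if seed is None else seed)
    n = int(round(schedule.duration * fs))
    t = np.arange(n) / fs
    for a, b in schedule.hold_windows + schedule.release_windows:
        if not (0 <= a < b <= schedule.duration):
            raise ValueError(f"gesture window ({a}, {b}) outside the session")

    activation = np.zeros((n, cal.n_channels))
    for a, b in schedule.hold_windows:
        activation += _trapezoid(t, a, b)[:, None] * HOLD_PROFILE
    for a, b in schedule.release_windows:
        activation += _trapezoid(t, a, b)[:, None] * RELEASE_PROFILE
    env = cal.rest + activation * cal.span
    env = env + rng.normal(0.0, noise_frac, size=env.shape) * cal.span
    env = np.maximum(env, 0.0)

    # 50 Hz rectangular carrier at fs=200: |carrier| = 1 at every sample.
    carrier = np.tile([1.0, 1.0, -1.0, -1.0], n // 4 + 1)[:n]
    raw = env / 10.0 * carrier[:, None]
    return EmgRecording(raw, fs=fs)


def gen_training_recording(
    gesture: str,
    cal: CalibrationProfile | None = None,
    fs: float = 200.0,
    seed: int = 0,
    duration: float = 8.0,
) -> EmgRecording:
    """One 8-s calibration-gesture recording (gesture held in seconds 2-6).

    These are the recordings the classifier is trained from: 20 frames are
    later sampled from the active window of each.
    """
    if gesture not in ("hold", "release"):
        raise ValueError(f"gesture must be 'hold' or 'release', got {gesture!r}")
    # The gesture ramps up slightly before second 2 so that, after the
    # causal envelope filter's ~0.1 s lag, every sampled frame in the
    # [2 s, 6 s) window carries the gesture at full activation.
    window = [(1.8, 6.2)]
    sched = SessionSchedule(
        phase=PLACING,
        hold_windows=window if gesture == "hold" else [],
        release_windows=window if gesture == "release" else [],
        duration=duration,
        seed=seed,
    )
    return gen_emg(sched, cal=cal, fs=fs, seed=seed)


# ---------------------------------------------------------------------------
# IMU


def gen_imu(
    schedule: SessionSchedule,
    fs: float = 50.0,
    seed: int | None = None,
    burst_width: float = 0.4,
    gyro_noise: float = 0.06,
    accel_noise_g: float = 0.004,
) -> ImuTrace:
    """Synthesize the IMU stream: half-sine bursts over a gravity baseline.

    Burst amplitudes are given in deg/s (gyro) or m/s^2 (gravity-compensated
    accel); amplitudes beyond the sensor ranges raise. Noise defaults are
    the sensor datasheet RMS figures (0.06 deg/s, 4 mg). Outside bursts the
    trace is baseline noise only, quiet enough to register as inactivity
    under the default thresholds; passing zero noise yields the noiseless
    kinematic profile of the same schedule (the inactivity ground truth).
    """
    rng = np.random.default_rng(schedule.seed if seed is None else seed)
    n = int(round(schedule.duration * fs))
    t = np.arange(n) / fs
    gyro = rng.normal(0.0, gyro_noise, size=(n, 3))
    accel = rng.normal(0.0, accel_noise_g, size=(n, 3))
    accel[:, 2] += 1.0  # gravity baseline

    for t0, kind, axis, amp in schedule.imu_bursts:
        if kind not in ("gyro", "accel"):
            raise ValueError(f"unknown burst kind {kind!r}")
        if kind == "gyro" and abs(amp) > GYRO_RANGE_DPS:
            raise ValueError(f"gyro burst {amp} deg/s exceeds sensor range")
        if kind == "accel" and abs(amp) / GRAVITY > ACCEL_RANGE_G:
            raise ValueError(f"accel burst {amp} m/s^2 exceeds sensor range")
        m = (t >= t0) & (t <= t0 + burst_width)
        pulse = np.sin(np.pi * (t[m] - t0) / burst_width)
        if kind == "gyro":
            gyro[m, axis] += amp * pulse
        else:
            accel[m, axis] += (amp / GRAVITY) * pulse
    return ImuTrace(t, gyro, accel, fs=fs)
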