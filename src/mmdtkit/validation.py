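"""Synthetic validation studies: detection, robustness, classifier, recovery.

These routines quantify the system's performance on seeded synthetic
sessions where the generator's schedule is the ground truth. They back the
acceptance checks and the reproduction script; each returns plain dicts of
measured quantities.
"""

from __future__ import annotations

import numpy as np

from . import synth
from .emg import build_training_samples
from .imu import quiet_intervals
from .llgmn import classify_motion, forward, gaussian_bayes_weights, total_hold_time, train
from .vision import PLACING, TURNING, BoardLayout, BoardState, advance_state, disc_timings, observe_board

__all__ = [
    "detection_study",
    "perturbation_study",
    "classifier_separation_study",
    "bayes_oracle_deviation",
    "pipeline_recovery_study",
]


def _session_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def run_session_vision(schedule, layout: BoardLayout, fps: float = 10.0,
                       seed: int | None = None) -> BoardState:
    state = BoardState(layout, phase=schedule.phase)
    for t, frame in synth.gen_board_frames(schedule, layout, fps=fps, seed=seed):
        advance_state(state, observe_board(frame, layout), t)
    return state


def detection_study(n_sessions: int = 50, seed: int = 0, n_discs: int = 60,
                    mean_gap: float = 0.35) -> dict:
    """Event-detection rate over seeded normal-light sessions, both phases.

    Every scheduled placement (placing sessions) or flip (turning sessions)
    must be detected at the right hole with the right event kind.
    """
    layout = BoardLayout.default_grid()
    expected_kind = {PLACING: "placed_correct", TURNING: "turned_correct"}
    total = correct = 0
    for i, s in enumerate(_session_seeds(seed, n_sessions)):
        phase = PLACING if i % 2 == 0 else TURNING
        sched = synth.SessionSchedule.generate(
            phase=phase, n_discs=n_discs, seed=s, mean_gap=mean_gap)
        state = run_session_vision(sched, layout)
        got = {(ev.hole_id, ev.kind) for ev in state.events}
        want = {(h, expected_kind[phase]) for h, _ in sched.disc_events}
        total += len(want)
        correct += len(got & want)
        correct -= len(got - want)  # spurious events count against
    return {"n_events": total, "n_correct": correct,
            "detection_pct": 100.0 * correct / total}


def perturbation_study(n_sessions: int = 10, seed: int = 1) -> dict:
    """Shadow/flash robustness: misdetections confined to perturbed holes.

    Observes the final frame of perturbed sessions and compares per-hole
    colour classes against the schedule's ground truth; counts how many
    mismatches fall on perturbed vs unperturbed holes.
    """
    layout = BoardLayout.default_grid()
    mis_perturbed = mis_clean = 0
    for i, s in enumerate(_session_seeds(seed, n_sessions)):
        lighting = "shadow" if i % 2 == 0 else "flash"
        phase = PLACING if lighting == "shadow" else TURNING
        sched = synth.SessionSchedule.generate(
            phase=phase, n_discs=30, seed=s, mean_gap=0.3,
            lighting=lighting, n_perturbed=2)
        t_end = sched.disc_events[-1][1] + 0.5
        frame = list(synth.gen_board_frames(sched, layout, fps=1.0, seed=s))[-1][1]
        truth = synth.board_colors_at(sched, t_end)
        obs = observe_board(frame, layout)
        for hole in layout.holes:
            want = truth.get(hole.id, "white")
            if obs[hole.id] != want:
                if hole.id in sched.perturbed_holes:
                    mis_perturbed += 1
                else:
                    mis_clean += 1
    contained = 100.0 * mis_perturbed / max(mis_perturbed + mis_clean, 1)
    return {"misdetections_perturbed": mis_perturbed,
            "misdetections_clean": mis_clean,
            "containment_pct": contained}


def classifier_separation_study(seed: int = 0, n_train: int = 20,
                                n_test: int = 200, sep_sigma: float = 4.0) -> dict:
    """Held-out accuracy on two well-separated 8-D unit-variance Gaussians.

    The class means differ by ``sep_sigma`` standard deviations along every
    coordinate; 20 training samples per class mirrors the 20-frame
    calibration protocol.
    """
    rng = np.random.default_rng(seed)
    d = 8
    mu_hold = np.zeros(d)
    mu_release = np.full(d, sep_sigma)
    def draw(mu, n):
        return rng.normal(size=(n, d)) + mu
    samples = ([(x, "hold") for x in draw(mu_hold, n_train)]
               + [(x, "release") for x in draw(mu_release, n_train)])
    model = train(samples, seed=seed)
    test = ([(x, "hold") for x in draw(mu_hold, n_test)]
            + [(x, "release") for x in draw(mu_release, n_test)])
    hits = sum(model.classes[int(np.argmax(forward(model, x)))] == lab
               for x, lab in test)
    return {"n_test": len(test), "holdout_accuracy_pct": 100.0 * hits / len(test)}


def bayes_oracle_deviation(seed: int = 0, n_points: int = 300) -> float:
    """Max |network posterior - brute-force Gaussian Bayes posterior|."""
    from scipy.stats import multivariate_normal
    rng = np.random.default_rng(seed)
    d = 4
    means = [rng.normal(size=d), rng.normal(size=d) + 1.5]
    covs = []
    for _ in range(2):
        a = rng.normal(size=(d, d))
        covs.append(a @ a.T + np.eye(d))
    model = gaussian_bayes_weights(means, covs)
    worst = 0.0
    for _ in range(n_points):
        x = rng.normal(scale=2, size=d)
        dens = np.array([multivariate_normal.pdf(x, mean=m, cov=c)
                         for m, c in zip(means, covs)])
        worst = max(worst, float(np.max(np.abs(forward(model, x)
                                               - dens / dens.sum()))))
    return worst


def pipeline_recovery_study(seed: int = 0, n_discs: int = 60,
                            mean_gap: float = 1.0, fps: float = 10.0) -> dict:
    """Full-stream recovery errors of one seeded session against its schedule.

    Runs vision, EMG and IMU in memory (same generators and analysis code
    the session pipeline uses) and reports: the worst per-disc duration
    error, total-time error, total-hold-time error, and the worst
    quiet-interval duration error against the noiseless realization.
    """
    layout = BoardLayout.default_grid()
    cal = synth.default_calibration()
    sched = synth.SessionSchedule.generate(n_discs=n_discs, seed=seed,
                                           mean_gap=mean_gap)

    state = run_session_vision(sched, layout, fps=fps)
    durations, total = disc_timings(state.events, phase_start=0.0)
    true_times = [t for _, t in sched.disc_events]
    true_durations = np.diff([0.0] + true_times)
    n_common = min(len(durations), len(true_durations))
    max_disc_err = float(np.max(np.abs(
        np.asarray(durations[:n_common]) - true_durations[:n_common])))
    total_err = abs(total - true_times[-1])

    samples = build_training_samples(
        synth.gen_training_recording("hold", cal, seed=seed + 1), "hold", cal)
    samples += build_training_samples(
        synth.gen_training_recording("release", cal, seed=seed + 2),
        "release", cal)
    model = train(samples, seed=seed)
    rec = synth.gen_emg(sched, cal, seed=seed)
    labels = classify_motion(rec, cal, model)
    hold_err = abs(total_hold_time(labels) - sched.total_hold_time())
    n_transitions = 2 * len(sched.hold_windows)

    noisy = synth.gen_imu(sched, seed=seed)
    clean = synth.gen_imu(sched, seed=seed, gyro_noise=0.0, accel_noise_g=0.0)
    qi_n, qi_c = quiet_intervals(noisy), quiet_intervals(clean)
    if len(qi_n) == len(qi_c):
        max_quiet_err = max(abs((b - a) - (d - c))
                            for (a, b), (c, d) in zip(qi_n, qi_c))
    else:
        max_quiet_err = float("inf")

    return {
        "n_events_detected": len(state.events),
        "n_events_scheduled": len(sched.disc_events),
        "max_disc_duration_error_s": max_disc_err,
        "total_time_error_s": float(total_err),
        "hold_time_error_s": float(hold_err),
        "n_hold_transitions": n_transitions,
        "emg_dt_s": 1.0 / rec.fs,
        "max_quiet_interval_error_s": float(max_quiet_err),
        "imu_sample_s": 1.0 / noisy.fs,
        "frame_interval_s": 1.0 / fps,
    }
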