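"""Session orchestration: simulate a session directory, analyze it, report.

A session directory is the on-disk exchange format between acquisition and
analysis:

    frames/            PNG frames + manifest.csv (t, filename)
    emg.csv            raw session EMG (t, ch1..ch8, mV)
    train_hold.csv     8-s calibration-gesture recordings used to train the
    train_release.csv  hold/release classifier for this session
    imu.csv            IMU trace (t, gx, gy, gz in deg/s, ax, ay, az in g)
    layout.json        hole-centre layout
    schedule.json      ground truth (synthetic sessions only)
    config.json        calibration, gates, thresholds, phase, seed

``analyze_session`` runs vision -> disc timings, EMG -> hold time,
IMU -> kinematics/inactivity, rules -> findings, and returns one report
dict (missing streams yield explicit nulls and a 'complete': False flag).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import llgmn, synth
from .emg import CalibrationProfile, EmgRecording, build_training_samples
from .imu import ImuTrace, inactivity_time, summarize_phase
from .rules import Thresholds, default_rulebase, default_thresholds, evaluate_rules
from .vision import (
    PLACING,
    BoardLayout,
    BoardState,
    advance_state,
    disc_timings,
    observe_board,
)

__all__ = ["simulate_session", "analyze_session", "report_text", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1
log = logging.getLogger("mmdtkit")


def simulate_session(
    out_dir,
    phase: str = PLACING,
    seed: int = 0,
    n_discs: int = 60,
    lighting: str = "normal",
    mean_gap: float = 1.0,
    fps: float = synth.DEFAULT_FPS,
    write_frames: bool = True,
) -> Path:
    """Generate a complete synthetic session directory. Deterministic per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = BoardLayout.default_grid()
    cal = synth.default_calibration()
    schedule = synth.SessionSchedule.generate(
        phase=phase, n_discs=n_discs, seed=seed,
        mean_gap=mean_gap, lighting=lighting)

    layout.to_json(out / "layout.json")
    schedule.to_json(out / "schedule.json")
    synth.gen_emg(schedule, cal, seed=seed).to_csv(out / "emg.csv")
    synth.gen_imu(schedule, seed=seed).to_csv(out / "imu.csv")
    synth.gen_training_recording("hold", cal, seed=seed + 1).to_csv(
        out / "train_hold.csv")
    synth.gen_training_recording("release", cal, seed=seed + 2).to_csv(
        out / "train_release.csv")

    if write_frames:
        frame_dir = out / "frames"
        frame_dir.mkdir(exist_ok=True)
        rows = []
        for k, (t, frame) in enumerate(
                synth.gen_board_frames(schedule, layout, fps=fps, seed=seed)):
            name = f"frame_{k:05d}_{int(round(t * 1000))}.png"
            Image.fromarray(frame).save(frame_dir / name)
            rows.append({"t": t, "filename": name})
        pd.DataFrame(rows).to_csv(frame_dir / "manifest.csv", index=False)

    config = {
        "schema_version": SCHEMA_VERSION,
        "phase": phase,
        "seed": seed,
        "fps": fps,
        "fs_emg": 200.0,
        "fs_imu": 50.0,
        "mcl_gate": llgmn.DEFAULT_MCL_GATE,
        "debounce": 2,
        "calibration": {"rest": cal.rest.tolist(), "max": cal.max.tolist()},
    }
    with open(out / "config.json", "w") as fh:
        json.dump(config, fh, indent=1)
    return out


def _iter_session_frames(session: Path, fps_hint: float):
    frame_dir = session / "frames"
    manifest = frame_dir / "manifest.csv"
    if manifest.exists():
        df = pd.read_csv(manifest)
        entries = [(float(r.t), frame_dir / r.filename) for r in df.itertuples()]
    else:
        entries = []
        for p in sorted(frame_dir.glob("frame_*.png")):
            t_ms = int(p.stem.split("_")[-1])
            entries.append((t_ms / 1000.0, p))
    for t, path in entries:
        try:
            yield t, np.asarray(Image.open(path).convert("RGB"))
        except Exception as exc:  # corrupt frame: warn and continue
            log.warning("skipping unreadable frame %s: %s", path.name, exc)


def _vision_block(session: Path, config: dict) -> dict | None:
    if not (session / "frames").exists() or not (session / "layout.json").exists():
        return None
    layout = BoardLayout.from_json(session / "layout.json")
    state = BoardState(layout, phase=config.get("phase", PLACING),
                       debounce=int(config.get("debounce", 2)))
    for t, frame in _iter_session_frames(session, config.get("fps", 10.0)):
        advance_state(state, observe_board(frame, layout), t)
    durations, total = disc_timings(state.events, phase_start=0.0)
    return {
        "phase": state.phase,
        "n_events": len(state.events),
        "events": [{"t": e.timestamp, "hole_id": e.hole_id, "kind": e.kind,
                    "phase": e.phase} for e in state.events],
        "disc_durations_s": [round(float(d), 4) for d in durations],
        "total_phase_time_s": round(float(total), 4),
        "placed": state.placed,
        "empty": state.empty,
    }


def _emg_block(session: Path, config: dict) -> dict | None:
    if not (session / "emg.csv").exists():
        return None
    needed = [session / "train_hold.csv", session / "train_release.csv"]
    if not all(p.exists() for p in needed):
        log.warning("EMG present but training recordings missing; skipping EMG")
        return None
    cal = CalibrationProfile(rest=np.array(config["calibration"]["rest"]),
                             max=np.array(config["calibration"]["max"]))
    fs = config.get("fs_emg")
    rec = EmgRecording.from_csv(session / "emg.csv", expected_fs=fs)
    samples = []
    for path, label in ((needed[0], llgmn.HOLD), (needed[1], llgmn.RELEASE)):
        samples += build_training_samples(
            EmgRecording.from_csv(path, expected_fs=fs), label, cal)
    model = llgmn.train(samples, seed=int(config.get("seed", 0)))
    labels = llgmn.classify_motion(
        rec, cal, model, mcl_gate=config.get("mcl_gate", llgmn.DEFAULT_MCL_GATE))
    return {
        "total_hold_time_s": round(llgmn.total_hold_time(labels), 4),
        "n_samples": len(labels),
        "dt": labels.dt,
    }


def _imu_block(session: Path, config: dict) -> dict | None:
    if not (session / "imu.csv").exists():
        return None
    trace = ImuTrace.from_csv(session / "imu.csv", fs=config.get("fs_imu"))
    summary = summarize_phase(trace)
    return {
        "summary": summary.as_dict(),
        "inactivity_time_s": round(inactivity_time(trace), 4),
    }


def build_rule_context(report: dict) -> dict:
    """Map an analysis report onto the rule-engine variable vocabulary.

    Per-disc variables d{i}_{p|t} are numbered by event order (disc 1 = first
    disc handled). Variables whose stream is missing are omitted so the
    corresponding rules never fire.
    """
    ctx: dict = {}
    phase = report.get("phase", PLACING)
    suffix = "p" if phase == PLACING else "t"
    vision = report.get("vision")
    if vision:
        ctx[f"tt_{suffix}"] = vision["total_phase_time_s"]
        for i, d in enumerate(vision["disc_durations_s"], start=1):
            ctx[f"d{i}_{suffix}"] = d
    imu_block = report.get("imu")
    if imu_block:
        axes = {"r": "roll", "p": "pitch", "y": "yaw"}
        for short, name in axes.items():
            ctx[f"rot_{short}_{suffix}"] = imu_block["summary"]["gyro_max_dps"][name]
        for ax in "xyz":
            ctx[f"acc_{ax}_{suffix}"] = imu_block["summary"]["accel_peak_mean_ms2"][ax]
        ctx[f"th_{suffix}"] = imu_block["inactivity_time_s"]
    return ctx


def analyze_session(
    session_dir,
    thresholds: Thresholds | None = None,
    rulebase=None,
) -> dict:
    """Run the full analysis pipeline over a session directory.

    Returns the report dict; ``report['complete']`` is False when any stream
    was missing (its block is null).
    """
    session = Path(session_dir)
    with open(session / "config.json") as fh:
        config = json.load(fh)
    report: dict = {"schema_version": SCHEMA_VERSION,
                    "session": str(session),
                    "phase": config.get("phase", PLACING)}
    report["vision"] = _vision_block(session, config)
    report["emg"] = _emg_block(session, config)
    report["imu"] = _imu_block(session, config)
    report["complete"] = all(
        report[k] is not None for k in ("vision", "emg", "imu"))

    thresholds = thresholds or default_thresholds()
    rulebase = rulebase or default_rulebase()
    ctx = build_rule_context(report)
    findings = evaluate_rules(ctx, thresholds, rulebase)
    report["rule_context"] = ctx
    report["findings"] = [{"rule_id": f.rule_id, "text": f.text} for f in findings]
    return report


def report_text(report: dict) -> str:
    """Plain-text session summary for the clinician-facing printout."""
    lines = [f"MMDT session report (phase: {report.get('phase')})"]
    vision = report.get("vision")
    if vision:
        lines.append(f"  discs detected : {vision['n_events']}"
                     f" (placed {vision['placed']}, empty {vision['empty']})")
        lines.append(f"  total phase time: {vision['total_phase_time_s']:.2f} s")
    else:
        lines.append("  vision stream missing")
    emg = report.get("emg")
    if emg:
        lines.append(f"  total hold time : {emg['total_hold_time_s']:.2f} s")
    else:
        lines.append("  EMG stream missing")
    imu_block = report.get("imu")
    if imu_block:
        gm = imu_block["summary"]["gyro_max_dps"]
        pm = imu_block["summary"]["accel_peak_mean_ms2"]
        lines.append("  max |angular velocity| (deg/s): "
                     + ", ".join(f"{k} {v:.1f}" for k, v in gm.items()))
        lines.append("  mean accel peaks (m/s^2): "
                     + ", ".join(f"{k} {v:.2f}" for k, v in pm.items()))
        lines.append(f"  inactivity time : {imu_block['inactivity_time_s']:.2f} s")
    else:
        lines.append("  IMU stream missing")
    lines.append("  findings:")
    for f in report.get("findings", []):
        lines.append(f"    - {f['text']}")
    if not report.get("findings"):
        lines.append("    (none)")
    return "\n".join(lines)
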