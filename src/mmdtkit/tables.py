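"""Packaged reference tables from the 20-participant healthy-cohort study.

table1: 25 hold-release sets — total time, classifier hold time, contact-rig
hold time, printed percent difference.
table4: per-participant total/hold times and hold percentage, both phases.
table5: per-participant peak angular velocities (deg/s), both phases.
table6: per-participant mean peak linear accelerations (m/s^2), both phases.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("table1", "table4", "table5", "table6")

_EXPECTED_SHAPE = {
    "table1": (25, 5),
    "table4": (20, 7),
    "table5": (20, 7),
    "table6": (20, 7),
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load one packaged reference table by name ('table1', 'table4', ...)."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    ref = resources.files("mmdtkit") / "fixtures" / f"{name}.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    if df.shape != _EXPECTED_SHAPE[name]:
        raise RuntimeError(f"fixture {name} has shape {df.shape}, "
                           f"expected {_EXPECTED_SHAPE[name]}")
    return df
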