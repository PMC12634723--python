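"""Timing-agreement metrics and aggregate statistics.

Two percent-difference conventions coexist in the assessment workflow and
are kept as distinct operations:

* ``time_error`` — E_T = |T_s - T_m| / T_m * 100, relative to the manual
  stopwatch reference (used for camera-vs-stopwatch disc timings);
* ``holdtime_difference`` — 100 * |ht_c - ht_t| / ht_c, relative to the
  CLASSIFIER hold time (the convention under which the published
  hold-time comparison column reproduces exactly).

All report-facing rounding is half-away-from-zero at the printed precision;
several aggregate means land exactly on .x5, where banker's rounding would
disagree with the published footers. Exact decimal arithmetic (fractions)
is used on the rounding path so such ties are not at the mercy of binary
floating point.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

__all__ = [
    "time_error",
    "holdtime_difference",
    "holdtime_accuracy",
    "accuracy_summary",
    "column_stats",
    "round_half_away",
]


def _as_fraction(x) -> Fraction:
    # repr() of a float is its shortest exact decimal form, so this recovers
    # the intended decimal value of table entries parsed as floats.
    return x if isinstance(x, Fraction) else Fraction(repr(float(x)))


def _round_fraction(q: Fraction, decimals: int) -> Fraction:
    scale = Fraction(10) ** decimals
    scaled = q * scale
    n, d = abs(scaled.numerator), scaled.denominator
    rounded = (2 * n + d) // (2 * d)  # floor(|x| + 1/2): ties away from zero
    if scaled < 0:
        rounded = -rounded
    return Fraction(rounded, 1) / scale


def round_half_away(x, decimals: int = 1) -> float:
    """Round with ties away from zero, exact on decimal-valued inputs."""
    return float(_round_fraction(_as_fraction(x), decimals))


def time_error(t_system: float, t_manual: float) -> float:
    """Percent timing error relative to the manual reference measurement."""
    if t_manual <= 0:
        raise ValueError("manual reference time must be positive")
    return abs(t_system - t_manual) / t_manual * 100.0


def holdtime_difference(ht_classifier: float, ht_testrig: float,
                        decimals: int | None = 1) -> float:
    """Percent hold-time disagreement, classifier time as denominator.

    Rounded to one decimal for reporting by default; ``decimals=None``
    returns the unrounded value.
    """
    if ht_classifier <= 0:
        raise ValueError("classifier hold time must be positive")
    diff = 100 * abs(_as_fraction(ht_classifier) - _as_fraction(ht_testrig)) \
        / _as_fraction(ht_classifier)
    if decimals is None:
        return float(diff)
    return float(_round_fraction(diff, decimals))


def holdtime_accuracy(ht_classifier: float, ht_testrig: float) -> float:
    """Per-set agreement accuracy: 100 minus the rounded percent difference."""
    return 100.0 - holdtime_difference(ht_classifier, ht_testrig)


def accuracy_summary(comparisons) -> dict:
    """Mean/min/max hold-time agreement accuracy over (classifier, rig) pairs.

    Per-set accuracies are computed at one-decimal precision and the mean is
    again rounded half-away-from-zero to one decimal.
    """
    comparisons = list(comparisons)
    if not comparisons:
        raise ValueError("no comparisons")
    accs = [Fraction(100) - _round_fraction(
        100 * abs(_as_fraction(c) - _as_fraction(t)) / _as_fraction(c), 1)
        for c, t in comparisons]
    mean = sum(accs, Fraction(0)) / len(accs)
    return {
        "mean": float(_round_fraction(mean, 1)),
        "min": float(min(accs)),
        "max": float(max(accs)),
    }


def column_stats(values, decimals: int | None = None) -> dict:
    """Mean, max, min and sample (n-1) standard deviation of a column.

    With ``decimals`` set, mean/max/min are computed in exact decimal
    arithmetic and rounded half-away-from-zero; the standard deviation
    (irrational in general) is rounded from its float value.
    """
    vals = list(values)
    if len(vals) < 2:
        raise ValueError("need at least two values for a sample std")
    arr = np.asarray(vals, dtype=float)
    if decimals is None:
        return {
            "mean": float(arr.mean()),
            "max": float(arr.max()),
            "min": float(arr.min()),
            "std": float(arr.std(ddof=1)),
        }
    fracs = [_as_fraction(v) for v in vals]
    mean = sum(fracs, Fraction(0)) / len(fracs)
    var = sum((f - mean) ** 2 for f in fracs) / (len(fracs) - 1)
    return {
        "mean": float(_round_fraction(mean, decimals)),
        "max": float(_round_fraction(max(fracs), decimals)),
        "min": float(_round_fraction(min(fracs), decimals)),
        "std": round_half_away(float(np.sqrt(float(var))), decimals),
    }
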