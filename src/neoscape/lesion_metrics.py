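"""CT-derived lesion volume and growth metrics.

Lesion volumes are estimated from two perpendicular axis measurements with
the ellipsoid formula, the third axis taken as the mean of the two:

    V = (4/3) * pi * a * b * c,   c = (a + b) / 2

Growth between consecutive scans is the ratio of the later to the earlier
volume; ratios inside a configurable stability band (default [0.9, 1.1])
are labelled stable, below it regressing, above it progressing.  The band
is a display convention only.  Axis units (cm by default) are carried
through unchanged — volumes come out in the cube of the input unit.
"""

from __future__ import annotations

import math

import pandas as pd

STABLE_BAND = (0.9, 1.1)


class LesionError(ValueError):
    pass


def ellipsoid_volume(a: float, b: float) -> float:
    """Ellipsoid volume from two axes; the third axis is their mean."""
    if a <= 0 or b <= 0:
        raise LesionError("axis lengths must be positive")
    c = (a + b) / 2.0
    return (4.0 / 3.0) * math.pi * a * b * c


def growth_ratio(
    volume_later: float,
    volume_earlier: float,
    stable_band: tuple[float, float] = STABLE_BAND,
) -> tuple[float, str]:
    """Later/earlier volume ratio with a regressing/stable/progressing label."""
    if volume_earlier <= 0:
        raise LesionError("earlier volume must be positive")
    if volume_later < 0:
        raise LesionError("later volume must be nonnegative")
    ratio = volume_later / volume_earlier
    lo, hi = stable_band
    if ratio < lo:
        label = "regressing"
    elif ratio > hi:
        label = "progressing"
    else:
        label = "stable"
    return ratio, label


def volumes_from_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Add derived mean axis and volume columns to a (lesion, scan, a, b)
    measurement table."""
    for col in ("lesion", "scan", "a", "b"):
        if col not in measurements.columns:
            raise LesionError(f"measurement table missing column {col!r}")
    out = measurements.copy()
    out["c"] = (out["a"] + out["b"]) / 2.0
    out["volume"] = [ellipsoid_volume(a, b) for a, b in zip(out["a"], out["b"])]
    return out
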