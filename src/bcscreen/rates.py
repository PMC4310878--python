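"""Age-specific annual rate schedules.

The cohort model consumes four age-indexed inputs — breast-cancer incidence
(h1), other-cause mortality (mu), screening specificity (sp) and screening
participation (e) — each defined as an annual probability for every integer
age 0..100.  This module provides the schedule container, conversion from
5-year age bands (the form in which registry and vital-statistics data are
usually published), delimited-table I/O, and a deterministic synthesizer for
registry-like curves used as fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

AGE_MIN = 0
AGE_MAX = 100
N_AGES = AGE_MAX - AGE_MIN + 1

__all__ = [
    "AgeRateSchedule",
    "BandedRates",
    "CurveProfile",
    "RateRangeError",
    "RateStructureError",
    "expand_banded",
    "read_rate_table",
    "write_rate_table",
    "synth_schedule",
]


class RateRangeError(ValueError):
    """A rate fell outside the admissible probability range [0, 1]."""


class RateStructureError(ValueError):
    """Structural defect in a rate input (gaps, overlaps, missing ages)."""


@dataclass(frozen=True)
class AgeRateSchedule:
    """Annual event probability per integer age, ages 0..100 inclusive.

    Values are per-person annual probabilities (dimensionless), not
    instantaneous hazards: the model runs in 12-month cycles and applies
    these numbers directly as per-cycle transition probabilities.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (N_AGES,):
            raise RateStructureError(
                f"schedule must have {N_AGES} values for ages "
                f"{AGE_MIN}-{AGE_MAX}, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise RateRangeError("schedule contains non-finite values")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise RateRangeError(
                f"schedule values must lie in [0, 1]; "
                f"range is [{arr.min()}, {arr.max()}]"
            )
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    def __getitem__(self, age: int) -> float:
        if not AGE_MIN <= age <= AGE_MAX:
            raise KeyError(f"age {age} outside schedule range {AGE_MIN}-{AGE_MAX}")
        return float(self.values[age - AGE_MIN])

    @classmethod
    def constant(cls, value: float) -> "AgeRateSchedule":
        return cls(np.full(N_AGES, float(value)))

    @classmethod
    def zeros(cls) -> "AgeRateSchedule":
        return cls(np.zeros(N_AGES))

    def to_frame(self, column: str = "rate") -> pd.DataFrame:
        return pd.DataFrame({"age": np.arange(AGE_MIN, AGE_MAX + 1), column: self.values})

    def __eq__(self, other: object) -> bool:  # value semantics
        if not isinstance(other, AgeRateSchedule):
            return NotImplemented
        return bool(np.array_equal(self.values, other.values))


@dataclass(frozen=True)
class BandedRates:
    """Ordered 5-year age bands, each carrying one annual probability.

    Bands are (age_lo, age_hi, value) with age_hi inclusive; they must be
    contiguous, non-overlapping and ascending.  A final open-ended band may
    extend past 100 and is clamped there on expansion.
    """

    bands: tuple[tuple[int, int, float], ...]

    def __init__(self, bands: Iterable[Sequence]) -> None:
        norm = tuple((int(lo), int(hi), float(v)) for lo, hi, v in bands)
        if not norm:
            raise RateStructureError("no bands supplied")
        for lo, hi, v in norm:
            if hi < lo:
                raise RateStructureError(f"band ({lo}, {hi}) has hi < lo")
            if not 0.0 <= v <= 1.0:
                raise RateRangeError(f"band ({lo}, {hi}) value {v} outside [0, 1]")
        for (lo0, hi0, _), (lo1, _, _) in zip(norm, norm[1:]):
            if lo1 != hi0 + 1:
                kind = "overlap" if lo1 <= hi0 else "gap"
                raise RateStructureError(
                    f"{kind} between bands ending {hi0} and starting {lo1}"
                )
        object.__setattr__(self, "bands", norm)


@dataclass(frozen=True)
class CurveProfile:
    """Parameterization of a synthetic registry-like rate curve.

    shape: one of {"peaked", "increasing", "gompertz", "constant"};
    anchors: (age, value) points the curve passes through exactly.
    """

    shape: str
    anchors: tuple[tuple[float, float], ...]
    label: str = ""

    SHAPES = ("peaked", "increasing", "gompertz", "constant")

    def __init__(self, shape: str, anchors: Iterable[Sequence], label: str = "") -> None:
        if shape not in self.SHAPES:
            raise ValueError(f"unknown curve shape {shape!r}; expected one of {self.SHAPES}")
        norm = tuple((float(a), float(v)) for a, v in anchors)
        if not norm:
            raise ValueError("profile needs at least one anchor")
        for a, v in norm:
            if not 0.0 <= v <= 1.0:
                raise RateRangeError(f"anchor value {v} at age {a} outside [0, 1]")
        if list(a for a, _ in norm) != sorted(set(a for a, _ in norm)):
            raise ValueError("anchor ages must be strictly increasing")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "anchors", norm)
        object.__setattr__(self, "label", label)


def profile_from_config(path) -> CurveProfile:
    """Load a CurveProfile from a YAML mapping with keys shape, anchors, label."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return CurveProfile(doc["shape"], doc["anchors"], doc.get("label", ""))


def expand_banded(banded: BandedRates) -> AgeRateSchedule:
    """Convert 5-year banded rates to a per-age schedule.

    The conversion is piecewise linear between band midpoints, clamped
    (held constant) outside the first/last midpoint, followed by a
    multiplicative per-band rescaling so that the mean of the per-age
    values inside each band equals the band value exactly (area
    preservation) while staying non-negative.  Ages not covered by any
    band are set to 0.
    """
    bands = banded.bands
    lo_all = bands[0][0]
    hi_all = min(bands[-1][1], AGE_MAX)
    if lo_all < AGE_MIN:
        raise RateStructureError(f"bands start before age {AGE_MIN}")

    mids = np.array([(lo + min(hi, AGE_MAX)) / 2.0 for lo, hi, _ in bands])
    vals = np.array([v for _, _, v in bands])

    ages = np.arange(lo_all, hi_all + 1, dtype=float)
    if len(bands) == 1:
        smooth = np.full_like(ages, vals[0])
    else:
        smooth = np.interp(ages, mids, vals)  # np.interp clamps at the ends

    out = np.zeros(N_AGES)
    for lo, hi, v in bands:
        hi = min(hi, AGE_MAX)
        seg = smooth[lo - lo_all : hi - lo_all + 1]
        mean = seg.mean()
        if mean > 0.0:
            out[lo : hi + 1] = seg * (v / mean)
        else:  # all-neighbouring values zero implies v == 0 by interpolation
            out[lo : hi + 1] = v

    if out.max() > 1.0:
        raise RateRangeError(
            "area-preserving rescaling pushed per-age values above 1; "
            "band values are too extreme for a smooth expansion"
        )
    return AgeRateSchedule(out)


def read_rate_table(path, column: str) -> AgeRateSchedule:
    """Read one schedule column from a delimited table.

    The file must be comma-separated with a header row, an ``age`` column
    and the named value column, one row per integer age 0..100.  Missing
    ages are an error, never silently filled.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "age" not in df.columns:
        raise RateStructureError(f"{path}: no 'age' column")
    if column not in df.columns:
        raise RateStructureError(f"{path}: no column {column!r} (have {list(df.columns)})")
    try:
        ages = df["age"].astype(int).to_numpy()
        vals = df[column].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise RateStructureError(f"{path}: non-numeric cell in 'age' or {column!r}: {exc}")
    if np.any((ages < AGE_MIN) | (ages > AGE_MAX)):
        bad = ages[(ages < AGE_MIN) | (ages > AGE_MAX)]
        raise RateStructureError(f"{path}: ages outside {AGE_MIN}-{AGE_MAX}: {bad.tolist()}")
    missing = sorted(set(range(AGE_MIN, AGE_MAX + 1)) - set(ages.tolist()))
    if missing:
        raise RateStructureError(f"{path}: missing ages {missing}")
    if len(ages) != len(set(ages.tolist())):
        raise RateStructureError(f"{path}: duplicate ages")
    order = np.argsort(ages)
    return AgeRateSchedule(vals[order])


def write_rate_table(schedule: AgeRateSchedule, path, column: str = "rate") -> None:
    """Write a schedule as ``age,<column>`` CSV with round-trip float precision."""
    df = schedule.to_frame(column)
    df.to_csv(path, index=False)


def _eval_pchip(anchors: Sequence[tuple[float, float]], ages: np.ndarray) -> np.ndarray:
    xs = np.array([a for a, _ in anchors])
    ys = np.array([v for _, v in anchors])
    if len(xs) == 1:
        return np.full_like(ages, ys[0], dtype=float)
    interp = PchipInterpolator(xs, ys, extrapolate=False)
    out = interp(np.clip(ages, xs[0], xs[-1]))
    return np.asarray(out, dtype=float)


def synth_schedule(profile: CurveProfile) -> AgeRateSchedule:
    """Synthesize a deterministic per-age schedule from a curve profile.

    All shapes pass exactly through the anchors and are clamped to the
    first/last anchor value outside the anchor range:

    - ``constant``: flat at the single anchor value.
    - ``increasing``: shape-preserving monotone interpolation (PCHIP);
      anchors must be non-decreasing, so the curve is non-decreasing and
      never exceeds the maximum anchor.
    - ``peaked``: PCHIP through a unimodal anchor set (rises to the peak,
      then falls); no overshoot beyond the peak anchor.
    - ``gompertz``: log-linear (exponential) interpolation between strictly
      positive anchors — the classical adult-mortality shape.
    """
    ages = np.arange(AGE_MIN, AGE_MAX + 1, dtype=float)
    anchors = profile.anchors
    ys = np.array([v for _, v in anchors])

    if profile.shape == "constant":
        if len(set(ys.tolist())) != 1:
            raise ValueError("constant profile anchors must share one value")
        out = np.full(N_AGES, ys[0])
    elif profile.shape == "increasing":
        if np.any(np.diff(ys) < 0):
            raise ValueError("increasing profile needs non-decreasing anchor values")
        out = _eval_pchip(anchors, ages)
    elif profile.shape == "peaked":
        k = int(np.argmax(ys))
        if np.any(np.diff(ys[: k + 1]) < 0) or np.any(np.diff(ys[k:]) > 0):
            raise ValueError("peaked profile anchors must rise to a single peak then fall")
        out = _eval_pchip(anchors, ages)
    elif profile.shape == "gompertz":
        if np.any(ys <= 0):
            raise ValueError("gompertz profile anchors must be strictly positive")
        log_anchors = [(a, np.log(v)) for a, v in anchors]
        xs = np.array([a for a, _ in log_anchors])
        lys = np.array([v for _, v in log_anchors])
        if len(xs) == 1:
            out = np.full(N_AGES, ys[0])
        else:
            out = np.exp(np.interp(np.clip(ages, xs[0], xs[-1]), xs, lys))
    else:  # pragma: no cover - guarded in CurveProfile
        raise ValueError(profile.shape)

    return AgeRateSchedule(out)
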