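"""Screening strategies, schedules, and the per-round screening operator.

A strategy is (start age, stop age, interval, participation schedule).
Rounds are anchored at the start age with modulo stepping, so a biennial
40-69 programme holds 15 rounds at ages 40, 42, ..., 68.

At a round, a fraction e (participation) of the unscreened-eligible women
(healthy plus undetected cancer; women already on treatment are never mass
screened) is screened.  Healthy participants test falsely positive with
probability 1 - sp(age) — a transient state, tallied as an event, after
which they return to healthy.  Undetected cancers of any stage are found
with sensitivity se and move to the detected state of the same stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .natural_history import CohortState, EventTally, ModelError, _check_prob
from .rates import AgeRateSchedule

__all__ = [
    "ScreeningStrategy",
    "ScreeningPerformance",
    "screening_ages",
    "apply_screening",
    "detection_rate",
]

# age-range grids used for policy comparison runs
GRID_START_AGES = (40, 45, 50, 55, 60)
GRID_STOP_AGES = (69, 74, 79, 84)


@dataclass(frozen=True)
class ScreeningStrategy:
    """Mass-screening policy: ages scmin..scmax, every `interval` years."""

    scmin: int
    scmax: int
    interval: int = 2
    participation: AgeRateSchedule = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.scmax < self.scmin:
            raise ModelError(f"scmax {self.scmax} < scmin {self.scmin}")
        if self.interval < 1:
            raise ModelError(f"interval must be >= 1, got {self.interval}")
        if self.participation is None:
            object.__setattr__(self, "participation", AgeRateSchedule.constant(1.0))

    @classmethod
    def make(cls, scmin: int, scmax: int, interval: int = 2,
             participation: float | AgeRateSchedule = 1.0) -> "ScreeningStrategy":
        if not isinstance(participation, AgeRateSchedule):
            participation = AgeRateSchedule.constant(float(participation))
        return cls(int(scmin), int(scmax), int(interval), participation)

    @property
    def label(self) -> str:
        kind = {1: "annual", 2: "biennial"}.get(self.interval, f"every-{self.interval}y")
        return f"{self.scmin}-{self.scmax} {kind}"


@dataclass(frozen=True)
class ScreeningPerformance:
    """Test characteristics: sensitivity se, per-age specificity sp.

    ``sd_reference`` is the published screen-detection rate used only for
    validation and for anchoring the estimation scale constraint — never as
    a model input (the realized detection rate is determined by occupancy
    and se).
    """

    se: float
    sp: AgeRateSchedule
    sd_reference: float | None = None

    def __post_init__(self) -> None:
        _check_prob("se", self.se)
        if self.sd_reference is not None:
            _check_prob("sd_reference", self.sd_reference)


def screening_ages(strategy: ScreeningStrategy) -> tuple[int, ...]:
    """Integer ages hosting a screening round under the strategy."""
    return tuple(range(strategy.scmin, strategy.scmax + 1, strategy.interval))


def apply_screening(state: CohortState, perf: ScreeningPerformance,
                    e_at_age: float, age: int) -> tuple[CohortState, EventTally]:
    """One screening round: detections from u2-u5, false positives from u1."""
    e = _check_prob("e", e_at_age)
    sp = perf.sp[age]
    screens = e * (state.u1 + state.u2 + state.u3 + state.u4 + state.u5)
    fp = e * state.u1 * (1.0 - sp)
    det = tuple(e * u * perf.se for u in state.undetected)
    out = replace(
        state,
        u2=state.u2 - det[0], u3=state.u3 - det[1],
        u4=state.u4 - det[2], u5=state.u5 - det[3],
        w2=state.w2 + det[0], w3=state.w3 + det[1],
        w4=state.w4 + det[2], w5=state.w5 + det[3],
        fp_cum=state.fp_cum + fp,
    )
    tally = EventTally(screen_detections=det, screens_performed=screens,
                       false_positives=fp)
    return out, tally


def detection_rate(total_detections: float, total_screens: float) -> float:
    """Realized screen-detection rate: detections per screening performed."""
    if total_screens <= 0:
        raise ModelError("detection rate undefined: no screens performed")
    return total_detections / total_screens
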