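"""Disease model: states, parameters, and per-cycle transition operators.

The cohort is tracked as expected (fractional) person counts in ten living
states — healthy (u1), undetected breast cancer stages 1-4 (u2-u5), detected
/ on-treatment stages 1-4 (w2-w5) plus the transient false-positive state
(tallied as events, not occupancy) — and nine cumulative death tallies:
other-cause deaths (du1), breast-cancer deaths while undetected by stage
(du2-du5) and while detected by stage (dw1-dw4).

Each 12-month cycle applies, in this fixed order: screening (scheduled ages
only), clinical detection, stage progression, incidence, mortality.  The
order is a documented modelling choice: detection acts on start-of-year
occupancies, newly incident cases cannot be detected or die of breast cancer
in their onset year, and newly detected cases receive the treated mortality
rate from the next cycle onward.

Detected women never change stage and never revert to undetected; their only
outflow is death.  Competing risks within a cycle are combined as
independent probabilities: in a diseased state the total death probability
is 1 - (1-mu)(1-delta), with mu deaths tallied as other-cause and the
remainder as breast-cancer deaths.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

from .rates import AgeRateSchedule

__all__ = [
    "CohortState",
    "EventTally",
    "NaturalHistoryParams",
    "ModelError",
    "apply_incidence",
    "apply_progression",
    "apply_clinical_detection",
    "apply_mortality",
]

CONSERVATION_RTOL = 1e-9


class ModelError(ValueError):
    """Invalid parameter or state for the disease model."""


def _check_prob(name: str, p: float) -> float:
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ModelError(f"{name}={p} outside [0, 1]")
    return p


@dataclass(frozen=True)
class CohortState:
    """Occupancy of the living states and cumulative death tallies at one age.

    Counts are expected values and may be fractional; the chain is
    deterministic.  ``fp_cum`` counts false-positive *events* (the w1 state
    is transient: participants return to healthy within the cycle).
    """

    u1: float = 0.0
    u2: float = 0.0
    u3: float = 0.0
    u4: float = 0.0
    u5: float = 0.0
    w2: float = 0.0
    w3: float = 0.0
    w4: float = 0.0
    w5: float = 0.0
    fp_cum: float = 0.0
    du1: float = 0.0
    du2: float = 0.0
    du3: float = 0.0
    du4: float = 0.0
    du5: float = 0.0
    dw1: float = 0.0
    dw2: float = 0.0
    dw3: float = 0.0
    dw4: float = 0.0
    age: int = 0

    @classmethod
    def initial(cls, n0: float = 100_000.0) -> "CohortState":
        """All-healthy cohort of size n0 at age 0."""
        return cls(u1=float(n0))

    @property
    def undetected(self) -> tuple[float, float, float, float]:
        return (self.u2, self.u3, self.u4, self.u5)

    @property
    def detected(self) -> tuple[float, float, float, float]:
        return (self.w2, self.w3, self.w4, self.w5)

    @property
    def total_living(self) -> float:
        return self.u1 + self.u2 + self.u3 + self.u4 + self.u5 \
            + self.w2 + self.w3 + self.w4 + self.w5

    @property
    def total_dead(self) -> float:
        return self.du1 + self.du2 + self.du3 + self.du4 + self.du5 \
            + self.dw1 + self.dw2 + self.dw3 + self.dw4

    @property
    def total(self) -> float:
        return self.total_living + self.total_dead

    def validate(self, n0: float | None = None) -> None:
        """Raise ModelError on negative occupancy or broken conservation."""
        for f in dataclasses.fields(self):
            if f.name == "age":
                continue
            v = getattr(self, f.name)
            if v < 0.0:
                raise ModelError(f"negative count {f.name}={v} at age {self.age}")
        if n0 is not None:
            if abs(self.total - n0) > CONSERVATION_RTOL * max(n0, 1.0):
                raise ModelError(
                    f"conservation violated at age {self.age}: "
                    f"total {self.total} vs initial {n0}"
                )


@dataclass(frozen=True)
class EventTally:
    """Per-cycle event counts (one year of bookkeeping).

    Stage-indexed tuples are ordered stage 1..4.  ``progressions[s]`` counts
    moves from stage s+1 to s+2 for s=0..2 (three possible transitions).
    """

    incident_cases: float = 0.0
    progressions: tuple[float, float, float] = (0.0, 0.0, 0.0)
    clinical_detections: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    screen_detections: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    screens_performed: float = 0.0
    false_positives: float = 0.0
    deaths_other: float = 0.0
    deaths_bc_undetected: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    deaths_bc_detected: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            vals = v if isinstance(v, tuple) else (v,)
            if any(x < -1e-12 for x in vals):
                raise ModelError(f"negative tally {f.name}={v}")
        if sum(self.screen_detections) > self.screens_performed + 1e-9:
            raise ModelError("screen detections exceed screens performed")

    @property
    def deaths_bc_total(self) -> float:
        return sum(self.deaths_bc_undetected) + sum(self.deaths_bc_detected)

    def __add__(self, other: "EventTally") -> "EventTally":
        def add(a, b):
            if isinstance(a, tuple):
                return tuple(x + y for x, y in zip(a, b))
            return a + b

        return EventTally(**{
            f.name: add(getattr(self, f.name), getattr(other, f.name))
            for f in dataclasses.fields(self)
        })


@dataclass(frozen=True)
class NaturalHistoryParams:
    """Scalar transition rates plus the two age-specific schedules.

    h2-h4: annual stage-progression probabilities (1→2, 2→3, 3→4), age
    independent.  f2-f5: annual probabilities that an undetected case of the
    given stage presents clinically (outpatient care).  delta1-delta4:
    annual breast-cancer mortality of *detected* (treated) stages; the
    undetected (untreated) mortality is delta' = m * delta with the
    multiplier m in [1.0, 3.0] (default 1.5).  h1 and mu are per-age
    schedules for incidence and other-cause mortality.
    """

    h1: AgeRateSchedule
    mu: AgeRateSchedule
    h2: float
    h3: float
    h4: float
    f2: float
    f3: float
    f4: float
    f5: float
    delta1: float
    delta2: float
    delta3: float
    delta4: float
    m: float = 1.5

    def __post_init__(self) -> None:
        for name in ("h2", "h3", "h4", "f2", "f3", "f4", "f5",
                     "delta1", "delta2", "delta3", "delta4"):
            _check_prob(name, getattr(self, name))
        if not 1.0 <= self.m <= 3.0:
            raise ModelError(f"m={self.m} outside sensitivity range [1.0, 3.0]")
        if self.m * self.delta4 > 1.0:
            raise ModelError(f"m*delta4 = {self.m * self.delta4} exceeds 1")

    @property
    def deltas(self) -> tuple[float, float, float, float]:
        return (self.delta1, self.delta2, self.delta3, self.delta4)

    @property
    def deltas_undetected(self) -> tuple[float, float, float, float]:
        """delta' per stage: m * delta, capped at 1."""
        return tuple(min(1.0, self.m * d) for d in self.deltas)

    def with_multiplier(self, m: float) -> "NaturalHistoryParams":
        return replace(self, m=float(m))

    def without_bc_death(self) -> "NaturalHistoryParams":
        """Companion parameter set with all breast-cancer mortality removed."""
        return replace(self, delta1=0.0, delta2=0.0, delta3=0.0, delta4=0.0)


def apply_incidence(state: CohortState, h1_at_age: float) -> tuple[CohortState, EventTally]:
    """Move healthy women into undetected stage 1 at the age-specific rate."""
    h1 = _check_prob("h1", h1_at_age)
    new_cases = state.u1 * h1
    out = replace(state, u1=state.u1 - new_cases, u2=state.u2 + new_cases)
    return out, EventTally(incident_cases=new_cases)


def apply_progression(state: CohortState, h2: float, h3: float, h4: float
                      ) -> tuple[CohortState, EventTally]:
    """Advance undetected cancers one stage, simultaneously.

    All moves are computed from start-of-operation occupancies, so no one
    advances two stages in a single cycle.  Detected states never change.
    """
    h2 = _check_prob("h2", h2)
    h3 = _check_prob("h3", h3)
    h4 = _check_prob("h4", h4)
    p12 = state.u2 * h2
    p23 = state.u3 * h3
    p34 = state.u4 * h4
    out = replace(
        state,
        u2=state.u2 - p12,
        u3=state.u3 + p12 - p23,
        u4=state.u4 + p23 - p34,
        u5=state.u5 + p34,
    )
    return out, EventTally(progressions=(p12, p23, p34))


def apply_clinical_detection(state: CohortState, f2: float, f3: float,
                             f4: float, f5: float) -> tuple[CohortState, EventTally]:
    """Undetected cases present clinically and start treatment, stage-preserving."""
    fs = tuple(_check_prob(f"f{i+2}", f) for i, f in enumerate((f2, f3, f4, f5)))
    det = tuple(u * f for u, f in zip(state.undetected, fs))
    out = replace(
        state,
        u2=state.u2 - det[0], u3=state.u3 - det[1],
        u4=state.u4 - det[2], u5=state.u5 - det[3],
        w2=state.w2 + det[0], w3=state.w3 + det[1],
        w4=state.w4 + det[2], w5=state.w5 + det[3],
    )
    return out, EventTally(clinical_detections=det)


def apply_mortality(state: CohortState, mu_at_age: float,
                    deltas: tuple[float, float, float, float],
                    m: float) -> tuple[CohortState, EventTally]:
    """Apply other-cause and breast-cancer mortality as independent risks.

    Every living woman faces the other-cause probability mu.  Survivors of
    that risk die of breast cancer with probability delta_s if detected
    (w states) or m*delta_s if undetected (u states); the combined per-cycle
    death probability in a diseased state is 1 - (1-mu)(1-delta).
    """
    mu = _check_prob("mu", mu_at_age)
    deltas = tuple(_check_prob(f"delta{i+1}", d) for i, d in enumerate(deltas))
    dprime = tuple(m * d for d in deltas)
    if dprime[3] > 1.0:
        raise ModelError(f"m*delta4 = {dprime[3]} exceeds 1")

    oth_u1 = state.u1 * mu
    oth_u = tuple(u * mu for u in state.undetected)
    oth_w = tuple(w * mu for w in state.detected)
    bc_u = tuple(u * (1.0 - mu) * dp for u, dp in zip(state.undetected, dprime))
    bc_w = tuple(w * (1.0 - mu) * d for w, d in zip(state.detected, deltas))

    out = replace(
        state,
        u1=state.u1 - oth_u1,
        u2=state.u2 - oth_u[0] - bc_u[0],
        u3=state.u3 - oth_u[1] - bc_u[1],
        u4=state.u4 - oth_u[2] - bc_u[2],
        u5=state.u5 - oth_u[3] - bc_u[3],
        w2=state.w2 - oth_w[0] - bc_w[0],
        w3=state.w3 - oth_w[1] - bc_w[1],
        w4=state.w4 - oth_w[2] - bc_w[2],
        w5=state.w5 - oth_w[3] - bc_w[3],
        du1=state.du1 + oth_u1 + sum(oth_u) + sum(oth_w),
        du2=state.du2 + bc_u[0],
        du3=state.du3 + bc_u[1],
        du4=state.du4 + bc_u[2],
        du5=state.du5 + bc_u[3],
        dw1=state.dw1 + bc_w[0],
        dw2=state.dw2 + bc_w[1],
        dw3=state.dw3 + bc_w[2],
        dw4=state.dw4 + bc_w[3],
    )
    tally = EventTally(
        deaths_other=oth_u1 + sum(oth_u) + sum(oth_w),
        deaths_bc_undetected=bc_u,
        deaths_bc_detected=bc_w,
    )
    return out, tally
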