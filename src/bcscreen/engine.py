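"""Cohort simulation engine: trace 100 000 women from age 0 to 100.

``simulate`` runs the deterministic expected-value chain, applying the
per-cycle operator sequence (screening at scheduled ages, then clinical
detection, progression, incidence, mortality) for each age 0..100 and
recording the state at the start of each age plus the event tally of that
year.  The chain is linear in cohort size, so counts scale exactly with n0.

``simulate_stochastic`` is the per-individual counterpart (binomial draws
for every transition) used as an independent oracle in tests; its
expectation equals the deterministic chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import natural_history as nh
from .natural_history import CohortState, EventTally, ModelError, NaturalHistoryParams
from .rates import AGE_MAX, AGE_MIN
from .screening import ScreeningPerformance, ScreeningStrategy, apply_screening, screening_ages

__all__ = [
    "Trajectory",
    "ValidationSummary",
    "simulate",
    "simulate_stochastic",
    "summarize_validation",
    "trajectory_to_frames",
]

DEFAULT_N0 = 100_000.0
DEFAULT_FOLLOWUP_AGE = 40  # metrics window: 60-year follow-up from age 40


@dataclass(frozen=True)
class Trajectory:
    """Full life-course record of one simulation.

    ``states[a]`` is the cohort at the *start* of age a (before that year's
    events); ``tallies[a]`` the events during age a.  ``final_state`` is the
    post-horizon state in which everyone remaining alive at the end of age
    100 has been assigned an other-cause death for accounting.
    """

    states: tuple[CohortState, ...]
    tallies: tuple[EventTally, ...]
    final_state: CohortState
    n0: float
    params: NaturalHistoryParams
    performance: Optional[ScreeningPerformance] = None
    strategy: Optional[ScreeningStrategy] = None

    def alive(self, age: int) -> float:
        """Living persons at the start of the given age."""
        return self.states[age].total_living

    def _window(self, from_age: Optional[int]) -> slice:
        lo = AGE_MIN if from_age is None else int(from_age)
        return slice(lo, AGE_MAX + 1)

    def bc_deaths(self, from_age: Optional[int] = DEFAULT_FOLLOWUP_AGE) -> float:
        return sum(t.deaths_bc_total for t in self.tallies[self._window(from_age)])

    def screens(self, from_age: Optional[int] = DEFAULT_FOLLOWUP_AGE) -> float:
        return sum(t.screens_performed for t in self.tallies[self._window(from_age)])

    def false_positives(self, from_age: Optional[int] = DEFAULT_FOLLOWUP_AGE) -> float:
        return sum(t.false_positives for t in self.tallies[self._window(from_age)])

    def screen_detections(self, from_age: Optional[int] = None) -> float:
        return sum(sum(t.screen_detections) for t in self.tallies[self._window(from_age)])

    def clinical_detections(self, from_age: Optional[int] = None) -> float:
        return sum(sum(t.clinical_detections) for t in self.tallies[self._window(from_age)])

    def incident_cases(self, from_age: Optional[int] = None) -> float:
        return sum(t.incident_cases for t in self.tallies[self._window(from_age)])

    def detections_by_stage(self, mode: str) -> tuple[float, float, float, float]:
        """Cumulative detections per stage for one detection mode."""
        if mode == "screening":
            rows = [t.screen_detections for t in self.tallies]
        elif mode == "outpatient":
            rows = [t.clinical_detections for t in self.tallies]
        else:
            raise ValueError(f"unknown detection mode {mode!r}")
        return tuple(float(s) for s in np.sum(np.array(rows), axis=0))


@dataclass(frozen=True)
class ValidationSummary:
    """Life-course totals comparable to registry statistics."""

    total_cases: float
    incidence_per_100k: float
    total_bc_deaths: float
    mortality_per_100k: float
    stage_distribution_outpatient: Optional[tuple[float, float, float, float]]
    stage_distribution_screening: Optional[tuple[float, float, float, float]]


def _cycle(state: CohortState, params: NaturalHistoryParams,
           perf: Optional[ScreeningPerformance],
           strategy: Optional[ScreeningStrategy],
           screen_set: frozenset[int]) -> tuple[CohortState, EventTally]:
    age = state.age
    tally = EventTally()
    if strategy is not None and age in screen_set:
        state, t = apply_screening(state, perf, strategy.participation[age], age)
        tally = tally + t
    state, t = nh.apply_clinical_detection(state, params.f2, params.f3, params.f4, params.f5)
    tally = tally + t
    state, t = nh.apply_progression(state, params.h2, params.h3, params.h4)
    tally = tally + t
    state, t = nh.apply_incidence(state, params.h1[age])
    tally = tally + t
    state, t = nh.apply_mortality(state, params.mu[age], params.deltas, params.m)
    tally = tally + t
    return state, tally


def simulate(params: NaturalHistoryParams,
             perf: Optional[ScreeningPerformance] = None,
             strategy: Optional[ScreeningStrategy] = None,
             n0: float = DEFAULT_N0) -> Trajectory:
    """Run the deterministic cohort chain from age 0 through age 100.

    ``strategy=None`` (or participation identically zero) is the
    no-screening baseline.  Raises ModelError, naming the offending age, if
    an invariant (non-negativity, conservation) breaks mid-run.
    """
    if strategy is not None and perf is None:
        raise ModelError("a strategy requires screening performance (se, sp)")
    screen_set = frozenset(screening_ages(strategy)) if strategy is not None else frozenset()

    state = CohortState.initial(n0)
    states: list[CohortState] = []
    tallies: list[EventTally] = []
    for age in range(AGE_MIN, AGE_MAX + 1):
        state = replace(state, age=age)
        states.append(state)
        try:
            state, tally = _cycle(state, params, perf, strategy, screen_set)
            state.validate(n0)
        except ModelError as exc:
            raise ModelError(f"simulation failed at age {age}: {exc}") from exc
        tallies.append(tally)

    # horizon accounting: anyone still alive after the age-100 cycle is
    # assigned an other-cause death in that final year
    leftover = state.total_living
    final = replace(
        state,
        u1=0.0, u2=0.0, u3=0.0, u4=0.0, u5=0.0,
        w2=0.0, w3=0.0, w4=0.0, w5=0.0,
        du1=state.du1 + leftover,
    )
    tallies[-1] = tallies[-1] + EventTally(deaths_other=leftover)
    final.validate(n0)
    return Trajectory(tuple(states), tuple(tallies), final, float(n0),
                      params, perf, strategy)


def summarize_validation(traj: Trajectory) -> ValidationSummary:
    """Totals and per-100k rates over the full life course.

    Only *detected* cancers (w2-w5 inflow) count as cases, mirroring how
    registries record diagnoses.  Rates are cases (deaths) per 100 000
    person-years.  A stage distribution whose mode saw zero detections is
    reported as None.
    """
    cases = traj.screen_detections(None) + traj.clinical_detections(None)
    deaths = traj.bc_deaths(None)
    person_years = sum(traj.alive(a) for a in range(AGE_MIN + 1, AGE_MAX + 1))
    py_100k = person_years / 100_000.0
    if py_100k <= 0:
        raise ModelError("no person-years lived; cannot summarize")

    def dist(mode: str):
        by_stage = traj.detections_by_stage(mode)
        tot = sum(by_stage)
        if tot <= 0:
            return None
        return tuple(s / tot for s in by_stage)

    return ValidationSummary(
        total_cases=cases,
        incidence_per_100k=cases / py_100k,
        total_bc_deaths=deaths,
        mortality_per_100k=deaths / py_100k,
        stage_distribution_outpatient=dist("outpatient"),
        stage_distribution_screening=dist("screening"),
    )


def trajectory_to_frames(traj: Trajectory) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Export (states long table, tallies table) as DataFrames.

    The states table has columns age, state, count; the tallies table one
    row per age with the per-year event counts.
    """
    import dataclasses as dc

    state_rows = []
    for s in traj.states:
        for f in dc.fields(s):
            if f.name == "age":
                continue
            state_rows.append({"age": s.age, "state": f.name, "count": getattr(s, f.name)})
    states_df = pd.DataFrame(state_rows)

    tally_rows = []
    for age, t in enumerate(traj.tallies):
        row = {"age": age,
               "incident_cases": t.incident_cases,
               "screens_performed": t.screens_performed,
               "false_positives": t.false_positives,
               "deaths_other": t.deaths_other}
        for i in range(4):
            row[f"clinical_detections_stage{i+1}"] = t.clinical_detections[i]
            row[f"screen_detections_stage{i+1}"] = t.screen_detections[i]
            row[f"deaths_bc_undetected_stage{i+1}"] = t.deaths_bc_undetected[i]
            row[f"deaths_bc_detected_stage{i+1}"] = t.deaths_bc_detected[i]
        for i in range(3):
            row[f"progressions_{i+1}to{i+2}"] = t.progressions[i]
        tally_rows.append(row)
    return states_df, pd.DataFrame(tally_rows)


def fast_detection_stats(params: NaturalHistoryParams,
                         perf: Optional[ScreeningPerformance] = None,
                         strategy: Optional[ScreeningStrategy] = None,
                         n0: float = DEFAULT_N0) -> dict:
    """Lean re-implementation of the cycle loop for optimizer inner loops.

    Same operator order and arithmetic as ``simulate`` but without the
    per-cycle object construction and invariant checks; returns only the
    aggregate statistics the estimator scores: detections by stage and
    mode, screens performed, breast-cancer deaths and person-years.
    Agreement with ``simulate`` is pinned to ~1e-12 in the test suite.
    """
    h1 = params.h1.values
    mu = params.mu.values
    fs = np.array([params.f2, params.f3, params.f4, params.f5])
    hs = (params.h2, params.h3, params.h4)
    deltas = np.array(params.deltas)
    dprime = np.array(params.deltas_undetected)
    screen_set = frozenset(screening_ages(strategy)) if strategy is not None else frozenset()
    e_sched = strategy.participation.values if strategy is not None else None
    sp_sched = perf.sp.values if perf is not None else None

    u1 = float(n0)
    u = np.zeros(4)
    w = np.zeros(4)
    clin = np.zeros(4)
    scr = np.zeros(4)
    screens = 0.0
    bc_deaths = 0.0
    bc_deaths_40 = 0.0
    person_years = 0.0

    for age in range(AGE_MIN, AGE_MAX + 1):
        if age > AGE_MIN:
            person_years += u1 + u.sum() + w.sum()
        if age in screen_set:
            e = e_sched[age]
            screens += e * (u1 + u.sum())
            det = e * perf.se * u
            u = u - det
            w = w + det
            scr += det
        det = u * fs
        u = u - det
        w = w + det
        clin += det
        moves = u[:3] * np.array(hs)
        u = u + np.concatenate(([0.0], moves)) - np.concatenate((moves, [0.0]))
        onset = u1 * h1[age]
        u1 -= onset
        u = u + np.array([onset, 0.0, 0.0, 0.0])
        m = mu[age]
        d_u = u * (1.0 - m) * dprime
        d_w = w * (1.0 - m) * deltas
        bc = d_u.sum() + d_w.sum()
        bc_deaths += bc
        if age >= DEFAULT_FOLLOWUP_AGE:
            bc_deaths_40 += bc
        u1 *= (1.0 - m)
        u = u * (1.0 - m) - d_u
        w = w * (1.0 - m) - d_w

    return {"clinical_detections": clin, "screen_detections": scr,
            "screens": screens, "bc_deaths": bc_deaths,
            "bc_deaths_from_40": bc_deaths_40, "person_years": person_years}


def simulate_stochastic(params: NaturalHistoryParams,
                        perf: Optional[ScreeningPerformance] = None,
                        strategy: Optional[ScreeningStrategy] = None,
                        n0: int = 10_000,
                        rng: np.random.Generator | int | None = None) -> dict:
    """Individual-level stochastic counterpart of ``simulate``.

    Every transition is a binomial draw on integer compartment counts with
    the same per-cycle probabilities and operator order as the deterministic
    chain, so the deterministic trajectory is its exact expectation.
    Returns summary totals (breast-cancer deaths, cases, screens, false
    positives).  Intended as a test oracle, not a production mode.
    """
    rng = np.random.default_rng(rng)
    screen_set = frozenset(screening_ages(strategy)) if strategy is not None else frozenset()
    deltas = params.deltas
    dprime = params.deltas_undetected

    u1 = int(n0)
    u = np.zeros(4, dtype=np.int64)   # undetected stages 1-4
    w = np.zeros(4, dtype=np.int64)   # detected stages 1-4
    bc_deaths = 0
    cases = 0
    screens = 0
    fps = 0

    def binom(n, p):
        return rng.binomial(int(n), p) if n > 0 and p > 0 else 0

    for age in range(AGE_MIN, AGE_MAX + 1):
        if strategy is not None and age in screen_set:
            e = strategy.participation[age]
            sp = perf.sp[age]
            part_u1 = binom(u1, e)
            part_u = np.array([binom(x, e) for x in u])
            screens += part_u1 + int(part_u.sum())
            fps += binom(part_u1, 1.0 - sp)
            det = np.array([binom(x, perf.se) for x in part_u])
            u -= det
            w += det
            cases += int(det.sum())
        # clinical detection
        det = np.array([binom(x, f) for x, f in zip(u, (params.f2, params.f3, params.f4, params.f5))])
        u -= det
        w += det
        cases += int(det.sum())
        # progression (simultaneous, from pre-move counts)
        moves = np.array([binom(u[i], h) for i, h in enumerate((params.h2, params.h3, params.h4))])
        u[:3] -= moves
        u[1:] += moves
        # incidence
        onset = binom(u1, params.h1[age])
        u1 -= onset
        u[0] += onset
        # mortality: other-cause first, breast cancer among survivors
        u1 -= binom(u1, params.mu[age])
        for i in range(4):
            du_oth = binom(u[i], params.mu[age])
            u[i] -= du_oth
            d = binom(u[i], dprime[i])
            u[i] -= d
            bc_deaths += d
            dw_oth = binom(w[i], params.mu[age])
            w[i] -= dw_oth
            d = binom(w[i], deltas[i])
            w[i] -= d
            bc_deaths += d

    return {"bc_deaths": bc_deaths, "cases": cases, "screens": screens,
            "false_positives": fps, "n0": int(n0)}
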