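"""Benefit, harm and efficiency metrics for screening strategies.

All strategy metrics are evaluated over the 60-year follow-up from age 40:
screenings, breast-cancer deaths and false positives are counted from age
40 onward and life expectancy is taken at age 40.  Day conversions use a
fixed 365 days/year with round-half-away-from-zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .engine import DEFAULT_FOLLOWUP_AGE, Trajectory, simulate
from .natural_history import ModelError
from .rates import AGE_MAX

__all__ = [
    "StrategyOutcome",
    "average_life_expectancy",
    "extension_days",
    "death_metrics",
    "maintained_fraction",
    "nns_metrics",
    "evaluate_strategy",
    "outcomes_to_frame",
]

DAYS_PER_YEAR = 365.0


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class StrategyOutcome:
    """One evaluation row for a screening strategy versus no screening."""

    label: str
    scmin: Optional[int]
    scmax: Optional[int]
    interval: Optional[int]
    screenings: float
    bc_deaths: float
    deaths_averted: float
    death_reduction_pct: float
    ale_extension_days: int
    false_positives: float
    screen_detections: float
    nns_detect: Optional[float]
    nns_avert_printed: Optional[float]
    nns_avert_conventional: Optional[float]
    life_expectancy: float
    maintained_pct: Optional[float] = None


def average_life_expectancy(traj: Trajectory, x: int = DEFAULT_FOLLOWUP_AGE,
                            exclude_bc_death: bool = False) -> float:
    """Expected age at death for those alive at age x.

    Computed as x + (person-years lived after x) / (alive at x) + 0.5; the
    half year accounts for deaths occurring on average mid-year.  With
    ``exclude_bc_death`` a companion trajectory with all breast-cancer
    mortality removed is simulated under identical inputs.
    """
    if exclude_bc_death:
        traj = simulate(traj.params.without_bc_death(), traj.performance,
                        traj.strategy, traj.n0)
    alive_x = traj.alive(x)
    if alive_x <= 0:
        raise ModelError(f"no one alive at age {x}")
    person_years = sum(traj.alive(a) for a in range(x + 1, AGE_MAX + 1))
    return x + person_years / alive_x + 0.5


def extension_days(le_a: float, le_b: float) -> int:
    """Life-expectancy difference in whole days (365 d/y, half away from zero)."""
    return _round_half_away((le_a - le_b) * DAYS_PER_YEAR)


def death_metrics(traj_strategy: Trajectory, traj_baseline: Trajectory,
                  from_age: int = DEFAULT_FOLLOWUP_AGE) -> tuple[float, float, float]:
    """(deaths under strategy, deaths averted, death reduction %)."""
    d_s = traj_strategy.bc_deaths(from_age)
    d_b = traj_baseline.bc_deaths(from_age)
    if d_b <= 0:
        raise ModelError("baseline has zero breast-cancer deaths; reduction undefined")
    averted = d_b - d_s
    return d_s, averted, 100.0 * averted / d_b


def maintained_fraction(outcomes_biennial: Sequence, outcomes_annual: Sequence
                        ) -> tuple[float, float, float]:
    """Fraction of annual screening's deaths averted kept by biennial screening.

    Inputs are paired sequences — StrategyOutcome lists matched on
    (scmin, scmax), or plain (averted_biennial, averted_annual) numbers in
    the same order.  Returns (mean %, min %, max %) over the pairs.
    """
    if len(outcomes_biennial) != len(outcomes_annual) or not outcomes_biennial:
        raise ModelError("maintained fraction needs equal-length non-empty lists")

    def pairs():
        if isinstance(outcomes_biennial[0], StrategyOutcome):
            ann = {(o.scmin, o.scmax): o for o in outcomes_annual}
            for b in outcomes_biennial:
                key = (b.scmin, b.scmax)
                if key not in ann:
                    raise ModelError(f"no annual counterpart for age range {key}")
                yield b.deaths_averted, ann[key].deaths_averted
        else:
            yield from zip(outcomes_biennial, outcomes_annual)

    ratios = []
    for averted_b, averted_a in pairs():
        if averted_a <= 0:
            raise ModelError("annual strategy averted no deaths; ratio undefined")
        ratios.append(100.0 * averted_b / averted_a)
    return (sum(ratios) / len(ratios), min(ratios), max(ratios))


def nns_metrics(screenings: float, screen_detections: float, bc_deaths: float,
                deaths_averted: float) -> tuple[float, float, float]:
    """Number-needed-to-screen efficiency ratios.

    Returns (nns_detect, nns_avert_printed, nns_avert_conventional):
    screenings per screen-detected diagnosis, screenings per breast-cancer
    death occurring under the strategy, and screenings per death averted.
    Both avert definitions are exposed because published strategy tables
    commonly head the deaths-under-strategy ratio as "to avert one death".
    """
    if screen_detections <= 0:
        raise ModelError("NNS-to-detect undefined: zero screen detections")
    if bc_deaths <= 0:
        raise ModelError("NNS (printed) undefined: zero deaths under strategy")
    if deaths_averted <= 0:
        raise ModelError("NNS-to-avert undefined: zero deaths averted")
    return (screenings / screen_detections,
            screenings / bc_deaths,
            screenings / deaths_averted)


def evaluate_strategy(traj_strategy: Trajectory, traj_baseline: Trajectory,
                      from_age: int = DEFAULT_FOLLOWUP_AGE) -> StrategyOutcome:
    """Assemble the full benefit/harm/efficiency row for one strategy."""
    strat = traj_strategy.strategy
    deaths, averted, reduction = death_metrics(traj_strategy, traj_baseline, from_age)
    le_s = average_life_expectancy(traj_strategy, from_age)
    le_b = average_life_expectancy(traj_baseline, from_age)
    screenings = traj_strategy.screens(from_age)
    detections = traj_strategy.screen_detections(from_age)
    fps = traj_strategy.false_positives(from_age)

    nns_d = nns_a_printed = nns_a_conv = None
    if detections > 0 and deaths > 0 and averted > 0:
        nns_d, nns_a_printed, nns_a_conv = nns_metrics(screenings, detections,
                                                       deaths, averted)
    elif detections > 0:
        nns_d = screenings / detections

    return StrategyOutcome(
        label=strat.label if strat is not None else "no screening",
        scmin=strat.scmin if strat is not None else None,
        scmax=strat.scmax if strat is not None else None,
        interval=strat.interval if strat is not None else None,
        screenings=screenings,
        bc_deaths=deaths,
        deaths_averted=averted,
        death_reduction_pct=reduction,
        ale_extension_days=extension_days(le_s, le_b),
        false_positives=fps,
        screen_detections=detections,
        nns_detect=nns_d,
        nns_avert_printed=nns_a_printed,
        nns_avert_conventional=nns_a_conv,
        life_expectancy=le_s,
    )


def outcomes_to_frame(rows: Sequence[StrategyOutcome], rounded: bool = False
                      ) -> pd.DataFrame:
    """Tabulate outcome rows; ``rounded`` gives the display convention
    (integer counts and percentages) while the default keeps full precision."""
    df = pd.DataFrame([vars(r) for r in rows])
    if rounded:
        for col in ("screenings", "bc_deaths", "deaths_averted", "false_positives",
                    "screen_detections", "nns_detect", "nns_avert_printed",
                    "nns_avert_conventional", "death_reduction_pct", "maintained_pct"):
            df[col] = df[col].map(
                lambda v: _round_half_away(v) if pd.notna(v) else v)
    return df
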