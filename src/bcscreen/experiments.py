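"""Study drivers: strategy grids, age-range regression, sensitivity sweep.

``run_grid`` evaluates every (interval, start age, stop age) combination of
a GridSpec against the matching no-screening baseline and appends the two
reference rows (no screening; no breast-cancer death).
``relative_benefit_regression`` regresses a relative-benefit response on the
initiating and terminating ages.  ``sensitivity_sweep`` is the one-way
analysis over the untreated-mortality multiplier m (delta' = m * delta).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .engine import DEFAULT_FOLLOWUP_AGE, DEFAULT_N0, Trajectory, simulate
from .natural_history import ModelError, NaturalHistoryParams
from .outcomes import (StrategyOutcome, average_life_expectancy, evaluate_strategy,
                       extension_days, outcomes_to_frame)
from .screening import (GRID_START_AGES, GRID_STOP_AGES, ScreeningPerformance,
                        ScreeningStrategy)

__all__ = [
    "GridSpec",
    "GridResult",
    "RegressionResult",
    "SensitivityResult",
    "run_grid",
    "relative_benefit_regression",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class GridSpec:
    """Factorial strategy grid: intervals x start ages x stop ages."""

    params: NaturalHistoryParams
    performance: ScreeningPerformance
    start_ages: tuple[int, ...] = GRID_START_AGES
    stop_ages: tuple[int, ...] = GRID_STOP_AGES
    intervals: tuple[int, ...] = (1, 2)
    participation: float = 1.0  # policy evaluation assumes full compliance
    n0: float = DEFAULT_N0
    from_age: int = DEFAULT_FOLLOWUP_AGE

    def __post_init__(self) -> None:
        if not (self.start_ages and self.stop_ages and self.intervals):
            raise ModelError("grid lists must be non-empty")
        if not 0.0 <= self.participation <= 1.0:
            raise ModelError(f"participation {self.participation} outside [0, 1]")


@dataclass(frozen=True)
class GridResult:
    """Outcome rows plus the reference quantities shared by all rows."""

    rows: tuple[StrategyOutcome, ...]
    baseline_deaths: float
    baseline_life_expectancy: float
    no_bc_life_expectancy: float
    theoretical_max_days: int
    spec: GridSpec

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        df = outcomes_to_frame(self.rows, rounded=rounded)
        df["maintained_pct"] = [r.maintained_pct for r in self.rows]
        if rounded:
            df["maintained_pct"] = df["maintained_pct"].map(
                lambda v: round(v) if pd.notna(v) else v)
        return df

    def row(self, interval: int, scmin: int, scmax: int) -> StrategyOutcome:
        for r in self.rows:
            if (r.interval, r.scmin, r.scmax) == (interval, scmin, scmax):
                return r
        raise KeyError(f"no grid row for interval={interval}, ages {scmin}-{scmax}")


def run_grid(spec: GridSpec) -> GridResult:
    """Simulate and evaluate every strategy cell in the grid.

    Rows are deterministic and independent, ordered interval-major then by
    (start, stop).  Biennial rows carry the maintained death-reduction
    percentage relative to the annual row of the same age range when both
    intervals are present.
    """
    baseline = simulate(spec.params, spec.performance, None, spec.n0)
    le_base = average_life_expectancy(baseline, spec.from_age)
    le_nobc = average_life_expectancy(
        simulate(spec.params.without_bc_death(), spec.performance, None, spec.n0),
        spec.from_age)

    rows: list[StrategyOutcome] = []
    for interval in spec.intervals:
        for scmin in spec.start_ages:
            for scmax in spec.stop_ages:
                strat = ScreeningStrategy.make(scmin, scmax, interval,
                                               spec.participation)
                try:
                    traj = simulate(spec.params, spec.performance, strat, spec.n0)
                    rows.append(evaluate_strategy(traj, baseline, spec.from_age))
                except ModelError as exc:
                    raise ModelError(
                        f"grid cell interval={interval} ages {scmin}-{scmax}: {exc}"
                    ) from exc

    # annotate biennial rows with the maintained death-reduction fraction
    annual = {(r.scmin, r.scmax): r for r in rows if r.interval == 1}
    out_rows = []
    for r in rows:
        if r.interval == 2 and (r.scmin, r.scmax) in annual:
            a = annual[(r.scmin, r.scmax)]
            if a.deaths_averted > 0:
                r = replace(r, maintained_pct=100.0 * r.deaths_averted / a.deaths_averted)
        out_rows.append(r)

    return GridResult(
        rows=tuple(out_rows),
        baseline_deaths=baseline.bc_deaths(spec.from_age),
        baseline_life_expectancy=le_base,
        no_bc_life_expectancy=le_nobc,
        theoretical_max_days=extension_days(le_nobc, le_base),
        spec=spec,
    )


@dataclass(frozen=True)
class RegressionResult:
    """OLS of a benefit response on initiating and terminating ages."""

    response: str
    coef: dict            # predictor -> unstandardized B
    beta: dict            # predictor -> standardized coefficient
    pvalues: dict
    adj_r2: float
    intercept: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"predictor": k, "B": self.coef[k], "beta": self.beta[k],
                 "p_value": self.pvalues[k], "adj_r2": self.adj_r2}
                for k in self.coef]
        return pd.DataFrame(rows)


def relative_benefit_regression(grid: GridResult | pd.DataFrame,
                                response: str = "death_reduction_pct",
                                interval: Optional[int] = None) -> RegressionResult:
    """Regress a benefit measure on (initiating age, terminating age).

    ``response`` is either ``death_reduction_pct`` or ``ale_extension_pct``
    (extension days as a percentage of the theoretical maximum; requires a
    GridResult so the maximum is known) or ``ale_extension_days``.
    Standardized betas are B * sd(x) / sd(y); adjusted R^2 follows the
    usual small-sample correction.
    """
    if isinstance(grid, GridResult):
        df = grid.to_frame()
        if response == "ale_extension_pct":
            if grid.theoretical_max_days <= 0:
                raise ModelError("theoretical maximum extension is zero")
            df["ale_extension_pct"] = 100.0 * df["ale_extension_days"] \
                / grid.theoretical_max_days
    else:
        df = grid.copy()
    df = df.dropna(subset=["scmin", "scmax"])
    if interval is not None:
        df = df[df["interval"] == interval]
    if response not in df.columns:
        raise ModelError(f"response {response!r} not in grid columns")
    if df[["scmin", "scmax"]].drop_duplicates().shape[0] < 4:
        raise ModelError("need at least 4 distinct (start, stop) combinations")
    if df["scmin"].nunique() < 2 or df["scmax"].nunique() < 2:
        raise ModelError("collinear design: need variation in both ages")

    X = sm.add_constant(df[["scmin", "scmax"]].astype(float))
    y = df[response].astype(float)
    fit = sm.OLS(y, X).fit()

    names = {"scmin": "initiating_age", "scmax": "terminating_age"}
    coef = {names[k]: float(fit.params[k]) for k in names}
    beta = {names[k]: float(fit.params[k] * df[k].std(ddof=1) / y.std(ddof=1))
            for k in names}
    pvals = {names[k]: float(fit.pvalues[k]) for k in names}
    return RegressionResult(
        response=response, coef=coef, beta=beta, pvalues=pvals,
        adj_r2=float(fit.rsquared_adj), intercept=float(fit.params["const"]),
        n=int(fit.nobs),
    )


@dataclass(frozen=True)
class SensitivityResult:
    """One-way sweep over the untreated-mortality multiplier m."""

    m_grid: tuple[float, ...]
    ext_wide: tuple[int, ...]       # extension days, wide age range
    ext_narrow: tuple[int, ...]     # extension days, narrow age range
    abs_diff_days: tuple[int, ...]
    rel_diff_pct: tuple[float, ...]
    wide: tuple[int, int]
    narrow: tuple[int, int]
    interval: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "m": self.m_grid,
            f"ext_days_{self.wide[0]}_{self.wide[1]}": self.ext_wide,
            f"ext_days_{self.narrow[0]}_{self.narrow[1]}": self.ext_narrow,
            "abs_diff_days": self.abs_diff_days,
            "rel_diff_pct": self.rel_diff_pct,
        })


def relative_effect_pct(ext_wide_days: float, ext_narrow_days: float) -> float:
    """Relative extra benefit of the wider age range, in percent."""
    if ext_narrow_days == 0:
        raise ModelError("relative effect undefined: narrow-range extension is zero")
    return 100.0 * (ext_wide_days - ext_narrow_days) / ext_narrow_days


def sensitivity_sweep(params: NaturalHistoryParams, perf: ScreeningPerformance,
                      m_grid: Sequence[float],
                      wide: tuple[int, int] = (40, 74),
                      narrow: tuple[int, int] = (50, 74),
                      interval: int = 2,
                      participation: float = 1.0,
                      n0: float = DEFAULT_N0,
                      from_age: int = DEFAULT_FOLLOWUP_AGE) -> SensitivityResult:
    """Re-simulate the two age-range strategies across the m grid.

    Nothing is re-estimated: only delta' = m * delta changes.  The baseline
    (no screening) is re-simulated per m because untreated mortality also
    shapes the unscreened cohort.
    """
    m_grid = tuple(float(m) for m in m_grid)
    if any(m < 1.0 or m > 3.0 for m in m_grid):
        raise ModelError(f"m grid {m_grid} outside [1.0, 3.0]")

    ext_w, ext_n, absd, reld = [], [], [], []
    for m in m_grid:
        p = params.with_multiplier(m)
        base = simulate(p, perf, None, n0)
        le_base = average_life_expectancy(base, from_age)
        exts = []
        for lo, hi in (wide, narrow):
            strat = ScreeningStrategy.make(lo, hi, interval, participation)
            traj = simulate(p, perf, strat, n0)
            exts.append(extension_days(average_life_expectancy(traj, from_age), le_base))
        ext_w.append(exts[0])
        ext_n.append(exts[1])
        absd.append(exts[0] - exts[1])
        reld.append(relative_effect_pct(exts[0], exts[1]))

    return SensitivityResult(
        m_grid=m_grid, ext_wide=tuple(ext_w), ext_narrow=tuple(ext_n),
        abs_diff_days=tuple(absd), rel_diff_pct=tuple(reld),
        wide=wide, narrow=narrow, interval=interval,
    )
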