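"""Model/Results facade over the estimation and simulation machinery.

``MassScreeningModel`` is built from the observable data — stage-at-
detection distributions, per-stage survival curves, and the age-specific
rate schedules — plus the fixed screening-test characteristics.  ``fit()``
first recovers the per-stage mortality rates delta from the survival curves
(log-linear least squares) and then the seven natural-history rates
(h2-h4, f2-f5) by penalized multinomial maximum likelihood, returning a
``MassScreeningResults`` object carrying estimates, standard errors from the
observed information, diagnostics and a ``summary()`` table.  Simulation and
policy evaluation hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import DEFAULT_N0, Trajectory, simulate
from .estimation import (EstimationContext, HistoryFit, StageDistribution,
                         SurvivalCurve, estimate_history_params,
                         fit_stage_mortality)
from .experiments import GridResult, GridSpec, run_grid
from .natural_history import ModelError, NaturalHistoryParams
from .outcomes import StrategyOutcome, evaluate_strategy
from .rates import AgeRateSchedule
from .screening import ScreeningPerformance, ScreeningStrategy

__all__ = ["MassScreeningModel", "MassScreeningResults"]


class MassScreeningModel:
    """Breast-cancer natural-history model fitted to detection-stage data.

    Parameters
    ----------
    stage_outpatient, stage_screening : StageDistribution
        Observed stage distributions of cases detected through outpatient
        care and through screening.
    survival_curves : sequence of SurvivalCurve
        One per stage 1-4; exponential survival is assumed per stage.
    incidence, other_mortality : AgeRateSchedule
        Age-specific incidence (h1) and other-cause mortality (mu).
    performance : ScreeningPerformance
        Sensitivity, specificity schedule and the published detection rate
        used for the identifiability constraint.
    observed_strategy : ScreeningStrategy or None
        The screening regime under which the stage data arose (observed
        participation), None for an unscreened population.
    m : float
        Untreated-to-treated mortality ratio delta'/delta.
    """

    def __init__(self, stage_outpatient: StageDistribution,
                 stage_screening: StageDistribution,
                 survival_curves: Sequence[SurvivalCurve],
                 incidence: AgeRateSchedule,
                 other_mortality: AgeRateSchedule,
                 performance: ScreeningPerformance,
                 observed_strategy: Optional[ScreeningStrategy] = None,
                 m: float = 1.5,
                 n0: float = DEFAULT_N0,
                 constraint: str = "detection_rate",
                 constraint_target: Optional[float] = None):
        if len(survival_curves) != 4:
            raise ModelError("need one survival curve per stage 1-4")
        stages = sorted(c.stage for c in survival_curves)
        if stages != [1, 2, 3, 4]:
            raise ModelError(f"survival curves must cover stages 1-4, got {stages}")
        self.stage_outpatient = stage_outpatient
        self.stage_screening = stage_screening
        self.survival_curves = tuple(sorted(survival_curves, key=lambda c: c.stage))
        self.incidence = incidence
        self.other_mortality = other_mortality
        self.performance = performance
        self.observed_strategy = observed_strategy
        self.m = float(m)
        self.n0 = float(n0)
        self.constraint = constraint
        self.constraint_target = constraint_target

    @classmethod
    def from_preset(cls, country: str, **kwargs) -> "MassScreeningModel":
        """Build from the shipped country preset on the synthetic fixture
        curves, with survival curves implied by the preset mortality rates
        (10-year exponential survival points)."""
        from . import presets

        p = presets.PRESETS[country]
        curves = [SurvivalCurve([(10.0, float(np.exp(-10.0 * p[f"delta{s}"])))], stage=s)
                  for s in range(1, 5)]
        strategy = ScreeningStrategy.make(
            40, 84, 1, presets.participation_fixture(country))
        defaults = dict(
            stage_outpatient=presets.stage_distribution_preset(country, "outpatient"),
            stage_screening=presets.stage_distribution_preset(country, "screening"),
            survival_curves=curves,
            incidence=presets.incidence_fixture(country),
            other_mortality=presets.other_mortality_fixture(country),
            performance=presets.performance_preset(country),
            observed_strategy=strategy,
            m=p["m"],
        )
        defaults.update(kwargs)
        return cls(**defaults)

    def fit(self, x0: Optional[Sequence[float]] = None, n_starts: int = 5,
            seed: int = 0) -> "MassScreeningResults":
        """Estimate deltas then (h2-h4, f2-f5); return the results object."""
        deltas = tuple(fit_stage_mortality(c) for c in self.survival_curves)
        base = NaturalHistoryParams(
            h1=self.incidence, mu=self.other_mortality,
            h2=0.1, h3=0.1, h4=0.1, f2=0.1, f3=0.1, f4=0.1, f5=0.1,
            delta1=deltas[0], delta2=deltas[1], delta3=deltas[2],
            delta4=deltas[3], m=self.m,
        )
        ctx = EstimationContext(
            base_params=base, performance=self.performance,
            strategy=self.observed_strategy, n0=self.n0,
            constraint=self.constraint, constraint_target=self.constraint_target,
        )
        hist = estimate_history_params(self.stage_outpatient, self.stage_screening,
                                       ctx, x0=x0, n_starts=n_starts, seed=seed)
        params = NaturalHistoryParams(
            h1=self.incidence, mu=self.other_mortality,
            delta1=deltas[0], delta2=deltas[1], delta3=deltas[2],
            delta4=deltas[3], m=self.m, **hist.params,
        )
        return MassScreeningResults(self, params, hist, deltas)


@dataclass
class MassScreeningResults:
    """Fitted natural-history parameters with diagnostics and evaluators."""

    model: MassScreeningModel
    natural_history: NaturalHistoryParams
    history_fit: HistoryFit
    deltas: tuple[float, float, float, float]

    @property
    def params(self) -> pd.Series:
        vals = dict(self.history_fit.params)
        vals.update({f"delta{s}": d for s, d in enumerate(self.deltas, start=1)})
        return pd.Series(vals)

    @property
    def bse(self) -> pd.Series:
        """Approximate standard errors for (h2-h4, f2-f5) from the inverse
        observed information; NaN where the information is singular."""
        from .estimation import PARAM_NAMES
        info = self._information_matrix
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(len(PARAM_NAMES), np.nan)
        return pd.Series(se, index=list(PARAM_NAMES))

    @property
    def _information_matrix(self) -> np.ndarray:
        # reconstructed from the stored eigen-decomposition is lossy; the
        # fit keeps only eigenvalues, so rebuild the Hessian numerically
        from .estimation import _observed_information
        ctx = EstimationContext(
            base_params=self.natural_history, performance=self.model.performance,
            strategy=self.model.observed_strategy, n0=self.model.n0,
            constraint=self.model.constraint,
            constraint_target=self.model.constraint_target,
        )
        theta = self.history_fit.as_vector()
        return _observed_information(theta, self.model.stage_outpatient,
                                     self.model.stage_screening, ctx,
                                     self.history_fit.constraint_target)

    @property
    def loglike(self) -> float:
        return self.history_fit.loglike

    def simulate(self, strategy: Optional[ScreeningStrategy] = None,
                 n0: Optional[float] = None) -> Trajectory:
        return simulate(self.natural_history, self.model.performance, strategy,
                        self.model.n0 if n0 is None else n0)

    def evaluate(self, strategy: ScreeningStrategy,
                 baseline: Optional[Trajectory] = None) -> StrategyOutcome:
        if baseline is None:
            baseline = self.simulate(None)
        return evaluate_strategy(self.simulate(strategy), baseline)

    def run_grid(self, **kwargs) -> GridResult:
        spec = GridSpec(params=self.natural_history,
                        performance=self.model.performance, **kwargs)
        return run_grid(spec)

    def summary(self) -> str:
        """Plain-text summary table of estimates and diagnostics."""
        h = self.history_fit
        lines = [
            "Mass screening natural-history model",
            "=" * 54,
            f"{'parameter':<12}{'estimate':>12}    note",
            "-" * 54,
        ]
        se = None
        for name, val in h.params.items():
            lines.append(f"{name:<12}{val:>12.5f}    (ML, multinomial + constraint)")
        for s, d in enumerate(self.deltas, start=1):
            lines.append(f"{'delta' + str(s):<12}{d:>12.5f}    (log-survival LSQ)")
        lines += [
            "-" * 54,
            f"log-likelihood        {h.loglike:.3f}",
            f"constraint ({self.model.constraint}): value {h.constraint_value:.5g} "
            f"vs target {h.constraint_target:.5g}",
            f"converged: {h.converged}   gradient norm: {h.gradient_norm:.3g}",
            f"information eigenvalues: "
            + ", ".join(f"{e:.3g}" for e in h.information_eigenvalues),
            f"predicted outpatient stage dist: "
            + ", ".join(f"{p:.3f}" for p in h.predicted_outpatient),
            f"predicted screening stage dist:  "
            + ", ".join(f"{p:.3f}" for p in h.predicted_screening),
        ]
        return "\n".join(lines)
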