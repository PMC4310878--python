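"""Parameter estimation from observable summaries.

Two estimators:

- ``fit_stage_mortality``: the annual breast-cancer mortality rate delta of
  one stage from a survival curve, assuming exponential survival
  S(t) = exp(-delta * t).  Survival is log-transformed and delta is the
  least-squares slope of -ln S on t *through the origin* (S(0) = 1 is
  structural, so no intercept is fitted); a single 10-year survival point
  gives the closed form delta = -ln S(t) / t.

- ``estimate_history_params``: the seven unobservable natural-history rates
  (h2-h4 progression, f2-f5 clinical presentation) by maximum likelihood
  from the stage distributions of detected cases.  The model-predicted
  distributions (a full cohort simulation under the supplied context) are
  scored against the observed outpatient and screening distributions with a
  multinomial likelihood.  Seven parameters against six free proportions is
  under-determined, so one scale-fixing constraint closes the gap: by
  default the predicted screen-detection rate is tied to a published sd
  value (alternatively the predicted breast-cancer mortality per 100 000).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .engine import fast_detection_stats
from .natural_history import ModelError, NaturalHistoryParams
from .screening import ScreeningPerformance, ScreeningStrategy, detection_rate

__all__ = [
    "StageDistribution",
    "SurvivalCurve",
    "EstimationContext",
    "HistoryFit",
    "fit_stage_mortality",
    "estimate_history_params",
]

PARAM_NAMES = ("h2", "h3", "h4", "f2", "f3", "f4", "f5")
_BOUND = (1e-6, 1.0 - 1e-6)
_CONSTRAINT_WEIGHT = 1e4  # quadratic penalty weight on the scale constraint


class BoundaryWarning(UserWarning):
    """An estimate landed on the feasible boundary."""


class IdentifiabilityWarning(UserWarning):
    """The observed information matrix is (near-)singular."""


@dataclass(frozen=True)
class StageDistribution:
    """Proportions of detected cases by stage (1-4) for one detection mode."""

    p1: float
    p2: float
    p3: float
    p4: float
    mode: str = "outpatient"
    n_effective: float = 10_000.0

    def __post_init__(self) -> None:
        ps = self.as_array()
        if np.any(ps < 0):
            raise ModelError(f"negative stage proportion in {ps}")
        if abs(ps.sum() - 1.0) > 1e-9:
            raise ModelError(f"stage proportions sum to {ps.sum()}, not 1")
        if self.mode not in ("outpatient", "screening"):
            raise ModelError(f"unknown detection mode {self.mode!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4], dtype=float)

    @classmethod
    def from_percent(cls, pcts: Sequence[float], mode: str,
                     n_effective: float = 10_000.0) -> "StageDistribution":
        arr = np.asarray(pcts, dtype=float)
        arr = arr / arr.sum()  # renormalize printed percentages
        return cls(*arr.tolist(), mode=mode, n_effective=n_effective)


@dataclass(frozen=True)
class SurvivalCurve:
    """(t years since diagnosis, surviving proportion) points for one stage."""

    points: tuple[tuple[float, float], ...]
    stage: int = 1

    def __init__(self, points, stage: int = 1):
        norm = tuple((float(t), float(s)) for t, s in points)
        if not norm:
            raise ModelError("empty survival curve")
        for t, s in norm:
            if s <= 0 or s > 1:
                raise ModelError(f"survival S({t})={s} outside (0, 1]")
            if t < 0:
                raise ModelError(f"negative time {t}")
        ts = [t for t, _ in norm]
        ss = [s for _, s in norm]
        if sorted(ts) != ts:
            raise ModelError("survival times must be non-decreasing")
        if any(b > a + 1e-12 for a, b in zip(ss, ss[1:])):
            raise ModelError("survival must be non-increasing")
        object.__setattr__(self, "points", norm)
        object.__setattr__(self, "stage", int(stage))


def fit_stage_mortality(curve: SurvivalCurve) -> float:
    """Annual mortality delta from log-linear least squares through the origin.

    delta = argmin sum_t (ln S(t) + delta t)^2 = sum(-ln S * t) / sum(t^2).
    Exact (machine precision) on noiseless exponential curves; with a single
    point this reduces to -ln S(t) / t.
    """
    t = np.array([p[0] for p in curve.points])
    s = np.array([p[1] for p in curve.points])
    mask = t > 0
    if not mask.any():
        raise ModelError("need at least one survival point with t > 0")
    t, s = t[mask], s[mask]
    neg_log_s = -np.log(s)
    return float(neg_log_s @ t / (t @ t))


@dataclass(frozen=True)
class EstimationContext:
    """Everything held fixed while (h2-h4, f2-f5) are estimated.

    The simulation context must mirror how the observed stage distributions
    arose: the country's incidence and other-cause mortality schedules, the
    detected/undetected mortality rates, screening performance and the
    participation regime actually observed (not a counterfactual policy).
    """

    base_params: NaturalHistoryParams
    performance: ScreeningPerformance
    strategy: Optional[ScreeningStrategy]
    n0: float = 100_000.0
    constraint: str = "detection_rate"        # or "bc_mortality"
    constraint_target: Optional[float] = None  # default: performance.sd_reference
    from_age: Optional[int] = None             # detection-tally window (whole life)

    def target(self) -> float:
        if self.constraint_target is not None:
            return float(self.constraint_target)
        if self.constraint == "detection_rate":
            if self.performance.sd_reference is None:
                raise ModelError("detection-rate constraint needs sd_reference "
                                 "or an explicit constraint_target")
            return float(self.performance.sd_reference)
        raise ModelError("bc_mortality constraint needs an explicit constraint_target")


@dataclass
class HistoryFit:
    """Result of the natural-history maximum-likelihood fit."""

    params: dict
    loglike: float
    constraint_value: float
    constraint_target: float
    predicted_outpatient: np.ndarray
    predicted_screening: np.ndarray
    information_eigenvalues: np.ndarray
    n_starts: int
    converged: bool
    gradient_norm: float
    boundary: bool

    def as_vector(self) -> np.ndarray:
        return np.array([self.params[k] for k in PARAM_NAMES])


def _predict(theta: np.ndarray, ctx: EstimationContext):
    """Model-predicted stage distributions and constraint statistic."""
    p = ctx.base_params
    params = NaturalHistoryParams(
        h1=p.h1, mu=p.mu,
        h2=theta[0], h3=theta[1], h4=theta[2],
        f2=theta[3], f3=theta[4], f4=theta[5], f5=theta[6],
        delta1=p.delta1, delta2=p.delta2, delta3=p.delta3, delta4=p.delta4,
        m=p.m,
    )
    stats = fast_detection_stats(params, ctx.performance, ctx.strategy, ctx.n0)
    out = stats["clinical_detections"]
    scr = stats["screen_detections"]
    if ctx.constraint == "detection_rate":
        screens = stats["screens"]
        stat = detection_rate(scr.sum(), screens) if screens > 0 else 0.0
    elif ctx.constraint == "bc_mortality":
        stat = 100_000.0 * stats["bc_deaths"] / stats["person_years"]
    else:
        raise ModelError(f"unknown constraint {ctx.constraint!r}")
    return out, scr, stat


def _loglike(theta: np.ndarray, obs_out: StageDistribution,
             obs_scr: StageDistribution, ctx: EstimationContext,
             target: float) -> tuple[float, float]:
    """Penalized multinomial log-likelihood (returned with constraint stat)."""
    out, scr, stat = _predict(theta, ctx)
    ll = 0.0
    for obs, pred in ((obs_out, out), (obs_scr, scr)):
        tot = pred.sum()
        if tot <= 0:
            return -np.inf, stat
        q = np.clip(pred / tot, 1e-300, None)
        ll += obs.n_effective * float(obs.as_array() @ np.log(q))
    # scale-fixing constraint as a quadratic penalty on the relative gap
    ll -= _CONSTRAINT_WEIGHT * ((stat - target) / max(abs(target), 1e-12)) ** 2
    return ll, stat


def estimate_history_params(p_out: StageDistribution, p_scr: StageDistribution,
                            context: EstimationContext,
                            x0: Optional[Sequence[float]] = None,
                            n_starts: int = 5,
                            seed: int = 0) -> HistoryFit:
    """Maximum-likelihood estimation of (h2, h3, h4, f2, f3, f4, f5).

    Bounded quasi-Newton (L-BFGS-B, numerical gradients) from ``n_starts``
    jittered starting points with a fixed seed; the best likelihood wins,
    ties broken by the smaller parameter norm.  Degenerate observed
    distributions push estimates to the feasible boundary, which is
    reported with a warning rather than an error.
    """
    if p_out.mode == p_scr.mode:
        raise ModelError("need one outpatient and one screening distribution")
    target = context.target()
    rng = np.random.default_rng(seed)
    base = np.array(x0, dtype=float) if x0 is not None else \
        np.array([0.2, 0.1, 0.05, 0.05, 0.1, 0.1, 0.3])

    def neg_ll(theta):
        ll, _ = _loglike(theta, p_out, p_scr, context, target)
        return -ll if np.isfinite(ll) else 1e12

    best = None
    for i in range(n_starts):
        start = base if i == 0 else np.clip(
            base * np.exp(rng.normal(0.0, 0.5, size=7)), *_BOUND)
        res = minimize(neg_ll, start, method="L-BFGS-B", bounds=[_BOUND] * 7,
                       options={"maxiter": 300, "ftol": 1e-12})
        key = (round(res.fun, 6), float(np.linalg.norm(res.x)))
        if best is None or key < (round(best.fun, 6), float(np.linalg.norm(best.x))):
            best = res

    theta = np.clip(best.x, *_BOUND)
    ll, stat = _loglike(theta, p_out, p_scr, context, target)
    out, scr, _ = _predict(theta, context)

    boundary = bool(np.any(theta <= _BOUND[0] * 1.01) or np.any(theta >= 1 - 2e-6))
    if boundary:
        warnings.warn("estimate(s) on the feasible boundary; observed "
                      "distributions may be degenerate", BoundaryWarning)

    info = _observed_information(theta, p_out, p_scr, context, target)
    eig = np.linalg.eigvalsh(info)
    if eig.min() < 1e-6 * max(eig.max(), 1.0):
        warnings.warn(
            "observed information is near-singular (7 parameters vs 6 free "
            "proportions); estimates are identified only through the scale "
            "constraint", IdentifiabilityWarning)

    grad = _num_grad(lambda th: -_loglike(th, p_out, p_scr, context, target)[0], theta)
    return HistoryFit(
        params=dict(zip(PARAM_NAMES, theta.tolist())),
        loglike=float(ll),
        constraint_value=float(stat),
        constraint_target=float(target),
        predicted_outpatient=out / out.sum() if out.sum() > 0 else out,
        predicted_screening=scr / scr.sum() if scr.sum() > 0 else scr,
        information_eigenvalues=eig,
        n_starts=n_starts,
        converged=bool(best.success),
        gradient_norm=float(np.linalg.norm(grad)),
        boundary=boundary,
    )


def _num_grad(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    g = np.zeros_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(np.clip(x + e, *_BOUND)) - f(np.clip(x - e, *_BOUND))) / (2 * h)
    return g


def _observed_information(theta, p_out, p_scr, ctx, target, h: float = 1e-4) -> np.ndarray:
    """Numerical Hessian of the negative log-likelihood at the optimum."""
    n = len(theta)
    H = np.zeros((n, n))

    def f(x):
        ll, _ = _loglike(np.clip(x, *_BOUND), p_out, p_scr, ctx, target)
        return -ll

    f0 = f(theta)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h**2)
    return H
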