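# Methods

## The model

`bcscreen` implements a deterministic cohort state-transition model of
breast-cancer natural history with a mass-screening layer, run in 12-month
cycles from age 0 to age 100 on a closed cohort (default 100 000 women, all
healthy at age 0).

Living states: healthy `u1`; undetected breast cancer by stage `u2`–`u5`
(stages 1–4); detected / on-treatment breast cancer by stage `w2`–`w5`.
A false-positive screen is a *transient* event — the participant returns to
`u1` within the cycle — tallied cumulatively rather than occupying a state.
Cumulative death tallies are kept by cause and stage: other-cause deaths
`du1`, breast-cancer deaths while undetected `du2`–`du5`, and while detected
`dw1`–`dw4`.

Per-cycle transitions:

- **Incidence**: `u1 → u2` at the age-specific annual probability `h1(a)`.
- **Progression**: `u_s → u_{s+1}` at age-independent probabilities
  `h2, h3, h4`, computed simultaneously from start-of-operation occupancies
  (no one advances two stages in one cycle). Detected women never change
  stage and never revert to undetected.
- **Clinical presentation**: `u_s → w_s` at stage-specific probabilities
  `f2`–`f5` (outpatient-care detection), stage-preserving.
- **Screening** (scheduled ages only): a fraction `e(a)` of the
  unscreened-eligible population (`u1`–`u5`; women on treatment are not mass
  screened) attends. Cancers are found with sensitivity `se` and move
  `u_s → w_s`; healthy attendees test falsely positive with probability
  `1 − sp(a)`.
- **Mortality**: everyone faces the other-cause probability `μ(a)`;
  survivors of that risk die of breast cancer with probability `δ_s` if
  detected and `δ′_s = m·δ_s` if undetected, so the combined per-cycle death
  probability in a diseased state is `1 − (1−μ)(1−δ)`.

All rates are **annual probabilities**, not instantaneous hazards; no
hazard↔probability conversion is applied, because the chain itself is the
discrete 12-month process.

### Operator order within a cycle

The within-year order is screening → clinical detection → progression →
incidence → mortality. The choice is deliberate and matters at the scale of
whole-cohort outcome tables: detection operates on start-of-year
occupancies; a newly incident case can neither be detected nor die of breast
cancer in its onset year; a newly detected case receives the treated
mortality rate `δ` from the next cycle onward. Any fixed order is defensible
for a 1-year cycle; this one is documented so results are reproducible.

### Competing risks

Other-cause and breast-cancer death within a cycle are combined as
independent risks (`μ` first, `δ` among survivors of `μ`). This keeps every
death attributable to a single cause — the property the cause-specific
tallies and the "remove breast-cancer death" counterfactual rely on — and is
the standard discrete-cycle treatment.

### Horizon

The horizon is age 100; whoever remains alive after the age-100 cycle is
assigned an other-cause death in that final year so person-count
conservation holds exactly and life-table arithmetic closes. The
deterministic chain is linear in cohort size, so all counts scale exactly
with `n0`.

## Parameters

| parameter | meaning | units | Japan default | US default |
|---|---|---|---|---|
| `h1(a)` | incidence, healthy → stage 1 | /year | fixture curve, max 0.00146 | fixture curve, max 0.00421 |
| `h2, h3, h4` | stage progression 1→2, 2→3, 3→4 | /year | 0.22, 0.06, 0.01 | 0.43, 0.12, 0.05 |
| `f2…f5` | clinical presentation by stage | /year | 0.07, 0.12, 0.11, 0.40 | 0.04, 0.05, 0.09, 0.16 |
| `δ1…δ4` | breast-cancer mortality, detected | /year | 0.008, 0.021, 0.062, 0.230 | 0.012, 0.043, 0.107, 0.273 |
| `m` | untreated/treated mortality ratio (`δ′ = m·δ`) | — | 1.5 (sweep 1.0–3.0) | 1.5 |
| `μ(a)` | other-cause mortality | /year | fixture, 1e-4 → 0.3136 | fixture, 1e-4 → 0.2948 |
| `se` | screening sensitivity | — | 0.815 | 0.835 |
| `sp(a)` | screening specificity | — | 0.904 → 0.947 | 0.902 → 0.931 |
| `e(a)` | participation | /round | 1.0 for policy runs; 0.30 observed | 1.0; 0.50 observed |

`δ′` is derived as `m·δ` from the unrounded `δ`, capped at 1. Published
parameter tables print `δ′` rows rounded from unrounded `δ` values (e.g.
Japan stage 4: 1.5 × 0.230 = 0.345, printed 0.344); this package always
computes `m·δ` exactly and never stores a separate `δ′`.

## Rate schedules and the synthetic fixtures

Schedules are annual probabilities for every integer age 0–100, read from
`age,<column>` CSV with strict completeness checking (a missing age is an
error, never silently filled). Five-year banded data are expanded by
piecewise-linear interpolation between band midpoints, clamped at the ends,
then rescaled multiplicatively within each band so band means are preserved
exactly; the multiplicative form keeps rates non-negative next to zero-valued
bands. The interpolation rule is a documented package choice — published
sources state only that banded data were converted.

The real registry incidence and vital-statistics mortality curves behind the
published results are not public; only their ranges and qualitative shapes
are. The fixture generator (`presets` + `rates.synth_schedule`) therefore
synthesizes deterministic curves through anchor points:

- **Japan-like incidence**: unimodal (PCHIP through anchors), zero before
  age 20, peaking at 0.00146 at age 47, declining gently into old age.
- **US-like incidence**: rising continuously from the 30s to a plateau of
  0.00421 around ages 75–79.
- **Other-cause mortality**: piecewise-Gompertz (log-linear between
  anchors) from 1e-4 at birth through realistic mid-life female rates to
  the published age-100 endpoints (0.3136 / 0.2948).
- **Specificity**: linear in age from its minimum at age 40 (dense-breast
  ages) to its maximum at 84, clamped outside; the true age shape between
  the published extremes is unpublished.
- **Observed participation**: flat at the national rate (30% / 50%) for ages
  40–65, declining linearly to zero by 85.

PCHIP is used because it is shape-preserving: fixtures pass exactly through
their anchors, never overshoot the anchor maximum, and are deterministic
(bitwise-identical on repeat calls).

**What the fixtures do and do not show.** On these curves the package
reproduces the *relative* structure of published strategy evaluations — a
biennial schedule keeps ~86% of annual death reduction on the Japan-like
fixture with a false-positive ratio of ~0.50, the benefit–harm regression
signs, and the sensitivity-sweep monotonicities — and lands in the published
ballpark for absolute Japan-like quantities (1.42 M screenings and ~830
deaths averted for biennial 40–69 on 100 000 women). Absolute counts are
properties of the input curves: passing tests on fixtures demonstrate the
machinery, not country-specific point predictions. Real analyses should
supply registry schedules via `rates.read_rate_table` or the config file.

## Estimation

- **Stage mortality** `δ_s`: survival is assumed exponential per stage;
  `−ln S(t)` is regressed on `t` through the origin (S(0)=1 is structural,
  so no intercept), giving `δ = Σ(−ln S·t)/Σt²` — the closed form
  `−ln S(10)/10` for a single 10-year survival point. Recovery is exact to
  machine precision on noiseless exponential input.
- **Natural-history rates** `(h2–h4, f2–f5)`: maximum likelihood against
  the observed stage distributions of outpatient-detected and
  screen-detected cases. Each candidate parameter vector is scored by
  simulating the full cohort under the observed context (incidence,
  mortality, test characteristics, observed participation) and evaluating a
  multinomial log-likelihood (effective sample size `n_effective`, default
  10 000 — the true registry denominators are not published) for both
  detection modes. Seven parameters against six free proportions are not
  identifiable, so one scale-fixing constraint closes the gap: by default
  the model-predicted screen-detection rate is tied to the published `sd`
  (alternatively, predicted breast-cancer mortality per 100 000 to a
  supplied value). The constraint enters as a quadratic penalty on the
  relative gap with weight 1e4 — large enough that the constraint binds to
  ~1% while leaving the likelihood surface smooth.
- **Optimizer**: L-BFGS-B with bounds [1e-6, 1−1e-6] from 5 jittered starts
  (log-normal jitter, fixed seed), best likelihood wins, ties broken by the
  smaller parameter norm. The optimizer's inner loop uses a lean array
  re-implementation of the cycle chain (`engine.fast_detection_stats`),
  pinned to the reference chain at ~1e-12 by tests. Diagnostics reported:
  convergence flag, final gradient norm, eigenvalues of the numerical
  observed-information matrix (a near-zero eigenvalue warns that the
  estimates lean on the scale constraint), and a boundary warning for
  degenerate inputs.

Round-trip behaviour on well-specified synthetic input (distributions
generated by the model itself) recovers all seven parameters to well within
10% relative — in practice to ~0.01% — and the predicted distributions match
the observed ones within total-variation distance 0.02.

## Outcome metrics

All strategy metrics use the 60-year follow-up from age 40: screenings,
breast-cancer deaths and false positives are summed from age 40 onward; life
expectancy is evaluated at age 40.

- **Average life expectancy at age x**: `x + Σ_{a>x} alive(a)/alive(x) + 0.5`
  (expected age at death; the half-year credits mid-year deaths). The
  "no breast-cancer death" counterfactual re-simulates with all `δ = 0`.
- **Extension days**: difference of life expectancies × 365 d/y, rounded
  half away from zero. One published value (408 days for a 1.12-year gap)
  is consistent only with truncation; this package keeps one convention
  (365, round-half-away → 409) rather than special-casing.
- **Deaths averted / reduction %**: baseline minus strategy deaths;
  percentage of baseline. Computed on unrounded counts, rounded only for
  display.
- **Maintained death reduction**: per age-range pair, biennial averted /
  annual averted × 100; mean and min–max over the pairs.
- **NNS**: screenings per screen-detected diagnosis (`nns_detect`);
  screenings per breast-cancer death under the strategy
  (`nns_avert_printed` — the definition that reproduces published
  strategy-table columns headed "to avert one death"); and screenings per
  death averted (`nns_avert_conventional` — what the column name suggests).
  Both avert definitions are first-class because the published usage is
  ambiguous. Zero denominators raise, never return infinity.

## Experiments

- **Grid**: full factorial interval × start × stop (defaults: 1–2 years ×
  {40,45,50,55,60} × {69,74,79,84}) at 100% participation, each row
  evaluated against the shared no-screening baseline; reference rows carry
  baseline deaths and the no-breast-cancer-death life expectancy. Rows are
  deterministic and order-independent.
- **Age-range regression**: OLS (statsmodels) of a benefit response on
  (initiating age, terminating age), analyzed per interval — whether
  published analyses pooled intervals is unstated, so pooling is not the
  default. `ale_extension_pct` normalizes extension days by the theoretical
  maximum (the no-BC-death extension); raw days are also accepted — the
  published normalization is not defined, so both are exposed. Standardized
  β = B·sd(x)/sd(y); adjusted R² uses the usual correction. Coefficient
  *signs* (negative initiating age, positive terminating age for death
  reduction) are the reproducible content; magnitudes depend on the input
  curves.
- **Sensitivity sweep**: one-way over m ∈ [1.0, 3.0]; for each m the
  baseline and both age-range strategies (40–74 vs 50–74 biennial) are
  re-simulated — nothing is re-estimated — and absolute and relative
  extension differences reported. The m = 1.5 grid cell is bit-identical to
  the default-grid computation (same code path).

## Numerical choices and degenerate inputs

- Conservation (living + cumulative dead = initial cohort) is checked every
  cycle at 1e-9 relative; violations abort with the offending age rather
  than clamping, so parameter combinations whose per-cycle probabilities
  exceed 1 surface immediately.
- Biennial rounds are anchored at the start age with modulo stepping
  (40–69 biennial ⇒ 15 rounds at 40, 42, …, 68); an odd-gap terminal age
  does not host a round.
- `simulate_stochastic` is an individual-level binomial counterpart of the
  deterministic chain (same operator order and probabilities) provided as a
  test oracle only; the deterministic chain is its exact expectation.
- Problem sizes used in the shipped tests and the acceptance script —
  100 000-woman deterministic cohorts, a 2×2×3 strategy grid, a 5-point
  sensitivity sweep, 10 000-individual stochastic runs, 3 optimizer
  starts — were chosen so the full suite exercises every code path at
  production scale for the deterministic parts while keeping the stochastic
  and optimization components at sizes where their diagnostics
  (3-standard-error bracket, 10% round-trip recovery) are sharp.

## Known limitations

- No remission, stage regression, carcinoma in situ, treatment-era survival
  trends, or overdiagnosis compartment; false positives are the only
  quantified harm.
- Detected-state mortality is stage- but not age-dependent; progression is
  age-independent by design.
- The fixture curves are synthetic stand-ins; absolute outcome counts on
  them are not country predictions.
- The estimation likelihood treats the two stage distributions as
  independent multinomials with an assumed effective sample size; standard
  errors inherit that assumption.
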