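# Methods

This note records the statistical models, the default parameters and the
numerical choices behind `prevalkit`, including the deliberate design
decisions that are not forced by the mathematics.

## 1. Quantities

- **Limited-duration prevalence** `N_L(type, sex, a)`: persons alive at the
  index date (January 1 of the index year) whose diagnosis lies within the
  last `L` years. Directly countable from registry records (*counting
  method*).
- **Complete prevalence** `N`: the same, without the duration restriction.
  Estimated as `N = N_L / R`.
- **Completeness index** `R ∈ (0, 1]`: the modelled fraction of all prevalent
  cases whose diagnosis falls inside the window.

## 2. Counting method

One record per tumour with person id, sex, birth date, diagnosis date, type,
sequence number, vital status and exit date. Rules:

- Ages and durations are computed from exact day differences floored to whole
  years (`⌊days / 365.25⌋`); ages are capped at 99.
- A person counts once per cancer type (earliest diagnosis of that type) and
  once in the all-types stratum (first primary: lowest sequence number, ties
  broken by date then type code). Duplicate (person, sequence) pairs are a
  hard input error, as is a death date before a diagnosis date.
- Persons dead before the index date are excluded; persons lost to follow-up
  count as alive by default (`count_lost_as_alive=False` reverses this).
- Diagnoses on or after the index date are excluded and logged.

A brute-force record-by-record enumeration in the test suite serves as the
oracle for these rules (100 randomized registries).

## 3. Mixture cure model for survival

Relative survival (observed survival of patients divided by expected survival
of the general population) is modelled per cancer type, sex and age class
(0–14, 15–44, 45–54, 55–64, 65–74, 75+):

```
RS(t; y) = π + (1 − π) · exp(−(t/λ)^γ · e^{β (y − y₀)})
```

- `π` — cured fraction (experiences only background mortality),
- `λ, γ` — Weibull scale/shape of the excess (cancer) hazard of the fatal
  fraction,
- `β` — period effect: a multiplicative calendar-time modifier of the excess
  cumulative hazard around the reference year `y₀`, capturing survival
  improvement over time.

Observed survival is `S_obs(t) = S_exp(t) · RS(t)` with `S_exp` the life-table
(expected) survival along the person's cohort diagonal.

**Fitting.** The primary fitter is maximum likelihood on individual follow-up
records (time, event, sex, age, diagnosis year): the log-likelihood uses the
total hazard `h_bg + h_ex(t)` for events and `log RS(t)` for at-risk time
(background cumulative hazard terms are data constants and dropped).
Optimisation is L-BFGS-B on `(logit π, log λ, log γ, β)` with a small grid of
`π` starting values; standard errors come from a finite-difference Hessian and
the delta method. A least-squares mode on annual actuarial relative-survival
points (Ederer-II expected survival) is available for grouped data. The fit
refuses strata with fewer than `min_events` deaths (default 25), flags `π̂`
at the boundary, and drops `β` with a warning when all diagnoses share one
calendar year (collinearity).

## 4. Age–cohort incidence model

Annual diagnosis probabilities `I(x, c)` over age `x` and birth cohort `c`
are modelled on the logit scale as the sum of two degree-6 polynomials in
centred/scaled age and cohort, fitted as a binomial GLM (statsmodels) on
(cases, person-years) cells. Properties relied on elsewhere:

- canonical link ⇒ fitted expected counts reproduce observed totals;
- an internal canonical sort of cells makes the fit exactly invariant to input
  row order;
- predictions outside the fitted age/cohort range are clamped to the nearest
  fitted value and logged (polynomials explode when extrapolated).

For the all-types stratum the first-primary probability is obtained by
thinning: `I₁(x, c) = I(x, c) · Π_{x' < x} (1 − I(x', c))`, so that the index
matches the one-count-per-person rule of the counting method.

## 5. Completeness index

For attained age `a` at the index date, birth cohort `c = index_year − 1 − a`,
and time since diagnosis `t` (diagnosis year `index_year − 1 − t`):

```
w(t) = I(a − t, c) · S(t + ½)
R(a, L) = Σ_{t=0}^{min(L,a)−1} w(t) / Σ_{t=0}^{a−1} w(t)
```

Design decisions worth recording:

- **Relative survival as the default weight.** Under the standard
  independence assumption, the complete and limited prevalent populations at
  a fixed attained age share the same background survival along the cohort
  diagonal, which therefore cancels in the ratio exactly; using observed
  survival instead double-counts background mortality and biased the
  synthetic-registry recovery by about −11%, versus +1–2% for relative
  survival. An `survival="observed"` mode remains available for comparison.
- **Midpoint rule**: survival is evaluated at `t + ½` to approximate the
  within-year average; with it, constant incidence and no mortality give the
  intuitive `R = L / a` exactly (e.g. `a = 50`, `L = 10` ⇒ `R = 0.2`).
- `a ≤ L` short-circuits to `R = 1` (the window reaches back to birth), and a
  stratum with zero modelled mass falls back to `R = 1` with a warning rather
  than dividing by zero.

## 6. Duration split and projection

The complete estimate is distributed over time-since-diagnosis bins
([0,2), [2,5), [5,10), [10,15), [15,20), ≥20 years): observed single-year
durations keep their counted values; the surplus `N − N_L` is spread over
beyond-window durations proportionally to `w(t)`. Sums are conserved exactly;
a negative surplus (sampling noise when `R ≈ 1`) is clamped to zero and
logged.

Projections fit an ordinary-least-squares line per stratum through the
proportions (per 100,000) of the last three observed years (five as a
sensitivity mode), evaluate it at the target year, clamp negative values at
zero, and multiply by the forecast population. Trends act on proportions, so
demographic change enters only through the population term. Percent changes
are reported as `100·(target/base − 1)`.

Counts are rounded half-even to integers and percentages to one decimal only
at report time; upstream arithmetic stays unrounded. Report CSVs are
byte-deterministic (fixed float format, explicit `NA` markers, caller-supplied
metadata only).

## 7. Synthetic registry generator

The generator is a person-level microsimulation used as the validation oracle;
its defaults are the study conditions of the acceptance runs, not tuning
knobs.

Per person (100 birth cohorts × 2 sexes × `cohort_size` persons, birth at
mid-year): a calendar-year sweep draws, with annual piecewise-constant
hazards and exponential within-year times, the competition between background
death (Gompertz-style life table with secular decline), new primary diagnoses
(age–cohort model, up to 3 primaries) and, after each diagnosis, cancer death
from the mixture cure model (a cured/fatal coin at diagnosis, Weibull excess
time if fatal, period effect applied). Dates live on a 365-day grid so that
floored durations align exactly with diagnosis-year differences. The registry
view truncates to the registration window and resequences tumours; the full
history retains everything, giving `true_complete_prevalence` by direct
enumeration. Optional exponential lost-to-follow-up censoring.

Default scale: `cohort_size = 21,000` ⇒ ≈ 48,000 registered cases over a
30-year window (1980–2009), index date 2010-01-01, follow-up cut end of 2013
— a desk-scale emulation of a multi-registry pool. The generator emulates
first-order registry structure only: no migration, no age/period interactions
beyond the models above, no diagnostic delay, no death-certificate-only
cases, and subsequent-primary survival is drawn from the same stratum
parameters as first primaries.

## 8. Validation and problem sizes

- `completeness_transport(seed)` (also `scripts/acceptance.py`): simulate a
  30-year registry, truncate to 10 years, recover complete prevalence; the
  absolute relative difference against the oracle is ≈ 1.2% at the default
  scale (claimed bound: 5%).
- Cure fitter: `π̂` within ±0.02 of truth at n = 20,000; mean bias < 0.02
  over 50 replicates at n = 5,000.
- Counting method: equality with brute-force enumeration on 100 randomized
  ~1,000-record registries.
- Projection: exact on linear trends; 3- vs 5-year windows within 10% on
  smooth trends.

## 9. Limitations

- Completeness indices are transported from the generating models; with
  models *fitted* on the truncated window (the realistic situation) the error
  budget grows with extrapolation distance of the incidence polynomial.
- The period effect is log-linear and shared across ages within a class;
  strong non-linear survival improvements would need spline extensions.
- Standard errors on `N` are Poisson-style on `N_L` only and ignore the
  (model-based) uncertainty of `R`.
- Projections are straight lines on proportions: they reproduce recent trends
  and cannot anticipate screening or treatment shocks.
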