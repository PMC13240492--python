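# Methods

## Decision problem and model structure

The package evaluates three strategies for an open diabetic foot ulcer
(DFU): standard wound care alone, and standard care plus low-dose or
high-dose extracorporeal shockwave therapy (ESWT, a three-session course
delivered within one week). The model is a four-state Markov cohort model
— open DFU, amputee, healed, dead — run at a one-day cycle for 365 cycles
from an NHS/Personal Social Services perspective. The whole cohort (1000
patients) starts with an open ulcer. Dead is absorbing; healed ulcers can
recur into the open state; amputees face only mortality. With a one-day
cycle a half-cycle correction changes nothing of consequence, and with a
one-year horizon discounting is not applied.

Costs and QALYs accrue on the state occupancy at the start of each cycle:
cycle cost = Σ occupancy × per-day state cost, cycle QALYs =
Σ occupancy × annual utility / 365. The intervention cost is a one-off at
cycle 0. An optional per-event amputation cost exists (default £0: the
base analysis carries amputation cost entirely in the daily amputee-state
cost, and the model description it follows gives only daily state costs).

## Healing model

Time to healing follows a Weibull proportional-hazards (PH) regression,

    h(t|x) = γ λ t^(γ−1),  λ = exp(β₀ + xᵀβ),  S(t|x) = exp(−λ t^γ),

with covariates low-dose ESWT, high-dose ESWT, ulcer age (days), ulcer
area (cm²) and infection status. The PH (rate) parameterisation is used —
rather than the accelerated-failure-time form most Python survival
libraries expose — because the downstream uncertainty analysis treats the
treatment effects as hazard-scale, log-normally distributed quantities.
The mapping from an AFT fit (scale exp(xᵀb), shape ρ) is γ = ρ,
β = −ρ·b; a test cross-checks the in-package maximum-likelihood fit
against `lifelines` through this mapping.

Fitting is maximum likelihood under right-censoring: amputation, death
and end of follow-up all censor the healing time. (The cohort model
reintroduces amputation and death as parallel daily probabilities, which
is consistent with this censoring treatment under the model's
conditional-independence assumption.) The optimiser is BFGS on
(log γ, β) with an analytic gradient; the design matrix is standardised
internally and estimates and covariance mapped back, which keeps the
problem well-conditioned with covariates on scales as different as days
(up to 365) and indicators. The covariance matrix is the inverse observed
information, from central finite differences of the analytic gradient.
The Weibull family is compared with the exponential (γ = 1) by AIC, ties
resolved toward fewer parameters.

The per-cycle healing probability is `1 − S(t+1)/S(t)`, evaluated with t
counting days since model entry (t = 0..364). Two modelling choices are
deliberate:

* **Time origin.** The hazard clock starts at model entry, not at ulcer
  onset; ulcer age enters as a covariate instead of a time offset. This
  matches how the subgroup analysis varies ulcer duration as a covariate.
* **Recurrence.** A recurrent ulcer re-enters the open state under the
  same time-since-entry hazard; there are no tunnel states. This is an
  approximation, acceptable because recurrence is rare (daily probability
  0.00308674) within a one-year horizon.

## Parameters

Fixed per-day transition probabilities, state utilities and state costs:

| quantity | value | notes |
|---|---|---|
| open → amputee | 0.00308674 | daily |
| open → dead | 0.00019921 | daily |
| amputee → dead | 0.000456958 | daily |
| healed → open (recurrence) | 0.00308674 | daily |
| healed → dead | 6.0435e-05 | daily |
| utility open / amputee / healed | 0.671 / 0.316 / 0.757 | annual weights, dead = 0 |
| cost open / amputee / healed | £15.01 / £22.64 / £1.89 | per day, dead = £0 |

The residual self-transition of each state is one minus the sum of its
exits, so every row of the transition matrix sums to exactly 1; the
engine rejects any day on which the sampled healing probability would
push the open-state exits above 1.

The ESWT course price is not an established figure; the default costs the
three sessions as podiatrist-delivered outpatient contacts at £47 each
(£141 per course, a repo default recorded in the run metadata, applied
identically to both doses). It is a config field
(`model.intervention_session_cost`, `model.n_sessions`).

## Probabilistic sensitivity analysis

Each PSA iteration draws one coherent parameter set:

* **Survival coefficients** (log γ, β): multivariate normal around the
  estimates with the fit covariance, sampled as mean + L·z through the
  Cholesky factor L — so γ and λ are log-normal and the coefficient
  correlations are preserved. A semidefinite covariance (plausible at
  pilot scale) gets a diagonal jitter of at most 1e-10 with a logged
  warning; an exactly zero matrix yields a zero factor.
* **Transition probabilities and utilities**: beta. **Daily costs**:
  gamma, (shape, scale) convention with mean = shape × scale.

Three of the published hyper-parameter sets contradict the deterministic
values they should average to, so `ParameterDistributions.published()`
has correction toggles, all on by default and all recorded in output
metadata:

1. the amputation/recurrence beta pair implies a mean ten-fold below the
   deterministic daily probability — corrected to
   Beta(0.308674, 99.691326), preserving α+β ≈ 100;
2. the healed-state cost gamma scale implies £0.19/day against the stated
   £1.89 — treated as a ten-fold scale typo;
3. the open and healed utility beta rows have means 0.757 and 0.671
   respectively, i.e. swapped relative to the stated state utilities —
   reassigned by matching means.

With the toggles on, every sampled parameter's expectation matches its
deterministic counterpart within 0.5% (closed-form beta/gamma means; a
test asserts this). `as printed` behaviour is available by switching the
toggles off.

Draws whose open-state exit probabilities could exceed 1 anywhere in the
horizon are rejected and redrawn rather than clamped (keeping the
distributions untruncated); the redraw count is logged and stored. All
three strategies are evaluated on the same draws. The engine is a
vectorised batch recursion over draws, verified draw-for-draw against the
scalar engine to 1e-12 relative.

The CEAC reports, at each threshold of a £0–£50 000 grid in £1 000 steps,
the fraction of draws in which each strategy has the highest net monetary
benefit, ties split equally.

## Subgroups

The subgroup analysis fixes the covariate profile at each cell of an
ulcer-size × duration × infection grid (defaults: {1, 5, 10} cm² crossed
with {30, 90, 180} days, infected and not — six scenarios) and reports
*incremental* NMB of each active strategy versus standard care at
£20 000/QALY, computed from PSA mean costs and QALYs with the same seed
for every profile (profiles then differ only through covariates).
Incremental NMB is the chosen definition because a single NMB per active
treatment only has meaning against a comparator. Profiles outside the
generator's covariate support produce a warning, not a failure.

## Value of information

Per-patient EVPI is the mean over PSA draws of the best-achievable NMB
minus the best average strategy's NMB. Population EVPI multiplies by an
annual incidence (defaults 50 000 and 100 000) over a one-year decision
horizon, undiscounted — consistent with the model horizon; the identity
`population = per-patient × incidence × horizon` is enforced and tested.

EVPPI uses two-level nested Monte-Carlo (defaults 1000 inner × 250 outer)
for three registered groups: the high-dose coefficient of the survival
model only (*high_dose_effect*), the three daily state costs, and the
three state utilities. The outer loop fixes the group at a fresh draw;
the inner loop integrates the complement — for the high-dose coefficient
the remaining survival parameters are drawn from their Gaussian
conditional given the fixed value, preserving the fit correlations.
Estimates are floored at 0, with the raw (possibly slightly negative)
value logged and reported in metadata. A generic `nested_evppi` engine is
exposed and validated against a closed-form two-parameter toy model.

## Synthetic trial generator

The generator emulates the pilot study the analysis presumes: 74 patients
allocated 1:1:1 (largest-remainder, then a random permutation → arm sizes
{25, 25, 24}), followed 183 days. Healing times are drawn by inverting
the Weibull PH survival function; amputation and death are independent
daily Bernoulli events at the cohort model's daily probabilities; the
first event wins (healing takes precedence on a tied day) and times are
recorded to the nearest day (minimum 1). Defaults, chosen once as
plausible for this population and fully exposed in `TrialConfig`:

* shape γ = 1.1 and baseline log-rate β₀ = −5.7, giving roughly half of
  standard-care ulcers healed within six months;
* hazard ratios 2.0 (high dose) and 1.35 (low dose), with ulcer age
  (−0.001/day), area (−0.04/cm²) and infection (−0.3) slowing healing;
* ulcer age uniform on [30, 365] days, area log-uniform on
  [0.5, 12] cm², infection Bernoulli(0.4) — spanning the subgroup grid;
* per-state utility observations from beta distributions moment-matched
  to mean/sd (0.671/0.20, 0.316/0.20, 0.757/0.15);
* resource-use counts Poisson with per-day, per-state rates and unit
  prices on an NHS outpatient-tariff scale.

What the generator does *not* emulate: sham-procedure blinding effects,
within-patient correlation beyond the covariates, dressing-level billing,
or any claim of fidelity to a real trial's effect sizes — the treatment
effects are configuration, not evidence. Passing tests therefore show
that the analysis machinery is correct under its own assumptions, not
that ESWT works.

A consequence worth stating: at n = 74 the high-dose log-hazard-ratio is
estimated with a standard error near 0.45, so different generator seeds
produce deterministic results on either side of dominance. That
instability is the pilot-scale parameter uncertainty the PSA and VOI
stages exist to quantify, and it is why the per-patient EVPI under the
default conditions is large relative to the intervention cost.

## Numerical choices and problem sizes

* QALY accrual divides by 365, matching the 365-cycle year.
* Cohort traces are validated row-stochastic to 1e-10 and checked against
  a transition-matrix-power oracle to 1e-9; the telescoping identity
  Π(1 − p_t) = S(365) holds to 1e-12.
* Cholesky reconstruction error is bounded at 1e-8; money is reported at
  2 dp, QALYs and probabilities at 3 dp.
* Test and acceptance runs use the analysis's stated sizes where cheap
  (1000 PSA draws, 1000 × 250 VOI loops, 365 cycles) and smaller nested
  loops in unit tests of VOI internals; parameter-recovery tests use
  n = 2000–5000 synthetic patients, where estimates sit within ~2% of
  truth.

## Known limitations

* One aggregated open-ulcer state (no ischaemia/gangrene split), one
  ulcer episode per patient, one-year horizon.
* Recurrent ulcers reuse the time-since-entry hazard (no tunnel states).
* The EVPPI estimator is plain nested Monte-Carlo; regression-based
  approximations are out of scope.
* Interval-censoring is ignored (event days are treated as exact).
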