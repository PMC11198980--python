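# Methods

## The scientific problem

In cohorts of patients with mild cognitive impairment (MCI), progression to
Alzheimer's disease and related dementias (AD/ADRD) competes with death:
death censors the dementia outcome, but not vice versa, and the two times
are positively correlated through shared, largely unobserved biology.  A
standard Cox model of time-to-dementia that codes death as random censoring
therefore conditions on an informatively selected risk set and can bias
hazard-ratio estimates.

This package implements the semi-competing-risks treatment of the problem:
an illness-death multistate model with three transitions (MCI → dementia,
MCI → death, dementia → death) and a shared subject-level frailty, its naive
Cox comparator, the diagnostics used to justify the model, and a synthetic
cohort generator so that every stage of the analysis runs and is tested
without access to protected health data.

## The model

Each subject carries a frailty `α ~ Gamma(shape 1/θ, rate 1/θ)` (mean 1,
variance θ ≥ 0) multiplying all three transition hazards:

    h_g(t | α, x) = α · κ_g λ_g t^{κ_g − 1} · exp(x'β_g),   g = 1, 2, 3

with Weibull baselines `H_{0g}(t) = λ_g t^{κ_g}`.  The transition-3 hazard
runs either on absolute time (Markov clock) or on the sojourn since illness
onset (semi-Markov clock); the semi-Markov clock is the default because
mortality after a dementia diagnosis is most naturally indexed by disease
duration.  Both clocks coincide exactly when κ₃ = 1 (memorylessness), which
the tests exploit as an invariant.

Observed data per subject are `(y₁, δ₁, y₂, δ₂, x)` on the wedge `y₁ ≤ y₂`,
with `y₁ = y₂` whenever `δ₁ = 0`.  Given α, a subject with event count
`d = δ₁ + δ₂` and total conditional cumulative hazard

    H = H₀₁(y₁) e^{x'β₁} + H₀₂(y₁) e^{x'β₂} + δ₁ · ΔH₃ e^{x'β₃}

(ΔH₃ accrued from illness to death/censoring on the configured clock)
contributes `[event log-hazards] + d log α − α H`.  Integrating the gamma
frailty analytically gives the marginal contribution

    [event log-hazards] + Σ_{j<d} log(1 + jθ) − (1/θ + d) log(1 + θH),

which reduces to the independent likelihood as θ → 0.  Because `d ≤ 2`, the
gamma-function ratio is evaluated exactly as `log1p(θ)` when `d = 2` (and
zero otherwise) rather than as a difference of `lgamma` values; this keeps
the likelihood accurate to ~1e−9 down to θ = 1e−10, where the naive
`lgamma(1/θ + d) − lgamma(1/θ)` form loses six digits to cancellation.

### Estimation

Maximum marginal likelihood over `(β₁, β₂, β₃, log κ, log λ, log θ)` with
L-BFGS-B and a hand-derived analytic gradient (verified against central
finite differences in the tests).  Standard errors come from the inverse
numerical Hessian on the optimisation scale; hazard ratios are `exp(β)` with
95% Wald intervals and two-sided p-values, no multiple-testing adjustment
(significance threshold 0.05 throughout, matching the comparison's
convention).

Numerical choices:

- Initialisation: moment-style start — β = 0, κ = 1, transition rates =
  events/person-time, θ = 0.5 — plus two jittered restarts (SD 0.1, fixed
  sub-seed), keeping the best optimum.  Fits are deterministic given data
  and options.
- The θ = 0 boundary: the no-frailty submodel is fitted separately, and the
  better likelihood is reported with a boundary flag (a log-scale optimiser
  cannot reach θ = 0 exactly).
- Convergence: optimiser success or gradient max-norm below 1e−3 on the
  optimisation scale; the gradient norm is always reported.
- Same-day illness and death (`y₁ = y₂`, both indicators 1) are accepted on
  input; half a day is added to the death time for the transition-3 sojourn
  so the sojourn hazard is well defined.  The alternative (dropping such
  rows) discards exactly the fast progressors.
- Degenerate inputs fail loudly: constant covariates, transitions with no
  events, invalid observation patterns, and non-finite likelihoods raise
  named errors instead of returning garbage.

### Absolute risk

The cumulative incidence of dementia by horizon `t` marginal over the
frailty,

    F₁(t|x) = ∫₀ᵗ h₀₁(s) e^{x'β₁} (1 + θ A(s))^{−(1/θ+1)} ds,
    A(s) = H₀₁(s) e^{x'β₁} + H₀₂(s) e^{x'β₂},

is evaluated by adaptive quadrature (`exp(−A)` integrand at θ = 0).  It is
validated against Monte-Carlo estimates from the simulator at three
horizons and collapses to the plain Weibull CDF when the death hazards
vanish.

## The Cox comparator and diagnostics

The naive analysis codes `(y₁, δ₁)` as the outcome — death and dropout both
as plain censoring — and fits a Cox model by Newton-Raphson with
step-halving on the log partial likelihood (Efron tie correction by
default, Breslow available; the two coincide exactly without ties).  The
fitter is written here rather than delegated so that the comparison between
the naive and joint analyses shares no code; it is checked against
exhaustive 1-D maximisation on tiny datasets and against lifelines
(coefficients and standard errors to 1e−5).

Proportional hazards are tested with the Grambsch–Therneau score test on
scaled Schoenfeld residuals, regressing on a transform of event time
(Kaplan–Meier by default, identity and rank available).  The per-covariate
statistic matches lifelines' implementation to three digits; its type-I
error under a hazards-proportional simulation sits in [0.03, 0.08] at
nominal 0.05, and a sign-flipping time-varying effect is detected with
power > 0.8 (n = 500 per replicate).

The dependence check is the Pearson correlation between the two event
indicators with its two-sided p-value.  Note a subtlety the tests encode:
even with θ = 0 the *observed* indicators are not exactly uncorrelated —
the shared observation window and the competition between events leave a
small structural (typically negative) correlation at realistic event rates,
vanishing in the rare-event limit.  Shared frailty flips the correlation
clearly positive (r ≈ 0.32 at θ = 2 in the bundled study), which is the
qualitative signature motivating the gamma-frailty assumption.

## The synthetic cohort generator

The generator emulates an EHR-derived MCI cohort: baseline covariates drawn
from independent per-variable marginals (Bernoulli prevalences, truncated
normals for age and BMI, categoricals for race/ethnicity and smoking,
expanded to indicators against the reference levels Male and non-Hispanic
White), and event times drawn from the frailty illness-death process by
inverse-CDF sampling — frailty first, then the race between the illness and
pre-illness death hazards, then (if illness wins) a transition-3 death time
on the configured clock.  Censoring is administrative at τ = 8 years plus
uniform dropout on (0, τ).  Covariate, event and censoring draws use split
sub-streams of one seed, so stages are independently reproducible.

Default marginals reproduce the reference baseline table's majority
(dementia-free) column: e.g. hypertension 64.5%, age ~ truncated
N(59.4, 21.2²) on [18, 110].  The full-cohort configuration
(`table1_config`) sets the onset log hazard ratios to the published
joint-model estimates for the matching predictors, plausible mortality
effects for transitions 2 and 3, θ = 1, and baseline rates calibrated once
so event fractions land broadly near the reference cohort's (~18%
dementia, ~20% mortality per group over the 8-year window); exact rates are
deliberately not a calibration target, since the reference follow-up and
censoring distributions are unpublished.

What the generator does *not* emulate — and therefore what passing tests do
not establish about real EHR data: visit processes and diagnosis-code
phenotyping, covariate correlation (an optional Gaussian-copula hook is out
of scope), measurement error and missingness, left truncation, and
time-varying covariates.  Tests on generated cohorts validate the
estimators under the model's own assumptions, not robustness to their
violation.

## Study designs fixed by the package

- Parameter recovery: 50 replicates of n = 2,000, p = 3 (two Bernoulli, one
  truncated-normal covariate), θ = 1, sojourn clock.  Mean absolute bias of
  each onset coefficient stays below 0.05 and Wald 95% coverage is within
  [0.88, 1.00].
- Discordance study (`death_only_covariate_config`): a covariate with a
  mortality hazard ratio of 6 on both death transitions, no effect on
  onset, θ = 2, n = 8,000.  Frailty selection then drags the naive
  cause-specific hazard ratio for that covariate below 1 (the survivors
  with the covariate are the low-frailty ones) while the joint model stays
  at the null; the two-column report flags the covariate as
  significance-discordant in ≥ 80% of seeds.  Sample size and effect were
  chosen once from a power consideration — the naive fit needs enough
  events to reach spurious significance reliably — and then frozen.  This
  reproduces, directionally, the phenomenon in which predictors such as
  renal disease, traumatic brain injury and visual impairment lose
  significance once death is modelled as a semi-competing risk.
- The bundled analysis (`analysis/01…05`) runs the full pipeline on a
  20,000-subject, 45-encoded-predictor cohort: simulate → validate → flow
  counts and baseline table → both fits → Schoenfeld tests and indicator
  correlation → two-column hazard-ratio comparison.

## Known limitations and discrepancies

- Estimation is frequentist maximum marginal likelihood; Bayesian posterior
  sampling for this model family is out of scope.
- Weibull baselines are an explicit parametric choice (they admit the
  closed-form frailty marginal); nonparametric or piecewise-constant
  baselines are not implemented.
- The reference publication's results section states "5890 (23.5%) of them
  died" among dementia patients; 5,890 is that group's size and 23.5% of it
  is 1,383, the death count its baseline table reports.  The flow-count
  arithmetic here follows the baseline table.
- No left truncation, time-varying covariates, subtype-specific outcomes,
  or real-EHR ingestion.
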