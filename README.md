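# semicompete

Semi-competing-risks analysis of progression from mild cognitive
impairment (MCI) to Alzheimer's disease and related dementias (AD/ADRD)
with death as a terminal event.

In an MCI cohort, death censors the dementia outcome but not vice versa,
and the two event times are positively correlated.  Treating death as
plain random censoring in a Cox model of time-to-dementia conditions on an
informatively selected risk set and can bias hazard ratios.  This package
implements the joint alternative — an illness-death multistate model with
shared gamma frailty — together with everything needed to run and stress
the comparison end to end on synthetic data:

- **`semicompete.illness_death`** — the core model.  Three Weibull
  proportional-hazards transitions (MCI → AD/ADRD, MCI → death,
  AD/ADRD → death), a shared frailty `α ~ Gamma(1/θ, 1/θ)` (mean 1,
  variance θ) multiplying all three hazards:

      h_g(t | α, x) = α · κ_g λ_g t^{κ_g−1} · exp(x'β_g),  g = 1, 2, 3

  with the frailty integrated out of the likelihood in closed form,
  maximum marginal likelihood fitting (analytic gradient, Wald inference),
  Markov or semi-Markov transition-3 clock, and cumulative-incidence
  prediction `F₁(t|x)` under competing death.
- **`semicompete.cox`** — the comparator: a from-scratch Cox
  partial-likelihood fitter (Efron/Breslow ties), Grambsch–Therneau
  proportional-hazards tests on scaled Schoenfeld residuals, the
  dementia/death indicator correlation check, and the two-column
  hazard-ratio comparison with significance-discordance flags.
- **`semicompete.cohort`** — the data model: validated semi-competing-risks
  tables on the wedge `y₁ ≤ y₂`, CSV I/O with schema remapping, study-flow
  counts and baseline-characteristics tables.
- **`semicompete.simulate`** — a synthetic EHR-like cohort generator:
  ~41 baseline predictors at reference prevalences and event times drawn
  from the frailty illness-death process, with administrative + dropout
  censoring and a latent ground-truth side file for testing.
- **`semicompete.pipeline`** / the `semicompete` CLI — one-command runs of
  the whole analysis with a reproducibility manifest.

## Worked example

```python
import semicompete as sc

cfg = sc.demo_config(n=2000, seed=42)          # 5 predictors, theta = 1
cohort, truth = sc.generate_cohort(cfg)

fit = sc.fit_mle(cohort, clock="semi-markov")
print(f"theta = {fit.estimates.theta:.2f}, loglik = {fit.loglik:.1f}")

t1 = fit.hr_table[fit.hr_table.transition == 1]
age = t1[t1.covariate == "age_dec"].iloc[0]
print(f"onset HR per decade of age: {age.hr:.2f} "
      f"({age.ci_low:.2f}, {age.ci_high:.2f})")

risk = sc.cif_nonterminal([1.0, 1, 1, 0, 0], 5 * 365.25, fit.estimates)
print(f"5-year dementia risk for a hypertensive woman aged 70: {risk:.1%}")
```

prints (exactly, for this seed):

```
theta = 0.86, loglik = -8232.5
onset HR per decade of age: 1.62 (1.50, 1.75)
5-year dementia risk for a hypertensive woman aged 70: 29.2%
```

The frailty variance is recovered near its generating value of 1, the age
effect per decade near its generating `exp(0.45) ≈ 1.57`, and the absolute
risk accounts for the competing risk of death — the same quantity computed
by naively inverting a censoring-blind Kaplan–Meier curve would be larger.

The full analysis on a 20,000-subject, 45-encoded-predictor cohort lives in
`analysis/01_simulate_cohort.py` … `05_hr_comparison.py`; each script
prints what it found and writes its tables under `results/`.  The same
pipeline is available as
`semicompete run --config cfg.yaml --outdir results/`.

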