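# Methods

## Model structure and assumptions

The package simulates one screening encounter per eligible adult aged 25–65
in India, in three stages: (1) estimate stratum-specific disease burden from
study-level evidence, (2) screen a weighted synthetic population, (3) cost
the programme and project complication benefits among detected cases. It is
a cross-sectional microsimulation: no aging, incidence or mortality
dynamics, and screening happens once per person (spread over the costing
horizon only for discounting).

Population heterogeneity enters at two levels: 24 demographic strata (age
band 25–44 / 45–65 × sex × urban/rural × income tertile of the standard of
living index), and person-level correlated risk factors within stratum.
Disease status is Bernoulli at the stratum prevalence; diagnosis status is
Bernoulli at the stratum probability of being undiagnosed given diabetes.
Previously diagnosed persons are ineligible for screening, which is what
reduces the 586 million national total to roughly 567 million eligible.

## Meta-regression (disease burden)

Study-level proportions are modelled as a linear function of moderator
*shares* (fraction of each study's sample in the non-reference category of
each demographic family: age 45–65, male, urban, income mid/high) plus
calendar year, with a between-study random effect. Choices:

- **Working scale.** Default logit, with delta-method variances
  `v_logit = v / (p(1−p))²`, so stratum predictions are automatically inside
  [0,1]. A raw-proportion scale is available for fidelity to the pooled
  model as conventionally written; its out-of-range predictions are clamped
  and logged, never silent.
- **Between-study variance.** τ² by restricted maximum likelihood, profiled:
  for candidate τ², coefficients come from GLS with weights 1/(vⱼ+τ²); the
  REML objective is optimised by bounded scalar search with an explicit
  check of the τ²=0 boundary. `tau2=0` can be pinned to obtain the
  fixed-effect inverse-variance limit, which must (and in tests does) agree
  with brute-force weighted least squares to 1e-8.
- **Coding.** One reference category per family is dropped (reference
  stratum: 25–44, female, rural, low income); year is centred at 2015.
  Collinear designs are rejected with the offending columns named (QR with
  column pivoting).
- **Uncertainty propagation.** Coefficient vectors are drawn from
  N(β̂, V̂) per outcome and mapped to full 24-stratum surfaces. On synthetic
  evidence bases with known truth, coefficient recovery falls within 2
  estimated SE ≥ 90% of the time (20 seeds × 7 coefficients), and the
  stratum-probability credible intervals cover the truth in ≈ 94% of
  stratum × replicate checks. Coverage is checked per stratum across 50
  replicate evidence bases rather than at a single extreme stratum, where
  the 50-trial binomial noise would dominate. The implementation was
  cross-checked against R `metafor::rma(method="REML")` on a shared fixture
  (coefficients to ~1e-5).

## Synthetic inputs

The real evidence base (58 published cohort studies, n = 447,481) and the
joint biomarker distributions are not machine-readable, so the package
generates statistically analogous inputs with known truth:

- **Cohort studies.** Per study: moderator shares from Dirichlet mixing
  distributions centred on the national marginals (concentration 4 per
  family); sample size log-normal (median 5,000, log-SD 0.8); year uniform
  1990–2014; true outcome proportion = truth linear predictor + N(0, σ_b)
  between-study effect (σ_b = 0.25 on the log-odds, 0.03 on raw
  proportions); observed proportion = Binomial(n) draw with a 0.5/(n+1)
  continuity guard; recorded sampling variance p̂(1−p̂)/n.
- **Truth coefficients** are calibrated once so the implied national pattern
  matches the headline burden figures: overall prevalence 12.0% (urban
  ≈ 18.8%, rural ≈ 8.6%), probability undiagnosed given diabetes 73.3%
  (higher among women, rural residents and the poor), leaving ≈ 567 million
  eligible of 586 million.
- **Risk-factor profiles.** Gaussian copula over eight continuous factors —
  Normal marginals for blood pressure, BMI, waist and LDL; log-Normal for
  random glucose, fasting glucose and HbA1c — with a single documented
  correlation matrix (BP pair 0.7, BMI–waist 0.8, glucose pair 0.7,
  glycaemia–HbA1c 0.5–0.6, adiposity–BP 0.2–0.25, weaker cross-links;
  smallest eigenvalue 0.2). Means/SDs are status-conditional: undiagnosed
  diabetics sit higher on every glycaemic marker (random glucose median 8.2
  vs 5.3 mmol/l; fasting 8.8 vs 4.9), so diabetic glucose stochastically
  dominates — the property glucometer screening and confirmatory testing
  rely on. Family history, physical activity, smoking and prior
  cardiovascular disease are status-conditional but stratum-constant
  categorical draws; age is uniform within band.
- **Unit costs** are documented placeholders (questionnaire \$0.05,
  glucometer \$0.15, confirmatory laboratory test \$1.75 per person,
  overhead \$0.02 per person-year, 2014 US dollars), chosen so confirmatory
  testing dominates programme cost. They are not authoritative cost
  estimates and are fully overridable.

What the generator does *not* emulate: real-world study selection bias
(published cohorts under-represent the poorest rural areas), non-Gaussian
dependence between risk factors, stratum-varying categorical prevalences,
and the empirical national operating points of the instruments. Passing
tests therefore demonstrate that the machinery is correct on data with the
assumed structure, not that the synthetic operating characteristics equal
the national ones: for example the Mohan score is more specific, and
glucometer screening more sensitive, here than in the national estimates,
so referral volumes (and hence which questionnaire is dearest) differ.
Quantities that are arithmetic consequences of burden counts (NNS,
false:true ratio, cost per case) are validated against the published counts
directly.

## Screening

- **Instruments** are declarative: items map a factor to ordered, mutually
  exclusive, exhaustive categories with non-negative integer points (gaps
  raise an error naming the factor); the score is the sum and the screen is
  positive at score ≥ cut point, inclusive. Encodings live in YAML data
  files, not code. Interval edges at printed integer boundaries are encoded
  half-open on the continuous factor (e.g. Chaturvedi female waist ≤ 75 /
  (75, 85] / > 85 cm; "age > 49" as ≥ 50). The blood-pressure item scores
  the worse of the systolic and diastolic categories. Two level-mapping
  choices were forced by the three-level activity factor and the combined
  parent/sibling family-history factor: Ramachandran "sedentary" maps to the
  no-exercise-and-no-strenuous-work level only, and Mohan family-history
  gives the single-parent points to the combined parent-or-sibling level.
- **Glucometer.** Measured value = true random glucose + N(0, 0.9 mmol/l)
  additive device error, fresh per encounter; positive at ≥ 6.1 mmol/l.
- **Combinations.** Serial = both positive, second test administered (and
  costed) only for first-stage positives; parallel = either positive, both
  tests administered to all. Serial classification is order-symmetric;
  staged test counts are not.
- **Truth and metrics.** A case is an eligible person with fasting glucose
  ≥ 7.0 mmol/l — the confirmatory criterion — so generator diabetics whose
  fasting value sits below 7.0 count as non-cases. All counts are weight
  sums in millions; undefined ratios (NNS with zero true positives) are NaN
  markers, never exceptions.
- **Recalibration.** ROC curves sweep every achievable score threshold
  (glucometer: a 0.1 mmol/l grid), with below-/above-range thresholds
  supplying the (1,0) and (0,1) endpoints; the recalibrated cut point
  maximises sensitivity × specificity, ties broken toward higher specificity
  (fewer referrals). Curves are computed on weighted (national) persons.

## Costs

Discount factor = Σ_{t=0}^{h−1} (1+r)^{−t} (year 0 undiscounted); defaults
h = 10 years, r = 3%. The population is screened at uniform annual
throughput over the horizon, so every component is scaled by (discount
factor)/h. Components: staged screening tests × unit costs, confirmatory
test × referrals, overhead per person screened per year. Cost per case
found = total / true positives. Costs are linear in unit costs and
non-decreasing in referrals by construction.

## Complications and NNST

The risk-equation stage is an interface: any mapping from a biomarker
profile to per-endpoint 20-year probabilities can be plugged in (e.g.
published diabetes outcome models). The shipped default is a parametric
logistic form, `expit(b₀ + Σ c_k (x_k − center_k)/scale_k)` with c_k ≥ 0
enforced, over five endpoints (heart disease events, stroke, blindness,
diabetic ulcer, renal failure); macrovascular endpoints load mainly on
blood pressure, LDL, smoking and age, microvascular on HbA1c. Best-case
treatment clamps SBP to ≤ 140 mm Hg, LDL to ≤ 2.6 mmol/l (≤ 1.8 with
cardiovascular history) and HbA1c to ≤ 7%, never raising a value, so
treated risk ≤ untreated risk for every person and endpoint. NNST per
endpoint = 1 / weighted mean absolute risk reduction among detected cases;
the any-complication probability assumes conditional independence of
endpoints given the profile. The minimum per-endpoint NNST and the
any-complication fraction answer different questions and are reported
separately, not forced to agree. An optional behavioural-modification
multiplier on microvascular endpoints is off by default.

## Uncertainty pipeline

Each Monte Carlo draw redraws the prevalence-model coefficients *and* the
person sample, so the intervals include both parameter and person-sampling
uncertainty. Random numbers are hierarchical: a root `SeedSequence` spawns
one child per draw, making per-draw results independent of execution order
and the whole run reproducible (same config + seed ⇒ byte-identical
report). Draw-level failures are logged, discarded and counted. Intervals
are empirical 2.5/50/97.5 percentiles with linear interpolation between
order statistics (the 2.5th percentile of 10,000 draws is the 250.975-th
order statistic); the median is the point estimate, with the mean also
reported.

## Problem sizes and defaults

Defaults are 200,000 weighted persons and 500 draws — sizes at which a full
run takes a few minutes on one CPU and interval endpoints are stable to
within a few percent; 10,000 draws reproduce the full uncertainty analysis
at proportional cost. The test suite uses smaller sizes (5,000–200,000
persons, 3–100 draws) chosen so each assertion's Monte Carlo error is well
inside its tolerance.

## Known limitations

- Operating characteristics depend on the synthetic joint distributions;
  they are structurally, not numerically, faithful to the national setting.
- Screening is a single cross-sectional pass: no repeat screening rounds,
  no incidence between rounds, no mortality.
- The default risk equations are stand-ins with plausible monotone
  structure, not validated clinical models; NNST outputs should be read as
  machinery demonstrations until a published equation set is plugged in.
- Costs use placeholder unit values; only their structure (confirmatory
  dominance, linearity, discounting) is meaningful.
- The meta-regression assumes independent study errors and main effects
  only; no publication-bias diagnostics or moderator interactions.
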