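# Methods

## Model structure and assumptions

The model is a deterministic Markov cohort simulation with annual cycles
and four states: *at risk of T2D*, *T2D*, *T2D with complications*, *dead*.
Movement is strictly forward (no remission, no skipping from at-risk
directly to complications). Each stratum — gender × entry age × FINDRISC
group (0–6, 7–11, 12–14, 15–19, 20–26 points) — starts 100% at risk.
The comparator arm is current practice (no programme); the intervention
arm charges recruitment (24.5€) and intervention (650€) per reached person
at cycle 0 and multiplies the T2D incidence hazard by HR 0.74 for cycles
1–15, after which the effect ends immediately with no catch-up adjustment.
All reached persons are assumed to receive the intervention and its cost.

Cycle conventions, chosen for reproducibility where the published analysis
is silent, and all exposed in the code rather than hidden:

- **No half-cycle correction.** State rewards (costs, utilities) accrue at
  cycle end on the post-transition occupancy; the one-off programme costs
  sit at cycle 0 undiscounted. Discounting is value/(1+r)^cycle with
  r = 0.03 by default.
- **Competing risks.** Within a cycle, mortality is applied first and
  incidence/complication probabilities to the survivors: the off-diagonal
  cells are q and (1−q)·p, which keeps rows stochastic without
  renormalization.
- **Ageing.** The cohort ages one year per cycle. Hazard and reward
  lookups use the age at cycle start; the utility band switches at the
  band boundaries (30–44, 45–54, 55–64, 65+) and productivity losses stop
  at age 65 exactly. Ages beyond the life table's last row reuse that
  row's probability; ages beyond 79 keep the 65+ utility band.
- **Complication clock.** The complication Weibull is indexed by time
  since T2D diagnosis. Rather than expanding tunnel states, each stratum
  carries one auxiliary accumulator: the occupancy-weighted mean duration
  in the T2D state (new entrants arrive with duration 0, stayers age by
  one year). The complication regression's age covariate is evaluated at
  the implied age at diagnosis (current age − mean duration). This is an
  approximation to the true duration mixture; it is exact while the T2D
  state is fed by a single entry cohort and errs toward averaging
  thereafter.
- **Mortality stacking.** T2D excess mortality uses gender-specific hazard
  ratios (women 2.47, men 1.93) applied to the life-table probability via
  1 − (1−q)^HR; the complications state multiplies a further HR 2.36 on
  the hazard scale. Multiplicative stacking is an interpretation of
  "further increased risk"; it is conservative relative to replacing the
  T2D HR and is flagged here as a modelling choice.

## Survival models

T2D incidence and complication onset are Weibull proportional-hazards
regressions, S(t|x) = exp(−exp(x′β)·t^ρ), fitted by full maximum
likelihood under right censoring with analytic gradient and Hessian
(safeguarded Newton iterations warm-started from the concave exponential
fit). The covariance over (β, ln ρ) is the inverse observed information;
AIC/BIC support an exponential-vs-Weibull comparison via a fixed-shape
refit, and the joint Wald chi-square test covers the non-intercept block.
An AFT (accelerated failure time) dialect is accepted for externally
estimated coefficient tables, whose coding (parameterization, reference
levels) must be declared explicitly rather than guessed; AFT and PH forms
are exact reparameterizations for the Weibull.

Annual transition probabilities come from conditional survival,
p(t) = 1 − S(t+1|x)/S(t|x), with incidence indexed by time since model
entry (covariates frozen at baseline, as fitted) and complications by time
since diagnosis. Literature hazard ratios act on probabilities through the
exact rate-scale identity 1 − (1−p)^HR, which composes multiplicatively.

## Parameter distributions

Each uncertain input carries a sampling distribution reproducing its
published summary exactly:

- costs: gamma with shape (m/s)², scale s²/m; where only a ±25% range is
  published the SE is (1.25m − 0.75m)/(2·1.96);
- utilities and disutilities: beta, from explicit alpha/beta pairs where
  published, otherwise by method of moments from mean and SE;
- hazard ratios: lognormal with location ln(point estimate) and log-scale
  (ln hi − ln lo)/(2·1.96) taken from the CI — self-consistent with the
  interval even where a printed natural-scale SE disagrees;
- Weibull coefficient blocks: one joint multivariate normal draw per fit
  over (β, ln ρ) using the full fitted covariance, so the coefficient
  correlation structure propagates into the PSA. Loaded coefficient
  tables combine an SE column with a correlation matrix as D·R·D.

PSA draws violating a support constraint (for example sampled disutilities
exceeding a sampled baseline utility) are rejected and redrawn, preserving
the stated marginal distributions elsewhere; redraws are logged. Results
report 2.5/97.5 sample percentiles of 1000 iterations as the 95% interval;
the point estimate is the deterministic run and can in principle fall
outside the percentile band. Cost-effectiveness-plane points landing
exactly on an axis are counted as saving/gaining and logged.

## The reached cohort

Per-stratum counts are population × pharmacy-visit rate × T2D-free
fraction × reach rate (9.9% = 662/6705 completions per handed-out form) ×
FINDRISC share, computed on integer ages 30–79 and rounded by the
largest-remainder method within gender so gender totals are conserved
exactly. The shipped base case aggregates entry ages into 5-year groups
(count-weighted mean age per group); the builder also supports 1-year
resolution. The default run therefore simulates 50 strata per gender over
20 annual cycles, and the PSA re-runs both arms 1000 times — about half a
minute on one CPU.

## Synthetic inputs and what they do (not) show

The source follow-up datasets (national cohort follow-up for incidence,
regional EHR data for complications), the national life table and the
pharmacy-visit tables are restricted, so the package generates synthetic
stand-ins with known ground truth:

- **Incidence**: Weibull PH with shape 1.3, age coefficient 0.02/year,
  gender coefficient 0.10, and FINDRISC-group effects anchored once to the
  published FINDRISC 10-year risk table (≈1/4/17/33/50% for the five score
  groups at the reference age 55). Event times are inverse-CDF draws,
  censored administratively at 10 years.
- **Complications**: shape 1.2, ≈40% cumulative incidence at 10 years for
  a 60-year-old; default scale 1151 subjects / 9-year horizon, mirroring
  the source EHR cohort.
- **Life table**: Gompertz form a·e^{b·age} (b = 0.09; men about twice
  women's level), tabulated to age 110.
- **Cohort tables**: visit rates rising with age within [0.30, 0.90] with
  population-weighted mean 0.61; a calibration mode rescales population
  counts per gender so the reached cohort totals 180 774 (100 399 women,
  80 375 men). FINDRISC shares default to 0.02/0.08/0.30/0.40/0.20 —
  mass concentrated above the programme-eligibility score of 12, with
  small below-threshold shares retained because screening reaches them
  too.

The reference survival models are obtained by *fitting* the generators'
output at the source studies' scale, so the PSA's coefficient covariance
is a genuine MLE covariance. Every generator is a pure function of its
seed.

What passing tests show: the estimation, extrapolation, cohort mechanics,
economics and sensitivity machinery are correct against independent
oracles (closed-form MLEs, matrix-product enumeration, analytic
distribution quantiles, external survival libraries). What they do not
show: agreement of euro magnitudes with any particular real population —
the synthetic incidence anchor is deliberately generic, produces a
higher-risk cohort than a specific national dataset would, and no attempt
is made to match restricted data statistically. Qualitative conclusions
(dominance of the programme, NMB sign change near the upper effectiveness
bound, effectiveness and discount rate driving the tornado) are the
transportable outputs.

## Numerical choices and degenerate inputs

- Newton fitting converges when the gradient's infinity norm falls below
  10⁻⁶ relative to the attained log-likelihood; non-convergence and
  all-censored data raise errors rather than returning partial fits.
- S(t) = 0 during probability conversion yields probability 1 with a
  warning; transition rows are validated to [0,1] and clipped only for
  floating-point dust.
- Model selection: lowest AIC, ties broken by lowest BIC, then fewest
  parameters.
- An empty cohort runs to a zero-valued result with a warning; a zero
  reach rate produces an empty cohort.
- Payback is reported in whole years (the first cycle index at break-even)
  or none within the horizon; a stream with no positive savings never
  pays back.
- The largest-remainder rounding distributes the fixed total by falling
  fractional part with a stable sort, making cohort construction
  deterministic.

## Known limitations

- The mean-duration approximation of the complication clock understates
  duration heterogeneity once T2D entry is spread over many cycles.
- Mortality HR stacking for the complications state is multiplicative by
  assumption.
- The per-cycle ordering "intervention arm has less prevalent T2D than
  comparator" holds while the effect is active; after year 15 the larger
  surviving at-risk pool converts at full hazard and prevalence can cross
  over late in long horizons. This is a property of the specified effect
  profile, not a numerical artefact.
- No individual-level microsimulation, remission, repeat screening
  rounds, currency conversion, or alternative parametric families beyond
  the exponential-vs-Weibull comparison.
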