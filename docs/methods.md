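# Methods

## Model structure and assumptions

The package implements a three-step semi-mechanistic exposure–response
model for dapagliflozin as an adjunct to basal–bolus insulin in type 1
diabetes. The causal chain is: drug exposure → basal insulin dose
reduction → mean daily (CGM) glucose → HbA1c, with an additional direct
drug effect on HbA1c.

All drug effects are saturable Emax functions of the steady-state 24-h
AUC. Three structural assumptions are deliberate simplifications,
consistent with the time course of the observations the model targets:

* **Instantaneous, sustained insulin effect.** The basal dose reduction
  appears at treatment start and is constant thereafter; no onset
  dynamics are parameterized. Trial insulin dose trajectories show the
  drop established by week 2 and sustained.
* **Instantaneous HbA1c transform.** HbA1c is an algebraic function of
  the current glucose ratio and exposure, with no turnover compartment;
  the observed HbA1c response is nearly complete by week 4, and no rate
  constant is carried in the parameter set. An indirect-response
  extension would be straightforward but is not the default.
* **Fractional glucose drift.** `keff` is interpreted as a *fractional*
  increase of baseline glucose per week (glucose multiplied by
  `1 + keff·t`). An additive reading of 0.0015 mg/dL/week would produce
  a vanishing placebo response, incompatible with the observed 2–4%
  placebo glucose rise by week 24 and the ≈ +0.07 placebo HbA1c drift;
  the fractional reading reproduces both.

Bolus insulin is generated by the synthetic-data module but is not a
model driver: its within-day compensatory dynamics destroy any
association with mean daily glucose, and the exploratory regression on
generated cohorts reproduces that null (slope ≈ 0 with RSE far above
100%).

## Parameters

| parameter | units | default | role |
|---|---|---|---|
| Imax_ins | – | 0.0941 | max fractional basal insulin reduction |
| IAUC50_ins | ng/mL·h | 38.8 | half-maximal exposure, insulin effect |
| k1 | – | 0.0674 | glucose ~ (INS/INS0)^(−k1) coupling |
| keff | /week | 0.0015 | background fractional glucose drift |
| Imax_glu | – | 0.15 | max fractional glucose reduction |
| IAUC50_glu | ng/mL·h | 67.4 | half-maximal exposure, glucose effect |
| k2 | – | 0.165 | relative glucose → relative HbA1c slope |
| Imax_hba1c | – | 0.0421 | max direct fractional HbA1c reduction |
| IAUC50_hba1c | ng/mL·h | = IAUC50_glu | fixed, not independently estimable |
| b_ins, b_glu | – | 0.185, 0.162 | proportional residual errors |
| a_hba1c | HbA1c % | 0.061 | constant residual error |

Inter-individual variability: lognormal on Imax_ins (ω = 1.09) and k2
(ω = 0.739); additive normal on keff (ω = 0.003). The normal family for
keff is a deliberate choice: its dispersion is twice the population
value, implausible as a lognormal SD, and individual placebo subjects
do show negative glucose drifts, which a lognormal would forbid.
Individual Imax draws are clipped at 0.999 (the ω = 1.09 lognormal puts
≈1.5% of subjects above 1, which would produce negative doses); the same
clip is part of the estimation likelihood, so the fitted model is
exactly the simulated one.

## Simulation conventions

* The t = 0 visit is pre-dose: simulated baseline observations equal the
  subject's baseline (plus residual error). On-treatment structural
  predictions at t = 0 already include the instantaneous insulin and
  drug effects.
* Replicate summaries are "N populations of n subjects": the 95% CI is
  the 2.5/97.5 percentile of replicate population means, not a normal
  approximation. Scenario defaults are 500 × 500 with mean baseline
  HbA1c 8.48%.
* Scenario endpoints use the noise-free week-24 individual prediction;
  residual error is mean-zero and is excluded from population means by
  convention. Change from baseline is absolute for HbA1c (%-units) and
  percent for insulin/glucose.
* Scenario arms fix the AUC at the arm mean (51.4 / 130.6 / 294.5 /
  594.3 ng/mL·h for 1 / 2.5 / 5 / 10 mg).

### Effect decomposition bookkeeping

The direct-effect share at a dose is `(Δtotal − Δglucose-only) / Δtotal`,
where Δglucose-only is the mean response with the direct HbA1c Emax term
switched off. The background drift cancels in the numerator difference;
the denominator is the total mean response as reported (which includes
the drift). An alternative bookkeeping that nets the placebo drift out
of the denominator (`net_drift=True`) attributes the share to
drug-attributable change only and yields ≈ 57% instead of ≈ 65% at the
5–10 mg exposures; the default reproduces the two-thirds share that the
decomposition is usually quoted as.

## Synthetic cohorts

The generator emulates the two study templates used in model
development: a one-week inpatient dose-ranging study (placebo/1/2.5/5/10
mg, daily insulin + CGM, no HbA1c; the placebo protocol raises bolus
doses 40% and basal 10% at start) and a 24-week outpatient study
(placebo/5/10 mg; insulin at weeks 0/2/12/24, CGM at 0/12/24, HbA1c and
hemoglobin at 0/4/8/12/18/24).

Baselines are lognormal around the published medians with the log-SD set
so the central 95% spans the published (min, max), then clipped to that
range (clipping, unlike rejection, preserves the median under the
asymmetric printed ranges). Basal and bolus doses are each taken as half
the published total daily insulin dose, the typical basal/bolus split.
Per-subject exposure is lognormal around the arm mean with CV 40%,
emulating the observed dose-proportional exposure spread; this
within-arm spread is also what makes the two Emax parameters of each
step jointly identifiable in the recovery study (with arm-mean-only
exposure the two active design points determine the Emax curve exactly
and IAUC50 recovery is ill-conditioned). Hemoglobin rises 4% on average
under treatment but independently of HbA1c changes.

What the generator does **not** emulate: real CGM within-day dynamics,
dropout and dose interruptions, the transient 5% week-2 placebo basal
dip, correlated baseline covariates, or glucose-driven insulin
titration behaviour (insulin adjustment is exposure-driven, as in the
model). Passing recovery tests therefore demonstrate internal
consistency of estimator and simulator under the model's own
assumptions, not robustness to these real-data features.

## Estimation

Fitting is sequential, mirroring the development workflow: step 1
(insulin ~ AUC; IIV on Imax_ins, proportional error), step 2 (glucose ~
insulin ratio, AUC, time; IIV on keff, proportional error), step 3
(HbA1c ~ glucose ratio, AUC; IIV on k2, constant error, IAUC50 fixed to
the step-2 estimate). Each step has a single subject-level random
effect, so the marginal likelihood is a one-dimensional integral per
subject; it is computed by deterministic trapezoid quadrature on a
standardized grid (default 121 nodes over ±5 prior SDs), which is
accurate for the posterior widths these designs produce, keeps the
objective smooth, and vectorizes across all subjects. ω = 0 reduces
exactly to the fixed-effect residual likelihood, and a Monte Carlo
cross-check of the integral is part of the test suite.

**Upstream drivers.** Steps 2 and 3 need the subject's insulin ratio and
glucose ratio. Three modes are provided; the default is `"ebe"` —
individual empirical-Bayes predictions from the previous step (the
sequential individual-parameters approach). Conditional posterior
predictions are regression-safe drivers: the subject's deviation from
them is mean-zero given the data, so downstream slopes are not
attenuated. The `"observed"` mode (raw upstream measurements,
interpolated in time) is an errors-in-variables regression — with a 16%
proportional CGM error against a glucose-ratio signal SD of ≈ 6% it
attenuates k2 several-fold — and is provided for sensitivity analysis
only. The `"population"` mode cannot separate the insulin-mediated from
the direct glucose pathway when exposure varies only between arms.

**Propagated driver uncertainty.** With CGM at only two post-baseline
visits, the subject's glucose drift is weakly identified; plugging in
its point estimate would push the unexplained variation into the HbA1c
residual. Since the drift deviation enters the step-3 prediction
linearly (conditional on k2), it is integrated out analytically: the
subject's HbA1c vector is multivariate normal with covariance
`a² I + s_i² v vᵀ` (s_i the step-2 posterior SD of the subject's drift,
v the sensitivity vector), evaluated in closed form via the
Sherman–Morrison identity. This restores unbiased recovery of both
`a_hba1c` and the step-3 fixed effects.

**Numerics.** Free parameters are optimized on transformed scales (log
for positive parameters, logit for fractions) with Nelder–Mead:
moment-based starts (residual magnitudes from baseline-visit scatter,
Emax parameters from a coarse least-squares grid, ω from the dispersion
of per-subject log effects), a coarse screen of 3 seeded starts, then a
full polish with fresh-simplex restarts until the objective stops
improving (the convergence criterion is ~10⁻⁷ relative). Standard
errors come from the numerically differentiated observed information on
the transformed scale, delta-transformed to the natural scale; an
ill-conditioned information matrix is flagged and falls back to a
pseudoinverse, with subject-resampling bootstrap available. Fractions
approaching their bounds are flagged in the fit message, and
non-convergence is always reported, never silent.

**Problem sizes.** The recovery study in the test suite uses 20
replicate 810-subject 24-week-template cohorts, chosen to match the
scale at which the reported relative standard errors apply; scenario
simulations use the full 500 × 500 replicate structure throughout.

## Known limitations

* The sequential fit conditions on point estimates of earlier steps
  (except for the drift uncertainty, which is propagated); a joint fit
  would tighten step-3 SEs slightly.
* IAUC50 parameters are weakly identified without within-arm exposure
  spread; designs restricted to two active arms at high exposures leave
  the Emax curvature poorly determined.
* k1 is structurally unidentifiable when subjects within an arm share
  one insulin ratio (no IIV and no exposure spread); it is identified
  through between-subject variation in realized insulin reductions.
* HbA1c is treated without turnover, so the model should not be used to
  interpolate sub-4-week HbA1c kinetics.
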