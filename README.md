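# dapaer

Semi-mechanistic population exposure–response modelling of **dapagliflozin
as an insulin adjunct in type 1 diabetes** — linking steady-state drug
exposure, basal insulin dose titration, mean CGM glucose and HbA1c in one
simulate / estimate / analyze pipeline.

## The problem

SGLT-2 inhibitors such as dapagliflozin lower plasma glucose independently
of insulin, so adding them to a basal–bolus insulin regimen in type 1
diabetes triggers compensatory insulin dose reductions. Whether those
reductions erode the drug's HbA1c benefit is a quantitative question: it
depends on how strongly glucose responds to the basal insulin dose, how
glucose maps into HbA1c, and whether the drug carries HbA1c benefits beyond
its glucose effect. `dapaer` implements a three-step population model for
exactly this network and the forward simulations that interrogate it.

## The model

With AUC the steady-state 24-h dapagliflozin exposure (ng/mL·h),
`E(AUC; Imax, IAUC50) = Imax·AUC/(IAUC50 + AUC)` a saturable Emax term, and
t in weeks:

```
step 1   INS(t)/INS0   = 1 − E(AUC; Imax_ins, IAUC50_ins)
step 2   GLU(t)/GLU0   = (1 + keff·t) · (INS/INS0)^(−k1) · (1 − E(AUC; Imax_glu, IAUC50_glu))
step 3   HbA1c(t)      = HbA1c0 · (1 + k2·(GLU/GLU0 − 1)) · (1 − E(AUC; Imax_hba1c, IAUC50_glu))
```

Inter-individual variability enters as a lognormal random effect on
`Imax_ins` and `k2` and an additive normal effect on the background glucose
drift `keff`; insulin and glucose observations carry proportional residual
errors, HbA1c a constant error. The third Emax term is the *direct*,
glucose-independent HbA1c effect needed to explain the roughly two-fold
steeper glucose–HbA1c slope seen under treatment. Estimation is sequential
(insulin → glucose → HbA1c), each step a one-random-effect nonlinear
mixed-effects problem whose marginal likelihood is integrated on a dense
deterministic grid; see `docs/methods.md` for the details and design
choices.

## Worked example

```python
from dapaer import (ScenarioSpec, StructuralParameters, glucose_ratio,
                    run_dose_response)

# How much does halving the basal insulin dose raise steady-state glucose?
p = StructuralParameters()           # published population estimates
print(round(100 * (glucose_ratio(0.5, 0, 0, p) - 1), 2))   # -> 4.78 (%)

# Week-24 HbA1c change by dose: 500 populations x 500 subjects
dr = run_dose_response(ScenarioSpec(seed=1))
print(dr[dr.component == "total"][["arm", "mean", "lo95", "hi95"]])
```

```
     arm      mean      lo95      hi95
 placebo  0.066499  0.050915  0.085308
     1mg -0.198121 -0.212324 -0.184428
   2.5mg -0.336887 -0.353724 -0.321888
     5mg -0.429443 -0.448060 -0.414627
    10mg -0.480355 -0.498414 -0.462564
```

Reading: placebo subjects drift up by ≈ +0.07 HbA1c %-units over 24 weeks
(the `keff` background worsening), while 10 mg dapagliflozin lowers HbA1c
by ≈ 0.48 units at its mean exposure of 594.3 ng/mL·h — and because the
insulin–glucose coupling `k1` is weak, even a fixed 50% basal insulin
reduction only trims that to ≈ −0.43. About two-thirds of the treatment
response comes from the direct (glucose-independent) drug term
(`direct_effect_share`).

The same experiments are available from the shell:

```bash
dapaer generate --preset phase3_24wk --n 270 --seed 7 --out cohort.csv
dapaer fit      --data cohort.csv --out estimates.csv
dapaer explore  --data cohort.csv --out explore_out
dapaer scenario --preset fig10 --seed 1 --out scenario_out
```

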