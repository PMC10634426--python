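"""Trial-shaped synthetic datasets with known ground truth.

Emulates the two study designs used for model development: a one-week
inpatient dose-ranging study (placebo/1/2.5/5/10 mg, daily insulin and
CGM sampling, no HbA1c) and a 24-week outpatient study (placebo/5/10 mg
with the standard visit schedule).  Baselines are drawn lognormally
around the published medians and truncated to the published ranges;
per-subject exposure is drawn lognormally around the arm-mean AUC
(CV 40% by default), emulating the observed dose-proportional exposure
spread.

Bolus insulin is generated around its baseline with multiplicative
noise and no glucose linkage (the observed bolus-glucose association is
null); hemoglobin rises 4% on average under active treatment but is
uncorrelated with HbA1c changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .model import StructuralParameters, SubjectBaseline, basal_insulin_ratio, \
    glucose_ratio, hba1c_level
from .simulate import (Arm, RandomEffectSpec, TrialDesign, design_preset,
                       simulate_population, DOSE_AUC)
from .table import ObservationTable, REQUIRED_COLUMNS

__all__ = ["BaselineDistribution", "CohortSpec", "generate_cohort",
           "make_worked_example"]


@dataclass(frozen=True)
class BaselineDistribution:
    """Median and (lo, hi) range of one baseline variable."""
    median: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo < self.median < self.hi):
            raise ValueError("need lo < median < hi")

    @property
    def sigma(self) -> float:
        # log-scale spread chosen so the central 95% of the untruncated
        # lognormal approximates the printed (min, max)
        return np.log(self.hi / self.lo) / (2 * 1.96)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        # clipping (rather than rejection) keeps the median at the
        # published value even when the printed range is asymmetric
        z = rng.normal(size=n)
        return np.clip(self.median * np.exp(self.sigma * z), self.lo, self.hi)


# Published baseline characteristics, medians (ranges).  Basal and bolus
# doses are taken as half of the printed total daily insulin dose each
# (the typical basal/bolus split in basal-bolus regimens).
_PHASE3_BASELINES = {
    "ins0": BaselineDistribution(25.8, 6.9, 104.0),
    "bolus0": BaselineDistribution(25.8, 6.9, 104.0),
    "glu0": BaselineDistribution(190.3, 65.1, 316.4),
    "hba1c0": BaselineDistribution(8.3, 7.5, 10.9),
    "hgb0": BaselineDistribution(139.0, 97.0, 178.0),
}
_PHASE2_BASELINES = {
    "ins0": BaselineDistribution(24.2, 9.0, 82.5),
    "bolus0": BaselineDistribution(24.2, 9.0, 82.5),
    "glu0": BaselineDistribution(170.3, 106.5, 263.9),
    "hba1c0": BaselineDistribution(8.4, 7.0, 9.9),
    "hgb0": BaselineDistribution(139.0, 89.0, 163.0),
}

# Deterministic protocol override for the inpatient placebo group:
# bolus raised 40% and basal 10% from baseline at treatment start.
_PHASE2_PLACEBO_BASAL_FACTOR = 1.10
_PHASE2_PLACEBO_BOLUS_FACTOR = 1.40

_HGB_ACTIVE_SHIFT = 0.04       # +4% mean hemoglobin under active treatment
_BOLUS_NOISE_SD = 0.20         # lognormal sd of bolus dose around its trend
_HGB_NOISE_SD = 0.02


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort."""

    template: str = "phase3_24wk"
    arm_sizes: Mapping[str, int] | None = None   # None -> template defaults
    baselines: Mapping[str, BaselineDistribution] | None = None
    auc_means: Mapping[float, float] = field(
        default_factory=lambda: dict(DOSE_AUC))
    auc_cv: float = 0.40

    def resolved_baselines(self) -> Mapping[str, BaselineDistribution]:
        if self.baselines is not None:
            return self.baselines
        return _PHASE2_BASELINES if self.template == "phase2_inpatient" \
            else _PHASE3_BASELINES


def _arm_list(spec: CohortSpec) -> list[tuple[Arm, int]]:
    base = design_preset(spec.template)
    sizes = dict(spec.arm_sizes) if spec.arm_sizes is not None else \
        {a.label: base.n_per_arm for a in base.arms}
    out = []
    for arm in base.arms:
        n = sizes.pop(arm.label, 0)
        if n < 0:
            raise ValueError(f"negative arm size for {arm.label!r}")
        if n == 0:
            continue
        if arm.dose_mg > 0:
            if arm.dose_mg not in spec.auc_means:
                raise ValueError(f"no AUC mean configured for dose {arm.dose_mg} mg")
            arm = Arm(arm.label, arm.dose_mg, spec.auc_means[arm.dose_mg],
                      spec.auc_cv)
        out.append((arm, n))
    if sizes:
        raise ValueError(f"arm sizes given for unknown arms: {sorted(sizes)}")
    return out


def generate_cohort(spec: CohortSpec,
                    params: StructuralParameters | None = None,
                    re_spec: RandomEffectSpec | None = None,
                    seed: int = 0) -> tuple[ObservationTable, dict]:
    """Generate a trial-shaped dataset plus its ground-truth record.

    The baseline columns of the returned table carry the drawn (latent)
    subject baselines; the t=0 rows carry noisy measurements of them.
    """
    params = params or StructuralParameters()
    re_spec = re_spec if re_spec is not None else RandomEffectSpec()
    rng = np.random.default_rng(seed)
    base_design = design_preset(spec.template)
    dists = spec.resolved_baselines()

    frames = []
    offset = 0
    for arm, n in _arm_list(spec):
        base = pd.DataFrame({k: d.sample(n, rng) for k, d in dists.items()})
        ins_override = None
        if spec.template == "phase2_inpatient" and arm.dose_mg == 0:
            ins_override = _PHASE2_PLACEBO_BASAL_FACTOR
        sched = {k: v for k, v in base_design.schedule.items()
                 if k in ("basal_insulin", "cgm_glucose", "hba1c")}
        design = TrialDesign(arms=(arm,), n_per_arm=n, schedule=sched)
        tab = simulate_population(
            design, params, re_spec, rng,
            baselines=base[["ins0", "glu0", "hba1c0", "hgb0"]],
            insulin_ratio_override=ins_override, id_offset=offset)
        df = tab.df
        ids = np.sort(df["subject_id"].unique())
        id_auc = df.groupby("subject_id")["auc"].first().reindex(ids)

        extra = []
        for obs_type in ("bolus_insulin", "hemoglobin"):
            times = base_design.schedule.get(obs_type, ())
            for t in times:
                if obs_type == "bolus_insulin":
                    pred = base["bolus0"].to_numpy(copy=True)
                    if t > 0 and arm.dose_mg == 0 and spec.template == "phase2_inpatient":
                        pred = pred * _PHASE2_PLACEBO_BOLUS_FACTOR
                    value = pred if t == 0 else pred * np.exp(
                        rng.normal(0.0, _BOLUS_NOISE_SD, size=n))
                else:
                    pred = base["hgb0"].to_numpy(copy=True)
                    if t > 0 and arm.dose_mg > 0:
                        pred = pred * (1.0 + _HGB_ACTIVE_SHIFT)
                    value = pred if t == 0 else pred * (
                        1.0 + rng.normal(0.0, _HGB_NOISE_SD, size=n))
                extra.append(pd.DataFrame({
                    "subject_id": ids, "arm": arm.label, "dose_mg": arm.dose_mg,
                    "time_wk": float(t), "obs_type": obs_type,
                    "value": np.maximum(value, 1e-6), "value_pred": pred,
                    "auc": id_auc.to_numpy(),
                    "ins0": base["ins0"].to_numpy(), "glu0": base["glu0"].to_numpy(),
                    "hba1c0": base["hba1c0"].to_numpy(), "hgb0": base["hgb0"].to_numpy(),
                }))
        frames.append(df if not extra else pd.concat([df] + extra, ignore_index=True))
        offset += n

    if frames:
        df = pd.concat(frames, ignore_index=True)
        df = df.sort_values(["subject_id", "obs_type", "time_wk"],
                            kind="stable").reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=list(REQUIRED_COLUMNS) + ["value_pred"])
    truth = {
        "structural": params.to_dict(),
        "omegas": {k: v.omega for k, v in re_spec.effects.items()},
        "families": {k: v.family for k, v in re_spec.effects.items()},
        "template": spec.template,
        "auc_cv": spec.auc_cv,
        "seed": seed,
    }
    return ObservationTable(df), truth


_EXAMPLE_SUBJECTS = (
    ("placebo", 0.0, 0.0),
    ("5mg", 5.0, 294.5),
    ("10mg", 10.0, 594.3),
)
_EXAMPLE_BASELINE = SubjectBaseline(ins0=40.0, glu0=180.0, hba1c0=8.4, hgb0=139.0)
_EXAMPLE_TIMES = (0.0, 12.0, 24.0)


def make_worked_example() -> tuple[ObservationTable, pd.DataFrame]:
    """Tiny deterministic fixture: 3 subjects x 3 visits, no noise, no IIV.

    Returns the observation table (t=0 rows are pre-dose baselines) and
    a frame of hand-checkable on-treatment structural predictions
    (insulin ratio, glucose, HbA1c at every time including t=0, where
    the on-treatment insulin ratio for the 10 mg subject is
    1 - 0.0941*594.3/(38.8 + 594.3) = 0.91166...).
    """
    p = StructuralParameters()
    b = _EXAMPLE_BASELINE
    rows, expected = [], []
    for i, (arm, dose, auc) in enumerate(_EXAMPLE_SUBJECTS):
        sid = f"EX{i}"
        ins_ratio = basal_insulin_ratio(auc, p)
        for t in _EXAMPLE_TIMES:
            gr = glucose_ratio(ins_ratio, auc, t, p)
            expected.append({
                "subject_id": sid, "time_wk": t,
                "insulin_ratio": ins_ratio,
                "glucose": b.glu0 * gr,
                "hba1c": hba1c_level(gr, auc, b.hba1c0, p),
            })
            obs = {
                "basal_insulin": b.ins0 if t == 0 else b.ins0 * ins_ratio,
                "cgm_glucose": b.glu0 if t == 0 else b.glu0 * gr,
                "hba1c": b.hba1c0 if t == 0 else hba1c_level(gr, auc, b.hba1c0, p),
            }
            for obs_type, value in obs.items():
                rows.append({
                    "subject_id": sid, "arm": arm, "dose_mg": dose,
                    "time_wk": t, "obs_type": obs_type, "value": value,
                    "value_pred": value, "auc": auc, "ins0": b.ins0,
                    "glu0": b.glu0, "hba1c0": b.hba1c0, "hgb0": b.hgb0,
                })
    df = pd.DataFrame(rows).sort_values(
        ["subject_id", "obs_type", "time_wk"], kind="stable").reset_index(drop=True)
    return ObservationTable(df), pd.DataFrame(expected)
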