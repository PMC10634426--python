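"""Virtual-population simulation with inter-individual variability.

Samples subjects around the population parameters, evaluates the
structural model on a visit schedule, applies the residual-error models
and summarizes replicate populations into means with percentile 95% CIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import StructuralParameters, SubjectBaseline
from .table import ObservationTable

__all__ = [
    "RandomEffect",
    "RandomEffectSpec",
    "Arm",
    "TrialDesign",
    "design_preset",
    "sample_subject_parameters",
    "apply_residual_error",
    "simulate_population",
    "summarize_replicates",
]

# Individual Imax draws are clipped just below 1 so that fractional
# effects (and hence doses/concentrations) stay positive in the far
# lognormal tail.  The same clip is part of the estimation likelihood.
IMAX_CLIP = 0.999

# Observed values are floored at a small positive bound.
VALUE_FLOOR = 1e-6

_FRACTION_PARAMS = ("imax_ins", "imax_glu", "imax_hba1c")


@dataclass(frozen=True)
class RandomEffect:
    omega: float
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be nonnegative")
        if self.family not in ("lognormal", "normal"):
            raise ValueError(f"unknown random-effect family {self.family!r}")


@dataclass(frozen=True)
class RandomEffectSpec:
    """Which parameters carry inter-individual variability.

    Defaults: lognormal IIV on imax_ins (omega 1.09) and k2 (omega
    0.739); additive normal IIV on keff (omega 0.003, twice the
    population value, allowing the negative placebo glucose drifts seen
    in individual subjects).
    """

    effects: Mapping[str, RandomEffect] = field(default_factory=lambda: {
        "imax_ins": RandomEffect(1.09, "lognormal"),
        "keff": RandomEffect(0.003, "normal"),
        "k2": RandomEffect(0.739, "lognormal"),
    })

    def __post_init__(self) -> None:
        for name, eff in self.effects.items():
            if not isinstance(eff, RandomEffect):
                raise TypeError(f"effect for {name!r} must be a RandomEffect")

    @classmethod
    def none(cls) -> "RandomEffectSpec":
        return cls(effects={})

    def omega(self, name: str) -> float:
        eff = self.effects.get(name)
        return eff.omega if eff is not None else 0.0

    def with_omega(self, name: str, omega: float) -> "RandomEffectSpec":
        effects = dict(self.effects)
        fam = effects[name].family if name in effects else "lognormal"
        effects[name] = RandomEffect(omega, fam)
        return RandomEffectSpec(effects=effects)


@dataclass(frozen=True)
class Arm:
    label: str
    dose_mg: float
    auc_mean: float          # ng/mL*h; 0 for placebo
    auc_cv: float = 0.0      # lognormal CV of per-subject AUC around the mean


@dataclass(frozen=True)
class TrialDesign:
    """Arms, cohort sizes and per-observation-type visit schedules (weeks)."""

    arms: tuple[Arm, ...]
    n_per_arm: int
    schedule: Mapping[str, tuple[float, ...]]
    n_replicate_populations: int = 1

    def __post_init__(self) -> None:
        if self.n_per_arm <= 0:
            raise ValueError("n_per_arm must be positive")
        if self.n_replicate_populations < 1:
            raise ValueError("n_replicate_populations must be >= 1")
        for obs_type, times in self.schedule.items():
            if any(t < 0 for t in times):
                raise ValueError(f"negative visit time in {obs_type} schedule")


# Mean steady-state 24-h AUC by daily dose (ng/mL*h), dose-proportional.
DOSE_AUC = {1.0: 51.4, 2.5: 130.6, 5.0: 294.5, 10.0: 594.3}

_PHASE2_DAYS = tuple(d / 7.0 for d in range(8))

_PRESETS: dict[str, TrialDesign] = {
    # Inpatient dose-ranging week: daily insulin and CGM, no HbA1c.
    "phase2_inpatient": TrialDesign(
        arms=tuple([Arm("placebo", 0.0, 0.0)] + [
            Arm(f"{d:g}mg", d, DOSE_AUC[d]) for d in (1.0, 2.5, 5.0, 10.0)]),
        n_per_arm=14,
        schedule={
            "basal_insulin": _PHASE2_DAYS,
            "bolus_insulin": _PHASE2_DAYS,
            "cgm_glucose": _PHASE2_DAYS,
        },
    ),
    # 24-week double-blind period of the phase 3 studies.
    "phase3_24wk": TrialDesign(
        arms=(Arm("placebo", 0.0, 0.0),
              Arm("5mg", 5.0, DOSE_AUC[5.0]),
              Arm("10mg", 10.0, DOSE_AUC[10.0])),
        n_per_arm=270,
        schedule={
            "basal_insulin": (0.0, 2.0, 12.0, 24.0),
            "bolus_insulin": (0.0, 2.0, 12.0, 24.0),
            "cgm_glucose": (0.0, 12.0, 24.0),
            "hba1c": (0.0, 4.0, 8.0, 12.0, 18.0, 24.0),
            "hemoglobin": (0.0, 4.0, 8.0, 12.0, 18.0, 24.0),
        },
    ),
}


def design_preset(name: str, *, n_per_arm: int | None = None,
                  auc_cv: float | None = None) -> TrialDesign:
    """Return a named trial design, optionally resized."""
    if name not in _PRESETS:
        raise ValueError(f"unknown design preset {name!r}; "
                         f"available: {sorted(_PRESETS)}")
    design = _PRESETS[name]
    if n_per_arm is not None:
        design = replace(design, n_per_arm=n_per_arm)
    if auc_cv is not None:
        design = replace(design, arms=tuple(
            replace(a, auc_cv=(auc_cv if a.auc_mean > 0 else 0.0))
            for a in design.arms))
    return design


def sample_subject_parameters(p: StructuralParameters, re_spec: RandomEffectSpec,
                              rng: np.random.Generator | int,
                              n: int = 1) -> dict[str, np.ndarray]:
    """Draw ``n`` individual parameter sets around the population values.

    lognormal family: theta_i = theta_pop * exp(eta), eta ~ N(0, omega^2)
    normal family:    theta_i = theta_pop + eta

    Parameters without IIV are returned as constant arrays.  Fraction
    parameters (Imax) are clipped just below 1.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out: dict[str, np.ndarray] = {}
    pop = p.to_dict()
    for name, value in pop.items():
        eff = re_spec.effects.get(name)
        if eff is None or eff.omega == 0.0:
            theta = np.full(n, value, dtype=float)
            # keep the stream independent of which omegas are zero? No:
            # the seed contract is on (design, parameters, spec, seed).
        else:
            eta = rng.normal(0.0, eff.omega, size=n)
            if eff.family == "lognormal":
                if value <= 0:
                    raise ValueError(
                        f"lognormal IIV requested for {name!r} with nonpositive "
                        f"population value {value!r}")
                theta = value * np.exp(eta)
            else:
                theta = value + eta
        if name in _FRACTION_PARAMS:
            theta = np.clip(theta, 0.0, IMAX_CLIP)
        out[name] = theta
    return out


def apply_residual_error(prediction, obs_type: str, p: StructuralParameters,
                         rng: np.random.Generator):
    """Apply the step's residual-error model to noise-free predictions.

    Insulin and glucose carry proportional errors (y = pred*(1 + b*eps));
    HbA1c a constant error (y = pred + a*eps).  Bolus insulin and
    hemoglobin, which are not model outputs, reuse the proportional
    insulin/glucose magnitudes respectively.  Values are floored at a
    small positive bound.
    """
    pred = np.asarray(prediction, dtype=float)
    if np.any(pred <= 0):
        raise ValueError("predictions must be strictly positive")
    eps = rng.normal(size=pred.shape)
    if obs_type in ("basal_insulin", "bolus_insulin"):
        y = pred * (1.0 + p.b_ins * eps)
    elif obs_type in ("cgm_glucose", "hemoglobin"):
        y = pred * (1.0 + p.b_glu * eps)
    elif obs_type == "hba1c":
        y = pred + p.a_hba1c * eps
    else:
        raise ValueError(f"unknown obs_type {obs_type!r}")
    return np.maximum(y, VALUE_FLOOR)


_SIM_TYPES = ("basal_insulin", "cgm_glucose", "hba1c")


def _subject_baselines(baselines, n: int, rng: np.random.Generator) -> pd.DataFrame:
    if baselines is None:
        baselines = SubjectBaseline(ins0=26.0, glu0=190.0, hba1c0=8.48, hgb0=139.0)
    if isinstance(baselines, SubjectBaseline):
        return pd.DataFrame({
            "ins0": np.full(n, baselines.ins0),
            "glu0": np.full(n, baselines.glu0),
            "hba1c0": np.full(n, baselines.hba1c0),
            "hgb0": np.full(n, baselines.hgb0),
        })
    if callable(baselines):
        df = baselines(n, rng)
    else:
        df = pd.DataFrame(baselines).reset_index(drop=True)
    for c in ("ins0", "glu0", "hba1c0", "hgb0"):
        if c not in df.columns:
            raise ValueError(f"baseline frame missing column {c!r}")
    if len(df) != n:
        raise ValueError("baseline frame has wrong length")
    return df


def simulate_population(design: TrialDesign, p: StructuralParameters | None = None,
                        re_spec: RandomEffectSpec | None = None,
                        seed: int | np.random.Generator = 0, *,
                        baselines=None,
                        insulin_ratio_override: float | None = None,
                        include_direct: bool = True,
                        noise: bool = True,
                        id_offset: int = 0) -> ObservationTable:
    """Simulate one population on the design's visit schedule.

    Returns an ObservationTable whose ``value`` column is noisy (unless
    ``noise=False``) and whose ``value_pred`` column is the noise-free
    individual prediction.  The t=0 visit is pre-dose: predictions equal
    the subject's baseline there.  Identical inputs and seed give
    bit-identical tables.

    ``baselines`` may be a single SubjectBaseline applied to everyone,
    a per-subject DataFrame (ins0/glu0/hba1c0/hgb0, length = total n),
    or a callable ``(n, rng) -> DataFrame``.
    """
    p = p or StructuralParameters()
    re_spec = re_spec if re_spec is not None else RandomEffectSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    unknown = set(design.schedule) - set(_SIM_TYPES)
    if unknown:
        raise ValueError(f"simulate_population cannot generate obs types {sorted(unknown)}; "
                         "use the cohort generator for bolus/hemoglobin columns")

    n_total = design.n_per_arm * len(design.arms)
    base = _subject_baselines(baselines, n_total, rng)
    indiv = sample_subject_parameters(p, re_spec, rng, n_total)

    rows: list[pd.DataFrame] = []
    for a_idx, arm in enumerate(design.arms):
        sl = slice(a_idx * design.n_per_arm, (a_idx + 1) * design.n_per_arm)
        n = design.n_per_arm
        if arm.auc_mean > 0 and arm.auc_cv > 0:
            sigma = np.sqrt(np.log1p(arm.auc_cv ** 2))
            mu = np.log(arm.auc_mean) - 0.5 * sigma ** 2
            auc = np.exp(rng.normal(mu, sigma, size=n))
        else:
            auc = np.full(n, arm.auc_mean)
        ids = np.array([f"S{id_offset + i:05d}" for i in range(sl.start, sl.stop)])
        b = base.iloc[sl].reset_index(drop=True)

        if insulin_ratio_override is None:
            ins_ratio = 1.0 - np.minimum(
                indiv["imax_ins"][sl], IMAX_CLIP) * auc / (indiv["iauc50_ins"][sl] + auc)
        else:
            if not insulin_ratio_override > 0:
                raise ValueError("insulin_ratio_override must be strictly positive")
            ins_ratio = np.full(n, insulin_ratio_override)

        for obs_type, times in design.schedule.items():
            for t in times:
                if t == 0:
                    pred = {"basal_insulin": b["ins0"], "cgm_glucose": b["glu0"],
                            "hba1c": b["hba1c0"]}[obs_type].to_numpy(copy=True)
                else:
                    if obs_type == "basal_insulin":
                        pred = b["ins0"].to_numpy() * ins_ratio
                    else:
                        drift = 1.0 + indiv["keff"][sl] * t
                        drug_glu = 1.0 - indiv["imax_glu"][sl] * auc / (indiv["iauc50_glu"][sl] + auc)
                        gratio = drift * ins_ratio ** (-indiv["k1"][sl]) * drug_glu
                        if obs_type == "cgm_glucose":
                            pred = b["glu0"].to_numpy() * gratio
                        else:
                            direct = 1.0
                            if include_direct:
                                direct = 1.0 - indiv["imax_hba1c"][sl] * auc / (
                                    indiv["iauc50_glu"][sl] + auc)
                            pred = (b["hba1c0"].to_numpy()
                                    * (1.0 + indiv["k2"][sl] * (gratio - 1.0)) * direct)
                pred = np.maximum(pred, VALUE_FLOOR)
                value = apply_residual_error(pred, obs_type, p, rng) if noise else pred
                rows.append(pd.DataFrame({
                    "subject_id": ids, "arm": arm.label, "dose_mg": arm.dose_mg,
                    "time_wk": float(t), "obs_type": obs_type,
                    "value": value, "value_pred": pred, "auc": auc,
                    "ins0": b["ins0"].to_numpy(), "glu0": b["glu0"].to_numpy(),
                    "hba1c0": b["hba1c0"].to_numpy(), "hgb0": b["hgb0"].to_numpy(),
                }))
    df = pd.concat(rows, ignore_index=True)
    df = df.sort_values(["subject_id", "obs_type", "time_wk"],
                        kind="stable").reset_index(drop=True)
    return ObservationTable(df)


def summarize_replicates(replicate_means: Sequence[float] | np.ndarray,
                         ci: float = 0.95) -> dict[str, float]:
    """Mean and percentile CI across replicate population means.

    The CI is the empirical 2.5th/97.5th percentile of the replicate
    means (matching the "N populations of n subjects" convention), not a
    normal approximation.
    """
    x = np.asarray(replicate_means, dtype=float)
    if x.size == 0:
        raise ValueError("no replicate means provided")
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(x, [100 * alpha, 100 * (1 - alpha)])
    return {"mean": float(x.mean()), "lo95": float(lo), "hi95": float(hi),
            "n_replicates": int(x.size)}
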