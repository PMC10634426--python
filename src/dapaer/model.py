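"""Structural (fixed-effect, noise-free) exposure-response model.

Three chained submodels link steady-state daily dapagliflozin exposure
(24-h AUC, ng/mL*h) and time on treatment to the glycemic state of a
subject with type 1 diabetes:

1. basal insulin dose ratio  INS(t)/INS0 = 1 - Emax_ins(AUC)
2. mean CGM glucose ratio    GLU(t)/GLU0 = (1 + keff*t) * (INS/INS0)^(-k1)
                                           * (1 - Emax_glu(AUC))
3. HbA1c level               HbA1c(t) = HbA1c0 * (1 + k2*(GLU/GLU0 - 1))
                                           * (1 - Emax_hba1c(AUC))

All drug effects are saturable Emax functions of exposure; the insulin
effect is treated as instantaneous at treatment start and sustained, and
HbA1c as an instantaneous transform of the current glucose ratio (the
observed HbA1c response is nearly complete within four weeks, so no
turnover compartment is carried).  ``keff`` is a treatment-independent
fractional drift of mean glucose per week, capturing the slow worsening
of glycemic control seen in placebo arms.

Functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "StructuralParameters",
    "SubjectBaseline",
    "emax_fraction",
    "basal_insulin_ratio",
    "glucose_ratio",
    "hba1c_level",
    "predict_trajectory",
]


@dataclass(frozen=True)
class StructuralParameters:
    """Fixed-effect parameter vector of the three-step model.

    Defaults are the population estimates from the pooled phase 2/3
    analysis.  ``iauc50_hba1c`` is structurally constrained equal to
    ``iauc50_glu`` and is exposed as a read-only property.

    Attributes
    ----------
    imax_ins : float
        Maximum fractional reduction of the basal insulin dose, in [0, 1).
    iauc50_ins : float
        Exposure (ng/mL*h) at half-maximal insulin-dose effect.
    k1 : float
        Exponent coupling the basal insulin ratio to glucose
        (GLU ~ (INS/INS0)^(-k1)).
    keff : float
        Treatment-independent fractional glucose drift per week.
    imax_glu : float
        Maximum fractional glucose reduction, in [0, 1).
    iauc50_glu : float
        Exposure at half-maximal glucose effect (shared with the direct
        HbA1c effect).
    k2 : float
        Slope coupling relative glucose change to relative HbA1c change.
    imax_hba1c : float
        Maximum direct (glucose-independent) fractional HbA1c reduction.
    b_ins, b_glu : float
        Proportional residual error magnitudes (steps 1 and 2).
    a_hba1c : float
        Constant residual error magnitude in HbA1c %-units (step 3).
    """

    imax_ins: float = 0.0941
    iauc50_ins: float = 38.8
    k1: float = 0.0674
    keff: float = 0.0015
    imax_glu: float = 0.15
    iauc50_glu: float = 67.4
    k2: float = 0.165
    imax_hba1c: float = 0.0421
    b_ins: float = 0.185
    b_glu: float = 0.162
    a_hba1c: float = 0.061

    @property
    def iauc50_hba1c(self) -> float:
        """Half-maximal exposure of the direct HbA1c effect (== iauc50_glu)."""
        return self.iauc50_glu

    def __post_init__(self) -> None:
        for name in ("imax_ins", "imax_glu", "imax_hba1c"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name}={v!r} must lie in [0, 1)")
        for name in ("iauc50_ins", "iauc50_glu", "b_ins", "b_glu", "a_hba1c"):
            v = getattr(self, name)
            if not v > 0.0:
                raise ValueError(f"{name}={v!r} must be > 0")

    def replace(self, **changes) -> "StructuralParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "StructuralParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown structural parameters: {sorted(unknown)}")
        return cls(**dict(d))


@dataclass(frozen=True)
class SubjectBaseline:
    """Pre-treatment state of one subject.

    ins0 : basal insulin dose, IU/day
    glu0 : mean CGM glucose, mg/dL
    hba1c0 : HbA1c, %
    hgb0 : hemoglobin, g/L (carried for exploratory analyses only)
    """

    ins0: float
    glu0: float
    hba1c0: float
    hgb0: float = 139.0

    def __post_init__(self) -> None:
        for name in ("ins0", "glu0", "hba1c0", "hgb0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (4.0 <= self.hba1c0 <= 15.0):
            raise ValueError(f"hba1c0={self.hba1c0!r} outside plausible range [4, 15]%")


def _check_exposure(auc, imax, iauc50) -> None:
    if np.any(np.asarray(auc) < 0):
        raise ValueError("exposure (AUC) must be nonnegative")
    if np.any(np.asarray(iauc50) <= 0):
        raise ValueError("IAUC50 must be strictly positive")
    if np.any((np.asarray(imax) < 0) | (np.asarray(imax) >= 1)):
        raise ValueError("Imax must lie in [0, 1)")


def emax_fraction(auc, imax, iauc50):
    """Saturable fractional drug effect imax*auc/(iauc50 + auc).

    Returns a value in [0, imax), monotone nondecreasing in ``auc``, and
    exactly imax/2 at ``auc == iauc50``.
    """
    _check_exposure(auc, imax, iauc50)
    auc = np.asarray(auc, dtype=float)
    out = imax * auc / (iauc50 + auc)
    return out if out.ndim else float(out)


def basal_insulin_ratio(auc, p: StructuralParameters):
    """Basal insulin dose relative to baseline, INS(t)/INS0.

    Time-constant under steady dosing; lies in (1 - imax_ins, 1].
    """
    return 1.0 - emax_fraction(auc, p.imax_ins, p.iauc50_ins)


def glucose_ratio(insulin_ratio, auc, t, p: StructuralParameters):
    """Mean CGM glucose relative to baseline, GLU(t)/GLU0.

    Combines the treatment-independent drift ``1 + keff*t``, the
    insulin-withdrawal effect ``insulin_ratio**(-k1)`` and the saturable
    direct glucose effect of the drug.  Equals 1 at
    ``(insulin_ratio=1, auc=0, t=0)``.
    """
    insulin_ratio = np.asarray(insulin_ratio, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(insulin_ratio <= 0):
        raise ValueError("insulin_ratio must be strictly positive")
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    drug = 1.0 - emax_fraction(auc, p.imax_glu, p.iauc50_glu)
    out = (1.0 + p.keff * t) * insulin_ratio ** (-p.k1) * drug
    return out if out.ndim else float(out)


def hba1c_level(glucose_ratio, auc, hba1c0, p: StructuralParameters, *,
                include_direct: bool = True):
    """HbA1c (%) as an instantaneous transform of the glucose ratio.

    ``include_direct=False`` switches off the glucose-independent drug
    term, giving the glucose-mediated component used in effect
    decomposition.
    """
    glucose_ratio = np.asarray(glucose_ratio, dtype=float)
    if np.any(glucose_ratio <= 0):
        raise ValueError("glucose_ratio must be strictly positive")
    if np.any(np.asarray(hba1c0) <= 0):
        raise ValueError("hba1c0 must be strictly positive")
    direct = 1.0
    if include_direct:
        direct = 1.0 - emax_fraction(auc, p.imax_hba1c, p.iauc50_hba1c)
    out = hba1c0 * (1.0 + p.k2 * (glucose_ratio - 1.0)) * direct
    return out if np.ndim(out) else float(out)


def predict_trajectory(p: StructuralParameters, auc: float,
                       baseline: SubjectBaseline, times: Iterable[float],
                       *, insulin_ratio_override: float | None = None,
                       include_direct: bool = True) -> dict[str, np.ndarray]:
    """Noise-free on-treatment trajectory at the given week times.

    Chains the three submodels with a single (individual) parameter set.
    ``insulin_ratio_override`` replaces the exposure-driven insulin
    adjustment with a fixed ratio (e.g. 0.5 for a 50% dose reduction).

    Returns a dict with keys ``time_wk``, ``insulin_ratio``,
    ``glucose`` (mg/dL) and ``hba1c`` (%), each an array over ``times``.
    """
    times = np.asarray(list(times), dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    if insulin_ratio_override is None:
        ins_ratio = float(basal_insulin_ratio(auc, p))
    else:
        ins_ratio = float(insulin_ratio_override)
        if not ins_ratio > 0:
            raise ValueError("insulin_ratio_override must be strictly positive")
    ins = np.full_like(times, ins_ratio)
    glu_ratio = glucose_ratio(ins, auc, times, p)
    hba1c = hba1c_level(glu_ratio, auc, baseline.hba1c0, p,
                        include_direct=include_direct)
    return {
        "time_wk": times,
        "insulin_ratio": ins,
        "glucose": baseline.glu0 * np.asarray(glu_ratio),
        "hba1c": np.asarray(hba1c),
    }
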