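"""Stepwise nonlinear mixed-effects estimation.

The model is fitted in three sequential steps, each a one-random-effect
NLME problem conditioned on the outputs of the previous step:

step 1: basal insulin dose ~ exposure          (IIV on imax_ins, prop. error)
step 2: CGM glucose ~ insulin ratio, exposure,
        time                                    (IIV on keff, prop. error)
step 3: HbA1c ~ glucose ratio, exposure        (IIV on k2, constant error;
                                                iauc50 fixed to step 2)

The marginal likelihood integrates the single subject-level random
effect on a dense standardized grid (deterministic trapezoid quadrature
over +/- `span` prior SDs), which is accurate for the posterior widths
arising at these designs and keeps the objective smooth and fully
vectorized across subjects.

Upstream drivers for steps 2 and 3 can be taken from three sources
(``driver_mode``):

``"ebe"`` (default)
    individual empirical-Bayes predictions from the previous step, the
    sequential "individual parameters" approach.  Conditional means are
    regression-safe drivers: subject-level deviations from them are
    mean-zero given the data, so downstream slopes are not attenuated.
``"observed"``
    the subject's observed upstream measurements (interpolated in time
    where schedules do not align).  Because observed CGM carries a 16%
    proportional error, this mode is an errors-in-variables regression
    and biases the glucose-HbA1c slope toward zero; it is provided for
    sensitivity analyses.
``"population"``
    population predictions (no subject-level information).  With
    arm-level-only exposure this cannot separate the insulin-mediated
    from the direct glucose effect and is mainly useful for simulation
    checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from .model import StructuralParameters
from .simulate import IMAX_CLIP, RandomEffect, RandomEffectSpec
from .table import ObservationTable

logger = logging.getLogger(__name__)

__all__ = [
    "FitOptions", "StepResults", "SequentialResults",
    "BasalInsulinStep", "GlucoseStep", "HbA1cStep",
    "fit_step", "fit_sequential", "approximate_marginal_loglik",
]

_LOG2PI = np.log(2.0 * np.pi)
_FACTOR_FLOOR = 0.01     # floors multiplicative factors deep in the IIV tail


def _trapezoid_nodes(n_nodes: int, span: float) -> tuple[np.ndarray, np.ndarray]:
    """Standardized-normal grid and log trapezoid weights."""
    u = np.linspace(-span, span, n_nodes)
    du = u[1] - u[0]
    w = np.exp(-0.5 * u ** 2) / np.sqrt(2 * np.pi) * du
    w[0] *= 0.5
    w[-1] *= 0.5
    return u, np.log(w)


def approximate_marginal_loglik(y: np.ndarray,
                                predict: Callable[[float], np.ndarray],
                                omega: float,
                                error_model: str,
                                magnitude: float,
                                *, n_nodes: int = 151,
                                span: float = 6.0) -> float:
    """Marginal log-likelihood of one subject's observations.

    Integrates exp(sum of observation log-densities) over a single
    random effect eta ~ N(0, omega^2) by dense-grid quadrature.
    ``predict(eta)`` returns the prediction vector for the subject's
    observations; ``error_model`` is "proportional" (sd = magnitude*pred)
    or "constant" (sd = magnitude).  With omega == 0 this reduces to the
    fixed-effect residual log-likelihood.
    """
    if magnitude <= 0:
        raise ValueError("residual error magnitude must be > 0")
    if error_model not in ("proportional", "constant"):
        raise ValueError(f"unknown error model {error_model!r}")
    y = np.asarray(y, dtype=float)
    if y.size < 1:
        raise ValueError("subject must have at least one observation")

    def cond(eta: float) -> float:
        pred = np.asarray(predict(eta), dtype=float)
        sd = magnitude * np.abs(pred) if error_model == "proportional" else \
            np.full_like(pred, magnitude)
        return float(np.sum(-0.5 * ((y - pred) / sd) ** 2 - np.log(sd) - 0.5 * _LOG2PI))

    if omega == 0.0:
        return cond(0.0)
    u, logw = _trapezoid_nodes(n_nodes, span)
    vals = np.array([cond(omega * ui) for ui in u])
    return float(logsumexp(vals + logw))


@dataclass
class FitOptions:
    n_starts: int = 3
    seed: int = 0
    maxfev: int = 3000
    fatol: float = 1e-3          # absolute; ~1e-7 relative at these objectives
    xatol: float = 1e-4
    n_nodes: int = 121
    span: float = 5.0
    compute_se: bool = True


@dataclass
class StepResults:
    """Estimates and diagnostics from one estimation step."""

    step: int
    params: dict[str, float]              # natural scale, incl. omega + error
    se: dict[str, float]
    rse_percent: dict[str, float]
    llf: float
    converged: bool
    message: str
    n_subjects: int
    n_obs: int
    driver_mode: str
    subject_ids: np.ndarray
    eta: np.ndarray                       # empirical-Bayes eta per subject
    eta_sd: np.ndarray = None             # posterior sd of eta per subject
    se_method: str = "hessian"
    fixed: dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"Step {self.step} ({self.driver_mode} drivers): "
                 f"{self.n_subjects} subjects, {self.n_obs} observations",
                 f"log-likelihood {self.llf:.3f}; "
                 f"{'converged' if self.converged else 'NOT CONVERGED'} "
                 f"({self.message}); SEs via {self.se_method}",
                 f"{'parameter':<14}{'estimate':>12}{'SE':>12}{'RSE%':>9}"]
        for k, v in self.params.items():
            se = self.se.get(k, float("nan"))
            rse = self.rse_percent.get(k, float("nan"))
            lines.append(f"{k:<14}{v:>12.5g}{se:>12.3g}{rse:>9.3g}")
        for k, v in self.fixed.items():
            lines.append(f"{k:<14}{v:>12.5g}{'(fixed)':>12}{'-':>9}")
        return "\n".join(lines)


class _StepModel:
    """Shared machinery: grid marginal likelihood, optimizer, SEs, EBEs."""

    step: int
    omega_name: str
    # (name, transform) pairs defining the free-parameter vector
    param_spec: tuple[tuple[str, str], ...]

    def __init__(self, data: ObservationTable, obs_type: str):
        sub = data.subset(obs_type).sort_values(
            ["subject_id", "time_wk"], kind="stable")
        if len(sub) == 0:
            raise ValueError(f"no {obs_type!r} observations in the data")
        self.data = data
        self.obs = sub.reset_index(drop=True)
        ids, idx = np.unique(self.obs["subject_id"].to_numpy(), return_inverse=True)
        self.subject_ids = ids
        self._subj_idx = idx
        order = np.argsort(idx, kind="stable")
        self._order = order
        self._seg_starts = np.searchsorted(idx[order], np.arange(ids.size))
        self.y = self.obs["value"].to_numpy(dtype=float)[order]
        self.t = self.obs["time_wk"].to_numpy(dtype=float)[order]
        self.auc = self.obs["auc"].to_numpy(dtype=float)[order]

    # -- step-specific hooks -------------------------------------------------
    def _pred(self, theta: Mapping[str, float], eta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _sd(self, theta: Mapping[str, float], pred: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _moment_init(self) -> dict[str, float]:
        raise NotImplementedError

    # -- likelihood ----------------------------------------------------------
    def _per_subject_loglik(self, theta, u, logw):
        omega = theta[self.omega_name]
        eta = (omega * u)[:, None]
        pred = self._pred(theta, eta)
        sd = self._sd(theta, pred)
        lp = -0.5 * ((self.y - pred) / sd) ** 2 - np.log(sd) - 0.5 * _LOG2PI
        per_sub = np.add.reduceat(lp, self._seg_starts, axis=1)
        if u.size == 1:
            return per_sub[0]
        return logsumexp(per_sub + logw[:, None], axis=0)

    def loglike(self, theta: Mapping[str, float], *, n_nodes: int = 151,
                span: float = 6.0) -> float:
        """Marginal log-likelihood at natural-scale parameters."""
        if theta[self.omega_name] == 0.0:
            u, logw = np.zeros(1), np.zeros(1)
        else:
            u, logw = _trapezoid_nodes(n_nodes, span)
        return float(self._per_subject_loglik(theta, u, logw).sum())

    # -- transforms ----------------------------------------------------------
    def _to_internal(self, theta: Mapping[str, float]) -> np.ndarray:
        x = []
        for name, kind in self.param_spec:
            v = theta[name]
            if kind == "log":
                x.append(np.log(v))
            elif kind == "logit":
                v = min(max(v, 1e-8), 1 - 1e-8)
                x.append(np.log(v / (1 - v)))
            else:
                x.append(v)
        return np.asarray(x)

    def _to_natural(self, x: np.ndarray) -> dict[str, float]:
        theta = {}
        for (name, kind), xi in zip(self.param_spec, x):
            if kind == "log":
                theta[name] = float(np.exp(np.clip(xi, -700, 700)))
            elif kind == "logit":
                theta[name] = float(1.0 / (1.0 + np.exp(-np.clip(xi, -35, 35))))
            else:
                theta[name] = float(xi)
        return theta

    # -- fitting -------------------------------------------------------------
    def fit(self, start: Mapping[str, float] | None = None,
            options: FitOptions | None = None) -> StepResults:
        opts = options or FitOptions()
        u, logw = _trapezoid_nodes(opts.n_nodes, opts.span)

        def objective(x: np.ndarray) -> float:
            theta = self._to_natural(x)
            if theta[self.omega_name] == 0.0:
                ll = self._per_subject_loglik(theta, np.zeros(1), np.zeros(1))
            else:
                ll = self._per_subject_loglik(theta, u, logw)
            val = -float(ll.sum())
            return val if np.isfinite(val) else 1e12

        theta0 = dict(self._moment_init())
        if start:
            theta0.update(start)
        x0 = self._to_internal(theta0)
        rng = np.random.default_rng(opts.seed)
        starts = [x0] + [x0 + rng.normal(0.0, 0.25, size=x0.size)
                         for _ in range(max(0, opts.n_starts - 1))]
        # coarse screen of all starts, then one full polish of the winner
        best_x, best_f = starts[0], np.inf
        if len(starts) > 1:
            for x_start in starts:
                res = optimize.minimize(
                    objective, x_start, method="Nelder-Mead",
                    options={"maxfev": 300, "fatol": 0.05, "xatol": 1e-3,
                             "adaptive": True})
                if res.fun < best_f:
                    best_x, best_f = res.x, res.fun
        # full polish with fresh-simplex restarts (Nelder-Mead can report
        # convergence from a degenerate simplex)
        best = optimize.minimize(
            objective, best_x, method="Nelder-Mead",
            options={"maxfev": opts.maxfev, "fatol": opts.fatol,
                     "xatol": opts.xatol, "adaptive": True})
        for _ in range(4):
            res = optimize.minimize(
                objective, best.x, method="Nelder-Mead",
                options={"maxfev": opts.maxfev, "fatol": opts.fatol,
                         "xatol": opts.xatol, "adaptive": True})
            improved = best.fun - res.fun
            if res.fun < best.fun:
                best = res
            if improved < 10 * opts.fatol:
                break
        theta_hat = self._to_natural(best.x)
        llf = -float(best.fun)
        converged = bool(best.success)
        message = str(best.message)
        if not converged:
            logger.warning("step %d optimizer did not converge: %s", self.step, message)

        se, rse, se_method = {}, {}, "hessian"
        if opts.compute_se:
            se, rse, se_method = self._standard_errors(best.x, objective)
        for name, kind in self.param_spec:
            v = theta_hat[name]
            if kind == "logit" and (v > 0.98 or v < 1e-4):
                message += f"; warning: {name} near bound ({v:.3g})"
                logger.warning("step %d: %s at bound (%.3g)", self.step, name, v)

        eta, eta_sd = self._ebe(theta_hat)
        return StepResults(
            step=self.step, params=theta_hat, se=se, rse_percent=rse,
            llf=llf, converged=converged, message=message,
            n_subjects=self.subject_ids.size, n_obs=self.y.size,
            driver_mode=getattr(self, "driver_mode", "-"),
            subject_ids=self.subject_ids, eta=eta, eta_sd=eta_sd,
            se_method=se_method, fixed=dict(getattr(self, "fixed", {})))

    def _standard_errors(self, x_hat, objective):
        n = x_hat.size
        h = 1e-3 * (1.0 + np.abs(x_hat))
        H = np.empty((n, n))
        f0 = objective(x_hat)
        for i in range(n):
            for j in range(i, n):
                if i == j:
                    fp = objective(x_hat + h[i] * _unit(n, i))
                    fm = objective(x_hat - h[i] * _unit(n, i))
                    H[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
                else:
                    fpp = objective(x_hat + h[i] * _unit(n, i) + h[j] * _unit(n, j))
                    fpm = objective(x_hat + h[i] * _unit(n, i) - h[j] * _unit(n, j))
                    fmp = objective(x_hat - h[i] * _unit(n, i) + h[j] * _unit(n, j))
                    fmm = objective(x_hat - h[i] * _unit(n, i) - h[j] * _unit(n, j))
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        se_method = "hessian"
        try:
            cov = np.linalg.inv(H)
            if np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError("non-positive variances")
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
            cov = np.where(np.diag(cov)[None, :] * np.eye(len(H)) < 0, np.nan, cov)
            se_method = "pseudoinverse (ill-conditioned information)"
            logger.warning("step %d: ill-conditioned observed information; "
                           "consider bootstrap SEs", self.step)
        theta = self._to_natural(x_hat)
        se, rse = {}, {}
        for i, (name, kind) in enumerate(self.param_spec):
            v = theta[name]
            jac = v if kind == "log" else (v * (1 - v) if kind == "logit" else 1.0)
            var = cov[i, i]
            s = float(np.sqrt(var) * abs(jac)) if var > 0 else float("nan")
            se[name] = s
            rse[name] = float(100.0 * s / abs(v)) if v != 0 else float("inf")
        return se, rse, se_method

    def _ebe(self, theta: Mapping[str, float], n_grid: int = 801,
             span: float = 6.0) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mode and curvature-based sd of eta per subject."""
        omega = theta[self.omega_name]
        if omega == 0.0:
            z = np.zeros(self.subject_ids.size)
            return z, z.copy()
        u = np.linspace(-span, span, n_grid)
        eta = (omega * u)[:, None]
        pred = self._pred(theta, eta)
        sd = self._sd(theta, pred)
        lp = -0.5 * ((self.y - pred) / sd) ** 2 - np.log(sd)
        per_sub = np.add.reduceat(lp, self._seg_starts, axis=1)
        joint = per_sub - 0.5 * u[:, None] ** 2
        k = np.argmax(joint, axis=0)
        # parabolic refinement where the argmax is interior
        km = np.clip(k, 1, n_grid - 2)
        f0, f1, f2 = (joint[km - 1, np.arange(km.size)],
                      joint[km, np.arange(km.size)],
                      joint[km + 1, np.arange(km.size)])
        denom = f0 - 2 * f1 + f2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (f0 - f2) / denom, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        du = u[1] - u[0]
        # posterior sd from the log-joint curvature at the mode (in eta units)
        curv = np.maximum(-denom / du ** 2, 1e-10)
        sd = np.minimum(omega / np.sqrt(curv), omega)
        return omega * (u[km] + shift * du), sd


def _unit(n: int, i: int) -> np.ndarray:
    e = np.zeros(n)
    e[i] = 1.0
    return e


def _emax(auc, imax, iauc50):
    return imax * auc / (iauc50 + auc)


class BasalInsulinStep(_StepModel):
    """Step 1: basal insulin dose vs exposure (lognormal IIV on imax_ins)."""

    step = 1
    omega_name = "omega_imax_ins"
    param_spec = (("imax_ins", "logit"), ("iauc50_ins", "log"),
                  ("omega_imax_ins", "log"), ("b_ins", "log"))

    def __init__(self, data: ObservationTable):
        super().__init__(data, "basal_insulin")
        self.ins0 = self.obs["ins0"].to_numpy(dtype=float)[self._order]
        self.driver_mode = "-"
        self.fixed = {}

    def _pred(self, theta, eta):
        imax_i = np.minimum(theta["imax_ins"] * np.exp(eta), IMAX_CLIP)
        frac = self.auc / (theta["iauc50_ins"] + self.auc)
        ratio = 1.0 - imax_i * frac
        on = self.t > 0
        return np.where(on, self.ins0 * ratio, self.ins0 * np.ones_like(ratio))

    def _sd(self, theta, pred):
        return theta["b_ins"] * np.maximum(pred, 1e-8)

    def _moment_init(self):
        base = self.y[self.t == 0] / self.ins0[self.t == 0]
        b0 = float(np.std(base - 1.0)) if base.size > 3 else 0.2
        b0 = min(max(b0, 0.02), 0.6)
        on = (self.t > 0) & (self.auc > 0)
        init = {"imax_ins": 0.1, "iauc50_ins": 50.0,
                "omega_imax_ins": 0.8, "b_ins": b0}
        if on.sum() >= 4:
            ratio = self.y[on] / self.ins0[on]
            effect = np.clip(1.0 - ratio, 1e-4, 0.95)
            auc = self.auc[on]
            best = None
            for i50 in (10.0, 30.0, 100.0, 300.0):
                f = auc / (i50 + auc)
                imax = float(np.clip(np.sum(effect * f) / np.sum(f * f), 0.005, 0.9))
                sse = float(np.sum((effect - imax * f) ** 2))
                if best is None or sse < best[0]:
                    best = (sse, imax, i50)
            init["imax_ins"], init["iauc50_ins"] = best[1], best[2]
            # dispersion of per-subject mean log-effects approximates the
            # lognormal omega (noise contributes ~b/sqrt(n_i) extra)
            sub = pd.DataFrame({"s": np.asarray(
                self.obs["subject_id"])[self._order][on], "e": effect})
            per_sub = sub.groupby("s")["e"].mean()
            if len(per_sub) > 5:
                init["omega_imax_ins"] = float(
                    np.clip(np.std(np.log(per_sub)), 0.05, 2.0))
        return init


def _interp_ratio(sub: pd.DataFrame, baseline_col: str,
                  query_t: np.ndarray) -> np.ndarray:
    """Per-subject linear-in-time interpolation of observed value/baseline."""
    t = sub["time_wk"].to_numpy(dtype=float)
    r = sub["value"].to_numpy(dtype=float) / sub[baseline_col].to_numpy(dtype=float)
    order = np.argsort(t)
    return np.interp(query_t, t[order], r[order])


class GlucoseStep(_StepModel):
    """Step 2: CGM glucose vs insulin ratio, exposure and time.

    Additive normal IIV on keff (its dispersion is twice the population
    value, so a lognormal family would be implausible and would forbid
    the negative drifts seen in placebo subjects).
    """

    step = 2
    omega_name = "omega_keff"
    param_spec = (("k1", "log"), ("keff", "identity"), ("omega_keff", "log"),
                  ("imax_glu", "logit"), ("iauc50_glu", "log"), ("b_glu", "log"))

    def __init__(self, data: ObservationTable, *, driver_mode: str = "ebe",
                 step1: StepResults | None = None,
                 fallback: StructuralParameters | None = None):
        super().__init__(data, "cgm_glucose")
        self.glu0 = self.obs["glu0"].to_numpy(dtype=float)[self._order]
        self.driver_mode = driver_mode
        self.fixed = {}
        self.insulin_ratio = self._build_driver(data, driver_mode, step1,
                                                fallback or StructuralParameters())

    def _build_driver(self, data, mode, step1, fb):
        n = self.y.size
        sids = self.obs["subject_id"].to_numpy()[self._order]
        if mode == "observed":
            r = np.ones(n)
            ins = data.subset("basal_insulin")
            ins = ins[ins["time_wk"] > 0]
            groups = dict(tuple(ins.groupby("subject_id")))
            for i in range(n):
                if self.t[i] == 0:
                    continue
                g = groups.get(sids[i])
                if g is None or len(g) == 0:
                    imax = step1.params["imax_ins"] if step1 else fb.imax_ins
                    i50 = step1.params["iauc50_ins"] if step1 else fb.iauc50_ins
                    r[i] = 1.0 - _emax(self.auc[i], imax, i50)
                else:
                    r[i] = _interp_ratio(g, "ins0", np.array([self.t[i]]))[0]
            return np.clip(r, 0.05, None)
        # ebe / population: time-constant individual or population ratio
        if step1 is not None:
            imax, i50 = step1.params["imax_ins"], step1.params["iauc50_ins"]
            eta = pd.Series(step1.eta, index=step1.subject_ids) \
                if mode == "ebe" else None
        else:
            imax, i50 = fb.imax_ins, fb.iauc50_ins
            eta = None
        eta_i = np.zeros(n) if eta is None else \
            eta.reindex(sids).fillna(0.0).to_numpy()
        imax_i = np.minimum(imax * np.exp(eta_i), IMAX_CLIP)
        r = 1.0 - imax_i * self.auc / (i50 + self.auc)
        return np.clip(np.where(self.t > 0, r, 1.0), 0.05, None)

    def _pred(self, theta, eta):
        drift = np.maximum(1.0 + (theta["keff"] + eta) * self.t, _FACTOR_FLOOR)
        drug = 1.0 - _emax(self.auc, theta["imax_glu"], theta["iauc50_glu"])
        on = self.t > 0
        gratio = drift * self.insulin_ratio ** (-theta["k1"]) * drug
        return np.where(on, self.glu0 * gratio, self.glu0 * np.ones_like(gratio))

    def _sd(self, theta, pred):
        return theta["b_glu"] * np.maximum(pred, 1e-8)

    def _moment_init(self):
        base = self.y[self.t == 0] / self.glu0[self.t == 0]
        b0 = float(np.std(base - 1.0)) if base.size > 3 else 0.16
        b0 = min(max(b0, 0.02), 0.6)
        init = {"k1": 0.05, "keff": 0.002, "omega_keff": 0.004,
                "imax_glu": 0.12, "iauc50_glu": 80.0, "b_glu": b0}
        pl = (self.t > 0) & (self.auc == 0)
        if pl.sum() >= 4:
            slope = (self.y[pl] / self.glu0[pl] - 1.0) / self.t[pl]
            keff0 = float(np.clip(np.mean(slope), -0.01, 0.02))
            init["keff"] = keff0 if abs(keff0) > 1e-5 else 1e-4
            init["omega_keff"] = float(np.clip(np.std(slope), 1e-4, 0.05))
        on = (self.t > 0) & (self.auc > 0)
        if on.sum() >= 4:
            drift = 1.0 + init["keff"] * self.t[on]
            effect = np.clip(1.0 - self.y[on] / (self.glu0[on] * drift), 1e-4, 0.9)
            auc = self.auc[on]
            best = None
            for i50 in (20.0, 70.0, 200.0, 600.0):
                f = auc / (i50 + auc)
                imax = float(np.clip(np.sum(effect * f) / np.sum(f * f), 0.01, 0.9))
                sse = float(np.sum((effect - imax * f) ** 2))
                if best is None or sse < best[0]:
                    best = (sse, imax, i50)
            init["imax_glu"], init["iauc50_glu"] = best[1], best[2]
        return init


class HbA1cStep(_StepModel):
    """Step 3: HbA1c vs glucose ratio and exposure (lognormal IIV on k2).

    The half-maximal exposure of the direct drug effect is fixed to the
    step-2 glucose IAUC50.
    """

    step = 3
    omega_name = "omega_k2"
    param_spec = (("k2", "log"), ("omega_k2", "log"),
                  ("imax_hba1c", "logit"), ("a_hba1c", "log"))

    def __init__(self, data: ObservationTable, *, driver_mode: str = "ebe",
                 step1: StepResults | None = None,
                 step2: StepResults | None = None,
                 fallback: StructuralParameters | None = None):
        super().__init__(data, "hba1c")
        self.hba1c0 = self.obs["hba1c0"].to_numpy(dtype=float)[self._order]
        self.driver_mode = driver_mode
        fb = fallback or StructuralParameters()
        self.iauc50_fixed = float(step2.params["iauc50_glu"]) if step2 is not None \
            else fb.iauc50_glu
        self.fixed = {"iauc50_hba1c": self.iauc50_fixed}
        # filled by _build_driver: propagated step-2 uncertainty
        self.dg_dkeff = np.zeros(self.y.size)
        self.keff_sd_subject = np.zeros(self.subject_ids.size)
        self._n_per_subject = np.diff(self._seg_starts, append=self.y.size)
        self.glucose_ratio_driver = self._build_driver(
            data, driver_mode, step1, step2, fb)

    def _build_driver(self, data, mode, step1, step2, fb):
        n = self.y.size
        sids = self.obs["subject_id"].to_numpy()[self._order]
        if mode == "observed":
            g = np.ones(n)
            cgm = data.subset("cgm_glucose")
            groups = dict(tuple(cgm.groupby("subject_id")))
            for i in range(n):
                if self.t[i] == 0:
                    continue
                grp = groups.get(sids[i])
                if grp is not None and len(grp) > 0:
                    g[i] = _interp_ratio(grp, "glu0", np.array([self.t[i]]))[0]
            return np.clip(g, 0.05, None)
        if step1 is not None:
            imax1, i501 = step1.params["imax_ins"], step1.params["iauc50_ins"]
            eta1 = pd.Series(step1.eta, index=step1.subject_ids)
        else:
            imax1, i501 = fb.imax_ins, fb.iauc50_ins
            eta1 = None
        if step2 is not None:
            k1 = step2.params["k1"]
            keff = step2.params["keff"]
            imax2, i502 = step2.params["imax_glu"], step2.params["iauc50_glu"]
            eta2 = pd.Series(step2.eta, index=step2.subject_ids)
        else:
            k1, keff = fb.k1, fb.keff
            imax2, i502 = fb.imax_glu, fb.iauc50_glu
            eta2 = None
        use_eta = mode == "ebe"
        e1 = np.zeros(n) if (eta1 is None or not use_eta) else \
            eta1.reindex(sids).fillna(0.0).to_numpy()
        e2 = np.zeros(n) if (eta2 is None or not use_eta) else \
            eta2.reindex(sids).fillna(0.0).to_numpy()
        imax_i = np.minimum(imax1 * np.exp(e1), IMAX_CLIP)
        r = np.clip(1.0 - imax_i * self.auc / (i501 + self.auc), 0.05, None)
        drift = np.maximum(1.0 + (keff + e2) * self.t, _FACTOR_FLOOR)
        base = r ** (-k1) * (1.0 - _emax(self.auc, imax2, i502))
        g = drift * base
        if use_eta and step2 is not None and step2.eta_sd is not None:
            # the subject's glucose drift is only partially identified by
            # the CGM visits; its posterior sd enters the step-3 likelihood
            # through a rank-one covariance term (dg/dkeff = t * base)
            self.dg_dkeff = np.where(self.t > 0, self.t * base, 0.0)
            sd = pd.Series(step2.eta_sd, index=step2.subject_ids)
            self.keff_sd_subject = sd.reindex(self.subject_ids).fillna(0.0).to_numpy()
        return np.where(self.t > 0, g, 1.0)

    def _pred(self, theta, eta):
        k2_i = theta["k2"] * np.exp(eta)
        factor = np.maximum(1.0 + k2_i * (self.glucose_ratio_driver - 1.0),
                            _FACTOR_FLOOR)
        direct = 1.0 - _emax(self.auc, theta["imax_hba1c"], self.iauc50_fixed)
        on = self.t > 0
        return np.where(on, self.hba1c0 * factor * direct,
                        self.hba1c0 * np.ones_like(factor))

    def _sd(self, theta, pred):
        return np.full_like(pred, theta["a_hba1c"])

    def _per_subject_loglik(self, theta, u, logw):
        """Marginal over the k2 random effect, with the uncertainty of the
        subject's glucose drift (from step 2) integrated out analytically.

        Conditional on k2, the drift deviation enters the predictions
        linearly, so the subject's observation vector is multivariate
        normal with covariance a^2 I + s_i^2 v v^T; the Sherman-Morrison
        identity gives the quadratic form and determinant in closed form.
        """
        omega = theta[self.omega_name]
        eta = (omega * u)[:, None]
        k2_i = theta["k2"] * np.exp(eta)
        g = self.glucose_ratio_driver
        on = self.t > 0
        direct = 1.0 - _emax(self.auc, theta["imax_hba1c"], self.iauc50_fixed)
        factor = np.maximum(1.0 + k2_i * (g - 1.0), _FACTOR_FLOOR)
        mu = np.where(on, self.hba1c0 * factor * direct,
                      self.hba1c0 * np.ones_like(factor))
        e = self.y - mu
        v = np.where(on, self.hba1c0 * k2_i * direct * self.dg_dkeff, 0.0)
        a2 = theta["a_hba1c"] ** 2
        s2 = self.keff_sd_subject ** 2
        Se2 = np.add.reduceat(e * e, self._seg_starts, axis=1)
        Sve = np.add.reduceat(v * e, self._seg_starts, axis=1)
        Sv2 = np.add.reduceat(v * v, self._seg_starts, axis=1)
        denom = a2 + s2 * Sv2
        quad = (Se2 - s2 * Sve ** 2 / denom) / a2
        logdet = self._n_per_subject * np.log(a2) + np.log(denom / a2)
        ll = -0.5 * (quad + logdet + self._n_per_subject * _LOG2PI)
        if u.size == 1:
            return ll[0]
        return logsumexp(ll + logw[:, None], axis=0)

    def _moment_init(self):
        base = self.y[self.t == 0] - self.hba1c0[self.t == 0]
        a0 = float(np.std(base)) if base.size > 3 else 0.06
        a0 = min(max(a0, 0.005), 0.5)
        init = {"k2": 0.2, "omega_k2": 0.6, "imax_hba1c": 0.03, "a_hba1c": a0}
        pl = (self.t > 0) & (self.auc == 0)
        g = self.glucose_ratio_driver
        if pl.sum() >= 4 and np.std(g[pl]) > 1e-6:
            x = g[pl] - 1.0
            yrel = self.y[pl] / self.hba1c0[pl] - 1.0
            k2_0 = float(np.sum(x * yrel) / np.sum(x * x))
            init["k2"] = float(np.clip(k2_0, 0.02, 1.0))
        on = (self.t > 0) & (self.auc > 0)
        if on.sum() >= 4:
            factor = 1.0 + init["k2"] * (g[on] - 1.0)
            effect = np.clip(1.0 - self.y[on] / (self.hba1c0[on] * factor),
                             1e-4, 0.5)
            f = self.auc[on] / (self.iauc50_fixed + self.auc[on])
            init["imax_hba1c"] = float(np.clip(
                np.sum(effect * f) / np.sum(f * f), 0.002, 0.5))
        return init


_STEP_CLASSES = {1: BasalInsulinStep, 2: GlucoseStep, 3: HbA1cStep}


def fit_step(step_id: int, data: ObservationTable,
             init: Mapping[str, float] | None = None,
             options: FitOptions | None = None, *,
             driver_mode: str = "ebe",
             step1: StepResults | None = None,
             step2: StepResults | None = None) -> StepResults:
    """Fit one estimation step; steps 2-3 condition on earlier results."""
    if step_id not in _STEP_CLASSES:
        raise ValueError("step_id must be 1, 2 or 3")
    if driver_mode not in ("ebe", "observed", "population"):
        raise ValueError(f"unknown driver_mode {driver_mode!r}")
    if step_id == 1:
        model = BasalInsulinStep(data)
    elif step_id == 2:
        model = GlucoseStep(data, driver_mode=driver_mode, step1=step1)
    else:
        model = HbA1cStep(data, driver_mode=driver_mode, step1=step1, step2=step2)
    return model.fit(start=init, options=options)


@dataclass
class SequentialResults:
    """Joint container for the three step fits."""

    steps: dict[int, StepResults]
    driver_mode: str

    @property
    def converged(self) -> bool:
        return all(s.converged for s in self.steps.values())

    @property
    def structural(self) -> StructuralParameters:
        p = {}
        for s in self.steps.values():
            for k, v in s.params.items():
                if not k.startswith("omega_"):
                    p[k] = v
        return StructuralParameters(**p)

    @property
    def random_effects(self) -> RandomEffectSpec:
        return RandomEffectSpec(effects={
            "imax_ins": RandomEffect(self.steps[1].params["omega_imax_ins"], "lognormal"),
            "keff": RandomEffect(abs(self.steps[2].params["omega_keff"]), "normal"),
            "k2": RandomEffect(self.steps[3].params["omega_k2"], "lognormal"),
        })

    @property
    def table(self) -> pd.DataFrame:
        """Machine-readable estimate table (step, parameter, estimate, RSE%)."""
        rows = []
        for sid, s in sorted(self.steps.items()):
            for k, v in s.params.items():
                rows.append({"step": sid, "parameter": k, "estimate": v,
                             "se": s.se.get(k, np.nan),
                             "rse_percent": s.rse_percent.get(k, np.nan)})
            for k, v in s.fixed.items():
                rows.append({"step": sid, "parameter": k, "estimate": v,
                             "se": np.nan, "rse_percent": np.nan})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        parts = [f"Sequential exposure-response fit ({self.driver_mode} drivers)"]
        parts += [s.summary() for _, s in sorted(self.steps.items())]
        return "\n\n".join(parts)


def fit_sequential(data: ObservationTable,
                   options: FitOptions | None = None, *,
                   driver_mode: str = "ebe",
                   init: Mapping[str, float] | None = None) -> SequentialResults:
    """Run the three estimation steps in sequence."""
    opts = options or FitOptions()
    init = dict(init or {})

    def sub_init(model_cls):
        names = {n for n, _ in model_cls.param_spec}
        return {k: v for k, v in init.items() if k in names} or None

    r1 = BasalInsulinStep(data).fit(start=sub_init(BasalInsulinStep), options=opts)
    r2 = GlucoseStep(data, driver_mode=driver_mode, step1=r1).fit(
        start=sub_init(GlucoseStep), options=opts)
    r3 = HbA1cStep(data, driver_mode=driver_mode, step1=r1, step2=r2).fit(
        start=sub_init(HbA1cStep), options=opts)
    return SequentialResults(steps={1: r1, 2: r2, 3: r3}, driver_mode=driver_mode)
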