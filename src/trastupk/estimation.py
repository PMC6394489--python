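"""Nonlinear mixed-effects estimation for the structural PK model.

The marginal likelihood integrates the lognormal random effects out of
each subject's data with a Laplace approximation at the posterior eta
mode (damped Newton inner search, compiled kernels).  The outer problem
maximizes the summed Laplace log-likelihood over log-transformed
structural parameters, covariate coefficients, log random-effect SDs (an
arctanh-transformed CL-Vc correlation keeps Omega positive definite) and
log residual SDs, with L-BFGS-B and finite-difference gradients.

Covariates enter the typical parameters multiplicatively:

* ``power``       -- (x / reference)^coef, for continuous covariates
                     centered at a fixed reference value;
* ``exponential`` -- exp(coef * x), for binary flags;
* ``indicator``   -- exp(coef * [column == level]), for categorical
                     contrasts against a reference category.

The stepwise covariate search mirrors standard pharmacometric practice:
a univariate screen (p < 0.005), forward addition (p < 0.001), backward
elimination (p < 0.001), then a clinical-relevance filter that drops
covariates whose span across the observed range moves none of Cmin,ss,
Cmax,ss or AUC,ss by more than 15%.

Below-quantification-limit observations are dropped before fitting
(assay LLOQ 0.156 ug/mL), matching the source analysis.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _engine
from .parameters import (PopulationParameters, CovariateVector,
                         SubjectParameters, TumorType)
from .regimen import Regimen, Q3W, build_schedule, simulate_subject, \
    steady_state_metrics

__all__ = [
    "LLOQ",
    "PKDataset",
    "CovariateEffect",
    "ModelConfig",
    "FitResult",
    "LikelihoodModel",
    "subject_loglik",
    "marginal_loglik",
    "fit",
    "lrt",
    "empirical_bayes",
    "stepwise_covariates",
    "StepwiseResult",
]

#: assay lower limit of quantification (ug/mL)
LLOQ = 0.156

PARAM_ORDER = ("cl", "vc", "q", "vp", "vmax", "km")
ETA_ORDER = ("cl", "vc", "vp", "km")
_ETA_SLOT = {"cl": 0, "vc": 1, "vp": 3, "km": 5}

_REQUIRED = ("ID", "TIME", "AMT", "EVID", "DV", "MDV")


@dataclass
class PKDataset:
    """NONMEM-style rectangular event records.

    Columns (case-insensitive on input): ID, TIME (day), AMT (mg),
    EVID (1 dose / 0 observation), DV (ug/mL), MDV, optional RATE
    (mg/day) and covariate columns (WT, SGOT, ALBU, LMET, TTYPE, ...).
    Every subject must be evaluable: at least one dose and one
    observation, with non-negative times sorted within subject.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        df.columns = [str(c).upper() for c in df.columns]
        for col in _REQUIRED:
            if col not in df.columns:
                raise ValueError(f"missing required column {col}")
        if "RATE" not in df.columns:
            df["RATE"] = 0.0
        df["RATE"] = pd.to_numeric(df["RATE"].replace(".", 0.0)).fillna(0.0)
        for col in ("TIME", "AMT", "DV", "MDV", "EVID"):
            df[col] = pd.to_numeric(df[col].replace(".", np.nan))
        df["AMT"] = df["AMT"].fillna(0.0)
        if (df["TIME"] < 0).any():
            raise ValueError("negative TIME values")
        for sid, sub in df.groupby("ID", sort=False):
            if not sub["TIME"].is_monotonic_increasing:
                raise ValueError(f"times not sorted for subject {sid}")
            if not ((sub["EVID"] == 1) & (sub["AMT"] > 0)).any():
                raise ValueError(f"subject {sid} has no dose record")
            if not ((sub["EVID"] == 0) & (sub["MDV"] == 0)).any():
                raise ValueError(f"subject {sid} has no observation")
        obs = df["EVID"] == 0
        bad = obs & (df["MDV"] == 0) & df["DV"].isna()
        if bad.any():
            raise ValueError("observation records with MDV=0 must carry DV")
        self.df = df

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    def drop_blq(self, lloq: float = LLOQ) -> tuple["PKDataset", int]:
        """Drop observations below the quantification limit (M1 handling).

        Subjects left without any observation are excluded entirely; both
        counts are reflected in the returned dataset.
        """
        df = self.df
        blq = (df["EVID"] == 0) & (df["MDV"] == 0) & (df["DV"] < lloq)
        n_dropped = int(blq.sum())
        out = df[~blq]
        keep_ids = out.groupby("ID").apply(
            lambda s: ((s["EVID"] == 0) & (s["MDV"] == 0)).any(),
            include_groups=False)
        out = out[out["ID"].isin(keep_ids[keep_ids].index)]
        return PKDataset(out.reset_index(drop=True)), n_dropped


@dataclass(frozen=True)
class CovariateEffect:
    """One multiplicative covariate term on a structural parameter."""

    parameter: str            # one of PARAM_ORDER
    covariate: str            # dataset column
    form: str                 # 'power' | 'exponential' | 'indicator'
    reference: float = 1.0    # centering value for 'power'
    level: str | None = None  # category for 'indicator'
    init: float = 0.1

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_ORDER:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.form not in ("power", "exponential", "indicator"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.form == "power" and self.reference <= 0:
            raise ValueError("power effects need a positive reference")
        if self.form == "indicator" and self.level is None:
            raise ValueError("indicator effects need a level")

    def design_column(self, df_sub: pd.DataFrame) -> np.ndarray:
        col = df_sub[self.covariate.upper()]
        if self.form == "power":
            return np.log(pd.to_numeric(col).to_numpy() / self.reference)
        if self.form == "exponential":
            return pd.to_numeric(col).to_numpy().astype(float)
        return (col.astype(str).str.upper() == str(self.level).upper()) \
            .to_numpy().astype(float)

    @property
    def label(self) -> str:
        lv = f"=={self.level}" if self.level else ""
        return f"{self.covariate}{lv}->{self.parameter} ({self.form})"


@dataclass
class ModelConfig:
    """What to estimate and from which starting values."""

    theta_init: dict = field(default_factory=lambda: {
        "cl": 0.15, "vc": 2.5, "q": 0.5, "vp": 3.0, "vmax": 8.0, "km": 9.0})
    estimate_theta: tuple = ("cl", "vc", "vp", "vmax")
    covariate_effects: tuple = ()
    eta_on: tuple = ("cl", "vc")
    omega_init: dict = field(default_factory=lambda: {
        "cl": 0.3, "vc": 0.25, "vp": 0.4, "km": 0.8})
    estimate_omega: bool = True
    corr_cl_vc_init: float = 0.0
    estimate_corr_cl_vc: bool = False
    sigma_init: tuple = (0.2, 1.0)
    estimate_sigma: tuple = ("prop",)
    h_max: float = 0.2

    def __post_init__(self) -> None:
        for p in self.estimate_theta:
            if p not in PARAM_ORDER:
                raise ValueError(f"unknown structural parameter {p!r}")
        for p in self.eta_on:
            if p not in ETA_ORDER:
                raise ValueError(f"no random effect defined on {p!r}")
        self.covariate_effects = tuple(self.covariate_effects)
        if self.estimate_corr_cl_vc and not {"cl", "vc"} <= set(self.eta_on):
            raise ValueError("CL-Vc correlation needs eta on both CL and Vc")

    def with_effect(self, eff: CovariateEffect) -> "ModelConfig":
        return dataclasses.replace(
            self, covariate_effects=self.covariate_effects + (eff,))

    def without_effect(self, eff: CovariateEffect) -> "ModelConfig":
        return dataclasses.replace(
            self, covariate_effects=tuple(e for e in self.covariate_effects
                                          if e != eff))


@dataclass
class FitResult:
    theta: dict
    covariate_coefs: dict
    omega: dict
    corr_cl_vc: float
    sigma: tuple
    ofv: float
    ebe: pd.DataFrame
    converged: bool
    n_inner_failures: int
    message: str
    n_subjects: int
    n_obs: int
    config: ModelConfig


class LikelihoodModel:
    """Packed data + parameter transform for one model configuration."""

    def __init__(self, data: PKDataset, config: ModelConfig):
        self.config = config
        df = data.df
        self.subject_ids = df["ID"].drop_duplicates().to_numpy()
        obs_t, dv, dose_t, dose_amt, dose_dur = [], [], [], [], []
        obs_ptr, dose_ptr = [0], [0]
        sub_rows = []
        for sid in self.subject_ids:
            sub = df[df["ID"] == sid]
            o = sub[(sub["EVID"] == 0) & (sub["MDV"] == 0)]
            d = sub[(sub["EVID"] == 1) & (sub["AMT"] > 0)]
            obs_t.append(o["TIME"].to_numpy(float))
            dv.append(o["DV"].to_numpy(float))
            dose_t.append(d["TIME"].to_numpy(float))
            dose_amt.append(d["AMT"].to_numpy(float))
            rate = d["RATE"].to_numpy(float)
            amt = d["AMT"].to_numpy(float)
            dur = np.where(rate > 0, amt / np.maximum(rate, 1e-300), 0.0)
            dose_dur.append(dur)
            obs_ptr.append(obs_ptr[-1] + len(o))
            dose_ptr.append(dose_ptr[-1] + len(d))
            sub_rows.append(sub.iloc[0])
        self.obs_t = np.concatenate(obs_t)
        self.dv = np.concatenate(dv)
        self.dose_t = np.concatenate(dose_t)
        self.dose_amt = np.concatenate(dose_amt)
        self.dose_dur = np.concatenate(dose_dur)
        self.obs_ptr = np.array(obs_ptr, dtype=np.int64)
        self.dose_ptr = np.array(dose_ptr, dtype=np.int64)
        self.n = len(self.subject_ids)
        self.n_obs = len(self.obs_t)
        sub_df = pd.DataFrame(sub_rows).reset_index(drop=True)
        # design columns for covariate effects, fixed across iterations
        self.designs = [eff.design_column(sub_df) for eff in
                        config.covariate_effects]
        self.sub_df = sub_df
        d = len(config.eta_on)
        self.d = d
        self.eta_idx = np.array([_ETA_SLOT[p] for p in config.eta_on],
                                dtype=np.int64)
        self.eta_warm = np.zeros((self.n, d))
        obs_per_subject = np.diff(self.obs_ptr)
        if np.median(obs_per_subject) < d + 1:
            warnings.warn(
                "sparse design: median observations per subject below "
                "n_random_effects + 1; the fit may be poorly identified",
                stacklevel=2)

    # -- parameter transform -------------------------------------------
    def x0(self) -> np.ndarray:
        c = self.config
        x = [math.log(c.theta_init[p]) for p in c.estimate_theta]
        x += [eff.init for eff in c.covariate_effects]
        if c.estimate_omega:
            x += [math.log(max(c.omega_init[p], 1e-3)) for p in c.eta_on]
        if c.estimate_corr_cl_vc:
            x.append(math.atanh(np.clip(c.corr_cl_vc_init, -0.99, 0.99)))
        if "prop" in c.estimate_sigma:
            x.append(math.log(max(c.sigma_init[0], 1e-4)))
        if "add" in c.estimate_sigma:
            x.append(math.log(max(c.sigma_init[1], 1e-4)))
        return np.array(x)

    def unpack(self, x: np.ndarray):
        c = self.config
        i = 0
        theta = dict(c.theta_init)
        for p in c.estimate_theta:
            theta[p] = math.exp(x[i])
            i += 1
        coefs = {}
        for eff in c.covariate_effects:
            coefs[eff.label] = float(x[i])
            i += 1
        omega = dict(c.omega_init)
        if c.estimate_omega:
            for p in c.eta_on:
                omega[p] = math.exp(x[i])
                i += 1
        corr = c.corr_cl_vc_init
        if c.estimate_corr_cl_vc:
            corr = math.tanh(x[i])
            i += 1
        sig_p, sig_a = c.sigma_init
        if "prop" in c.estimate_sigma:
            sig_p = math.exp(x[i])
            i += 1
        if "add" in c.estimate_sigma:
            sig_a = math.exp(x[i])
            i += 1
        return theta, coefs, omega, corr, (sig_p, sig_a)

    def base_params(self, theta: dict, coef_values: np.ndarray) -> np.ndarray:
        """(n, 6) typical structural parameters after covariate effects."""
        base = np.tile([theta[p] for p in PARAM_ORDER], (self.n, 1))
        for eff, col, coef in zip(self.config.covariate_effects,
                                  self.designs, coef_values):
            j = PARAM_ORDER.index(eff.parameter)
            base[:, j] *= np.exp(coef * col)
        return base

    def omega_block(self, omega: dict, corr: float):
        d = self.d
        if d == 0:
            return np.zeros((0, 0)), np.zeros((0, 0)), 0.0
        om = np.zeros((d, d))
        for a, pa in enumerate(self.config.eta_on):
            om[a, a] = max(omega[pa], 1e-6) ** 2
        if {"cl", "vc"} <= set(self.config.eta_on):
            ia = self.config.eta_on.index("cl")
            ib = self.config.eta_on.index("vc")
            om[ia, ib] = om[ib, ia] = corr * math.sqrt(om[ia, ia] * om[ib, ib])
        om_inv = np.linalg.inv(om)
        _, logdet = np.linalg.slogdet(om)
        return om, om_inv, logdet

    def ofv(self, x: np.ndarray) -> float:
        """-2 log marginal likelihood (Laplace) at packed parameters."""
        theta, coefs, omega, corr, (sig_p, sig_a) = self.unpack(x)
        base = self.base_params(theta, np.array(list(coefs.values())))
        if self.d == 0:
            return self._ofv_fixed(base, sig_p, sig_a)
        _, om_inv, logdet = self.omega_block(omega, corr)
        total, n_fail = _engine.ofv_laplace(
            self.obs_ptr, self.obs_t, self.dv, self.dose_ptr, self.dose_t,
            self.dose_amt, self.dose_dur, base, self.eta_idx, om_inv,
            logdet, sig_p, sig_a, self.eta_warm, self.config.h_max)
        self._last_inner_failures = n_fail
        return float(total)

    def _ofv_fixed(self, base, sig_p, sig_a) -> float:
        total = 0.0
        for i in range(self.n):
            o0, o1 = self.obs_ptr[i], self.obs_ptr[i + 1]
            d0, d1 = self.dose_ptr[i], self.dose_ptr[i + 1]
            f = _engine.simulate_conc(
                self.obs_t[o0:o1], self.dose_t[d0:d1], self.dose_amt[d0:d1],
                self.dose_dur[d0:d1], *base[i], self.config.h_max)
            v = np.maximum((sig_p * f) ** 2 + sig_a ** 2, 1e-12)
            r = self.dv[o0:o1] - f
            total += float(np.sum(np.log(2 * math.pi * v) + r * r / v))
        self._last_inner_failures = 0
        return total

    def eta_modes(self, x: np.ndarray) -> np.ndarray:
        self.ofv(x)
        return self.eta_warm.copy()


def subject_loglik(records: pd.DataFrame, theta: dict, omega: dict,
                   sigma: tuple, eta, eta_on: tuple = ("cl", "vc"),
                   corr_cl_vc: float = 0.0, h_max: float = 0.1) -> float:
    """Joint log density log p(y | eta) + log p(eta) for one subject.

    ``records`` holds the subject's NONMEM-style rows; ``theta`` the
    typical structural values (after any covariate adjustment); ``omega``
    the log-scale SDs keyed like ``eta_on``.  With no observations the
    prior log density alone is returned.
    """
    eta = np.asarray(eta, dtype=float)
    df = records.copy()
    df.columns = [str(c).upper() for c in df.columns]
    obs = df[(df["EVID"] == 0) & (df.get("MDV", 0) == 0)]
    doses = df[(df["EVID"] == 1) & (df["AMT"] > 0)]
    d = len(eta_on)
    if len(eta) != d:
        raise ValueError("eta length must match eta_on")
    om = np.zeros((d, d))
    for a, pa in enumerate(eta_on):
        om[a, a] = omega[pa] ** 2
    if {"cl", "vc"} <= set(eta_on):
        ia, ib = eta_on.index("cl"), eta_on.index("vc")
        om[ia, ib] = om[ib, ia] = corr_cl_vc * omega["cl"] * omega["vc"]
    om_inv = np.linalg.inv(om)
    _, logdet = np.linalg.slogdet(om)
    base = np.array([theta[p] for p in PARAM_ORDER])
    rate = doses["RATE"].to_numpy(float) if "RATE" in doses else \
        np.zeros(len(doses))
    dur = np.where(rate > 0, doses["AMT"].to_numpy(float) / np.maximum(rate, 1e-300), 0.0)
    eta_idx = np.array([_ETA_SLOT[p] for p in eta_on], dtype=np.int64)
    neg2 = _engine._neg2_joint(
        eta, obs["TIME"].to_numpy(float), obs["DV"].to_numpy(float),
        doses["TIME"].to_numpy(float), doses["AMT"].to_numpy(float),
        dur, base, eta_idx, om_inv, logdet, sigma[0], sigma[1], h_max)
    return -0.5 * float(neg2)


def marginal_loglik(data: PKDataset, theta: dict, omega: dict, sigma: tuple,
                    eta_on: tuple = ("cl", "vc"), corr_cl_vc: float = 0.0,
                    covariate_effects: tuple = (), coefs: tuple = (),
                    h_max: float = 0.1) -> float:
    """Laplace-approximate log marginal likelihood of a dataset."""
    config = ModelConfig(theta_init=dict(theta), estimate_theta=(),
                         covariate_effects=tuple(covariate_effects),
                         eta_on=tuple(eta_on), omega_init=dict(omega),
                         estimate_omega=False, corr_cl_vc_init=corr_cl_vc,
                         estimate_corr_cl_vc=False, sigma_init=tuple(sigma),
                         estimate_sigma=(), h_max=h_max)
    model = LikelihoodModel(data, config)
    x = np.asarray(list(coefs), dtype=float)
    if len(x) != len(config.covariate_effects):
        raise ValueError("one coefficient per covariate effect is required")
    return -0.5 * model.ofv(x)


def fit(data: PKDataset, config: ModelConfig, maxiter: int = 200) -> FitResult:
    """Maximize the Laplace marginal likelihood.

    Deterministic given the starting values in ``config``; returns a
    partial result flagged unconverged rather than raising when the
    optimizer stalls.
    """
    model = LikelihoodModel(data, config)
    x0 = model.x0()

    def objective(x):
        val = model.ofv(x)
        if not math.isfinite(val):
            return 1e12
        return val

    res = optimize.minimize(objective, x0, method="L-BFGS-B",
                            options={"maxiter": maxiter, "ftol": 1e-9,
                                     "gtol": 1e-6, "eps": 1e-5})
    theta, coefs, omega, corr, sigma = model.unpack(res.x)
    final_ofv = model.ofv(res.x)  # refresh eta modes at the optimum
    ebe = pd.DataFrame(model.eta_warm,
                       columns=[f"eta_{p}" for p in config.eta_on])
    ebe.insert(0, "ID", model.subject_ids)
    return FitResult(theta=theta, covariate_coefs=coefs, omega=omega,
                     corr_cl_vc=corr, sigma=sigma, ofv=float(final_ofv),
                     ebe=ebe, converged=bool(res.success),
                     n_inner_failures=getattr(model, "_last_inner_failures", 0),
                     message=str(res.message), n_subjects=model.n,
                     n_obs=model.n_obs, config=config)


def lrt(base_ofv: float, extended_ofv: float, df: int) -> float:
    """Likelihood-ratio p-value for nested models (OFV = -2 log L)."""
    delta = base_ofv - extended_ofv
    if delta < 0:
        warnings.warn("extended model fits worse than the base model "
                      f"(delta OFV = {delta:.3f}); p set to 1", stacklevel=2)
        return 1.0
    return float(stats.chi2.sf(delta, df))


def empirical_bayes(data: PKDataset, theta: dict, omega: dict, sigma: tuple,
                    eta_on: tuple = ("cl", "vc"), corr_cl_vc: float = 0.0,
                    covariate_effects: tuple = (), coefs: tuple = (),
                    h_max: float = 0.1) -> pd.DataFrame:
    """Posterior eta modes per subject at fixed population parameters."""
    config = ModelConfig(theta_init=dict(theta), estimate_theta=(),
                         covariate_effects=tuple(covariate_effects),
                         eta_on=tuple(eta_on), omega_init=dict(omega),
                         estimate_omega=False, corr_cl_vc_init=corr_cl_vc,
                         sigma_init=tuple(sigma), estimate_sigma=(),
                         h_max=h_max)
    model = LikelihoodModel(data, config)
    x = np.asarray(list(coefs), dtype=float) if coefs else model.x0()
    modes = model.eta_modes(x)
    out = pd.DataFrame(modes, columns=[f"eta_{p}" for p in eta_on])
    out.insert(0, "ID", model.subject_ids)
    return out


# -- stepwise covariate machinery --------------------------------------

@dataclass
class StepwiseResult:
    selected: tuple
    final_fit: FitResult
    audit: pd.DataFrame


def _exposure_change(eff: CovariateEffect, coef: float, theta: dict,
                     data: PKDataset, reg: Regimen) -> float:
    """Largest relative change in Cmin/Cmax/AUC at steady state when the
    covariate spans its observed 5th-95th percentile range (continuous)
    or toggles (binary/indicator)."""
    col = eff.covariate.upper()
    sub = data.df.groupby("ID").first()
    if eff.form == "power":
        vals = pd.to_numeric(sub[col])
        lo, hi = np.percentile(vals, [5, 95])
        factors = [(v / eff.reference) ** coef for v in (lo, hi)]
        wts = (lo, hi) if col == "WT" else (66.0, 66.0)
    else:
        factors = [1.0, math.exp(coef)]
        wts = (66.0, 66.0)

    def metrics(factor, wt):
        th = dict(theta)
        th[eff.parameter] = th[eff.parameter] * factor
        sp = SubjectParameters(cl=th["cl"], vc=th["vc"], q=th["q"],
                               vp=th["vp"], vmax=th["vmax"], km=th["km"])
        sched = build_schedule(reg, wt)
        horizon = sched[-1].time + reg.interval
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = simulate_subject(sp, sched, horizon, backend="fast",
                                    interval_for_troughs=reg.interval)
            m = steady_state_metrics(prof, sp, reg)
        return np.array([m.cmin_ss, m.cmax_ss, m.auc_ss])

    ref = metrics(1.0, 66.0)
    worst = 0.0
    for factor, wt in zip(factors, wts):
        change = np.abs(metrics(factor, wt) / ref - 1.0)
        worst = max(worst, float(change.max()))
    return worst


def stepwise_covariates(data: PKDataset, base_config: ModelConfig,
                        candidates: list[CovariateEffect],
                        forward_p: float = 0.001, screen_p: float = 0.005,
                        backward_p: float = 0.001,
                        relevance_threshold: float = 0.15,
                        relevance_regimen: Regimen = Q3W,
                        maxiter: int = 200) -> StepwiseResult:
    """Forward addition / backward elimination / relevance filtering.

    Returns the selected effects, the final fit, and a full audit trail
    (one row per decision, with OFVs and p-values).
    """
    audit = []
    # collinearity flag among continuous candidates
    sub = data.df.groupby("ID").first()
    cont = [c for c in candidates if c.form == "power"]
    for i in range(len(cont)):
        for j in range(i + 1, len(cont)):
            a = np.log(pd.to_numeric(sub[cont[i].covariate.upper()]))
            b = np.log(pd.to_numeric(sub[cont[j].covariate.upper()]))
            r = np.corrcoef(a, b)[0, 1]
            if abs(r) > 0.95:
                warnings.warn(f"candidates {cont[i].label} and "
                              f"{cont[j].label} are collinear (r={r:.3f})",
                              stacklevel=2)

    base_fit = fit(data, base_config, maxiter=maxiter)
    audit.append({"step": "base", "effect": "", "ofv": base_fit.ofv,
                  "p": np.nan, "decision": "reference"})

    screened = []
    for cand in candidates:
        f1 = fit(data, base_config.with_effect(cand), maxiter=maxiter)
        p = lrt(base_fit.ofv, f1.ofv, 1)
        keep = p < screen_p
        audit.append({"step": "screen", "effect": cand.label, "ofv": f1.ofv,
                      "p": p, "decision": "pass" if keep else "drop"})
        if keep:
            screened.append(cand)

    current_cfg = base_config
    current_fit = base_fit
    remaining = list(screened)
    while remaining:
        fits = [(cand, fit(data, current_cfg.with_effect(cand),
                           maxiter=maxiter)) for cand in remaining]
        cand, f1 = min(fits, key=lambda cf: cf[1].ofv)
        p = lrt(current_fit.ofv, f1.ofv, 1)
        if p < forward_p:
            audit.append({"step": "forward", "effect": cand.label,
                          "ofv": f1.ofv, "p": p, "decision": "add"})
            current_cfg = current_cfg.with_effect(cand)
            current_fit = f1
            remaining.remove(cand)
        else:
            for c2, f2 in fits:
                p2 = lrt(current_fit.ofv, f2.ofv, 1)
                audit.append({"step": "forward", "effect": c2.label,
                              "ofv": f2.ofv, "p": p2, "decision": "stop"})
            break

    changed = True
    while changed and current_cfg.covariate_effects:
        changed = False
        drops = []
        for eff in current_cfg.covariate_effects:
            f0 = fit(data, current_cfg.without_effect(eff), maxiter=maxiter)
            p = lrt(f0.ofv, current_fit.ofv, 1)
            drops.append((eff, f0, p))
        eff, f0, p = max(drops, key=lambda t: t[2])
        if p >= backward_p:
            audit.append({"step": "backward", "effect": eff.label,
                          "ofv": f0.ofv, "p": p, "decision": "remove"})
            current_cfg = current_cfg.without_effect(eff)
            current_fit = f0
            changed = True
        else:
            for eff2, f2, p2 in drops:
                audit.append({"step": "backward", "effect": eff2.label,
                              "ofv": f2.ofv, "p": p2, "decision": "retain"})

    # clinical-relevance filter on steady-state exposure
    for eff in list(current_cfg.covariate_effects):
        coef = current_fit.covariate_coefs[eff.label]
        impact = _exposure_change(eff, coef, current_fit.theta, data,
                                  relevance_regimen)
        if impact < relevance_threshold:
            audit.append({"step": "relevance", "effect": eff.label,
                          "ofv": np.nan, "p": np.nan,
                          "decision": f"drop (max impact {impact:.3f})"})
            current_cfg = current_cfg.without_effect(eff)
        else:
            audit.append({"step": "relevance", "effect": eff.label,
                          "ofv": np.nan, "p": np.nan,
                          "decision": f"retain (max impact {impact:.3f})"})
    if tuple(current_cfg.covariate_effects) != \
            tuple(current_fit.config.covariate_effects):
        current_fit = fit(data, current_cfg, maxiter=maxiter)

    return StepwiseResult(tuple(current_cfg.covariate_effects), current_fit,
                          pd.DataFrame(audit))
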