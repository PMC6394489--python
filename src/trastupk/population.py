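"""Virtual populations: inter-individual variability, residual error,
and Monte-Carlo regimen/washout studies.

Random effects are lognormal: individual parameters are typical values
times exp(eta), with eta drawn from a multivariate normal whose CL-Vc
block is correlated and whose Vp and Km components are independent.  The
Km variability is very large (log-SD 1.39), so draws are truncated at
+-4 SD componentwise to keep the integrator in a sane regime; truncation
events are counted and logged.

Residual (observation) error is combined proportional + additive and is
applied only when emitting synthetic observations -- exposure summaries
describe model-predicted concentrations, as is standard for simulation
studies of this kind.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (CovariateVector, PopulationParameters,
                         SubjectParameters, subject_from_covariates)
from .regimen import Regimen, build_schedule, simulate_subject, \
    steady_state_metrics, washout_time

__all__ = [
    "RandomEffectSpec",
    "VirtualPopulation",
    "PopulationWashoutResult",
    "sample_eta",
    "sample_subject_params",
    "sample_population",
    "apply_residual_error",
    "population_washout",
    "exposure_summary",
]

logger = logging.getLogger(__name__)

#: componentwise truncation of eta draws, in units of each SD
ETA_TRUNCATION_SD = 4.0


@dataclass(frozen=True)
class RandomEffectSpec:
    """Magnitudes of the inter-individual random effects.

    ``sd_*`` are log-scale standard deviations; ``cov_cl_vc`` is the raw
    covariance between eta_CL and eta_Vc.  The implied 4x4 covariance must
    be positive semi-definite.
    """

    sd_cl: float = 0.401
    sd_vc: float = 0.246
    sd_vp: float = 0.495
    sd_km: float = 1.39
    cov_cl_vc: float = 0.0230
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_cl", "sd_vc", "sd_vp", "sd_km"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        w = np.linalg.eigvalsh(self.omega_matrix())
        if w.min() < -1e-12:
            raise ValueError("implied Omega matrix is not positive semi-definite")

    @classmethod
    def from_parameters(cls, pp: PopulationParameters,
                        rng_seed: int = 0) -> "RandomEffectSpec":
        return cls(pp.omega_cl, pp.omega_vc, pp.omega_vp, pp.omega_km,
                   pp.omega_cl_vc_cov, rng_seed)

    @classmethod
    def none(cls, rng_seed: int = 0) -> "RandomEffectSpec":
        """Degenerate spec: every subject is the typical subject."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, rng_seed)

    def omega_matrix(self) -> np.ndarray:
        om = np.diag([self.sd_cl ** 2, self.sd_vc ** 2,
                      self.sd_vp ** 2, self.sd_km ** 2])
        om[0, 1] = om[1, 0] = self.cov_cl_vc
        return om


def sample_eta(spec: RandomEffectSpec, rng: np.random.Generator,
               size: int = 1) -> tuple[np.ndarray, int]:
    """Draw (size, 4) eta vectors; returns (draws, n_truncated).

    Components are clipped at +-4 SD; the count of clipped components is
    returned and logged (large-Km draws otherwise produce profiles far
    outside anything observable).
    """
    om = spec.omega_matrix()
    # eigen-decomposition handles the semi-definite (zero-SD) cases
    w, v = np.linalg.eigh(om)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    draws = rng.standard_normal((size, 4)) @ root.T
    sds = np.array([spec.sd_cl, spec.sd_vc, spec.sd_vp, spec.sd_km])
    lim = ETA_TRUNCATION_SD * sds
    clipped = np.abs(draws) > lim + 1e-15
    n_trunc = int(clipped.sum())
    if n_trunc:
        logger.info("truncated %d eta component(s) at +-%g SD",
                    n_trunc, ETA_TRUNCATION_SD)
        draws = np.clip(draws, -lim, lim)
    return draws, n_trunc


def sample_subject_params(cov: CovariateVector, pp: PopulationParameters,
                          spec: RandomEffectSpec,
                          rng: np.random.Generator) -> SubjectParameters:
    """One subject: typical values from the covariate model times exp(eta)."""
    eta, _ = sample_eta(spec, rng, size=1)
    return subject_from_covariates(cov, pp, eta[0])


@dataclass
class VirtualPopulation:
    """A reproducible set of virtual subjects."""

    subjects: list[tuple[CovariateVector, SubjectParameters]]
    seed: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.subjects) < 1:
            raise ValueError("a virtual population needs at least one subject")

    def __len__(self) -> int:
        return len(self.subjects)


def sample_population(n: int, cov: CovariateVector | list[CovariateVector],
                      pp: PopulationParameters, spec: RandomEffectSpec,
                      ) -> VirtualPopulation:
    """Draw a virtual population; fully reproducible from ``spec.rng_seed``."""
    if n < 1:
        raise ValueError("n must be at least 1")
    covs = [cov] * n if isinstance(cov, CovariateVector) else list(cov)
    if len(covs) != n:
        raise ValueError("covariate list length must equal n")
    rng = np.random.default_rng(spec.rng_seed)
    eta, n_trunc = sample_eta(spec, rng, size=n)
    subjects = [(c, subject_from_covariates(c, pp, eta[i]))
                for i, c in enumerate(covs)]
    return VirtualPopulation(subjects, spec.rng_seed,
                             {"n": n, "spec": spec, "n_truncated": n_trunc})


def apply_residual_error(conc, pp: PopulationParameters,
                         rng: np.random.Generator) -> np.ndarray:
    """Observed concentration: conc * (1 + eps1) + eps2.

    eps1 ~ N(0, sigma_prop^2), eps2 ~ N(0, sigma_add^2).  Used only when
    emitting synthetic observations (DV), never for exposure metrics.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    e1 = rng.standard_normal(conc.shape) * pp.sigma_prop
    e2 = rng.standard_normal(conc.shape) * pp.sigma_add
    return conc * (1.0 + e1) + e2


@dataclass(frozen=True)
class PopulationWashoutResult:
    """Coverage-quantile washout day with a bootstrap Monte-Carlo CI."""

    day: float
    ci_low: float
    ci_high: float
    n: int
    coverage: float
    threshold: float
    seed: int
    n_truncated_etas: int


def population_washout(n: int, cov: CovariateVector, reg: Regimen,
                       spec: RandomEffectSpec, threshold: float = 1.0,
                       coverage: float = 0.95, n_bootstrap: int = 500,
                       pp: PopulationParameters | None = None,
                       ) -> PopulationWashoutResult:
    """Days after the last dose until ``coverage`` of virtual subjects are
    below ``threshold``.

    Per-subject washout days are computed on the compiled fast path; the
    population answer is the ``coverage`` quantile of those days (the
    smallest day at which the below-threshold fraction reaches the
    coverage), with a percentile-bootstrap CI over subjects.
    """
    if n < 100:
        raise ValueError("population washout needs n >= 100 for a stable "
                         "quantile")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    pp = _PP_DEFAULT if pp is None else pp
    rng = np.random.default_rng(spec.rng_seed)
    eta, n_trunc = sample_eta(spec, rng, size=n)
    days = np.empty(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # horizon-extension notices
        for i in range(n):
            sp = subject_from_covariates(cov, pp, eta[i])
            days[i] = washout_time(sp, reg, threshold, wt=cov.wt,
                                   backend="fast", dt=0.25)
    day = float(np.quantile(days, coverage))
    boot_rng = np.random.default_rng(spec.rng_seed + 1)
    idx = boot_rng.integers(0, n, size=(n_bootstrap, n))
    boot = np.quantile(days[idx], coverage, axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return PopulationWashoutResult(day, float(lo), float(hi), n, coverage,
                                   threshold, spec.rng_seed, n_trunc)


_PP_DEFAULT = PopulationParameters()


def exposure_summary(popn: VirtualPopulation, reg: Regimen,
                     pp: PopulationParameters | None = None) -> pd.DataFrame:
    """Median and 2.5/97.5 percentiles of steady-state exposure metrics,
    per tumor-type stratum.

    Every subject is simulated to one interval past the final dose of the
    regimen (>= 36 weeks for the labelled regimens).  Empty strata appear
    as all-NaN rows rather than being dropped.
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cov, sp in popn.subjects:
            sched = build_schedule(reg, cov.wt)
            horizon = sched[-1].time + reg.interval
            prof = simulate_subject(sp, sched, horizon, backend="fast",
                                    interval_for_troughs=reg.interval)
            m = steady_state_metrics(prof, sp, reg)
            rows.append({"tumor_type": cov.tumor_type.value,
                         "cmin_ss": m.cmin_ss, "cmax_ss": m.cmax_ss,
                         "auc_ss": m.auc_ss,
                         "time_to_ss_90": m.time_to_ss_90})
    df = pd.DataFrame(rows)
    metrics = ["cmin_ss", "cmax_ss", "auc_ss", "time_to_ss_90"]
    out = []
    strata = sorted(df["tumor_type"].unique())
    for stratum in strata:
        sub = df[df["tumor_type"] == stratum]
        for met in metrics:
            vals = sub[met].to_numpy()
            out.append({
                "tumor_type": stratum, "metric": met, "n": len(vals),
                "median": float(np.median(vals)),
                "p2.5": float(np.percentile(vals, 2.5)),
                "p97.5": float(np.percentile(vals, 97.5)),
            })
    return pd.DataFrame(out)
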