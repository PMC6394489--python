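"""Population parameters and the covariate model for IV trastuzumab.

Trastuzumab disposition is described by a two-compartment model with
parallel first-order (linear) and Michaelis-Menten (target-mediated)
elimination from the central compartment.  The published population
estimates pooled 18 phase I-III trials across metastatic breast cancer
(MBC), early breast cancer (EBC), advanced gastric cancer (AGC), other
tumor types and healthy volunteers (HV).

Units follow pharmacometric convention throughout: clearances in L/day,
volumes in L, amounts in mg, time in days, concentrations in mg/L, which
is identical to ug/mL.

The covariate model acts multiplicatively on the linear clearance

    CL_i = CL_type * (WT_i/66)^t7 * (SGOT_i/24)^t10 * (ALBU_i/4)^t11
           * exp(t12 * [LMET_i]) * exp(eta_CL)

with CL_type the tumor-type-specific typical clearance (breast cancer /
healthy volunteers share one value; AGC and "other" each have their own),
and on the central volume via a tumor-type switch (AGC vs non-AGC).
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TumorType",
    "PopulationParameters",
    "CovariateVector",
    "SubjectParameters",
    "REFERENCE_WT",
    "REFERENCE_SGOT",
    "REFERENCE_ALBU",
    "linear_clearance",
    "central_volume",
    "km_with_shed",
    "total_clearance_at",
    "subject_from_covariates",
]

#: Reference covariate values used to center the power terms (population
#: medians of the pooled dataset: 66 kg, 24 IU/L, 4.0 g/dL).
REFERENCE_WT = 66.0
REFERENCE_SGOT = 24.0
REFERENCE_ALBU = 4.0


class TumorType(str, enum.Enum):
    """Primary tumor type strata used by the covariate model."""

    MBC = "MBC"
    EBC = "EBC"
    HV = "HV"
    AGC = "AGC"
    OTHER = "OTHER"

    @classmethod
    def coerce(cls, value: "TumorType | str") -> "TumorType":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            raise ValueError(
                f"unknown tumor type {value!r}; expected one of "
                f"{[t.value for t in cls]}"
            ) from None


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, random-effect magnitudes and residual error.

    Defaults reproduce the published final population estimates for the
    intravenous formulation.  IIV magnitudes are stored as log-scale
    standard deviations (the published percentages divided by 100, the
    usual convention for lognormal random effects); the CL-Vc off-diagonal
    is a raw covariance.

    Attributes
    ----------
    cl_bc, cl_other, cl_agc
        Typical linear elimination clearance (L/day) for breast cancer /
        healthy volunteers, other tumor types, and AGC.
    vc_nonagc, vc_agc
        Typical central volume (L) for non-AGC and AGC patients.
    q, vp
        Inter-compartmental clearance (L/day) and peripheral volume (L).
    vmax, km
        Michaelis-Menten maximum elimination rate (mg/day) and
        half-saturation concentration (mg/L).
    wt_exp, sgot_exp, albu_exp
        Power-model exponents for body weight, SGOT and albumin on CL.
    lmet_coef
        Log-scale shift in CL for baseline liver metastases.
    omega_cl, omega_vc, omega_vp, omega_km
        Log-scale SDs of the inter-individual random effects.
    omega_cl_vc_cov
        Covariance between eta_CL and eta_Vc.
    sigma_prop, sigma_add
        Proportional (fraction) and additive (ug/mL) residual error SDs.
    shed_km_exp
        Exponent of the shed-antigen (circulating HER2 extracellular
        domain) ratio on Km; exploratory, applied only when
        ``shed_enabled`` is True.
    km_agc
        Optional AGC-specific Km override.  The pooled analysis retained a
        common Km (tumor type on Km was dropped during backward
        elimination), so this is ``None`` by default.
    """

    cl_bc: float = 0.127
    cl_other: float = 0.148
    cl_agc: float = 0.176
    vc_nonagc: float = 2.62
    vc_agc: float = 3.63
    q: float = 0.544
    vp: float = 2.97
    vmax: float = 8.81
    km: float = 8.92
    wt_exp: float = 0.967
    sgot_exp: float = 0.205
    albu_exp: float = -0.998
    lmet_coef: float = 0.152
    omega_cl: float = 0.401
    omega_vc: float = 0.246
    omega_vp: float = 0.495
    omega_km: float = 1.39
    omega_cl_vc_cov: float = 0.0230
    sigma_prop: float = 0.197
    sigma_add: float = 1.38
    shed_km_exp: float = -0.771
    shed_enabled: bool = False
    km_agc: float | None = None

    def __post_init__(self) -> None:
        for name in ("cl_bc", "cl_other", "cl_agc", "vc_nonagc", "vc_agc",
                     "q", "vp", "vmax", "km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("omega_cl", "omega_vc", "omega_vp", "omega_km",
                     "sigma_prop", "sigma_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.km_agc is not None and self.km_agc <= 0:
            raise ValueError("km_agc must be strictly positive")
        # Omega must be a valid covariance matrix.
        w = np.linalg.eigvalsh(self.omega_matrix())
        if w.min() < -1e-12:
            raise ValueError("implied Omega matrix is not positive semi-definite")

    def omega_matrix(self) -> np.ndarray:
        """4x4 covariance of (eta_CL, eta_Vc, eta_Vp, eta_Km).

        CL and Vc are correlated; Vp and Km are independent diagonal
        entries.  There is no random effect on Q.
        """
        om = np.diag([self.omega_cl ** 2, self.omega_vc ** 2,
                      self.omega_vp ** 2, self.omega_km ** 2])
        om[0, 1] = om[1, 0] = self.omega_cl_vc_cov
        return om

    def replace(self, **kwargs) -> "PopulationParameters":
        return dataclasses.replace(self, **kwargs)

    def typical_cl(self, tumor_type: TumorType | str) -> float:
        tt = TumorType.coerce(tumor_type)
        if tt is TumorType.AGC:
            return self.cl_agc
        if tt is TumorType.OTHER:
            return self.cl_other
        return self.cl_bc

    def typical_vc(self, tumor_type: TumorType | str) -> float:
        tt = TumorType.coerce(tumor_type)
        return self.vc_agc if tt is TumorType.AGC else self.vc_nonagc

    def typical_km(self, tumor_type: TumorType | str) -> float:
        tt = TumorType.coerce(tumor_type)
        if tt is TumorType.AGC and self.km_agc is not None:
            return self.km_agc
        return self.km

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True)
class CovariateVector:
    """One subject's baseline covariates.

    Missing (``None``) continuous covariates are imputed to the reference
    medians (66 kg, 24 IU/L, 4.0 g/dL); missing categorical covariates
    fall to the predominant category (no liver metastases, MBC), mirroring
    the handling used in the pooled analysis.
    """

    wt: float | None = None
    sgot: float | None = None
    albu: float | None = None
    lmet: bool | None = None
    tumor_type: TumorType | str | None = None
    shed: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "wt", REFERENCE_WT if self.wt is None else float(self.wt))
        object.__setattr__(self, "sgot", REFERENCE_SGOT if self.sgot is None else float(self.sgot))
        object.__setattr__(self, "albu", REFERENCE_ALBU if self.albu is None else float(self.albu))
        object.__setattr__(self, "lmet", False if self.lmet is None else bool(self.lmet))
        object.__setattr__(
            self, "tumor_type",
            TumorType.MBC if self.tumor_type is None else TumorType.coerce(self.tumor_type),
        )
        for name in ("wt", "sgot", "albu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"covariate {name} must be strictly positive, "
                                 f"got {getattr(self, name)}")
        if self.shed is not None and self.shed <= 0:
            raise ValueError("shed ratio must be strictly positive")


#: The typical (reference) patient: 66 kg, SGOT 24 IU/L, albumin 4 g/dL,
#: no liver metastases, MBC.
TYPICAL_BC = CovariateVector()
TYPICAL_AGC = CovariateVector(tumor_type=TumorType.AGC)


@dataclass(frozen=True)
class SubjectParameters:
    """Individual structural parameters (typical values times exp(eta))."""

    cl: float
    vc: float
    q: float
    vp: float
    vmax: float
    km: float
    eta: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("cl", "vc", "q", "vp", "vmax", "km"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"subject parameter {name} must be finite and "
                                 f"strictly positive, got {v}")
        object.__setattr__(self, "eta", tuple(float(e) for e in self.eta))


def linear_clearance(cov: CovariateVector, pp: PopulationParameters,
                     eta_cl: float = 0.0) -> float:
    """Individual linear elimination clearance (L/day).

    Multiplicative power model on weight, SGOT and albumin (centered at
    66 kg / 24 IU/L / 4 g/dL), an exponential shift for liver metastases,
    a tumor-type-specific intercept, and a lognormal random effect.
    """
    base = pp.typical_cl(cov.tumor_type)
    return (base
            * (cov.wt / REFERENCE_WT) ** pp.wt_exp
            * (cov.sgot / REFERENCE_SGOT) ** pp.sgot_exp
            * (cov.albu / REFERENCE_ALBU) ** pp.albu_exp
            * math.exp(pp.lmet_coef * float(cov.lmet))
            * math.exp(eta_cl))


def central_volume(cov: CovariateVector, pp: PopulationParameters,
                   eta_vc: float = 0.0) -> float:
    """Individual central volume (L): tumor-type switch times exp(eta)."""
    return pp.typical_vc(cov.tumor_type) * math.exp(eta_vc)


def km_with_shed(pp: PopulationParameters, shed_ratio: float,
                 eta_km: float = 0.0) -> float:
    """Km (mg/L) adjusted for the shed-antigen level.

    ``shed_ratio`` is the subject's circulating HER2-ECD level divided by
    the chosen reference level; at the reference (ratio 1) the typical Km
    is returned.  The power exponent is negative, so higher shed antigen
    lowers Km and thereby raises the target-mediated clearance.  Requires
    ``pp.shed_enabled``; the term is exploratory and off by default.
    """
    if not pp.shed_enabled:
        raise ValueError("shed-antigen term is disabled; construct "
                         "PopulationParameters with shed_enabled=True")
    if shed_ratio <= 0:
        raise ValueError("shed_ratio must be strictly positive")
    return pp.km * shed_ratio ** pp.shed_km_exp * math.exp(eta_km)


def total_clearance_at(conc: float, sp: SubjectParameters) -> float:
    """Total (linear + Michaelis-Menten) clearance at a concentration.

    CL_tot(C) = CL + Vmax / (Km + C): strictly decreasing in C, tending
    to CL + Vmax/Km as C -> 0 and saturating to CL alone at high
    concentrations.
    """
    if conc < 0 or not math.isfinite(conc):
        raise ValueError(f"concentration must be finite and non-negative, got {conc}")
    return sp.cl + sp.vmax / (sp.km + conc)


def subject_from_covariates(cov: CovariateVector, pp: PopulationParameters,
                            eta: Sequence[float] = (0.0, 0.0, 0.0, 0.0),
                            ) -> SubjectParameters:
    """Assemble individual parameters from covariates and random effects.

    ``eta`` is (eta_CL, eta_Vc, eta_Vp, eta_Km).  With all etas zero and
    reference covariates this returns the typical patient exactly.
    """
    e = tuple(float(x) for x in eta)
    if len(e) != 4:
        raise ValueError("eta must have 4 components (CL, Vc, Vp, Km)")
    km_typ = pp.typical_km(cov.tumor_type)
    if pp.shed_enabled and cov.shed is not None:
        km = km_typ * cov.shed ** pp.shed_km_exp * math.exp(e[3])
    else:
        km = km_typ * math.exp(e[3])
    return SubjectParameters(
        cl=linear_clearance(cov, pp, e[0]),
        vc=central_volume(cov, pp, e[1]),
        q=pp.q,
        vp=pp.vp * math.exp(e[2]),
        vmax=pp.vmax,
        km=km,
        eta=e,
    )
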