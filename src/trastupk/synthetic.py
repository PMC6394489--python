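"""Virtual multi-study PK datasets with the pooled-trial structure.

The generator emulates the statistical skeleton of the pooled 18-trial
dataset: tumor-type strata dominated by metastatic breast cancer
(810 : 391 : 274 : 107 for MBC : EBC : AGC : other), q3w and qw dosing
arms, covariates centered on the published medians (weight 66 kg, SGOT
24 IU/L, albumin 4.0 g/dL), lognormal inter-individual variability,
combined residual error, and an assay floor of 0.156 ug/mL below which
samples are dropped (M1) while being counted.

Covariate spreads are package defaults chosen to give plausible clinical
ranges (weight log-SD 0.2, SGOT log-SD 0.4, albumin SD 0.35 g/dL); the
source publication pins only the medians and stratum counts, not the full
distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import LLOQ, PKDataset
from .parameters import (CovariateVector, PopulationParameters, TumorType,
                         subject_from_covariates)
from .population import RandomEffectSpec, apply_residual_error, sample_eta
from .regimen import Q3W, QW, Regimen, build_schedule
from . import _engine

__all__ = ["StudyDesign", "generate_covariates", "generate_dataset"]

#: pooled-analysis stratum counts (MBC, EBC, AGC, other)
DEFAULT_STRATUM_COUNTS = {
    TumorType.MBC: 810, TumorType.EBC: 391,
    TumorType.AGC: 274, TumorType.OTHER: 107,
}
#: q3w vs qw arm sizes in the pooled dataset
DEFAULT_REGIMEN_COUNTS = {"q3w": 917, "qw": 643}


@dataclass(frozen=True)
class StudyDesign:
    """Configuration of a virtual study.

    ``schedule`` selects the sampling template: "rich" draws a pre-dose
    trough plus post-dose samples on cycles 1, 4 and 13; "sparse" draws
    troughs only, every cycle.  ``washout_times`` optionally appends
    samples at the given days after the last dose (washout sampling
    produces the low concentrations where the assay floor bites).
    """

    n_subjects: int = 100
    stratum_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_STRATUM_COUNTS))
    regimen_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_REGIMEN_COUNTS))
    wt_median: float = 66.0
    wt_sdlog: float = 0.2
    sgot_median: float = 24.0
    sgot_sdlog: float = 0.4
    albu_mean: float = 4.0
    albu_sd: float = 0.35
    lmet_prob: float = 0.2
    schedule: str = "rich"
    rich_cycles: tuple = (1, 4, 13)
    n_cycles: int = 13
    washout_times: tuple = ()
    lloq: float = LLOQ
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if self.schedule not in ("rich", "sparse"):
            raise ValueError("schedule must be 'rich' or 'sparse'")
        for w in list(self.stratum_weights.values()) + \
                list(self.regimen_weights.values()):
            if w < 0:
                raise ValueError("stratum weights must be non-negative")
        if sum(self.stratum_weights.values()) <= 0:
            raise ValueError("stratum weights must sum to a positive value")
        for m in (self.wt_median, self.sgot_median, self.albu_mean):
            if m <= 0:
                raise ValueError("covariate centers must be positive")

    def regimen_for(self, arm: str) -> Regimen:
        base = Q3W if arm == "q3w" else QW
        return base.with_cycles(self.n_cycles)


def generate_covariates(design: StudyDesign, rng: np.random.Generator,
                        ) -> list[CovariateVector]:
    """Draw baseline covariates for ``design.n_subjects`` subjects."""
    strata = list(design.stratum_weights.keys())
    w = np.array([design.stratum_weights[s] for s in strata], dtype=float)
    w = w / w.sum()
    picks = rng.choice(len(strata), size=design.n_subjects, p=w)
    wt = design.wt_median * np.exp(rng.standard_normal(design.n_subjects)
                                   * design.wt_sdlog)
    sgot = design.sgot_median * np.exp(rng.standard_normal(design.n_subjects)
                                       * design.sgot_sdlog)
    albu = design.albu_mean + rng.standard_normal(design.n_subjects) \
        * design.albu_sd
    albu = np.maximum(albu, 0.5)  # truncated well above zero
    lmet = rng.random(design.n_subjects) < design.lmet_prob
    return [CovariateVector(wt=wt[i], sgot=sgot[i], albu=albu[i],
                            lmet=bool(lmet[i]),
                            tumor_type=TumorType.coerce(strata[picks[i]]))
            for i in range(design.n_subjects)]


def _sample_times(design: StudyDesign, reg: Regimen,
                  schedule_events) -> np.ndarray:
    interval = reg.interval
    dose_times = [ev.time for ev in schedule_events]
    times: list[float] = []
    if design.schedule == "sparse":
        times.extend(dose_times[1:])
        times.append(dose_times[-1] + interval)
    else:
        offsets = [o for o in (1.0, 2.0, 7.0, 14.0, 21.0) if o <= interval]
        for c in design.rich_cycles:
            if c > len(dose_times):
                continue
            t_c = dose_times[c - 1]
            if c > 1:
                times.append(t_c)  # pre-dose trough
            times.extend(t_c + o for o in offsets)
    t_last = dose_times[-1]
    times.extend(t_last + w for w in design.washout_times)
    return np.unique(np.asarray(times, dtype=float))


def generate_dataset(design: StudyDesign, pp: PopulationParameters,
                     spec: RandomEffectSpec,
                     ) -> tuple[PKDataset, pd.DataFrame, int]:
    """Simulate a NONMEM-style dataset plus a true-parameter ledger.

    Returns ``(dataset, truth, n_blq)``: the event records after dropping
    below-LLOQ observations, one truth row per emitted subject (etas and
    individual parameters), and the number of dropped samples.  Subjects
    losing every observation to the assay floor are excluded and appear in
    the ledger with ``evaluable = False``.
    """
    rng = np.random.default_rng(design.seed)
    covs = generate_covariates(design, rng)
    arms = list(design.regimen_weights.keys())
    warm = np.array([design.regimen_weights[a] for a in arms], dtype=float)
    warm = warm / warm.sum()
    arm_pick = rng.choice(len(arms), size=design.n_subjects, p=warm)
    eta, _ = sample_eta(spec, rng, size=design.n_subjects)

    records = []
    truth_rows = []
    n_blq = 0
    for i, cov in enumerate(covs):
        sid = i + 1
        arm = arms[arm_pick[i]]
        reg = design.regimen_for(arm)
        sched = build_schedule(reg, cov.wt)
        sp = subject_from_covariates(cov, pp, eta[i])
        times = _sample_times(design, reg, sched)
        st = np.array([d.time for d in sched])
        sa = np.array([d.amount for d in sched])
        sd = np.array([d.infusion_duration for d in sched])
        f = _engine.simulate_conc(times, st, sa, sd, sp.cl, sp.vc, sp.q,
                                  sp.vp, sp.vmax, sp.km)
        dv = apply_residual_error(np.maximum(f, 0.0), pp, rng)
        keep = dv >= design.lloq
        n_blq += int((~keep).sum())
        evaluable = bool(keep.any())
        truth_rows.append({
            "ID": sid, "arm": arm, "tumor_type": cov.tumor_type.value,
            "WT": cov.wt, "SGOT": cov.sgot, "ALBU": cov.albu,
            "LMET": int(cov.lmet),
            "eta_cl": eta[i, 0], "eta_vc": eta[i, 1],
            "eta_vp": eta[i, 2], "eta_km": eta[i, 3],
            "cl": sp.cl, "vc": sp.vc, "vp": sp.vp, "km": sp.km,
            "evaluable": evaluable, "n_blq": int((~keep).sum()),
        })
        if not evaluable:
            continue
        common = {"ID": sid, "WT": cov.wt, "SGOT": cov.sgot,
                  "ALBU": cov.albu, "LMET": int(cov.lmet),
                  "TTYPE": cov.tumor_type.value}
        for ev in sched:
            rate = ev.amount / ev.infusion_duration \
                if ev.infusion_duration > 0 else 0.0
            records.append({**common, "TIME": ev.time, "AMT": ev.amount,
                            "RATE": rate, "EVID": 1, "DV": np.nan, "MDV": 1})
        for t, v in zip(times[keep], dv[keep]):
            records.append({**common, "TIME": t, "AMT": 0.0, "RATE": 0.0,
                            "EVID": 0, "DV": float(v), "MDV": 0})
    df = pd.DataFrame.from_records(records)
    # pre-dose (trough) observations precede the dose given at the same time
    df = df.sort_values(["ID", "TIME", "EVID"], kind="stable")
    cols = ["ID", "TIME", "AMT", "RATE", "EVID", "DV", "MDV",
            "WT", "SGOT", "ALBU", "LMET", "TTYPE"]
    dataset = PKDataset(df[cols].reset_index(drop=True))
    return dataset, pd.DataFrame(truth_rows), n_blq
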