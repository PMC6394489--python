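"""Model evaluation: visual and numerical predictive checks, shrinkage.

Predictive checks simulate many replicate datasets under the *design* of
the observed data (identical doses, sampling times and covariates; fresh
inter-individual random effects and residual error) and compare the
distribution of observations with the distribution of simulations:

* VPC -- binwise 5th/50th/95th percentiles of the observed concentrations
  against the envelope of the same percentiles across replicates;
* NPC -- per observation, prediction-interval bounds at several nominal
  levels, reporting the fraction of observed values outside each bound.

Eta shrinkage is 100 * (1 - SD(EBE)/omega), the standard diagnostic for
how much individual-level information the data carry about each random
effect (sparse designs shrink the EBEs toward zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _engine
from .estimation import PKDataset
from .parameters import (CovariateVector, PopulationParameters, TumorType,
                         subject_from_covariates)
from .population import RandomEffectSpec, apply_residual_error, sample_eta

__all__ = ["VPCResult", "NPCResult", "vpc", "npc", "eta_shrinkage"]


@dataclass
class VPCResult:
    """Tidy binwise summary; one row per (stratum, bin)."""

    table: pd.DataFrame
    n_replicates: int
    seed: int

    def coverage_fraction(self) -> float:
        """Fraction of (bin, percentile) cells whose observed percentile
        lies inside the simulated envelope."""
        t = self.table
        inside = 0
        total = 0
        for p in ("p5", "p50", "p95"):
            total += len(t)
            inside += int(((t[f"obs_{p}"] >= t[f"sim_{p}_lo"])
                           & (t[f"obs_{p}"] <= t[f"sim_{p}_hi"])).sum())
        return inside / total if total else float("nan")


@dataclass
class NPCResult:
    """Outside-fractions per prediction-interval level."""

    table: pd.DataFrame
    n_replicates: int
    seed: int


def _subject_arrays(data: PKDataset):
    """Per-subject covariates, dose arrays and observation times."""
    df = data.df
    subjects = []
    for sid, sub in df.groupby("ID", sort=False):
        o = sub[(sub["EVID"] == 0) & (sub["MDV"] == 0)]
        d = sub[(sub["EVID"] == 1) & (sub["AMT"] > 0)]
        rate = d["RATE"].to_numpy(float)
        amt = d["AMT"].to_numpy(float)
        dur = np.where(rate > 0, amt / np.maximum(rate, 1e-300), 0.0)
        row = sub.iloc[0]
        cov = CovariateVector(
            wt=row.get("WT"), sgot=row.get("SGOT"), albu=row.get("ALBU"),
            lmet=bool(row.get("LMET", 0)) if pd.notna(row.get("LMET", np.nan)) else None,
            tumor_type=row.get("TTYPE") if pd.notna(row.get("TTYPE", np.nan)) else None)
        subjects.append({
            "id": sid, "cov": cov,
            "obs_t": o["TIME"].to_numpy(float),
            "dv": o["DV"].to_numpy(float),
            "dose_t": d["TIME"].to_numpy(float),
            "dose_amt": amt, "dose_dur": dur,
            "stratum": str(row.get("TTYPE", "all")),
        })
    return subjects


def _simulate_replicates(subjects, pp: PopulationParameters,
                         spec: RandomEffectSpec, n_replicates: int,
                         rng: np.random.Generator) -> np.ndarray:
    """(n_replicates, n_obs_total) simulated observations (with residual
    error) under the design of the observed data."""
    n_obs = sum(len(s["obs_t"]) for s in subjects)
    out = np.empty((n_replicates, n_obs))
    for r in range(n_replicates):
        eta, _ = sample_eta(spec, rng, size=len(subjects))
        pos = 0
        for i, s in enumerate(subjects):
            sp = subject_from_covariates(s["cov"], pp, eta[i])
            f = _engine.simulate_conc(s["obs_t"], s["dose_t"], s["dose_amt"],
                                      s["dose_dur"], sp.cl, sp.vc, sp.q,
                                      sp.vp, sp.vmax, sp.km)
            out[r, pos:pos + len(f)] = apply_residual_error(
                np.maximum(f, 0.0), pp, rng)
            pos += len(f)
    return out


def vpc(data: PKDataset, pp: PopulationParameters, spec: RandomEffectSpec,
        n_replicates: int = 200, n_bins: int = 10,
        stratify: bool = False, min_bin_obs: int = 10) -> VPCResult:
    """Visual predictive check.

    Observed binwise percentiles (5/50/95) against the 2.5-97.5%
    envelope of the same percentiles over simulated replicates.  Bins are
    quantile-based on time after first dose.  Deterministic given
    ``spec.rng_seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    subjects = _subject_arrays(data)
    rng = np.random.default_rng(spec.rng_seed)
    sims = _simulate_replicates(subjects, pp, spec, n_replicates, rng)
    obs = np.concatenate([s["dv"] for s in subjects])
    t = np.concatenate([s["obs_t"] for s in subjects])
    strata = np.concatenate([[s["stratum"]] * len(s["obs_t"])
                             for s in subjects]) if stratify else \
        np.array(["all"] * len(t))

    rows = []
    for stratum in np.unique(strata):
        m = strata == stratum
        if m.sum() < 2:
            warnings.warn(f"stratum {stratum!r} has fewer than 2 "
                          "observations; bands will be degenerate",
                          stacklevel=2)
        edges = np.unique(np.quantile(t[m], np.linspace(0, 1, n_bins + 1)))
        idx = np.clip(np.searchsorted(edges, t[m], side="right") - 1,
                      0, len(edges) - 2)
        for b in range(len(edges) - 1):
            sel = idx == b
            n_in = int(sel.sum())
            if n_in == 0:
                continue
            if n_in < min_bin_obs:
                warnings.warn(f"bin {b} in stratum {stratum!r} has only "
                              f"{n_in} observations", stacklevel=2)
            o = obs[m][sel]
            s_rep = sims[:, m][:, sel]
            row = {"stratum": stratum, "bin": b,
                   "t_lo": edges[b], "t_hi": edges[b + 1],
                   "t_mid": float(np.median(t[m][sel])), "n": n_in,
                   "flagged": n_in < min_bin_obs}
            for p, name in ((5, "p5"), (50, "p50"), (95, "p95")):
                row[f"obs_{name}"] = float(np.percentile(o, p))
                rep_pcts = np.percentile(s_rep, p, axis=1)
                row[f"sim_{name}_lo"] = float(np.percentile(rep_pcts, 2.5))
                row[f"sim_{name}_hi"] = float(np.percentile(rep_pcts, 97.5))
            rows.append(row)
    return VPCResult(pd.DataFrame(rows), n_replicates, spec.rng_seed)


def npc(data: PKDataset, pp: PopulationParameters, spec: RandomEffectSpec,
        n_replicates: int = 200,
        pi_levels=(0.95, 0.75, 0.5, 0.25, 0.05)) -> NPCResult:
    """Numerical predictive check.

    For each nominal prediction-interval level, per-observation bounds are
    the ((1-level)/2, 1-(1-level)/2) quantiles of the simulated
    replicates; the result reports the fractions of observations below the
    lower and above the upper bound (each nominally (1-level)/2).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    subjects = _subject_arrays(data)
    rng = np.random.default_rng(spec.rng_seed)
    sims = _simulate_replicates(subjects, pp, spec, n_replicates, rng)
    obs = np.concatenate([s["dv"] for s in subjects])
    rows = []
    for level in pi_levels:
        if not 0.0 <= level < 1.0:
            raise ValueError("PI levels must be in [0, 1)")
        a = (1.0 - level) / 2.0
        lo = np.quantile(sims, a, axis=0)
        hi = np.quantile(sims, 1.0 - a, axis=0)
        rows.append({
            "level": level,
            "frac_below": float(np.mean(obs < lo)),
            "frac_above": float(np.mean(obs > hi)),
            "nominal_each_side": a,
            "n_obs": len(obs),
        })
    return NPCResult(pd.DataFrame(rows), n_replicates, spec.rng_seed)


def eta_shrinkage(ebes: pd.DataFrame, omega: dict) -> dict:
    """Shrinkage (%) per random effect: 100 * (1 - SD(eta_hat) / omega).

    ``ebes`` carries ``eta_<name>`` columns (as produced by the fit);
    ``omega`` maps names to population log-SDs, which must be positive.
    """
    out = {}
    for col in ebes.columns:
        if not col.startswith("eta_"):
            continue
        name = col[4:]
        if name not in omega:
            raise KeyError(f"omega has no entry for {name!r}")
        if omega[name] <= 0:
            raise ValueError(f"omega for {name!r} must be positive")
        sd = float(np.std(ebes[col].to_numpy(), ddof=1)) \
            if len(ebes) > 1 else 0.0
        out[name] = 100.0 * (1.0 - sd / omega[name])
    return out
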