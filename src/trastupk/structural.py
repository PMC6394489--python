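"""Structural two-compartment model with parallel linear and
Michaelis-Menten elimination.

State is tracked in amounts (mg): central compartment, peripheral
compartment, and cumulatively eliminated drug.  The last slot exists only
to support mass-balance checks and AUC bookkeeping; it does not feed back
into the dynamics.

Two integration paths are provided.  This module holds the high-accuracy
reference path built on scipy's stiff-capable LSODA (rtol 1e-8 /
atol 1e-10 by default) with dose start/stop times handled as exact segment
boundaries.  A compiled fixed-step path used for population-scale
simulation and likelihood evaluation lives in :mod:`trastupk._engine`;
the two are cross-validated in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import SubjectParameters

__all__ = [
    "ModelState",
    "structural_rhs",
    "integrate_profile",
    "linear_bolus_concentration",
]


@dataclass
class ModelState:
    """Amounts (mg) in each compartment plus cumulative elimination."""

    a_central: float = 0.0
    a_peripheral: float = 0.0
    cumulative_eliminated: float = 0.0
    time: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.a_central, self.a_peripheral,
                         self.cumulative_eliminated], dtype=float)

    @property
    def total(self) -> float:
        """Total drug accounted for; equals the administered dose."""
        return self.a_central + self.a_peripheral + self.cumulative_eliminated


def structural_rhs(y, t: float, sp: SubjectParameters,
                   infusion_rate: float = 0.0) -> np.ndarray:
    """Time derivatives of (A_central, A_peripheral, A_eliminated).

    dA_c/dt = R_inf - (CL/Vc) A_c - (Q/Vc) A_c + (Q/Vp) A_p - Vmax C/(Km+C)
    dA_p/dt = (Q/Vc) A_c - (Q/Vp) A_p
    dA_e/dt = (CL/Vc) A_c + Vmax C/(Km+C)

    with C = A_c/Vc.  The three derivatives sum to the infusion rate, so
    total drug is conserved.  ``t`` is accepted for ODE-solver signatures
    but the system is autonomous within a dosing segment.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y[:2])):
        raise ValueError("non-finite compartment amounts")
    ac, ap = y[0], y[1]
    conc = ac / sp.vc
    mm = sp.vmax * conc / (sp.km + conc)
    lin = (sp.cl / sp.vc) * ac
    transfer = (sp.q / sp.vc) * ac - (sp.q / sp.vp) * ap
    return np.array([infusion_rate - lin - transfer - mm,
                     transfer,
                     lin + mm])


def _rhs_ivp(t, y, sp, rate):
    ac, ap = y[0], y[1]
    conc = ac / sp.vc
    mm = sp.vmax * conc / (sp.km + conc)
    lin = (sp.cl / sp.vc) * ac
    transfer = (sp.q / sp.vc) * ac - (sp.q / sp.vp) * ap
    return (rate - lin - transfer - mm, transfer, lin + mm)


def integrate_profile(sp: SubjectParameters,
                      dose_times: np.ndarray,
                      dose_amounts: np.ndarray,
                      dose_durations: np.ndarray,
                      t_grid: np.ndarray,
                      rtol: float = 1e-8,
                      atol: float = 1e-10,
                      y0: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the structural model over a dosing schedule (LSODA).

    Dose start and stop instants are exact segment boundaries, so the
    piecewise-constant infusion rate is never smeared across an event.
    Zero-duration doses are applied as instantaneous boluses into the
    central compartment.  Grid points that coincide with a bolus instant
    report the pre-dose (trough) state.

    Returns ``(conc, states)``: concentration (mg/L) at each ``t_grid``
    point, and the (n, 3) state trajectory.
    """
    dose_times = np.asarray(dose_times, dtype=float)
    dose_amounts = np.asarray(dose_amounts, dtype=float)
    dose_durations = np.asarray(dose_durations, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    t0, t_end = float(t_grid[0]), float(t_grid[-1])

    starts = dose_times
    stops = dose_times + dose_durations
    bounds = np.unique(np.concatenate([[t0, t_end], starts, stops]))
    bounds = bounds[(bounds >= t0) & (bounds <= t_end)]

    y = np.zeros(3) if y0 is None else np.asarray(y0, dtype=float).copy()
    out = np.empty((len(t_grid), 3))
    filled = np.zeros(len(t_grid), dtype=bool)

    # grid points at segment starts are recorded before any bolus there
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1]
        at_start = np.isclose(t_grid, a) & ~filled
        out[at_start] = y
        filled |= at_start
        # bolus doses fire at the segment start, after the trough record
        bolus = (dose_durations == 0.0) & np.isclose(dose_times, a)
        y[0] += dose_amounts[bolus].sum()
        rate = float(np.sum(dose_amounts[(dose_durations > 0)
                                         & (starts <= a + 1e-12)
                                         & (stops >= b - 1e-12)]
                            / np.maximum(dose_durations[(dose_durations > 0)
                                                        & (starts <= a + 1e-12)
                                                        & (stops >= b - 1e-12)],
                                         1e-300)))
        interior = t_grid[(t_grid > a) & (t_grid < b) & ~np.isclose(t_grid, a)]
        t_eval = np.unique(np.concatenate([interior, [b]]))
        sol = solve_ivp(_rhs_ivp, (a, b), y, args=(sp, rate), method="LSODA",
                        rtol=rtol, atol=atol, t_eval=t_eval)
        if not sol.success:  # pragma: no cover - LSODA failure is exceptional
            raise RuntimeError(
                f"ODE integration failed on segment [{a}, {b}]: {sol.message}")
        for tj, yj in zip(sol.t, sol.y.T):
            hits = np.isclose(t_grid, tj) & ~filled & (t_grid < b)
            out[hits] = yj
            filled |= hits
        y = sol.y[:, -1]

    at_end = np.isclose(t_grid, t_end) & ~filled
    out[at_end] = y
    conc = out[:, 0] / sp.vc
    return conc, out


def linear_bolus_concentration(t, dose: float, cl: float, vc: float,
                               q: float, vp: float) -> np.ndarray:
    """Closed-form concentration after an IV bolus, linear two-compartment.

    Bi-exponential solution C(t) = A e^{-alpha t} + B e^{-beta t} from the
    macro-constants of (CL, Vc, Q, Vp); the analytic reference for the
    numerical integrators when Vmax = 0.
    """
    t = np.asarray(t, dtype=float)
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    disc = math.sqrt(s * s - 4.0 * k10 * k21)
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    c0 = dose / vc
    a_coef = c0 * (alpha - k21) / (alpha - beta)
    b_coef = c0 * (k21 - beta) / (alpha - beta)
    return a_coef * np.exp(-alpha * t) + b_coef * np.exp(-beta * t)
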