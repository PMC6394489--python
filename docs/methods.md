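# Methods

## Model

Serum trastuzumab kinetics after intravenous dosing are described by a
two-compartment disposition model with two parallel elimination pathways
from the central compartment: a first-order (linear) clearance CL and a
saturable Michaelis–Menten pathway with maximum rate Vmax and
half-saturation concentration Km, the standard description for an IgG1
antibody whose target (here HER2) mediates part of its elimination.
In amounts (mg), with C = A_c/V_c in mg/L ≡ µg/mL:

    dA_c/dt = R_inf − (CL/V_c)·A_c − (Q/V_c)·A_c + (Q/V_p)·A_p − Vmax·C/(Km + C)
    dA_p/dt = (Q/V_c)·A_c − (Q/V_p)·A_p

A third state accumulates eliminated drug so that mass balance
(dose = compartments + eliminated) can be asserted to integrator
tolerance at any time.

Default parameters are the published final population estimates for the
pooled intravenous dataset (packaged in
`src/trastupk/data/default_parameters.yaml`, with reported precision and
the bootstrap column kept as metadata): CL 0.127 L/day for breast cancer
and healthy volunteers (0.176 for advanced gastric cancer, 0.148 for
other tumors), V_c 2.62 L (3.63 L for AGC), Q 0.544 L/day, V_p 2.97 L,
Vmax 8.81 mg/day, Km 8.92 mg/L. At the q3w steady-state trough
(≈48 µg/mL) the two pathways contribute comparably; above ~100 µg/mL the
linear route dominates.

### Covariate model

Covariates act multiplicatively on the typical values:

    CL_i = CL_type · (WT_i/66)^0.967 · (SGOT_i/24)^0.205 · (ALBU_i/4)^−0.998
           · e^(0.152·[LMET_i]) · e^η_CL
    Vc_i = [2.62·(non-AGC) + 3.63·(AGC)] · e^η_Vc

References (66 kg, 24 IU/L, 4 g/dL) are the pooled-study medians and are
fixed, not re-estimated.  Missing continuous covariates impute to these
references; missing categorical covariates fall to the predominant
category (no liver metastases; MBC).  An exploratory shed-antigen
(HER2-ECD) term on Km with exponent −0.771 is implemented but disabled by
default; its reference level is configurable because no canonical value
exists.  Tumor type on Km is likewise off by default (the source analysis
excluded it during backward elimination, despite a separate remark that
AGC ran lower); `PopulationParameters(km_agc=...)` overrides this.

### Random effects and residual error

η ~ N(0, Ω) on CL, V_c, V_p and Km, lognormally applied; Ω is diagonal
(SDs 0.401, 0.246, 0.495, 1.39) plus a single CL–Vc covariance of
0.0230.  Q carries no random effect.  The Km SD of 1.39 produces draws
spanning four orders of magnitude, so sampled η are truncated
componentwise at ±4 SD (logged when it happens); this affects well under
0.1% of draws and keeps washout simulations physically interpretable.
Residual error is combined: DV = F·(1+ε₁) + ε₂ with SDs 0.197
(proportional) and 1.38 µg/mL (additive).  Exposure metrics are
model-predicted concentrations; residual error is added only when
emitting synthetic observations.

## Numerics

Two integration paths, cross-validated in the tests to <0.1%:

* **Reference path** — scipy LSODA, rtol 1e-8 / atol 1e-10, with dose
  start/stop instants as exact segment boundaries.  Used for
  single-subject simulation by default.
* **Compiled path** — fixed-step RK4 (numba) across the same event
  segments, h ≤ 0.1 day for simulation and h ≤ 0.2–0.3 day inside
  likelihood evaluation.  The system's rate constants are all below
  ~1/day at therapeutic concentrations, so these steps resolve the
  dynamics to ~1e-5 relative; the fixed grid also makes the likelihood a
  smooth function of parameters, which finite-difference gradients need.

Troughs use the pre-dose convention (the value the instant before a
dose).  Infusion durations are not stated in the source description;
defaults are 90 min (loading) and 30 min (maintenance), configurable —
trough and AUC metrics are insensitive at this timescale.  AUC_ss is the
trapezoid over the final dosing interval of the simulated grid
(0.25-day spacing by default).

## Regimen analyses and their conventions

* **Time to steady state** is resolved on the trough sequence: the week
  of the first pre-dose trough ≥ 90% of the terminal-cycle trough of a
  36-week simulation.  This reproduces 12 weeks (q3w breast cancer) and
  9 weeks (AGC).  For the weekly regimen the week-12 trough sits at
  89.8% of the 36-week trough — a knife-edge 0.2% short of the
  threshold, within the print precision of the three-significant-figure
  parameters — so the criterion lands at week 13 there.
* **Washout** is the time from the last dose until the concentration
  falls below 1 µg/mL (≈97% washout for the typical BC patient) and
  stays below; the population version reports the coverage quantile
  (default 95%) of per-subject crossing days over ≥1000 virtual
  subjects with a subject-bootstrap CI.  Population covariates default
  to the typical vector because the real per-patient covariate mix is
  unavailable; the synthetic covariate sampler can be plugged in.  The
  source text does not state its Monte-Carlo size or covariate scheme —
  a fidelity limit of this reproduction.
* **Missed doses.**  One maintenance dose (by default the first dose on
  or after day 168, deep into steady state) is delayed; dosing restarts
  at the delayed administration (maintenance or reloading amount) and
  continues at the regimen interval from that point.  Recovery is
  measured from the originally scheduled dose time as the entry of the
  trough trajectory into the two-sided ±15% band around the no-miss
  steady-state trough, with linear interpolation between troughs as the
  continuous refinement (the trough grid itself is 3-weekly on q3w).
  A gap exceeding interval + 7 days triggers the reloading amount when
  schedules are built with `reload_after_delay`.

  Under this convention the model recovers in ≈5.6 weeks after a 7-day
  delay with maintenance restart and ≈10 weeks after a 14-day delay,
  while a 14-day delay followed by a reloading dose is back inside the
  band at the first post-reload trough.  The shorter published summary
  figures for the two maintenance scenarios (≈3 and ≈6 weeks) could not
  be reproduced under any measurement variant we examined (measuring
  from the restart dose, resynchronizing to the original calendar,
  one-sided bands, grid vs interpolated troughs): they are consistent
  only with a band drawn around a reference trough a few percent below
  the typical-patient steady-state trough, measured from the restart
  dose.  We report our convention's numbers rather than tuning the
  reference, and note that the qualitative ordering — one-week misses
  heal in roughly one cycle-scale, two-week misses take about twice as
  long, reloading heals immediately — is reproduced.

## Estimation

The marginal likelihood integrates η out per subject with a Laplace
approximation at the posterior mode: a damped Newton search (FD
gradients, curvature refreshed sparingly, tolerance 1e-6·(1+|−2LL|) on
the gradient) followed by the log-determinant correction.  This is the
closest well-defined surrogate for NONMEM's FOCEI, whose interaction
expansion is implementation-specific; on small subjects the Laplace −2LL
agrees with 11-node adaptive Gauss–Hermite quadrature to <0.1 (asserted
in the tests).  The outer problem runs L-BFGS-B on log-transformed
structural parameters and SDs, raw covariate coefficients, and an
arctanh-transformed CL–Vc correlation (guaranteeing a positive-definite
Ω), with η modes warm-started across iterations.  Convergence follows
scipy defaults tightened to ftol 1e-9; a stalled optimizer returns a
partial result flagged unconverged rather than raising.

Below-LLOQ observations (<0.156 µg/mL) are dropped before fitting (M1),
and subjects losing all observations are excluded and counted — the
evaluability rule of the source analysis.

### Covariate search

Candidates enter as power terms (continuous, centered at fixed
references), exponential terms (binary) or indicator contrasts
(categorical).  The pipeline: univariate screen (LRT p < 0.005), forward
addition (p < 0.001), backward elimination (p < 0.001), then a
clinical-relevance filter dropping any retained covariate whose span
across the observed 5th–95th percentile range (or toggle, for flags)
changes none of Cmin,ss, Cmax,ss and AUC,ss by at least 15% for a
typical q3w patient.  Weight relevance accounts for mg/kg dosing (the
dose moves with the covariate).  Every decision lands in an audit table.
The source's procedure is known only in summary; any unlisted internal
steps of its three-step scheme are not emulated.

## Synthetic data

The generator pins what the source states — stratum ratios
810:391:274:107 (MBC:EBC:AGC:other), q3w:qw arm ratio 917:643, covariate
medians 66 kg / 24 IU/L / 4.0 g/dL, LLOQ 0.156 µg/mL — and fills the
unstated distributions with defaults a PK scientist would call
plausible: lognormal weight (log-SD 0.2) and SGOT (log-SD 0.4),
truncated-normal albumin (SD 0.35), 20% liver-metastasis prevalence.
Sampling templates: "rich" (pre-dose trough plus 1, 2, 7, 14, 21-day
post-dose samples on cycles 1, 4, 13) and "sparse" (troughs only), with
optional washout samples.  Real per-study schedules are unknown; the
template is a stand-in, so passing recovery tests demonstrate internal
consistency of estimator and generator, not fidelity to any particular
trial's design.

## Problem sizes

Chosen as the package's defaults for its own studies: washout
Monte-Carlo n = 1000 (the 95% quantile then carries a ±4–6% bootstrap
CI); parameter recovery n = 100 subjects with rich sampling (one
replicate; estimates land within ~10% of truth, against a ±20%
criterion); covariate-selection operating characteristics 10 replicates
of n = 100 single-dose subjects; predictive checks 200 replicates.

## Known limitations

* Laplace, not FOCEI: OFV values are not comparable to NONMEM's run
  records, only differences within this package are meaningful.
* No inter-occasion variability (none was estimated in the source);
  residual error therefore absorbs day-to-day variation.
* Covariates are baseline-only; no time-varying covariates.
* Ω estimation in the fit is diagonal + the single CL–Vc covariance;
  richer structures are out of scope.
* The exposure summaries with typical covariates cannot reproduce the
  published population medians exactly — those depend on the real
  1582-patient covariate mix, which is not public.
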