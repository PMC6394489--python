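# Final population PK estimates for intravenous trastuzumab
# (two-compartment model, parallel linear + Michaelis-Menten elimination;
# pooled phase I-III analysis, 1582 patients / 26,040 samples).
parameters:
  cl_bc: 0.127        # linear CL, breast cancer / healthy volunteers (L/day)
  cl_other: 0.148     # linear CL, other tumor types (L/day)
  cl_agc: 0.176       # linear CL, advanced gastric cancer (L/day)
  vc_nonagc: 2.62     # central volume, non-AGC (L)
  vc_agc: 3.63        # central volume, AGC (L)
  q: 0.544            # inter-compartmental clearance (L/day)
  vp: 2.97            # peripheral volume (L)
  vmax: 8.81          # Michaelis-Menten Vmax (mg/day)
  km: 8.92            # Michaelis-Menten Km (mg/L)
  wt_exp: 0.967       # weight exponent on CL
  sgot_exp: 0.205     # SGOT exponent on CL
  albu_exp: -0.998    # albumin exponent on CL
  lmet_coef: 0.152    # liver-metastases coefficient on CL
  omega_cl: 0.401     # IIV log-SD of CL
  omega_vc: 0.246     # IIV log-SD of Vc
  omega_vp: 0.495     # IIV log-SD of Vp
  omega_km: 1.39      # IIV log-SD of Km
  omega_cl_vc_cov: 0.0230
  sigma_prop: 0.197   # proportional residual SD (fraction)
  sigma_add: 1.38     # additive residual SD (ug/mL)
  shed_km_exp: -0.771 # exploratory shed-antigen exponent on Km
  shed_enabled: false
metadata:
  rse_percent:
    cl_bc: 2.36
    cl_other: 5.81
    cl_agc: 4.19
    vc_nonagc: 0.79
    vc_agc: 1.94
    q: 3.38
    vp: 1.81
    vmax: 1.44
    km: 8.61
    wt_exp: 7.19
    sgot_exp: 16.6
    albu_exp: 12.2
    lmet_coef: 21.4
    omega_cl: 6.71
    omega_vc: 4.98
    omega_vp: 9.39
    omega_km: 20.3
    sigma_prop: 1.35
    sigma_add: 31.8
  bootstrap_mean:
    cl_bc: 0.126
    cl_other: 0.147
    cl_agc: 0.175
    vc_nonagc: 2.62
    vc_agc: 3.63
    q: 0.543
    vp: 2.97
    vmax: 8.86
    km: 8.97
    wt_exp: 0.973
    sgot_exp: 0.211
    albu_exp: -1.0
    lmet_coef: 0.148
    omega_cl: 0.401
    omega_vc: 0.245
    omega_vp: 0.496
    omega_km: 1.41
    sigma_prop: 0.197
    sigma_add: 1.33
  bootstrap_runs: {total: 200, successful: 169}
  shrinkage_percent: {cl: 14.7, vc: 13.0, vp: 22.9, km: 44.0, sigma: 7.0}
  residual_rse_note: RSE of sigma terms is relative to the variance scale.
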