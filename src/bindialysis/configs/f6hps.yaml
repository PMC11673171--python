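# Bench condition 1: F6HPS dialyzer, BSA both sides, Qb=180 / Qd=90 mL/min.
# KfreeA and KB are the values fitted on this condition.
name: f6hps
dialyzer:
  n_fibers: 8400
  r_inner_um: 100
  r_outer_um: 140
  fiber_length_cm: 21
  housing_radius_mm: 20
  area_nominal_m2: 1.3
  Lp_m_per_s_Pa: 8.61e-11
  sigma: 0.0
solute:
  KB_per_M: 0.5e+7
operating:
  Qb_mL_min: 180
  Qd_mL_min: 90
  Vb_mL: 628.33
  Vd_mL: 626.67
  Cb_toxin0_mg_dL: 15.37
  Cb_albumin_g_dL: 2.24
  Cd_albumin_g_dL: 1.77
  Cd_toxin0_mg_dL: 0.0
  duration_h: 3
transport:
  KfreeA_at_500_mL_min: 2500.0
  beta_Qd: 0.05544
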