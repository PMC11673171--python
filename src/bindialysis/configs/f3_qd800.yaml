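# Bench condition 4: F3 dialyzer, BSA both sides, Qb=150 / Qd=800 mL/min.
# KfreeA_at_500 is the F6HPS fitted value rescaled by nominal area (0.4/1.3);
# beta_Qd is the best-fit flow-dependence for this dialyzer.
name: f3_qd800
dialyzer:
  n_fibers: 2304
  r_inner_um: 100
  r_outer_um: 140
  fiber_length_cm: 20
  housing_radius_mm: 11
  area_nominal_m2: 0.4
  Lp_m_per_s_Pa: 8.61e-11
  sigma: 0.0
solute:
  KB_per_M: 0.5e+7
operating:
  Qb_mL_min: 150
  Qd_mL_min: 800
  Vb_mL: 200
  Vd_mL: 200
  Cb_toxin0_mg_dL: 18.28
  Cb_albumin_g_dL: 2.03
  Cd_albumin_g_dL: 2.1
  Cd_toxin0_mg_dL: 0.0
  duration_h: 5
transport:
  KfreeA_at_500_mL_min: 769.23
  beta_Qd: 0.45
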