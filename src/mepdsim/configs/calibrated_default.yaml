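kndy:
  I0: 0.3
  K_DN: 0.3
  K_F: 1.0
  K_Nv: 0.3
  K_vD: 0.35
  K_vN: 0.12
  g_Nv: 3.0
  k_D: 1.0
  k_N: 1.0
  k_N0: 0.125
  n_DN: 4.0
  n_F: 4.0
  n_Nv: 2.0
  n_vD: 4.0
  n_vN: 2.0
  tau_D: 10.0
  tau_N: 2.0
  tau_v: 1.0
  v_max: 1.0
mepd:
  e0: 0.0
  g0: 1.0
  kappa0: 0.0
  kappa_opt: 1.0
  slope_E: 8.0
  slope_G1: 8.0
  slope_G2: 4.0
  tau_m: 2.0
  theta_E: 3.0
  theta_G1: 3.0
  theta_G2: 1.0949
  w_A: 0.5925
  w_B: 0.3491
  w_EG2: 0.922
  w_Eout: 0.25
  w_G2out: 0.8
  w_KE: 6.0
  w_KG1: 6.0
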