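kind: 1s-hA
geometry_cm:
  r_AM:
  - 7.0
  - -1.4
  r_MT:
  - 6.0
  - -4.6
  r_A_CoM:
  - 5.0
  - -5.0
  r_A_H:
  - -2.0
  - -6.0
  r_M_B:
  - -2.0
  - -6.0
  r_A_CH:
  - -4.0
  - -3.0
  r_A_CB:
  - 13.0
  - -2.27
  r_A_CT:
  - 18.5
  - -8.0
  R_H: 5.0
  R_B: 5.73
  R_T: 0.0
  R_PF: 1.0
contact:
  k_y: 78300.0
  v_max: 0.03
  mu_d: 0.8
  mu_s: 0.9
  v_t: 0.01
ligaments:
  PF:
    area_mm2: 50.0
    k_mpa: 340.0
    d_s: 3.0
    l0_cm: 15.0
    alpha: 9.0
  PL:
    area_mm2: 120.0
    k_mpa: 340.0
    d_s: 30.0
    l0_cm: 15.0
    alpha: 9.0
inertia:
  m_foot: 1.16
  I_foot: 0.005
  light_mass_fraction: 0.03
gains:
  k_phi: 2.94
  G_HAMHFL: 3.0
  G_GAS: 1.1
  G_TA: 1.1
  G_VAS: 1.15
  G_SOLTA: 4.27
  G_SOL: 1.2
  G_HFL: 0.38
  G_HAM: 0.65
  G_GLU: 0.49
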