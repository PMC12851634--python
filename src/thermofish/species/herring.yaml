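# Atlantic herring (Clupea harengus) — boreal, juvenile-adult in the Wadden Sea
name: herring
w_b: 0.0007
q_j: 0.7
q_a: 1.13
q_r: 0.7
k_r: 0.5
E_d: 17
A_f: 25
L_m: 14
lambda1: 5.65
lambda2: 0.32
d1: 0.97
d2: 0.303
rho1: 0.03
rho2: 0.8
k_e: 0.5
intake_thermal:
  gamma_opt: 17
  v_opt: -0.031
  gamma_max: 23
  v_max: -0.0475
  theta_coef: 1.8
  theta_exp: 0.0775
maintenance_thermal:
  gamma_opt: 16.5
  v_opt: -0.028
  gamma_max: 24
  v_max: -0.05
  theta_coef: 2.2
  theta_exp: 0.081
max_lifespan_years: 12
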