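# European sprat (Sprattus sprattus) — Lusitanian seasonal migrant
name: sprat
w_b: 0.0005
q_j: 0.9
q_a: 1.4
q_r: 0.9
k_r: 0.5
E_d: 17
A_f: 25
L_m: 9
lambda1: 5.4
lambda2: 0.33
d1: 0.46
d2: 0.215
rho1: 0.03
rho2: 0.8
k_e: 0.5
intake_thermal:
  gamma_opt: 21
  v_opt: -0.055
  gamma_max: 25
  v_max: -0.0475
  theta_coef: 2.2
  theta_exp: 0.0775
maintenance_thermal:
  gamma_opt: 20
  v_opt: -0.028
  gamma_max: 26.5
  v_max: -0.05
  theta_coef: 2.25
  theta_exp: 0.081
max_lifespan_years: 6
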