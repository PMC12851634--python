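# Thinlip mullet (Chelon ramada) — Lusitanian opportunist
name: mullet
w_b: 0.00038
q_j: 0.8
q_a: 1.0
q_r: 0.8
k_r: 0.5
E_d: 2
A_f: 7
L_m: 25.9
lambda1: 4.48
lambda2: 0.341
d1: 0.3
d2: 0.52
rho1: 0.03
rho2: 0.79
k_e: 0.5
intake_thermal:
  gamma_opt: 30
  v_opt: -0.041
  gamma_max: 37
  v_max: -0.031
  theta_coef: 1.81
  theta_exp: 0.075
maintenance_thermal:
  gamma_opt: 34
  v_opt: -0.04
  gamma_max: 42
  v_max: -0.0295
  theta_coef: 2.27
  theta_exp: 0.077
max_lifespan_years: 25
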