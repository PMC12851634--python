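# Five-bearded rockling (Ciliata mustela) — boreal estuarine resident
name: rockling
w_b: 0.00149
q_j: 0.8
q_a: 1.03
q_r: 0.8
k_r: 0.5
E_d: 11
A_f: 16
L_m: 14
lambda1: 5.26
lambda2: 0.3174
d1: 1.80
d2: 0.05
rho1: 0.03
rho2: 0.79
k_e: 0.5
intake_thermal:
  gamma_opt: 16
  v_opt: -0.072
  gamma_max: 27
  v_max: -0.0275
  theta_coef: 2.0
  theta_exp: 0.075
maintenance_thermal:
  gamma_opt: 17.5
  v_opt: -0.025
  gamma_max: 29
  v_max: -0.029
  theta_coef: 2
  theta_exp: 0.077
# typical maximum lifespan of 3-4 years
max_lifespan_years: 4
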