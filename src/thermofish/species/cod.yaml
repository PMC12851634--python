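# Atlantic cod (Gadus morhua) — boreal, marine juvenile in the Wadden Sea
name: cod
w_b: 0.00039
q_j: 0.7
q_a: 1.2
q_r: 0.7
k_r: 0.5
E_d: 15
A_f: 22
L_m: 62
lambda1: 4.95
lambda2: 0.325
d1: 0.2
d2: 0.635
rho1: 0.03
rho2: 0.8
k_e: 0.5
intake_thermal:
  gamma_opt: 16.78
  v_opt: -0.078
  gamma_max: 22
  v_max: -0.0435
  theta_coef: 2.2
  theta_exp: 0.075
maintenance_thermal:
  gamma_opt: 15.5
  v_opt: -0.02
  gamma_max: 24
  v_max: -0.029
  theta_coef: 2.6
  theta_exp: 0.077
# FishBase-style longevity approximation (not a laboratory value)
max_lifespan_years: 25
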