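[morphology]
r_um = 0.2
h_um = 0.0

[model]
literal_recycling = False

[release]
r_max = 8.513526e-06
v_cr = -40.0
v_hi = 30.0
n_max = 0.008
k_rec = 0.0001
clamp_quadratic = False

[receptors]
g_nmda = 0.1389
g_ampa = 0.4861
alpha_nmda = 0.072
beta_nmda = 0.0066
alpha_ampa = 1.1
beta_ampa = 0.19
mg = 1.0

[uptake]
v_cn_max = 0.03
k_m = 0.02
d_g = 0.4
dx = 40.0

[membrane]
c_m = 1.0
g_na_gated = 100.0
g_k_gated = 40.0
g_cl_leak = 0.005
phi = 3.0
tau_s_ms = 30000.0
s_v_half = -40.0
s_slope = 5.0

[pumpglia]
rho_p = 5.25
pump_na_half = 25.0
pump_na_slope = 3.0
pump_k_half = 5.5
pump_k_slope = 1.0
lambda_bath = 2e-05
k_f_glia = 3e-06
k_glia_thr = 18.0
k_glia_width = 2.5
w_max = 800.0
w0 = 150.0
p_water_n = 0.001
p_water_g = 0.001
bath_mode = 'na_swap'
bath_hyper_amp = 0.0
bath_hyper_thr = 22.0
bath_hyper_width = 3.0

[rest]
v0 = -67.0
na_n = 25.0
k_n = 130.0
na_e = 125.0
k_e = 4.0
na_g = 15.0
k_g = 120.0
cl_g = 20.0

[protocol]
kind = 'perfusion'
k_bath_high_mm = 15.0
k_bath_rest_mm = 4.0
t_on_ms = 0.0
ogd_t_start_ms = 10000.0
ogd_ramp_ms = 15000.0
ogd_hold_ms = 40000.0
ogd_shape = 'linear'
uptake_fraction = 1.0
t_end_ms = 300000.0

[solver]
rtol = 1e-08
atol_scale = 1e-10
sample_dt_ms = 10.0
method = 'LSODA'

[events]
baseline_window_ms = 5000.0
depol_threshold_mv = -30.0
persistence_ms = 5000.0
repol_tolerance_mv = 2.0

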