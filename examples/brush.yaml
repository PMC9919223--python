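# Polymer-brush adsorption in water on a 5 MHz crystal.
f0: 5.0e6
Zq: 8.8e6
bulk: newtonian
rho_bulk: 1000.0
eta_bulk: 1.0e-3

# film material (compliance representation, values at f_cen)
representation: compliance
rho_f: 1000.0
f_cen: 30.0e6
value1: 2.9e-7     # J' in 1/Pa
value2: 1.68e-6    # J'' in 1/Pa
beta1: -1.61
beta2: -0.91

# growth and sampling
growth: langmuir
d_max: 1.0e-8      # m
tau: 50.0          # s
t_end: 300.0
dt: 1.0

# noise (Hz): constant per-crystal offsets + white noise per sample
offset_scale: 0.1
white_scale: 0.02

# fit weights (Hz)
sigma_f: 0.1
sigma_g: 0.1
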