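# Published-scale two-membrane interface, thermal undulations only.
# Reference observables: mean separation ~70 nm (entropic blister above
# dz_inf = 60 nm), separation SD ~4.6 nm, two-timescale autocorrelation
# (tau_fast ~ 5.3e-7 s, tau_slow ~ 8.2e-5 s, slow fraction c^2 ~ 0.48).
n_membranes: 2
r_cell: 1000.0
r_free: 150.0
dz_inf: 60.0
dz_star: 20.0
eta: 1.0e-3
kappa_B: 50.0
sigma0: 100.0
F_active: 0.0
a_force: 10.0
psi: 0.0
thermal: true
dx: 5.0
mesh_edge: 10.0
dt: 1.0e-10
t_total: 1.0
sample_every: 100
overdamped: false
seed: 0
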