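# Published-scale active-force interface run: F = 20 pN over a 10 nm disk
# drives proximity from dz_inf = 50 nm; deterministic (thermal off).
n_membranes: 2
r_cell: 1000.0
r_free: 150.0
dz_inf: 50.0
dz_star: 20.0
eta: 1.0e-3
kappa_B: 50.0
sigma0: 100.0
F_active: 20.0
a_force: 10.0
psi: 0.0
thermal: false
dx: 5.0
mesh_edge: 10.0
dt: 1.0e-10
t_total: 1.0e-2
sample_every: 100
overdamped: true
seed: 0
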