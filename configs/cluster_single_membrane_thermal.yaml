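# Published-scale single-membrane thermal run (ghost-tethered control).
# Grid dx = 5 nm over a ~2 um lateral domain; requires cluster resources
# (~1e8 cells x 1e7+ steps); desk-scale analogues are built by the tests.
n_membranes: 1
r_cell: 1000.0
r_free: 150.0
dz_inf: 60.0
dz_star: 20.0
eta: 1.0e-3          # Pa s
kappa_B: 50.0        # pN nm
sigma0: 100.0        # pN/um
F_active: 0.0
a_force: 10.0
psi: 0.0
thermal: true
dx: 5.0
mesh_edge: 10.0
dt: 1.0e-10          # s
t_total: 1.0         # s
sample_every: 100
overdamped: false
seed: 0
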