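"""Equilibrium displacement under an active force, vs tension and adhesion.

The equilibrium of a constant force involves no fluid, so it is computed
by direct energy minimization.  Run:  python examples/03_active_force_equilibrium.py  (~30 s)
"""
from ibmem import Scenario, equilibrium_displacement, scan

# reduced-scale interface geometry: 170 nm membrane patch, 85 nm
# adhesion-free zone, bending modulus scaled to keep the published
# tension-to-bending balance
base = Scenario(n_membranes=1, r_cell=170.0, r_free=85.0, dz_inf=40.0,
                dz_star=20.0, kappa_B=16.0, sigma0=100.0, F_active=3.0,
                mesh_edge=16.0, dx=40.0 / 3.0, grid_shape=(30, 30, 16),
                thermal=False)

d = equilibrium_displacement(base)
print(f"F = 3 pN  ->  equilibrium receptor displacement {d:.1f} nm")

df = scan(base, "sigma0", [25.0, 100.0, 400.0], mode="static")
print("\nsurface tension scan (higher tension -> smaller displacement):")
print(df[["sigma0", "equilibrium_displacement"]].to_string(index=False))

df = scan(base, "r_free", [50.0, 85.0, 120.0], mode="static")
print("\nadhesion-free radius scan (denser adhesions = smaller r_free -> smaller displacement):")
print(df[["r_free", "equilibrium_displacement"]].to_string(index=False))
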