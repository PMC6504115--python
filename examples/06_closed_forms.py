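"""Closed forms: rigid-sphere drainage and the critical permeability scale.

Run:  python examples/06_closed_forms.py   (instant)
"""
from ibmem import critical_permeability, rigid_sphere_drainage
from ibmem.scenario import drainage_time_constant

# two rigid 1-um spheres squeezed by 10 pN: the gap closes exponentially
tau = drainage_time_constant(F=10.0, r_cell=1000.0, eta=1e-3)
z = rigid_sphere_drainage(z0=60.0, F=10.0, r_cell=1000.0, eta=1e-3, t=tau)
print(f"drainage e-folding time: {tau:.2e} s  (10 pN, 1 um spheres, water)")
print(f"gap after one time constant: {z:.1f} nm (from 60 nm)")
print("the (z/r_cell) factor in the drag makes this ~1000x slower than free-space Stokes drag")

# permeability needed for permeation to beat parallel drainage
psi_c = critical_permeability(dz_inf=60.0, eta=1e-3, r_free=150.0)
print(f"\ncritical permeability: {psi_c:.3g} nm/(s Pa)  (~1e4)")
print("physiological estimates are 1e-2..1e1 nm/(s Pa): orders of magnitude below -")
print("real membranes cannot drain the thin layer by permeation")
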