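"""Thermal equilibrium of the fluctuating fluid: equipartition.

Every divergence-free Fourier mode should carry kBT/2 of kinetic energy.
Run:  python examples/02_fluctuating_fluid.py   (~20 s)
"""
import numpy as np

from ibmem import FluidGrid, fluid_step
from ibmem.fluid import mode_energies

grid = FluidGrid((8, 8, 8), dx=10.0, kBT=4.1)
kmin = 2 * np.pi / (8 * 10.0)
tau_slowest = grid.rho / (grid.eta * kmin**2)  # slowest viscous relaxation [us]
dt = 2.0 * tau_slowest
rng = np.random.default_rng(0)

energies = []
for i in range(3000):
    grid, _ = fluid_step(grid, None, dt, rng, thermal=True)
    if i > 100:
        energies.append(mode_energies(grid))
E = np.mean(energies, axis=0)

# each retained wavevector entry carries 2 kBT (4 real dof at kBT/2 each)
print(f"modes: {grid.n_modes()}")
print(f"mean mode energy / 2 kBT : {E.mean() / (2 * grid.kBT):.4f}   (=> 1.00)")
print(f"worst single-mode deviation: {np.abs(E / (2 * grid.kBT) - 1).max():.3f}")
print("a flat spectrum at kBT/2 per degree of freedom is the discrete")
print("fluctuation-dissipation balance - the fluid samples true thermal equilibrium")
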