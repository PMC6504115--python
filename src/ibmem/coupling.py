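"""Fluid--structure coupling through the 4-point immersed-boundary kernel.

The spreading operator Lambda carries Lagrangian vertex forces onto the
Eulerian grid as force densities, and the interpolation operator Gamma
evaluates grid fields at vertex positions:

    (Lambda F)(x) = sum_v F_v delta(x - X_v),
    (Gamma u)(X_v) = sum_x u(x) delta(x - X_v) dx^3,

with delta the tensor product of the classic 4-point kernel phi scaled
by 1/dx^3.  Lambda and Gamma are exact adjoints in the discrete inner
products, which is what makes the coupled scheme energy-consistent.

Membrane permeability enters as a slip term in the structure update:
vertices move with the interpolated fluid velocity plus
psi * (normal force per vertex area), the linear velocity/pressure-
difference law, with a matching thermal slip force when kBT > 0 so the
permeable coupling also satisfies detailed balance.

Note on symbols: the kernel width equals the grid spacing dx and is
unrelated to the active-force disk radius (also called "a" in the
membrane layer); the two never meet in code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fluid import FluidGrid
from .mesh import TriMesh


@dataclass
class PermeabilityParams:
    """Membrane surface permeability.

    psi : surface permeability [nm/(s Pa)]; numerically identical in the
        internal nm^3/(us pN) system (1 nm/(s Pa) = 1 nm/us per pN/nm^2).
    kBT : thermal energy [pN nm] for the slip noise.
    """

    psi: float = 0.0
    kBT: float = 0.0

    def __post_init__(self) -> None:
        if self.psi < 0:
            raise ValueError("psi must be >= 0")

    def psi_bar(self, dx: float) -> float:
        """Force-density slip coefficient psi*dx (internal)."""
        return self.psi * dx


def kernel_phi(r):
    """The 4-point immersed-boundary kernel weight phi(r), r >= 0.

    phi(r) = (3 - 2r + sqrt(1 + 4r - 4r^2))/8      on [0, 1],
             (5 - 2r - sqrt(-7 + 12r - 4r^2))/8    on (1, 2],
             0                                     beyond 2.

    Continuous, supported on [0, 2), and satisfies the partition of
    unity sum_j phi(|x - j|) = 1 on the integer lattice.
    """
    r = np.abs(np.asarray(r, dtype=float))
    out = np.zeros_like(r)
    m1 = r <= 1.0
    m2 = (r > 1.0) & (r <= 2.0)
    r1 = r[m1]
    out[m1] = (3.0 - 2.0 * r1 + np.sqrt(1.0 + 4.0 * r1 - 4.0 * r1 * r1)) / 8.0
    r2 = r[m2]
    out[m2] = (5.0 - 2.0 * r2 - np.sqrt(-7.0 + 12.0 * r2 - 4.0 * r2 * r2)) / 8.0
    return out if out.ndim else float(out)


def kernel_phi_prime(r):
    """d phi/dr for r >= 0 (phi' (0) = 0; continuous at 1 and 2)."""
    r = np.abs(np.asarray(r, dtype=float))
    out = np.zeros_like(r)
    m1 = r <= 1.0
    m2 = (r > 1.0) & (r < 2.0)
    r1 = r[m1]
    out[m1] = (-2.0 + (2.0 - 4.0 * r1) / np.sqrt(1.0 + 4.0 * r1 - 4.0 * r1 * r1)) / 8.0
    r2 = r[m2]
    out[m2] = (-2.0 - (6.0 - 4.0 * r2) / np.sqrt(-7.0 + 12.0 * r2 - 4.0 * r2 * r2)) / 8.0
    return out if out.ndim else float(out)


def delta3(offset: np.ndarray, dx: float):
    """Tensor-product smoothed delta, weight density [1/nm^3].

    delta(x) = phi(|x|/dx) phi(|y|/dx) phi(|z|/dx) / dx^3; support 4^3 cells.
    """
    if dx <= 0:
        raise ValueError("dx must be > 0")
    off = np.asarray(offset, float)
    w = kernel_phi(off[..., 0] / dx) * kernel_phi(off[..., 1] / dx) * kernel_phi(off[..., 2] / dx)
    return w / dx**3


def _kernel_weights(positions: np.ndarray, grid: FluidGrid):
    """Stencil indices and per-axis weights for each position.

    Returns (idx, wx, wy, wz): idx is (M, 3, 4) wrapped grid indices,
    w* are (M, 4) kernel weights along each axis (summing to 1).
    """
    dx = grid.dx
    pos = np.asarray(positions, float)
    base = np.floor(pos / dx).astype(np.int64)  # cell containing the point
    offs = np.arange(-1, 3)  # 4-point stencil
    idx = np.empty((len(pos), 3, 4), dtype=np.int64)
    w = np.empty((len(pos), 3, 4))
    for ax in range(3):
        nodes = base[:, ax : ax + 1] + offs[None, :]
        r = (pos[:, ax : ax + 1] - nodes * dx) / dx
        w[:, ax, :] = kernel_phi(r)
        idx[:, ax, :] = np.mod(nodes, grid.shape[ax])
    return idx, w


def spread(mesh_or_positions, forces: np.ndarray, grid: FluidGrid) -> np.ndarray:
    """(Lambda F): vertex forces [pN] -> grid force density [pN/nm^3].

    Conserves momentum exactly: sum_grid (Lambda F) dx^3 = sum_v F_v.
    """
    pos = _positions(mesh_or_positions)
    F = np.asarray(forces, float)
    out = np.zeros((3, *grid.shape))
    if len(pos) == 0:
        return out
    idx, w = _kernel_weights(pos, grid)
    inv_dx3 = 1.0 / grid.dx**3
    # outer product of the three axis stencils per vertex
    wxyz = w[:, 0, :, None, None] * w[:, 1, None, :, None] * w[:, 2, None, None, :]
    ii = idx[:, 0, :, None, None] * (grid.shape[1] * grid.shape[2])
    jj = idx[:, 1, None, :, None] * grid.shape[2]
    kk = idx[:, 2, None, None, :]
    flat = (ii + jj + kk).reshape(len(pos), -1)
    vals = wxyz.reshape(len(pos), -1) * inv_dx3
    for c in range(3):
        np.add.at(out[c].ravel(), flat.ravel(), (vals * F[:, c : c + 1]).ravel())
    return out


def interpolate(grid: FluidGrid, mesh_or_positions, field: np.ndarray | None = None) -> np.ndarray:
    """(Gamma u): grid field -> per-vertex values (velocities [nm/us]).

    Exact for spatially uniform fields (partition of unity).
    """
    pos = _positions(mesh_or_positions)
    u = grid.velocity if field is None else np.asarray(field, float)
    if len(pos) == 0:
        return np.zeros((0, 3))
    idx, w = _kernel_weights(pos, grid)
    wxyz = w[:, 0, :, None, None] * w[:, 1, None, :, None] * w[:, 2, None, None, :]
    ii = idx[:, 0, :, None, None] * (grid.shape[1] * grid.shape[2])
    jj = idx[:, 1, None, :, None] * grid.shape[2]
    kk = idx[:, 2, None, None, :]
    flat = (ii + jj + kk).reshape(len(pos), -1)
    wf = wxyz.reshape(len(pos), -1)
    out = np.empty((len(pos), 3))
    for c in range(3):
        out[:, c] = np.sum(u[c].ravel()[flat] * wf, axis=1)
    return out


def _positions(mesh_or_positions) -> np.ndarray:
    if isinstance(mesh_or_positions, TriMesh):
        return mesh_or_positions.vertices
    return np.asarray(mesh_or_positions, float)


def spread_drift_term(mesh_or_positions, grid: FluidGrid, kBT: float) -> np.ndarray:
    """Thermal kernel-drift force density (div_X Lambda) kBT [pN/nm^3].

    Per vertex the i-th component is -kBT d_i delta(x - X_v), computed
    from the analytic kernel derivative; integrates to zero total force.
    """
    if kBT < 0:
        raise ValueError("kBT must be >= 0")
    pos = _positions(mesh_or_positions)
    out = np.zeros((3, *grid.shape))
    if kBT == 0.0 or len(pos) == 0:
        return out
    dx = grid.dx
    base = np.floor(pos / dx).astype(np.int64)
    offs = np.arange(-1, 3)
    w = np.empty((len(pos), 3, 4))
    dwdr = np.empty((len(pos), 3, 4))
    idx = np.empty((len(pos), 3, 4), dtype=np.int64)
    for ax in range(3):
        nodes = base[:, ax : ax + 1] + offs[None, :]
        r = (pos[:, ax : ax + 1] - nodes * dx) / dx
        w[:, ax, :] = kernel_phi(r)
        # d/dx phi(|r|) = sign(r) phi'(|r|) / dx
        dwdr[:, ax, :] = np.sign(r) * kernel_phi_prime(r) / dx
        idx[:, ax, :] = np.mod(nodes, grid.shape[ax])
    ii = idx[:, 0, :, None, None] * (grid.shape[1] * grid.shape[2])
    jj = idx[:, 1, None, :, None] * grid.shape[2]
    kk = idx[:, 2, None, None, :]
    flat = (ii + jj + kk).reshape(len(pos), -1)
    inv_dx3 = 1.0 / dx**3
    parts = {
        0: dwdr[:, 0, :, None, None] * w[:, 1, None, :, None] * w[:, 2, None, None, :],
        1: w[:, 0, :, None, None] * dwdr[:, 1, None, :, None] * w[:, 2, None, None, :],
        2: w[:, 0, :, None, None] * w[:, 1, None, :, None] * dwdr[:, 2, None, None, :],
    }
    for c in range(3):
        # f_c(x) = -kBT sum_v (d_c delta)(x - X_v)
        vals = -kBT * parts[c].reshape(len(pos), -1) * inv_dx3
        np.add.at(out[c].ravel(), flat.ravel(), vals.ravel())
    return out


def structure_step(
    mesh: TriMesh,
    grid: FluidGrid,
    forces: np.ndarray,
    perm: PermeabilityParams,
    dt: float,
    rng: np.random.Generator | None = None,
    *,
    displacement_field: np.ndarray | None = None,
) -> TriMesh:
    """Advect the membrane: dX/dt = Gamma u + slip.

    ``forces`` must be the total vertex forces F_mem + F_ex [pN] at the
    current configuration.  ``displacement_field`` is the time-integrated
    fluid velocity w = int u dt [nm] from the matching fluid step; when
    omitted, grid.velocity * dt is used.

    When psi > 0 the slip velocity is psi * F_v / A_v per vertex (force
    per lumped vertex area = local pressure difference), plus a Gaussian
    slip noise of variance 2 kBT psi dt / A_v per component when kBT > 0.
    A_v is the *reference* lumped vertex area: a configuration-dependent
    mobility would demand a spurious-drift correction to keep detailed
    balance, while for a near-inextensible membrane the reference area
    is the physical one anyway.  psi = 0 recovers the no-slip immersed
    boundary exactly (no slip noise term).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if displacement_field is None:
        displacement_field = grid.velocity * dt
    dX = interpolate(grid, mesh, displacement_field)
    if perm.psi > 0:
        F = np.asarray(forces, float)
        Av = mesh.vertex_areas_ref()
        dX = dX + dt * perm.psi * F / Av[:, None]
        if perm.kBT > 0:
            if rng is None:
                raise ValueError("slip noise needs an rng")
            std = np.sqrt(2.0 * perm.kBT * perm.psi * dt / Av)
            dX = dX + std[:, None] * rng.standard_normal(dX.shape)
    out = mesh.copy()
    out.vertices = mesh.vertices + dX
    return out
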