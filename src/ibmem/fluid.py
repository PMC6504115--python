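"""Periodic incompressible fluctuating hydrodynamics on a Fourier grid.

The fluid obeys  rho du/dt = eta lap(u) - grad p + f_total,  div u = 0,
with thermal forcing balanced against the discrete viscous operator so
that every divergence-free Fourier mode carries kBT/2 of kinetic energy
at equilibrium (discrete fluctuation--dissipation balance).

Discretization is a collocated Fourier-spectral grid: projection and the
viscous term are diagonal per mode.  Time stepping treats each mode as
an exact Ornstein--Uhlenbeck update, and crucially samples the pair
(u(t+dt), w = int_t^{t+dt} u ds) *jointly* from the exact Gaussian
bridge statistics, so the structure advection X += Gamma(w) produces the
correct Stokes-level diffusion no matter how large dt is relative to
the fluid's own (very fast) relaxation time rho*dx^2/eta.

An overdamped (inertia-free) steady-Stokes mode is available for
deterministic runs; an Euler--Maruyama stepper is retained as a
cross-check of the exponential integrator.

Internal units: nm, us, pN (eta_water = 1e-3 pN us/nm^2,
rho_water = 1e-9 pN us^2/nm^4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ETA_WATER = 1.0e-3       # pN us / nm^2  (= 1e-3 Pa s)
RHO_WATER = 1.0e-9       # pN us^2 / nm^4 (= 1000 kg/m^3)
KBT_ROOM = 4.1           # pN nm

from functools import lru_cache


@lru_cache(maxsize=32)
def spectral_basis(shape: tuple[int, int, int], dx: float):
    """Wavevectors, |k|^2 and the retained-mode mask for a periodic grid.

    The Nyquist planes (index n/2 on even axes) are truncated: the
    projector I - k k^T/k^2 is not Hermitian-symmetric across them, so
    they cannot carry divergence-free dynamics consistently.  ``keep``
    is True on retained modes (k = 0 included; handled separately).
    """
    ks = [2 * np.pi * np.fft.fftfreq(n, d=dx) for n in shape]
    kx, ky, kz = np.meshgrid(*ks, indexing="ij")
    k = np.stack([kx, ky, kz])
    keep = np.ones(shape, dtype=bool)
    for ax, n in enumerate(shape):
        if n % 2 == 0:
            idx = [slice(None)] * 3
            idx[ax] = n // 2
            keep[tuple(idx)] = False
    k = k * keep
    k2 = np.sum(k * k, axis=0)
    k.setflags(write=False)
    k2.setflags(write=False)
    keep.setflags(write=False)
    return k, k2, keep


@dataclass
class FluidGrid:
    """Eulerian periodic velocity field.

    shape : (nx, ny, nz) cells; dx : spacing [nm]; velocity : (3, nx, ny, nz)
    [nm/us]; rho [pN us^2/nm^4]; eta [pN us/nm^2]; kBT [pN nm].
    """

    shape: tuple[int, int, int]
    dx: float
    eta: float = ETA_WATER
    rho: float = RHO_WATER
    kBT: float = KBT_ROOM
    velocity: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.velocity is None:
            self.velocity = np.zeros((3, *self.shape))
        if self.dx <= 0 or self.eta <= 0 or self.rho < 0 or self.kBT < 0:
            raise ValueError("invalid fluid parameters")

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    @property
    def volume(self) -> float:
        return self.n_cells * self.dx**3

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.shape) * self.dx

    def wavenumbers(self) -> tuple[np.ndarray, np.ndarray]:
        """(kvec components stacked (3, ...), k^2) for this grid."""
        k, k2, _ = spectral_basis(self.shape, self.dx)
        return k, k2

    def kinetic_energy(self) -> float:
        """(rho/2) int |u|^2 dV [pN nm]."""
        return float(0.5 * self.rho * np.sum(self.velocity**2) * self.dx**3)

    def max_divergence(self) -> float:
        k, _, _ = spectral_basis(self.shape, self.dx)
        uh = np.fft.fftn(self.velocity, axes=(1, 2, 3))
        div = np.sum(1j * k * uh, axis=0)
        return float(np.abs(np.fft.ifftn(div)).max())

    def n_modes(self) -> int:
        """Retained nonzero wavevector entries (each carrying 2 div-free
        complex components; 2 kBT expected energy per entry)."""
        _, _, keep = spectral_basis(self.shape, self.dx)
        return int(keep.sum()) - 1


@dataclass
class FluidStepReport:
    time: float
    max_divergence: float
    kinetic_energy: float


def _project_hat(uh: np.ndarray, k: np.ndarray, k2: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Leray projection in Fourier space: remove the gradient part and
    truncate the (non-projectable) Nyquist planes."""
    k2s = np.where(k2 == 0, 1.0, k2)
    kdot = np.sum(k * uh, axis=0)
    return (uh - k * (kdot / k2s)) * keep


def project_divergence_free(field: np.ndarray, dx: float) -> np.ndarray:
    """Orthogonal projection of a periodic vector field onto div-free fields.

    Idempotent; leaves divergence-free fields (including the uniform mode)
    untouched and annihilates pure gradients up to their mean.
    """
    field = np.asarray(field, float)
    k, k2, keep = spectral_basis(tuple(field.shape[1:]), dx)
    uh = np.fft.fftn(field, axes=(1, 2, 3))
    return np.real(np.fft.ifftn(_project_hat(uh, k, k2, keep), axes=(1, 2, 3)))


def _white_hat(rng: np.random.Generator, shape) -> np.ndarray:
    """FFT of a real white field, normalized to unit per-mode variance."""
    w = rng.standard_normal((3, *shape))
    return np.fft.fftn(w, axes=(1, 2, 3)) / np.sqrt(np.prod(shape))


def fluid_step(
    grid: FluidGrid,
    f_total: np.ndarray | None,
    dt: float,
    rng: np.random.Generator | None = None,
    *,
    thermal: bool = False,
    overdamped: bool = False,
    scheme: str = "exponential",
) -> tuple[FluidGrid, np.ndarray]:
    """Advance the fluid one step; return (new grid, w = int u dt) [nm].

    ``f_total`` is a deterministic force density (3, nx, ny, nz) [pN/nm^3]
    (already including spread membrane/external forces and the kernel
    drift term).  Thermal forcing is generated internally per mode when
    ``thermal`` is true.  The uniform (k = 0) mode is pinned to zero:
    tether anchors exert a net force on the fluid which would otherwise
    uniformly accelerate the periodic frame.

    In ``overdamped`` mode the velocity is the steady-Stokes response to
    f_total (no inertia, no noise) and w = u*dt.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    k, k2, keep = spectral_basis(grid.shape, grid.dx)
    N = grid.n_cells
    fh = None
    if f_total is not None:
        fh = np.fft.fftn(np.asarray(f_total, float), axes=(1, 2, 3))
        fh = _project_hat(fh, k, k2, keep)
        fh[:, k2 == 0] = 0.0

    if overdamped:
        k2s = np.where(k2 == 0, 1.0, k2)
        uh = (fh / (grid.eta * k2s)) if fh is not None else np.zeros((3, *grid.shape), complex)
        uh[:, k2 == 0] = 0.0
        u = np.real(np.fft.ifftn(uh, axes=(1, 2, 3)))
        out = FluidGrid(grid.shape, grid.dx, grid.eta, grid.rho, grid.kBT, velocity=u)
        return out, u * dt

    nu = grid.eta / grid.rho
    gam = nu * k2
    uh = np.fft.fftn(grid.velocity, axes=(1, 2, 3))
    uh = _project_hat(uh, k, k2, keep)
    uh[:, k2 == 0] = 0.0

    if scheme == "euler":
        uh_new = uh * (1.0 - gam * dt)
        wh = uh * dt
        if fh is not None:
            uh_new = uh_new + fh * (dt / grid.rho)
        if thermal and grid.kBT > 0:
            if rng is None:
                raise ValueError("thermal stepping needs an rng")
            sig2 = grid.kBT / (grid.rho * grid.volume)
            xi = _project_hat(_white_hat(rng, grid.shape), k, k2, keep)
            amp = np.sqrt(2.0 * gam * sig2 * dt) * N
            uh_new = uh_new + amp * xi
            uh_new[:, k2 == 0] = 0.0
    elif scheme == "exponential":
        a = np.exp(-gam * dt)
        gs = np.where(gam == 0, 1.0, gam)
        b = (1.0 - a) / gs          # int_0^dt e^{-gam s} ds
        uh_new = a * uh
        wh = b * uh                 # int u ds from the initial condition
        if fh is not None:
            # constant force over the step: u gains (f/rho) b ; w gains (f/rho)(dt-b)/gam
            uh_new = uh_new + fh * (b / grid.rho)
            wh = wh + fh * ((dt - b) / (gs * grid.rho))
        if thermal and grid.kBT > 0:
            if rng is None:
                raise ValueError("thermal stepping needs an rng")
            sig2 = grid.kBT / (grid.rho * grid.volume)  # per div-free complex component
            # joint Gaussian for (noise part of u', noise part of w):
            var_u = sig2 * (1.0 - a**2)
            cov_uw = sig2 * (1.0 - a) ** 2 / gs
            var_w = (2.0 * sig2 / gs) * (dt - 2.0 * b + (1.0 - a**2) / (2.0 * gs))
            var_u = np.maximum(var_u, 0.0)
            su = np.sqrt(var_u)
            sus = np.where(su == 0, 1.0, su)
            c12 = cov_uw / sus
            s22 = np.sqrt(np.maximum(var_w - c12**2, 0.0))
            xi1 = _project_hat(_white_hat(rng, grid.shape), k, k2, keep)
            xi2 = _project_hat(_white_hat(rng, grid.shape), k, k2, keep)
            uh_new = uh_new + su * N * xi1
            wh = wh + N * (c12 * xi1 + s22 * xi2)
            uh_new[:, k2 == 0] = 0.0
            wh[:, k2 == 0] = 0.0
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    u = np.real(np.fft.ifftn(uh_new, axes=(1, 2, 3)))
    w = np.real(np.fft.ifftn(wh, axes=(1, 2, 3)))
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("fluid velocity non-finite (instability?)")
    ke = 0.5 * grid.rho * np.sum(u**2) * grid.dx**3
    n_dof = 2 * (int(keep.sum()) - 1)
    if thermal and grid.kBT > 0 and ke > 50.0 * n_dof * grid.kBT:
        raise FloatingPointError("kinetic-energy blow-up detected")
    out = FluidGrid(grid.shape, grid.dx, grid.eta, grid.rho, grid.kBT, velocity=u)
    return out, w


def thermal_forcing(grid: FluidGrid, dt: float, rng: np.random.Generator) -> np.ndarray:
    """One realization of the discrete thermal force density [pN/nm^3].

    Zero-mean Gaussian, divergence-free, with covariance balanced against
    the discrete viscous operator: applying ``u += dt * g/rho`` together
    with the viscous Euler step reproduces equipartition for small dt.
    Provided for the Euler--Maruyama cross-check path; the exponential
    integrator draws its noise internally.
    """
    if grid.kBT == 0:
        return np.zeros((3, *grid.shape))
    k, k2, keep = spectral_basis(grid.shape, grid.dx)
    sig2 = grid.kBT / (grid.rho * grid.volume)
    gam = (grid.eta / grid.rho) * k2
    xi = _project_hat(_white_hat(rng, grid.shape), k, k2, keep)
    amp = grid.rho * np.sqrt(2.0 * gam * sig2 / dt) * grid.n_cells
    gh = amp * xi
    gh[:, k2 == 0] = 0.0
    return np.real(np.fft.ifftn(gh, axes=(1, 2, 3)))


def mode_energies(grid: FluidGrid) -> np.ndarray:
    """Kinetic energy rho*V*|u_hat_k|^2 of each retained k != 0 wavevector [pN nm].

    At thermal equilibrium each entry averages kBT (two real degrees of
    freedom per Hermitian mode pair and per div-free polarization), i.e.
    kBT/2 per mode in the real-degree-of-freedom count.
    """
    _, _, keep = spectral_basis(grid.shape, grid.dx)
    uh = np.fft.fftn(grid.velocity, axes=(1, 2, 3)) / grid.n_cells
    e = grid.rho * grid.volume * np.sum(np.abs(uh) ** 2, axis=0)
    m = keep.copy()
    m.flat[0] = False
    return e[m]
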