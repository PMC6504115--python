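"""Experiment assembly and execution.

A :class:`Scenario` holds the full physical parameterization of a run --
one membrane tethered to a "ghost" membrane of fixed anchors, or a
two-membrane interface tethered vertex-to-vertex outside the
adhesion-free radius -- plus the numerical configuration (grid, time
step, duration, seed).  :func:`run` time-steps fluid -> coupling ->
structure and records the receptor observable; :func:`scan` repeats a
scenario over one parameter axis.

Closed forms from the thin-film literature (rigid-sphere drainage,
critical permeability scale) live here too.

Physical fields use the conventional units of the problem (eta in Pa s,
sigma0 in pN/um, psi in nm/(s Pa), lengths in nm, times in s at the
interface; internally everything runs in nm/us/pN).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .coupling import PermeabilityParams, interpolate, spread, spread_drift_term, structure_step
from .fluid import FluidGrid, fluid_step
from .membrane import (
    MembraneParams,
    active_force,
    adhesion_energy,
    adhesion_forces,
    membrane_forces,
    total_energy,
)
from .mesh import TriMesh, build_disk_mesh
from .trace import Trace

US_PER_S = 1.0e6


@dataclass
class Scenario:
    """Full parameterization of a simulation.

    Physical parameters (defaults follow the reference parameter set,
    geometrically reduced so runs fit on a desktop; the shipped cluster
    configs restore the published scale):

    n_membranes : 1 (ghost-tethered control) or 2 (interface)
    r_cell [nm], r_free [nm], dz_inf [nm] (far-field separation),
    dz_star [nm] (proximity threshold), eta [Pa s], kappa_B [pN nm],
    sigma0 [pN/um], F_active [pN], a_force [nm], psi [nm/(s Pa)],
    kBT [pN nm]; thermal toggles the stochastic forcing.  k_rim [pN/nm]
    softly anchors the boundary loop to its initial position (the
    continuation of the cell surface beyond the simulated patch).
    inextensible_tethers immobilizes the tethered vertices outright --
    the idealization of the nonspecific adhesion molecules as rigid
    spacers -- leaving only the adhesion-free zone dynamical (used for
    the thermal-undulation studies, where soft tethers would add a
    spurious slow collective mode and throttle the stable step size).

    Numerical: mesh_edge [nm]; grid_shape, dx [nm] (derived from the
    geometry when left as None); dt [s] (auto from a stability heuristic
    when None); t_total [s]; sample_every (steps); overdamped selects the
    inertia-free Stokes solver (deterministic runs); seed.
    """

    n_membranes: int = 1
    r_cell: float = 160.0
    r_free: float = 48.0
    dz_inf: float = 24.0
    dz_star: float = 20.0
    eta: float = 1.0e-3
    kappa_B: float = 50.0
    sigma0: float = 100.0
    F_active: float = 0.0
    a_force: float = 10.0
    psi: float = 0.0
    kBT: float = 4.1
    thermal: bool = False
    k_adh: float = 1.0
    k_rim: float = 2.0
    inextensible_tethers: bool = False
    k_shear: float = 0.02
    mesh_edge: float | None = None
    grid_shape: tuple[int, int, int] | None = None
    dx: float | None = None
    dt: float | None = None
    t_total: float = 1.0e-4
    sample_every: int = 10
    overdamped: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_membranes not in (1, 2):
            raise ValueError("n_membranes must be 1 or 2")
        if not (self.dz_star < self.dz_inf):
            raise ValueError("need dz_star < dz_inf")
        if not (self.r_free < self.r_cell):
            raise ValueError("need r_free < r_cell")
        if self.psi < 0 or self.eta <= 0:
            raise ValueError("invalid eta/psi")

    # --- derived numerics -------------------------------------------------
    def resolved_dx(self) -> float:
        return self.dx if self.dx is not None else max(self.dz_inf / 3.0, 4.0)

    def resolved_mesh_edge(self) -> float:
        if self.mesh_edge is not None:
            return self.mesh_edge
        return max(self.r_cell / 14.0, 1.2 * self.resolved_dx())

    def resolved_grid_shape(self) -> tuple[int, int, int]:
        if self.grid_shape is not None:
            return tuple(self.grid_shape)
        dx = self.resolved_dx()
        nlat = _next_even(2.3 * self.r_cell / dx)
        nz = _next_even(max(0.5 * nlat, (4 * self.dz_inf + 8 * dx) / dx))
        return (nlat, nlat, nz)

    def membrane_params(self) -> MembraneParams:
        return MembraneParams(
            kappa_B=self.kappa_B,
            sigma0=self.sigma0 * 1.0e-3,  # pN/um -> pN/nm
            k_shear=self.k_shear,
            k_adh=self.k_adh,
            rest_len=self.dz_inf,
            F_active=self.F_active,
            a_force=self.a_force,
        )

    def resolved_dt(self) -> float:
        """Time step [s]; explicit-coupling stability heuristic when unset."""
        if self.dt is not None:
            return self.dt
        edge = self.resolved_mesh_edge()
        # stiffest per-vertex restoring-rate estimate: tethers + bending + tension
        k_springs = 0.0 if self.inextensible_tethers else self.k_adh + self.k_rim
        k_est = (k_springs + 30.0 * self.kappa_B / edge**2
                 + 2.0 * self.sigma0 * 1e-3 + self.k_shear)
        mobility = 1.0 / (3.0 * np.pi * (self.eta * 1.0) * self.resolved_dx())  # nm/(us pN)
        if self.psi > 0:
            # permeable slip adds mobility psi / (lumped vertex area)
            a_vertex = np.sqrt(3.0) / 2.0 * edge**2
            mobility += self.psi / a_vertex
        dt_us = 0.5 / (mobility * k_est)
        if self.thermal and self.kBT > 0:
            # keep the per-step thermal kick below ~a tenth of a mesh edge,
            # or the explicit membrane forces see disruptive distortions
            kick_cap = (0.1 * edge) ** 2 / (2.0 * self.kBT * mobility)
            dt_us = min(dt_us, kick_cap)
        return dt_us / US_PER_S


def _next_even(x: float) -> int:
    n = int(np.ceil(x))
    return n + (n % 2)


@dataclass
class SimState:
    meshes: list[TriMesh]
    grid: FluidGrid
    anchors: np.ndarray | None  # ghost anchors (single membrane) [nm]
    rim_positions: list[np.ndarray]  # clamped rim coordinates per mesh
    z_init: list[float]  # initial receptor heights [nm]
    time: float = 0.0  # [us]


def assemble(scenario: Scenario) -> SimState:
    """Build meshes, grid and tether anchors for a scenario.

    Single membrane: mesh at the grid mid-plane, tethered to fixed ghost
    anchors offset -dz_inf in z.  Interface: two meshes dz_inf apart,
    tethered vertex-to-vertex outside r_free; the active force loads the
    top membrane and points at the bottom one.  Rim (boundary-loop)
    vertices are additionally anchored to their initial positions by soft
    springs of stiffness k_rim: they stand for the continuation of the
    cell surface beyond the simulated patch (for the interface pair this
    is what holds the system in the lab frame).
    """
    dx = scenario.resolved_dx()
    shape = scenario.resolved_grid_shape()
    ext = np.asarray(shape) * dx
    if 2.0 * scenario.r_cell > ext[0]:
        raise ValueError(
            f"membrane (diameter {2*scenario.r_cell} nm) does not fit the grid ({ext[0]} nm)"
        )
    grid = FluidGrid(shape, dx, eta=scenario.eta * 1.0, kBT=scenario.kBT if scenario.thermal else 0.0)
    cx, cy = ext[0] / 2.0, ext[1] / 2.0
    zmid = ext[2] / 2.0
    edge = scenario.resolved_mesh_edge()

    def _mk(zc):
        return build_disk_mesh(
            scenario.r_cell, edge, r_free=scenario.r_free, a_force=scenario.a_force,
            center=(cx, cy, zc),
        )

    if scenario.n_membranes == 1:
        mesh = _mk(zmid)
        idx = np.flatnonzero(mesh.tethered)
        anchors = mesh.vertices[idx] - np.array([0.0, 0.0, scenario.dz_inf])
        meshes = [mesh]
    else:
        bottom = _mk(zmid - scenario.dz_inf / 2.0)
        top = _mk(zmid + scenario.dz_inf / 2.0)
        bottom.force_loaded[:] = False  # force acts on the top membrane only
        anchors = None
        meshes = [top, bottom]
    rims = [m.vertices[m.boundary].copy() for m in meshes]
    z0 = [float(m.vertices[m.receptor, 2]) for m in meshes]
    return SimState(meshes=meshes, grid=grid, anchors=anchors, rim_positions=rims, z_init=z0)


def _external_forces(state: SimState, params: MembraneParams, scenario: Scenario) -> list[np.ndarray]:
    """Adhesion + rim-anchor + active forces per mesh [pN]."""
    out = []
    if scenario.n_membranes == 1:
        mesh = state.meshes[0]
        F = adhesion_forces(mesh, state.anchors, params)
        if scenario.F_active > 0:
            F = F + active_force(mesh, params, np.array([0.0, 0.0, -1.0]))
        out.append(F)
    else:
        top, bottom = state.meshes
        idx_t = np.flatnonzero(top.tethered)
        idx_b = np.flatnonzero(bottom.tethered)
        # identical meshes: tether pairs share indices
        d = top.vertices[idx_t] - bottom.vertices[idx_b]
        dist = np.linalg.norm(d, axis=1)
        safe = np.where(dist > 0, dist, 1.0)
        spring = -params.k_adh * ((dist - params.rest_len) / safe)[:, None] * d
        Ft = np.zeros_like(top.vertices)
        Fb = np.zeros_like(bottom.vertices)
        Ft[idx_t] = spring
        Fb[idx_b] = -spring
        if scenario.F_active > 0:
            Ft = Ft + active_force(top, params, np.array([0.0, 0.0, -1.0]))
        out.extend([Ft, Fb])
    if scenario.k_rim > 0:
        for i, (mesh, F) in enumerate(zip(state.meshes, out)):
            F[mesh.boundary] -= scenario.k_rim * (
                mesh.vertices[mesh.boundary] - state.rim_positions[i]
            )
    return out


def receptor_displacement(state: SimState, mesh_index: int = 0) -> float:
    """Displacement of a membrane's receptor from its initial height,
    positive toward the target [nm]."""
    m = state.meshes[mesh_index]
    sign = -1.0 if mesh_index == 0 else 1.0  # top (or single) membrane pushes -z
    return sign * (m.vertices[m.receptor, 2] - state.z_init[mesh_index])


def receptor_separation(state: SimState) -> float:
    """Vertical distance between the two receptor vertices [nm]."""
    if len(state.meshes) != 2:
        raise ValueError("receptor_separation needs an interface state; "
                         "use receptor_displacement for a single membrane")
    top, bottom = state.meshes
    return float(top.vertices[top.receptor, 2] - bottom.vertices[bottom.receptor, 2])


def max_residual_force(state: SimState, scenario: Scenario) -> float:
    params = scenario.membrane_params()
    ext = _external_forces(state, params, scenario)
    worst = 0.0
    for mesh, Fx in zip(state.meshes, ext):
        F = membrane_forces(mesh, params) + Fx
        F = F[~mesh.boundary]
        worst = max(worst, float(np.abs(F).max()))
    return worst


@dataclass
class RunResult:
    trace: Trace                    # receptor observable (z0 or separation)
    membrane_traces: list[Trace]    # per-membrane receptor heights [nm]
    state: SimState
    reports: dict


def run(state: SimState, scenario: Scenario, rng: np.random.Generator | None = None,
        *, stop_below: float | None = None) -> RunResult:
    """Time-step the assembled scenario and record receptor observables.

    Deterministic (thermal=False) runs are bit-reproducible for a fixed
    configuration; thermal runs are reproducible for a fixed seed.
    ``stop_below`` ends the run early once the sampled observable drops
    to or below the given value (e.g. a proximity threshold).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    params = scenario.membrane_params()
    perm = PermeabilityParams(psi=scenario.psi,
                              kBT=scenario.kBT if scenario.thermal else 0.0)
    dt_us = scenario.resolved_dt() * US_PER_S
    n_steps = max(1, int(round(scenario.t_total * US_PER_S / dt_us)))
    sample = max(1, int(scenario.sample_every))
    grid = state.grid
    thermal = bool(scenario.thermal)

    times = [0.0]
    obs = [_observable(state, scenario)]
    per_mem = [[float(m.vertices[m.receptor, 2]) for m in state.meshes]]
    for step in range(1, n_steps + 1):
        forces = []
        all_pos = []
        all_F = []
        ext = _external_forces(state, params, scenario)
        for mesh, Fx in zip(state.meshes, ext):
            F = membrane_forces(mesh, params) + Fx
            forces.append(F)
            if scenario.inextensible_tethers:
                # pinned vertices are phantom for the fluid: a static vertex
                # whose elastic force were spread would stir the fluid with
                # energy from nowhere
                mobile = ~mesh.tethered
                all_pos.append(mesh.vertices[mobile])
                all_F.append(F[mobile])
            else:
                all_pos.append(mesh.vertices)
                all_F.append(F)
        pos_cat = np.concatenate(all_pos)
        F_cat = np.concatenate(all_F)
        f_grid = spread(pos_cat, F_cat, grid)
        if thermal and grid.kBT > 0:
            f_grid += spread_drift_term(pos_cat, grid, grid.kBT)
        grid, w = fluid_step(
            grid, f_grid, dt_us, rng,
            thermal=thermal, overdamped=scenario.overdamped,
        )
        new_meshes = []
        for mesh, F in zip(state.meshes, forces):
            m2 = structure_step(mesh, grid, F, perm, dt_us, rng, displacement_field=w)
            if scenario.inextensible_tethers:
                pinned = mesh.tethered
                m2.vertices[pinned] = mesh.vertices[pinned]
            new_meshes.append(m2)
        state = SimState(new_meshes, grid, state.anchors, state.rim_positions,
                         state.z_init, state.time + dt_us)
        if step % sample == 0:
            times.append(state.time / US_PER_S)
            obs.append(_observable(state, scenario))
            per_mem.append([float(m.vertices[m.receptor, 2]) for m in state.meshes])
            if stop_below is not None and obs[-1] <= stop_below:
                break

    meta = {"scenario": scenario_to_dict(scenario), "seed": scenario.seed,
            "observable": "separation" if scenario.n_membranes == 2 else "displacement"}
    per_mem_arr = np.asarray(per_mem)
    tarr = np.asarray(times)
    mem_traces = [Trace(tarr, per_mem_arr[:, i], {"membrane": i}) for i in range(len(state.meshes))]
    return RunResult(
        trace=Trace(tarr, np.asarray(obs), meta),
        membrane_traces=mem_traces,
        state=state,
        reports={"n_steps": n_steps, "dt_s": dt_us / US_PER_S,
                 "max_divergence": state.grid.max_divergence()},
    )


def _observable(state: SimState, scenario: Scenario) -> float:
    if scenario.n_membranes == 2:
        return receptor_separation(state)
    return receptor_displacement(state, 0)


# ---------------------------------------------------------------------------
# static equilibria (no fluid: the equilibrium of a constant force is a
# property of the energies alone)
# ---------------------------------------------------------------------------

def equilibrium_state(scenario: Scenario, state: SimState | None = None) -> SimState:
    """Minimize total energy over free vertices (rim clamped).

    Uses L-BFGS with the exact analytic gradient over all vertices.  The
    active force enters through its potential -F.z per loaded vertex.
    """
    from scipy.optimize import minimize

    if state is None:
        state = assemble(scenario)
    params = scenario.membrane_params()
    meshes = [m.copy() for m in state.meshes]
    if scenario.inextensible_tethers:
        free = [~m.tethered for m in meshes]
    else:
        free = [np.ones(m.n_vertices, dtype=bool) for m in meshes]
    sizes = [int(f.sum()) for f in free]

    def pack():
        return np.concatenate([m.vertices[f].ravel() for m, f in zip(meshes, free)])

    def unpack(x):
        o = 0
        for m, f, n in zip(meshes, free, sizes):
            m.vertices[f] = x[o:o + 3 * n].reshape(n, 3)
            o += 3 * n

    def fg(x):
        unpack(x)
        st = SimState(meshes, state.grid, state.anchors, state.rim_positions, state.z_init)
        e = 0.0
        ext = _external_forces(st, params, scenario)
        grads = []
        for i, (m, Fx) in enumerate(zip(meshes, ext)):
            e += total_energy(m, params)
            g = -membrane_forces(m, params)
            # external forces: adhesion springs + constant active force
            g -= Fx
            grads.append(g[free[i]].ravel())
        # rim-anchor energy
        for i, m in enumerate(meshes):
            d2 = np.sum((m.vertices[m.boundary] - state.rim_positions[i]) ** 2)
            e += 0.5 * scenario.k_rim * d2
        # adhesion energy (for the objective value; its gradient is in Fx)
        if scenario.n_membranes == 1:
            e += adhesion_energy(meshes[0], state.anchors, params)
            idx = np.flatnonzero(meshes[0].force_loaded)
            if scenario.F_active > 0:
                e += (scenario.F_active / len(idx)) * np.sum(meshes[0].vertices[idx, 2])
        else:
            top, bottom = meshes
            idx_t = np.flatnonzero(top.tethered)
            d = np.linalg.norm(top.vertices[idx_t] - bottom.vertices[idx_t], axis=1)
            e += 0.5 * params.k_adh * np.sum((d - params.rest_len) ** 2)
            idx = np.flatnonzero(top.force_loaded)
            if scenario.F_active > 0:
                e += (scenario.F_active / len(idx)) * np.sum(top.vertices[idx, 2])
        return e, np.concatenate(grads)

    x0 = pack()
    res = minimize(fg, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9})
    unpack(res.x)
    return SimState(meshes, state.grid, state.anchors, state.rim_positions,
                    state.z_init, state.time)


def equilibrium_displacement(scenario: Scenario) -> float:
    """Receptor displacement [nm] of the driven membrane at static equilibrium."""
    st = equilibrium_state(scenario)
    return receptor_displacement(st, 0)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def rigid_sphere_drainage(z0: float, F: float, r_cell: float, eta: float, t) -> np.ndarray:
    """Gap between rigid impermeable spheres squeezed by force F.

    dz/dt = -(z / r_cell) F / (6 pi eta r_cell) integrates to
    z(t) = z0 exp(-F t / (6 pi eta r_cell^2)).

    z0, r_cell in nm; F in pN; eta in Pa s; t in s.  Returns nm.
    """
    if z0 <= 0 or r_cell <= 0 or eta <= 0:
        raise ValueError("z0, r_cell, eta must be positive")
    eta_i = eta * 1.0  # Pa s -> pN us / nm^2
    tau_us = 6.0 * np.pi * eta_i * r_cell**2 / F if F != 0 else np.inf
    t_us = np.asarray(t, float) * US_PER_S
    if F == 0:
        return z0 * np.ones_like(t_us)
    return z0 * np.exp(-t_us / tau_us)


def drainage_time_constant(F: float, r_cell: float, eta: float) -> float:
    """e-folding time 6 pi eta r_cell^2 / F [s]."""
    return 6.0 * np.pi * (eta * 1.0) * r_cell**2 / F / US_PER_S


def critical_permeability(dz_inf: float, eta: float, r_free: float) -> float:
    """Permeability scale above which permeation beats parallel drainage:
    (dz_inf)^3 / (eta r_free^2) [nm/(s Pa)] (dz_inf, r_free nm; eta Pa s)."""
    if dz_inf <= 0 or eta <= 0 or r_free <= 0:
        raise ValueError("inputs must be positive")
    return dz_inf**3 / (eta * r_free**2)


# ---------------------------------------------------------------------------
# scans and qualitative response analysis
# ---------------------------------------------------------------------------

def scan(template: Scenario, parameter: str, values, mode: str = "static"):
    """One run per value of a Scenario field; returns a pandas DataFrame.

    mode='static'  : summary = equilibrium receptor displacement (no fluid;
                     appropriate for constant-force equilibria).
    mode='dynamic' : time-steps the scenario; summary = final observable and,
    when the trace crosses dz_star (interface) the time-to-proximity.
    Failed runs are reported in the 'error' column; the scan continues.
    """
    import pandas as pd

    if not hasattr(template, parameter):
        raise ValueError(f"{parameter!r} is not a Scenario field")
    rows = []
    for v in values:
        row = {parameter: v, "seed": template.seed, "error": ""}
        try:
            sc = replace(template, **{parameter: v})
            if mode == "static":
                row["equilibrium_displacement"] = equilibrium_displacement(sc)
            else:
                stop = sc.dz_star if sc.n_membranes == 2 else None
                res = run(assemble(sc), sc, stop_below=stop)
                row["final_observable"] = float(res.trace.values[-1])
                if sc.n_membranes == 2:
                    below = res.trace.values <= sc.dz_star
                    row["time_to_proximity"] = (
                        float(res.trace.times[np.argmax(below)]) if below.any() else np.nan
                    )
        except Exception as exc:  # noqa: BLE001 - scan must continue
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TwoTimescaleReport:
    """Fast push / passive depression / slow recovery decomposition."""

    t_fast: float            # driven membrane reaches half its early plateau [s]
    depression: float        # passive-membrane max depression, positive [nm]
    t_depression: float      # time of that extremum [s]
    t_recover: float         # passive membrane halfway back to final level [s]
    has_depression: bool


def two_timescale_response(
    top: Trace, bottom: Trace | None, *, depression_tol: float = 0.05
) -> TwoTimescaleReport:
    """Detect the interface's two-timescale force response.

    The driven membrane moves on a fast timescale; incompressibility
    pushes the passive membrane away transiently; the trapped fluid then
    drains on the slow thin-layer timescale and the passive membrane
    recovers.  ``depression_tol`` is the detection threshold as a
    fraction of the driven membrane's displacement.
    """
    t = top.times
    if len(t) < 8:
        raise ValueError("insufficient sampling for timescale analysis")
    disp = top.values[0] - top.values  # driven membrane moves -z
    early = max(4, len(t) // 4)
    plateau = np.median(disp[early - 2 : early + 3])
    t_fast = float(t[np.argmax(disp >= 0.5 * plateau)]) if plateau > 0 else 0.0
    if bottom is None:
        return TwoTimescaleReport(t_fast, 0.0, 0.0, 0.0, False)
    dep = bottom.values[0] - bottom.values  # positive = pushed away (-z)
    i_min = int(np.argmax(dep))
    depth = float(dep[i_min])
    scale = max(abs(plateau), 1e-12)
    has = depth > depression_tol * scale
    t_dep = float(t[i_min])
    t_rec = t[-1]
    if has:
        target = 0.5 * (dep[i_min] + dep[-1])
        after = dep[i_min:]
        j = np.argmax(after <= target)
        t_rec = float(t[i_min + j]) if after.min() <= target else float(t[-1])
    return TwoTimescaleReport(t_fast, depth, t_dep, float(t_rec), bool(has))


def scenario_to_dict(s: Scenario) -> dict:
    from dataclasses import asdict

    d = asdict(s)
    if d.get("grid_shape") is not None:
        d["grid_shape"] = list(d["grid_shape"])
    return d
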