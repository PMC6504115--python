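"""Scenario engine: assembly, closed forms, scans, and the scaled-down
qualitative reproductions of the interface phenomenology."""

import numpy as np
import pytest

from conftest import REDUCED, reduced_scenario
from ibmem.ou import autocorrelation, fit_double_exp, fit_single_exp
from ibmem.scenario import (
    Scenario,
    assemble,
    critical_permeability,
    drainage_time_constant,
    equilibrium_displacement,
    max_residual_force,
    receptor_separation,
    rigid_sphere_drainage,
    run,
    scan,
    two_timescale_response,
)


class TestAssembly:
    def test_interface_initial_separation(self):
        sc = reduced_scenario(n_membranes=2)
        st = assemble(sc)
        assert receptor_separation(st) == pytest.approx(REDUCED["dz_inf"])

    def test_single_membrane_equilibrium_start(self):
        sc = reduced_scenario(n_membranes=1, F_active=0.0)
        st = assemble(sc)
        assert max_residual_force(st, sc) < 1e-9

    def test_no_tethers_inside_r_free(self):
        sc = reduced_scenario(n_membranes=1)
        st = assemble(sc)
        m = st.meshes[0]
        center = m.vertices[m.receptor, :2]
        r = np.linalg.norm(m.vertices[:, :2] - center, axis=1)
        assert not np.any(m.tethered & (r < REDUCED["r_free"]))

    def test_separation_requires_interface(self):
        sc = reduced_scenario(n_membranes=1)
        with pytest.raises(ValueError, match="interface"):
            receptor_separation(assemble(sc))

    def test_geometry_must_fit_grid(self):
        sc = reduced_scenario(r_cell=120.0, r_free=20.0, grid_shape=(16, 16, 8))
        with pytest.raises(ValueError, match="fit"):
            assemble(sc)

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            Scenario(dz_star=30.0, dz_inf=20.0)
        with pytest.raises(ValueError):
            Scenario(r_free=300.0, r_cell=200.0)


class TestClosedForms:
    def test_drainage_no_force_is_constant(self):
        z = rigid_sphere_drainage(60.0, 0.0, 1000.0, 1e-3, np.array([0.0, 1.0]))
        assert np.allclose(z, 60.0)

    def test_drainage_time_constant_10pN_1um(self):
        # 6 pi eta r^2 / F at F = 10 pN, r = 1 um, water
        tau = drainage_time_constant(10.0, 1000.0, 1e-3)
        assert tau == pytest.approx(1.88e-3, rel=0.01)

    def test_drainage_halving_time(self):
        tau = drainage_time_constant(10.0, 1000.0, 1e-3)
        z = rigid_sphere_drainage(60.0, 10.0, 1000.0, 1e-3, tau * np.log(2.0))
        assert z == pytest.approx(30.0, rel=1e-9)

    def test_critical_permeability_reference_values(self):
        psi = critical_permeability(60.0, 1e-3, 150.0)
        assert psi == pytest.approx(216000.0 / 22.5, rel=1e-12)  # 9.6e3 ~ 1e4
        assert critical_permeability(120.0, 1e-3, 150.0) == pytest.approx(8 * psi)
        assert critical_permeability(60.0, 1e-3, 300.0) == pytest.approx(psi / 4)


class TestStaticEquilibria:
    def test_displacement_decreases_with_tension(self):
        base = reduced_scenario(n_membranes=1, F_active=3.0, thermal=False)
        df = scan(base, "sigma0", [25.0, 100.0, 400.0], mode="static")
        d = df["equilibrium_displacement"].to_numpy()
        assert np.all(np.diff(d) < 0)

    def test_displacement_decreases_with_adhesion_density(self):
        # adhesion density rho = 1/r_free^2: smaller r_free = denser tethers
        base = reduced_scenario(n_membranes=1, F_active=3.0, thermal=False)
        df = scan(base, "r_free", [50.0, 85.0, 120.0], mode="static")
        d = df["equilibrium_displacement"].to_numpy()
        assert np.all(np.diff(d) > 0)  # displacement grows with r_free

    def test_scan_reports_failures_and_continues(self):
        base = reduced_scenario(n_membranes=1, F_active=3.0)
        df = scan(base, "r_free", [85.0, 5000.0], mode="static")
        assert df.loc[0, "error"] == ""
        assert df.loc[1, "error"] != ""


class TestDeterministicDynamics:
    def test_equilibrium_start_stays_flat(self):
        sc = reduced_scenario(n_membranes=1, F_active=0.0, thermal=False,
                              overdamped=True, t_total=2e-6, sample_every=5)
        res = run(assemble(sc), sc)
        assert np.abs(res.trace.values).max() < 1e-6

    def test_viscosity_rescaling_overlays_trajectories(self):
        """Doubling eta with doubled dt gives the same trajectory: all
        times scale linearly with viscosity."""
        kw = dict(n_membranes=1, F_active=3.0, thermal=False, overdamped=True,
                  sample_every=10)
        sc1 = reduced_scenario(**kw)
        dt = sc1.resolved_dt()
        sc1 = reduced_scenario(dt=dt, t_total=100 * dt, **kw)
        sc2 = reduced_scenario(eta=2e-3, dt=2 * dt, t_total=200 * dt, **kw)
        r1 = run(assemble(sc1), sc1)
        r2 = run(assemble(sc2), sc2)
        assert np.allclose(r1.trace.values, r2.trace.values, rtol=1e-10, atol=1e-10)
        assert np.allclose(2 * r1.trace.times, r2.trace.times)

    def test_steady_state_matches_static_minimization(self):
        """The dynamic steady displacement equals the energy minimum to
        <1% -- a constant-force equilibrium has no fluid contribution.
        Uses a stiff small patch so the relaxation completes quickly."""
        kw = dict(n_membranes=1, r_cell=80.0, r_free=24.0, dz_inf=24.0,
                  dz_star=10.0, kappa_B=50.0, sigma0=100.0, F_active=2.0,
                  a_force=10.0, k_adh=1.0, dx=8.0, grid_shape=(24, 24, 12),
                  mesh_edge=12.0, thermal=False)
        static = equilibrium_displacement(Scenario(**kw))
        scd = Scenario(overdamped=True, t_total=2.5e-5, sample_every=100, **kw)
        dyn = run(assemble(scd), scd).trace.values[-1]
        assert dyn == pytest.approx(static, rel=0.01)

    def test_deterministic_rerun_is_bit_identical(self):
        sc = reduced_scenario(n_membranes=1, F_active=3.0, thermal=False,
                              overdamped=True, t_total=1.5e-6, sample_every=2)
        a = run(assemble(sc), sc)
        b = run(assemble(sc), sc)
        assert np.array_equal(a.trace.values, b.trace.values)


class TestInterfacePhenomenology:
    def test_entropic_blister(self, thermal_interface, athermal_interface):
        """Thermal interface separation blisters above dz_inf; the
        athermal interface does not."""
        v = thermal_interface.trace.values
        warm = v[len(v) // 4:].mean()
        cold = athermal_interface.trace.values[-1]
        assert warm > REDUCED["dz_inf"] + 0.5
        assert cold < REDUCED["dz_inf"] + 0.15

    def test_interface_needs_two_timescales_single_does_not(
        self, thermal_single, thermal_interface
    ):
        """Scaled-down reproduction of the confinement signature: the
        interface autocorrelation is far better described by two
        exponentials, the single-membrane one is not."""
        def improvement(res):
            # drop the warm-up quarter: the trace starts from the flat
            # athermal state and takes a while to reach stationarity
            tr = res.trace
            i0 = len(tr) // 4
            from ibmem.trace import Trace
            v = tr.values[i0:]
            t = Trace(tr.times[i0:] - tr.times[i0], v - v.mean())
            ml = min(len(t) - 2, int(len(t) * 0.25))
            lags, alpha = autocorrelation(t, ml)
            fs = fit_single_exp(lags, alpha)
            fd = fit_double_exp(lags, alpha)
            if fd.fallback_single or fd.c2 > 0.97:
                return 1.0, fd
            return fs.sse / max(fd.sse, 1e-300), fd
        gain_iface, fit_iface = improvement(thermal_interface)
        gain_single, _ = improvement(thermal_single)
        assert gain_iface > 3.0
        assert gain_iface > gain_single
        assert not fit_iface.fallback_single
        assert fit_iface.tau_slow / fit_iface.tau_fast > 3.0

    def test_two_timescale_force_response(self, forced_interface_strong, forced_single):
        """Active force at an interface: fast push of the driven membrane,
        transient depression of the passive one, slow recovery once the
        squeeze saturates.  A single membrane shows no depression phase."""
        top, bottom = forced_interface_strong.membrane_traces
        rep = two_timescale_response(top, bottom)
        assert rep.has_depression
        assert rep.depression > 0.2
        assert rep.t_fast < rep.t_depression <= rep.t_recover
        single = two_timescale_response(forced_single.membrane_traces[0], None)
        assert not single.has_depression

    def test_interface_approach_slower_than_single(self, forced_interface, forced_single):
        """The thin layer retards the closing of the gap: the interface
        separation changes far more slowly than a ghost-tethered single
        membrane displaces under the same force."""
        t_mid = 1.0e-5
        d_single = np.interp(t_mid, forced_single.trace.times,
                             forced_single.trace.values)
        sep = forced_interface.trace
        d_iface = sep.values[0] - np.interp(t_mid, sep.times, sep.values)
        assert d_iface < 0.5 * d_single

    def test_permeability_collapses_interface_dynamics(
        self, forced_interface, forced_interface_permeable, forced_single
    ):
        """At the critical permeability scale the interface separation
        time series collapses onto the single-membrane response: fluid
        crosses the membranes instead of draining sideways."""
        t_star = 1.0e-5

        def sep_displacement(res):
            tr = res.trace
            return np.interp(t_star, tr.times, tr.values[0] - tr.values)
        d_imperm = sep_displacement(forced_interface)
        d_perm = sep_displacement(forced_interface_permeable)
        d_single = np.interp(t_star, forced_single.trace.times,
                             forced_single.trace.values)
        assert d_perm > d_imperm
        assert abs(d_perm - d_single) < 0.3 * abs(d_imperm - d_single)

    def test_time_to_proximity_plateaus_with_far_field_separation(self, dz_scan):
        """Time until the gap closes to the threshold is non-monotone or
        plateaued in dz_inf: beyond a critical separation the weakened
        thin-layer drag compensates the longer travel distance."""
        values, df = dz_scan
        assert (df["error"] == "").all()
        tt = df["time_to_proximity"].to_numpy()
        assert np.all(np.isfinite(tt))
        # marginal time per nm of extra travel falls sharply with dz_inf:
        # beyond the critical separation the weakened thin-layer drag more
        # than compensates the longer approach
        travel = np.asarray(values) - 20.0
        marginal = np.diff(tt) / np.diff(travel)
        assert np.all(np.diff(marginal) < 0)
        assert marginal[-1] < 0.5 * marginal[0]
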