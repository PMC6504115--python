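"""Configuration files, trace I/O, run manifests and test fixtures.

Config files are YAML mirroring the Scenario fields (conventional units:
lengths nm, eta Pa s, sigma0 pN/um, psi nm/(s Pa), times s); an empty
file yields the reference defaults.  Traces round-trip through CSV
(headered, two columns) or HDF5 (lossless, with metadata).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from pathlib import Path

import numpy as np
import yaml

from .scenario import Scenario, scenario_to_dict
from .trace import Trace


def load_config(path) -> Scenario:
    """Read a YAML scenario config; unknown keys are rejected with paths."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(data).__name__}")
    return scenario_from_dict(data, origin=str(path))


def scenario_from_dict(data: dict, origin: str = "<dict>") -> Scenario:
    fields = {f.name for f in dataclasses.fields(Scenario)}
    unknown = sorted(set(data) - fields)
    if unknown:
        raise ValueError(f"{origin}: unknown config keys: {', '.join(unknown)}")
    if "grid_shape" in data and data["grid_shape"] is not None:
        data = dict(data)
        data["grid_shape"] = tuple(int(x) for x in data["grid_shape"])
    try:
        return Scenario(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{origin}: {exc}") from exc


def save_config(path, scenario: Scenario) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(scenario), sort_keys=False))


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def write_trace(path, trace: Trace) -> None:
    """CSV (.csv) or HDF5 (any other suffix); NaN-containing traces refused."""
    path = Path(path)
    if not np.all(np.isfinite(trace.values)):
        raise ValueError("refusing to write a trace with non-finite values")
    if path.suffix == ".csv":
        import pandas as pd

        df = pd.DataFrame({"time_s": trace.times, "value_nm": trace.values})
        df.to_csv(path, index=False, float_format="%.12g")
    else:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=trace.times)
            f.create_dataset("values", data=trace.values)
            f.attrs["units"] = "s, nm"
            f.attrs["metadata"] = json.dumps(trace.metadata, default=str)


def read_trace(path) -> Trace:
    path = Path(path)
    if path.suffix == ".csv":
        import pandas as pd

        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise ValueError(f"{path}: malformed CSV trace: {exc}") from exc
        cols = list(df.columns)
        if len(cols) < 2:
            raise ValueError(f"{path}: expected two columns (time, value), got {cols}")
        return Trace(df[cols[0]].to_numpy(float), df[cols[1]].to_numpy(float))
    import h5py

    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs.get("metadata", "{}"))
        return Trace(f["times"][:], f["values"][:], meta)


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def write_manifest(path, scenario: Scenario, outputs: dict[str, str]) -> dict:
    """Record everything needed to re-run bit-identically: resolved config,
    package version, seed, timestamps and output checksums."""
    from . import __version__

    checks = {}
    for name, p in outputs.items():
        p = Path(p)
        checks[name] = {
            "path": str(p),
            "sha256": hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None,
        }
    manifest = {
        "config": scenario_to_dict(scenario),
        "resolved": {
            "dx": scenario.resolved_dx(),
            "grid_shape": list(scenario.resolved_grid_shape()),
            "mesh_edge": scenario.resolved_mesh_edge(),
            "dt_s": scenario.resolved_dt(),
        },
        "version": __version__,
        "seed": scenario.seed,
        "written_at": _time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": checks,
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, params: dict | None, seed: int, out_dir) -> list[Path]:
    """Deterministic seeded fixtures used across the test suite.

    kinds: ou1, ou2 (synthetic traces), taylor_green (divergence-free
    velocity field), piston (flat pressure-loaded membrane scenario),
    sphere_mesh (closed icosphere).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = dict(params or {})
    if kind == "ou1":
        from .ou import OUParams1, simulate_ou1

        p = OUParams1(tau=params.pop("tau", 1.05e-6), sigma=params.pop("sigma", 3.12))
        dt = params.pop("dt", p.tau / 10.0)
        n = int(params.pop("n_steps", 50000))
        tr = simulate_ou1(p, dt, n, seed)
        path = out / "ou1_trace.h5"
        write_trace(path, tr)
        return [path]
    if kind == "ou2":
        from .ou import OUParams2, simulate_ou2

        p = OUParams2(
            tau_slow=params.pop("tau_slow", 8.2e-5),
            tau_fast=params.pop("tau_fast", 5.3e-7),
            sigma=params.pop("sigma", 4.6),
            c=params.pop("c", float(np.sqrt(0.48))),
        )
        dt = params.pop("dt", p.tau_fast / 2.0)
        n = int(params.pop("n_steps", 200000))
        tr = simulate_ou2(p, dt, n, seed)
        path = out / "ou2_trace.h5"
        write_trace(path, tr)
        return [path]
    if kind == "taylor_green":
        from .fluid import FluidGrid

        n = int(params.pop("n", 16))
        dx = float(params.pop("dx", 10.0))
        L = n * dx
        k = 2 * np.pi / L
        x = np.arange(n) * dx
        X, Y, _Z = np.meshgrid(x, x, x, indexing="ij")
        u = np.zeros((3, n, n, n))
        u[0] = np.sin(k * X) * np.cos(k * Y)
        u[1] = -np.cos(k * X) * np.sin(k * Y)
        import h5py

        path = out / "taylor_green.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("velocity", data=u)
            f.attrs["dx"] = dx
        return [path]
    if kind == "piston":
        from .scenario import Scenario
        sc = Scenario(n_membranes=1, psi=float(params.pop("psi", 1.0e3)),
                      thermal=False, overdamped=True)
        path = out / "piston_scenario.yaml"
        save_config(path, sc)
        return [path]
    if kind == "sphere_mesh":
        from .mesh import sphere_mesh, write_vtk

        m = sphere_mesh(float(params.pop("radius", 100.0)), int(params.pop("subdivisions", 2)))
        path = out / "sphere.vtk"
        write_vtk(path, m)
        return [path]
    raise ValueError(f"unknown fixture kind {kind!r}")
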