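"""HDF5/CSV serialization of experiment bundles.

Every run writes a single HDF5 bundle with a fixed schema version: the
echoed inputs (parameters, numerics, initial-condition spec, seed), the
outputs of the owning module, and provenance (code version, wall time).
Deterministic solvers reproduce bundles bit-for-bit from a config;
stochastic ones seed-for-seed.  CSV export is provided for small tables
(curves, dispersion tables, kymograph slices).
"""

from __future__ import annotations

import time
from pathlib import Path

import h5py
import numpy as np

from . import __version__
from .params import ModelParams
from .pde import Trajectory

SCHEMA_VERSION = 1


def _write_params(g, params: ModelParams) -> None:
    for k, v in params.to_dict().items():
        if v is not None:
            g.attrs[k] = v


def _read_params(g) -> ModelParams:
    d = {k: g.attrs[k] for k in ("Pe", "L", "phi_a", "phi_p", "h", "aspect")
         if k in g.attrs}
    return ModelParams.from_dict({k: (float(v) if k != "h" else float(v))
                                  for k, v in d.items()})


def write_trajectory(path: str | Path, traj: Trajectory, *,
                     meta: dict | None = None) -> None:
    """Write a PDE (or mesoscopic lattice) trajectory bundle."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "trajectory"
        f.attrs["code_version"] = __version__
        f.attrs["written_at"] = time.time()
        f.create_dataset("x", data=traj.x)
        f.create_dataset("t", data=traj.times)
        f.create_dataset("frames", data=traj.frames, compression="gzip",
                         compression_opts=4)
        if traj.params is not None:
            _write_params(f.create_group("params"), traj.params)
        if meta:
            g = f.create_group("meta")
            for k, v in meta.items():
                g.attrs[k] = v


def read_trajectory(path: str | Path) -> Trajectory:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "trajectory":
            raise ValueError(f"{path} is not a trajectory bundle")
        params = _read_params(f["params"]) if "params" in f else None
        return Trajectory(
            x=f["x"][:], times=f["t"][:], frames=f["frames"][:], params=params
        )


def write_curve_csv(path: str | Path, columns: dict) -> None:
    """Write named columns (equal-length 1D arrays) as CSV."""
    keys = list(columns)
    arrs = [np.asarray(columns[k]) for k in keys]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("columns must have equal length")
    with open(path, "w") as fh:
        fh.write(",".join(keys) + "\n")
        for i in range(n):
            fh.write(",".join(repr(float(a[i])) for a in arrs) + "\n")


def read_curve_csv(path: str | Path) -> dict:
    with open(path) as fh:
        keys = fh.readline().strip().split(",")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    return {k: data[:, i] for i, k in enumerate(keys)}


def export_kymograph(traj: Trajectory, species: str) -> np.ndarray:
    """t x grid matrix for one species.

    ``species`` is one of '+', '-', '0', 'a' (active), 'rho' (total).
    """
    table = {"+": 0, "-": 1, "0": 2}
    if species in table:
        return traj.frames[:, table[species], :]
    if species == "a":
        return traj.frames[:, 0, :] + traj.frames[:, 1, :]
    if species == "rho":
        return traj.frames.sum(axis=1)
    raise ValueError(f"unknown species {species!r}")


def write_wave_solution(path: str | Path, sol) -> None:
    """Serialize a TravelingSolution (profiles, speed, interface records)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "wave"
        f.attrs["code_version"] = __version__
        f.attrs["c"] = sol.c
        f.attrs["regime"] = sol.regime
        f.attrs["residual_norm"] = sol.residual_norm
        f.create_dataset("z", data=sol.z)
        for k, v in sol.profiles.items():
            f.create_dataset(f"profile_{k}", data=v)
        if sol.params is not None:
            _write_params(f.create_group("params"), sol.params)
        for i, rec in enumerate(sol.interfaces):
            g = f.create_group(f"interface_{i}")
            for k, v in rec.items():
                g.attrs[k] = v


def read_wave_solution(path: str | Path):
    from .waves import TravelingSolution

    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "wave":
            raise ValueError(f"{path} is not a wave bundle")
        profiles = {
            k.split("_", 1)[1]: f[k][:] for k in f if k.startswith("profile_")
        }
        interfaces = []
        i = 0
        while f"interface_{i}" in f:
            interfaces.append(dict(f[f"interface_{i}"].attrs))
            i += 1
        return TravelingSolution(
            z=f["z"][:],
            profiles=profiles,
            c=float(f.attrs["c"]),
            residual_norm=float(f.attrs["residual_norm"]),
            regime=str(f.attrs["regime"]),
            params=_read_params(f["params"]) if "params" in f else None,
            interfaces=interfaces,
        )
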