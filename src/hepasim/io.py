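"""Snapshot and time-series writers plus the run manifest.

Cell snapshots go to CSV (one row per agent) and legacy-ASCII VTK
poly-data points; substrate fields go to legacy-ASCII VTK structured
points and/or HDF5.  The VTK legacy format is a simple line-oriented text
format, written directly here.  A JSON manifest records the configuration
hash, seed, package/library versions and wall time of a run so outputs
are traceable.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "cells_frame",
    "write_cells_csv",
    "write_series_csv",
    "write_vtk_points",
    "write_vtk_structured",
    "write_fields_h5",
    "write_manifest",
]


def cells_frame(pop) -> pd.DataFrame:
    """Per-cell snapshot table: id, type, position, radius, volumes, phase."""
    return pd.DataFrame(
        {
            "id": pop.id,
            "type": pop.cell_type,
            "x": pop.position[:, 0],
            "y": pop.position[:, 1],
            "z": pop.position[:, 2],
            "radius": pop.radius,
            "V": pop.V,
            "V_N": pop.V_N,
            "phase": [pop.table.names[p] for p in pop.phase],
            "generation": pop.generation,
        }
    )


def write_cells_csv(pop, path) -> None:
    cells_frame(pop).to_csv(path, index=False)


def write_series_csv(series: pd.DataFrame, path) -> None:
    series.to_csv(path, index=False)


def write_vtk_points(pop, path, title: str = "cells") -> None:
    """Legacy-ASCII VTK poly-data: cell centres with radius/type/phase scalars."""
    n = len(pop)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        for p in pop.position:
            fh.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
        fh.write(f"POINT_DATA {n}\n")
        for name, values, kind in (
            ("radius", pop.radius, "float"),
            ("cell_type", pop.cell_type, "int"),
            ("phase", pop.phase, "int"),
        ):
            fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
            fmt = "{:.4f}\n" if kind == "float" else "{:d}\n"
            for v in values:
                fh.write(fmt.format(v if kind == "int" else float(v)))


def write_vtk_structured(env, substrate: str, path) -> None:
    """Legacy-ASCII VTK structured points of one substrate field."""
    mesh = env.mesh
    j = env.substrate_index(substrate)
    field = env.conc[j]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{substrate}\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {mesh.nx} {mesh.ny} {mesh.nz}\n")
        o = mesh.voxel_center((0, 0, 0))
        fh.write(f"ORIGIN {o[0]:.4f} {o[1]:.4f} {o[2]:.4f}\n")
        fh.write(f"SPACING {mesh.dx} {mesh.dx} {mesh.dx}\n")
        fh.write(f"POINT_DATA {mesh.n_voxels}\n")
        fh.write(f"SCALARS {substrate} float 1\nLOOKUP_TABLE default\n")
        # VTK structured points run x fastest
        for v in field.transpose(2, 1, 0).ravel():
            fh.write(f"{v:.6g}\n")


def write_fields_h5(env, path) -> None:
    """All substrate fields to HDF5 with axis order and origin in metadata."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["axis_order"] = "xyz"
        fh.attrs["origin_um"] = np.asarray(env.mesh.origin, dtype=float)
        fh.attrs["dx_um"] = env.mesh.dx
        for i, s in enumerate(env.substrates):
            fh.create_dataset(s.name, data=env.conc[i])


def config_hash(config) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(path, config, seed: int, wall_time_s: float,
                   status: str = "ok", extra: dict | None = None) -> None:
    import hepasim

    manifest = {
        "config_sha256_16": config_hash(config),
        "seed": seed,
        "status": status,
        "wall_time_s": round(wall_time_s, 2),
        "versions": {
            "hepasim": hepasim.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2))
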