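"""Result writers: CSV tables, JSON diagnostics, OBJ mesh export.

CSV files use a comma separator, '.' decimal, a header row and no index
column; floats are written with 17 significant digits so reruns are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .field import GaussReport, PotentialMap, PotentialProfile
from .geometry import BoundaryMesh
from .solvers import REDUCED_TO_VOLTS, InducedSolution

__all__ = [
    "write_mesh_csv",
    "write_mesh_obj",
    "write_solution_csv",
    "write_diagnostics_json",
    "write_profile_csv",
    "write_map_csv",
    "write_table_csv",
]

_FLOAT_FMT = "%.17g"


def write_table_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_mesh_csv(mesh: BoundaryMesh, path: str | Path) -> Path:
    df = pd.DataFrame(
        {
            "cx": mesh.centers[:, 0],
            "cy": mesh.centers[:, 1],
            "cz": mesh.centers[:, 2],
            "nx": mesh.normals[:, 0],
            "ny": mesh.normals[:, 1],
            "nz": mesh.normals[:, 2],
            "area": mesh.areas,
            "delta_eps": mesh.delta_eps,
            "mean_eps": mesh.mean_eps,
        }
    )
    return write_table_csv(df, path)


def write_mesh_obj(mesh: BoundaryMesh, path: str | Path) -> Path:
    """Wavefront OBJ export of the tile patch corners (quads), for viewing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["# tile quads"]
    faces = []
    v = 0
    for i in range(len(mesh)):
        u0, u1, v0, v1 = mesh.patches[i]
        corners = [(u0, v0), (u1, v0), (u1, v1), (u0, v1)]
        for (u, vv) in corners:
            p = mesh.surface.point(np.array(u), np.array(vv))
            lines.append(f"v {p[0]:.8g} {p[1]:.8g} {p[2]:.8g}")
        faces.append(f"f {v + 1} {v + 2} {v + 3} {v + 4}")
        v += 4
    path.write_text("\n".join(lines + faces) + "\n")
    return path


def write_solution_csv(
    solution: InducedSolution, mesh: BoundaryMesh, path: str | Path
) -> Path:
    df = pd.DataFrame(
        {
            "tile": np.arange(len(mesh)),
            "h_e_per_A2": solution.h,
            "area_A2": mesh.areas,
            "induced_charge_e": solution.h * mesh.areas,
        }
    )
    return write_table_csv(df, path)


def write_diagnostics_json(
    solution: InducedSolution,
    gauss: GaussReport,
    path: str | Path,
    *,
    extra: dict | None = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "method": solution.method,
        "N": int(len(solution.h)),
        "iterations": int(solution.iterations),
        "final_update": float(solution.final_update),
        "residual_inf": float(solution.residual_inf),
        "condition_estimate": float(solution.condition_estimate),
        "total_induced_charge_e": float(solution.total_induced_charge),
        "gauss_expected_e": float(gauss.expected_e),
        "gauss_error_e": float(gauss.error_e),
        "gauss_error_percent_of_e": float(gauss.error_percent_of_e),
    }
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")
    return path


def write_profile_csv(profile: PotentialProfile, path: str | Path) -> Path:
    df = pd.DataFrame(
        {
            "x": profile.points[:, 0],
            "y": profile.points[:, 1],
            "z": profile.points[:, 2],
            "potential_reduced": profile.total,
            "potential_V": profile.total * REDUCED_TO_VOLTS,
            "source_part": profile.source_part,
            "induced_part": profile.induced_part,
        }
    )
    return write_table_csv(df, path)


def write_map_csv(pmap: PotentialMap, path: str | Path) -> Path:
    """Dense matrix CSV of a potential map plus a JSON grid-metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, pmap.values, delimiter=",", fmt=_FLOAT_FMT)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "plane_z_angstrom": pmap.plane_z,
                "x_angstrom": pmap.x.tolist(),
                "y_angstrom": pmap.y.tolist(),
                "units": "reduced (e/A); multiply by "
                f"{REDUCED_TO_VOLTS} for volts",
                "masked_value": "nan",
            },
            indent=2,
        )
        + "\n"
    )
    return path
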