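"""Config files (YAML) and result export (legacy-VTK rectilinear, CSV).

The VTK writer emits the legacy ASCII ``RECTILINEAR_GRID`` dialect with
cell data, viewable in ParaView; values are written with 17 significant
digits so a read-back reproduces the float64 arrays bit for bit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import (DomainModel, ElectrodeConfiguration, GeometryParams,
                       build_domain, place_electrodes)


# ---------------------------------------------------------------------------
# YAML configuration files


def config_to_dict(params: GeometryParams,
                   config: ElectrodeConfiguration | None = None,
                   grid: dict | None = None) -> dict:
    out: dict = {"geometry": {
        "lumen_diameter_mm": 1e3 * params.lumen_diameter,
        "wall_thickness_mm": 1e3 * params.wall_thickness,
        "vessel_length_mm": 1e3 * params.vessel_length,
        "muscle_width_mm": 1e3 * params.muscle_width,
        "muscle_height_mm": 1e3 * params.muscle_height,
        "top_extension_mm": 1e3 * params.top_extension,
    }}
    if config is not None:
        out["configuration"] = {
            "scheme": config.scheme,
            "n_electrodes": config.n_electrodes,
            "inter_electrode_distance_mm":
                1e3 * config.inter_electrode_distance,
            "pulse_potential_V": config.pulse_potential,
        }
    if grid:
        out["grid"] = dict(grid)
    return out


def dict_to_config(data: dict
                   ) -> tuple[GeometryParams, ElectrodeConfiguration | None,
                              dict]:
    g = data.get("geometry", {})
    params = GeometryParams(
        lumen_diameter=g.get("lumen_diameter_mm", 12.0) * 1e-3,
        wall_thickness=g.get("wall_thickness_mm", 1.5) * 1e-3,
        vessel_length=g.get("vessel_length_mm", 250.0) * 1e-3,
        muscle_width=g.get("muscle_width_mm", 700.0) * 1e-3,
        muscle_height=g.get("muscle_height_mm", 200.0) * 1e-3,
        top_extension=g.get("top_extension_mm", 0.0) * 1e-3,
    )
    config = None
    if "configuration" in data:
        c = data["configuration"]
        config = ElectrodeConfiguration(
            scheme=c["scheme"], n_electrodes=c["n_electrodes"],
            inter_electrode_distance=c.get("inter_electrode_distance_mm",
                                           0.0) * 1e-3,
            pulse_potential=c.get("pulse_potential_V", 40.0))
    grid = dict(data.get("grid", {}))
    return params, config, grid


def save_config(path, params: GeometryParams,
                config: ElectrodeConfiguration | None = None,
                grid: dict | None = None) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(params, config, grid),
                                         sort_keys=False))


def load_config(path) -> tuple[GeometryParams, ElectrodeConfiguration | None,
                               dict]:
    return dict_to_config(yaml.safe_load(Path(path).read_text()))


def domain_from_config(path) -> DomainModel:
    params, config, grid = load_config(path)
    kwargs = {}
    if "spacing_mm" in grid:
        kwargs["spacing"] = grid["spacing_mm"] * 1e-3
    if "axial_spacing_mm" in grid:
        kwargs["axial_spacing"] = grid["axial_spacing_mm"] * 1e-3
    domain = build_domain(params, **kwargs)
    if config is not None:
        domain = place_electrodes(domain, config)
    return domain


# ---------------------------------------------------------------------------
# VTK rectilinear-grid export (legacy ASCII)


def _fmt(values) -> str:
    return " ".join(np.format_float_scientific(v, precision=17, trim="-")
                    for v in np.asarray(values, dtype=float).ravel())


def write_vtk_rectilinear(path, domain: DomainModel,
                          cell_arrays: dict[str, np.ndarray]) -> None:
    """Write cell-centered scalar arrays on the domain grid."""
    nxp, nyp = domain.x.faces.size, domain.y.faces.size
    lines = [
        "# vtk DataFile Version 3.0",
        "endostim field export",
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {nxp} {nyp} 1",
        f"X_COORDINATES {nxp} double",
        _fmt(domain.x.faces),
        f"Y_COORDINATES {nyp} double",
        _fmt(domain.y.faces),
        "Z_COORDINATES 1 double",
        "0",
        f"CELL_DATA {domain.n_cells}",
    ]
    for name, arr in cell_arrays.items():
        if arr.shape != domain.shape:
            raise ValueError(f"array {name!r} does not match the grid")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.append(_fmt(arr))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_rectilinear(path) -> tuple[np.ndarray, np.ndarray,
                                        dict[str, np.ndarray]]:
    """Read back a file written by :func:`write_vtk_rectilinear`.

    Returns (x_faces, y_faces, {name: (ny, nx) array}).
    """
    tokens = Path(path).read_text().split("\n")
    idx = {line.split()[0]: i for i, line in enumerate(tokens)
           if line and line[0].isalpha()}

    def parse(i):
        return np.array(tokens[i].split(), dtype=float)

    x = parse(idx["X_COORDINATES"] + 1)
    y = parse(idx["Y_COORDINATES"] + 1)
    shape = (y.size - 1, x.size - 1)
    arrays: dict[str, np.ndarray] = {}
    for i, line in enumerate(tokens):
        if line.startswith("SCALARS"):
            arrays[line.split()[1]] = parse(i + 2).reshape(shape)
    return x, y, arrays


def metrics_to_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)
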