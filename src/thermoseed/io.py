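"""File I/O: run configs (YAML), field export (legacy VTK, CSV), provenance.

Solved fields are written as legacy ASCII VTK rectilinear grids (cell data:
temperature and region label), readable by ParaView/VisIt, and as flat CSV
tables (x, y, z, T).  Every run can emit a provenance record (config hash,
material-registry version, package version, rng seed) sufficient to reproduce
deterministic outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import LabeledGrid
from .solver import TemperatureField

__all__ = [
    "ConfigError",
    "load_run_config",
    "write_vtk_rectilinear",
    "field_to_dataframe",
    "write_field_csv",
    "provenance_record",
]


class ConfigError(ValueError):
    """Invalid or unknown keys in a run configuration."""


_KNOWN_KEYS = {
    "scenario",
    "resolution_m",
    "d_mm",
    "slp",
    "solver",
    "convection",
    "material_registry",
    "output_dir",
    "rng_seed",
}
_KNOWN_SOLVER_KEYS = {"tol", "damping", "max_iterations", "semi_implicit_source"}
_KNOWN_SLP_KEYS = {"a", "b", "c", "d", "samples_csv"}
_KNOWN_CONV_KEYS = {"coefficient_W_m2C", "ambient_C"}


def load_run_config(path) -> dict:
    """Load and validate a YAML run config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    for key in raw:
        if key not in _KNOWN_KEYS:
            raise ConfigError(f"unknown config key: {key!r}")
    for sub, allowed in (
        ("solver", _KNOWN_SOLVER_KEYS),
        ("slp", _KNOWN_SLP_KEYS),
        ("convection", _KNOWN_CONV_KEYS),
    ):
        for key in raw.get(sub) or {}:
            if key not in allowed:
                raise ConfigError(f"unknown config key: {sub}.{key!r}")
    if "scenario" not in raw:
        raise ConfigError("missing config key: 'scenario'")
    raw.setdefault("rng_seed", 0)
    return raw


def write_vtk_rectilinear(path, grid: LabeledGrid, cell_data: dict) -> None:
    """Write a legacy ASCII VTK rectilinear grid with per-cell scalar arrays.

    Axisymmetric (r, z) grids are written as a one-cell-thick slab with r on
    the X axis and z on the Y axis.
    """
    axes = list(grid.axes)
    if len(axes) == 2:
        axes = [axes[0], axes[1], np.array([0.0, 1e-4])]
    nx, ny, nz = (len(a) for a in axes)
    n_cells = (nx - 1) * (ny - 1) * (nz - 1)

    def fmt(arr):
        return "\n".join(" ".join(f"{v:.9g}" for v in row) for row in
                         np.array_split(np.asarray(arr, float).ravel(),
                                        max(1, len(arr) // 8 + 1)))

    lines = [
        "# vtk DataFile Version 3.0",
        "thermoseed field export",
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"X_COORDINATES {nx} double",
        " ".join(f"{v:.9g}" for v in axes[0]),
        f"Y_COORDINATES {ny} double",
        " ".join(f"{v:.9g}" for v in axes[1]),
        f"Z_COORDINATES {nz} double",
        " ".join(f"{v:.9g}" for v in axes[2]),
        f"CELL_DATA {n_cells}",
    ]
    for name, values in cell_data.items():
        arr = np.asarray(values)
        # VTK cell ordering is x-fastest; our arrays are C-ordered (x slowest)
        flat = arr.reshape(grid.shape).transpose().ravel()
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.append(fmt(flat))
    Path(path).write_text("\n".join(lines) + "\n")


def field_to_dataframe(field: TemperatureField, grid: LabeledGrid | None = None
                       ) -> pd.DataFrame:
    """Flatten a field to (x, y, z, T_C, region) rows (axisym: r, z)."""
    grid = grid or field.grid
    centers = grid.centers()
    mesh = np.meshgrid(*centers, indexing="ij")
    cols = {}
    names = ("x_m", "y_m", "z_m") if len(centers) == 3 else ("r_m", "z_m")
    for name, m in zip(names, mesh):
        cols[name] = m.ravel()
    cols["T_C"] = field.values.ravel()
    cols["region"] = grid.cell_region.ravel()
    return pd.DataFrame(cols)


def write_field_csv(path, field: TemperatureField,
                    grid: LabeledGrid | None = None) -> None:
    field_to_dataframe(field, grid).to_csv(path, index=False)


def provenance_record(config: dict, registry_version: str, rng_seed: int) -> dict:
    """Machine-readable reproducibility record for one run."""
    from . import __version__

    text = json.dumps(config, sort_keys=True, default=str)
    return {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(text.encode()).hexdigest(),
        "material_registry_version": registry_version,
        "rng_seed": int(rng_seed),
    }
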