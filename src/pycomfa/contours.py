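"""STDEV*COEFF contour fields and OpenDX export.

The interpretable output of a CoMFA model is, per grid point and field, the
product of the PLS coefficient and the column's standard deviation: regions
where this product is large and positive favour activity (bulk for the
steric field, positive probe energy for the electrostatic field), large
negative regions disfavour it.  Contour levels default to the 80th
percentile of the positive values (favoured) and the 20th percentile of the
negative values (disfavoured).  Fields are exported as OpenDX scalar grids,
readable by the common molecular viewers for overlay on the receptor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fields import FieldMatrix, GridRegion
from .pls import PLSModel

__all__ = [
    "stdev_coeff_field",
    "contour_thresholds",
    "export_dx",
    "read_dx",
    "export_contour_set",
]


def stdev_coeff_field(model: PLSModel, matrix: FieldMatrix) -> dict[str, np.ndarray]:
    """Per-grid-point STDEV*COEFF values for each field.

    Returns a flat array of length grid.n_points per field; grid points
    whose column was dropped by the minimum-sigma filter are zero.
    """
    out: dict[str, np.ndarray] = {}
    values = model.coefficients * model.column_sd
    for name in np.unique(matrix.column_field):
        m = matrix.column_field == name
        flat = np.zeros(matrix.grid.n_points)
        flat[matrix.column_point[m]] = values[m]
        out[str(name)] = flat
    return out


def contour_thresholds(values: np.ndarray, favored_pct: float = 80.0,
                       disfavored_pct: float = 20.0) -> dict[str, float | None]:
    """Isolevels bracketing the strongest favourable/unfavourable voxels.

    ``favored`` is the favored_pct percentile of the positive values,
    ``disfavored`` the disfavored_pct percentile of the negative values;
    either is None when that sign is absent.
    """
    values = np.asarray(values, dtype=float)
    pos = values[values > 0]
    neg = values[values < 0]
    return {
        "favored": float(np.percentile(pos, favored_pct)) if pos.size else None,
        "disfavored": float(np.percentile(neg, disfavored_pct)) if neg.size else None,
    }


def export_dx(values: np.ndarray, grid: GridRegion, path) -> None:
    """Write a flat scalar field as an OpenDX grid (z fastest, as produced
    by :meth:`GridRegion.points`)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size != grid.n_points:
        raise ValueError(
            f"value count {values.size} does not match grid {grid.dims}")
    nx, ny, nz = grid.dims
    ox, oy, oz = grid.origin
    s = grid.spacing
    lines = [
        "# STDEV*COEFF field exported by pycomfa",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {s:.6f} 0.000000 0.000000",
        f"delta 0.000000 {s:.6f} 0.000000",
        f"delta 0.000000 0.000000 {s:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {values.size} data follows",
    ]
    for k in range(0, values.size, 3):
        lines.append(" ".join(f"{v:.10g}" for v in values[k:k + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    Path(path).write_text("\n".join(lines) + "\n")


def read_dx(path) -> tuple[np.ndarray, GridRegion]:
    """Read back an OpenDX scalar grid written by :func:`export_dx`."""
    dims = origin = None
    deltas = []
    data: list[float] = []
    n_items = None
    in_data = False
    for line in Path(path).read_text().splitlines():
        t = line.strip()
        if not t or t.startswith("#"):
            continue
        if in_data and n_items is not None and len(data) < n_items:
            data.extend(float(v) for v in t.split())
            continue
        if t.startswith("object 1"):
            dims = tuple(int(v) for v in t.split()[-3:])
        elif t.startswith("origin"):
            origin = tuple(float(v) for v in t.split()[1:4])
        elif t.startswith("delta"):
            deltas.append([float(v) for v in t.split()[1:4]])
        elif "data follows" in t:
            n_items = int(t.split("items")[1].split()[0])
            in_data = True
    if dims is None or origin is None or len(deltas) != 3:
        raise ValueError(f"{path}: not a recognisable OpenDX grid")
    spacing = deltas[0][0]
    grid = GridRegion(origin, spacing, dims)
    values = np.array(data[:n_items])
    if values.size != grid.n_points:
        raise ValueError(f"{path}: {values.size} values for grid {dims}")
    return values, grid


def export_contour_set(model: PLSModel, matrix: FieldMatrix, out_dir,
                       favored_pct: float = 80.0, disfavored_pct: float = 20.0,
                       receptor_pdb: str | None = None) -> dict:
    """Export one DX file per field plus a manifest with the isolevels."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fields = stdev_coeff_field(model, matrix)
    manifest = {"receptor_pdb": receptor_pdb, "fields": []}
    for name, vals in sorted(fields.items()):
        fn = out_dir / f"{name}_stdev_coeff.dx"
        export_dx(vals, matrix.grid, fn)
        manifest["fields"].append({
            "field": name,
            "file": fn.name,
            "levels": contour_thresholds(vals, favored_pct, disfavored_pct),
        })
    (out_dir / "contours_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
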