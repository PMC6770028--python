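"""CoMFA molecular interaction fields.

Every aligned compound is evaluated on a common rectangular lattice with an
sp3-carbon probe of charge +1 e.  The steric field is a 6-12 Lennard-Jones
energy with Tripos-style parameters,

    E_vdw = sum_i eps_i * [ (R_i/r_i)^12 − 2 (R_i/r_i)^6 ],   R_i = R_atom + R_probe,

capped at +30 kcal/mol; the electrostatic field is a Coulomb sum with the
distance-dependent dielectric eps(r) = r,

    E_ele = 332.0636 * q_probe * sum_i q_i / r_i^2   [kcal/mol],

clamped to ±30 kcal/mol.  Electrostatic values at lattice points buried
inside a molecule are replaced by that column's mean over the remaining
compounds, the convention CoMFA uses to keep meaningless in-core Coulomb
values out of the regression.  Columns that barely vary across compounds
(sd below the minimum-sigma threshold, default 2.0 kcal/mol) are dropped,
and each field block is scaled to equal total variance (CoMFA standard
scaling) so neither field dominates the PLS just by its energy units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .alignment import AlignedDataset
from .structures import LigandPose

__all__ = [
    "GridRegion",
    "ProbeSpec",
    "FieldMatrix",
    "TRIPOS_LJ_PARAMS",
    "build_grid",
    "steric_energy",
    "electrostatic_energy",
    "compute_field_matrix",
    "filter_and_scale",
]

#: Coulomb constant, kcal·Å·mol⁻¹·e⁻².
COULOMB_CONSTANT = 332.0636
PAPER_DEFAULT_SPACING = 2.0
PAPER_DEFAULT_MARGIN = 4.0
PAPER_DEFAULT_STERIC_CAP = 30.0
PAPER_DEFAULT_ELE_CLAMP = 30.0
PAPER_DEFAULT_MIN_SIGMA = 2.0

# Tripos-5.2-style Lennard-Jones parameters by coarse atom class:
# (R* van der Waals radius in Å, epsilon well depth in kcal/mol).
TRIPOS_LJ_PARAMS: dict[str, tuple[float, float]] = {
    "sp3-C": (1.70, 0.107),
    "sp2-C": (1.70, 0.107),
    "aromatic-C": (1.70, 0.107),
    "N-cationic": (1.55, 0.095),
    "N-neutral": (1.55, 0.095),
    "O": (1.52, 0.116),
    "S": (1.80, 0.314),
    "halogen": (1.75, 0.314),
    "H": (1.50, 0.042),
    "other": (1.70, 0.107),
}


@dataclass(frozen=True)
class ProbeSpec:
    """The CoMFA probe: an sp3 carbon bearing +1 e."""

    charge: float = 1.0
    lj_radius: float = TRIPOS_LJ_PARAMS["sp3-C"][0]
    lj_epsilon: float = TRIPOS_LJ_PARAMS["sp3-C"][1]


@dataclass(frozen=True)
class GridRegion:
    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must be positive")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice points, shape (n_points, 3), x slowest / z fastest."""
        ax = [np.asarray(self.origin)[k] + self.spacing * np.arange(self.dims[k])
              for k in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass(frozen=True)
class FieldMatrix:
    """Compounds × field-columns energy matrix with column metadata.

    Columns are ordered: all steric grid points first, then all
    electrostatic points (same point order).  ``column_point`` gives each
    column's flat grid-point index and ``column_field`` its field name.
    """

    values: np.ndarray                # (n_compounds, n_columns), kcal/mol
    compound_ids: tuple[str, ...]
    grid: GridRegion
    column_point: np.ndarray          # (n_columns,) int
    column_field: np.ndarray          # (n_columns,) "steric"/"electrostatic"
    block_scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.compound_ids), len(self.column_point)):
            raise ValueError("field matrix shape mismatch")

    @property
    def column_sd(self) -> np.ndarray:
        return self.values.std(axis=0, ddof=1) if len(self.compound_ids) > 1 \
            else np.zeros(self.values.shape[1])

    def block(self, name: str) -> np.ndarray:
        return self.values[:, self.column_field == name]


def build_grid(dataset: AlignedDataset | Sequence[LigandPose],
               spacing: float = PAPER_DEFAULT_SPACING,
               margin: float = PAPER_DEFAULT_MARGIN) -> GridRegion:
    """Axis-aligned lattice enclosing all poses plus a margin.

    Edges snap outward to whole multiples of the spacing, so translating
    the molecules by a lattice vector translates the grid identically.
    """
    poses = dataset.poses if isinstance(dataset, AlignedDataset) else tuple(dataset)
    if not poses:
        raise ValueError("cannot build a grid for an empty dataset")
    xyz = np.vstack([p.coords for p in poses])
    lo = np.floor((xyz.min(axis=0) - margin) / spacing) * spacing
    hi = np.ceil((xyz.max(axis=0) + margin) / spacing) * spacing
    dims = tuple(int(round((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    return GridRegion(tuple(lo), spacing, dims)


def _atom_arrays(pose: LigandPose):
    coords = pose.coords
    lj = np.array([TRIPOS_LJ_PARAMS[a.atom_class] for a in pose.atoms])
    q = np.array([a.partial_charge for a in pose.atoms])
    return coords, lj[:, 0], lj[:, 1], q


def _steric_at_points(points: np.ndarray, pose: LigandPose, probe: ProbeSpec,
                      cap: float = PAPER_DEFAULT_STERIC_CAP) -> np.ndarray:
    coords, radii, eps, _ = _atom_arrays(pose)
    rij = radii + probe.lj_radius
    epsij = np.sqrt(eps * probe.lj_epsilon)
    d = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=-1)
    # a probe exactly on an atom must hit the cap, not divide by zero
    d = np.maximum(d, 1e-6)
    with np.errstate(over="ignore"):
        x = (rij[None, :] / d) ** 6
        e = (epsij[None, :] * (x * x - 2.0 * x)).sum(axis=1)
    e[~np.isfinite(e)] = cap
    return np.minimum(e, cap)


def _electrostatic_at_points(points: np.ndarray, pose: LigandPose, probe: ProbeSpec,
                             clamp: float = PAPER_DEFAULT_ELE_CLAMP) -> np.ndarray:
    coords, _, _, q = _atom_arrays(pose)
    d2 = ((points[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        # q/r^2 implements the 1/r distance-dependent dielectric; a probe
        # sitting exactly on an atom gives ±inf, which the clamp absorbs
        e = COULOMB_CONSTANT * probe.charge * np.nansum(q[None, :] / d2, axis=1)
    return np.clip(e, -clamp, clamp)


def _inside_mask(points: np.ndarray, pose: LigandPose) -> np.ndarray:
    """Points lying within any atom's LJ radius (the steric envelope)."""
    coords = pose.coords
    radii = np.array([TRIPOS_LJ_PARAMS[a.atom_class][0] for a in pose.atoms])
    d = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=-1)
    return (d <= radii[None, :]).any(axis=1)


def steric_energy(pose: LigandPose, point, probe: ProbeSpec = ProbeSpec(),
                  cap: float = PAPER_DEFAULT_STERIC_CAP) -> float:
    """Lennard-Jones probe energy at one point (kcal/mol, capped)."""
    return float(_steric_at_points(np.atleast_2d(np.asarray(point, float)),
                                   pose, probe, cap)[0])


def electrostatic_energy(pose: LigandPose, point, probe: ProbeSpec = ProbeSpec(),
                         clamp: float = PAPER_DEFAULT_ELE_CLAMP) -> float:
    """Coulomb probe energy with eps(r) = r at one point (kcal/mol, clamped)."""
    return float(_electrostatic_at_points(np.atleast_2d(np.asarray(point, float)),
                                          pose, probe, clamp)[0])


def compute_field_matrix(dataset: AlignedDataset, grid: GridRegion,
                         probe: ProbeSpec = ProbeSpec(),
                         require_charges: bool = True) -> FieldMatrix:
    """Evaluate both fields for every compound at every lattice point."""
    points = grid.points()
    n, p = len(dataset), grid.n_points
    steric = np.empty((n, p))
    ele = np.empty((n, p))
    inside = np.zeros((n, p), dtype=bool)
    for k, pose in enumerate(dataset.poses):
        if require_charges and all(a.partial_charge == 0.0 for a in pose.atoms) \
                and pose.net_formal_charge != 0:
            raise ValueError(
                f"{pose.compound_id}: no partial charges assigned; "
                "run the charges stage first")
        steric[k] = _steric_at_points(points, pose, probe)
        ele[k] = _electrostatic_at_points(points, pose, probe)
        inside[k] = _inside_mask(points, pose)
    # CoMFA convention: in-core electrostatic values take the column mean of
    # the compounds that actually see the probe at that point.
    for j in range(p):
        m = inside[:, j]
        if m.any():
            ele[m, j] = ele[~m, j].mean() if (~m).any() else 0.0
    values = np.hstack([steric, ele])
    column_point = np.concatenate([np.arange(p), np.arange(p)])
    column_field = np.array(["steric"] * p + ["electrostatic"] * p)
    return FieldMatrix(values, dataset.compound_ids, grid, column_point, column_field)


def filter_and_scale(matrix: FieldMatrix,
                     min_sigma: float = PAPER_DEFAULT_MIN_SIGMA,
                     scaling: str = "CoMFA-STD") -> FieldMatrix:
    """Drop low-variance columns and apply CoMFA standard block scaling.

    After column centering, each retained field block is rescaled so the two
    blocks carry equal total variance (each block's centered sum of squares
    becomes 1).  Values stay uncentered; only the scale is applied, so the
    PLS stage's own centering reproduces the scaled centered matrix.
    """
    sd = matrix.column_sd
    keep = sd >= min_sigma
    if not keep.any():
        raise ValueError("minimum-sigma filter removed every column")
    vals = matrix.values[:, keep].copy()
    cfield = matrix.column_field[keep]
    cpoint = matrix.column_point[keep]
    scales: dict[str, float] = {}
    if scaling == "CoMFA-STD":
        for name in ("steric", "electrostatic"):
            m = cfield == name
            if not m.any():
                continue
            centered = vals[:, m] - vals[:, m].mean(axis=0)
            total_var = (centered ** 2).sum() / max(len(matrix.compound_ids) - 1, 1)
            s = 1.0 / np.sqrt(total_var) if total_var > 0 else 1.0
            vals[:, m] *= s
            scales[name] = s
    elif scaling != "none":
        raise ValueError(f"unknown scaling {scaling!r}")
    return FieldMatrix(vals, matrix.compound_ids, matrix.grid, cpoint, cfield, scales)
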