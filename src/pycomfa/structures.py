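"""Molecular data model and structure IO.

Ligand poses arrive pre-docked in a shared receptor coordinate frame; this
module reads and writes them (SDF V2000, MOL2) and locates the receptor
anchor carboxylate (the conserved aspartate of aminergic GPCRs) in a PDB
file. Coordinates are Å in the receptor frame and are never re-centered:
the alignment is the docking output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "LigandPose",
    "AnchorSite",
    "read_poses",
    "write_poses_sdf",
    "locate_anchor",
]

AtomClass = Literal[
    "sp3-C", "sp2-C", "aromatic-C", "N-cationic", "N-neutral",
    "O", "S", "halogen", "H", "other",
]

_HALOGENS = {"F", "Cl", "Br", "I"}


@dataclass(frozen=True)
class Atom:
    element: str
    position: tuple[float, float, float]
    partial_charge: float = 0.0
    formal_charge: int = 0
    atom_class: AtomClass = "other"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")
        if abs(self.partial_charge) >= 2.0:
            raise ValueError(f"implausible partial charge {self.partial_charge}")


@dataclass(frozen=True)
class LigandPose:
    """One docked conformer of one compound in the shared receptor frame.

    ``bonds`` are (i, j, order) with order in {1, 2, 3} or 1.5 for aromatic.
    """

    compound_id: str
    pose_index: int
    atoms: tuple[Atom, ...]
    bonds: tuple[tuple[int, int, float], ...]
    frame_id: str = "receptor"

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def net_formal_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        out = []
        for a, b, order in self.bonds:
            if a == i:
                out.append((b, order))
            elif b == i:
                out.append((a, order))
        return out

    def with_charges(self, charges: Sequence[float]) -> "LigandPose":
        if len(charges) != len(self.atoms):
            raise ValueError("charge vector length mismatch")
        atoms = tuple(replace(a, partial_charge=float(q))
                      for a, q in zip(self.atoms, charges))
        return replace(self, atoms=atoms)


@dataclass(frozen=True)
class AnchorSite:
    """The two carboxylate oxygens of the anchor residue (e.g. Asp 3.32)."""

    oxygens: tuple[tuple[float, float, float], tuple[float, float, float]]
    residue_label: str

    def __post_init__(self) -> None:
        d = np.linalg.norm(np.subtract(*self.oxygens))
        if d > 2.5:
            raise ValueError(
                f"carboxylate oxygens {d:.2f} Å apart; not a single carboxylate")

    @property
    def oxygen_coords(self) -> np.ndarray:
        return np.array(self.oxygens, dtype=float)


def classify_atom(element: str, formal_charge: int,
                  bond_orders: Iterable[float]) -> AtomClass:
    """Assign the coarse atom class used for force-field parameter lookup."""
    orders = list(bond_orders)
    el = element.capitalize()
    if el == "C":
        if any(o == 1.5 for o in orders):
            return "aromatic-C"
        if any(o >= 2 for o in orders):
            return "sp2-C"
        return "sp3-C"
    if el == "N":
        return "N-cationic" if formal_charge > 0 else "N-neutral"
    if el == "O":
        return "O"
    if el == "S":
        return "S"
    if el in _HALOGENS:
        return "halogen"
    if el == "H":
        return "H"
    return "other"


def _pose_from_rdkit(mol, compound_id: str, pose_index: int,
                     frame_id: str) -> LigandPose:
    conf = mol.GetConformer()
    bonds = []
    for b in mol.GetBonds():
        order = 1.5 if b.GetIsAromatic() else float(b.GetBondTypeAsDouble())
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    per_atom_orders: dict[int, list[float]] = {i: [] for i in range(mol.GetNumAtoms())}
    for i, j, o in bonds:
        per_atom_orders[i].append(o)
        per_atom_orders[j].append(o)
    atoms = []
    for at in mol.GetAtoms():
        i = at.GetIdx()
        pos = conf.GetAtomPosition(i)
        q = 0.0
        if at.HasProp("_TriposPartialCharge"):
            q = at.GetDoubleProp("_TriposPartialCharge")
        atoms.append(Atom(
            element=at.GetSymbol(),
            position=(pos.x, pos.y, pos.z),
            partial_charge=q,
            formal_charge=at.GetFormalCharge(),
            atom_class=classify_atom(at.GetSymbol(), at.GetFormalCharge(),
                                     per_atom_orders[i]),
        ))
    return LigandPose(compound_id, pose_index, tuple(atoms), tuple(bonds), frame_id)


def read_poses(path, fmt: str | None = None, frame_id: str = "receptor") -> list[LigandPose]:
    """Read docked poses from an SDF or MOL2 file (one pose per record).

    The compound id comes from the molecule title (text before an optional
    ``|pose=k`` suffix, which sets the pose index; otherwise poses of the
    same title are numbered in file order).  Records whose coordinates are
    all-zero in z with a 2D flag, or that fail to parse, are skipped with a
    warning.
    """
    from rdkit import Chem

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    raw: list[tuple[object, bool]] = []  # (mol, is_2d)
    if fmt == "sdf":
        supp = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for k, mol in enumerate(supp):
            if mol is None:
                log.warning("skipping unparseable SDF record %d in %s", k, path)
                continue
            is_2d = mol.GetNumConformers() > 0 and not mol.GetConformer().Is3D()
            raw.append((mol, is_2d))
    elif fmt == "mol2":
        text = path.read_text()
        blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE")[1:]]
        for k, block in enumerate(blocks):
            mol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=True)
            if mol is None:
                log.warning("skipping unparseable MOL2 record %d in %s", k, path)
                continue
            raw.append((mol, False))
    else:
        raise ValueError(f"unsupported pose format: {fmt!r}")

    poses: list[LigandPose] = []
    counters: dict[str, int] = {}
    for mol, is_2d in raw:
        title = (mol.GetProp("_Name") if mol.HasProp("_Name") else "") or f"mol{len(poses)}"
        if is_2d:
            warnings.warn(f"record {title!r}: 2D coordinates; rejected")
            continue
        if "|pose=" in title:
            cid, _, k = title.partition("|pose=")
            pose_index = int(k)
        else:
            cid = title
            pose_index = counters.get(cid, 0)
        counters[cid] = pose_index + 1
        poses.append(_pose_from_rdkit(mol, cid, pose_index, frame_id))
    return poses


def _pose_to_rdkit(pose: LigandPose):
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                 3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
    em = Chem.RWMol()
    for a in pose.atoms:
        at = Chem.Atom(a.element)
        at.SetFormalCharge(a.formal_charge)
        at.SetNoImplicit(True)
        em.AddAtom(at)
    for i, j, o in pose.bonds:
        em.AddBond(int(i), int(j), order_map[float(o)])
    mol = em.GetMol()
    conf = Chem.Conformer(len(pose.atoms))
    for i, a in enumerate(pose.atoms):
        conf.SetAtomPosition(i, Point3D(*a.position))
    conf.Set3D(True)
    mol.AddConformer(conf)
    mol.SetProp("_Name", f"{pose.compound_id}|pose={pose.pose_index}")
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                     | Chem.SanitizeFlags.SANITIZE_SETAROMATICITY)
    return mol


def write_poses_sdf(poses: Sequence[LigandPose], path) -> None:
    """Write poses to an SDF (V2000) file, one record per pose."""
    from rdkit import Chem

    with Chem.SDWriter(str(path)) as w:
        for pose in poses:
            mol = _pose_to_rdkit(pose)
            mol.SetDoubleProp("net_formal_charge", float(pose.net_formal_charge))
            w.write(mol)


_CARBOXYLATE_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


def locate_anchor(receptor_pdb, residue_spec: str) -> AnchorSite:
    """Locate the anchor carboxylate in a receptor PDB.

    ``residue_spec`` is ``chain:resnum:resname``, e.g. ``"A:114:ASP"``.
    """
    from Bio.PDB import PDBParser

    chain_id, resnum, resname = residue_spec.split(":")
    resname = resname.upper()
    if resname not in _CARBOXYLATE_ATOMS:
        raise ValueError(f"residue {resname} is not a carboxylate (ASP/GLU)")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("receptor", str(receptor_pdb))
    for model in structure:
        for chain in model:
            if chain.id != chain_id:
                continue
            for res in chain:
                if res.id[1] == int(resnum) and res.get_resname() == resname:
                    names = _CARBOXYLATE_ATOMS[resname]
                    try:
                        o1, o2 = (res[n].coord for n in names)
                    except KeyError as exc:
                        raise ValueError(
                            f"{residue_spec}: missing carboxylate atom {exc}") from exc
                    return AnchorSite(
                        (tuple(map(float, o1)), tuple(map(float, o2))),
                        residue_label=f"{resname}{resnum}",
                    )
    raise ValueError(f"residue {residue_spec} not found in {receptor_pdb}")
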