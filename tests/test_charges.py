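"""PEOE sigma charges and Hückel pi increments."""

import numpy as np
import pytest

from pycomfa.charges import (assign_charges, gasteiger_sigma_charges,
                             huckel_pi_charges)
from pycomfa.structures import LigandPose

from conftest import make_pose, pose_from_smiles

RING_BONDS = [(k, (k + 1) % 6, 1.5) for k in range(6)]


def hexagon(elements, charges):
    atoms = []
    for k, (el, fc) in enumerate(zip(elements, charges)):
        th = k * np.pi / 3
        atoms.append((el, (1.4 * np.cos(th), 1.4 * np.sin(th), 0.0), fc))
    return make_pose(atoms, RING_BONDS)


@pytest.mark.parametrize("smiles", ["CCO", "CCN", "c1ccccc1O", "CC(=O)NC"])
def test_neutral_molecules_conserve_charge(smiles):
    pose = pose_from_smiles(smiles)
    q = gasteiger_sigma_charges(pose)
    assert abs(q.sum()) < 1e-6


def test_equivalent_atoms_get_equal_charges():
    ethane = pose_from_smiles("CC")
    q = gasteiger_sigma_charges(ethane)
    carbons = [q[i] for i, a in enumerate(ethane.atoms) if a.element == "C"]
    assert carbons[0] == pytest.approx(carbons[1], abs=1e-9)
    hydrogens = [q[i] for i, a in enumerate(ethane.atoms) if a.element == "H"]
    assert np.ptp(hydrogens) < 1e-9


@pytest.mark.parametrize("smiles", ["CO", "CCN"])
def test_peoe_matches_reference_toolkit(smiles):
    """Per-atom agreement with RDKit's Gasteiger implementation (the
    independent PEOE oracle) within 0.02 e."""
    from rdkit import Chem
    from rdkit.Chem import AllChem, rdPartialCharges

    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=7)
    rdPartialCharges.ComputeGasteigerCharges(mol, nIter=12)
    ref = np.array([a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()])

    from pycomfa.structures import _pose_from_rdkit
    pose = _pose_from_rdkit(mol, "m", 0, "t")
    q = gasteiger_sigma_charges(pose, iterations=12)
    assert np.abs(q - ref).max() < 0.02


def test_permutation_invariance():
    pose = pose_from_smiles("NCCO")
    q = gasteiger_sigma_charges(pose)
    perm = np.arange(len(pose.atoms))[::-1]
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    atoms = tuple(pose.atoms[p] for p in perm)
    bonds = tuple((int(inv[i]), int(inv[j]), o) for i, j, o in pose.bonds)
    permuted = LigandPose("m", 0, atoms, bonds, "t")
    qp = gasteiger_sigma_charges(permuted)
    np.testing.assert_allclose(qp, q[perm], atol=1e-12)


def test_saturated_molecule_has_zero_pi_increments():
    pose = pose_from_smiles("CCNCCO")
    assert np.all(huckel_pi_charges(pose) == 0.0)


def test_benzene_pi_increments_symmetric_and_neutral():
    benzene = hexagon(["C"] * 6, [0] * 6)
    inc = huckel_pi_charges(benzene)
    assert np.ptp(inc) < 1e-9
    assert abs(inc.sum()) < 1e-9


def test_pyridinium_pi_increments_match_huckel_oracle():
    """Charged-ring increments equal an independent 6-site Hückel solve
    (h_N+ = 2.0, unit ring k) and sum to the fragment's +1 charge."""
    pyridinium = hexagon(["N", "C", "C", "C", "C", "C"], [1, 0, 0, 0, 0, 0])
    inc = huckel_pi_charges(pyridinium)
    assert inc.sum() == pytest.approx(1.0, abs=1e-9)

    H = np.zeros((6, 6))
    H[0, 0] = 2.0
    for k in range(6):
        H[k, (k + 1) % 6] = H[(k + 1) % 6, k] = 1.0
    evals, evecs = np.linalg.eigh(H)
    occ = np.argsort(-evals)[:3]          # 6 pi electrons, beta < 0
    pop = 2.0 * (evecs[:, occ] ** 2).sum(axis=1)
    core = np.array([2.0, 1, 1, 1, 1, 1])  # N+: 1 contributed e + formal charge
    np.testing.assert_allclose(inc, core - pop, atol=1e-9)


def test_gh_reduces_to_peoe_without_pi_system():
    pose = pose_from_smiles("CC(C)CO")
    a = assign_charges(pose, "peoe")
    b = assign_charges(pose, "gh")
    qa = [at.partial_charge for at in a.atoms]
    qb = [at.partial_charge for at in b.atoms]
    np.testing.assert_allclose(qa, qb, atol=1e-12)


def test_gh_conserves_net_charge_on_cation():
    pyridinium = hexagon(["N", "C", "C", "C", "C", "C"], [1, 0, 0, 0, 0, 0])
    charged = assign_charges(pyridinium, "gh")
    total = sum(a.partial_charge for a in charged.atoms)
    assert total == pytest.approx(1.0, abs=1e-6)


def test_unknown_element_rejected():
    pose = make_pose([("Xe", (0, 0, 0), 0), ("C", (1.5, 0, 0), 0)],
                     [(0, 1, 1.0)])
    with pytest.raises(ValueError, match="Xe"):
        gasteiger_sigma_charges(pose)
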