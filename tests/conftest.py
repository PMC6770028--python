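"""Shared fixtures: small molecule builders and the session-wide benchmark."""

from __future__ import annotations

import numpy as np
import pytest

from pycomfa.activities import ActivityRecord, split_train_test
from pycomfa.fields import build_grid, compute_field_matrix, filter_and_scale
from pycomfa.pls import fit_pls, select_onc
from pycomfa.structures import Atom, LigandPose, classify_atom
from pycomfa.synthetic_data import SyntheticSpec, generate_dataset


def pose_from_smiles(smiles: str, name: str = "mol", seed: int = 7) -> LigandPose:
    """Build a 3D LigandPose from SMILES (test convenience only)."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    from pycomfa.structures import _pose_from_rdkit

    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=seed)
    return _pose_from_rdkit(mol, name, 0, "test")


def make_pose(atoms, bonds, compound_id="m", pose_index=0, frame="test"):
    """Assemble a LigandPose from (element, xyz, formal_charge) tuples."""
    per_atom = {i: [] for i in range(len(atoms))}
    for i, j, o in bonds:
        per_atom[i].append(o)
        per_atom[j].append(o)
    built = tuple(
        Atom(el, tuple(map(float, pos)), 0.0, fc, classify_atom(el, fc, per_atom[i]))
        for i, (el, pos, fc) in enumerate(atoms))
    return LigandPose(compound_id, pose_index, built, tuple(bonds), frame)


@pytest.fixture(scope="session")
def benchmark():
    """The default synthetic benchmark (seed 42) with fields, split and model.

    Generated once per session; every consumer treats it as read-only.
    """
    dataset, truth = generate_dataset(SyntheticSpec(seed=42))
    grid = build_grid(dataset)
    matrix = compute_field_matrix(dataset, grid)
    filt = filter_and_scale(matrix)
    y = dataset.pic50
    split = split_train_test(list(dataset.activities), 0.10, 42)
    train_ids = set(split.training_ids)
    tr = [i for i, c in enumerate(dataset.compound_ids) if c in train_ids]
    te = [i for i, c in enumerate(dataset.compound_ids) if c not in train_ids]
    onc, cv = select_onc(filt.values[tr], y[tr], 10)
    model = fit_pls(filt.values[tr], y[tr], onc, filt.column_field, filt.column_sd)
    return {
        "dataset": dataset, "truth": truth, "grid": grid, "matrix": matrix,
        "filt": filt, "y": y, "split": split, "train": tr, "test": te,
        "onc": onc, "cv": cv, "model": model,
    }


@pytest.fixture(scope="session")
def benchmark_scrambling(benchmark):
    """Progressive scrambling of the benchmark training model, components 2..7."""
    from pycomfa.validation import progressive_scrambling

    tr = benchmark["train"]
    return progressive_scrambling(
        benchmark["filt"].values[tr], benchmark["y"][tr],
        component_range=range(2, 8), bins_range=range(2, 11),
        reps_per_bin=10, critical_point=0.85, seed=42)


def synthetic_activity_records(n=176, seed=0):
    """Cheap activity table: two families, span 5..9.4, censored floor."""
    rng = np.random.default_rng(seed)
    recs = []
    for k in range(n):
        fam = ("benzamide", "arylpiperazine")[k % 2]
        pic = float(np.clip(rng.normal(7.2, 1.2), 5.0, 9.4))
        if k == 0:
            pic = 9.4
        censored = pic <= 5.0 or k % 23 == 1
        if censored:
            pic = 5.0
        ic50 = None if censored else 10.0 ** (9.0 - pic)
        recs.append(ActivityRecord(f"c{k:03d}", ic50, pic, censored, fam))
    return recs
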