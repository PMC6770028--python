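"""Grid construction and probe-field energies."""

import dataclasses

import numpy as np
import pytest

from pycomfa.activities import ActivityRecord
from pycomfa.alignment import AlignedDataset
from pycomfa.fields import (COULOMB_CONSTANT, TRIPOS_LJ_PARAMS, FieldMatrix,
                            GridRegion, ProbeSpec, build_grid,
                            compute_field_matrix, electrostatic_energy,
                            filter_and_scale, steric_energy)
from pycomfa.structures import AnchorSite

from conftest import make_pose

ANCHOR = AnchorSite(((0.0, 3.0, 1.1), (0.0, 3.0, -1.1)), "ASP")


def carbon_at(*pos):
    return make_pose([("C", pos, 0)], [])


def tiny_dataset(poses):
    acts = tuple(ActivityRecord(p.compound_id, 10.0, 8.0, False) for p in poses)
    return AlignedDataset(tuple(poses), acts, ANCHOR)


class TestGrid:
    def test_single_atom_margin4_spacing2(self):
        grid = build_grid([carbon_at(0, 0, 0)], spacing=2.0, margin=4.0)
        assert grid.origin == (-4.0, -4.0, -4.0)
        assert grid.dims == (5, 5, 5)

    def test_halving_spacing_roughly_doubles_dims(self):
        pose = make_pose([("C", (0, 0, 0), 0), ("C", (6.0, 3.0, 1.0), 0)],
                         [(0, 1, 1.0)])
        g2 = build_grid([pose], spacing=2.0)
        g1 = build_grid([pose], spacing=1.0)
        for d1, d2 in zip(g1.dims, g2.dims):
            assert d1 == pytest.approx(2 * d2, abs=2)

    def test_every_atom_has_margin_inside_box(self):
        rng = np.random.default_rng(5)
        poses = [make_pose([("C", tuple(rng.uniform(-5, 5, 3)), 0)
                            for _ in range(8)],
                           [(k, k + 1, 1.0) for k in range(7)], f"c{i}")
                 for i in range(2)]
        grid = build_grid(poses, spacing=2.0, margin=4.0)
        lo = np.array(grid.origin)
        hi = lo + grid.spacing * (np.array(grid.dims) - 1)
        for p in poses:
            assert np.all(p.coords - lo >= 4.0 - 1e-9)
            assert np.all(hi - p.coords >= 4.0 - 1e-9)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            build_grid([])


class TestSteric:
    def test_decays_to_zero_far_away(self):
        e = steric_energy(carbon_at(0, 0, 0), (25.0, 0, 0))
        assert abs(e) < 1e-3

    def test_cap_at_atom_position(self):
        assert steric_energy(carbon_at(0, 0, 0), (0.0, 0.0, 0.0)) == 30.0

    def test_minimum_is_minus_epsilon_at_contact_distance(self):
        probe = ProbeSpec()
        r_atom, eps_atom = TRIPOS_LJ_PARAMS["sp3-C"]
        rij = r_atom + probe.lj_radius
        epsij = np.sqrt(eps_atom * probe.lj_epsilon)
        e = steric_energy(carbon_at(0, 0, 0), (rij, 0, 0), probe)
        assert e == pytest.approx(-epsij, abs=1e-12)

    def test_additive_over_atom_subsets(self):
        pose = make_pose([("C", (0, 0, 0), 0), ("O", (3, 0, 0), 0)], [(0, 1, 1.0)])
        point = (1.2, 2.5, 0.3)
        whole = steric_energy(pose, point)
        parts = steric_energy(carbon_at(0, 0, 0), point) + \
            steric_energy(make_pose([("O", (3, 0, 0), 0)], []), point)
        assert whole == pytest.approx(parts, abs=1e-9)


class TestElectrostatic:
    def test_zero_charges_give_zero(self):
        assert electrostatic_energy(carbon_at(0, 0, 0), (3.0, 0, 0)) == 0.0

    def test_unit_charge_at_10A_closed_form(self):
        pose = carbon_at(0, 0, 0).with_charges([1.0])
        e = electrostatic_energy(pose, (10.0, 0, 0))
        assert e == pytest.approx(COULOMB_CONSTANT / 100.0, rel=1e-12)
        assert e == pytest.approx(3.320636, abs=1e-6)

    def test_mirror_symmetric_pair_cancels_on_plane(self):
        pose = make_pose([("C", (0, 0, 1.5), 0), ("C", (0, 0, -1.5), 0)],
                         [(0, 1, 1.0)]).with_charges([0.5, -0.5])
        e = electrostatic_energy(pose, (4.0, 2.0, 0.0))
        assert abs(e) < 1e-9


class TestFieldMatrix:
    def test_shape_is_n_by_2p(self):
        poses = [dataclasses.replace(carbon_at(0, 0, 0).with_charges([0.1]),
                                     compound_id=f"c{i}") for i in range(3)]
        ds = tiny_dataset(poses)
        grid = build_grid(ds)
        m = compute_field_matrix(ds, grid)
        assert m.values.shape == (3, 2 * grid.n_points)

    def test_duplicate_compound_gives_identical_rows(self):
        base = carbon_at(0.3, 0.1, -0.2).with_charges([0.2])
        poses = [dataclasses.replace(base, compound_id="a"),
                 dataclasses.replace(base, compound_id="b")]
        ds = tiny_dataset(poses)
        m = compute_field_matrix(ds, build_grid(ds))
        np.testing.assert_array_equal(m.values[0], m.values[1])

    def test_cells_match_single_point_calls(self):
        rng = np.random.default_rng(9)
        poses = []
        for i in range(5):
            xyz = rng.uniform(-3, 3, (4, 3))
            p = make_pose([("C", tuple(x), 0) for x in xyz],
                          [(k, k + 1, 1.0) for k in range(3)], f"c{i}")
            poses.append(p.with_charges(rng.uniform(-0.3, 0.3, 4)))
        ds = tiny_dataset(poses)
        grid = build_grid(ds)
        m = compute_field_matrix(ds, grid, require_charges=False)
        pts = grid.points()
        steric_block = m.values[:, m.column_field == "steric"]
        for _ in range(10):
            i = int(rng.integers(5))
            j = int(rng.integers(grid.n_points))
            assert steric_block[i, j] == pytest.approx(
                steric_energy(poses[i], pts[j]), abs=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        # multiples of 1/16 are exactly representable, so the shifted
        # coordinates subtract without rounding and bit-identity is exact
        xyz = rng.integers(-32, 32, (5, 3)) / 16.0
        p0 = make_pose([("C", tuple(x), 0) for x in xyz],
                       [(k, k + 1, 1.0) for k in range(4)], "c0")
        p0 = p0.with_charges(rng.uniform(-0.2, 0.2, 5))
        shift = np.array([6.0, -4.0, 2.0])  # whole multiples of the spacing
        p1 = dataclasses.replace(
            p0, atoms=tuple(dataclasses.replace(a, position=tuple(np.add(a.position, shift)))
                            for a in p0.atoms))
        anchor1 = AnchorSite(tuple(tuple(np.add(o, shift)) for o in ANCHOR.oxygens), "ASP")
        ds0 = tiny_dataset([p0])
        ds1 = AlignedDataset((p1,), ds0.activities, anchor1)
        g0 = build_grid(ds0, 2.0, 4.0)
        g1 = build_grid(ds1, 2.0, 4.0)
        np.testing.assert_allclose(np.subtract(g1.origin, g0.origin), shift, atol=1e-12)
        m0 = compute_field_matrix(ds0, g0)
        m1 = compute_field_matrix(ds1, g1)
        np.testing.assert_array_equal(m0.values, m1.values)


class TestFilterScale:
    def _matrix(self, values, fields):
        grid = GridRegion((0, 0, 0), 2.0, (len(fields) // 2, 1, 2))
        n_half = len(fields) // 2
        return FieldMatrix(np.asarray(values, float),
                           tuple(f"c{i}" for i in range(len(values))), grid,
                           np.concatenate([np.arange(n_half), np.arange(len(fields) - n_half)]),
                           np.asarray(fields))

    def test_constant_column_dropped(self):
        m = self._matrix([[1.0, 5.0], [1.0, 9.0], [1.0, 1.0]],
                         ["steric", "steric"])
        out = filter_and_scale(m, min_sigma=2.0)
        assert out.values.shape == (3, 1)

    def test_min_sigma_zero_retains_all(self):
        m = self._matrix([[1.0, 5.0], [1.0, 9.0], [1.0, 1.0]],
                         ["steric", "steric"])
        out = filter_and_scale(m, min_sigma=0.0, scaling="none")
        assert out.values.shape == (3, 2)

    def test_block_variances_equalised(self):
        rng = np.random.default_rng(4)
        vals = np.hstack([rng.normal(0, 8.0, (20, 3)), rng.normal(0, 0.5, (20, 2))])
        m = self._matrix(vals, ["steric"] * 3 + ["electrostatic"] * 2)
        out = filter_and_scale(m, min_sigma=0.0)
        for name in ("steric", "electrostatic"):
            blk = out.block(name)
            centered = blk - blk.mean(axis=0)
            total_var = (centered ** 2).sum() / (len(blk) - 1)
            assert total_var == pytest.approx(1.0, abs=1e-9)
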