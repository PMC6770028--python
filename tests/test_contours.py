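"""STDEV*COEFF fields, contour levels and OpenDX round trips."""

import numpy as np
import pytest

from pycomfa.contours import (contour_thresholds, export_contour_set,
                              export_dx, read_dx, stdev_coeff_field)
from pycomfa.fields import FieldMatrix, GridRegion
from pycomfa.pls import PLSModel


def toy_matrix(n_points=8):
    grid = GridRegion((0.0, 0.0, 0.0), 2.0, (2, 2, 2))
    values = np.arange(4 * 2 * n_points, dtype=float).reshape(4, -1)
    cp = np.concatenate([np.arange(n_points), np.arange(n_points)])
    cf = np.array(["steric"] * n_points + ["electrostatic"] * n_points)
    return FieldMatrix(values, ("a", "b", "c", "d"), grid, cp, cf)


def toy_model(coef, sd, fields):
    return PLSModel(2, np.asarray(coef, float), np.zeros(len(coef)), 7.0,
                    0.9, 0.2, 100.0, np.asarray(fields), np.asarray(sd, float))


class TestStdevCoeff:
    def test_zero_coefficients_give_zero_field(self):
        m = toy_matrix()
        model = toy_model(np.zeros(16), np.ones(16), m.column_field)
        out = stdev_coeff_field(model, m)
        assert set(out) == {"steric", "electrostatic"}
        assert all(np.all(v == 0) for v in out.values())

    def test_single_nonzero_column_lights_single_voxel(self):
        m = toy_matrix()
        coef = np.zeros(16)
        coef[3] = 2.5
        sd = np.full(16, 1.2)
        out = stdev_coeff_field(toy_model(coef, sd, m.column_field), m)
        steric = out["steric"]
        assert steric[3] == pytest.approx(3.0)
        assert np.count_nonzero(steric) == 1
        assert np.count_nonzero(out["electrostatic"]) == 0

    def test_voxel_count_equals_dims_product(self):
        m = toy_matrix()
        out = stdev_coeff_field(toy_model(np.ones(16), np.ones(16),
                                          m.column_field), m)
        for v in out.values():
            assert v.size == np.prod(m.grid.dims)


class TestThresholds:
    def test_symmetric_values_give_symmetric_levels(self):
        v = np.concatenate([np.linspace(0.1, 3, 40), -np.linspace(0.1, 3, 40)])
        t = contour_thresholds(v)
        assert t["favored"] == pytest.approx(-t["disfavored"], abs=1e-9)

    def test_all_positive_field_has_no_disfavored_level(self):
        t = contour_thresholds(np.linspace(0.5, 2.0, 10))
        assert t["disfavored"] is None
        assert t["favored"] is not None

    def test_percentile_linear_interpolation_convention(self):
        t = contour_thresholds(np.arange(1.0, 101.0), favored_pct=80)
        assert t["favored"] == pytest.approx(80.2)


class TestDX:
    def test_round_trip_bitwise(self, tmp_path):
        grid = GridRegion((-4.0, -2.0, 0.0), 2.0, (3, 4, 5))
        rng = np.random.default_rng(0)
        vals = rng.normal(size=grid.n_points)
        path = tmp_path / "field.dx"
        export_dx(vals, grid, path)
        back, grid2 = read_dx(path)
        assert grid2 == grid
        np.testing.assert_allclose(back, vals, rtol=1e-9)

    def test_mismatched_dims_rejected(self, tmp_path):
        grid = GridRegion((0, 0, 0), 2.0, (2, 2, 2))
        with pytest.raises(ValueError, match="does not match"):
            export_dx(np.zeros(7), grid, tmp_path / "bad.dx")

    def test_reference_parser_reads_export(self, tmp_path):
        """Independent oracle: the gridDataFormats OpenDX parser reproduces
        origin, spacing and values of our export."""
        gridData = pytest.importorskip("gridData")
        grid = GridRegion((1.0, -3.0, 2.0), 2.0, (4, 3, 2))
        vals = np.arange(grid.n_points, dtype=float)
        path = tmp_path / "ref.dx"
        export_dx(vals, grid, path)
        g = gridData.Grid(str(path))
        np.testing.assert_allclose(g.origin, grid.origin, atol=1e-9)
        np.testing.assert_allclose(g.delta, [2.0, 2.0, 2.0], atol=1e-9)
        np.testing.assert_allclose(g.grid.ravel(), vals, rtol=1e-9)


def test_export_contour_set_manifest(tmp_path):
    m = toy_matrix()
    rng = np.random.default_rng(1)
    model = toy_model(rng.normal(size=16), np.ones(16), m.column_field)
    manifest = export_contour_set(model, m, tmp_path)
    assert {f["field"] for f in manifest["fields"]} == {"steric", "electrostatic"}
    for entry in manifest["fields"]:
        vals, grid = read_dx(tmp_path / entry["file"])
        assert vals.size == np.prod(grid.dims)
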