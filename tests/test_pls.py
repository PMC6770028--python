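"""NIPALS PLS, LOO cross-validation and model statistics."""

import numpy as np
import pytest

from pycomfa.pls import (external_r2, field_contributions, fit_pls, loo_q2,
                         predict, regression_stats, select_onc)


def random_xy(n, p, seed, informative=3, noise=0.1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:informative] = rng.uniform(0.5, 1.5, informative)
    y = X @ beta + rng.normal(0, noise, n)
    return X, y


def orth_design(n, p, seed):
    """Column-centered orthonormal design: in-sample correlations are exactly
    zero, so single-column relations are recovered exactly."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, p))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    return Q[:, :p]


def test_exact_linear_single_column_gives_r2_one():
    X = orth_design(25, 10, 0)
    y = 2.0 + 1.5 * X[:, 4]
    model = fit_pls(X, y, 1)
    assert model.r2 == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("n, p", [(30, 12), (15, 40)])
def test_full_rank_pls_equals_least_squares(n, p):
    """At n_components = rank, PLS predictions equal the normal-equations
    (minimum-norm) least-squares fit."""
    X, y = random_xy(n, p, 3)
    rank = min(n - 1, p)
    model = fit_pls(X, y, rank)
    yhat = predict(model, X)
    Xc = X - X.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
    yls = y.mean() + Xc @ beta
    np.testing.assert_allclose(yhat, yls, atol=1e-6)


def test_scores_pairwise_orthogonal():
    X, y = random_xy(30, 50, 1)
    model = fit_pls(X, y, 6)
    G = model.scores.T @ model.scores
    off = G - np.diag(np.diag(G))
    assert np.abs(off).max() < 1e-8


def test_pls_matches_sklearn_reference():
    """Dual-route check: coefficients and predictions agree with the
    scikit-learn PLS implementation (independent NIPALS)."""
    from sklearn.cross_decomposition import PLSRegression

    X, y = random_xy(40, 25, 8)
    model = fit_pls(X, y, 4)
    ref = PLSRegression(n_components=4, scale=False).fit(X, y)
    np.testing.assert_allclose(predict(model, X),
                               ref.predict(X).ravel(), atol=1e-8)
    np.testing.assert_allclose(model.coefficients, ref.coef_.ravel(), atol=1e-8)


class TestLOO:
    def test_matches_naive_per_sample_refit(self):
        """The single-sweep LOO equals explicitly refitting for each left-out
        sample on a 15×40 fixture."""
        X, y = random_xy(15, 40, 5)
        res = loo_q2(X, y, 3)
        naive = np.empty(15)
        for i in range(15):
            keep = np.arange(15) != i
            m = fit_pls(X[keep], y[keep], 3)
            naive[i] = predict(m, X[i:i + 1])[0]
        np.testing.assert_allclose(res.predictions, naive, atol=1e-8)
        assert res.check(y)

    def test_noiseless_planted_model_recovers(self):
        X = orth_design(40, 30, 6)
        y = X[:, 0] - 0.5 * X[:, 1]
        res = loo_q2(X, y, 2)
        assert res.q2 > 0.999

    def test_permuted_y_has_no_predictivity(self):
        rng = np.random.default_rng(7)
        q2s = []
        for _ in range(20):
            X = rng.normal(size=(30, 200))
            y = rng.permutation(np.linspace(5, 9, 30))
            q2s.append(max(loo_q2(X, y, c).q2 for c in (1, 3, 5)))
        assert np.median(q2s) <= 0.05
        assert all(q <= 1.0 for q in q2s)

    def test_too_few_samples_rejected(self):
        X, y = random_xy(5, 10, 0)
        with pytest.raises(ValueError):
            loo_q2(X, y, 4)


class TestONC:
    def test_single_signal_direction_gives_onc_one(self):
        # one dominant latent factor carries y; extra components only fit
        # noise, so LOO punishes them
        rng = np.random.default_rng(2)
        t = rng.normal(size=60)
        loadings = rng.uniform(0.5, 1.5, 12)
        X = np.outer(t, loadings) + rng.normal(0, 0.1, (60, 12))
        y = t + rng.normal(0, 0.05, 60)
        onc, _ = select_onc(X, y, 8)
        assert onc == 1

    def test_plateau_tie_broken_toward_fewer_components(self):
        # y exactly in the column span of an orthonormal design: Q² hits 1
        # at two components and stays there; the tie resolves to the
        # smallest such count
        X = orth_design(30, 10, 4)
        y = X[:, 0]
        onc, res = select_onc(X, y, 6)
        assert res[onc].q2 == pytest.approx(1.0, abs=1e-9)
        plateau = [c for c in res if abs(res[c].q2 - res[onc].q2) <= 1e-12]
        assert onc == min(plateau)


class TestStatistics:
    def test_f_formula_hand_value(self):
        # R²=0.5, n=12, c=1 → F = 0.5·10 / (1·0.5) = 10
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        model = fit_pls(X, y, 1)
        from pycomfa.pls import _stats_from_resid
        r2, see, f = _stats_from_resid(np.sqrt(1 - 0.5) * (y - y.mean()), y, 1)
        assert r2 == pytest.approx(0.5, abs=1e-12)
        assert f == pytest.approx(10.0, abs=1e-9)

    def test_perfect_fit_gives_zero_see_and_inf_f(self):
        X = orth_design(20, 8, 9)
        y = X[:, 2]
        model = fit_pls(X, y, 2)
        r2, see, f = regression_stats(model, X, y)
        assert see == pytest.approx(0.0, abs=1e-7)
        assert f == np.inf or f > 1e10

    def test_training_r2_non_decreasing_in_components(self):
        X, y = random_xy(30, 40, 12, informative=6, noise=0.5)
        r2s = [fit_pls(X, y, c).r2 for c in range(1, 8)]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))


class TestContributions:
    def _model(self, coef, sd, fields):
        from pycomfa.pls import PLSModel
        return PLSModel(1, np.asarray(coef, float), np.zeros(len(coef)), 0.0,
                        0.9, 0.1, 10.0, np.asarray(fields), np.asarray(sd, float))

    def test_zero_electrostatic_gives_100_0(self):
        m = self._model([1.0, -2.0, 0.0], [1, 1, 1],
                        ["steric", "steric", "electrostatic"])
        c = field_contributions(m)
        assert c["steric"] == pytest.approx(100.0)
        assert c["electrostatic"] == pytest.approx(0.0)

    def test_contributions_sum_to_100(self):
        X, y = random_xy(30, 20, 3)
        fields = np.array(["steric"] * 12 + ["electrostatic"] * 8)
        model = fit_pls(X, y, 3, column_field=fields)
        assert sum(field_contributions(model).values()) == pytest.approx(100.0, abs=1e-9)

    def test_planted_block_split_recovered(self):
        """A planted 60/40 |coef|·sd split across blocks is recovered within
        5 points after fitting."""
        rng = np.random.default_rng(11)
        n, ps, pe = 200, 15, 15
        X = rng.normal(size=(n, ps + pe))
        beta = np.zeros(ps + pe)
        beta[:3] = 0.60 / 3          # steric block share 60%
        beta[ps:ps + 3] = 0.40 / 3   # electrostatic share 40%
        y = X @ beta + rng.normal(0, 0.02, n)
        fields = np.array(["steric"] * ps + ["electrostatic"] * pe)
        model = fit_pls(X, y, 6, column_field=fields)
        c = field_contributions(model)
        assert c["steric"] == pytest.approx(60.0, abs=5.0)


class TestPredict:
    def test_training_matrix_reproduces_training_predictions(self):
        X, y = random_xy(25, 10, 5)
        model = fit_pls(X, y, 3)
        np.testing.assert_allclose(predict(model, X), predict(model, X.copy()))

    def test_empty_input_gives_empty_output(self):
        X, y = random_xy(25, 10, 5)
        model = fit_pls(X, y, 3)
        assert predict(model, np.empty((0, 10))).size == 0

    def test_external_r2_is_squared_pearson(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(size=30)
        pred = 2.0 + 3.0 * obs + rng.normal(0, 0.1, 30)
        assert external_r2(obs, pred) == pytest.approx(
            np.corrcoef(obs, pred)[0, 1] ** 2, abs=1e-12)


def test_duplicated_row_perturbs_coefficients_only_via_centering():
    X, y = random_xy(30, 15, 6)
    m1 = fit_pls(X, y, 3)
    X2 = np.vstack([X, X[:1]])
    y2 = np.append(y, y[0])
    m2 = fit_pls(X2, y2, 3)
    # duplicating one row shifts the column means slightly; coefficients
    # move by at most the same order
    shift = np.abs(m2.coefficients - m1.coefficients).max()
    assert shift < 0.15 * max(np.abs(m1.coefficients).max(), 1e-9)
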