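"""Partial least squares for CoMFA: NIPALS fit, LOO validation, statistics.

The field matrix X (compounds × retained grid columns, block-scaled) is
correlated with pIC50 by PLS1.  NIPALS extracts latent components t = Xw
with mutually orthogonal scores; the regression vector in (centered) column
space is b = W (PᵀW)⁻¹ q.  Model quality is summarised the way the QSAR
literature reports it:

    Q²  = 1 − PRESS / SS_tot          (leave-one-out, PRESS = Σ(y_i − ŷ_(i))²)
    SEP = sqrt(PRESS / (n − c − 1))   (cross-validated standard error)
    R²  = 1 − RSS / SS_tot            (training fit)
    SEE = sqrt(RSS / (n − c − 1))
    F   = R² (n − c − 1) / (c (1 − R²))

and the optimal number of components (ONC) maximises Q², breaking ties by
smaller SEP and then by fewer components.  Per-field contributions are
Σ|b_j|·sd_j over each field block, normalised to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fields import FieldMatrix

__all__ = [
    "PLSModel",
    "CrossValidationResult",
    "fit_pls",
    "loo_q2",
    "select_onc",
    "regression_stats",
    "field_contributions",
    "predict",
    "fit_comfa_model",
]


@dataclass(frozen=True)
class PLSModel:
    n_components: int
    coefficients: np.ndarray      # regression vector on centered columns
    x_mean: np.ndarray
    y_mean: float
    r2: float
    see: float
    f_statistic: float
    column_field: np.ndarray | None = None
    column_sd: np.ndarray | None = None
    scores: np.ndarray | None = None

    @property
    def contributions(self) -> dict[str, float]:
        if self.column_field is None or self.column_sd is None:
            raise ValueError("model carries no column metadata")
        return field_contributions(self)


@dataclass(frozen=True)
class CrossValidationResult:
    q2: float
    sep: float
    predictions: np.ndarray       # ŷ_(i): LOO prediction for each sample

    def check(self, y: np.ndarray) -> bool:
        press = float(((y - self.predictions) ** 2).sum())
        ss = float(((y - y.mean()) ** 2).sum())
        return abs(self.q2 - (1.0 - press / ss)) < 1e-10


def _nipals(xc: np.ndarray, yc: np.ndarray, n_components: int):
    """NIPALS PLS1 on centered data; returns (W, P, q, T)."""
    n, p = xc.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds min(n-1, p)")
    X = xc.copy()
    y = yc.copy()
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    T = np.empty((n, n_components))
    for a in range(n_components):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            # y already fully deflated: pad with zero components
            W[:, a:] = 0.0; P[:, a:] = 0.0; q[a:] = 0.0; T[:, a:] = 0.0
            break
        w /= norm
        t = X @ w
        tt = t @ t
        p_a = X.T @ t / tt
        q_a = (y @ t) / tt
        X -= np.outer(t, p_a)
        y = y - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
    return W, P, q, T


def _coef_per_component(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> list[np.ndarray]:
    """Regression vectors for 1..A components (cumulative)."""
    A = W.shape[1]
    out = []
    R = np.zeros_like(W)  # R = W (P'W)^-1, built column by column
    b = np.zeros(W.shape[0])
    for a in range(A):
        r = W[:, a] - R[:, :a] @ (P[:, :a].T @ W[:, a])
        R[:, a] = r
        b = b + q[a] * r
        out.append(b.copy())
    return out


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int,
            column_field: np.ndarray | None = None,
            column_sd: np.ndarray | None = None) -> PLSModel:
    """Fit a PLS1 model; X rows are compounds, y is pIC50."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.std() == 0:
        raise ValueError("y has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T = _nipals(X - x_mean, y - y_mean, n_components)
    b = _coef_per_component(W, P, q)[n_components - 1]
    resid = y - (y_mean + (X - x_mean) @ b)
    r2, see, f = _stats_from_resid(resid, y, n_components)
    sd = column_sd if column_sd is not None else X.std(axis=0, ddof=1)
    return PLSModel(n_components, b, x_mean, y_mean, r2, see, f,
                    column_field, sd, T)


def _stats_from_resid(resid: np.ndarray, y: np.ndarray, c: int):
    n = len(y)
    rss = float(resid @ resid)
    ss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / ss
    dof = max(n - c - 1, 1)
    see = float(np.sqrt(rss / dof))
    f = float("inf") if r2 >= 1.0 else r2 * dof / (c * (1.0 - r2))
    return r2, see, f


def regression_stats(model: PLSModel, X: np.ndarray, y: np.ndarray):
    """(R², SEE, F) of the model on the given training data."""
    resid = y - predict(model, X)
    return _stats_from_resid(np.asarray(resid), np.asarray(y, float),
                             model.n_components)


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.asarray(X_new, dtype=float)
    if X_new.size == 0:
        return np.empty(0)
    return model.y_mean + (X_new - model.x_mean) @ model.coefficients


def external_r2(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Squared Pearson correlation between observed and predicted."""
    y_obs = np.asarray(y_obs, float)
    y_pred = np.asarray(y_pred, float)
    r = np.corrcoef(y_obs, y_pred)[0, 1]
    return float(r * r)


def loo_q2(X: np.ndarray, y: np.ndarray, n_components: int,
           dof_convention: str = "n-c-1") -> CrossValidationResult:
    """Leave-one-out cross-validation at a fixed component count.

    Each left-out sample is predicted by a model refit (including
    re-centering) on the remaining n−1 samples; the retained-column set is
    fixed upstream and not re-selected per fold.
    """
    res = _loo_multi(X, y, [n_components], dof_convention)
    return res[n_components]


def _loo_multi(X: np.ndarray, y: np.ndarray, components: Sequence[int],
               dof_convention: str = "n-c-1") -> dict[int, CrossValidationResult]:
    """One LOO sweep, harvesting predictions at several component counts."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    cmax = max(components)
    if n <= cmax + 1:
        raise ValueError("too few samples for LOO at this component count")
    preds = {c: np.empty(n) for c in components}
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        x_mean = Xi.mean(axis=0)
        y_mean = yi.mean()
        W, P, q, _ = _nipals(Xi - x_mean, yi - y_mean, cmax)
        bs = _coef_per_component(W, P, q)
        xc = X[i] - x_mean
        for c in components:
            preds[c][i] = y_mean + xc @ bs[c - 1]
        mask[i] = True
    ss = float(((y - y.mean()) ** 2).sum())
    out = {}
    for c in components:
        press = float(((y - preds[c]) ** 2).sum())
        dof = max(n - c - 1, 1) if dof_convention == "n-c-1" else n
        out[c] = CrossValidationResult(1.0 - press / ss,
                                       float(np.sqrt(press / dof)), preds[c])
    return out


def select_onc(X: np.ndarray, y: np.ndarray, max_components: int = 10,
               tol: float = 1e-12) -> tuple[int, dict[int, CrossValidationResult]]:
    """Optimal number of components: max Q², ties → smaller SEP, then smaller c."""
    n, p = np.asarray(X).shape
    cmax = min(max_components, n - 2, p)
    comps = list(range(1, cmax + 1))
    res = _loo_multi(X, y, comps)
    best = comps[0]
    for c in comps[1:]:
        r, b = res[c], res[best]
        if r.q2 > b.q2 + tol or (abs(r.q2 - b.q2) <= tol and r.sep < b.sep - tol):
            best = c
    return best, res


def field_contributions(model: PLSModel) -> dict[str, float]:
    """Percent contribution of each field block: Σ|b_j|·sd_j, normalised."""
    raw = {}
    for name in np.unique(model.column_field):
        m = model.column_field == name
        raw[str(name)] = float(np.abs(model.coefficients[m]) @ model.column_sd[m])
    total = sum(raw.values())
    if total == 0:
        return {k: 0.0 for k in raw}
    return {k: 100.0 * v / total for k, v in raw.items()}


def fit_comfa_model(matrix: FieldMatrix, y: np.ndarray,
                    max_components: int = 10):
    """Convenience: select ONC by LOO on a filtered field matrix, then fit.

    Returns (model, onc, cv_results) where cv_results maps component count
    to its LOO result.
    """
    onc, cv = select_onc(matrix.values, y, max_components)
    model = fit_pls(matrix.values, y, onc,
                    column_field=matrix.column_field,
                    column_sd=matrix.column_sd)
    return model, onc, cv
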