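"""Progressive scrambling: stability analysis of a cross-validated QSAR model.

The activities are sorted and partitioned into a number of contiguous bins;
values are permuted within bins, so fewer bins means a stronger perturbation
while the coarse structure of the data survives.  For each perturbation the
squared correlation R²yy between original and perturbed activities is
recorded together with the LOO Q² of the model refit on the perturbed data.
For every component count a quadratic Q² = a + b·R²yy + d·R²yy² is fitted
over all perturbations; the statistics reported at the critical point
R²yy* (default 0.85) are

    Q²s        — the quadratic evaluated at R²yy*,
    cSDEP      — sqrt((1 − Q²s)·SS_tot/(n − c − 1)),
    dQ²/dR²yy  — the quadratic's slope at R²yy*.

A stable model keeps the slope at or below ~1.2 (ideally near 1): a slope
that grows with the component count beyond the true model dimension is the
signature of components that fit redundancy in the training set rather than
structure–activity signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pls import _loo_multi

__all__ = ["ScramblingResult", "scramble_y", "progressive_scrambling"]

PAPER_DEFAULT_CRITICAL_POINT = 0.85
PAPER_DEFAULT_SLOPE_BOUND = 1.2
PAPER_DEFAULT_ROBUSTNESS_BAR = 0.35


@dataclass(frozen=True)
class ScramblingResult:
    """Per-component scrambling statistics plus the raw perturbation cloud."""

    components: tuple[int, ...]
    q2s: dict[int, float]              # quadratic Q² at the critical point
    csdep: dict[int, float]
    slope: dict[int, float]            # dQ²/dR²yy at the critical point
    critical_point: float
    perturbations: pd.DataFrame        # columns: components, r2yy, q2

    def table(self) -> pd.DataFrame:
        """The summary in the conventional (components, Q², cSDEP, slope) shape."""
        return pd.DataFrame({
            "components": list(self.components),
            "q2": [self.q2s[c] for c in self.components],
            "csdep": [self.csdep[c] for c in self.components],
            "dq2_dr2yy": [self.slope[c] for c in self.components],
        })


def scramble_y(y: np.ndarray, n_bins: int, seed) -> tuple[np.ndarray, float]:
    """Permute activities within contiguous bins of the sorted order.

    Returns the perturbed vector (in the original sample order) and R²yy,
    the squared Pearson correlation with the original.  ``n_bins == n`` is
    the identity; ``n_bins == 1`` is a full permutation.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not 1 <= n_bins <= n:
        raise ValueError(f"n_bins must be in [1, {n}]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = np.argsort(y, kind="stable")
    edges = np.linspace(0, n, n_bins + 1).round().astype(int)
    perm = np.empty(n, dtype=int)
    for k in range(n_bins):
        seg = order[edges[k]:edges[k + 1]]
        perm[seg] = rng.permutation(seg)
    y_pert = y[perm]
    if np.std(y_pert) == 0 or np.std(y) == 0:
        r2yy = 1.0
    else:
        r = np.corrcoef(y, y_pert)[0, 1]
        r2yy = float(r * r)
    return y_pert, r2yy


def progressive_scrambling(
    X: np.ndarray,
    y: np.ndarray,
    component_range: Sequence[int] = range(2, 8),
    bins_range: Sequence[int] = range(2, 11),
    reps_per_bin: int = 10,
    critical_point: float = PAPER_DEFAULT_CRITICAL_POINT,
    seed: int = 0,
) -> ScramblingResult:
    """Run the full scrambling protocol over bin granularities and components.

    The unperturbed model (R²yy = 1) is included as an anchor point of the
    quadratic fit.  Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    comps = sorted(set(int(c) for c in component_range))
    rng = np.random.default_rng(seed)
    rows = []
    # anchor: the unperturbed model's own LOO Q²
    base = _loo_multi(X, y, comps)
    for c in comps:
        rows.append((c, 1.0, base[c].q2))
    for n_bins in bins_range:
        for _ in range(reps_per_bin):
            y_pert, r2yy = scramble_y(y, int(n_bins), rng)
            if np.std(y_pert) == 0:
                continue
            res = _loo_multi(X, y_pert, comps)
            for c in comps:
                rows.append((c, r2yy, res[c].q2))
    pert = pd.DataFrame(rows, columns=["components", "r2yy", "q2"])

    ss = float(((y - y.mean()) ** 2).sum())
    n = len(y)
    q2s, csdep, slope = {}, {}, {}
    for c in comps:
        sub = pert[pert.components == c]
        if sub.r2yy.nunique() < 3:
            raise ValueError("fewer than 3 distinct perturbation levels; "
                             "cannot fit the quadratic")
        coef = np.polyfit(sub.r2yy.to_numpy(), sub.q2.to_numpy(), 2)  # d, b, a
        q2s[c] = float(np.polyval(coef, critical_point))
        slope[c] = float(2 * coef[0] * critical_point + coef[1])
        press = max(1.0 - q2s[c], 0.0) * ss
        csdep[c] = float(np.sqrt(press / max(n - c - 1, 1)))
    return ScramblingResult(tuple(comps), q2s, csdep, slope, critical_point, pert)
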