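"""Activity handling: IC50 → pIC50 conversion, censoring, and train/test splitting.

Activities enter the pipeline as IC50 values in nanomolar. They are converted
to pIC50 = 9 − log10(IC50/nM) (i.e. −log10 of the molar concentration).
Assays that cannot resolve an IC50 above a limit (default 100 μM) are kept in
the dataset as left-censored records pinned to pIC50 = 5.0, so that inactive
compounds still inform the model. Note the pin is a convention, not the
algebraic −log10(1e-4 M) = 4; both the limit and the pinned value are
configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivityRecord",
    "SplitDataset",
    "ic50_to_pic50",
    "pic50_to_ic50",
    "read_activity_csv",
    "write_activity_csv",
    "split_train_test",
]

#: IC50 above this (nM) is treated as "not measurable" and censored.
PAPER_DEFAULT_CENSOR_LIMIT_NM = 100_000.0
#: pIC50 assigned to censored records.
PAPER_DEFAULT_CENSOR_VALUE = 5.0


@dataclass(frozen=True)
class ActivityRecord:
    """One compound's activity.

    ``ic50`` is in nM; ``None`` means the assay only established
    "above limit". ``censored`` records carry the pinned pIC50.
    """

    compound_id: str
    ic50: float | None
    pic50: float
    censored: bool
    family: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.pic50):
            raise ValueError(f"{self.compound_id}: non-finite pIC50")


@dataclass(frozen=True)
class SplitDataset:
    """A disjoint training/test partition of compound ids."""

    training_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fraction: float

    def __post_init__(self) -> None:
        if set(self.training_ids) & set(self.test_ids):
            raise ValueError("training and test sets overlap")


def ic50_to_pic50(
    ic50: float | None,
    *,
    above_limit: bool = False,
    censor_limit: float = PAPER_DEFAULT_CENSOR_LIMIT_NM,
    censor_value: float = PAPER_DEFAULT_CENSOR_VALUE,
) -> tuple[float, bool]:
    """Convert an IC50 in nM to (pIC50, censored).

    A record flagged ``above_limit`` (reported as "> X") is censored
    regardless of X; otherwise values exceeding ``censor_limit`` are
    censored.  Censored records get exactly ``censor_value``.
    """
    if above_limit:
        return censor_value, True
    if ic50 is None:
        raise ValueError("ic50 is missing and record is not flagged above-limit")
    if not (isinstance(ic50, (int, float)) and math.isfinite(ic50)) or ic50 <= 0:
        raise ValueError(f"ic50 must be a positive finite number, got {ic50!r}")
    if ic50 > censor_limit:
        return censor_value, True
    return 9.0 - math.log10(float(ic50)), False


def pic50_to_ic50(pic50: float) -> float:
    """Inverse of :func:`ic50_to_pic50` for non-censored values (nM)."""
    return 10.0 ** (9.0 - pic50)


def read_activity_csv(
    path,
    *,
    censor_limit: float = PAPER_DEFAULT_CENSOR_LIMIT_NM,
    censor_value: float = PAPER_DEFAULT_CENSOR_VALUE,
) -> list[ActivityRecord]:
    """Read a compound_id,ic50_nM[,family] table.

    ``ic50_nM`` entries of the form ``>100000`` mark above-limit censoring.
    """
    df = pd.read_csv(path, dtype={"compound_id": str})
    if "compound_id" not in df.columns or "ic50_nM" not in df.columns:
        raise ValueError("activity CSV needs columns compound_id, ic50_nM")
    records = []
    for row in df.itertuples(index=False):
        raw = str(row.ic50_nM).strip()
        above = raw.startswith(">")
        ic50 = None if above else float(raw)
        try:
            pic50, censored = ic50_to_pic50(
                ic50, above_limit=above,
                censor_limit=censor_limit, censor_value=censor_value,
            )
        except ValueError as exc:
            raise ValueError(f"record {row.compound_id}: {exc}") from exc
        family = getattr(row, "family", None)
        family = None if family is None or pd.isna(family) else str(family)
        records.append(ActivityRecord(str(row.compound_id), ic50, pic50, censored, family))
    return records


def write_activity_csv(records: Sequence[ActivityRecord], path,
                       split: SplitDataset | None = None,
                       censor_limit: float = PAPER_DEFAULT_CENSOR_LIMIT_NM) -> None:
    test = set(split.test_ids) if split is not None else set()
    rows = []
    for r in records:
        rows.append({
            "compound_id": r.compound_id,
            "ic50_nM": f">{censor_limit:g}" if r.ic50 is None else r.ic50,
            "family": r.family or "",
            "pic50": r.pic50,
            "censored": r.censored,
            "split": ("test" if r.compound_id in test else "train") if split else "",
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def _solve_test_size(n: int, fraction: float) -> int:
    # test = round(fraction * train) with train = n - test
    if fraction <= 0:
        return 0
    t = int(round(fraction * n / (1.0 + fraction)))
    for cand in (t, t - 1, t + 1):
        if 0 <= cand < n and cand == round(fraction * (n - cand)):
            return cand
    return t


def split_train_test(
    records: Sequence[ActivityRecord],
    fraction: float = 0.10,
    seed: int = 0,
) -> SplitDataset:
    """Stratified train/test split under the test = round(fraction × train) rule.

    Stratification is by (family, activity quartile).  The split is repaired
    deterministically so that, whenever the input spans [5, 9] in pIC50,
    both sets do too, and every declared family appears in both sets.
    """
    n = len(records)
    if fraction < 0 or fraction >= 1:
        raise ValueError("fraction must be in [0, 1)")
    if fraction > 0 and n < 20:
        raise ValueError("need at least 20 records to split")
    pic = np.array([r.pic50 for r in records])
    if fraction > 0 and pic.max() - pic.min() < 2.0:
        raise ValueError("activity span below 2 log units; split criteria unsatisfiable")

    n_test = _solve_test_size(n, fraction)
    ids = [r.compound_id for r in records]
    if n_test == 0:
        return SplitDataset(tuple(ids), (), fraction)

    rng = np.random.default_rng(seed)
    quart = np.searchsorted(np.quantile(pic, [0.25, 0.5, 0.75]), pic, side="right")
    strata: dict[tuple, list[int]] = {}
    for i, r in enumerate(records):
        strata.setdefault((r.family or "", int(quart[i])), []).append(i)

    # proportional allocation with largest-remainder rounding
    keys = sorted(strata)
    exact = np.array([len(strata[k]) * n_test / n for k in keys])
    counts = np.floor(exact).astype(int)
    rem = n_test - counts.sum()
    order = np.argsort(-(exact - counts))
    for j in order[:rem]:
        counts[j] += 1
    test_idx: set[int] = set()
    for k, c in zip(keys, counts):
        pool = strata[k]
        c = min(c, max(0, len(pool) - 1))  # keep each stratum represented in training
        if c > 0:
            test_idx.update(rng.choice(pool, size=c, replace=False).tolist())
    # top up if capping lost slots
    while len(test_idx) < n_test:
        cand = int(rng.integers(0, n))
        if cand not in test_idx:
            test_idx.add(cand)

    test_idx = _repair_split(records, pic, test_idx, rng)
    test_ids = tuple(ids[i] for i in sorted(test_idx))
    train_ids = tuple(ids[i] for i in range(n) if i not in test_idx)
    return SplitDataset(train_ids, test_ids, fraction)


def _repair_split(records, pic, test_idx: set[int], rng) -> set[int]:
    """Ensure span and family coverage on both sides of the split.

    Requirements: where the input spans [5, 9], each side must hold a
    record with pIC50 ≤ 5 and one with pIC50 ≥ 9; every family with at
    least two members must appear on both sides.  A stratified draw that
    already satisfies everything is returned untouched.  Otherwise the
    test set is rebuilt: an exact minimum set cover over the requirement
    bitmasks (dynamic programming over masks — the number of requirements
    is tiny) seeds the test set, preferring records from the original
    draw, and the remaining slots are refilled in draw order; no record is
    admitted if that would strip the training side of its last holder of
    any requirement.  Deterministic; raises when genuinely unsatisfiable.
    """
    n = len(records)
    n_test = len(test_idx)
    spans_5_9 = pic.min() <= 5.0 and pic.max() >= 9.0

    reqs: list[tuple[str, frozenset[int]]] = []
    if spans_5_9:
        reqs.append(("low", frozenset(i for i in range(n) if pic[i] <= 5.0)))
        reqs.append(("high", frozenset(i for i in range(n) if pic[i] >= 9.0)))
    for f in sorted({r.family for r in records if r.family}):
        members = frozenset(i for i in range(n) if records[i].family == f)
        if len(members) >= 2:
            reqs.append((f, members))
    for name, members in reqs:
        if len(members) < 2:
            raise ValueError(
                f"split criteria unsatisfiable: only {len(members)} record(s) "
                f"cover the {name!r} requirement, but both sets need one")

    def satisfied(te: set[int]) -> bool:
        return all(members & te and members - te for _, members in reqs)

    if satisfied(test_idx):
        return test_idx

    R = len(reqs)
    full = (1 << R) - 1
    preference = sorted(test_idx) + [i for i in range(n) if i not in test_idx]
    sig = {i: sum(1 << k for k, (_, m) in enumerate(reqs) if i in m)
           for i in range(n)}

    # exact set cover over signatures: cost[mask] = fewest records
    available = sorted({s for s in sig.values() if s})
    cost = [0] + [n + 1] * full
    back: dict[int, tuple[int, int]] = {}
    for mask in range(1, full + 1):
        for s in available:
            if s & mask:
                c = cost[mask & ~s] + 1
                if c < cost[mask]:
                    cost[mask] = c
                    back[mask] = (s, mask & ~s)
    if cost[full] > n_test:
        raise ValueError(
            "could not satisfy split criteria: the test set is too small to "
            "cover the activity span and family requirements")

    cover_sigs = []
    mask = full
    while mask:
        s, mask = back[mask]
        cover_sigs.append(s)

    chosen: list[int] = []

    def admissible(i: int) -> bool:
        # training side keeps at least one holder of every requirement
        return all(len(m - set(chosen) - {i}) >= 1
                   for _, m in reqs if i in m)

    for s in cover_sigs:
        pick = next((i for i in preference
                     if i not in chosen and sig[i] == s and admissible(i)), None)
        if pick is None:  # signature exhausted by train-side constraints
            pick = next((i for i in preference
                         if i not in chosen and sig[i] & s == s
                         and admissible(i)), None)
        if pick is None:
            raise ValueError(
                "could not satisfy split criteria (training coverage exhausted)")
        chosen.append(pick)
    for i in preference:
        if len(chosen) >= n_test:
            break
        if i not in chosen and admissible(i):
            chosen.append(i)
    out = set(chosen)
    if len(out) < n_test or not satisfied(out):
        raise ValueError(
            "could not satisfy split criteria (span/family coverage)")
    return out
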