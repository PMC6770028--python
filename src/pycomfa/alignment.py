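"""Docking-pose alignment: salt-bridge filtering and representative-pose choice.

Aminergic-GPCR antagonists anchor through an ionic contact between a
protonatable ligand nitrogen and the conserved TM3 aspartate (3.32).  The
alignment stage therefore keeps, for each compound, only docking poses whose
protonatable nitrogen sits within a salt-bridge distance of the anchor
carboxylate, and then picks one representative pose per compound with a
deterministic key: shortest anchor distance, then best heavy-atom overlap
with the reference pose (the most active compound of the same family), then
lowest pose index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .activities import ActivityRecord
from .structures import AnchorSite, LigandPose

log = logging.getLogger(__name__)

__all__ = [
    "AlignedDataset",
    "find_protonatable_nitrogens",
    "anchor_distance",
    "salt_bridge_filter",
    "select_representative_pose",
    "build_aligned_dataset",
]

#: Typical donor–acceptor cutoff for an ionic contact.
PAPER_DEFAULT_MAX_ANCHOR_DIST = 4.0


@dataclass(frozen=True)
class AlignedDataset:
    """One selected, filter-passing pose per compound plus its activity."""

    poses: tuple[LigandPose, ...]
    activities: tuple[ActivityRecord, ...]
    anchor: AnchorSite
    excluded: tuple[tuple[str, str], ...] = ()  # (compound_id, reason)

    def __post_init__(self) -> None:
        ids = [p.compound_id for p in self.poses]
        if len(ids) != len(set(ids)):
            raise ValueError("more than one pose per compound")
        if [a.compound_id for a in self.activities] != ids:
            raise ValueError("pose/activity id mismatch")
        frames = {p.frame_id for p in self.poses}
        if len(frames) > 1:
            raise ValueError(f"poses span multiple frames: {frames}")

    def __len__(self) -> int:
        return len(self.poses)

    @property
    def compound_ids(self) -> tuple[str, ...]:
        return tuple(p.compound_id for p in self.poses)

    @property
    def pic50(self) -> np.ndarray:
        return np.array([a.pic50 for a in self.activities])


def find_protonatable_nitrogens(pose: LigandPose) -> list[int]:
    """Indices of the nitrogens eligible for the ionic anchor contact.

    Cationic nitrogens qualify outright.  If a molecule carries none, the
    fallback accepts neutral sp3 amine nitrogens that are not amide- or
    aryl-conjugated (those are not basic at physiological pH).
    """
    charged = [i for i, a in enumerate(pose.atoms)
               if a.element.capitalize() == "N" and a.formal_charge > 0]
    if charged:
        return charged
    basic = []
    for i, a in enumerate(pose.atoms):
        if a.element.capitalize() != "N" or a.formal_charge != 0:
            continue
        nbrs = pose.neighbors(i)
        if any(o != 1.0 for _, o in nbrs):
            continue  # imine/nitrile/aromatic N
        conjugated = False
        for j, _ in nbrs:
            nb = pose.atoms[j]
            if nb.element.capitalize() == "C" and nb.atom_class in ("sp2-C", "aromatic-C"):
                conjugated = True  # amide or aniline nitrogen
        if not conjugated:
            basic.append(i)
    return basic


def anchor_distance(pose: LigandPose, anchor: AnchorSite) -> float:
    """Min distance from any protonatable N to either carboxylate oxygen (Å)."""
    nitrogens = find_protonatable_nitrogens(pose)
    if not nitrogens:
        return float("inf")
    npos = pose.coords[nitrogens]
    d = np.linalg.norm(npos[:, None, :] - anchor.oxygen_coords[None, :, :], axis=-1)
    return float(d.min())


def salt_bridge_filter(
    poses: Sequence[LigandPose],
    anchor: AnchorSite,
    max_dist: float = PAPER_DEFAULT_MAX_ANCHOR_DIST,
) -> list[LigandPose]:
    """Keep poses whose protonatable N contacts the anchor carboxylate."""
    return [p for p in poses if anchor_distance(p, anchor) <= max_dist]


def _overlap_score(pose: LigandPose, reference: LigandPose, tol: float = 1.5) -> float:
    """Fraction of reference heavy atoms with a same-class atom within tol Å."""
    ref_heavy = [(a.atom_class, a.position) for a in reference.atoms
                 if a.element.capitalize() != "H"]
    if not ref_heavy:
        return 0.0
    by_class: dict[str, list] = {}
    for a in pose.atoms:
        if a.element.capitalize() != "H":
            by_class.setdefault(a.atom_class, []).append(a.position)
    hit = 0
    for cls, rpos in ref_heavy:
        cand = by_class.get(cls)
        if cand and np.min(np.linalg.norm(np.array(cand) - rpos, axis=1)) <= tol:
            hit += 1
    return hit / len(ref_heavy)


def select_representative_pose(
    passing: Sequence[LigandPose],
    anchor: AnchorSite,
    reference: LigandPose | None = None,
) -> LigandPose:
    """Deterministic pose choice among filter-passing poses.

    Key: (anchor distance, −overlap with reference, pose_index), minimised.
    """
    if not passing:
        raise ValueError("no passing pose to select from")
    def key(p: LigandPose):
        overlap = _overlap_score(p, reference) if reference is not None else 0.0
        return (round(anchor_distance(p, anchor), 9), -round(overlap, 9), p.pose_index)
    return min(passing, key=key)


def build_aligned_dataset(
    poses: Sequence[LigandPose],
    activities: Sequence[ActivityRecord],
    anchor: AnchorSite,
    max_dist: float = PAPER_DEFAULT_MAX_ANCHOR_DIST,
) -> AlignedDataset:
    """Filter and select one pose per compound; drop and report failures.

    The most active filter-passing compound of each family provides the
    overlap reference for the rest of that family.
    """
    act_by_id: Mapping[str, ActivityRecord] = {a.compound_id: a for a in activities}
    by_compound: dict[str, list[LigandPose]] = {}
    for p in poses:
        by_compound.setdefault(p.compound_id, []).append(p)

    passing = {cid: salt_bridge_filter(ps, anchor, max_dist)
               for cid, ps in by_compound.items()}

    # per-family reference: most active compound with a passing pose
    refs: dict[str, LigandPose] = {}
    for fam in {a.family for a in activities if a.family}:
        cands = [a for a in activities
                 if a.family == fam and passing.get(a.compound_id)]
        if cands:
            top = max(cands, key=lambda a: (a.pic50, a.compound_id))
            refs[fam] = select_representative_pose(passing[top.compound_id], anchor)

    selected, kept_acts, excluded = [], [], []
    for cid in sorted(by_compound):
        act = act_by_id.get(cid)
        if act is None:
            excluded.append((cid, "no activity record"))
            continue
        if not passing[cid]:
            reason = ("no protonatable nitrogen"
                      if not any(find_protonatable_nitrogens(p) for p in by_compound[cid])
                      else f"no pose within {max_dist} Å of anchor")
            log.info("excluding %s: %s", cid, reason)
            excluded.append((cid, reason))
            continue
        ref = refs.get(act.family) if act.family else None
        selected.append(select_representative_pose(passing[cid], anchor, ref))
        kept_acts.append(act)
    return AlignedDataset(tuple(selected), tuple(kept_acts), anchor, tuple(excluded))
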