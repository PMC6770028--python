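"""Empirical point charges: PEOE sigma charges and simple-Hückel pi charges.

The sigma component is the Gasteiger–Marsili partial equalization of orbital
electronegativity (PEOE): each atom carries an electronegativity that is
quadratic in its charge, chi(q) = a + b q + c q^2, and in each sweep every
bond transfers charge from the less to the more electronegative end,
normalised by the donor's cation electronegativity and damped geometrically
(damping^k at sweep k).  The pi component is a per-fragment Hückel
calculation on the conjugated subsystems with a conventional heteroatom
(h, k) parameter table; the pi population difference against the atom's
core charge is added on top of the sigma charge.

Combined, this is the classical "Gasteiger–Hückel" scheme of 3D-QSAR
practice.  The exact commercial parameterisation of the Hückel part is not
public, so the plain PEOE mode is the reproducible default and the Hückel
term is an explicit opt-in.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np

from .structures import LigandPose

log = logging.getLogger(__name__)

__all__ = ["gasteiger_sigma_charges", "huckel_pi_charges", "assign_charges"]

# Gasteiger–Marsili PEOE parameters (a, b, c), eV, by (element, hybridisation).
# chi(q) = a + b*q + c*q^2; cation chi = a + b + c except hydrogen (20.02).
PEOE_PARAMS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("H", "any"): (7.17, 6.24, -0.56),
    ("C", "sp3"): (7.98, 9.18, 1.88),
    ("C", "sp2"): (8.79, 9.32, 1.51),
    ("C", "sp"): (10.39, 9.45, 0.73),
    ("N", "sp3"): (11.54, 10.82, 1.36),
    ("N", "sp2"): (12.87, 11.15, 0.85),
    ("N", "sp"): (15.68, 11.70, -0.27),
    ("O", "sp3"): (14.18, 12.92, 1.39),
    ("O", "sp2"): (17.07, 13.79, 0.47),
    ("F", "any"): (14.66, 13.85, 2.31),
    ("Cl", "any"): (11.00, 9.69, 1.35),
    ("Br", "any"): (10.08, 8.47, 1.16),
    ("I", "any"): (9.90, 7.96, 0.96),
    ("S", "sp3"): (10.14, 9.13, 1.38),
    ("S", "sp2"): (10.14, 9.13, 1.38),
}
_H_CATION_CHI = 20.02


def _hybridisation(pose: LigandPose, i: int) -> str:
    orders = [o for _, o in pose.neighbors(i)]
    if any(o == 3.0 for o in orders) or sum(1 for o in orders if o == 2.0) >= 2:
        return "sp"
    if any(o in (2.0, 1.5) for o in orders):
        return "sp2"
    return "sp3"


def _peoe_params(pose: LigandPose) -> np.ndarray:
    out = np.empty((len(pose.atoms), 3))
    for i, atom in enumerate(pose.atoms):
        el = atom.element.capitalize()
        key = (el, "any") if (el, "any") in PEOE_PARAMS else (el, _hybridisation(pose, i))
        try:
            out[i] = PEOE_PARAMS[key]
        except KeyError:
            raise ValueError(
                f"no PEOE electronegativity parameters for atom {i} "
                f"({atom.element}, {key[1]})") from None
    return out


def gasteiger_sigma_charges(
    pose: LigandPose,
    iterations: int = 8,
    damping: float = 0.5,
    seed_charges: np.ndarray | None = None,
) -> np.ndarray:
    """PEOE sigma charges for one pose.

    Seeded with formal charges (or ``seed_charges``); every sweep applies all
    bond transfers simultaneously from a charge snapshot, so the result is
    invariant under atom reordering.  Total charge is conserved exactly.
    """
    n = len(pose.atoms)
    abc = _peoe_params(pose)
    q = np.array([float(a.formal_charge) for a in pose.atoms]) \
        if seed_charges is None else np.asarray(seed_charges, dtype=float).copy()
    if n == 0:
        return q
    chi_plus = abc.sum(axis=1)
    for i, atom in enumerate(pose.atoms):
        if atom.element.capitalize() == "H":
            chi_plus[i] = _H_CATION_CHI
    bonds = np.array([(i, j) for i, j, _ in pose.bonds], dtype=int).reshape(-1, 2)
    for k in range(1, iterations + 1):
        chi = abc[:, 0] + abc[:, 1] * q + abc[:, 2] * q * q
        dq = np.zeros(n)
        f = damping ** k
        for i, j in bonds:
            if chi[j] > chi[i]:
                d = (chi[j] - chi[i]) / chi_plus[i] * f
            else:
                d = -(chi[i] - chi[j]) / chi_plus[j] * f
            # electrons flow to the more electronegative atom
            dq[i] += d
            dq[j] -= d
        q += dq
    return q


# Hückel heteroatom parameters: diagonal h (alpha + h*beta) and bond factor k,
# keyed by (element, n_pi_electrons_contributed).  Conventional textbook set.
HUCKEL_PARAMS: dict[tuple[str, int], tuple[float, float]] = {
    ("C", 1): (0.0, 1.0),
    ("C", 0): (0.0, 1.0),     # carbocation centre
    ("N", 1): (0.5, 1.0),     # pyridine-type
    ("N", 2): (1.5, 0.8),     # pyrrole/amide-type
    ("O", 1): (1.0, 1.0),     # carbonyl
    ("O", 2): (2.0, 0.8),     # ether/furan/enol
    ("S", 1): (0.5, 0.6),
    ("S", 2): (1.3, 0.6),
    ("F", 2): (3.0, 0.7),
    ("Cl", 2): (2.0, 0.4),
    ("Br", 2): (1.5, 0.3),
}
# protonated pyridine-type nitrogen
_HUCKEL_N_CATION = (2.0, 1.0)


def _pi_centers(pose: LigandPose) -> dict[int, int]:
    """Map atom index -> pi electrons contributed, for conjugated atoms.

    Atoms carrying a double/triple/aromatic bond contribute one electron
    (zero for a bare carbocation centre); single-bonded N/O/S/halogen
    neighbours of such atoms join with their lone pair (two electrons).
    sp3 cationic nitrogens stay out of the pi system.
    """
    centers: dict[int, int] = {}
    for i, atom in enumerate(pose.atoms):
        orders = [o for _, o in pose.neighbors(i)]
        el = atom.element.capitalize()
        if any(o in (1.5, 2.0, 3.0) for o in orders):
            centers[i] = 0 if (el == "C" and atom.formal_charge > 0) else 1
    for i, atom in enumerate(pose.atoms):
        if i in centers:
            continue
        el = atom.element.capitalize()
        if el not in ("N", "O", "S", "F", "Cl", "Br"):
            continue
        if el == "N" and atom.formal_charge > 0:
            continue  # sp3 ammonium-type: sigma charge only
        if any(j in centers for j, _ in pose.neighbors(i)):
            centers[i] = 2
    return centers


def huckel_pi_charges(pose: LigandPose) -> np.ndarray:
    """Per-atom pi-charge increments from simple Hückel theory.

    Each conjugated fragment is solved as an eigenproblem of the topological
    alpha/beta matrix; the increment is (core pi charge) − (pi population),
    with the core including the atom's formal charge, so the increments sum
    to each fragment's net pi charge.  Open-shell fragments are skipped.
    """
    n = len(pose.atoms)
    inc = np.zeros(n)
    centers = _pi_centers(pose)
    if not centers:
        return inc

    # connected components over bonds between pi centers
    seen: set[int] = set()
    adj: dict[int, list[int]] = {i: [] for i in centers}
    for i, j, _ in pose.bonds:
        if i in centers and j in centers:
            adj[i].append(j)
            adj[j].append(i)
    for start in sorted(centers):
        if start in seen:
            continue
        frag = []
        stack = [start]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            frag.append(u)
            stack.extend(adj[u])
        if len(frag) < 2:
            continue
        frag.sort()
        inc[frag] += _solve_fragment(pose, frag, centers)
    return inc


def _solve_fragment(pose: LigandPose, frag: list[int],
                    centers: dict[int, int]) -> np.ndarray:
    idx = {a: k for k, a in enumerate(frag)}
    m = len(frag)
    h = np.zeros(m)
    kfac = np.ones(m)
    n_elec = 0
    for a in frag:
        atom = pose.atoms[a]
        el = atom.element.capitalize()
        ne = centers[a]
        n_elec += ne
        if el == "N" and atom.formal_charge > 0:
            h[idx[a]], kfac[idx[a]] = _HUCKEL_N_CATION
        else:
            try:
                h[idx[a]], kfac[idx[a]] = HUCKEL_PARAMS[(el, ne)]
            except KeyError:
                raise ValueError(
                    f"no Hückel parameters for atom {a} ({el}, {ne} pi e)") from None
    if n_elec % 2:
        log.warning("open-shell pi fragment (%d electrons) skipped: atoms %s",
                    n_elec, frag)
        return np.zeros(m)
    H = np.zeros((m, m))
    np.fill_diagonal(H, h)
    for i, j, _ in pose.bonds:
        if i in idx and j in idx:
            H[idx[i], idx[j]] = H[idx[j], idx[i]] = kfac[idx[i]] * kfac[idx[j]]
    evals, evecs = np.linalg.eigh(H)
    # beta < 0: orbitals with the largest eigenvalue are lowest in energy
    order = np.argsort(-evals)
    evals, evecs = evals[order], evecs[:, order]
    pop = np.zeros(m)
    remaining = n_elec
    k = 0
    while remaining > 0 and k < m:
        # fill whole degenerate shells together so symmetry survives
        shell = [k]
        while k + len(shell) < m and abs(evals[k + len(shell)] - evals[k]) < 1e-8:
            shell.append(k + len(shell))
        cap = 2 * len(shell)
        elec = min(remaining, cap)
        dens = (evecs[:, shell] ** 2).sum(axis=1)
        pop += dens * (elec / len(shell))
        remaining -= elec
        k += len(shell)
    core = np.array([centers[a] + pose.atoms[a].formal_charge for a in frag],
                    dtype=float)
    return core - pop


def assign_charges(
    pose: LigandPose,
    method: Literal["peoe", "gh"] = "peoe",
    iterations: int = 8,
    damping: float = 0.5,
) -> LigandPose:
    """Return a copy of the pose with partial charges assigned.

    ``peoe`` (default): pure Gasteiger sigma charges seeded with all formal
    charges.  ``gh``: Gasteiger–Hückel — formal charges of atoms inside a
    conjugated system are booked to the pi calculation and the sigma stage
    is seeded with the remaining (sigma-frame) formal charges, so the total
    still sums to the molecular net charge.
    """
    formal = np.array([float(a.formal_charge) for a in pose.atoms])
    if method == "peoe":
        q = gasteiger_sigma_charges(pose, iterations, damping)
    elif method == "gh":
        centers = _pi_centers(pose)
        seed = formal.copy()
        for i in centers:
            seed[i] = 0.0
        q = gasteiger_sigma_charges(pose, iterations, damping, seed_charges=seed)
        q = q + huckel_pi_charges(pose)
    else:
        raise ValueError(f"unknown charge method {method!r}")
    total = q.sum()
    if abs(total - formal.sum()) > 1e-6:
        raise AssertionError(
            f"charge conservation violated: {total} vs {formal.sum()}")
    return pose.with_charges(q)
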