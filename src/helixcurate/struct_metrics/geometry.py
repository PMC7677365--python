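"""Superposition, RMSD, distances, B-factor comparison, clashes,
side-chain rotation."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from ..errors import GeometryError, SelectionError
from .sasa import vdw_radius
from .select import Selector
from .types import Atom, Clash, ClashReport, Structure, Superposition

__all__ = [
    "kabsch_superpose",
    "rmsd_selection",
    "min_group_distance",
    "bfactor_group_percent_diff",
    "clash_scan",
    "sidechain_rotation",
]

#: ring heavy atoms used for plane fits, per aromatic residue type
AROMATIC_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


def kabsch_superpose(mobile: np.ndarray,
                     reference: np.ndarray) -> Superposition:
    """Least-squares optimal proper rotation + translation (Kabsch).

    Maps ``mobile`` onto ``reference``; a reflection-only optimum is
    corrected to a proper rotation (det +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise SelectionError(
            f"coordinate count mismatch: {mobile.shape} vs {reference.shape}"
        )
    if mobile.shape[0] < 3:
        raise GeometryError("need at least 3 atom pairs")

    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd,
                         n_atoms=mobile.shape[0])


def _matched_pairs(a: Structure, b: Structure, sel: Selector):
    """Atom pairs matched by (chain, residue number, atom name)."""
    def key(atom: Atom):
        return (atom.chain_id, atom.residue_number, atom.atom_name)

    bmap = {key(atom): atom for atom in b.atoms if sel.matches(atom)}
    pairs = [
        (atom, bmap[key(atom)])
        for atom in a.atoms
        if sel.matches(atom) and key(atom) in bmap
    ]
    return pairs


def rmsd_selection(
    a: Structure, b: Structure, sel: Selector, superpose: bool = True
) -> float:
    """RMSD over matched selected atoms, Kabsch-fitted when requested."""
    pairs = _matched_pairs(a, b, sel)
    if not pairs:
        raise SelectionError("no matched atom pairs")
    pa = np.array([p[0].position for p in pairs])
    pb = np.array([p[1].position for p in pairs])
    if superpose:
        return kabsch_superpose(pb, pa).rmsd
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def min_group_distance(
    structure: Structure, sel_a: Selector, sel_b: Selector
) -> tuple[float, tuple[Atom, Atom]]:
    """Minimum cross-pair distance between two selections."""
    ga = sel_a.apply(structure)
    gb = sel_b.apply(structure)
    if len(ga) == 0 or len(gb) == 0:
        raise SelectionError("empty selection")
    d = cdist(ga.coords(), gb.coords())
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return float(d[i, j]), (ga.atoms[i], gb.atoms[j])


def bfactor_group_percent_diff(
    a: Structure, b: Structure, residues: Selector
) -> float:
    """100 x (mean B of a - mean B of b) / mean B of b over a selection."""
    ba = [at.b_factor for at in a.atoms if residues.matches(at)]
    bb = [at.b_factor for at in b.atoms if residues.matches(at)]
    if not ba or not bb:
        raise SelectionError("selection empty in one of the structures")
    mean_a, mean_b = float(np.mean(ba)), float(np.mean(bb))
    return 100.0 * (mean_a - mean_b) / mean_b


def clash_scan(
    a: Structure, b: Structure, overlap_threshold: float = 0.4,
    radii_overrides: dict[str, float] | None = None,
) -> ClashReport:
    """Cross-structure van der Waals overlaps above a threshold.

    Hydrogens are excluded; pairs are sorted by decreasing overlap.
    The structures must already share a coordinate frame.
    """
    heavy_a = [at for at in a.atoms if not at.is_hydrogen()]
    heavy_b = [at for at in b.atoms if not at.is_hydrogen()]
    clashes: list[Clash] = []
    if heavy_a and heavy_b:
        ra = np.array([vdw_radius(at.element, radii_overrides)
                       for at in heavy_a])
        rb = np.array([vdw_radius(at.element, radii_overrides)
                       for at in heavy_b])
        ca = np.array([at.position for at in heavy_a])
        cb = np.array([at.position for at in heavy_b])
        cutoff = ra.max() + rb.max() - overlap_threshold
        tree = cKDTree(cb)
        for i, neighbors in enumerate(tree.query_ball_point(ca, cutoff)):
            for j in neighbors:
                dist = float(np.linalg.norm(ca[i] - cb[j]))
                overlap = float(ra[i] + rb[j] - dist)
                if overlap > overlap_threshold:
                    clashes.append(
                        Clash(heavy_a[i], heavy_b[j], dist, overlap)
                    )
    clashes.sort(key=lambda c: -c.overlap)
    return ClashReport(clashes=clashes, threshold=overlap_threshold)


def _ring_atoms(atoms: list[Atom]) -> list[Atom] | None:
    if not atoms:
        return None
    names = AROMATIC_RING_ATOMS.get(atoms[0].residue_name)
    if names is None:
        return None
    ring = [a for a in atoms if a.atom_name in names]
    return ring if len(ring) >= 3 else None


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-9:
        raise GeometryError("ring atoms collinear; no unique plane")
    return vt[2]


def _vector_axis(atoms: list[Atom]) -> np.ndarray:
    by_name = {a.atom_name: a for a in atoms}
    if "CB" not in by_name:
        raise GeometryError("no CB atom for side-chain vector")
    cb = by_name["CB"].position
    sidechain = [a for a in atoms
                 if a.atom_name not in {"N", "CA", "C", "O", "OXT", "CB"}
                 and not a.is_hydrogen()]
    if not sidechain:
        raise GeometryError("no terminal side-chain heavy atom")
    tip = max(sidechain,
              key=lambda a: float(np.linalg.norm(a.position - cb)))
    return tip.position - cb


def sidechain_rotation(
    res_a: list[Atom], res_b: list[Atom],
    frame: Superposition | None = None,
) -> float:
    """Angle between two residues' side-chain orientations (degrees).

    Aromatic residues compare best-fit ring-plane normals (range 0-90);
    others compare the CB -> most-distal heavy atom vectors (0-180).
    ``frame`` is applied to res_b before comparison.
    """
    if frame is not None:
        res_b = [
            Atom(a.element, a.atom_name, a.residue_name, a.residue_number,
                 a.chain_id, frame.apply(a.position.reshape(1, 3))[0],
                 a.b_factor, a.occupancy)
            for a in res_b
        ]
    ring_a, ring_b = _ring_atoms(res_a), _ring_atoms(res_b)
    if ring_a is not None and ring_b is not None:
        na = _plane_normal(np.array([a.position for a in ring_a]))
        nb = _plane_normal(np.array([a.position for a in ring_b]))
        cosang = abs(float(na @ nb)) / (
            np.linalg.norm(na) * np.linalg.norm(nb)
        )
        return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    va, vb = _vector_axis(res_a), _vector_axis(res_b)
    cosang = float(va @ vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
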