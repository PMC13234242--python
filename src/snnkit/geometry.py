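"""Metric geometry on structures: torsions, contacts, hydrogen bonds,
turns, and rigid-body superposition with iterative outlier rejection.

All angles are IUPAC-signed torsions in degrees on (−180, +180].
Contacts default to the 4 Å heavy-atom cutoff used for succinimide
environment analysis; hydrogen bonds default to the donor–acceptor
< 3.5 Å / donor–H–acceptor > 140° criteria.  Crystal structures carry
no hydrogens, so a distance-only "crystal mode" is the default for
H-bond style checks, with an optional inferred-amide-H mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import Atom, Residue, Structure

__all__ = [
    "GeometryError",
    "DihedralSet",
    "ContactRecord",
    "HBond",
    "TurnRecord",
    "SuperpositionResult",
    "dihedral",
    "backbone_dihedrals",
    "sidechain_dihedrals",
    "contacts",
    "hydrogen_bonds",
    "detect_turns",
    "superpose",
    "pair_ca_atoms",
    "CHI1_ATOMS",
    "CHI2_ATOMS",
]


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# torsions

def dihedral(p1, p2, p3, p4) -> float:
    """IUPAC-signed torsion angle p1-p2-p3-p4 in degrees, in (−180, +180].

    Raises :class:`GeometryError` when consecutive points coincide or the
    middle triplet is collinear (torsion undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < 1e-9:
            raise GeometryError("coincident consecutive points; torsion undefined")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("collinear triplet; torsion undefined")
    b2n = b2 / np.linalg.norm(b2)
    angle = math.degrees(math.atan2(np.dot(np.cross(n1, n2), b2n), np.dot(n1, n2)))
    if angle <= -180.0:
        angle += 360.0
    return angle


@dataclass
class DihedralSet:
    """Backbone and side-chain torsions for one residue; ``None`` = undefined."""

    phi: float | None = None
    psi: float | None = None
    omega: float | None = None
    chi1: float | None = None
    chi2: float | None = None


def _tors(*atoms: Atom | None) -> float | None:
    if any(a is None for a in atoms):
        return None
    try:
        return dihedral(*(a.coords for a in atoms))  # type: ignore[union-attr]
    except GeometryError:
        return None


def _neighbours(structure: Structure, chain: str, resnum: int) -> tuple[Residue | None, Residue, Residue | None]:
    residues = structure.chain(chain)
    idx = next((i for i, r in enumerate(residues) if r.number == resnum), None)
    if idx is None:
        raise GeometryError(f"no residue {resnum} in chain {chain!r}")
    res = residues[idx]
    prev_res = residues[idx - 1] if idx > 0 and residues[idx - 1].number == resnum - 1 else None
    next_res = (
        residues[idx + 1]
        if idx + 1 < len(residues) and residues[idx + 1].number == resnum + 1
        else None
    )
    return prev_res, res, next_res


def backbone_dihedrals(structure: Structure, chain: str, resnum: int) -> DihedralSet:
    """φ, ψ, ω for one residue; angles at chain termini are ``None``.

    φ = C(i−1)–N–CA–C, ψ = N–CA–C–N(i+1), ω = CA(i−1)–C(i−1)–N–CA.
    """
    prev_res, res, next_res = _neighbours(structure, chain, resnum)
    out = DihedralSet()
    n, ca, c = res.get("N"), res.get("CA"), res.get("C")
    if prev_res is not None:
        out.phi = _tors(prev_res.get("C"), n, ca, c)
        out.omega = _tors(prev_res.get("CA"), prev_res.get("C"), n, ca)
    if next_res is not None:
        out.psi = _tors(n, ca, c, next_res.get("N"))
    return out


# χ1 fourth atom and χ2 fourth atom per residue type.  The succinimide SNN
# keeps the asparagine mapping (CB→CB, CG→CG, OD1→OD1), so its ring
# χ-equivalents come out of the same formula.
CHI1_ATOMS: dict[str, str] = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "PRO": "CG", "TRP": "CG", "TYR": "CG", "ILE": "CG1", "VAL": "CG1",
    "SER": "OG", "THR": "OG1", "CYS": "SG", "SNN": "CG",
}
CHI2_ATOMS: dict[str, str] = {
    "ARG": "CD", "ASN": "OD1", "ASP": "OD1", "GLN": "CD", "GLU": "CD",
    "HIS": "ND1", "LEU": "CD1", "LYS": "CD", "MET": "SD", "PHE": "CD1",
    "PRO": "CD", "TRP": "CD1", "TYR": "CD1", "ILE": "CD1", "SNN": "OD1",
}


def sidechain_dihedrals(residue: Residue) -> tuple[float | None, float | None]:
    """(χ1, χ2) of a residue; ``None`` where atoms are missing or undefined.

    χ1 = N–CA–CB–X with X from :data:`CHI1_ATOMS`; χ2 = CA–CB–X–Y with Y
    from :data:`CHI2_ATOMS` (CA–CB–CG–OD1 for Asn and for the SNN ring).
    """
    name = residue.name
    g1 = CHI1_ATOMS.get(name)
    chi1 = _tors(residue.get("N"), residue.get("CA"), residue.get("CB"),
                 residue.get(g1) if g1 else None)
    g2 = CHI2_ATOMS.get(name)
    chi2 = None
    if g1 and g2:
        chi2 = _tors(residue.get("CA"), residue.get("CB"), residue.get(g1), residue.get(g2))
    return chi1, chi2


# ---------------------------------------------------------------------------
# contacts

@dataclass
class ContactRecord:
    """One heavy-atom contact within the query cutoff, sorted by distance."""

    atom_a: tuple[str, str]  # (residue id, atom name)
    atom_b: tuple[str, str]
    distance: float
    is_hbond_candidate: bool = False


_HBOND_ELEMENTS = {"N", "O"}

# 1-2/1-3 pairs across the peptide bond (atom of residue i, atom of residue i+1)
_PEPTIDE_EXCLUDE = {("C", "N"), ("CA", "N"), ("O", "N"), ("C", "CA"), ("C", "H")}


def _contact_pool(structure: Structure, include_waters: bool, include_ions: bool):
    pool = []
    for res in structure.residues():
        if res.is_water and not include_waters:
            continue
        if res.is_ion and not include_ions:
            continue
        for atom in res.heavy_atoms():
            pool.append((res, atom))
    return pool


def _excluded(res_a: Residue, atom_a: Atom, res_b: Residue, atom_b: Atom) -> bool:
    if res_a is res_b:
        return True
    if res_a.chain_id != res_b.chain_id:
        return False
    if res_b.number - res_a.number == 1:
        return (atom_a.name, atom_b.name) in _PEPTIDE_EXCLUDE
    if res_a.number - res_b.number == 1:
        return (atom_b.name, atom_a.name) in _PEPTIDE_EXCLUDE
    return False


def contacts(
    structure: Structure,
    target: Sequence[tuple[Residue, Atom]] | Residue,
    cutoff: float = 4.0,
    include_waters: bool = False,
    include_ions: bool = False,
) -> list[ContactRecord]:
    """All heavy-atom (target atom, non-target atom) pairs within ``cutoff`` Å.

    Same-residue pairs and 1-2/1-3 covalent neighbours across the peptide
    bond are excluded; waters and ions are excluded by default.  Records
    come back sorted by distance.
    """
    if cutoff <= 0:
        raise GeometryError("cutoff must be positive")
    if isinstance(target, Residue):
        target = [(target, a) for a in target.heavy_atoms()]
    target = list(target)
    if not target:
        raise GeometryError("empty target atom set")

    pool = _contact_pool(structure, include_waters, include_ions)
    target_ids = {id(a) for _, a in target}
    others = [(r, a) for r, a in pool if id(a) not in target_ids]
    if not others:
        return []
    tree = cKDTree(np.array([a.coords for _, a in others]))
    records: list[ContactRecord] = []
    for res_t, atom_t in target:
        for j in tree.query_ball_point(atom_t.coords, cutoff):
            res_o, atom_o = others[j]
            if _excluded(res_t, atom_t, res_o, atom_o):
                continue
            d = atom_t.distance(atom_o)
            if d <= cutoff:
                records.append(
                    ContactRecord(
                        atom_a=(res_t.id, atom_t.name),
                        atom_b=(res_o.id, atom_o.name),
                        distance=d,
                        is_hbond_candidate=(
                            atom_t.element.upper() in _HBOND_ELEMENTS
                            and atom_o.element.upper() in _HBOND_ELEMENTS
                            and d < 3.5
                        ),
                    )
                )
    records.sort(key=lambda r: (r.distance, r.atom_a, r.atom_b))
    return records


# ---------------------------------------------------------------------------
# hydrogen bonds

@dataclass
class HBond:
    donor: tuple[str, str]
    acceptor: tuple[str, str]
    d_DA: float
    hydrogen: tuple[str, str] | None = None
    angle_DHA: float | None = None


def _dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    v1, v2 = d - h, a - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def hydrogen_bonds(
    donors: Sequence[tuple[Residue, Atom]],
    acceptors: Sequence[tuple[Residue, Atom]],
    d_max: float = 3.5,
    angle_min: float = 140.0,
    require_angle: bool = False,
    hydrogens: dict[int, tuple[Residue, Atom]] | None = None,
) -> list[HBond]:
    """Donor/acceptor pairs meeting the < ``d_max`` Å (and optionally the
    > ``angle_min``° donor–H–acceptor) criterion.

    With ``require_angle=False`` (crystal mode) distance alone decides and
    ``angle_DHA`` is ``None``.  With ``require_angle=True``, ``hydrogens``
    must map ``id(donor_atom)`` to the attached hydrogen.
    """
    if require_angle and not hydrogens:
        raise GeometryError("require_angle=True needs hydrogen positions")
    out: list[HBond] = []
    for res_d, atom_d in donors:
        for res_a, atom_a in acceptors:
            if atom_d is atom_a:
                continue
            d = atom_d.distance(atom_a)
            if d >= d_max:
                continue
            if require_angle:
                entry = hydrogens.get(id(atom_d)) if hydrogens else None
                if entry is None:
                    continue
                res_h, atom_h = entry
                ang = _dha_angle(atom_d.coords, atom_h.coords, atom_a.coords)
                if ang <= angle_min:
                    continue
                out.append(
                    HBond((res_d.id, atom_d.name), (res_a.id, atom_a.name), d,
                          (res_h.id, atom_h.name), ang)
                )
            else:
                out.append(HBond((res_d.id, atom_d.name), (res_a.id, atom_a.name), d))
    out.sort(key=lambda h: (h.d_DA, h.donor, h.acceptor))
    return out


# ---------------------------------------------------------------------------
# turns

@dataclass
class TurnRecord:
    """α (i→i+4) or β (i→i+3) turn anchored by an O(i)…N(i+k) hydrogen bond."""

    kind: str  # "alpha" | "beta"
    start_residue: str
    hbond: HBond


def detect_turns(
    structure: Structure,
    chain: str,
    start: int,
    end: int,
    d_max: float = 3.5,
) -> list[TurnRecord]:
    """Scan residues ``start``..``end`` for α-turns (C=O of i to NH of i+4)
    and β-turns (C=O of i to NH of i+3), distance-only (crystal mode)."""
    residues = {r.number: r for r in structure.chain(chain) if start <= r.number <= end}
    turns: list[TurnRecord] = []
    for num in sorted(residues):
        res_i = residues[num]
        o = res_i.get("O")
        if o is None:
            continue
        for span, kind in ((4, "alpha"), (3, "beta")):
            res_j = residues.get(num + span)
            if res_j is None:
                continue
            n = res_j.get("N")
            if n is None:
                continue
            d = o.distance(n)
            if d < d_max:
                turns.append(
                    TurnRecord(kind, res_i.id, HBond((res_j.id, "N"), (res_i.id, "O"), d))
                )
    return turns


# ---------------------------------------------------------------------------
# superposition

@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    retained_pairs: int
    cycles_run: int
    retained_mask: np.ndarray = field(repr=False, default=None)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    return rot, trans


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    cycles: int = 5,
    reject_factor: float = 2.0,
) -> SuperpositionResult:
    """Least-squares rigid superposition with iterative outlier rejection.

    After the initial Kabsch fit, up to ``cycles`` rounds each drop pairs
    whose deviation exceeds ``reject_factor`` × current RMSD and refit.
    The "cutoff 2" of common align tools is read as 2 × RMSD per cycle.
    """
    mobile = np.asarray(mobile, float).reshape(-1, 3)
    reference = np.asarray(reference, float).reshape(-1, 3)
    if mobile.shape != reference.shape:
        raise GeometryError("paired coordinate sets must have equal shape")
    n = len(mobile)
    if n < 3:
        raise GeometryError("need at least 3 pairs to superpose")

    mask = np.ones(n, dtype=bool)
    rot, trans = _kabsch(mobile, reference)
    dev = np.linalg.norm(mobile @ rot.T + trans - reference, axis=1)
    rmsd = float(np.sqrt(np.mean(dev[mask] ** 2)))
    cycles_run = 0
    for _ in range(cycles):
        keep = mask & (dev <= max(reject_factor * rmsd, 1e-8))
        if keep.sum() < 3:
            break
        if keep.sum() == mask.sum():
            break
        mask = keep
        rot, trans = _kabsch(mobile[mask], reference[mask])
        dev = np.linalg.norm(mobile @ rot.T + trans - reference, axis=1)
        rmsd = float(np.sqrt(np.mean(dev[mask] ** 2)))
        cycles_run += 1
    if mask.sum() < 3:
        raise GeometryError("fewer than 3 pairs retained; degenerate fit")
    return SuperpositionResult(rot, trans, rmsd, int(mask.sum()), cycles_run, mask)


def pair_ca_atoms(
    mobile: Structure, reference: Structure, chain_mobile: str, chain_reference: str
) -> tuple[np.ndarray, np.ndarray]:
    """CA coordinate pairs matched by author residue number."""
    ref = {r.number: r for r in reference.chain(chain_reference) if "CA" in r}
    xs, ys = [], []
    for r in mobile.chain(chain_mobile):
        if "CA" in r and r.number in ref:
            xs.append(r["CA"].coords)
            ys.append(ref[r.number]["CA"].coords)
    if len(xs) < 3:
        raise GeometryError("fewer than 3 matched CA pairs")
    return np.array(xs), np.array(ys)
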