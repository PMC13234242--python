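"""Succinimide-formation site scanning.

Classifies Asn residues as prone or not prone to intramolecular
cyclization by the near-attack geometry (side-chain CG of residue n
close to the backbone N of residue n+1, with optional χ1/χ2/ψ windows),
assigns Ramachandran quadrants, and shortlists residues around a site
that could act as internal catalysts (direct base, proton relay, or
electrostatic stabiliser) from the 4 Å contact network.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .geometry import ContactRecord, DihedralSet, backbone_dihedrals, contacts, sidechain_dihedrals
from .structure import Residue, Structure, read_structure

__all__ = [
    "NearAttackCriteria",
    "SiteReport",
    "CatalystCandidate",
    "classify_quadrant",
    "circular_difference",
    "near_attack_assess",
    "scan_asn_sites",
    "candidate_catalysts",
    "n1_acidity_label",
    "scan_directory",
    "write_site_tsv",
    "DEFAULT_ACIDITY_RANGES",
]

SITE_RESIDUE_NAMES = ("ASN", "SNN")


@dataclass
class NearAttackCriteria:
    """Geometric criteria for the near-attack conformation.

    The distance criterion (CG of residue n to backbone N of n+1 below
    ``d_max``) is mandatory.  The angular windows — χ1 near +120°, χ2
    near ±90°, ψ near −120°, each within ``angular_tolerance`` — are
    individually switchable and all off by default, because crystal
    geometries called near-attack-like in practice (e.g. χ1 ≈ 174°) sit
    outside the canonical χ1 window.
    """

    d_max: float = 3.5
    chi1_center: float = 120.0
    chi2_centers: tuple[float, float] = (90.0, -90.0)
    psi_center: float = -120.0
    angular_tolerance: float = 40.0
    use_chi1: bool = False
    use_chi2: bool = False
    use_psi: bool = False

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0 < self.angular_tolerance < 90:
            raise ValueError("angular_tolerance must lie in (0, 90)")


def circular_difference(a: float, b: float) -> float:
    """Absolute angular difference in degrees, wrapped to [0, 180]."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


def classify_quadrant(phi: float, psi: float) -> str:
    """Ramachandran quadrant from the signs of (φ, ψ); 0° counts positive.

    top-left (φ<0, ψ≥0), top-right (φ≥0, ψ≥0), bottom-left (φ<0, ψ<0),
    bottom-right (φ≥0, ψ<0).
    """
    vert = "top" if psi >= 0 else "bottom"
    horiz = "right" if phi >= 0 else "left"
    return f"{vert}-{horiz}"


def near_attack_assess(
    d_cg_n: float | None,
    chi1: float | None,
    chi2: float | None,
    psi: float | None,
    criteria: NearAttackCriteria | None = None,
) -> tuple[bool, dict[str, str]]:
    """Verdict + per-criterion evidence for the near-attack conformation.

    Evidence values are ``"pass"``, ``"fail"``, ``"not-evaluated"`` (angle
    undefined or check disabled).  The verdict is distance AND all
    evaluated angular criteria.
    """
    c = criteria or NearAttackCriteria()
    evidence: dict[str, str] = {}
    if d_cg_n is None:
        evidence["distance"] = "not-evaluated"
        return False, evidence
    evidence["distance"] = "pass" if d_cg_n < c.d_max else "fail"

    def angular(name: str, value: float | None, centers: Sequence[float], enabled: bool) -> bool:
        if not enabled or value is None:
            evidence[name] = "not-evaluated"
            return True
        ok = min(circular_difference(value, ctr) for ctr in centers) <= c.angular_tolerance
        evidence[name] = "pass" if ok else "fail"
        return ok

    ok = evidence["distance"] == "pass"
    ok &= angular("chi1", chi1, (c.chi1_center,), c.use_chi1)
    ok &= angular("chi2", chi2, c.chi2_centers, c.use_chi2)
    ok &= angular("psi", psi, (c.psi_center,), c.use_psi)
    return ok, evidence


@dataclass
class SiteReport:
    residue: str
    d_CG_to_next_N: float | None
    dihedrals: DihedralSet
    next_residue_psi: float | None
    quadrant: str | None
    near_attack: bool
    evidence: dict[str, str] = field(default_factory=dict)


def scan_asn_sites(
    structure: Structure,
    criteria: NearAttackCriteria | None = None,
) -> list[SiteReport]:
    """One :class:`SiteReport` per Asn/SNN residue, sorted by CG–N(n+1)
    distance (undefined distances sort last)."""
    reports: list[SiteReport] = []
    found_any = False
    for chain_id, residues in structure.chains.items():
        index = {r.number: r for r in residues}
        for res in residues:
            if res.name not in SITE_RESIDUE_NAMES:
                continue
            found_any = True
            nxt = index.get(res.number + 1)
            cg = res.get("CG")
            d = None
            if nxt is not None and cg is not None and "N" in nxt:
                d = cg.distance(nxt["N"])
            dih = backbone_dihedrals(structure, chain_id, res.number)
            dih.chi1, dih.chi2 = sidechain_dihedrals(res)
            next_psi = None
            if nxt is not None:
                next_psi = backbone_dihedrals(structure, chain_id, nxt.number).psi
            quadrant = (
                classify_quadrant(dih.phi, dih.psi)
                if dih.phi is not None and dih.psi is not None
                else None
            )
            verdict, evidence = near_attack_assess(d, dih.chi1, dih.chi2, dih.psi, criteria)
            reports.append(SiteReport(res.id, d, dih, next_psi, quadrant, verdict, evidence))
    if not found_any:
        return []
    reports.sort(key=lambda r: (r.d_CG_to_next_N is None, r.d_CG_to_next_N or 0.0))
    return reports


# ---------------------------------------------------------------------------
# catalyst shortlisting

_CARBOXYLATE_O = {"OD1", "OD2", "OE1", "OE2"}
_RELAY_ATOMS = {"OH", "OG", "OG1", "NZ", "NE2", "ND1", "NE", "NH1", "NH2", "SG"}
_CHARGED_ATOMS = {"NZ", "NH1", "NH2", "NE", "OD1", "OD2", "OE1", "OE2"}


@dataclass
class CatalystCandidate:
    residue: str
    contacting_atoms: list[ContactRecord]
    role_hint: str  # direct-base | relay | electrostatic | vdw
    min_distance: float


def candidate_catalysts(
    structure: Structure,
    chain: str,
    site_number: int,
    cutoff: float = 4.0,
) -> list[CatalystCandidate]:
    """Residues with ≥1 heavy atom within ``cutoff`` of the site's
    side-chain/ring atoms, with structural role hints.

    direct-base: carboxylate O within H-bond range of the n+1 backbone N;
    relay: hydroxyl/amine H-bonded (< 3.5 Å) to an atom of a residue in
    direct contact with the site; electrostatic: other charged-group atom
    within the cutoff; vdw: anything else in contact.
    """
    residues = {r.number: r for r in structure.chain(chain)}
    site = residues[site_number] if site_number in residues else None
    if site is None:
        raise ValueError(f"no residue {site_number} in chain {chain!r}")
    backbone = {"N", "CA", "C", "O"}
    side_atoms = [(site, a) for a in site.heavy_atoms() if a.name not in backbone or site.name == "SNN"]
    if not side_atoms:
        side_atoms = [(site, a) for a in site.heavy_atoms()]
    recs = contacts(structure, side_atoms, cutoff=cutoff)

    by_res: dict[str, list[ContactRecord]] = {}
    for rec in recs:
        by_res.setdefault(rec.atom_b[0], []).append(rec)

    nxt = residues.get(site_number + 1)
    next_n = nxt["N"] if (nxt is not None and "N" in nxt) else None
    res_by_id = {r.id: r for r in structure.residues()}
    direct_ids = set(by_res)

    out: list[CatalystCandidate] = []
    for res_id, res_recs in by_res.items():
        res = res_by_id[res_id]
        if res.number == site_number:
            continue
        role = "vdw"
        if next_n is not None and any(
            a.name in _CARBOXYLATE_O and a.distance(next_n) < 3.5 for a in res.heavy_atoms()
        ):
            role = "direct-base"
        elif _is_relay(res, res_by_id, direct_ids):
            role = "relay"
        elif any(rec.atom_b[1] in _CHARGED_ATOMS for rec in res_recs):
            role = "electrostatic"
        out.append(
            CatalystCandidate(res_id, res_recs, role, min(r.distance for r in res_recs))
        )
    out.sort(key=lambda c: c.min_distance)
    return out


def _is_relay(res: Residue, res_by_id: dict[str, Residue], direct_ids: set[str]) -> bool:
    # a polar side-chain atom chained (<3.5 Å) to a *different* residue that
    # itself contacts the site
    for atom in res.heavy_atoms():
        if atom.name not in _RELAY_ATOMS:
            continue
        for other_id in direct_ids:
            other = res_by_id[other_id]
            if other is res:
                continue
            for oa in other.heavy_atoms():
                if oa.element.upper() in ("N", "O") and atom.distance(oa) < 3.5:
                    return True
    return False


# ---------------------------------------------------------------------------
# n+1 backbone-amide acidity from ψ

#: wrapped ψ intervals (lo, hi) → label; lo may exceed hi to wrap through ±180
DEFAULT_ACIDITY_RANGES: list[tuple[float, float, str]] = [
    (-50.0, -10.0, "moderately-low"),
]


def n1_acidity_label(
    psi_n1: float,
    ranges: Sequence[tuple[float, float, str]] | None = None,
) -> str:
    """Qualitative proton-affinity label for the n+1 backbone amide from
    its ψ, via a configurable range table (``"unclassified"`` otherwise)."""
    for lo, hi, label in ranges if ranges is not None else DEFAULT_ACIDITY_RANGES:
        if lo <= hi:
            if lo <= psi_n1 <= hi:
                return label
        elif psi_n1 >= lo or psi_n1 <= hi:  # wrapped interval
            return label
    return "unclassified"


# ---------------------------------------------------------------------------
# batch survey

_TSV_COLUMNS = [
    "file", "residue", "d_CG_nextN_A", "phi", "psi", "chi1", "chi2",
    "next_psi", "quadrant", "near_attack", "evidence",
]


def scan_directory(
    directory: str | Path,
    criteria: NearAttackCriteria | None = None,
    pattern: str = "*",
) -> list[dict]:
    """Scan every parseable structure file in a directory; one row per site."""
    rows: list[dict] = []
    for path in sorted(Path(directory).glob(pattern)):
        if path.suffix.lower() not in (".pdb", ".ent", ".cif", ".mmcif"):
            continue
        structure = read_structure(path)
        for rep in scan_asn_sites(structure, criteria):
            rows.append(
                {
                    "file": path.name,
                    "residue": rep.residue,
                    "d_CG_nextN_A": _fmt(rep.d_CG_to_next_N, 3),
                    "phi": _fmt(rep.dihedrals.phi, 1),
                    "psi": _fmt(rep.dihedrals.psi, 1),
                    "chi1": _fmt(rep.dihedrals.chi1, 1),
                    "chi2": _fmt(rep.dihedrals.chi2, 1),
                    "next_psi": _fmt(rep.next_residue_psi, 1),
                    "quadrant": rep.quadrant or "",
                    "near_attack": str(rep.near_attack).lower(),
                    "evidence": ";".join(f"{k}={v}" for k, v in rep.evidence.items()),
                }
            )
    return rows


def _fmt(value: float | None, ndigits: int) -> str:
    return "" if value is None else f"{value:.{ndigits}f}"


def write_site_tsv(rows: list[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_TSV_COLUMNS, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)
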