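"""Hierarchical coordinate model for protein structures.

The model is deliberately small: ``Structure`` → ``Residue`` → ``Atom``,
with author residue numbering preserved verbatim and nonstandard residues
(notably the cyclic succinimide, three-letter code ``SNN``) kept in the
chain at their deposited position rather than stripped as heteroatoms.
File I/O (fixed-column PDB and mmCIF ``atom_site`` records) is delegated
to :mod:`gemmi`; alternate locations are collapsed to the highest-occupancy
conformer (ties broken by altloc letter order) so downstream geometry is
single-conformer and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "StructureError",
    "read_structure",
    "write_structure",
    "select_residue",
    "WATER_NAMES",
    "ION_NAMES",
]

#: residue names treated as solvent in contact searches
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})
#: common monoatomic ions excluded from contact searches by default
ION_NAMES = frozenset({"NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE", "SO4", "PO4", "ACT", "GOL", "EDO"})


class StructureError(ValueError):
    """Raised for unreadable files, unknown formats, and failed selections."""


@dataclass
class Atom:
    """A single atom: label, element, position in Å, occupancy and B-factor."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    serial: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.name:
            raise StructureError("atom name must be nonempty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def distance(self, other: "Atom") -> float:
        return float(np.linalg.norm(self.coords - other.coords))


@dataclass
class Residue:
    """One residue of a chain, atoms keyed by (unique) atom name.

    ``number`` is the author residue number exactly as deposited; the
    succinimide at position 109 of MjGATase keeps its author number.
    """

    chain_id: str
    number: int
    name: str
    insertion_code: str = ""
    atoms: dict[str, Atom] = field(default_factory=dict)

    def add_atom(self, atom: Atom) -> None:
        if atom.name in self.atoms:
            raise StructureError(
                f"duplicate atom {atom.name!r} in {self.name} {self.chain_id}{self.number}"
            )
        self.atoms[atom.name] = atom

    def get(self, atom_name: str) -> Atom | None:
        return self.atoms.get(atom_name)

    def __getitem__(self, atom_name: str) -> Atom:
        try:
            return self.atoms[atom_name]
        except KeyError:
            raise StructureError(
                f"no atom {atom_name!r} in {self.name} {self.chain_id}{self.number} "
                f"(have: {sorted(self.atoms)})"
            ) from None

    def __contains__(self, atom_name: str) -> bool:
        return atom_name in self.atoms

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms.values())

    @property
    def id(self) -> str:
        return f"{self.chain_id}/{self.name}{self.number}{self.insertion_code}"

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def is_ion(self) -> bool:
        return self.name in ION_NAMES

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self if not a.is_hydrogen]


@dataclass
class Structure:
    """Ordered chains of residues plus provenance."""

    id: str = "model"
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    source_format: str = "pdb"

    def add_residue(self, residue: Residue) -> None:
        self.chains.setdefault(residue.chain_id, []).append(residue)

    def sort(self) -> None:
        for residues in self.chains.values():
            residues.sort(key=lambda r: (r.number, r.insertion_code))

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise StructureError(
                f"no chain {chain_id!r} (have: {sorted(self.chains)})"
            ) from None

    def residues(self, chain_id: str | None = None) -> Iterator[Residue]:
        if chain_id is not None:
            yield from self.chain(chain_id)
        else:
            for residues in self.chains.values():
                yield from residues

    def atoms(self, include_water: bool = True) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues():
            if not include_water or not res.is_water:
                for atom in res:
                    yield res, atom

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def coordinates(self) -> np.ndarray:
        """All atom coordinates in deterministic (chain, residue, atom) order."""
        return np.array([a.coords for _, a in self.atoms()], dtype=float).reshape(-1, 3)

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        """Deep copy with every atom position replaced, in iteration order."""
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        out = Structure(id=self.id, source_format=self.source_format)
        k = 0
        for res in self.residues():
            new_res = Residue(res.chain_id, res.number, res.name, res.insertion_code)
            for atom in res:
                new_res.add_atom(
                    Atom(atom.name, atom.element, coords[k], atom.occupancy, atom.b_factor, atom.serial)
                )
                k += 1
            out.add_residue(new_res)
        if k != len(coords):
            raise StructureError(f"coordinate array has {len(coords)} rows, structure has {k} atoms")
        return out


# ---------------------------------------------------------------------------
# I/O via gemmi

def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in ("pdb", "mmcif"):
            raise StructureError(f"unknown format {fmt!r}; expected pdb, mmcif or auto")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def _pick_altloc(atoms: Iterable[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties go to the alphabetically first altloc
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc or "~"))[0]


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    All ATOM and HETATM records of the first model are retained, so the
    succinimide residue SNN survives as an in-chain residue.  Alternate
    locations collapse to the highest-occupancy conformer.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = _detect_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")

    out = Structure(id=st.name or path.stem, source_format=fmt)
    model = st[0]
    for chain in model:
        for res in chain:
            residue = Residue(
                chain_id=chain.name,
                number=res.seqid.num,
                name=res.name.strip(),
                insertion_code=(res.seqid.icode or "").strip(),
            )
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            for name, group in by_name.items():
                g = _pick_altloc(group)
                residue.add_atom(
                    Atom(
                        name=name,
                        element=g.element.name,
                        coords=np.array([g.pos.x, g.pos.y, g.pos.z]),
                        occupancy=g.occ,
                        b_factor=g.b_iso,
                        serial=g.serial,
                    )
                )
            out.add_residue(residue)
    out.sort()
    if not out.chains:
        raise StructureError(f"{path}: no residues found")
    return out


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for chain_id, residues in structure.chains.items():
        chain = gemmi.Chain(chain_id)
        for res in residues:
            g_res = gemmi.Residue()
            g_res.name = res.name
            g_res.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            # nonstandard residues must be written as HETATM to stay valid PDB
            g_res.het_flag = "A" if gemmi.find_tabulated_residue(res.name) else "H"
            for atom in res:
                g_atom = gemmi.Atom()
                g_atom.name = atom.name
                g_atom.element = gemmi.Element(atom.element or atom.name[0])
                g_atom.pos = gemmi.Position(*atom.coords)
                g_atom.occ = atom.occupancy
                g_atom.b_iso = atom.b_factor
                g_atom.serial = atom.serial
                g_res.add_atom(g_atom)
            chain.add_residue(g_res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path, format: str = "auto") -> None:
    """Write a :class:`Structure` as PDB or mmCIF; round-trips coordinates to 1e-3 Å."""
    if not structure.chains or structure.n_atoms == 0:
        raise StructureError("refusing to write an empty structure")
    path = Path(path)
    fmt = _detect_format(path, format)
    st = _to_gemmi(structure)
    try:
        if fmt == "pdb":
            st.write_pdb(str(path))
        else:
            doc = st.make_mmcif_document()
            doc.write_file(str(path))
    except (RuntimeError, OSError) as exc:
        raise StructureError(f"cannot write {path}: {exc}") from exc


def select_residue(structure: Structure, chain: str, number: int, insertion_code: str = "") -> Residue:
    """Return the unique residue ``chain``/``number`` (author numbering)."""
    matches = [
        r
        for r in structure.chain(chain)
        if r.number == number and (not insertion_code or r.insertion_code == insertion_code)
    ]
    if not matches:
        numbers = [r.number for r in structure.chain(chain)]
        lo, hi = (min(numbers), max(numbers)) if numbers else (math.nan, math.nan)
        raise StructureError(
            f"no residue {number} in chain {chain!r} (available range {lo}–{hi})"
        )
    if len(matches) > 1:
        codes = [m.insertion_code or "' '" for m in matches]
        raise StructureError(
            f"residue {chain}/{number} is ambiguous: insertion codes {codes}; pass insertion_code"
        )
    return matches[0]
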