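"""Monoisotopic mass arithmetic for the MS evidence layer.

Peptide/protein neutral monoisotopic masses, the modification shifts
relevant to succinimide chemistry (ammonia loss at Asn −17.027 Da,
deamidation +0.984 Da, Met oxidation +15.995 Da, N-terminal acetylation
+42.011 Da), tryptic digestion with missed cleavages and an optional
semi-specific mode, charge-state m/z, b/y fragment ions, and
classification of deconvoluted neutral masses into the SNN (M−17),
intact (M) and hydrolyzed (M+1) populations.

Residue and small-molecule masses ship as a versioned constants table
(monoisotopic, Da); the proton mass used for charging is 1.007276 Da.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "MassError",
    "MASS_TABLE_VERSION",
    "RESIDUE_MONO",
    "WATER_MONO",
    "PROTON",
    "ModificationShift",
    "MODIFICATIONS",
    "PeptideSpec",
    "MassReport",
    "DigestParams",
    "peptide_neutral_mass",
    "mz",
    "fragment_ions",
    "digest",
    "protein_neutral_mass",
    "classify_population",
    "parse_mutation",
    "apply_mutations",
]


class MassError(ValueError):
    pass


MASS_TABLE_VERSION = "2023-monoisotopic-1"

#: monoisotopic residue masses (Da): peptide-bonded residue, i.e. amino acid − water
RESIDUE_MONO: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER_MONO = 18.010565
PROTON = 1.007276

#: mass shifts used to classify whole-protein populations
SNN_SHIFT = -17.026549     # ammonia loss: Asn → succinimide
DEAMIDATION_SHIFT = 0.984016  # Asn/Gln amide → carboxylate (via SNN hydrolysis)


@dataclass(frozen=True)
class ModificationShift:
    name: str
    delta_mass: float
    applies_to: tuple[str, ...]  # residue one-letter codes, or "N-term"/"C-term"


#: registry of the dynamic modifications used in the MS searches
MODIFICATIONS: dict[str, ModificationShift] = {
    m.name: m
    for m in (
        ModificationShift("snn", SNN_SHIFT, ("N",)),           # ammonia loss at Asn
        ModificationShift("deamidation", DEAMIDATION_SHIFT, ("N", "Q")),
        ModificationShift("oxidation", 15.994915, ("M",)),
        ModificationShift("acetyl", 42.010565, ("N-term",)),
    )
}


def _check_sequence(sequence: str) -> None:
    bad = sorted({c for c in sequence if c not in RESIDUE_MONO})
    if bad:
        raise MassError(f"unknown residue code(s): {bad}")
    if not sequence:
        raise MassError("empty sequence")


@dataclass
class PeptideSpec:
    """A peptide sequence with positioned modifications and a charge.

    ``modifications`` holds ``(position, shift)`` with 1-based positions
    (0 = N-terminus, len+1 = C-terminus for terminal shifts).
    """

    sequence: str
    modifications: list[tuple[int, ModificationShift]] = field(default_factory=list)
    charge: int = 0
    missed_cleavages: int | None = None

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        for pos, m in self.modifications:
            if not 0 <= pos <= len(self.sequence) + 1:
                raise MassError(f"modification position {pos} outside 0..{len(self.sequence) + 1}")


@dataclass
class MassReport:
    neutral_mono: float
    mz_by_charge: dict[int, float]
    population_class: str = "unassigned"


def peptide_neutral_mass(spec: PeptideSpec | str) -> float:
    """Neutral monoisotopic mass: Σ residue masses + water + Σ shift deltas."""
    if isinstance(spec, str):
        spec = PeptideSpec(spec)
    mass = sum(RESIDUE_MONO[c] for c in spec.sequence) + WATER_MONO
    mass += sum(m.delta_mass for _, m in spec.modifications)
    return mass


def mz(neutral: float, z: int) -> float:
    """m/z of the [M + zH]^z+ ion."""
    if z < 1:
        raise MassError("charge must be a positive integer")
    return (neutral + z * PROTON) / z


def fragment_ions(
    spec: PeptideSpec | str,
    series: str,
    charge: int = 1,
) -> list[tuple[str, float]]:
    """Singly- (or multiply-) charged b or y fragment ions.

    b_i = Σ residues 1..i (+ mods in the fragment) + z·proton, /z;
    y_j = Σ residues n−j+1..n + water (+ mods) + z·proton, /z.
    Terminal modifications (position 0 / n+1) follow their terminus.
    """
    if isinstance(spec, str):
        spec = PeptideSpec(spec)
    if series not in ("b", "y"):
        raise MassError(f"unknown ion series {series!r}; expected 'b' or 'y'")
    if charge < 1:
        raise MassError("charge must be a positive integer")
    n = len(spec.sequence)
    out: list[tuple[str, float]] = []
    for i in range(1, n):  # full-length b_n / y_n are not fragments
        if series == "b":
            residues = spec.sequence[:i]
            mods = sum(m.delta_mass for pos, m in spec.modifications if 0 <= pos <= i)
            neutral = sum(RESIDUE_MONO[c] for c in residues) + mods
        else:
            residues = spec.sequence[n - i:]
            mods = sum(
                m.delta_mass for pos, m in spec.modifications if pos > n - i or pos == n + 1
            )
            neutral = sum(RESIDUE_MONO[c] for c in residues) + WATER_MONO + mods
        out.append((f"{series}{i}", (neutral + charge * PROTON) / charge))
    return out


# ---------------------------------------------------------------------------
# digestion

@dataclass
class DigestParams:
    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    semi_specific: bool = False

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise MassError(f"unsupported enzyme {self.enzyme!r}")
        if self.max_missed_cleavages < 0:
            raise MassError("max_missed_cleavages must be >= 0")


def _cleavage_sites(sequence: str) -> list[int]:
    """Indices i such that trypsin cleaves between sequence[i-1] and
    sequence[i]: C-terminal to K/R, except before P."""
    return [
        i
        for i in range(1, len(sequence))
        if sequence[i - 1] in "KR" and sequence[i] != "P"
    ]


def digest(sequence: str, params: DigestParams | None = None) -> list[PeptideSpec]:
    """Tryptic peptides with up to ``max_missed_cleavages`` internal sites.

    With ``semi_specific`` additionally emits every peptide with exactly
    one non-enzymatic terminus (the other terminus enzymatic or a protein
    terminus).  Zero-missed peptides tile the input exactly once.
    """
    _check_sequence(sequence)
    params = params or DigestParams()
    bounds = [0] + _cleavage_sites(sequence) + [len(sequence)]
    peptides: list[PeptideSpec] = []
    seen: set[tuple[int, int]] = set()
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + 2 + params.max_missed_cleavages, len(bounds))):
            start, end = bounds[a], bounds[b]
            seen.add((start, end))
            peptides.append(
                PeptideSpec(sequence[start:end], missed_cleavages=b - a - 1)
            )
            if params.semi_specific:
                missed = b - a - 1
                for s in range(start + 1, end):  # ragged N-terminus
                    if (s, end) not in seen:
                        seen.add((s, end))
                        peptides.append(PeptideSpec(sequence[s:end], missed_cleavages=missed))
                for e in range(start + 1, end):  # ragged C-terminus
                    if (start, e) not in seen:
                        seen.add((start, e))
                        peptides.append(PeptideSpec(sequence[start:e], missed_cleavages=missed))
    return peptides


# ---------------------------------------------------------------------------
# intact proteins and mutations

def parse_mutation(spec: str) -> list[tuple[int, str, str]]:
    """Parse mutation specs like ``"D110V"`` or combined ``"D110V_K151L"``
    into (position, from, to) triples (1-based positions)."""
    out = []
    for token in spec.split("_"):
        token = token.strip()
        if len(token) < 3 or token[0] not in RESIDUE_MONO or token[-1] not in RESIDUE_MONO:
            raise MassError(f"malformed mutation {token!r}")
        try:
            pos = int(token[1:-1])
        except ValueError:
            raise MassError(f"malformed mutation {token!r}") from None
        out.append((pos, token[0], token[-1]))
    return out


def apply_mutations(sequence: str, mutations: Iterable[tuple[int, str, str]]) -> str:
    chars = list(sequence)
    for pos, src, dst in mutations:
        if not 1 <= pos <= len(chars):
            raise MassError(f"mutation position {pos} outside 1..{len(chars)}")
        if chars[pos - 1] != src:
            raise MassError(
                f"mutation {src}{pos}{dst}: sequence has {chars[pos - 1]!r} at position {pos}"
            )
        chars[pos - 1] = dst
    return "".join(chars)


def protein_neutral_mass(
    sequence: str,
    mutations: Sequence[tuple[int, str, str]] = (),
    modifications: Sequence[ModificationShift] = (),
    exclude_initiator_met: bool = False,
) -> float:
    """Monoisotopic mass of a full (optionally mutated) chain plus shifts.

    The initiator Met is included by default; ``exclude_initiator_met``
    removes position 1 when it is Met (raises otherwise).
    """
    seq = apply_mutations(sequence, mutations)
    if exclude_initiator_met:
        if not seq.startswith("M"):
            raise MassError("exclude_initiator_met set but sequence does not start with Met")
        seq = seq[1:]
    mass = sum(RESIDUE_MONO[c] for c in seq) + WATER_MONO
    mass += sum(m.delta_mass for m in modifications)
    return mass


def classify_population(
    observed: float,
    expected_intact: float,
    tolerance: float = 0.05,
) -> str:
    """Assign a deconvoluted neutral mass to the nearest of the SNN
    (expected − 17.0265), intact (expected) or hydrolyzed (expected +
    0.984) windows, or ``"unassigned"`` outside all of them."""
    if tolerance <= 0:
        raise MassError("tolerance must be positive")
    windows = {
        "snn": expected_intact + SNN_SHIFT,
        "intact": expected_intact,
        "hydrolyzed": expected_intact + DEAMIDATION_SHIFT,
    }
    best, best_err = "unassigned", tolerance
    for label, center in windows.items():
        err = abs(observed - center)
        if err <= best_err:
            best, best_err = label, err
    return best


def mass_report(spec: PeptideSpec | str, charges: Sequence[int] = (1, 2, 3)) -> MassReport:
    neutral = peptide_neutral_mass(spec)
    return MassReport(neutral, {z: mz(neutral, z) for z in charges})
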