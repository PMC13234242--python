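"""Synthetic inputs with constructed ground truth.

Four generator families cover every input class the analysis layers
consume, so the whole pipeline is testable without external downloads:

* :func:`build_peptide` — internal-coordinate (NeRF) chain growth with
  ideal bond lengths/angles and caller-prescribed φ/ψ/ω/χ1/χ2, so
  measured torsions round-trip to < 0.1°.  Fidelity target is torsion
  round-trip, not force-field realism.
* :func:`gen_hills_on_surface` — a seeded Metropolis walker on an
  analytic 2D surface *plus its own deposited bias* (standard
  metadynamics dynamics), emitting a hills stream whose negated sum
  approximates the surface in the visited region; the surface's true
  barrier is independently computable by dense-grid search.
* :func:`gen_trajectory` — harmonic positional noise around a reference
  structure with scripted atom-displacement events (e.g. a proton
  transferred from a backbone amide N to a carboxylate O).
* :func:`mutate_sequence` — point mutations parsed from names like
  ``"D110V_K151L"``.

All generators are seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .masses import apply_mutations, parse_mutation
from .metad import FESGrid, Hill, minimax_barrier_threshold
from .structure import Atom, Residue, Structure
from .trajectory import Trajectory

__all__ = [
    "SynthError",
    "ResidueTorsions",
    "PeptideBuildSpec",
    "build_peptide",
    "GaussianFeature",
    "SurfaceSpec",
    "default_double_well",
    "gen_hills_on_surface",
    "TrajectoryEvent",
    "TrajectoryScript",
    "gen_trajectory",
    "mutate_sequence",
    "place_atom",
]


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# NeRF peptide builder

def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement: the new atom D bonded
    to C with |CD| = ``bond``, angle(B,C,D) = ``angle_deg`` and torsion
    (A,B,C,D) = ``torsion_deg``."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise SynthError("collinear reference atoms in NeRF placement")
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ideal heavy-atom geometry (Engh–Huber-like averages, Å / degrees)
_BB = {
    "N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.530,
    "C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-N": 116.2, "CA-C-O": 120.8,
    "C-CA-CB": 111.1, "N-C-CA-CB": 122.7,  # improper fixing L-chirality
}

# generic side-chain steps beyond CB: (atom, prev3 refs, bond, angle, torsion rule)
# torsion rules: "chi1", "chi2", or a float offset added to chi2
_SIDECHAINS: dict[str, list[tuple[str, tuple[str, str, str], float, float, object]]] = {
    "ASN": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, "chi1"),
        ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, "chi2"),
        ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, 180.0),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, "chi1"),
        ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, "chi2"),
        ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, 180.0),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, "chi1"),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, "chi2"),
    ],
    "GLN": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, "chi1"),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, "chi2"),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, "chi1"),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, "chi2"),
        ("CE", ("CB", "CG", "CD"), 1.520, 111.3, 180.0),
        ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, 180.0),
    ],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, 120.0),
    ],
    "PHE": [
        ("CG", ("N", "CA", "CB"), 1.502, 113.8, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.384, 120.8, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.384, 120.8, 180.0),
    ],
    "TYR": [
        ("CG", ("N", "CA", "CB"), 1.512, 113.9, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.389, 120.8, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.389, 120.8, 180.0),
    ],
    "VAL": [
        ("CG1", ("N", "CA", "CB"), 1.521, 110.5, "chi1"),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, 120.0),
    ],
    "SER": [("OG", ("N", "CA", "CB"), 1.417, 111.1, "chi1")],
    "THR": [("OG1", ("N", "CA", "CB"), 1.433, 109.6, "chi1")],
    "CYS": [("SG", ("N", "CA", "CB"), 1.808, 114.4, "chi1")],
    "MET": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, "chi1"),
        ("SD", ("CA", "CB", "CG"), 1.803, 112.7, "chi2"),
    ],
    "ILE": [
        ("CG1", ("N", "CA", "CB"), 1.530, 110.4, "chi1"),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, 120.0),
        ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, "chi2"),
    ],
    "ARG": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, "chi1"),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, "chi2"),
    ],
    "HIS": [
        ("CG", ("N", "CA", "CB"), 1.497, 113.8, "chi1"),
        ("ND1", ("CA", "CB", "CG"), 1.371, 122.7, "chi2"),
    ],
    "TRP": [
        ("CG", ("N", "CA", "CB"), 1.498, 113.6, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, "chi2"),
    ],
    "PRO": [
        ("CG", ("N", "CA", "CB"), 1.492, 104.5, "chi1"),
        ("CD", ("CA", "CB", "CG"), 1.503, 106.1, "chi2"),
    ],
    "ALA": [],
    "GLY": [],
}

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _wrap(angle: float) -> float:
    a = (angle + 180.0) % 360.0 - 180.0
    return a if a != -180.0 else 180.0


@dataclass
class ResidueTorsions:
    """Requested torsions for one residue; ``None`` → builder default
    (extended backbone φ = −135°, ψ = 135°, trans ω, χ1 = −65°, χ2 = 180°)."""

    phi: float | None = None
    psi: float | None = None
    omega: float | None = None
    chi1: float | None = None
    chi2: float | None = None

    def resolved(self) -> "ResidueTorsions":
        return ResidueTorsions(
            phi=-135.0 if self.phi is None else _wrap(self.phi),
            psi=135.0 if self.psi is None else _wrap(self.psi),
            omega=180.0 if self.omega is None else _wrap(self.omega),
            chi1=-65.0 if self.chi1 is None else _wrap(self.chi1),
            chi2=180.0 if self.chi2 is None else _wrap(self.chi2),
        )


@dataclass
class PeptideBuildSpec:
    sequence: str
    torsions: list[ResidueTorsions] = field(default_factory=list)
    chain_id: str = "A"
    first_residue_number: int = 1

    def __post_init__(self) -> None:
        bad = sorted({c for c in self.sequence if c not in _THREE})
        if bad:
            raise SynthError(f"unknown residue code(s): {bad}")
        if not self.sequence:
            raise SynthError("empty sequence")
        if not self.torsions:
            self.torsions = [ResidueTorsions() for _ in self.sequence]
        if len(self.torsions) != len(self.sequence):
            raise SynthError("torsions list must match sequence length")


_STERIC_WARN = 0.5  # Å: nonbonded atoms closer than this trigger a warning


def build_peptide(spec: PeptideBuildSpec, warn=None) -> Structure:
    """Grow a peptide chain in internal coordinates at the requested
    torsions.  Side chains are built through the χ2-bearing atom (and the
    full amide/carboxylate for Asn/Asp); aromatic rings stop at CD1/CD2.

    ``warn`` is an optional callable receiving a message on steric
    collapse (< 0.5 Å between nonbonded atoms) — a warning, not an error,
    since impossible torsion sets are legitimate test inputs.
    """
    tors = [t.resolved() for t in spec.torsions]
    structure = Structure(id=f"synthetic:{spec.sequence}", source_format="pdb")
    placed: list[tuple[str, np.ndarray, int]] = []  # (atom name, coords, residue index)

    serial = 0
    prev: dict[str, np.ndarray] = {}
    for i, letter in enumerate(spec.sequence):
        name3 = _THREE[letter]
        t = tors[i]
        atoms: dict[str, np.ndarray] = {}
        if i == 0:
            atoms["N"] = np.zeros(3)
            atoms["CA"] = np.array([_BB["N-CA"], 0.0, 0.0])
            ang = np.radians(_BB["N-CA-C"])
            atoms["C"] = atoms["CA"] + _BB["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            atoms["N"] = place_atom(prev["N"], prev["CA"], prev["C"],
                                    _BB["C-N"], _BB["CA-C-N"], tors[i - 1].psi)
            atoms["CA"] = place_atom(prev["CA"], prev["C"], atoms["N"],
                                     _BB["N-CA"], _BB["C-N-CA"], t.omega)
            atoms["C"] = place_atom(prev["C"], atoms["N"], atoms["CA"],
                                    _BB["CA-C"], _BB["N-CA-C"], t.phi)
        # carbonyl O anti to the next backbone N: torsion N-CA-C-O = psi + 180
        atoms["O"] = place_atom(atoms["N"], atoms["CA"], atoms["C"],
                                _BB["C-O"], _BB["CA-C-O"], t.psi + 180.0)
        if name3 != "GLY":
            atoms["CB"] = place_atom(atoms["N"], atoms["C"], atoms["CA"],
                                     _BB["CA-CB"], _BB["C-CA-CB"], _BB["N-C-CA-CB"])
            for atom_name, refs, bond, angle, rule in _SIDECHAINS[name3]:
                if rule == "chi1":
                    torsion = t.chi1
                elif rule == "chi2":
                    torsion = t.chi2
                else:
                    torsion = t.chi2 + float(rule)  # rotamer-fixed offset from chi2
                    if refs == ("N", "CA", "CB"):
                        torsion = t.chi1 + float(rule)
                a, b, c = (atoms[r] for r in refs)
                atoms[atom_name] = place_atom(a, b, c, bond, angle, torsion)

        residue = Residue(spec.chain_id, spec.first_residue_number + i, name3)
        for atom_name, coords in atoms.items():
            serial += 1
            element = atom_name[0] if atom_name[0] in "CNOS" else atom_name[:1]
            residue.add_atom(Atom(atom_name, element, coords, serial=serial))
            for other_name, other_coords, other_res in placed:
                if other_res >= i - 1:
                    continue  # skip bonded/adjacent residues
                if np.linalg.norm(coords - other_coords) < _STERIC_WARN:
                    if warn is not None:
                        warn(
                            f"steric collapse: {atom_name}@res{i + 1} within "
                            f"{_STERIC_WARN} Å of {other_name}@res{other_res + 1}"
                        )
            placed.append((atom_name, coords, i))
        structure.add_residue(residue)
        prev = atoms
    return structure


# ---------------------------------------------------------------------------
# analytic surfaces and hill streams

@dataclass(frozen=True)
class GaussianFeature:
    """One well (depth > 0 lowers the surface) or bump (depth < 0)."""

    center: tuple[float, float]
    sigma: float
    depth: float


@dataclass
class SurfaceSpec:
    """Sum-of-Gaussians analytic 2D surface, kcal/mol over CV space."""

    features: tuple[GaussianFeature, ...]
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((-0.8, 0.8), (-0.8, 0.8))

    def energy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x, y = np.asarray(x, float), np.asarray(y, float)
        u = np.zeros(np.broadcast(x, y).shape)
        for f in self.features:
            u -= f.depth * np.exp(
                -((x - f.center[0]) ** 2 + (y - f.center[1]) ** 2) / (2 * f.sigma**2)
            )
        return u

    def dense_grid(self, spacing: float = 0.005) -> FESGrid:
        """The surface on a dense grid, min-shifted to 0 (oracle use)."""
        (x0, x1), (y0, y1) = self.bounds
        ax1 = x0 + spacing * np.arange(int(round((x1 - x0) / spacing)) + 1)
        ax2 = y0 + spacing * np.arange(int(round((y1 - y0) / spacing)) + 1)
        u = self.energy(ax1[:, None], ax2[None, :])
        return FESGrid((ax1, ax2), u - u.min())

    def true_barrier(self, start: Sequence[float], end: Sequence[float],
                     spacing: float = 0.005) -> float:
        """Known saddle height via dense-grid search: minimax level between
        the two basins minus the free energy at the start node."""
        grid = self.dense_grid(spacing)
        level = minimax_barrier_threshold(grid, start, end)
        return level - float(grid.values[grid.node_of(start)])


def default_double_well() -> SurfaceSpec:
    """Two 5 kcal/mol wells at (∓0.4, ∓0.4) mimicking the reactant/product
    basins of the deprotonation CV space, on a wall-confined domain
    (the simulated system likewise confines the reactive partners with an
    upper-wall bias); saddle near the origin."""
    return SurfaceSpec(
        features=(
            GaussianFeature((-0.4, -0.4), 0.12, 5.0),
            GaussianFeature((0.4, 0.4), 0.12, 5.0),
        ),
        bounds=((-0.6, 0.6), (-0.6, 0.6)),
    )


def gen_hills_on_surface(
    spec: SurfaceSpec,
    n_hills: int = 60000,
    sigma: tuple[float, float] = (0.005, 0.006),
    height: float = 0.59,
    seed: int = 0,
    mode: str = "quadrature",
    kT: float = 0.6,
    step_sigma: float = 0.02,
    start: tuple[float, float] | None = None,
    stride_ps: float = 0.1,
) -> list[Hill]:
    """Seeded hill stream on an analytic surface whose negated sum
    approximates the surface.

    Two constructions are available:

    ``"quadrature"`` (default, oracle-grade): hills sit on a jittered
    lattice with per-axis spacing equal to σ, heights proportional to
    C − U(center) with C = max U + one hill height, normalised so that
    the Gaussian-kernel quadrature Σ hᵢGᵢΔ²/(2πσ₁σ₂) reproduces C − U up
    to a σ-scale smoothing; the stream is shuffled into a random
    deposition order.  The reconstruction error is well below the hill
    height everywhere, so the known saddle height is recoverable to a
    few percent.

    ``"walk"``: a Metropolis walker on ``U + V`` (V = bias already
    deposited, kept on an internal fine grid), one fixed-height Gaussian
    per step — the dynamical emulation of a nontempered metadynamics
    engine.  Fixed-height deposition leaves fill fluctuations of the
    order of the hill height to a few kT between regions, so barriers
    recovered from walk streams carry an O(1 kcal/mol) noise floor;
    use quadrature streams when a quantitative ground truth is needed.

    Hill height/σ defaults follow the study conditions (0.59 kcal/mol,
    0.005/0.006 CV units); ``n_hills`` caps the stream length.
    """
    if n_hills <= 0:
        raise SynthError("n_hills must be positive")
    if mode == "quadrature":
        return _hills_quadrature(spec, n_hills, sigma, height, seed, stride_ps)
    if mode == "walk":
        return _hills_walk(spec, n_hills, sigma, height, seed, kT, step_sigma, start, stride_ps)
    raise SynthError(f"unknown mode {mode!r}; expected 'quadrature' or 'walk'")


def _hills_quadrature(spec, n_hills, sigma, height, seed, stride_ps) -> list[Hill]:
    rng = np.random.default_rng(seed)
    (x0, x1), (y0, y1) = spec.bounds
    dx, dy = sigma
    # lattice at σ spacing, extended one step beyond the bounds so the
    # represented region fully covers the domain
    gx = np.arange(x0 - dx, x1 + 2 * dx, dx)
    gy = np.arange(y0 - dy, y1 + 2 * dy, dy)
    cx, cy = np.meshgrid(gx, gy, indexing="ij")
    # small jitter (±0.1 spacing) keeps the stream seeded without the
    # density noise a full-cell jitter would add to the kernel quadrature
    cx = cx + rng.uniform(-0.1 * dx, 0.1 * dx, cx.shape)
    cy = cy + rng.uniform(-0.1 * dy, 0.1 * dy, cy.shape)
    u = spec.energy(cx, cy)
    c_level = float(u.max()) + height
    # V(x) = Σ h_i G_i(x); with lattice spacing (dx, dy) = (σ1, σ2) the
    # kernel sum obeys Σ a(x_i) G_i(x) ≈ a(x) · 2πσ1σ2/(dx·dy) = a(x) · 2π
    heights = (c_level - u).ravel() / (2.0 * math.pi)
    cxf, cyf = cx.ravel(), cy.ravel()
    order = rng.permutation(len(cxf))
    if len(order) > n_hills:
        raise SynthError(
            f"n_hills={n_hills} too small to cover the domain at σ spacing "
            f"({len(order)} lattice hills needed)"
        )
    hills = [
        Hill(
            time=round((k + 1) * stride_ps, 10),
            center=(float(cxf[i]), float(cyf[i])),
            sigma=np.array(sigma),
            height=float(max(heights[i], 0.0)),
        )
        for k, i in enumerate(order)
    ]
    return hills


def _hills_walk(spec, n_hills, sigma, height, seed, kT, step_sigma, start, stride_ps) -> list[Hill]:
    rng = np.random.default_rng(seed)
    (x0, x1), (y0, y1) = spec.bounds
    spacing = min(sigma) / 2.0
    nx = int(round((x1 - x0) / spacing)) + 1
    ny = int(round((y1 - y0) / spacing)) + 1
    ax1 = x0 + spacing * np.arange(nx)
    ax2 = y0 + spacing * np.arange(ny)
    u_grid = spec.energy(ax1[:, None], ax2[None, :])
    bias = np.zeros((nx, ny))
    wx = max(1, int(np.ceil(6 * sigma[0] / spacing)))
    wy = max(1, int(np.ceil(6 * sigma[1] / spacing)))

    def node(p):
        i = int(round((p[0] - x0) / spacing))
        j = int(round((p[1] - y0) / spacing))
        return min(max(i, 0), nx - 1), min(max(j, 0), ny - 1)

    pos = np.array(start if start is not None else spec.features[0].center, float)
    hills: list[Hill] = []
    for k in range(n_hills):
        hills.append(Hill(time=round((k + 1) * stride_ps, 10), center=pos.copy(),
                          sigma=np.array(sigma), height=height))
        i, j = node(pos)
        sl1 = slice(max(i - wx, 0), min(i + wx + 1, nx))
        sl2 = slice(max(j - wy, 0), min(j + wy + 1, ny))
        z1 = (ax1[sl1] - pos[0]) / sigma[0]
        z2 = (ax2[sl2] - pos[1]) / sigma[1]
        bias[sl1, sl2] += height * np.exp(-0.5 * (z1[:, None] ** 2 + z2[None, :] ** 2))
        e_cur = u_grid[i, j] + bias[i, j]
        # Metropolis move on U + V; out-of-bounds proposals are rejected
        # (hard walls at the domain edge)
        trial = pos + rng.normal(scale=step_sigma, size=2)
        if x0 <= trial[0] <= x1 and y0 <= trial[1] <= y1:
            ii, jj = node(trial)
            e_trial = u_grid[ii, jj] + bias[ii, jj]
            if e_trial <= e_cur or rng.random() < np.exp(-(e_trial - e_cur) / kT):
                pos = trial
    return hills


# ---------------------------------------------------------------------------
# scripted trajectories

@dataclass
class TrajectoryEvent:
    """Move one atom to a target position, linearly over ``ramp`` frames
    ending at ``frame`` (e.g. a proton hopping from a backbone N to a
    carboxylate O)."""

    frame: int
    chain: str
    resnum: int
    atom: str
    target: tuple[float, float, float]
    ramp: int = 5


@dataclass
class TrajectoryScript:
    reference: Structure
    noise_sigma: float = 0.0
    events: list[TrajectoryEvent] = field(default_factory=list)
    seed: int = 0


def gen_trajectory(script: TrajectoryScript, n_frames: int, timestep: float = 1.0) -> Trajectory:
    """Seeded Gaussian positional noise around the reference, with scripted
    displacement events; event atoms interpolate to their targets over the
    ramp and stay there afterwards."""
    if n_frames <= 0:
        raise SynthError("n_frames must be positive")
    for ev in script.events:
        if not 0 <= ev.frame < n_frames:
            raise SynthError(f"event frame {ev.frame} outside 0..{n_frames - 1}")
    rng = np.random.default_rng(script.seed)
    ref = script.reference.coordinates()
    n_atoms = len(ref)
    frames = np.repeat(ref[None, :, :], n_frames, axis=0)
    if script.noise_sigma > 0:
        frames = frames + rng.normal(scale=script.noise_sigma, size=frames.shape)

    # resolve event atom indices against the topology
    index = {}
    for k, (res, atom) in enumerate(script.reference.atoms()):
        index[(res.chain_id, res.number, atom.name)] = k
    for ev in script.events:
        key = (ev.chain, ev.resnum, ev.atom)
        if key not in index:
            raise SynthError(f"no atom {key} in reference structure")
        k = index[key]
        target = np.asarray(ev.target, float)
        start_frame = max(ev.frame - ev.ramp, 0)
        origin = ref[k]
        for f in range(start_frame, n_frames):
            if f >= ev.frame:
                lam = 1.0
            else:
                lam = (f - start_frame) / max(ev.frame - start_frame, 1)
            base = origin + lam * (target - origin)
            noise = frames[f, k] - ref[k] if script.noise_sigma > 0 else 0.0
            frames[f, k] = base + noise
    times = timestep * np.arange(n_frames)
    return Trajectory(script.reference, frames, times)


def mutate_sequence(sequence: str, mutations: str | Sequence[tuple[int, str, str]]) -> str:
    """Apply point mutations given as triples or as a name like
    ``"D110V_K151L"`` (1-based positions, from-residue checked)."""
    if isinstance(mutations, str):
        mutations = parse_mutation(mutations)
    return apply_mutations(sequence, mutations)
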