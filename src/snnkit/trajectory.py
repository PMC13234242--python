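"""Frame-wise geometric statistics on coordinate trajectories.

A :class:`Trajectory` is a topology :class:`~snnkit.structure.Structure`
plus an (n_frames, n_atoms, 3) coordinate array with strictly increasing
frame times in ps.  Supported on-disk formats are multi-model PDB and a
plain-text XYZ-like frame format (atom-count header, comment line with
the frame time, one ``name x y z`` row per atom); binary trajectory
formats are deliberately out of scope.

Distance histograms default to the 0.01 Å bin width used for
proton-abstraction distance distributions; hydrogen-bond occupancies use
the < 3.5 Å donor–acceptor / > 140° donor–H–acceptor criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .structure import Atom, Residue, Structure, StructureError

__all__ = [
    "TrajectoryError",
    "Trajectory",
    "Histogram",
    "OccupancyReport",
    "distance_series",
    "distance_histogram",
    "hbond_occupancy",
    "extract_frames",
    "read_trajectory_pdb",
    "read_trajectory_xyz",
    "write_trajectory_xyz",
]


class TrajectoryError(ValueError):
    pass


@dataclass
class Trajectory:
    topology: Structure
    frames: np.ndarray          # (n_frames, n_atoms, 3), Å
    frame_times: np.ndarray     # ps, strictly increasing

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        n_atoms = self.topology.n_atoms
        if self.frames.ndim != 3 or self.frames.shape[1] != n_atoms or self.frames.shape[2] != 3:
            raise TrajectoryError(
                f"frames must be (n_frames, {n_atoms}, 3); got {self.frames.shape}"
            )
        if len(self.frame_times) != len(self.frames):
            raise TrajectoryError("frame_times length must match frame count")
        if len(self.frame_times) > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise TrajectoryError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def atom_index(self, chain: str, resnum: int, atom_name: str) -> int:
        """Flat atom index (topology iteration order) of one named atom."""
        for k, (res, atom) in enumerate(self.topology.atoms()):
            if res.chain_id == chain and res.number == resnum and atom.name == atom_name:
                return k
        raise TrajectoryError(f"no atom {chain}/{resnum}/{atom_name} in topology")


def distance_series(traj: Trajectory, atom_a: int, atom_b: int) -> np.ndarray:
    """Euclidean distance between two (flat-indexed) atoms per frame, Å."""
    for idx in (atom_a, atom_b):
        if not 0 <= idx < traj.frames.shape[1]:
            raise TrajectoryError(f"atom index {idx} outside topology")
    return np.linalg.norm(traj.frames[:, atom_a] - traj.frames[:, atom_b], axis=1)


@dataclass
class Histogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray      # unit-area normalisation
    cumulative: np.ndarray   # fraction of samples below each right edge

    def fraction_below(self, x: float) -> float:
        """Exact fraction of samples strictly below ``x`` (from the raw
        cumulative, interpolated at bin resolution)."""
        idx = np.searchsorted(self.bin_edges[1:], x, side="right")
        if idx == 0:
            return 0.0
        return float(self.cumulative[min(idx, len(self.cumulative)) - 1])


def distance_histogram(series: np.ndarray, bin_width: float = 0.01) -> Histogram:
    """Histogram of a distance series with uniform ``bin_width`` (Å),
    reporting raw counts, unit-area density, and cumulative fraction."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise TrajectoryError("empty distance series")
    if bin_width <= 0:
        raise TrajectoryError("bin width must be positive")
    lo = math.floor(series.min() / bin_width) * bin_width
    hi = math.ceil(series.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(series, bins=edges)
    density = counts / (counts.sum() * bin_width)
    cumulative = np.cumsum(counts) / counts.sum()
    return Histogram(edges, counts, density, cumulative)


@dataclass
class OccupancyReport:
    interaction: tuple[str, str, str]  # donor, hydrogen, acceptor labels
    frames_present: int
    n_frames: int

    @property
    def fraction(self) -> float:
        """Percent of frames in which the hydrogen bond is formed."""
        return 100.0 * self.frames_present / self.n_frames


def hbond_occupancy(
    traj: Trajectory,
    donor: int,
    hydrogen: int,
    acceptor: int,
    d_max: float = 3.5,
    angle_min: float = 140.0,
) -> OccupancyReport:
    """Fraction of frames in which donor–acceptor < ``d_max`` Å and the
    donor–H–acceptor angle > ``angle_min``° (both criteria per frame)."""
    d = traj.frames[:, donor]
    h = traj.frames[:, hydrogen]
    a = traj.frames[:, acceptor]
    d_da = np.linalg.norm(d - a, axis=1)
    v1, v2 = d - h, a - h
    cosang = np.sum(v1 * v2, axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    present = int(np.sum((d_da < d_max) & (angles > angle_min)))
    labels = tuple(str(i) for i in (donor, hydrogen, acceptor))
    return OccupancyReport(labels, present, traj.n_frames)  # type: ignore[arg-type]


def extract_frames(traj: Trajectory, times: list[float]) -> list[Structure]:
    """Nearest-frame snapshot per requested time (ties to the earlier
    frame), exported as full structures."""
    out = []
    t = traj.frame_times
    for query in times:
        if not t[0] <= query <= t[-1]:
            raise TrajectoryError(f"time {query} outside trajectory span [{t[0]}, {t[-1]}]")
        diffs = np.abs(t - query)
        idx = int(np.argmin(diffs))  # argmin takes the first (earlier) on ties
        out.append(traj.topology.with_coordinates(traj.frames[idx]))
    return out


# ---------------------------------------------------------------------------
# I/O

def read_trajectory_pdb(path: str | Path, dt: float = 1.0, t0: float = 0.0) -> Trajectory:
    """Read a multi-model PDB as a trajectory; frame k gets time t0 + k·dt."""
    st = gemmi.read_pdb(str(Path(path)))
    if len(st) == 0:
        raise TrajectoryError(f"{path}: no models")
    topology = _model_to_structure(st[0], Path(path).stem)
    frames = []
    n_atoms = topology.n_atoms
    for model in st:
        coords = [
            [a.pos.x, a.pos.y, a.pos.z] for chain in model for res in chain for a in res
        ]
        if len(coords) != n_atoms:
            raise TrajectoryError(f"{path}: model atom counts differ")
        frames.append(coords)
    times = t0 + dt * np.arange(len(frames))
    return Trajectory(topology, np.array(frames), times)


def _model_to_structure(model: gemmi.Model, name: str) -> Structure:
    out = Structure(id=name, source_format="pdb")
    for chain in model:
        for res in chain:
            residue = Residue(chain.name, res.seqid.num, res.name.strip(),
                              (res.seqid.icode or "").strip())
            for atom in res:
                residue.add_atom(
                    Atom(atom.name, atom.element.name,
                         np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                         atom.occ, atom.b_iso, atom.serial)
                )
            out.add_residue(residue)
    return out


def write_trajectory_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write the documented plain-text frame format: per frame an atom
    count line, a ``t= <ps>`` comment line, then ``name x y z`` rows."""
    names = [a.name for _, a in traj.topology.atoms()]
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"{len(names)}\n")
            fh.write(f"t= {traj.frame_times[k]:.6g}\n")
            for name, (x, y, z) in zip(names, traj.frames[k]):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_trajectory_xyz(path: str | Path, topology: Structure) -> Trajectory:
    """Read the plain-text frame format back against a known topology."""
    frames: list[list[list[float]]] = []
    times: list[float] = []
    n_atoms = topology.n_atoms
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            count = int(lines[k].strip())
        except ValueError:
            raise TrajectoryError(f"{path}:{k + 1}: expected atom count") from None
        if count != n_atoms:
            raise TrajectoryError(f"{path}:{k + 1}: atom count {count} != topology {n_atoms}")
        comment = lines[k + 1].strip()
        time = float(comment.split()[-1]) if comment.startswith("t=") else float(len(times))
        coords = []
        for row in lines[k + 2 : k + 2 + count]:
            parts = row.split()
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(coords)
        times.append(time)
        k += 2 + count
    if not frames:
        raise TrajectoryError(f"{path}: no frames")
    return Trajectory(topology, np.array(frames), np.array(times))
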