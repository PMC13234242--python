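"""Reaction-coordinate and free-energy machinery for metadynamics
post-processing.

Collective variables (CVs) are signed combinations of coordination
numbers built from the rational switching function
``s(r) = (1 − (r/r0)^nn) / (1 − (r/r0)^mm)`` (defaults nn=6, mm=12,
value nn/mm at the removable singularity r = r0).  Gaussian hills
deposited along a nontempered run are summed into a bias potential; the
free-energy surface (FES) estimator is plain −V(s), min-shifted to 0.
The activation barrier is extracted as the minimax cost of a path on the
8-connected FES grid (the path minimising the maximum free energy met
en route), with an integrated-cost mode as an option.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MetadError",
    "SwitchingParams",
    "CVDefinition",
    "Hill",
    "WallBias",
    "FESGrid",
    "PathResult",
    "switching",
    "coordination",
    "evaluate_cv",
    "wall_energy",
    "bias_potential",
    "read_hills",
    "write_hills",
    "reconstruct_fes",
    "min_free_energy_path",
    "minimax_barrier_threshold",
    "detect_transition",
]


class MetadError(ValueError):
    pass


@dataclass(frozen=True)
class SwitchingParams:
    """Rational switching function parameters; r0 in Å."""

    r0: float
    nn: int = 6
    mm: int = 12

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise MetadError("r0 must be positive")
        if not 0 < self.nn < self.mm:
            raise MetadError("exponents must satisfy mm > nn > 0")


def switching(r: float | np.ndarray, params: SwitchingParams) -> float | np.ndarray:
    """s(r) = (1 − (r/r0)^nn) / (1 − (r/r0)^mm), with s(r0) = nn/mm.

    Strictly decreasing from 1 (r → 0) to 0 (r → ∞); the apparent 0/0 at
    r = r0 is removable (L'Hôpital: nn/mm).
    """
    x = np.asarray(r, dtype=float) / params.r0
    xp_n, xp_m = x**params.nn, x**params.mm
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (1.0 - xp_n) / (1.0 - xp_m)
    near = np.isclose(x, 1.0, atol=1e-8)
    if np.any(near):
        s = np.where(near, params.nn / params.mm, s)
    return float(s) if np.isscalar(r) else s


def coordination(distance: float, params: SwitchingParams) -> float:
    """Coordination number of a single atom pair = switching(distance)."""
    if distance < 0:
        raise MetadError("distance must be nonnegative")
    return float(switching(distance, params))


@dataclass
class CVDefinition:
    """A CV combining the coordination numbers of a forming and a breaking
    contact: cv = c_formed·s(d_formed) + c_broken·s(d_broken).

    With the default coefficients (+0.5, −0.5) the reactant (formed
    contact absent, broken contact present) sits near −0.5 and the
    product near +0.5.
    """

    name: str
    pair_formed: tuple[int, int]
    params_formed: SwitchingParams
    pair_broken: tuple[int, int]
    params_broken: SwitchingParams
    coefficients: tuple[float, float] = (0.5, -0.5)

    def __post_init__(self) -> None:
        if set(self.pair_formed) == set(self.pair_broken):
            raise MetadError("formed and broken pairs must differ")


def evaluate_cv(coords: np.ndarray, cvdef: CVDefinition) -> float:
    """Evaluate a CV on one frame of coordinates (n_atoms × 3, Å)."""
    coords = np.asarray(coords, dtype=float)
    for idx in (*cvdef.pair_formed, *cvdef.pair_broken):
        if not 0 <= idx < len(coords):
            raise MetadError(f"atom index {idx} outside frame of {len(coords)} atoms")
    d_formed = float(np.linalg.norm(coords[cvdef.pair_formed[0]] - coords[cvdef.pair_formed[1]]))
    d_broken = float(np.linalg.norm(coords[cvdef.pair_broken[0]] - coords[cvdef.pair_broken[1]]))
    c_f, c_b = cvdef.coefficients
    return c_f * coordination(d_formed, cvdef.params_formed) + c_b * coordination(
        d_broken, cvdef.params_broken
    )


@dataclass(frozen=True)
class WallBias:
    """One-sided (upper) harmonic wall: 0 below ``location``, then
    ``force_constant``·(d − location)^``exponent`` (kcal/mol)."""

    atom_pair: tuple[int, int] = (0, 1)
    location: float = 5.5
    force_constant: float = 200.0
    exponent: int = 2

    def __post_init__(self) -> None:
        if self.location <= 0:
            raise MetadError("wall location must be positive")
        if self.force_constant < 0:
            raise MetadError("force constant must be nonnegative")


def wall_energy(distance: float, wall: WallBias) -> float:
    if distance < 0:
        raise MetadError("distance must be nonnegative")
    if distance <= wall.location:
        return 0.0
    return wall.force_constant * (distance - wall.location) ** wall.exponent


# ---------------------------------------------------------------------------
# hills

@dataclass
class Hill:
    """One deposited Gaussian: time (ps), center in CV space, per-CV sigma,
    height (kcal/mol).  Defaults follow the study conditions (σ 0.005 and
    0.006 in CV units, 0.59 kcal/mol every 100 fs)."""

    time: float
    center: np.ndarray
    sigma: np.ndarray
    height: float = 0.59

    def __post_init__(self) -> None:
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if self.center.shape != self.sigma.shape:
            raise MetadError("center and sigma must have equal dimensionality")
        if np.any(self.sigma <= 0):
            raise MetadError("sigma must be positive")
        if self.height < 0:
            raise MetadError("height must be nonnegative")


def bias_potential(point: Sequence[float], hills: Sequence[Hill]) -> float:
    """Exact hill sum V(s) = Σ h·exp(−Σ_d (s_d − c_d)² / (2σ_d²))."""
    point = np.atleast_1d(np.asarray(point, dtype=float))
    total = 0.0
    for hill in hills:
        if hill.center.shape != point.shape:
            raise MetadError(
                f"hill dimensionality {hill.center.shape} != point {point.shape}"
            )
        z = (point - hill.center) / hill.sigma
        total += hill.height * math.exp(-0.5 * float(np.dot(z, z)))
    return total


def read_hills(path: str | Path) -> list[Hill]:
    """Read a PLUMED-style HILLS text file.

    Columns: time, one per CV center, one per CV sigma, height, and an
    optional (ignored) bias-factor column.  Lines starting with ``#`` are
    comments.  The CV dimensionality is inferred from the column count.
    """
    hills: list[Hill] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                values = [float(tok) for tok in stripped.split()]
            except ValueError:
                raise MetadError(f"{path}:{lineno}: malformed hills row") from None
            n = len(values)
            if n >= 4 and (n - 2) % 2 == 0:
                ndim = (n - 2) // 2
                biasf = False
            elif n >= 5 and (n - 3) % 2 == 0:
                ndim = (n - 3) // 2
                biasf = True
            else:
                raise MetadError(f"{path}:{lineno}: cannot infer CV dimensionality from {n} columns")
            time = values[0]
            center = values[1 : 1 + ndim]
            sigma = values[1 + ndim : 1 + 2 * ndim]
            height = values[1 + 2 * ndim]
            _ = biasf  # bias-factor column, tolerated and ignored
            hills.append(Hill(time, center, sigma, height))
    return hills


def write_hills(hills: Sequence[Hill], path: str | Path, comment: str | None = None) -> None:
    """Write hills in the same whitespace-column layout (lossless round-trip)."""
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        if hills:
            ndim = len(hills[0].center)
            cols = ["time"] + [f"cv{i+1}" for i in range(ndim)] + [
                f"sigma_cv{i+1}" for i in range(ndim)
            ] + ["height"]
            fh.write("#! FIELDS " + " ".join(cols) + "\n")
        for h in hills:
            row = [h.time, *h.center, *h.sigma, h.height]
            # repr-level precision: the round-trip is lossless
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# free-energy surface

@dataclass
class FESGrid:
    """Uniform 2D grid of free energies (kcal/mol), min-shifted to 0."""

    axes: tuple[np.ndarray, np.ndarray]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.axes[0]), len(self.axes[1])):
            raise MetadError("values shape must match axes lengths")

    def node_of(self, point: Sequence[float]) -> tuple[int, int]:
        """Index of the grid node nearest to a CV-space point."""
        point = np.asarray(point, dtype=float)
        out = []
        for k, axis in enumerate(self.axes):
            if not (axis[0] - 1e-9 <= point[k] <= axis[-1] + 1e-9):
                raise MetadError(
                    f"point component {point[k]} outside grid axis [{axis[0]}, {axis[-1]}]"
                )
            out.append(int(np.argmin(np.abs(axis - point[k]))))
        return tuple(out)  # type: ignore[return-value]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("cv1\tcv2\tfree_energy\n")
            for i, x in enumerate(self.axes[0]):
                for j, y in enumerate(self.axes[1]):
                    fh.write(f"{x:.6g}\t{y:.6g}\t{self.values[i, j]:.6g}\n")


def _make_axis(spec: tuple[float, float, float]) -> np.ndarray:
    lo, hi, step = spec
    if step <= 0 or hi <= lo:
        raise MetadError(f"bad axis spec {spec}")
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def reconstruct_fes(
    hills: Sequence[Hill],
    grid: Sequence[tuple[float, float, float]] = ((-0.8, 0.8, 0.01), (-0.8, 0.8, 0.01)),
    truncate_sigmas: float = 8.0,
) -> FESGrid:
    """Nontempered FES estimate F(s) = −Σ hills, min-shifted to 0.

    Each Gaussian is deposited on the grid with support truncated at
    ``truncate_sigmas``·σ (exp(−32) ≈ 1e−14 at the default), which makes
    reconstruction linear in the number of hills.  Hills whose centers
    fall outside the grid are clipped to it with a warning-free best
    effort (their in-grid tails still contribute).
    """
    ax1, ax2 = _make_axis(tuple(grid[0])), _make_axis(tuple(grid[1]))
    bias = np.zeros((len(ax1), len(ax2)))
    for h in hills:
        if h.center.shape != (2,):
            raise MetadError("reconstruct_fes expects 2D hills")
        lo1 = np.searchsorted(ax1, h.center[0] - truncate_sigmas * h.sigma[0])
        hi1 = np.searchsorted(ax1, h.center[0] + truncate_sigmas * h.sigma[0]) + 1
        lo2 = np.searchsorted(ax2, h.center[1] - truncate_sigmas * h.sigma[1])
        hi2 = np.searchsorted(ax2, h.center[1] + truncate_sigmas * h.sigma[1]) + 1
        if lo1 >= hi1 - 0 or lo2 >= hi2 - 0 or lo1 >= len(ax1) or lo2 >= len(ax2):
            continue
        z1 = (ax1[lo1:hi1] - h.center[0]) / h.sigma[0]
        z2 = (ax2[lo2:hi2] - h.center[1]) / h.sigma[1]
        bias[lo1:hi1, lo2:hi2] += h.height * np.exp(
            -0.5 * (z1[:, None] ** 2 + z2[None, :] ** 2)
        )
    fes = -bias
    fes -= fes.min()
    return FESGrid((ax1, ax2), fes)


# ---------------------------------------------------------------------------
# minimum free energy path

@dataclass
class PathResult:
    """Grid path with its free-energy profile; barrier = max − profile[0]."""

    nodes: list[tuple[int, int]]
    coords: list[tuple[float, float]]
    free_energy_profile: np.ndarray
    mode: str = "minimax"

    @property
    def barrier(self) -> float:
        return float(np.max(self.free_energy_profile) - self.free_energy_profile[0])


_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def min_free_energy_path(
    grid: FESGrid,
    start: Sequence[float],
    end: Sequence[float],
    mode: str = "minimax",
) -> PathResult:
    """Path between two CV points on the 8-connected grid graph.

    ``minimax`` (default) minimises the maximum free energy on the path
    (ties broken by minimal integrated free energy, then lexicographic
    node order); ``integrated`` minimises the sum of node free energies.
    """
    if mode not in ("minimax", "integrated"):
        raise MetadError(f"unknown path mode {mode!r}")
    f = grid.values
    n1, n2 = f.shape
    s = grid.node_of(start)
    t = grid.node_of(end)

    inf = math.inf
    best = {s: (f[s], f[s])}  # node -> (max so far, sum so far)
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    heap = [(f[s], f[s], s)] if mode == "minimax" else [(f[s], s)]
    done: set[tuple[int, int]] = set()
    while heap:
        if mode == "minimax":
            cur_max, cur_sum, node = heapq.heappop(heap)
        else:
            cur_sum, node = heapq.heappop(heap)
            cur_max = cur_sum
        if node in done:
            continue
        done.add(node)
        if node == t:
            break
        i, j = node
        for di, dj in _NEIGHBOURS:
            ni, nj = i + di, j + dj
            if not (0 <= ni < n1 and 0 <= nj < n2):
                continue
            nb = (ni, nj)
            if nb in done:
                continue
            if mode == "minimax":
                cand = (max(cur_max, f[nb]), cur_sum + f[nb])
            else:
                cand = (cur_sum + f[nb], cur_sum + f[nb])
            old = best.get(nb, (inf, inf))
            key_new = cand if mode == "minimax" else (cand[0],)
            key_old = old if mode == "minimax" else (old[0],)
            if key_new < key_old:
                best[nb] = cand
                parent[nb] = node
                if mode == "minimax":
                    heapq.heappush(heap, (cand[0], cand[1], nb))
                else:
                    heapq.heappush(heap, (cand[0], nb))
    if t not in done:
        raise MetadError("end point unreachable on grid")

    nodes = [t]
    while nodes[-1] != s:
        nodes.append(parent[nodes[-1]])
    nodes.reverse()
    coords = [(float(grid.axes[0][i]), float(grid.axes[1][j])) for i, j in nodes]
    profile = np.array([f[n] for n in nodes])
    return PathResult(nodes, coords, profile, mode)


def minimax_barrier_threshold(grid: FESGrid, start, end) -> float:
    """Independent minimax value via the threshold/connectivity
    characterisation: the smallest level t such that start and end are
    connected through nodes with F ≤ t (union-find over sorted levels).

    Serves as a cross-check oracle for :func:`min_free_energy_path`.
    """
    f = grid.values
    n1, n2 = f.shape
    s = grid.node_of(start)
    t = grid.node_of(end)
    order = np.argsort(f, axis=None)
    parent = list(range(n1 * n2))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    active = np.zeros(f.shape, dtype=bool)
    si, ti = s[0] * n2 + s[1], t[0] * n2 + t[1]
    for flat in order:
        i, j = divmod(int(flat), n2)
        active[i, j] = True
        for di, dj in _NEIGHBOURS:
            ni, nj = i + di, j + dj
            if 0 <= ni < n1 and 0 <= nj < n2 and active[ni, nj]:
                parent[find(int(flat))] = find(ni * n2 + nj)
        if find(si) == find(ti):
            return float(f[i, j])
    raise MetadError("start and end never connected")


# ---------------------------------------------------------------------------
# transitions

def detect_transition(
    times: np.ndarray,
    series: Sequence[np.ndarray],
    threshold: float = 0.0,
    dwell: float = 0.2,
) -> float | None:
    """Earliest time at which every CV series exceeds ``threshold`` and
    stays above it for at least ``dwell`` (same time units as ``times``),
    or ``None`` if no such crossing exists."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise MetadError("empty time series")
    stack = np.vstack([np.asarray(s, dtype=float) for s in series])
    if stack.shape[1] != times.size:
        raise MetadError("series length must match times")
    above = np.all(stack > threshold, axis=0)
    n = times.size
    k = 0
    while k < n:
        if not above[k]:
            k += 1
            continue
        j = k
        while j + 1 < n and above[j + 1]:
            j += 1
        # a run reaching the last sample counts as sustained: the series
        # ends while still above threshold
        if times[j] - times[k] >= dwell or j == n - 1:
            return float(times[k])
        k = j + 1
    return None
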