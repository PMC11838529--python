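"""Trajectory-derived statistics: side-chain chi time series, periodic
density maps, rotamer-state detection, and hydration counts around a
selection.

Trajectories are multi-model structures (each model one frame, identical
topology).  Angles live on a circle; the density estimate replicates the
data at ±360° (±180° for symmetry-folded torsions) and the state detector
uses circular distances throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structcore import ProteinStructure, chi_angles

__all__ = [
    "ChiSeries",
    "DensityMap",
    "RotamerStates",
    "HydrationSeries",
    "extract_chi_series",
    "kde_density",
    "detect_rotamer_states",
    "count_waters_near",
]


@dataclass
class ChiSeries:
    residue: tuple  # (chain, seqnum)
    resname: str
    times: np.ndarray  # ns
    chi1: np.ndarray  # degrees, canonicalized
    chi2: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.chi1 = np.asarray(self.chi1, dtype=float)
        self.chi2 = np.asarray(self.chi2, dtype=float)
        if not (len(self.times) == len(self.chi1) == len(self.chi2)):
            raise ValueError("times/chi arrays differ in length")

    def __len__(self):
        return len(self.times)


@dataclass
class DensityMap:
    grid: np.ndarray  # (n1, n2) density over (chi1, chi2)
    chi1_edges: np.ndarray
    chi2_edges: np.ndarray
    bandwidth: tuple
    degenerate: bool = False

    @property
    def integral(self) -> float:
        d1 = np.diff(self.chi1_edges).mean()
        d2 = np.diff(self.chi2_edges).mean()
        return float(self.grid.sum() * d1 * d2)

    def argmax(self):
        i, j = np.unravel_index(int(np.argmax(self.grid)), self.grid.shape)
        c1 = 0.5 * (self.chi1_edges[i] + self.chi1_edges[i + 1])
        c2 = 0.5 * (self.chi2_edges[j] + self.chi2_edges[j + 1])
        return c1, c2


@dataclass
class RotamerStates:
    n_states: int
    modes: np.ndarray  # degrees
    occupancy: np.ndarray
    labels: np.ndarray  # per-frame state index
    dwell_segments: list  # (state, start, length)


@dataclass
class HydrationSeries:
    times: np.ndarray
    counts: np.ndarray
    selection: tuple
    cutoff: float

    @property
    def mean(self) -> float:
        return float(self.counts.mean())

    @property
    def sd(self) -> float:
        return float(self.counts.std(ddof=1)) if len(self.counts) > 1 else 0.0


def extract_chi_series(
    trajectory: ProteinStructure,
    residue: tuple,
    stride: int = 1,
    frame_interval_ns: float = 1.0,
    canonicalize_symmetry: bool = True,
) -> ChiSeries:
    """Per-frame chi1/chi2 for one residue, with symmetry canonicalization
    and stride subsampling."""
    trajectory.validate_trajectory()
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames = range(0, trajectory.n_models, stride)
    chi1, chi2, times = [], [], []
    resname = None
    for m in frames:
        r = trajectory.find(residue[0], residue[1], model=m)
        if r is None:
            raise ValueError(f"residue {residue} missing from model {m + 1}")
        resname = r.name
        chis = chi_angles(r, canonicalize_symmetry=canonicalize_symmetry)
        if len(chis) < 2 or chis[0] is None or chis[1] is None:
            raise ValueError(f"residue {residue} lacks chi1/chi2 atoms in model {m + 1}")
        chi1.append(chis[0])
        chi2.append(chis[1])
        times.append(m * frame_interval_ns)
    return ChiSeries((residue[0], residue[1]), resname, np.array(times), np.array(chi1), np.array(chi2))


def _scott_bw(x, period):
    # circular std via resultant length, capped to stay positive
    rad = np.radians(x * (360.0 / period))
    R = abs(np.mean(np.exp(1j * rad)))
    R = min(max(R, 1e-12), 1 - 1e-12)
    circ_sd = np.degrees(np.sqrt(-2 * np.log(R))) * (period / 360.0)
    return max(circ_sd, 1.0) * len(x) ** (-1.0 / 6.0)


def kde_density(
    chi1,
    chi2,
    bandwidth="auto",
    grid_step: float = 2.0,
    window1: tuple = (-180.0, 180.0),
    window2: tuple = (-180.0, 180.0),
) -> DensityMap:
    """Gaussian product-kernel density on the torus.

    Data are replicated at ±period in both dimensions before evaluation and
    the grid is restricted to the canonical windows; the map is normalized
    to unit integral.  ``bandwidth="auto"`` uses Scott's rule per dimension
    on the circular spread.
    """
    x = np.asarray(chi1, dtype=float)
    y = np.asarray(chi2, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 points")
    p1 = window1[1] - window1[0]
    p2 = window2[1] - window2[0]
    degenerate = False
    if bandwidth == "auto":
        b1, b2 = _scott_bw(x, p1), _scott_bw(y, p2)
    else:
        b1 = b2 = float(bandwidth)
    if np.ptp(x) < 1e-9 and np.ptp(y) < 1e-9:
        warnings.warn("zero variance in both chi dimensions; density is delta-like")
        degenerate = True
        b1 = b2 = max(grid_step, 1.0)
    reps = []
    for dx in (-p1, 0.0, p1):
        for dy in (-p2, 0.0, p2):
            reps.append(np.column_stack([x + dx, y + dy]))
    pts = np.vstack(reps)
    e1 = np.arange(window1[0], window1[1] + grid_step / 2, grid_step)
    e2 = np.arange(window2[0], window2[1] + grid_step / 2, grid_step)
    c1 = 0.5 * (e1[:-1] + e1[1:])
    c2 = 0.5 * (e2[:-1] + e2[1:])
    G1, G2 = np.meshgrid(c1, c2, indexing="ij")
    dens = np.zeros_like(G1)
    # vectorized over grid, chunked over points to bound memory
    for start in range(0, len(pts), 2000):
        chunk = pts[start : start + 2000]
        d1 = (G1[..., None] - chunk[:, 0]) / b1
        d2 = (G2[..., None] - chunk[:, 1]) / b2
        dens += np.exp(-0.5 * (d1**2 + d2**2)).sum(axis=-1)
    total = dens.sum() * grid_step * grid_step
    if total <= 0:
        raise RuntimeError("density normalization failed")
    dens /= total
    return DensityMap(dens, e1, e2, (b1, b2), degenerate=degenerate)


def _circ_dist(a, b, period=360.0):
    d = np.abs((a - b) % period)
    return np.minimum(d, period - d)


def detect_rotamer_states(
    series: ChiSeries,
    which: str = "auto",
    min_separation: float = 60.0,
    min_occupancy: float = 0.05,
    period: float = 360.0,
    bandwidth: float | str = "auto",
) -> RotamerStates:
    """Circular 1-D mode clustering of a chi series.

    Modes are KDE maxima separated by at least ``min_separation``; frames
    are assigned to the circularly nearest mode, and states below
    ``min_occupancy`` merge into their nearest neighbour.  ``which`` picks
    the torsion: chi2 for Gln/Leu (their gating torsion in practice),
    chi1 otherwise, when "auto".
    """
    if len(series) < 50:
        raise ValueError("need at least 50 frames")
    if which == "auto":
        which = "chi2" if series.resname.upper() in ("GLN", "LEU") else "chi1"
    x = getattr(series, which)
    bw = _scott_bw(x, period) if bandwidth == "auto" else float(bandwidth)
    grid = np.arange(-180.0, 180.0, 1.0)
    # periodic KDE on the circle
    d = _circ_dist(grid[:, None], x[None, :], period)
    dens = np.exp(-0.5 * (d / bw) ** 2).sum(axis=1)
    # local maxima on the circular grid
    left = np.roll(dens, 1)
    right = np.roll(dens, -1)
    peaks = grid[(dens >= left) & (dens > right)]
    heights = dens[(dens >= left) & (dens > right)]
    order = np.argsort(-heights)
    modes: list[float] = []
    for i in order:
        if all(_circ_dist(peaks[i], m, period) >= min_separation for m in modes):
            modes.append(float(peaks[i]))
    modes_arr = np.array(sorted(modes))

    def assign(modes_arr):
        dd = _circ_dist(x[:, None], modes_arr[None, :], period)
        return np.argmin(dd, axis=1)

    labels = assign(modes_arr)
    while True:
        occ = np.array([(labels == k).mean() for k in range(len(modes_arr))])
        weak = np.where((occ < min_occupancy) & (occ >= 0))[0]
        weak = [k for k in weak if occ[k] < min_occupancy]
        if len(modes_arr) <= 1 or not weak:
            break
        k = weak[int(np.argmin(occ[weak]))]
        modes_arr = np.delete(modes_arr, k)
        labels = assign(modes_arr)
    occ = np.array([(labels == k).mean() for k in range(len(modes_arr))])
    segments = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segments.append((int(labels[start]), start, i - start))
            start = i
    return RotamerStates(len(modes_arr), modes_arr, occ, labels, segments)


def count_waters_near(
    trajectory: ProteinStructure,
    selection,
    cutoff: float = 3.5,
    water_resnames=("HOH", "WAT"),
    frame_interval_ns: float = 1.0,
) -> HydrationSeries:
    """Per-frame count of water oxygens within ``cutoff`` (closed interval)
    of any selection atom.  ``selection`` is a list of (chain, seqnum,
    atomname) specs; water hydrogens are ignored."""
    if not selection:
        raise ValueError("empty selection")
    trajectory.validate_trajectory()
    counts, times = [], []
    any_waters = False
    for m in range(trajectory.n_models):
        sel_pts = []
        for chain, seqnum, name in selection:
            r = trajectory.find(chain, seqnum, model=m)
            if r is None:
                raise ValueError(f"selection residue {chain}:{seqnum} missing from model {m + 1}")
            sel_pts.append(r.coord(name))
        tree = cKDTree(np.array(sel_pts))
        n = 0
        for r in trajectory.residues(m):
            if r.name.upper() not in water_resnames:
                continue
            for a in r.atoms:
                if a.element.strip().upper() != "O":
                    continue
                any_waters = True
                d, _ = tree.query(a.pos)
                if d <= cutoff:
                    n += 1
        counts.append(n)
        times.append(m * frame_interval_ns)
    if not any_waters:
        warnings.warn("no waters in topology; hydration series is all zero")
    return HydrationSeries(np.array(times), np.array(counts), tuple(map(tuple, selection)), cutoff)
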