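"""Shrake–Rupley solvent-accessible surface area.

Deterministic golden-spiral point set (no RNG), 960 points per atom by
default; a 1.4 Å probe approximates water.  "Fully inaccessible" in the
placement filters means per-atom SASA below 0.1 Ų.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .model import ProteinStructure, VdwTable

__all__ = ["golden_spiral", "sasa_points", "shrake_rupley_sasa", "relative_ca_accessibility"]


def golden_spiral(n: int) -> np.ndarray:
    """n points quasi-uniformly distributed on the unit sphere (Fibonacci lattice)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa_points(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
    return_directions: bool = False,
):
    """Per-atom SASA (Ų) for spheres at ``coords`` with vdW ``radii``.

    When ``return_directions`` is set, also returns the mean unit direction
    of each atom's accessible surface points (zero vector if buried) —
    useful for asking *where* an atom is exposed.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    areas = np.zeros(n)
    dirs = np.zeros((n, 3))
    if n == 0:
        return (areas, dirs) if return_directions else areas
    sphere = golden_spiral(n_points)
    ext = radii + probe_radius
    tree = cKDTree(coords)
    max_reach = 2.0 * ext.max()
    pairs = tree.query_ball_tree(tree, r=max_reach)
    for i in range(n):
        ri = ext[i]
        pts = coords[i] + ri * sphere
        nbrs = [j for j in pairs[i] if j != i]
        acc = np.ones(n_points, dtype=bool)
        for j in nbrs:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            acc &= d2 > ext[j] ** 2
            if not acc.any():
                break
        frac = acc.mean()
        areas[i] = frac * 4.0 * np.pi * ri**2
        if return_directions and acc.any():
            v = sphere[acc].mean(axis=0)
            norm = np.linalg.norm(v)
            if norm > 1e-12:
                dirs[i] = v / norm
    return (areas, dirs) if return_directions else areas


def shrake_rupley_sasa(
    structure: ProteinStructure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    vdw: VdwTable | None = None,
    model: int = 0,
    extra_coords=None,
    extra_elements=None,
):
    """Per-atom SASA for all heavy atoms of one model.

    Returns ``(areas, keys)`` where ``keys[i]`` is (chain, seqnum, resname,
    atomname); ``extra_coords``/``extra_elements`` (e.g. a posed ligand) are
    occluders *and* get areas appended at the end with key
    ('*', 0, 'EXT', index).
    """
    vdw = vdw or VdwTable()
    coords, elements, keys = structure.atom_table(model=model, heavy_only=True)
    if extra_coords is not None:
        extra_coords = np.asarray(extra_coords, dtype=float).reshape(-1, 3)
        coords = np.vstack([coords, extra_coords]) if len(coords) else extra_coords
        elements = list(elements) + list(extra_elements)
        keys = list(keys) + [("*", 0, "EXT", i) for i in range(len(extra_coords))]
    radii = vdw.radii_for(elements)
    areas = sasa_points(coords, radii, probe_radius=probe_radius, n_points=n_points)
    return areas, keys


def relative_ca_accessibility(
    structure: ProteinStructure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    vdw: VdwTable | None = None,
    model: int = 0,
) -> dict:
    """Cα accessibility of every residue relative to the same Cα occluded
    only by its own residue — a cheap, deterministic surface/interior score
    in [0, 1]."""
    vdw = vdw or VdwTable()
    areas, keys = shrake_rupley_sasa(structure, probe_radius, n_points, vdw, model)
    in_struct = {k[:2]: a for k, a in zip(keys, areas) if k[3] == "CA"}
    out = {}
    for r in structure.residues(model):
        if r.atom("CA") is None:
            continue
        heavy = r.heavy_atoms()
        coords = np.array([a.pos for a in heavy])
        radii = vdw.radii_for([a.element for a in heavy])
        alone = sasa_points(coords, radii, probe_radius, n_points)
        idx = [i for i, a in enumerate(heavy) if a.name == "CA"][0]
        ref = alone[idx]
        out[r.key] = float(in_struct.get(r.key, 0.0) / ref) if ref > 1e-9 else 0.0
    return out
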