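"""Steric clash detection and distance-shell residue selection.

Bonds are inferred by distance (heavy-heavy < 1.8 Å, 2.0 Å when either atom
is sulfur) unless a bond list is supplied; pairs within three bonds
(1-2, 1-3, 1-4) are excluded from clash reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import ProteinStructure, VdwTable

__all__ = ["Clash", "infer_bonds", "count_clashes", "select_shell"]

_BOND_CC = 1.8
_BOND_S = 2.0


@dataclass(frozen=True)
class Clash:
    i: int
    j: int
    key_i: tuple
    key_j: tuple
    distance: float
    overlap: float  # depth beyond tolerance, Å


def infer_bonds(coords: np.ndarray, elements) -> set[tuple[int, int]]:
    """Distance-based covalent bond inference over heavy atoms."""
    coords = np.asarray(coords, dtype=float)
    els = [e.strip().upper() for e in elements]
    if len(coords) == 0:
        return set()
    tree = cKDTree(coords)
    bonds = set()
    for i, j in tree.query_pairs(r=_BOND_S):
        cut = _BOND_S if ("S" in (els[i], els[j])) else _BOND_CC
        if np.linalg.norm(coords[i] - coords[j]) < cut:
            bonds.add((min(i, j), max(i, j)))
    return bonds


def _excluded_pairs(bonds: set[tuple[int, int]]) -> set[tuple[int, int]]:
    """Pairs within 3 bonds (1-2, 1-3 and 1-4): their contacts are governed
    by bond/angle/torsion terms, not vdW overlap."""
    adj: dict[int, set[int]] = {}
    for i, j in bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    excl = set(bonds)
    for k, nbrs in adj.items():
        nb = sorted(nbrs)
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                excl.add((nb[a], nb[b]))
    # 1-4: endpoints of any 3-bond path
    for i, j in bonds:
        for ni in adj.get(i, ()):
            for nj in adj.get(j, ()):
                if ni != j and nj != i and ni != nj:
                    excl.add((min(ni, nj), max(ni, nj)))
    return excl


def count_clashes(
    structure: ProteinStructure,
    extra_coords=None,
    extra_elements=None,
    extra_keys=None,
    overlap_tol: float = 0.4,
    vdw: VdwTable | None = None,
    bonds: set | None = None,
    model: int = 0,
) -> list[Clash]:
    """All heavy-atom pairs with vdW overlap beyond ``overlap_tol``.

    A pair (i, j) clashes iff d(i,j) < r_i + r_j - overlap_tol and lies
    more than three bonds apart.  ``extra_*`` appends ligand atoms (keys
    default to ('*', 0, 'EXT', idx)).
    """
    vdw = vdw or VdwTable()
    coords, elements, keys = structure.atom_table(model=model, heavy_only=True)
    if extra_coords is not None:
        extra_coords = np.asarray(extra_coords, dtype=float).reshape(-1, 3)
        coords = np.vstack([coords, extra_coords]) if len(coords) else extra_coords
        elements = list(elements) + list(extra_elements)
        if extra_keys is None:
            extra_keys = [("*", 0, "EXT", i) for i in range(len(extra_coords))]
        keys = list(keys) + list(extra_keys)
    n = len(coords)
    if n < 2:
        return []
    radii = vdw.radii_for(elements)
    if bonds is None:
        bonds = infer_bonds(coords, elements)
    excl = _excluded_pairs(bonds)
    tree = cKDTree(coords)
    out = []
    rmax = 2.0 * radii.max()
    for i, j in sorted(tree.query_pairs(r=rmax)):
        if (i, j) in excl:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        thresh = radii[i] + radii[j] - overlap_tol
        if d < thresh:
            out.append(Clash(i, j, keys[i], keys[j], d, thresh - d))
    return out


def select_shell(
    structure: ProteinStructure,
    center_atoms,
    cutoff: float = 5.0,
    model: int = 0,
) -> set[tuple[str, int]]:
    """Residues with >= 1 heavy atom within ``cutoff`` (closed interval) of
    any center atom.  ``center_atoms`` is an (n, 3) array or a list of
    (chain, seqnum, atomname) specs; residues owning a center atom are
    excluded."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    own: set[tuple[str, int]] = set()
    if isinstance(center_atoms, np.ndarray) or (
        len(center_atoms) and isinstance(center_atoms[0], (list, np.ndarray))
        and len(center_atoms[0]) == 3 and not isinstance(center_atoms[0][0], str)
    ):
        centers = np.asarray(center_atoms, dtype=float).reshape(-1, 3)
    else:
        pts = []
        for chain, seqnum, name in center_atoms:
            r = structure.find(chain, seqnum, model)
            if r is None:
                raise ValueError(f"center residue {chain}:{seqnum} not found")
            pts.append(r.coord(name))
            own.add((chain, seqnum))
        centers = np.array(pts)
    if len(centers) == 0:
        raise ValueError("empty center atom set")
    tree = cKDTree(centers)
    hit: set[tuple[str, int]] = set()
    for r in structure.residues(model):
        if r.key in own:
            continue
        for a in r.heavy_atoms():
            d, _ = tree.query(a.pos)
            if d <= cutoff:
                hit.add(r.key)
                break
    return hit
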