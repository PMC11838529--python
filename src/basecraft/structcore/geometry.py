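"""Torsion angles, optimal superposition and paired-subset RMSD."""

from __future__ import annotations

import numpy as np

from .model import ProteinStructure

__all__ = [
    "dihedral",
    "fold_symmetric",
    "wrap_angle",
    "kabsch_superpose",
    "rmsd_subset",
]

_COLLINEAR_TOL = 1e-8


def wrap_angle(x):
    """Wrap angle(s) in degrees into (-180, 180]."""
    x = np.asarray(x, dtype=float)
    w = -((-x + 180.0) % 360.0 - 180.0)
    return w if w.ndim else float(w)


def fold_symmetric(x):
    """Fold a 2-fold symmetric torsion (period 180°) into (-90, 90]."""
    x = np.asarray(x, dtype=float)
    w = -((-x + 90.0) % 180.0 - 90.0)
    return w if w.ndim else float(w)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, right-hand rule about p2->p3.

    Returns a value in (-180, 180].  Raises on collinear consecutive triples.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < _COLLINEAR_TOL * max(np.linalg.norm(b1) * nb2, 1e-30) or np.linalg.norm(
        n2
    ) < _COLLINEAR_TOL * max(np.linalg.norm(b3) * nb2, 1e-30):
        raise ValueError("degenerate geometry: three consecutive points are collinear")
    m = np.cross(n1, b2 / nb2)
    ang = float(np.degrees(np.arctan2(-np.dot(m, n2), np.dot(n1, n2))))
    return wrap_angle(ang)


def kabsch_superpose(mobile, target, mapping=None):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Parameters
    ----------
    mobile, target : (n, 3) arrays
    mapping : optional list of (i_mobile, j_target) index pairs; by default
        points are paired positionally.

    Returns
    -------
    (rotation (3,3), translation (3,), rmsd) such that
    ``mobile @ rotation.T + translation`` best fits ``target``.  The rotation
    is always proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mapping is not None:
        mi = np.array([m for m, _ in mapping], dtype=int)
        ti = np.array([t for _, t in mapping], dtype=int)
        P, Q = mobile[mi], target[ti]
    else:
        if len(mobile) != len(target):
            raise ValueError("point sets differ in length and no mapping given")
        P, Q = mobile, target
    if len(P) < 3:
        raise ValueError("need at least 3 mapped point pairs")
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - Pc, Q - Qc
    # collinearity check: second singular value of the centered cloud
    if np.linalg.svd(P0, compute_uv=False)[1] < 1e-8:
        raise ValueError("mapped points are collinear; superposition is degenerate")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Qc - R @ Pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, rmsd


def _collect(structure: ProteinStructure, names: set, model: int = 0):
    out = {}
    for r in structure.residues(model):
        for a in r.atoms:
            if a.name in names:
                out[(r.chain, r.seqnum, a.name)] = a.pos
    return out


def rmsd_subset(
    a: ProteinStructure,
    b: ProteinStructure,
    atom_selection=("CA",),
    superpose: bool = False,
    model_a: int = 0,
    model_b: int = 0,
):
    """RMSD over atoms paired by (chain, seqnum, name), optionally after
    superposing in the Cα frame.

    Returns ``(rmsd, pairs)`` where ``pairs`` lists the paired atom keys.
    Raises if the selections do not resolve to the same atom set, naming the
    orphans.
    """
    names = set(atom_selection)
    da = _collect(a, names, model_a)
    db = _collect(b, names, model_b)
    only_a = sorted(set(da) - set(db))
    only_b = sorted(set(db) - set(da))
    if only_a or only_b:
        raise ValueError(f"unmatched atoms; only in first: {only_a[:5]}, only in second: {only_b[:5]}")
    keys = sorted(da)
    if not keys:
        raise ValueError("selection resolves to no atoms")
    P = np.array([da[k] for k in keys])
    Q = np.array([db[k] for k in keys])
    if superpose:
        ca_a = _collect(a, {"CA"}, model_a)
        ca_b = _collect(b, {"CA"}, model_b)
        common = sorted(set(ca_a) & set(ca_b))
        R, t, _ = kabsch_superpose(
            np.array([ca_a[k] for k in common]), np.array([ca_b[k] for k in common])
        )
        P = P @ R.T + t
    rmsd = float(np.sqrt(((P - Q) ** 2).sum() / len(keys)))
    return rmsd, keys
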