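"""Side-chain chi torsion angles with IUPAC atom quadruples.

Terminal torsions of 2-fold symmetric groups (Tyr/Phe ring chi2, Asp
carboxylate chi2, Glu carboxylate chi3) are physically equivalent modulo
180°; ``canonicalize_symmetry`` folds them into (-90, 90].
"""

from __future__ import annotations

from .geometry import dihedral, fold_symmetric
from .model import ResidueView

__all__ = ["CHI_ATOMS", "SYMMETRIC_CHI", "chi_angles", "n_chi"]

#: chi torsion atom quadruples, per residue type, in chi1..chiN order.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"),
        ("CG", "CD", "CE", "NZ"),
    ],
}

#: (residue, chi index (0-based)) pairs whose torsion has 180° symmetry.
SYMMETRIC_CHI: set[tuple[str, int]] = {
    ("TYR", 1),
    ("PHE", 1),
    ("ASP", 1),
    ("GLU", 2),
}


def n_chi(resname: str) -> int:
    return len(CHI_ATOMS.get(resname.upper(), []))


def chi_angles(residue: ResidueView, canonicalize_symmetry: bool = False) -> list:
    """Ordered chi angles (degrees) for ``residue``; ``None`` marks an angle
    whose atoms are missing.  Unknown residue types raise."""
    resname = residue.name.upper()
    if resname not in CHI_ATOMS:
        raise ValueError(f"no chi definition for residue type {resname!r}")
    out = []
    for i, quad in enumerate(CHI_ATOMS[resname]):
        atoms = [residue.atom(n) for n in quad]
        if any(a is None for a in atoms):
            out.append(None)
            continue
        ang = dihedral(*(a.pos for a in atoms))
        if canonicalize_symmetry and (resname, i) in SYMMETRIC_CHI:
            ang = fold_symmetric(ang)
        out.append(ang)
    return out
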