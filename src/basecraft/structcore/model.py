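"""Hierarchical coordinate model: atoms, residues, multi-model structures.

The model is deliberately small: ordered residue lists per model, plain
numpy positions, author residue numbering kept verbatim.  Multi-model
structures double as trajectories, in which case every model must share
the same topology.
"""

from __future__ import annotations

import copy as _copy
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueView",
    "ProteinStructure",
    "VdwTable",
    "BONDI_RADII",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Bondi van der Waals radii (Å) for the elements that occur in protein /
#: small-molecule crystallography.  Unknown elements fall back to a default.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "ZN": 1.39,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA_ION": 2.31,
}


@dataclass
class VdwTable:
    """Element -> van der Waals radius (Å), with a declared default."""

    radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    default: float = 1.8
    warn_unknown: bool = True
    _warned: set = field(default_factory=set, repr=False)

    def radius(self, element: str) -> float:
        el = element.strip().upper()
        r = self.radii.get(el)
        if r is None:
            if self.warn_unknown and el not in self._warned:
                warnings.warn(
                    f"no van der Waals radius for element {el!r}; "
                    f"using default {self.default} Å"
                )
                self._warned.add(el)
            return self.default
        if r <= 0:
            raise ValueError(f"non-positive vdW radius for {el!r}")
        return r

    def radii_for(self, elements) -> np.ndarray:
        return np.array([self.radius(e) for e in elements], dtype=float)


@dataclass
class AtomRecord:
    """One atom: label, element, position (Å), occupancy, altloc, B-factor."""

    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class ResidueView:
    """A residue: chain id, author sequence number, 3-letter code, atoms."""

    chain: str
    seqnum: int
    name: str
    atoms: list = field(default_factory=list)

    @property
    def key(self) -> tuple:
        return (self.chain, self.seqnum)

    def atom(self, name: str, altloc: str | None = None) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name and (altloc is None or a.altloc == altloc):
                return a
        return None

    def coord(self, name: str) -> np.ndarray:
        a = self.atom(name)
        if a is None:
            raise KeyError(f"residue {self.chain}:{self.seqnum} ({self.name}) has no atom {name!r}")
        return a.pos

    def has_atoms(self, names) -> bool:
        return all(self.atom(n) is not None for n in names)

    def heavy_atoms(self):
        return [a for a in self.atoms if a.element.strip().upper() not in ("H", "D")]


class ProteinStructure:
    """Ordered models of residues; model 0 is the primary conformation.

    Invariant: (model, chain, seqnum, altloc, atom name) is unique.  When the
    structure is used as a trajectory every model must have identical
    topology (checked by :meth:`validate_trajectory`).
    """

    def __init__(self, models: list[list[ResidueView]], title: str = ""):
        if not models:
            models = [[]]
        self.models = models
        self.title = title

    # -- convenience ---------------------------------------------------
    @property
    def n_models(self) -> int:
        return len(self.models)

    def residues(self, model: int = 0):
        return self.models[model]

    def find(self, chain: str, seqnum: int, model: int = 0) -> ResidueView | None:
        for r in self.models[model]:
            if r.chain == chain and r.seqnum == seqnum:
                return r
        return None

    def copy(self) -> "ProteinStructure":
        return _copy.deepcopy(self)

    def atom_table(self, model: int = 0, heavy_only: bool = False, include_het: bool = True):
        """Flat view: (coords (n,3), elements, keys) with keys (chain, seqnum, resname, atomname)."""
        coords, elements, keys = [], [], []
        for r in self.models[model]:
            for a in r.atoms:
                if heavy_only and a.element.strip().upper() in ("H", "D"):
                    continue
                if not include_het and a.is_hetero:
                    continue
                coords.append(a.pos)
                elements.append(a.element)
                keys.append((r.chain, r.seqnum, r.name, a.name))
        if coords:
            return np.array(coords), elements, keys
        return np.zeros((0, 3)), elements, keys

    def validate_unique(self, model: int = 0):
        seen = set()
        for r in self.models[model]:
            for a in r.atoms:
                k = (r.chain, r.seqnum, a.altloc, a.name)
                if k in seen:
                    raise ValueError(f"duplicate atom key {k}")
                seen.add(k)

    def validate_trajectory(self):
        """Require identical (chain, seqnum, resname, atom-name) topology in every model."""
        ref = [(r.chain, r.seqnum, r.name, tuple(a.name for a in r.atoms)) for r in self.models[0]]
        for m in range(1, self.n_models):
            top = [(r.chain, r.seqnum, r.name, tuple(a.name for a in r.atoms)) for r in self.models[m]]
            if top != ref:
                raise ValueError(f"model {m + 1} topology differs from model 1")
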