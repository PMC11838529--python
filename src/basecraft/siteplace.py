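"""Catalytic carboxylate placement search and preorganization filters.

Two routes place a general base (Asp/Glu) so that its carboxylate abstracts
the substrate proton in a Kemp elimination:

* an exhaustive position x rotamer search against a transition-state
  analogue held in a fixed pose or in a ring-plane prior (hydrogen-bond
  geometry to the analogue's triazole NH, full burial of both the ring and
  the carboxylate oxygens, and zero steric clashes), and
* direct docking of the analogue onto an existing carboxylate along the
  more basic *syn* lone pairs of either oxygen.

Side chains are built from ideal internal coordinates (bond lengths/angles
frozen from ideal residue templates) at rotamer chi values; a small embedded
backbone-independent rotamer table supplies the low-energy rotamers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structcore import (
    AtomRecord,
    ProteinStructure,
    ResidueView,
    VdwTable,
    count_clashes,
    dihedral,
    kabsch_superpose,
    relative_ca_accessibility,
    rmsd_subset,
    shrake_rupley_sasa,
)

__all__ = [
    "RotamerSpec",
    "TSGeometryConstraint",
    "LigandPose",
    "PlanePrior",
    "PlacementCandidate",
    "PreorgReport",
    "HBondGeometry",
    "ROTAMER_TABLE",
    "place_atom",
    "build_sidechain",
    "ligand_template_6nbt",
    "superpose_ligand_by_shared_atoms",
    "score_hbond_geometry",
    "dock_ts_to_base",
    "enumerate_base_placements",
    "inter_residue_clashes",
    "preorganization_filter",
    "best_candidates",
]


# --------------------------------------------------------------------------
# types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RotamerSpec:
    """A discrete low-energy side-chain conformation: chi means + population."""

    resname: str
    chis: tuple
    probability: float

    def __post_init__(self):
        if not (0.0 < self.probability <= 1.0):
            raise ValueError("rotamer probability must be in (0, 1]")


@dataclass
class TSGeometryConstraint:
    """Hydrogen-bond geometry window for the base...analogue contact.

    Distance and angle windows bracket carboxylate H-bond statistics around
    the ~2.5–2.9 Å O–N contacts seen crystallographically; ``require_syn``
    demands the donor sit near the carboxylate plane on the *syn* side.
    """

    d_range: tuple = (2.6, 3.2)
    theta_range: tuple = (100.0, 140.0)
    syn_dihedral_max: float = 40.0
    require_syn: bool = True
    donor_atom: str = "N3"

    def __post_init__(self):
        if self.d_range[0] < 2.2:
            raise ValueError("lower distance bound below 2.2 Å is unphysical")
        for lo, hi in (self.theta_range,):
            if not (0.0 <= lo <= hi <= 180.0):
                raise ValueError("theta bounds must lie in [0, 180]")

    @property
    def d_mid(self) -> float:
        return 0.5 * (self.d_range[0] + self.d_range[1])

    @property
    def theta_mid(self) -> float:
        return 0.5 * (self.theta_range[0] + self.theta_range[1])


@dataclass
class LigandPose:
    """A rigidly placed ligand: atom name -> position, plus provenance."""

    atoms: dict
    source_fragment: str = ""
    transform: tuple | None = None  # (R, t) from the reference frame
    donor_atom: str = "N3"

    def coords(self, names=None) -> np.ndarray:
        names = names or list(self.atoms)
        return np.array([self.atoms[n] for n in names])

    @property
    def donor(self) -> np.ndarray:
        return np.asarray(self.atoms[self.donor_atom])


@dataclass
class PlanePrior:
    """Ring-plane prior: the analogue ring must lie near a given plane
    (normal + centroid), within a tilt tolerance — the plane is typically
    taken from an anchor fragment pose."""

    normal: np.ndarray
    centroid: np.ndarray
    tilt_max: float = 20.0  # degrees
    centroid_max: float = 3.0  # Å

    def __post_init__(self):
        self.normal = np.asarray(self.normal, dtype=float)
        self.normal = self.normal / np.linalg.norm(self.normal)
        self.centroid = np.asarray(self.centroid, dtype=float)

    def accepts(self, pose: "LigandPose", ring_atoms) -> bool:
        pts = pose.coords(ring_atoms)
        c = pts.mean(axis=0)
        pts0 = pts - c
        # ring normal = smallest principal axis
        _, _, vt = np.linalg.svd(pts0)
        n = vt[2]
        tilt = math.degrees(math.acos(min(1.0, abs(float(np.dot(n, self.normal))))))
        return tilt <= self.tilt_max and np.linalg.norm(c - self.centroid) <= self.centroid_max


@dataclass
class HBondGeometry:
    distance: float
    theta: float
    syn_dihedral: float
    is_syn: bool
    acceptor: str


@dataclass
class PlacementCandidate:
    position: tuple  # (chain, seqnum)
    base_type: str
    rotamer: RotamerSpec
    pose: LigandPose | None
    hbond_distance: float
    hbond_theta: float
    syn_dihedral: float
    base_carboxylate_sasa: float
    ligand_ring_sasa: float
    clash_count: int
    geometry_ok: bool
    burial_ok: bool
    surface_flag: bool
    passes: bool


@dataclass
class PreorgReport:
    backbone_rmsd: float
    active_site_rmsd_ca_cb_cg: float
    plddt: float
    passes: bool


# --------------------------------------------------------------------------
# internal-coordinate construction
# --------------------------------------------------------------------------


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position a new atom bonded to ``c`` given bond length (Å), angle
    new-c-b (deg) and torsion new-c-b-a (deg) — the standard NeRF step."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("reference atoms are collinear")
    n /= nn
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


# Ideal side-chain internal coordinates, frozen from ideal residue
# templates.  Each entry: (new_atom, (a, b, c), bond, angle, torsion_spec)
# where torsion_spec is a float (fixed), ("chi", i) for the i-th chi, or
# ("chi+", i, offset).  Carboxylate C-O bonds use the symmetric ionized
# value (1.25 Å).
_CB = ("CB", ("C", "N", "CA"), 1.530, 109.5, -120.0)

SIDECHAIN_GEOMETRY: dict[str, list] = {
    "ASP": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.508, 109.5, ("chi", 0)),
        ("OD1", ("CA", "CB", "CG"), 1.250, 118.4, ("chi", 1)),
        ("OD2", ("CA", "CB", "CG"), 1.250, 118.4, ("chi+", 1, 180.0)),
    ],
    "GLU": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.531, 109.4, ("chi", 0)),
        ("CD", ("CA", "CB", "CG"), 1.508, 109.4, ("chi", 1)),
        ("OE1", ("CB", "CG", "CD"), 1.250, 118.4, ("chi", 2)),
        ("OE2", ("CB", "CG", "CD"), 1.250, 118.4, ("chi+", 2, 180.0)),
    ],
    "LEU": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.530, 109.5, ("chi", 0)),
        ("CD1", ("CA", "CB", "CG"), 1.530, 109.5, ("chi", 1)),
        ("CD2", ("CA", "CB", "CG"), 1.529, 109.5, ("chi+", 1, 120.0)),
    ],
    "TYR": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.506, 109.5, ("chi", 0)),
        ("CD1", ("CA", "CB", "CG"), 1.382, 120.0, ("chi", 1)),
        ("CD2", ("CA", "CB", "CG"), 1.383, 120.0, ("chi+", 1, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.381, 120.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.381, 120.0, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.387, 120.0, 0.0),
        ("OH", ("CD1", "CE1", "CZ"), 1.358, 120.1, 180.0),
    ],
}

_N_CHI_BUILD = {"ASP": 2, "GLU": 3, "LEU": 2, "TYR": 2}

#: carboxylate atom labels per base type: (C, O1, O2)
CARBOXYLATE_ATOMS = {"ASP": ("CG", "OD1", "OD2"), "GLU": ("CD", "OE1", "OE2")}

_ELEMENT_FROM_NAME = lambda n: n[0]  # noqa: E731  (sidechain atom names start with element)


def build_sidechain(
    residue_backbone,
    base_type: str,
    rotamer: RotamerSpec,
    chain: str = "A",
    seqnum: int = 1,
) -> ResidueView:
    """Build a full residue (backbone + ideal-geometry side chain) at the
    rotamer's chi values.

    ``residue_backbone`` is a :class:`ResidueView` or a dict with at least
    N/CA/C positions.  Supported types: ASP, GLU (catalytic bases) plus
    LEU, TYR for trajectory emulation.  The number of chi values must match
    the residue type.
    """
    base_type = base_type.upper()
    if base_type not in SIDECHAIN_GEOMETRY:
        raise ValueError(f"unsupported residue type {base_type!r}")
    if len(rotamer.chis) != _N_CHI_BUILD[base_type]:
        raise ValueError(
            f"{base_type} takes {_N_CHI_BUILD[base_type]} chi values, got {len(rotamer.chis)}"
        )
    if isinstance(residue_backbone, ResidueView):
        pos = {a.name: a.pos for a in residue_backbone.atoms}
        chain, seqnum = residue_backbone.chain, residue_backbone.seqnum
    else:
        pos = {k: np.asarray(v, dtype=float) for k, v in residue_backbone.items()}
    for req in ("N", "CA", "C"):
        if req not in pos:
            raise ValueError(f"backbone atom {req} missing")
    coords = dict(pos)
    for new, (a, b, c), bond, angle, tspec in SIDECHAIN_GEOMETRY[base_type]:
        if isinstance(tspec, tuple):
            if tspec[0] == "chi":
                tor = float(rotamer.chis[tspec[1]])
            else:
                tor = float(rotamer.chis[tspec[1]]) + tspec[2]
        else:
            tor = tspec
        coords[new] = place_atom(coords[a], coords[b], coords[c], bond, angle, tor)
    atoms = []
    for name in ["N", "CA", "C", "O"] + [e[0] for e in SIDECHAIN_GEOMETRY[base_type]]:
        if name not in coords:
            continue
        el = "N" if name == "N" else ("O" if name.startswith("O") else "C")
        atoms.append(AtomRecord(name=name, element=el, pos=coords[name]))
    return ResidueView(chain=chain, seqnum=seqnum, name=base_type, atoms=atoms)


# --------------------------------------------------------------------------
# rotamer table (embedded, backbone-independent)
# --------------------------------------------------------------------------

#: Low-energy backbone-independent rotamers (chi means in degrees, rounded
#: populations).  Small by design: enough to cover the populated wells.
ROTAMER_TABLE: dict[str, list[RotamerSpec]] = {
    "ASP": [
        RotamerSpec("ASP", (-68.0, -19.0), 0.45),
        RotamerSpec("ASP", (-177.0, 1.0), 0.23),
        RotamerSpec("ASP", (62.0, -5.0), 0.14),
        RotamerSpec("ASP", (-68.0, 60.0), 0.08),
        RotamerSpec("ASP", (-177.0, 65.0), 0.06),
    ],
    "GLU": [
        RotamerSpec("GLU", (-67.0, -178.0, -10.0), 0.24),
        RotamerSpec("GLU", (-67.0, -65.0, -40.0), 0.18),
        RotamerSpec("GLU", (-177.0, 178.0, 0.0), 0.15),
        RotamerSpec("GLU", (-177.0, 65.0, 10.0), 0.08),
        RotamerSpec("GLU", (62.0, 180.0, 0.0), 0.07),
        RotamerSpec("GLU", (-67.0, 77.0, 10.0), 0.07),
        RotamerSpec("GLU", (-177.0, -80.0, -25.0), 0.06),
        RotamerSpec("GLU", (70.0, -80.0, 0.0), 0.05),
    ],
}


# --------------------------------------------------------------------------
# ligand template: idealized 6-nitrobenzotriazole (TS analogue)
# --------------------------------------------------------------------------

# Heavy-atom coordinates generated once from an idealized, minimized 3-D
# build of 6-nitro-1H-benzotriazole and frozen.  N3 is the triazole NH
# nitrogen (the hydrogen-bond donor to the catalytic carboxylate).
_6NBT_COORDS = {
    "O1": (3.472, 0.964, 0.278),
    "N7": (2.829, -0.089, 0.160),
    "O2": (3.335, -1.218, 0.104),
    "C6": (1.365, 0.011, 0.081),
    "C5": (0.757, 1.277, 0.142),
    "C4": (-0.636, 1.410, 0.070),
    "C3A": (-1.363, 0.227, -0.063),
    "N3": (-2.701, -0.045, -0.162),
    "N2": (-2.936, -1.361, -0.276),
    "N1": (-1.763, -1.981, -0.254),
    "C7A": (-0.784, -1.034, -0.125),
    "C7": (0.609, -1.166, -0.053),
}

#: fused bicyclic ring atoms (the part that must be buried)
RING_ATOMS_6NBT = ("C4", "C5", "C6", "C7", "C7A", "C3A", "N1", "N2", "N3")

#: ring neighbours of the donor nitrogen (define the exocyclic N-H direction)
_DONOR_NEIGHBORS = ("C3A", "N2")


def ligand_template_6nbt() -> dict:
    """Idealized 6-nitrobenzotriazole heavy-atom template (name -> xyz)."""
    return {k: np.array(v, dtype=float) for k, v in _6NBT_COORDS.items()}


def _ligand_elements(names):
    return [n[0] for n in names]


# --------------------------------------------------------------------------
# geometry scoring and docking
# --------------------------------------------------------------------------


def score_hbond_geometry(donor_N, carbox_C, carbox_O1, carbox_O2, syn_dihedral_max: float = 40.0):
    """H-bond geometry of a donor N against a carboxylate.

    distance: min over the two oxygens of |O - N|; theta: C-O...N angle at
    the closer oxygen; syn_dihedral: torsion (O_far, C, O_near, N); the
    contact is *syn* when |syn_dihedral| <= ``syn_dihedral_max``.
    """
    N, C, O1, O2 = (np.asarray(p, dtype=float) for p in (donor_N, carbox_C, carbox_O1, carbox_O2))
    if np.linalg.norm(np.cross(O1 - C, O2 - C)) < 1e-6:
        raise ValueError("collinear carboxylate atoms")
    d1, d2 = np.linalg.norm(O1 - N), np.linalg.norm(O2 - N)
    if d1 <= d2:
        O_near, O_far, d, acceptor = O1, O2, d1, "O1"
    else:
        O_near, O_far, d, acceptor = O2, O1, d2, "O2"
    v1 = C - O_near
    v2 = N - O_near
    theta = math.degrees(
        math.acos(np.clip(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1))
    )
    sdih = dihedral(O_far, C, O_near, N)
    return HBondGeometry(
        distance=float(d),
        theta=float(theta),
        syn_dihedral=float(sdih),
        is_syn=abs(sdih) <= syn_dihedral_max,
        acceptor=acceptor,
    )


def _geometry_within(geom: HBondGeometry, constraint: TSGeometryConstraint) -> bool:
    ok = constraint.d_range[0] <= geom.distance <= constraint.d_range[1]
    ok &= constraint.theta_range[0] <= geom.theta <= constraint.theta_range[1]
    if constraint.require_syn:
        ok &= geom.is_syn
    return bool(ok)


def superpose_ligand_by_shared_atoms(new_ligand: dict, anchor_ligand: dict, atom_map) -> tuple:
    """Rigidly place ``new_ligand`` onto ``anchor_ligand`` by a Kabsch fit
    over explicitly mapped atom names.  Returns (LigandPose, mapped-RMSD)."""
    missing = [a for _, a in atom_map if a not in anchor_ligand]
    missing += [n for n, _ in atom_map if n not in new_ligand]
    if missing:
        raise ValueError(f"unmapped atom names: {missing}")
    if len(atom_map) < 3:
        raise ValueError("need at least 3 mapped atoms")
    P = np.array([new_ligand[n] for n, _ in atom_map], dtype=float)
    Q = np.array([anchor_ligand[a] for _, a in atom_map], dtype=float)
    R, t, rmsd = kabsch_superpose(P, Q)
    placed = {n: np.asarray(p, dtype=float) @ R.T + t for n, p in new_ligand.items()}
    return LigandPose(atoms=placed, source_fragment="shared-atom", transform=(R, t)), rmsd


def _carboxylate(base: ResidueView):
    names = CARBOXYLATE_ATOMS.get(base.name.upper())
    if names is None:
        raise ValueError(f"{base.name!r} is not a carboxylate base")
    try:
        return tuple(base.coord(n) for n in names)
    except KeyError as e:
        raise ValueError(f"missing carboxylate atom: {e}") from e


def dock_ts_to_base(
    base: ResidueView,
    ligand_template: dict | None = None,
    constraint: TSGeometryConstraint | None = None,
    dedupe_rmsd: float | None = 0.75,
) -> list[LigandPose]:
    """Enumerate analogue poses hydrogen-bonded to a carboxylate's *syn*
    lone pairs.

    For each acceptor oxygen and each ring face the donor nitrogen is placed
    in the carboxylate plane at the midpoint of the constraint's distance
    and theta windows, on the syn side (toward the other oxygen); the
    ligand is rotated rigidly so its N-H direction points at the acceptor
    and its ring plane aligns with the carboxylate plane (two faces).
    Near-duplicate poses (heavy-atom RMSD < ``dedupe_rmsd``) are merged.
    """
    constraint = constraint or TSGeometryConstraint()
    template = ligand_template or ligand_template_6nbt()
    C, O1, O2 = _carboxylate(base)
    donor_name = constraint.donor_atom

    # ligand local frame at the donor N
    Nloc = np.asarray(template[donor_name], dtype=float)
    nbrs = [np.asarray(template[n]) for n in _DONOR_NEIGHBORS if n in template]
    if len(nbrs) < 2:
        raise ValueError("template lacks the donor's ring neighbours")
    e1 = Nloc - 0.5 * (nbrs[0] + nbrs[1])  # exocyclic N-H direction
    e1 /= np.linalg.norm(e1)
    ring = np.array([template[n] for n in RING_ATOMS_6NBT if n in template])
    _, _, vt = np.linalg.svd(ring - ring.mean(axis=0))
    e2 = vt[2]
    e2 -= e1 * np.dot(e2, e1)
    e2 /= np.linalg.norm(e2)
    E = np.column_stack([e1, e2, np.cross(e1, e2)])

    poses = []
    for acc, other in ((O1, O2), (O2, O1)):
        u = acc - C
        u /= np.linalg.norm(u)
        w_other = other - C
        v = w_other - u * np.dot(w_other, u)
        v /= np.linalg.norm(v)
        plane_n = np.cross(u, v)
        # donor direction from the acceptor O: angle theta_mid to C-O bond,
        # in-plane, on the syn side (toward the other oxygen)
        th = math.radians(constraint.theta_mid)
        # N direction from the acceptor O: in-plane, syn side, making the
        # target C-O...N angle with the C->O bond (so u . w = -cos theta)
        w = -math.cos(th) * u + math.sin(th) * v
        Npos = acc + constraint.d_mid * w
        t1 = acc - Npos
        t1 /= np.linalg.norm(t1)
        for face in (1.0, -1.0):
            t2 = plane_n * face
            t2 = t2 - t1 * np.dot(t2, t1)
            t2 /= np.linalg.norm(t2)
            T = np.column_stack([t1, t2, np.cross(t1, t2)])
            R = T @ E.T
            placed = {k: R @ (np.asarray(p) - Nloc) + Npos for k, p in template.items()}
            poses.append(
                LigandPose(atoms=placed, source_fragment="6NBT", transform=(R, Npos), donor_atom=donor_name)
            )
    if dedupe_rmsd:
        kept: list[LigandPose] = []
        names = sorted(template)
        for p in poses:
            Xp = p.coords(names)
            dup = any(
                np.sqrt(((Xp - q.coords(names)) ** 2).sum(axis=1).mean()) < dedupe_rmsd
                for q in kept
            )
            if not dup:
                kept.append(p)
        poses = kept
    return poses


# --------------------------------------------------------------------------
# placement enumeration
# --------------------------------------------------------------------------


def inter_residue_clashes(clashes):
    """Drop intra-residue pairs: a rotamer's internal contacts are the
    rotamer library's concern, not the placement filter's."""
    return [c for c in clashes if (c.key_i[0], c.key_i[1]) != (c.key_j[0], c.key_j[1])]


def _strip_sidechain(structure: ProteinStructure, position, model=0) -> ProteinStructure:
    s = structure.copy()
    r = s.find(*position, model)
    if r is None:
        raise ValueError(f"position {position} not in scaffold")
    r.atoms = [a for a in r.atoms if a.name in ("N", "CA", "C", "O")]
    return s


def enumerate_base_placements(
    scaffold: ProteinStructure,
    ligand_pose_prior,
    candidate_positions,
    rotamers: dict | None = None,
    constraint: TSGeometryConstraint | None = None,
    base_types=("ASP", "GLU"),
    burial_probe: float = 1.4,
    burial_sasa_max: float = 0.1,
    min_rotamer_prob: float = 0.05,
    dedupe_rmsd: float = 0.75,
    surface_rel_sasa: float = 0.25,
    ring_atoms=RING_ATOMS_6NBT,
    overlap_tol: float = 0.4,
    sasa_n_points: int = 960,
    evaluate_all: bool = False,
    vdw: VdwTable | None = None,
) -> list[PlacementCandidate]:
    """Evaluate every (position x base type x rotamer) combination against a
    transition-state analogue prior.

    ``ligand_pose_prior`` is either a fixed :class:`LigandPose` (the
    analogue stays put; each candidate base is scored against it) or a
    :class:`PlanePrior` (poses are generated per base by
    :func:`dock_ts_to_base` and must respect the ring-plane prior).

    A candidate passes iff the H-bond geometry lies inside the constraint,
    the carboxylate oxygens and analogue ring atoms are fully buried
    (per-atom SASA < ``burial_sasa_max`` Ų with the analogue included) and
    there are no steric clashes.  Candidates at surface positions (native
    Cα relative accessibility > ``surface_rel_sasa``) are flagged.  Burial
    is evaluated lazily: only for candidates that already satisfy geometry
    and clash checks (or always, with ``evaluate_all``).
    """
    constraint = constraint or TSGeometryConstraint()
    rotamers = rotamers or ROTAMER_TABLE
    vdw = vdw or VdwTable()
    if not any(rotamers.get(bt) for bt in base_types):
        raise ValueError("empty rotamer table")
    rel_acc = relative_ca_accessibility(scaffold, n_points=min(sasa_n_points, 480), vdw=vdw)
    fixed_pose = isinstance(ligand_pose_prior, LigandPose)

    out: list[PlacementCandidate] = []
    for position in candidate_positions:
        stripped = _strip_sidechain(scaffold, position)
        bb = stripped.find(*position)
        surface = rel_acc.get(tuple(position), 0.0) > surface_rel_sasa
        for bt in base_types:
            for rot in rotamers.get(bt, []):
                if rot.probability < min_rotamer_prob:
                    continue
                built = build_sidechain(bb, bt, rot)
                C, Oa, Ob = _carboxylate(built)
                # choose the pose
                if fixed_pose:
                    pose = ligand_pose_prior
                else:
                    cand_poses = dock_ts_to_base(built, constraint=constraint, dedupe_rmsd=dedupe_rmsd)
                    cand_poses = [
                        p for p in cand_poses if ligand_pose_prior is None
                        or ligand_pose_prior.accepts(p, [a for a in ring_atoms if a in p.atoms])
                    ]
                    pose = cand_poses[0] if cand_poses else None
                if pose is None:
                    out.append(
                        PlacementCandidate(
                            tuple(position), bt, rot, None,
                            math.nan, math.nan, math.nan, math.nan, math.nan,
                            clash_count=-1, geometry_ok=False, burial_ok=False,
                            surface_flag=surface, passes=False,
                        )
                    )
                    continue
                geom = score_hbond_geometry(pose.donor, C, Oa, Ob, constraint.syn_dihedral_max)
                geometry_ok = _geometry_within(geom, constraint)

                work = stripped.copy()
                wr = work.find(*position)
                wr.name = bt
                wr.atoms = list(built.atoms)
                lig_names = sorted(pose.atoms)
                lig_coords = pose.coords(lig_names)
                lig_elements = _ligand_elements(lig_names)

                clash_count = math.nan
                sasa_base = math.nan
                sasa_ring = math.nan
                burial_ok = False
                if geometry_ok or evaluate_all:
                    clashes = inter_residue_clashes(
                        count_clashes(
                            work, extra_coords=lig_coords, extra_elements=lig_elements,
                            overlap_tol=overlap_tol, vdw=vdw,
                        )
                    )
                    clash_count = len(clashes)
                    if clash_count == 0 or evaluate_all:
                        areas, keys = shrake_rupley_sasa(
                            work, probe_radius=burial_probe, n_points=sasa_n_points,
                            vdw=vdw, extra_coords=lig_coords, extra_elements=lig_elements,
                        )
                        amap = dict(zip(keys, areas))
                        onames = CARBOXYLATE_ATOMS[bt][1:]
                        sasa_base = max(
                            amap[(wr.chain, wr.seqnum, bt, n)] for n in onames
                        )
                        ring_idx = [lig_names.index(a) for a in ring_atoms if a in pose.atoms]
                        sasa_ring = max(amap[("*", 0, "EXT", i)] for i in ring_idx)
                        burial_ok = sasa_base < burial_sasa_max and sasa_ring < burial_sasa_max
                passes = bool(
                    geometry_ok and burial_ok and (clash_count == 0)
                )
                out.append(
                    PlacementCandidate(
                        tuple(position), bt, rot, pose,
                        geom.distance, geom.theta, geom.syn_dihedral,
                        sasa_base, sasa_ring,
                        clash_count=int(clash_count) if not math.isnan(clash_count) else -1,
                        geometry_ok=geometry_ok, burial_ok=burial_ok,
                        surface_flag=surface, passes=passes,
                    )
                )
    return out


def best_candidates(candidates, constraint: TSGeometryConstraint | None = None) -> dict:
    """Per-position best passing candidate: highest rotamer probability,
    then smallest H-bond distance deviation from the constraint midpoint."""
    constraint = constraint or TSGeometryConstraint()
    best: dict = {}
    for c in candidates:
        if not c.passes or c.surface_flag:
            continue
        key = c.position
        rank = (-c.rotamer.probability, abs(c.hbond_distance - constraint.d_mid))
        if key not in best or rank < best[key][0]:
            best[key] = (rank, c)
    return {k: v[1] for k, v in best.items()}


# --------------------------------------------------------------------------
# preorganization filter
# --------------------------------------------------------------------------


def preorganization_filter(
    design: ProteinStructure,
    predicted: ProteinStructure,
    plddt: float,
    active_site_residues,
    rmsd_max: float = 1.0,
    plddt_min: float = 90.0,
) -> PreorgReport:
    """Design-vs-prediction agreement filter: global backbone Cα RMSD below
    ``rmsd_max``, predictor confidence above ``plddt_min``, and sub-Å
    CA/CB/CG RMSD over the active-site residues (all in the Cα frame)."""
    for chain, seqnum in active_site_residues:
        for s, tag in ((design, "design"), (predicted, "predicted")):
            if s.find(chain, seqnum) is None:
                raise ValueError(f"active-site residue {chain}:{seqnum} absent from {tag}")
    bb_rmsd, _ = rmsd_subset(design, predicted, atom_selection=("CA",), superpose=True)

    # active-site CA/CB/CG RMSD in the global Cα frame
    from .structcore.geometry import _collect  # shared pairing helper

    da = _collect(design, {"CA", "CB", "CG"})
    db = _collect(predicted, {"CA", "CB", "CG"})
    keys = [
        k for k in sorted(set(da) & set(db)) if (k[0], k[1]) in {tuple(r) for r in active_site_residues}
    ]
    if not keys:
        raise ValueError("no paired CA/CB/CG atoms in the active site")
    ca_a = _collect(design, {"CA"})
    ca_b = _collect(predicted, {"CA"})
    common = sorted(set(ca_a) & set(ca_b))
    R, t, _ = kabsch_superpose(
        np.array([ca_a[k] for k in common]), np.array([ca_b[k] for k in common])
    )
    P = np.array([da[k] for k in keys]) @ R.T + t
    Q = np.array([db[k] for k in keys])
    site_rmsd = float(np.sqrt(((P - Q) ** 2).sum() / len(keys)))
    passes = bb_rmsd < rmsd_max and plddt > plddt_min and site_rmsd < 1.0
    return PreorgReport(bb_rmsd, site_rmsd, plddt, bool(passes))
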