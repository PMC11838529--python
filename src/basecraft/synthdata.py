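"""Seeded generators emulating every input the pipeline consumes.

Each generator embeds its ground truth in the returned object's metadata so
every fitting/analysis module has a closure test (generate -> analyse ->
recover truth).  Defaults mirror the study conditions: two fluorophore
concentrations of 3 and 6 µM, triplicate measurements, multiplicative
log-normal noise, a 43-hit / 199-fragment screen, pH grids spanning the
profile midpoint.

The four-helix bundle is an idealized stand-in for the de novo scaffold:
ideal phi/psi helices placed antiparallel on a square, alanine side chains,
an optional pocket carved by truncating inward residues to glycine.  It is
geometrically faithful (helical rise, CA-CA distances, clash-free packing)
but makes no claim to physical energetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bindfit import TitrationDataset, bound_fraction
from .kinfit import RateDataset, mm_rate, ph_profile
from .siteplace import (
    CARBOXYLATE_ATOMS,
    RING_ATOMS_6NBT,
    PlacementCandidate,
    RotamerSpec,
    TSGeometryConstraint,
    build_sidechain,
    dock_ts_to_base,
    inter_residue_clashes,
    ligand_template_6nbt,
    place_atom,
    score_hbond_geometry,
)
from .structcore import (
    AtomRecord,
    ProteinStructure,
    ResidueView,
    VdwTable,
    count_clashes,
    fold_symmetric,
    sasa_points,
    wrap_angle,
)
from .trajstats import ChiSeries

__all__ = [
    "BundleSpec",
    "SimConfig",
    "build_bundle",
    "plant_catalytic_site",
    "sim_chi_trajectory",
    "sim_hydration_frames",
    "sim_mm",
    "sim_ph_profile",
    "sim_titration",
    "sim_fragment_table",
]


@dataclass
class BundleSpec:
    """Idealized antiparallel four-helix bundle geometry."""

    n_helices: int = 4
    helix_length: int = 14
    radius: float = 7.5  # Å, helix axis to bundle axis
    rise_per_res: float = 1.5  # Å (informational; set by ideal phi/psi)
    pocket_glycines: tuple = ()  # ((chain, seqnum), ...) truncated to Gly

    def __post_init__(self):
        if self.helix_length < 8:
            raise ValueError("helix_length must be >= 8")
        if self.radius <= 4.0:
            raise ValueError("radius must exceed 4 Å")


@dataclass
class SimConfig:
    """Shared simulation conditions; the seed is mandatory and recorded in
    every generator output's metadata."""

    seed: int
    noise_cv: float = 0.05
    n_replicates: int = 3
    grids: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# scaffold generator
# --------------------------------------------------------------------------

_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0
_B_NCA, _B_CAC, _B_CN, _B_CO = 1.458, 1.525, 1.329, 1.231
_A_NCAC, _A_CACN, _A_CNCA, _A_CACO = 111.2, 116.2, 121.7, 120.5


def _ideal_helix(n_res: int):
    """Backbone (N, CA, C, O) coordinates of an ideal alpha-helix, axis on z."""
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_NCA, 0.0, 0.0])]
    a = math.radians(_A_NCAC)
    C = [CA[0] + _B_CAC * np.array([-math.cos(a), math.sin(a), 0.0])]
    for _ in range(1, n_res):
        N.append(place_atom(N[-1], CA[-1], C[-1], _B_CN, _A_CACN, _PSI))
        CA.append(place_atom(CA[-1], C[-1], N[-1], _B_NCA, _A_CNCA, _OMEGA))
        C.append(place_atom(C[-1], N[-1], CA[-1], _B_CAC, _A_NCAC, _PHI))
    O = []
    for i in range(n_res):
        if i < n_res - 1:
            O.append(place_atom(N[i + 1], CA[i], C[i], _B_CO, _A_CACO, 180.0))
        else:
            O.append(place_atom(N[i], CA[i], C[i], _B_CO, _A_CACO, _PSI + 180.0))
    N, CA, C, O = (np.array(v) for v in (N, CA, C, O))
    # rotate so the CA principal axis lies on +z, centroid at origin
    cen = CA.mean(axis=0)
    _, _, vt = np.linalg.svd(CA - cen)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(np.dot(axis, z))
    if s < 1e-12:
        R = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return tuple((arr - cen) @ R.T for arr in (N, CA, C, O))


def build_bundle(spec: BundleSpec | None = None) -> ProteinStructure:
    """Ideal antiparallel helical bundle with alanine side chains.

    Helices sit on a square of circumradius ``spec.radius`` around the z
    axis, alternating up/down.  Residues listed in ``pocket_glycines`` are
    built without CB (glycine), carving the pocket.  The backbone is
    checked clash-free; overlapping helices raise.
    """
    spec = spec or BundleSpec()
    N, CA, C, O = _ideal_helix(spec.helix_length)
    chains = "ABCDEFGH"[: spec.n_helices]
    residues = []
    gly = {tuple(k) for k in spec.pocket_glycines}
    flip = np.diag([1.0, -1.0, -1.0])  # 180° about x: antiparallel partner
    for h in range(spec.n_helices):
        ang = 2.0 * math.pi * h / spec.n_helices + math.pi / spec.n_helices
        offset = spec.radius * np.array([math.cos(ang), math.sin(ang), 0.0])
        M = flip if h % 2 else np.eye(3)
        for i in range(spec.helix_length):
            key = (chains[h], i + 1)
            pos = {
                "N": N[i] @ M.T + offset,
                "CA": CA[i] @ M.T + offset,
                "C": C[i] @ M.T + offset,
                "O": O[i] @ M.T + offset,
            }
            name = "GLY" if key in gly else "ALA"
            atoms = [
                AtomRecord("N", "N", pos["N"]),
                AtomRecord("CA", "C", pos["CA"]),
                AtomRecord("C", "C", pos["C"]),
                AtomRecord("O", "O", pos["O"]),
            ]
            if name == "ALA":
                cb = place_atom(pos["C"], pos["N"], pos["CA"], 1.530, 109.5, -120.0)
                atoms.append(AtomRecord("CB", "C", cb))
            residues.append(ResidueView(chains[h], i + 1, name, atoms))
    s = ProteinStructure([residues], title="idealized four-helix bundle")
    bb_only = s.copy()
    for r in bb_only.residues():
        r.atoms = [a for a in r.atoms if a.name in ("N", "CA", "C", "O")]
    if count_clashes(bb_only):
        raise ValueError("helices overlap: backbone clash check failed")
    return s


# --------------------------------------------------------------------------
# planted catalytic site
# --------------------------------------------------------------------------


def _blockers_for_burial(
    structure: ProteinStructure,
    extra_coords: np.ndarray,
    extra_elements,
    target_global_idx: list,
    probe: float = 1.4,
    sasa_max: float = 0.1,
    n_points: int = 960,
    max_rounds: int = 10,
    vdw: VdwTable | None = None,
):
    """Add inert carbon 'wall' atoms until the target atoms are buried.

    The combined atom array is [structure heavy atoms..., extra atoms...,
    blockers...]; ``target_global_idx`` indexes into it (so targets may be
    structure atoms or extras).  Blockers go ~4.2 Å out along each exposed
    atom's mean accessible direction, at >= 3.05 Å from everything, so they
    occlude a 1.4 Å probe without clashing.  Returns the blocker list.
    """
    vdw = vdw or VdwTable()
    coords, elements, _ = structure.atom_table(heavy_only=True)
    blockers: list[np.ndarray] = []
    for _ in range(max_rounds):
        allc = np.vstack([coords, extra_coords] + ([np.array(blockers)] if blockers else []))
        alle = list(elements) + list(extra_elements) + ["C"] * len(blockers)
        radii = vdw.radii_for(alle)
        areas, dirs = sasa_points(allc, radii, probe_radius=probe, n_points=n_points, return_directions=True)
        exposed = [(allc[i], dirs[i]) for i in target_global_idx if areas[i] >= sasa_max]
        if not exposed:
            return blockers
        added = 0
        for pos, d in exposed:
            nd = np.linalg.norm(d)
            if nd < 1e-6:
                continue
            d = d / nd
            # mean accessible direction first, then tilted variants to cover
            # patches the mean misses or where the straight slot is occupied
            perp1 = np.cross(d, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp1) < 1e-6:
                perp1 = np.cross(d, [1.0, 0.0, 0.0])
            perp1 /= np.linalg.norm(perp1)
            perp2 = np.cross(d, perp1)
            dir_trials = [d]
            for tilt in (25.0, 50.0):
                s_t, c_t = math.sin(math.radians(tilt)), math.cos(math.radians(tilt))
                for p in (perp1, -perp1, perp2, -perp2):
                    dir_trials.append(c_t * d + s_t * p)
            placed = False
            for dt in dir_trials:
                for reach in (3.6, 4.0, 3.3, 4.4):
                    cand = pos + reach * dt
                    if np.min(np.linalg.norm(allc - cand, axis=1)) >= 3.05:
                        blockers.append(cand)
                        allc = np.vstack([allc, cand[None, :]])
                        added += 1
                        placed = True
                        break
                if placed:
                    break
        if added == 0:
            break
    raise ValueError("cannot achieve burial at the requested position")


def _faces_lumen(bundle: ProteinStructure, position) -> bool:
    """Interior test for the idealized scaffold: does the side chain point
    at the bundle axis?  (The open lumen is probe-accessible by design, so
    a solvent-accessibility criterion cannot distinguish inward from
    outward positions here.)"""
    cas = np.array([r.coord("CA") for r in bundle.residues() if r.atom("CA")])
    centroid = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - centroid)
    axis = vt[0]
    r = bundle.find(*position)
    if r is None:
        raise ValueError(f"position {position} not in bundle")
    ca = r.coord("CA")
    cb = r.atom("CB")
    if cb is None:  # glycine: synthesize the CB direction
        cbv = place_atom(r.coord("C"), r.coord("N"), ca, 1.53, 109.5, -120.0) - ca
    else:
        cbv = cb.pos - ca
    v = ca - centroid
    radial = v - axis * np.dot(v, axis)
    nr = np.linalg.norm(radial)
    if nr < 1e-9:
        return True
    return float(np.dot(cbv, radial / nr)) < 0.0


def plant_catalytic_site(
    bundle: ProteinStructure,
    position: tuple,
    base_type: str = "ASP",
    rotamer: RotamerSpec | None = None,
    ligand_template: dict | None = None,
    constraint: TSGeometryConstraint | None = None,
):
    """Graft a catalytic base + analogue pose that satisfies every
    placement criterion by construction.

    Returns ``(structure, pose, ground_truth)`` where the structure carries
    the built base at ``position`` plus inert wall atoms enforcing burial,
    ``pose`` is the analogue pose, and ``ground_truth`` is the fully scored
    :class:`PlacementCandidate`.  Outward-facing (surface) positions are
    rejected.
    """
    constraint = constraint or TSGeometryConstraint()
    base_type = base_type.upper()
    if not _faces_lumen(bundle, position):
        raise ValueError(f"position {position} is a surface position (side chain "
                         "points away from the bundle axis)")
    if rotamer is None:
        from .siteplace import ROTAMER_TABLE

        rotamer_trials = list(ROTAMER_TABLE[base_type])
    else:
        rotamer_trials = [rotamer]
    template = ligand_template or ligand_template_6nbt()
    lig_names = sorted(template)
    lig_elements = [n[0] for n in lig_names]

    chosen = rotamer_used = None
    for rot in rotamer_trials:
        work = bundle.copy()
        res = work.find(*position)
        if res is None:
            raise ValueError(f"position {position} not in bundle")
        res.atoms = [a for a in res.atoms if a.name in ("N", "CA", "C", "O")]
        built = build_sidechain(res, base_type, rot)
        res.name = base_type
        res.atoms = list(built.atoms)
        # the base itself must sit clash-free before the analogue arrives
        if inter_residue_clashes(count_clashes(work)):
            continue
        poses = dock_ts_to_base(res, ligand_template=template, constraint=constraint,
                                dedupe_rmsd=None)
        for pose in poses:
            lig_coords = pose.coords(lig_names)
            trial = work.copy()
            clashes = inter_residue_clashes(
                count_clashes(trial, extra_coords=lig_coords, extra_elements=lig_elements)
            )
            # carve side chains (drop CB -> Gly) that clash with the
            # analogue; any backbone clash disqualifies the pose
            carve = set()
            ok = True
            for cl in clashes:
                for key in (cl.key_i, cl.key_j):
                    if key[2] == "EXT" or key[0] == "*":
                        continue
                    if key[3] == "CB" and (key[0], key[1]) != tuple(position):
                        carve.add((key[0], key[1]))
                    else:
                        ok = False
            if not ok:
                continue
            for ck in carve:
                cr = trial.find(*ck)
                cr.name = "GLY"
                cr.atoms = [a for a in cr.atoms if a.name != "CB"]
            if inter_residue_clashes(
                count_clashes(trial, extra_coords=lig_coords, extra_elements=lig_elements)
            ):
                continue
            chosen, work, rotamer_used = pose, trial, rot
            break
        if chosen is not None:
            break
    if chosen is None:
        raise ValueError("no clash-free analogue pose at the requested position")
    rotamer = rotamer_used

    lig_coords = chosen.coords(lig_names)
    ring_idx = [lig_names.index(a) for a in RING_ATOMS_6NBT if a in template]
    # burial targets: the analogue ring plus the carboxylate oxygens
    cnames = CARBOXYLATE_ATOMS[base_type]
    _, _, wkeys = work.atom_table(heavy_only=True)
    n_struct = len(wkeys)
    oxy_idx = [
        i for i, k in enumerate(wkeys)
        if (k[0], k[1]) == tuple(position) and k[3] in cnames[1:]
    ]
    targets = [n_struct + i for i in ring_idx] + oxy_idx
    blockers = _blockers_for_burial(work, lig_coords, lig_elements, targets)
    work = _with_blockers(work, blockers)

    # final verification and ground-truth scoring
    C, O1, O2 = (work.find(*position).coord(n) for n in cnames)
    geom = score_hbond_geometry(chosen.donor, C, O1, O2, constraint.syn_dihedral_max)
    clashes = inter_residue_clashes(
        count_clashes(work, extra_coords=lig_coords, extra_elements=lig_elements)
    )
    if clashes:
        raise ValueError("planting failed: residual clashes after wall construction")
    from .structcore import shrake_rupley_sasa

    areas, keys = shrake_rupley_sasa(work, extra_coords=lig_coords, extra_elements=lig_elements)
    amap = dict(zip(keys, areas))
    resn = work.find(*position)
    sasa_base = max(amap[(resn.chain, resn.seqnum, base_type, n)] for n in cnames[1:])
    sasa_ring = max(amap[("*", 0, "EXT", i)] for i in ring_idx)
    if sasa_base >= 0.1 or sasa_ring >= 0.1:
        raise ValueError("cannot achieve burial at the requested position")
    truth = PlacementCandidate(
        tuple(position), base_type, rotamer, chosen,
        geom.distance, geom.theta, geom.syn_dihedral,
        sasa_base, sasa_ring, clash_count=0,
        geometry_ok=True, burial_ok=True, surface_flag=False, passes=True,
    )
    return work, chosen, truth


def _with_blockers(structure: ProteinStructure, blockers) -> ProteinStructure:
    if not blockers:
        return structure
    s = structure.copy()
    existing = [r for r in s.residues() if r.name == "BLK"]
    start = sum(len(r.atoms) for r in existing)
    if existing:
        res = existing[0]
    else:
        res = ResidueView("X", 1, "BLK", [])
        s.models[0].append(res)
    for i, b in enumerate(blockers):
        res.atoms.append(AtomRecord(f"W{start + i + 1}", "C", np.asarray(b), is_hetero=True))
    return s


# --------------------------------------------------------------------------
# trajectory generators
# --------------------------------------------------------------------------


def sim_chi_trajectory(
    modes,
    sigma: float = 10.0,
    n_frames: int = 500,
    switch_rate: float = 0.02,
    seed: int = 0,
    residue_name: str = "TYR",
    frame_interval_ns: float = 1.0,
    as_structure: bool = False,
):
    """Two-state (or k-state) Markov chi trajectory with wrapped-normal noise.

    ``modes``: list of (chi1, chi2, occupancy); occupancies must sum to 1.
    States persist in segments with geometric dwell times of mean
    1/``switch_rate``; per-state total time is quota-matched to the stated
    occupancies (so the realized occupancy is a controlled condition, not a
    random draw — rare-switching chains would otherwise wander far from
    their stationary occupancies on short runs).  Returns
    ``(ChiSeries, labels)`` — or ``(ProteinStructure, ChiSeries, labels)``
    with ``as_structure`` (frames are real residues built at the noisy
    angles, so chi extraction closes the loop).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    occ = np.array([m[2] for m in modes], dtype=float)
    if abs(occ.sum() - 1.0) > 1e-9:
        raise ValueError("occupancies must sum to 1")
    rng = np.random.default_rng(seed)
    k = len(modes)
    quota = np.round(occ * n_frames).astype(int)
    quota[int(np.argmax(quota))] += n_frames - quota.sum()
    labels = np.empty(n_frames, dtype=int)
    t, prev = 0, -1
    while t < n_frames:
        avail = [s for s in range(k) if quota[s] > 0]
        pick = [s for s in avail if s != prev] or avail
        p = quota[pick].astype(float)
        s = int(rng.choice(pick, p=p / p.sum()))
        dwell = int(min(rng.geometric(min(max(switch_rate, 1e-9), 1.0)), quota[s]))
        labels[t : t + dwell] = s
        quota[s] -= dwell
        t += dwell
        prev = s
    chi1 = np.array([modes[s][0] for s in labels]) + rng.normal(0, sigma, n_frames)
    chi2 = np.array([modes[s][1] for s in labels]) + rng.normal(0, sigma, n_frames)
    chi1 = np.array([wrap_angle(c) for c in chi1])
    symmetric = residue_name.upper() in ("TYR", "PHE")
    chi2 = np.array([fold_symmetric(c) if symmetric else wrap_angle(c) for c in chi2])
    times = np.arange(n_frames) * frame_interval_ns
    series = ChiSeries(("A", 1), residue_name.upper(), times, chi1, chi2,
                       meta={"seed": seed, "modes": list(modes), "sigma": sigma,
                             "switch_rate": switch_rate})
    if not as_structure:
        return series, labels
    bb = {"N": np.zeros(3), "CA": np.array([1.458, 0.0, 0.0]),
          "C": np.array([1.996, 1.423, 0.0]), "O": np.array([1.246, 2.39, 0.0])}
    models = []
    for c1, c2 in zip(chi1, chi2):
        r = build_sidechain(bb, residue_name.upper(), RotamerSpec(residue_name.upper(), (c1, c2), 0.5))
        models.append([r])
    traj = ProteinStructure(models, title="synthetic chi trajectory")
    return traj, series, labels


def sim_hydration_frames(
    selection_atoms: dict,
    lambda_near: float = 2.0,
    n_frames: int = 200,
    seed: int = 0,
    cutoff: float = 3.5,
    exclusion: float = 4.5,
    n_distractors: int = 4,
):
    """Frames of water oxygens around a rigid selection.

    Per frame, Poisson(``lambda_near``) waters go uniformly into the
    [2.7, cutoff] shell of randomly chosen selection atoms; distractors sit
    beyond ``exclusion`` from every selection atom.  The water topology is
    constant across frames (extra waters park with the distractors) so the
    result is a valid trajectory.  Returns (ProteinStructure, truth counts).
    """
    if lambda_near < 0:
        raise ValueError("lambda_near must be >= 0")
    rng = np.random.default_rng(seed)
    names = sorted(selection_atoms)
    sel = np.array([selection_atoms[n] for n in names], dtype=float)
    centroid = sel.mean(axis=0)
    counts = rng.poisson(lambda_near, n_frames)
    n_water = int(counts.max(initial=0)) + n_distractors

    def far_point():
        while True:
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            p = centroid + d * rng.uniform(exclusion + 2.0, exclusion + 5.0)
            if np.min(np.linalg.norm(sel - p, axis=1)) > exclusion:
                return p

    models = []
    for f in range(n_frames):
        waters = []
        for _ in range(counts[f]):
            a = sel[rng.integers(len(sel))]
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            waters.append(a + d * rng.uniform(2.7, cutoff - 0.01))
        while len(waters) < n_water:
            waters.append(far_point())
        residues = [
            ResidueView("L", 1, "LIG", [
                AtomRecord(n, "C", selection_atoms[n], is_hetero=True) for n in names
            ])
        ]
        for i, w in enumerate(waters):
            residues.append(
                ResidueView("W", i + 1, "HOH", [AtomRecord("O", "O", w, is_hetero=True)])
            )
        models.append(residues)
    traj = ProteinStructure(models, title=f"synthetic hydration frames (seed {seed})")
    return traj, counts


# --------------------------------------------------------------------------
# tabular generators
# --------------------------------------------------------------------------


def _lognormal_noise(rng, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def sim_mm(
    kcat: float,
    km: float,
    e0: float = 1e-8,
    s_grid=None,
    cv: float = 0.05,
    n_rep: int = 3,
    seed: int = 0,
) -> RateDataset:
    """Noisy Michaelis–Menten initial rates; default 8 substrate levels
    log-spaced over 0.1–10 Km, triplicates, log-normal noise of the given CV."""
    rng = np.random.default_rng(seed)
    if s_grid is None:
        s_grid = np.geomspace(0.1 * km, 10.0 * km, 8)
    s = np.tile(np.asarray(s_grid, dtype=float), n_rep)
    rep = np.repeat(np.arange(n_rep), len(s_grid))
    v = mm_rate(s, kcat, km, e0) * _lognormal_noise(rng, cv, len(s))
    return RateDataset(
        substrate=s, rate=v, enzyme_total=e0, replicate=rep,
        meta={"seed": seed, "cv": cv, "truth": {"kcat": kcat, "km": km, "e0": e0}},
    )


def sim_ph_profile(
    max_eff: float,
    pka: float,
    ph_grid=None,
    cv: float = 0.05,
    n_rep: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy sigmoidal pH-rate profile; default grid pH 7.0–10.5 in 0.25
    steps, triplicates, log-normal noise."""
    rng = np.random.default_rng(seed)
    if ph_grid is None:
        ph_grid = np.arange(7.0, 10.5 + 1e-9, 0.25)
    ph = np.tile(np.asarray(ph_grid, dtype=float), n_rep)
    rep = np.repeat(np.arange(n_rep), len(ph_grid))
    eff = ph_profile(ph, max_eff, pka) * _lognormal_noise(rng, cv, len(ph))
    df = pd.DataFrame({"ph": ph, "eff": eff, "replicate": rep})
    df.attrs["truth"] = {"max_eff": max_eff, "pka": pka}
    df.attrs["seed"] = seed
    df.attrs["cv"] = cv
    return df


def sim_titration(
    kd: float,
    f_free: float = 1.0e6,
    f_bound: float = 4.8e7,
    l_totals=(3e-6, 6e-6),
    p_grid=None,
    cv: float = 0.02,
    n_rep: int = 3,
    seed: int = 0,
) -> list[TitrationDataset]:
    """Fluorescence titrations of protein into fixed fluorophore.

    One dataset per fixed ligand concentration (defaults 3 and 6 µM);
    default protein grid 12 points log-spaced 1–300 µM; signal is linear in
    free/bound ligand with a 48-fold bound-state enhancement by default.
    """
    rng = np.random.default_rng(seed)
    if p_grid is None:
        p_grid = np.geomspace(1e-6, 3e-4, 12)
    out = []
    for lt in l_totals:
        p = np.tile(np.asarray(p_grid, dtype=float), n_rep)
        pl = bound_fraction(p, lt, kd)
        sig = (f_free * (lt - pl) + f_bound * pl) * _lognormal_noise(rng, cv, len(p))
        out.append(
            TitrationDataset(
                ligand_total=lt, protein_totals=p, signal=sig,
                meta={"seed": seed, "cv": cv,
                      "truth": {"kd": kd, "f_free": f_free, "f_bound": f_bound}},
            )
        )
    return out


_LIBRARY_DISTS = {
    "mw": (250.0, 60.0),
    "heavy_atoms": (17.0, 3.5),
    "aromatic_rings": (1.5, 0.9),
    "logp": (1.5, 1.2),
}


def sim_fragment_table(
    n_hits: int = 43,
    n_library: int = 199,
    effect: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fragment screening table with an optional planted hit-vs-library
    property shift.

    ``effect`` maps property -> additive shift (property units) applied to
    the hit rows; defaults emulate a 242-fragment screen with 43 hits.
    Hits carry BDC values; count-like properties are rounded and floored
    at zero.
    """
    rng = np.random.default_rng(seed)
    effect = effect or {}
    rows = {}
    n = n_hits + n_library
    is_hit = np.zeros(n, dtype=bool)
    is_hit[:n_hits] = True
    for prop, (mu, sd) in _LIBRARY_DISTS.items():
        vals = rng.normal(mu, sd, n)
        vals[:n_hits] += effect.get(prop, 0.0)
        if prop in ("heavy_atoms", "aromatic_rings"):
            vals = np.maximum(np.round(vals), 0)
        rows[prop] = vals
    bdc = np.full(n, np.nan)
    bdc[:n_hits] = rng.uniform(0.2, 0.9, n_hits)
    df = pd.DataFrame(
        {
            "fragment_id": [f"F{i + 1:04d}" for i in range(n)],
            "dataset_quality_ok": True,
            "is_hit": is_hit,
            "bdc": bdc,
            **rows,
        }
    )
    df.attrs["seed"] = seed
    df.attrs["effect"] = dict(effect)
    return df
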