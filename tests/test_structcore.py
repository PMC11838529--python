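"""Geometric primitives against independent oracles: a second torsion
formula, analytic sphere areas, brute-force clash scans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from basecraft import structcore as sc
from basecraft.siteplace import RotamerSpec, build_sidechain

from conftest import apply_rigid, random_rigid_transform

# --------------------------------------------------------------------------
# PDB I/O
# --------------------------------------------------------------------------

MINI_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.182  -4.916  1.00  0.00           C
"""

ALTLOC_PDB = MINI_PDB + """\
ATOM      4  CB AALA A   2      11.000   6.000  -5.000  0.60  0.00           C
ATOM      5  CB BALA A   2      12.000   6.000  -5.000  0.40  0.00           C
ATOM      6  N   ALA A   2      10.000   5.000  -4.000  1.00  0.00           N
"""


class TestPdbIO:
    def test_minimal_block_parses(self):
        s = sc.parse_pdb(MINI_PDB)
        assert len(s.residues()) == 1
        assert len(s.residues()[0].atoms) == 3
        np.testing.assert_allclose(s.find("A", 1).coord("CA"), [11.639, 6.071, -5.147])

    def test_highest_occupancy_policy_keeps_major_conformer(self):
        s = sc.parse_pdb(ALTLOC_PDB)
        cbs = [a for a in s.find("A", 2).atoms if a.name == "CB"]
        assert len(cbs) == 1 and cbs[0].altloc == "A"

    def test_keep_all_and_label_policies(self):
        s = sc.parse_pdb(ALTLOC_PDB, altloc_policy="keep_all")
        assert sum(a.name == "CB" for a in s.find("A", 2).atoms) == 2
        s = sc.parse_pdb(ALTLOC_PDB, altloc_policy="label", altloc_label="B")
        cbs = [a for a in s.find("A", 2).atoms if a.name == "CB"]
        assert len(cbs) == 1 and cbs[0].altloc == "B"

    def test_multi_model_becomes_trajectory(self):
        text = f"MODEL     1\n{MINI_PDB}ENDMDL\nMODEL     2\n{MINI_PDB}ENDMDL\n"
        s = sc.parse_pdb(text)
        assert s.n_models == 2
        s.validate_trajectory()

    def test_malformed_coordinate_names_line(self):
        bad = MINI_PDB.replace("11.104", "xx.xxx")
        with pytest.raises(ValueError, match="line 1"):
            sc.parse_pdb(bad)

    def test_duplicate_atom_key_rejected(self):
        dup = MINI_PDB + MINI_PDB.splitlines()[0] + "\n"
        with pytest.raises(ValueError, match="duplicate"):
            sc.parse_pdb(dup)

    def test_round_trip_preserves_coordinates(self, bundle):
        s2 = sc.parse_pdb(sc.write_pdb(bundle))
        c1, _, _ = bundle.atom_table()
        c2, _, _ = s2.atom_table()
        assert np.abs(c1 - c2).max() < 1.5e-3  # PDB fixed-width: 3 decimals

    def test_write_rejects_large_seqnum_and_long_names(self):
        r = sc.ResidueView("A", 10000, "ALA", [sc.AtomRecord("CA", "C", np.zeros(3))])
        with pytest.raises(ValueError, match="residue number"):
            sc.write_pdb(sc.ProteinStructure([[r]]))
        r = sc.ResidueView("A", 1, "ALA", [sc.AtomRecord("CAXXX", "C", np.zeros(3))])
        with pytest.raises(ValueError, match="atom name"):
            sc.write_pdb(sc.ProteinStructure([[r]]))

    def test_empty_structure_writes_header_only(self):
        out = sc.write_pdb(sc.ProteinStructure([[]]))
        assert "ATOM" not in out


# --------------------------------------------------------------------------
# dihedrals and chi
# --------------------------------------------------------------------------


def _dihedral_oracle(p1, p2, p3, p4):
    """Independent torsion via the two-plane-normal formula."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return ang


class TestDihedral:
    def test_planar_trans_is_180(self):
        assert sc.dihedral([1, 1, 0], [1, 0, 0], [0, 0, 0], [-1, -1, 0]) == pytest.approx(180.0)

    def test_planar_cis_is_0(self):
        assert sc.dihedral([1, 1, 0], [1, 0, 0], [0, 0, 0], [-1, 1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3
            try:
                got = sc.dihedral(*pts)
            except ValueError:
                continue
            assert got == pytest.approx(_dihedral_oracle(*pts), abs=1e-9)

    def test_collinear_triple_raises(self):
        with pytest.raises(ValueError, match="collinear"):
            sc.dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_reversal_invariance_and_mirror_antisymmetry(self, seed):
        # the IUPAC torsion is unchanged by reversing the atom order and
        # changes sign under reflection
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 3
        try:
            fwd = sc.dihedral(*pts)
        except ValueError:
            return
        assert sc.dihedral(*pts[::-1]) == pytest.approx(fwd, abs=1e-9)
        if abs(abs(fwd) - 180.0) > 1e-6:
            assert sc.dihedral(*(pts * [1, 1, -1])) == pytest.approx(-fwd, abs=1e-9)


class TestChiAngles:
    def test_symmetric_fold_tyr_and_asp(self):
        assert sc.fold_symmetric(135.0) == pytest.approx(-45.0)
        assert sc.fold_symmetric(-170.0) == pytest.approx(10.0)

    @pytest.mark.parametrize(
        "resname,chis",
        [("LEU", (-60.0, 170.0)), ("ASP", (-65.0, -15.0)), ("GLU", (-67.0, -178.0, -10.0))],
    )
    def test_build_then_measure_round_trip(self, helix_backbone, resname, chis):
        r = build_sidechain(helix_backbone, resname, RotamerSpec(resname, chis, 0.5))
        got = sc.chi_angles(r)
        np.testing.assert_allclose(got, chis, atol=1e-6)

    def test_canonicalization_folds_tyr_chi2(self, helix_backbone):
        r = build_sidechain(helix_backbone, "TYR", RotamerSpec("TYR", (-65.0, 135.0), 0.5))
        raw = sc.chi_angles(r)
        canon = sc.chi_angles(r, canonicalize_symmetry=True)
        assert raw[1] == pytest.approx(135.0, abs=1e-6)
        assert canon[1] == pytest.approx(-45.0, abs=1e-6)

    def test_missing_chi_atom_marks_undefined(self, helix_backbone):
        r = build_sidechain(helix_backbone, "ASP", RotamerSpec("ASP", (-65.0, -15.0), 0.5))
        r.atoms = [a for a in r.atoms if a.name != "OD1"]
        got = sc.chi_angles(r)
        assert got[0] is not None and got[1] is None

    def test_unknown_residue_type_raises(self):
        r = sc.ResidueView("A", 1, "XXX", [])
        with pytest.raises(ValueError, match="no chi definition"):
            sc.chi_angles(r)


# --------------------------------------------------------------------------
# superposition and RMSD
# --------------------------------------------------------------------------


class TestKabsch:
    def test_identical_sets_identity(self):
        P = np.random.default_rng(0).normal(size=(6, 3))
        R, t, rmsd = sc.kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(10, 3))
        th = np.radians(37.0)
        Rz = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        Q = P @ Rz.T + [1.0, 2.0, 3.0]
        R, t, rmsd = sc.kabsch_superpose(P, Q)
        np.testing.assert_allclose(R, Rz, atol=1e-9)
        assert rmsd < 1e-9

    def test_reflection_still_proper_rotation(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(8, 3))
        Q = P * [-1, 1, 1]  # mirror image
        R, t, rmsd = sc.kabsch_superpose(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert rmsd > 0

    def test_too_few_or_collinear_raises(self):
        with pytest.raises(ValueError):
            sc.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            sc.kabsch_superpose(line, line)

    def test_rmsd_invariant_under_joint_rigid_transform(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(12, 3))
        Q = P + rng.normal(scale=0.5, size=(12, 3))
        _, _, rmsd0 = sc.kabsch_superpose(P, Q)
        R, t = random_rigid_transform(rng)
        _, _, rmsd1 = sc.kabsch_superpose(P @ R.T + t, Q @ R.T + t)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)


class TestRmsdSubset:
    def test_self_is_zero(self, bundle):
        rmsd, pairs = sc.rmsd_subset(bundle, bundle)
        assert rmsd == 0.0 and len(pairs) == 56

    def test_single_displaced_ca_closed_form(self, bundle):
        other = bundle.copy()
        other.find("A", 3).atom("CA").pos += [1.0, 0.0, 0.0]
        rmsd, pairs = sc.rmsd_subset(bundle, other, superpose=False)
        assert rmsd == pytest.approx(np.sqrt(1.0 / len(pairs)))

    def test_gaussian_displacement_matches_direct_formula(self, bundle):
        rng = np.random.default_rng(5)
        other = bundle.copy()
        disp = {}
        for r in other.residues():
            d = rng.normal(scale=0.3, size=3)
            r.atom("CA").pos = r.atom("CA").pos + d
            disp[r.key] = d
        expected = np.sqrt(np.mean([np.sum(d**2) for d in disp.values()]))
        rmsd, _ = sc.rmsd_subset(bundle, other, superpose=False)
        assert rmsd == pytest.approx(expected, abs=1e-12)

    def test_unmatched_numbering_lists_orphans(self, bundle):
        other = bundle.copy()
        other.residues()[0].seqnum = 999
        with pytest.raises(ValueError, match="unmatched"):
            sc.rmsd_subset(bundle, other)


# --------------------------------------------------------------------------
# SASA
# --------------------------------------------------------------------------


class TestSasa:
    def test_single_atom_closed_form(self):
        area = sc.sasa_points(np.zeros((1, 3)), np.array([1.70]), 1.4, 960)[0]
        assert area == pytest.approx(4 * np.pi * 3.10**2, rel=0.01)

    def test_enclosed_atom_is_zero(self):
        pts = [np.zeros(3)]
        # cage of atoms on a sphere of radius 3 Å: every probe position blocked
        g = sc.golden_spiral(60)
        pts.extend(3.0 * g)
        coords = np.array(pts)
        areas = sc.sasa_points(coords, np.full(len(coords), 1.7), 1.4, 960)
        assert areas[0] == 0.0

    def test_two_sphere_analytic_caps(self):
        # two equal spheres: exposed fraction = 1 - h/(2(r+p)) with
        # h the buried cap height, from the spherical-cap formula
        r, p = 1.7, 1.4
        ext = r + p
        for d in (1.0, 2.0, 3.0, 4.0, 5.0):
            coords = np.array([[0.0, 0, 0], [d, 0, 0]])
            areas = sc.sasa_points(coords, np.array([r, r]), p, 1920)
            if d >= 2 * ext:
                expected = 4 * np.pi * ext**2
            else:
                cap_h = ext - d / 2.0
                expected = 4 * np.pi * ext**2 - 2 * np.pi * ext * cap_h
            assert areas[0] == pytest.approx(expected, rel=0.02)

    def test_monotone_occlusion(self):
        rng = np.random.default_rng(7)
        core = rng.normal(scale=2.0, size=(10, 3))
        added = rng.normal(scale=2.0, size=(5, 3)) + 1.0
        a0 = sc.sasa_points(core, np.full(10, 1.7), 1.4, 480)
        a1 = sc.sasa_points(np.vstack([core, added]), np.full(15, 1.7), 1.4, 480)[:10]
        assert np.all(a1 <= a0 + 1e-9)

    def test_bad_probe_raises(self):
        with pytest.raises(ValueError):
            sc.sasa_points(np.zeros((1, 3)), np.array([1.7]), 0.0)


# --------------------------------------------------------------------------
# clashes and shells
# --------------------------------------------------------------------------


def _clash_oracle(coords, radii, tol):
    """Brute-force O(n^2) clash scan with its own bond-path exclusion."""
    n = len(coords)
    bonds = set()
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) < 1.8:
                bonds.add((i, j))
    adj = {}
    for i, j in bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)

    def path_leq3(i, j):
        seen = {i}
        frontier = {i}
        for _ in range(3):
            frontier = set().union(*(adj.get(k, set()) for k in frontier)) - seen
            if j in frontier:
                return True
            seen |= frontier
        return False

    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(coords[i] - coords[j])
            if d < radii[i] + radii[j] - tol and not path_leq3(i, j):
                out.add((i, j))
    return out


class TestClashes:
    def _structure_from_points(self, coords):
        atoms = [sc.AtomRecord(f"C{i + 1}", "C", c) for i, c in enumerate(coords)]
        # one atom per residue so no intra-residue special-casing applies
        residues = [sc.ResidueView("A", i + 1, "UNK", [a]) for i, a in enumerate(atoms)]
        return sc.ProteinStructure([residues])

    def test_touching_carbons_do_not_clash(self):
        s = self._structure_from_points(np.array([[0.0, 0, 0], [3.4, 0, 0]]))
        assert sc.count_clashes(s) == []

    def test_overlap_depth_arithmetic(self):
        s = self._structure_from_points(np.array([[0.0, 0, 0], [2.8, 0, 0]]))
        (c,) = sc.count_clashes(s)
        assert c.overlap == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 60)
        coords = rng.normal(scale=4.0, size=(n, 3))
        s = self._structure_from_points(coords)
        got = {(c.i, c.j) for c in sc.count_clashes(s)}
        expected = _clash_oracle(coords, np.full(n, 1.7), 0.4)
        assert got == expected


class TestSelectShell:
    def test_empty_box_empty_shell(self):
        s = sc.ProteinStructure([[sc.ResidueView("L", 1, "LIG",
                                                 [sc.AtomRecord("C1", "C", np.zeros(3), is_hetero=True)])]])
        assert sc.select_shell(s, [("L", 1, "C1")], cutoff=5.0) == set()

    def test_cutoff_is_closed_interval(self):
        lig = sc.ResidueView("L", 1, "LIG", [sc.AtomRecord("C1", "C", np.zeros(3), is_hetero=True)])
        at_cut = sc.ResidueView("A", 1, "ALA", [sc.AtomRecord("CB", "C", np.array([5.0, 0, 0]))])
        beyond = sc.ResidueView("A", 2, "ALA", [sc.AtomRecord("CB", "C", np.array([5.001, 0, 0]))])
        s = sc.ProteinStructure([[lig, at_cut, beyond]])
        assert sc.select_shell(s, [("L", 1, "C1")], cutoff=5.0) == {("A", 1)}

    def test_matches_brute_force_on_bundle(self, bundle):
        center = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 1.0]])
        got = sc.select_shell(bundle, center, cutoff=6.0)
        expected = set()
        for r in bundle.residues():
            for a in r.heavy_atoms():
                if np.linalg.norm(center - a.pos, axis=1).min() <= 6.0:
                    expected.add(r.key)
                    break
        assert got == expected

    def test_empty_center_raises(self, bundle):
        with pytest.raises(ValueError):
            sc.select_shell(bundle, np.zeros((0, 3)))


class TestRigidInvariance:
    def test_sasa_invariant_under_rigid_transform(self, bundle):
        rng = np.random.default_rng(9)
        R, t = random_rigid_transform(rng)
        moved = apply_rigid(bundle, R, t)
        a0, _ = sc.shrake_rupley_sasa(bundle, n_points=480)
        a1, _ = sc.shrake_rupley_sasa(moved, n_points=480)
        # the quadrature grid is fixed in space, so equality is approximate
        assert np.abs(a0 - a1).max() < 3.0
        assert abs(a0.sum() - a1.sum()) / a0.sum() < 0.01
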