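"""Catalytic-base placement: construction round trips, docking closure,
planted-solution recovery and the preorganization filter."""

import numpy as np
import pytest

from basecraft import siteplace as sp
from basecraft import structcore as sc
from basecraft import synthdata as sd

from conftest import apply_rigid, random_rigid_transform


class TestBuildSidechain:
    @pytest.mark.parametrize(
        "base,chis",
        [("ASP", (-65.0, -15.0)), ("ASP", (62.0, -5.0)), ("GLU", (-67.0, -178.0, -10.0)),
         ("GLU", (70.0, -80.0, 0.0))],
    )
    def test_round_trip(self, helix_backbone, base, chis):
        r = sp.build_sidechain(helix_backbone, base, sp.RotamerSpec(base, chis, 0.5))
        np.testing.assert_allclose(sc.chi_angles(r), chis, atol=1e-6)

    def test_wrong_chi_count_rejected(self, helix_backbone):
        with pytest.raises(ValueError, match="chi values"):
            sp.build_sidechain(helix_backbone, "ASP",
                               sp.RotamerSpec("ASP", (-65.0, -15.0, 0.0, 0.0), 0.5))

    def test_unknown_type_rejected(self, helix_backbone):
        with pytest.raises(ValueError, match="unsupported"):
            sp.build_sidechain(helix_backbone, "SER", sp.RotamerSpec("SER", (60.0,), 0.5))

    def test_missing_backbone_atom_rejected(self):
        with pytest.raises(ValueError, match="backbone"):
            sp.build_sidechain({"N": np.zeros(3), "CA": np.array([1.458, 0, 0])},
                               "ASP", sp.RotamerSpec("ASP", (-65.0, -15.0), 0.5))


class TestLigandSuperposition:
    def test_identity_map(self):
        t = sp.ligand_template_6nbt()
        pose, rmsd = sp.superpose_ligand_by_shared_atoms(t, t, [(n, n) for n in list(t)[:5]])
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_rotation(self):
        t = sp.ligand_template_6nbt()
        th = np.radians(25.0)
        R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        anchor = {k: R @ v + [1.0, -2.0, 0.5] for k, v in t.items()}
        pose, rmsd = sp.superpose_ligand_by_shared_atoms(t, anchor, [(n, n) for n in t])
        assert rmsd < 1e-9
        np.testing.assert_allclose(pose.transform[0], R, atol=1e-9)

    def test_two_atom_map_rejected(self):
        t = sp.ligand_template_6nbt()
        with pytest.raises(ValueError, match="3 mapped"):
            sp.superpose_ligand_by_shared_atoms(t, t, [("N3", "N3"), ("N2", "N2")])

    def test_unmapped_names_listed(self):
        t = sp.ligand_template_6nbt()
        with pytest.raises(ValueError, match="XX"):
            sp.superpose_ligand_by_shared_atoms(t, t, [("N3", "XX"), ("N2", "N2"), ("N1", "N1")])


class TestHbondGeometry:
    def _carboxylate(self):
        # planar carboxylate in the xy plane
        C = np.array([0.0, 0.0, 0.0])
        O1 = np.array([1.25, 0.0, 0.0])
        O2 = np.array([-0.62, 1.08, 0.0])
        return C, O1, O2

    def test_constructed_syn_contact(self):
        C, O1, O2 = self._carboxylate()
        # donor in-plane, 2.8 Å from O1, on the O2 side
        th = np.radians(120.0)
        u = (O1 - C) / np.linalg.norm(O1 - C)
        v = np.array([0.0, 1.0, 0.0])
        N = O1 + 2.8 * (-np.cos(th) * u + np.sin(th) * v)
        g = sp.score_hbond_geometry(N, C, O1, O2)
        assert g.distance == pytest.approx(2.8)
        assert g.theta == pytest.approx(120.0)
        assert abs(g.syn_dihedral) < 1e-6 and g.is_syn

    def test_anti_contact_flagged(self):
        C, O1, O2 = self._carboxylate()
        u = (O1 - C) / np.linalg.norm(O1 - C)
        v = np.array([0.0, -1.0, 0.0])  # opposite side from O2: anti
        N = O1 + 2.8 * (-np.cos(np.radians(120.0)) * u + np.sin(np.radians(120.0)) * v)
        g = sp.score_hbond_geometry(N, C, O1, O2)
        assert abs(abs(g.syn_dihedral) - 180.0) < 1e-6
        assert not g.is_syn

    def test_collinear_carboxylate_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            sp.score_hbond_geometry([0, 0, 3.0], [0, 0, 0], [1.25, 0, 0], [2.5, 0, 0])


class TestDocking:
    def test_four_raw_poses(self, helix_backbone):
        base = sp.build_sidechain(helix_backbone, "ASP", sp.RotamerSpec("ASP", (-65.0, -15.0), 0.5))
        assert len(sp.dock_ts_to_base(base, dedupe_rmsd=None)) == 4

    def test_every_pose_satisfies_the_constraint(self, helix_backbone):
        base = sp.build_sidechain(helix_backbone, "GLU", sp.RotamerSpec("GLU", (-67.0, -178.0, -10.0), 0.5))
        con = sp.TSGeometryConstraint()
        for pose in sp.dock_ts_to_base(base, constraint=con, dedupe_rmsd=None):
            g = sp.score_hbond_geometry(pose.donor, base.coord("CD"), base.coord("OE1"),
                                        base.coord("OE2"), con.syn_dihedral_max)
            assert con.d_range[0] <= g.distance <= con.d_range[1]
            assert con.theta_range[0] <= g.theta <= con.theta_range[1]
            assert g.is_syn

    def test_pose_rigidity(self, helix_backbone):
        base = sp.build_sidechain(helix_backbone, "ASP", sp.RotamerSpec("ASP", (-65.0, -15.0), 0.5))
        t = sp.ligand_template_6nbt()
        names = sorted(t)
        ref = np.array([t[n] for n in names])
        d0 = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
        for pose in sp.dock_ts_to_base(base):
            X = pose.coords(names)
            d1 = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
            assert np.abs(d0 - d1).max() < 1e-6

    def test_missing_carboxylate_atom_rejected(self, helix_backbone):
        base = sp.build_sidechain(helix_backbone, "ASP", sp.RotamerSpec("ASP", (-65.0, -15.0), 0.5))
        base.atoms = [a for a in base.atoms if a.name != "OD2"]
        with pytest.raises(ValueError, match="carboxylate"):
            sp.dock_ts_to_base(base)


class TestEnumeration:
    def test_planted_solution_recovered(self, wide_bundle, planted):
        work, pose, truth = planted
        positions = [(ch, i) for ch in "ABCD" for i in range(5, 11)
                     if sd._faces_lumen(wide_bundle, (ch, i))]
        cands = sp.enumerate_base_placements(work, pose, positions)
        passing = [c for c in cands if c.passes]
        assert {c.position for c in passing} == {truth.position}
        best = [c for c in passing if c.rotamer == truth.rotamer and c.base_type == truth.base_type]
        assert best, "planted rotamer not among the passing candidates"

    def test_scores_invariant_under_rigid_transform(self, planted):
        work, pose, truth = planted
        rng = np.random.default_rng(21)
        R, t = random_rigid_transform(rng)
        moved = apply_rigid(work, R, t)
        moved_pose = sp.LigandPose({k: R @ v + t for k, v in pose.atoms.items()},
                                   pose.source_fragment, donor_atom=pose.donor_atom)
        pos = [truth.position]
        c0 = sp.enumerate_base_placements(work, pose, pos)
        c1 = sp.enumerate_base_placements(moved, moved_pose, pos)
        for a, b in zip(c0, c1):
            assert a.geometry_ok == b.geometry_ok and a.passes == b.passes
            if a.geometry_ok:
                assert a.hbond_distance == pytest.approx(b.hbond_distance, abs=1e-6)
                assert a.hbond_theta == pytest.approx(b.hbond_theta, abs=1e-6)

    def test_no_pocket_means_no_burial(self, bundle):
        # default bundle: lumen too narrow, no walls -> nothing passes
        positions = [("A", 6), ("B", 7)]
        rot = sp.ROTAMER_TABLE["ASP"][1]
        work = bundle.copy()
        res = work.find("A", 6)
        res.atoms = [a for a in res.atoms if a.name in ("N", "CA", "C", "O")]
        built = sp.build_sidechain(res, "ASP", rot)
        pose = sp.dock_ts_to_base(built)[0]
        cands = sp.enumerate_base_placements(work, pose, positions, evaluate_all=True)
        assert not any(c.passes for c in cands)

    def test_empty_rotamer_table_rejected(self, bundle):
        with pytest.raises(ValueError, match="rotamer"):
            sp.enumerate_base_placements(bundle, None, [("A", 6)], rotamers={"ASP": []},
                                         base_types=("ASP",))

    def test_burial_monotone_in_probe(self, planted):
        # anywhere a large probe reaches, a smaller one fits too, so
        # enlarging the probe can never expose a buried atom
        work, pose, truth = planted
        lig_names = sorted(pose.atoms)
        lig_coords = pose.coords(lig_names)
        for probe in (1.4, 1.8, 2.4):
            areas, keys = sc.shrake_rupley_sasa(
                work, probe_radius=probe, extra_coords=lig_coords,
                extra_elements=[n[0] for n in lig_names],
            )
            amap = dict(zip(keys, areas))
            ring_idx = [lig_names.index(a) for a in sp.RING_ATOMS_6NBT]
            assert max(amap[("*", 0, "EXT", i)] for i in ring_idx) < 0.1


class TestPreorganization:
    def test_self_comparison_passes(self, bundle):
        rep = sp.preorganization_filter(bundle, bundle, plddt=95.0,
                                        active_site_residues=[("A", 6), ("B", 7)])
        assert rep.passes and rep.backbone_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_low_confidence_fails(self, bundle):
        rep = sp.preorganization_filter(bundle, bundle, plddt=85.0,
                                        active_site_residues=[("A", 6)])
        assert not rep.passes

    def test_large_backbone_deviation_fails(self, bundle):
        rng = np.random.default_rng(3)
        moved = bundle.copy()
        for r in moved.residues():
            r.atom("CA").pos = r.atom("CA").pos + rng.normal(scale=1.5, size=3)
        rep = sp.preorganization_filter(bundle, moved, plddt=95.0,
                                        active_site_residues=[("A", 6)])
        assert rep.backbone_rmsd > 1.0 and not rep.passes

    def test_missing_active_site_residue_rejected(self, bundle):
        with pytest.raises(ValueError, match="absent"):
            sp.preorganization_filter(bundle, bundle, 95.0, [("Z", 99)])
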