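"""Pose clustering, ranking, active-site assignment, hydrogen-bond detection."""

import numpy as np
import pytest

from inhibikit import dockrank, pdbio, synthdata
from inhibikit.dockrank import (
    PoseGroup,
    assign_location,
    center_of_mass,
    cluster_poses,
    copper_midpoint,
    detect_hbonds,
    list_donors_acceptors,
    rank_compounds,
)
from inhibikit.structures import Atom, Pose, apply_rigid, random_rotation


def atom(name, element, xyz, res="LIG", seq=900, serial=1, chain="L"):
    return Atom(serial, name, element, res, seq, chain, *map(float, xyz))


def pose(xyzs, energy, compound="cpd", run_id=0):
    atoms = tuple(atom(f"C{i + 1}", "C", p, serial=i + 1) for i, p in enumerate(xyzs))
    return Pose(compound, atoms, energy, run_id)


def cu_receptor(midpoint=(0.0, 0.0, 0.0), sep=3.0):
    m = np.asarray(midpoint, float)
    return (
        atom("CU", "CU", m + [sep / 2, 0, 0], res="CU", seq=400, serial=1, chain="A"),
        atom("CU", "CU", m - [sep / 2, 0, 0], res="CU", seq=401, serial=2, chain="A"),
    )


class TestCenterOfMass:
    def test_geometric_mean(self):
        p = pose([(0, 0, 0), (2, 0, 0)], -5.0)
        np.testing.assert_allclose(center_of_mass(p), [1, 0, 0])

    def test_translation_covariance(self):
        p = pose([(0, 0, 0), (2, 0, 0), (1, 1, 0)], -5.0)
        shifted = Pose(p.compound_id, apply_rigid(p.atoms, np.eye(3), [3, -1, 2]), p.energy)
        np.testing.assert_allclose(
            center_of_mass(shifted), center_of_mass(p) + [3, -1, 2], atol=1e-12
        )

    def test_mass_weighting_pulls_toward_heavy_atom(self):
        atoms = (atom("O", "O", (0, 0, 0)), atom("H", "H", (1, 0, 0)))
        p = Pose("w", atoms, -1.0)
        com = center_of_mass(p, weighting="mass")
        # hand-weighted mean: x = 1.008/(15.999+1.008)
        assert com[0] == pytest.approx(1.008 / 17.007, rel=1e-9)

    def test_unknown_weighting_rejected(self):
        with pytest.raises(ValueError):
            center_of_mass(pose([(0, 0, 0)], -1.0), weighting="charge")


class TestClustering:
    def test_planted_clouds_recovered(self):
        scen = synthdata.PoseScenario(
            cluster_centers=((0.0, 0.0, 0.0), (30.0, 0.0, 0.0)),
            spreads=(1.0, 1.0),
            energies_mean=(-6.5, -4.0),
            energies_sd=(0.3, 0.3),
            n_per_cluster=(40, 20),
            seed=11,
        )
        poses, labels = synthdata.gen_pose_cloud(scen)
        groups = cluster_poses(poses, cutoff=5.0)
        assert len(groups) == 2
        assert sorted(g.n for g in groups) == [20, 40]
        # membership matches the planted labels exactly
        for g in groups:
            members = {p.run_id for p in g.poses}
            planted = {i for i, lab in enumerate(labels) if lab == labels[next(iter(members))]}
            assert members == planted

    def test_identical_poses_single_group(self):
        poses = [pose([(0, 0, 0), (1, 0, 0)], -3.0, run_id=i) for i in range(5)]
        groups = cluster_poses(poses, cutoff=1.0)
        assert len(groups) == 1 and groups[0].n == 5

    def test_tiny_cutoff_gives_singletons(self):
        poses = [pose([(3.0 * i, 0, 0)], -3.0, run_id=i) for i in range(4)]
        assert len(cluster_poses(poses, cutoff=1e-9)) == 4

    def test_deterministic_rerun(self):
        scen = synthdata.PoseScenario(
            cluster_centers=((0.0, 0.0, 0.0),), spreads=(2.0,), energies_mean=(-5.0,),
            energies_sd=(1.0,), n_per_cluster=(30,), seed=2,
        )
        poses, _ = synthdata.gen_pose_cloud(scen)
        a = cluster_poses(poses, cutoff=3.0)
        b = cluster_poses(list(poses), cutoff=3.0)
        assert [sorted(p.run_id for p in g.poses) for g in a] == [
            sorted(p.run_id for p in g.poses) for g in b
        ]

    def test_n_conservation(self):
        scen = synthdata.PoseScenario(
            cluster_centers=((0.0, 0.0, 0.0), (8.0, 0.0, 0.0), (50.0, 0.0, 0.0)),
            spreads=(1.5, 1.5, 1.5), energies_mean=(-6.0, -5.0, -4.0),
            energies_sd=(0.5, 0.5, 0.5), n_per_cluster=(17, 13, 23), seed=5,
        )
        poses, _ = synthdata.gen_pose_cloud(scen)
        groups = cluster_poses(poses, cutoff=3.5)
        assert sum(g.n for g in groups) == len(poses)

    def test_group_energy_statistics(self):
        poses = [pose([(0, 0, 0)], e, run_id=i) for i, e in enumerate([-6.0, -5.0, -4.0])]
        (g,) = cluster_poses(poses, cutoff=1.0)
        assert g.lowest_energy == -6.0
        assert g.mean_energy == pytest.approx(-5.0)
        assert g.lowest_energy <= g.mean_energy

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            cluster_poses([pose([(0, 0, 0)], -1.0)], cutoff=0.0)


class TestLocation:
    def test_centroid_at_cu_midpoint_is_active(self):
        g = PoseGroup((pose([(0, 0, 0)], -5.0),), centroid=np.zeros(3))
        assert assign_location(g, cu_receptor()).location == "active"

    def test_far_centroid_is_other(self):
        g = PoseGroup((pose([(30, 0, 0)], -5.0),), centroid=np.array([30.0, 0, 0]))
        assert assign_location(g, cu_receptor()).location == "other"

    def test_boundary_is_strict(self):
        g = PoseGroup((pose([(8, 0, 0)], -5.0),), centroid=np.array([8.0, 0, 0]))
        assert assign_location(g, cu_receptor(), cutoff=8.0).location == "other"

    def test_missing_copper_pair_rejected(self):
        with pytest.raises(ValueError, match="two metal"):
            copper_midpoint((atom("CU", "CU", (0, 0, 0), res="CU"),))


class TestRanking:
    def group(self, centroid, energies, location="active"):
        poses = tuple(pose([centroid], e, run_id=i) for i, e in enumerate(energies))
        return PoseGroup(poses, centroid=np.asarray(centroid, float), location=location)

    def test_lower_energy_ranks_first(self):
        table = rank_compounds(
            {
                "A": [self.group((0, 0, 0), [-6.9] + [-4.0] * 42)],
                "B": [self.group((0, 0, 0), [-6.6] + [-4.0] * 29)],
            }
        )
        assert list(table["compound"]) == ["A", "B"]
        assert list(table["n_in_group"]) == [43, 30]

    def test_tie_broken_by_occupancy(self):
        table = rank_compounds(
            {
                "A": [self.group((0, 0, 0), [-6.0, -5.0])],
                "B": [self.group((0, 0, 0), [-6.0, -5.0, -5.0])],
            }
        )
        assert list(table["compound"]) == ["B", "A"]

    def test_active_group_preferred_over_lower_energy_other(self):
        table = rank_compounds(
            {
                "A": [
                    self.group((30, 0, 0), [-8.0], location="other"),
                    self.group((0, 0, 0), [-6.0], location="active"),
                ]
            }
        )
        assert table.loc[0, "binding_location"] == "active"
        assert table.loc[0, "lowest_energy_kcal_mol"] == -6.0

    def test_single_compound_rank_one(self):
        table = rank_compounds({"A": [self.group((0, 0, 0), [-5.0])]})
        assert list(table["rank"]) == [1]


class TestDonorsAcceptors:
    def test_hydroxyl_is_donor_and_acceptor(self):
        s = (atom("O", "O", (0, 0, 0)), atom("H", "H", (0.96, 0, 0)))
        donors, acceptors = list_donors_acceptors(s)
        assert len(donors) == 1 and donors[0][0].name == "O"
        assert [a.name for a in acceptors] == ["O"]

    def test_carbonyl_is_acceptor_only(self):
        s = (atom("O", "O", (0, 0, 0)), atom("C", "C", (1.23, 0, 0)))
        with pytest.warns(UserWarning, match="no explicit hydrogens"):
            donors, acceptors = list_donors_acceptors(s)
        assert not donors and len(acceptors) == 1

    def test_carbon_never_listed(self):
        s = (atom("C", "C", (0, 0, 0)), atom("H", "H", (1.0, 0, 0)))
        donors, acceptors = list_donors_acceptors(s)
        assert not donors and not acceptors


class TestHbondDetection:
    def test_planted_scene_exact_recovery(self):
        rec, lig, planted = synthdata.gen_hbond_scene(7, 5, seed=3)
        bonds = detect_hbonds(lig, rec)
        assert len(bonds) == 7
        assert all(b.da_distance < 4.0 and b.dha_angle > 120.0 for b in bonds)
        # sorted by distance
        dists = [b.da_distance for b in bonds]
        assert dists == sorted(dists)

    def test_empty_scene_empty_detection(self):
        rec, lig, _ = synthdata.gen_hbond_scene(0, 5, seed=1)
        assert detect_hbonds(lig, rec) == []

    def test_distance_criterion_strict(self):
        lig = (atom("O", "O", (0, 0, 0)), atom("H", "H", (0.96, 0, 0)))
        rec = (atom("O", "O", (4.2, 0, 0), res="SER", seq=1, chain="A"),)
        assert detect_hbonds(lig, rec) == []

    def test_angle_criterion_excludes_bent_contact(self):
        # 3.0 A donor-acceptor but ~100 degree DHA angle
        lig = (atom("O", "O", (0, 0, 0)), atom("H", "H", (0.48, 0.83, 0)))
        rec = (atom("O", "O", (3.0, 0, 0), res="SER", seq=1, chain="A"),)
        assert detect_hbonds(lig, rec) == []

    def test_both_directions_scanned(self):
        # receptor hydroxyl donates to a bare ligand acceptor
        rec = (
            atom("OG", "O", (0, 0, 0), res="SER", seq=1, chain="A"),
            atom("HG", "H", (0.96, 0, 0), res="SER", seq=1, chain="A"),
        )
        lig = (atom("O1", "O", (2.9, 0, 0)),)
        bonds = detect_hbonds(lig, rec)
        assert len(bonds) == 1 and bonds[0].donor.res_name == "SER"

    def test_rigid_body_invariance(self, rng):
        rec, lig, planted = synthdata.gen_hbond_scene(5, 3, seed=9)
        R = random_rotation(rng)
        t = rng.normal(0, 20, 3)
        bonds0 = detect_hbonds(lig, rec)
        bonds1 = detect_hbonds(apply_rigid(lig, R, t), apply_rigid(rec, R, t))
        assert len(bonds0) == len(bonds1)
        for b0, b1 in zip(bonds0, bonds1):
            assert b1.da_distance == pytest.approx(b0.da_distance, abs=1e-9)
            assert b1.dha_angle == pytest.approx(b0.dha_angle, abs=1e-6)


class TestRigidInvarianceClustering:
    def test_groups_and_location_invariant(self, rng):
        scen = synthdata.PoseScenario(
            cluster_centers=((0.0, 0.0, 0.0), (30.0, 0.0, 0.0)),
            spreads=(1.0, 1.0), energies_mean=(-6.0, -4.0), energies_sd=(0.3, 0.3),
            n_per_cluster=(15, 10), seed=21,
        )
        poses, _ = synthdata.gen_pose_cloud(scen)
        receptor = cu_receptor()
        R = random_rotation(rng)
        t = rng.normal(0, 15, 3)
        moved = [Pose(p.compound_id, apply_rigid(p.atoms, R, t), p.energy, p.run_id) for p in poses]
        rec_moved = apply_rigid(receptor, R, t)
        g0 = cluster_poses(poses, cutoff=5.0)
        g1 = cluster_poses(moved, cutoff=5.0)
        assert [sorted(p.run_id for p in g.poses) for g in g0] == [
            sorted(p.run_id for p in g.poses) for g in g1
        ]
        for a, b in zip(g0, g1):
            assert (
                assign_location(a, receptor).location
                == assign_location(b, rec_moved).location
            )


class TestPoseIO:
    def test_round_trip_through_pdb(self, tmp_path):
        scen = synthdata.PoseScenario(
            cluster_centers=((0.0, 0.0, 0.0),), spreads=(1.0,), energies_mean=(-6.0,),
            energies_sd=(0.5,), n_per_cluster=(3,), compound_id="cpd1", seed=13,
        )
        poses, _ = synthdata.gen_pose_cloud(scen)
        path = tmp_path / "cpd1_poses.pdb"
        pdbio.write_poses(path, poses)
        back = pdbio.read_poses(path, compound_id="cpd1")
        assert len(back) == 3
        for orig, rt in zip(poses, back):
            assert rt.energy == pytest.approx(orig.energy, abs=5e-4)
            np.testing.assert_allclose(
                [a.xyz for a in rt.atoms], [a.xyz for a in orig.atoms], atol=1e-3
            )
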