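"""Helix superposition and two-stage ligand-pose clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from carriermd import (
    cluster_ligand_poses,
    representative_configuration,
    superpose_to_reference,
)
from carriermd.errors import AnalysisError
from carriermd.pose_clustering import PoseMatrix, kabsch_transform
from carriermd.traj_core import Frame


def rigid_transform(coords, angle, axis, shift):
    c, s = np.cos(angle), np.sin(angle)
    if axis == "z":
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    else:
        rot = np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])
    return coords @ rot.T + shift


class TestSuperposition:
    def test_rigid_copies_collapse_to_reference(self, pocket_blobs, rng):
        res = pocket_blobs
        top = res.topology
        helix_ca = top.select("segid PROT and name CA")
        ligand = top.select("resname GDP")
        ref = res.frames[0]
        moved = [Frame(coordinates=rigid_transform(
                     ref.coordinates, rng.uniform(0, np.pi), "z",
                     rng.uniform(-20, 20, 3)), time=float(i))
                 for i in range(5)]
        pm = superpose_to_reference(top, moved, helix_ca, ligand, ref)
        assert np.max(pm.fit_rmsd) < 1e-6
        assert np.max(np.abs(pm.coordinates - pm.coordinates[0])) < 1e-6

    def test_known_z_rotation_is_undone(self, pocket_blobs):
        res = pocket_blobs
        top = res.topology
        helix_ca = top.select("segid PROT and name CA")
        ligand = top.select("resname GDP")
        ref = res.frames[0]
        rotated = Frame(coordinates=rigid_transform(
            ref.coordinates, np.pi / 2, "z", np.zeros(3)))
        pm = superpose_to_reference(top, [rotated], helix_ca, ligand, ref)
        assert np.max(np.abs(
            pm.poses()[0] - ref.coordinates[ligand.indices])) < 1e-6

    def test_fit_never_worse_than_no_fit(self, pocket_blobs, rng):
        res = pocket_blobs
        top = res.topology
        helix_ca = top.select("segid PROT and name CA")
        ligand = top.select("resname GDP")
        ref = res.frames[0]
        noisy = Frame(coordinates=ref.coordinates +
                      rng.normal(0, 2.0, ref.coordinates.shape))
        pre = np.sqrt(np.mean(np.sum(
            (noisy.coordinates[helix_ca.indices] -
             ref.coordinates[helix_ca.indices]) ** 2, axis=1)))
        pm = superpose_to_reference(top, [noisy], helix_ca, ligand, ref)
        assert pm.fit_rmsd[0] <= pre + 1e-12

    def test_no_reflection(self, rng):
        mobile = rng.uniform(0, 10, (6, 3))
        mirrored = mobile * np.array([-1.0, 1.0, 1.0])
        rot, _t, _r = kabsch_transform(mobile, mirrored)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_too_few_fit_atoms(self, rng):
        with pytest.raises(AnalysisError):
            kabsch_transform(rng.uniform(0, 1, (2, 3)),
                             rng.uniform(0, 1, (2, 3)))


class TestClustering:
    def poses(self, pocket_blobs):
        top = pocket_blobs.topology
        return superpose_to_reference(
            top, pocket_blobs.frames, top.select("segid PROT and name CA"),
            top.select("resname GDP"), pocket_blobs.frames[0])

    def test_planted_partition_recovered(self, pocket_blobs):
        pm = self.poses(pocket_blobs)
        result = cluster_ligand_poses(pm, k=3, seed=0)
        assert adjusted_rand_score(pocket_blobs.blob_labels,
                                   result.labels) == 1.0
        assert sorted(result.occupancy) == pytest.approx(
            sorted(pocket_blobs.blob_occupancy))
        assert result.occupancy.sum() == pytest.approx(1.0, abs=1e-12)

    def test_auto_k_selects_three(self, pocket_blobs):
        pm = self.poses(pocket_blobs)
        assert cluster_ligand_poses(pm, k="auto", seed=0).k == 3

    def test_k_one_single_cluster(self, pocket_blobs):
        pm = self.poses(pocket_blobs)
        result = cluster_ligand_poses(pm, k=1, seed=0)
        assert result.k == 1 and result.occupancy[0] == 1.0

    def test_duplication_invariance(self, pocket_blobs):
        pm = self.poses(pocket_blobs)
        doubled = PoseMatrix(
            coordinates=np.vstack([pm.coordinates, pm.coordinates]),
            ligand_atom_ids=pm.ligand_atom_ids,
            times=np.concatenate([pm.times, pm.times]),
            fit_rmsd=np.concatenate([pm.fit_rmsd, pm.fit_rmsd]))
        r1 = cluster_ligand_poses(pm, k=3, seed=0)
        r2 = cluster_ligand_poses(doubled, k=3, seed=0)
        assert sorted(r1.occupancy) == pytest.approx(sorted(r2.occupancy))

    def test_deterministic_given_seed(self, pocket_blobs):
        pm = self.poses(pocket_blobs)
        r1 = cluster_ligand_poses(pm, k=3, seed=123)
        r2 = cluster_ligand_poses(pm, k=3, seed=123)
        assert np.array_equal(r1.labels, r2.labels)
        assert np.array_equal(r1.representative_frame, r2.representative_frame)

    def test_identical_poses_single_cluster_with_warning(self):
        data = np.tile(np.arange(6.0), (10, 1))
        pm = PoseMatrix(coordinates=data, ligand_atom_ids=np.arange(2),
                        times=np.arange(10.0), fit_rmsd=np.zeros(10))
        with pytest.warns(UserWarning):
            result = cluster_ligand_poses(pm, k=3, seed=0)
        assert result.k == 1

    def test_invalid_k(self, pocket_blobs):
        pm = self.poses(pocket_blobs)
        with pytest.raises(AnalysisError):
            cluster_ligand_poses(pm, k=pm.n_frames + 1, seed=0)

    def test_whole_system_transform_invariance(self, pocket_blobs, rng):
        """A rigid transform applied to every frame is absorbed by the fit."""
        res = pocket_blobs
        top = res.topology
        helix_ca = top.select("segid PROT and name CA")
        ligand = top.select("resname GDP")
        moved = [Frame(coordinates=rigid_transform(
            f.coordinates, 1.1, "x", np.array([5.0, -3.0, 8.0])),
            time=f.time) for f in res.frames]
        pm0 = self.poses(res)
        pm1 = superpose_to_reference(top, moved, helix_ca, ligand,
                                     res.frames[0])
        r0 = cluster_ligand_poses(pm0, k=3, seed=0)
        r1 = cluster_ligand_poses(pm1, k=3, seed=0)
        assert adjusted_rand_score(r0.labels, r1.labels) == 1.0


class TestRepresentative:
    def test_member_equal_to_centroid_wins(self):
        data = np.array([[0.0, 0], [10, 0], [0.1, 0], [9.9, 0], [5.0, 0]])
        pm = PoseMatrix(coordinates=data, ligand_atom_ids=np.arange(1),
                        times=np.arange(5.0), fit_rmsd=np.zeros(5))
        result = cluster_ligand_poses(pm, k=2, seed=0)
        reps = representative_configuration(pm, result)
        for c in range(2):
            members = np.flatnonzero(result.labels == c)
            dists = np.linalg.norm(data[members] - result.centroids[c], axis=1)
            assert reps[c] == members[np.argmin(dists)]

    def test_tie_broken_by_lowest_frame_index(self):
        # two frames exactly equidistant from the centroid
        data = np.array([[1.0, 0], [-1.0, 0], [1.0, 0], [-1.0, 0]])
        pm = PoseMatrix(coordinates=data, ligand_atom_ids=np.arange(1),
                        times=np.arange(4.0), fit_rmsd=np.zeros(4))
        from carriermd.pose_clustering import ClusterResult

        result = ClusterResult(labels=np.zeros(4, dtype=int),
                               occupancy=np.ones(1),
                               centroids=np.zeros((1, 2)),
                               representative_frame=np.zeros(1, dtype=int),
                               k=1, seed=0)
        assert representative_configuration(pm, result)[0] == 0

    def test_matches_argmin_oracle(self, pocket_blobs):
        pm = self.poses_matrix(pocket_blobs)
        result = cluster_ligand_poses(pm, k=3, seed=0)
        for c in range(result.k):
            members = np.flatnonzero(result.labels == c)
            best = min(members, key=lambda i: (float(np.linalg.norm(
                pm.coordinates[i] - result.centroids[c])), i))
            assert result.representative_frame[c] == best

    def poses_matrix(self, pocket_blobs):
        top = pocket_blobs.topology
        return superpose_to_reference(
            top, pocket_blobs.frames, top.select("segid PROT and name CA"),
            top.select("resname GDP"), pocket_blobs.frames[0])
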