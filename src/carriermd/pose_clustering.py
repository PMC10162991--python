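"""Ligand-pose clustering after superposition on the transmembrane helices.

Frames are first superposed on the helix alpha-carbons of a reference
frame (optimal least-squares rotation + translation, no reflection);
the fitted transform is applied to the ligand atoms, whose flattened
coordinates form the pose matrix.  Poses are then clustered with
Ward-linkage agglomerative clustering followed by K-means refinement
seeded from the agglomerative centroids.  Each cluster reports its
occupancy (fraction of frames) and a representative frame — the member
closest to the K-means centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence
import warnings

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import AnalysisError, EmptySelectionError
from .traj_core import Frame, Selection, Topology

__all__ = [
    "PoseMatrix",
    "ClusterResult",
    "kabsch_transform",
    "superpose_to_reference",
    "cluster_ligand_poses",
    "representative_configuration",
]


@dataclass
class PoseMatrix:
    """F frames × (3·M) flattened ligand coordinates after helix fit."""

    coordinates: np.ndarray         # (F, 3M) Å
    ligand_atom_ids: np.ndarray     # (M,)
    times: np.ndarray               # (F,) ns
    fit_rmsd: np.ndarray            # (F,) helix-CA RMSD to reference after fit

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def poses(self) -> np.ndarray:
        """Poses reshaped to (F, M, 3)."""
        return self.coordinates.reshape(self.n_frames, -1, 3)


@dataclass
class ClusterResult:
    """Cluster labels, occupancies and representatives for a pose matrix."""

    labels: np.ndarray              # (F,) cluster id in [0, k)
    occupancy: np.ndarray           # (k,) fractions summing to 1
    centroids: np.ndarray           # (k, 3M)
    representative_frame: np.ndarray  # (k,) frame index per cluster
    k: int
    seed: int

    def main_cluster(self) -> int:
        return int(np.argmax(self.occupancy))


def kabsch_transform(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation mapping mobile onto reference.

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` best fits
    ``reference`` in the least-squares sense.  Reflections are excluded
    (det R = +1).
    """
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise AnalysisError("superposition needs ≥3 matched fit atoms")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    h = (mobile - mob_c).T @ (reference - ref_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = ref_c - rotation @ mob_c
    fitted = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return rotation, translation, rmsd


def superpose_to_reference(topology: Topology, frames: Iterable[Frame],
                           helix_ca: Selection, ligand: Selection,
                           reference: Frame) -> PoseMatrix:
    """Fit each frame's helix CAs onto the reference; collect ligand poses.

    The rigid transform (rotation + translation, no reflection) that
    minimises the helix-CA RMSD to the reference frame is computed per
    frame and applied to the ligand atoms.  The post-fit RMSD never
    exceeds the pre-fit RMSD (least-squares optimality).
    """
    if len(helix_ca) < 3:
        raise AnalysisError("helix-CA selection needs at least 3 atoms")
    if ligand.is_empty:
        raise EmptySelectionError("ligand selection is empty")
    ref_ca = reference.coordinates[helix_ca.indices]
    rows, times, rmsds = [], [], []
    for frame in frames:
        rot, trans, rmsd = kabsch_transform(
            frame.coordinates[helix_ca.indices], ref_ca)
        pose = frame.coordinates[ligand.indices] @ rot.T + trans
        rows.append(pose.ravel())
        times.append(frame.time)
        rmsds.append(rmsd)
    if not rows:
        raise AnalysisError("no frames supplied")
    return PoseMatrix(coordinates=np.array(rows),
                      ligand_atom_ids=ligand.indices.copy(),
                      times=np.array(times), fit_rmsd=np.array(rmsds))


def _auto_k(data: np.ndarray, link: np.ndarray, k_range=range(2, 7)) -> int:
    """Silhouette-maximising cut of the Ward dendrogram."""
    best_k, best_score = 2, -np.inf
    for k in k_range:
        if k >= data.shape[0]:
            break
        labels = fcluster(link, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(data, labels)
        if score > best_score:
            best_k, best_score = k, score
    return best_k


def cluster_ligand_poses(poses: PoseMatrix, k: int | str = "auto",
                         seed: int = 0) -> ClusterResult:
    """Two-stage pose clustering: Ward agglomerative, then K-means.

    Stage 1 cuts a Ward-linkage dendrogram (Euclidean distance on the
    flattened pose coordinates) into ``k`` clusters; with ``k="auto"``
    the cut maximising the silhouette score over k ∈ [2, 6] is chosen.
    Stage 2 refines with K-means initialised from the stage-1 centroids
    (tolerance 1e-6, max 500 iterations).  Deterministic given
    (data, k, seed).
    """
    data = poses.coordinates
    n = data.shape[0]
    if np.allclose(data, data[0]):
        warnings.warn("all poses identical; returning a single cluster")
        return ClusterResult(labels=np.zeros(n, dtype=int),
                             occupancy=np.array([1.0]), centroids=data[:1].copy(),
                             representative_frame=np.array([0]), k=1, seed=seed)
    if k == 1:
        centroid = data.mean(axis=0, keepdims=True)
        result = ClusterResult(labels=np.zeros(n, dtype=int),
                               occupancy=np.array([1.0]), centroids=centroid,
                               representative_frame=np.array([0]), k=1, seed=seed)
        result.representative_frame = representative_configuration(poses, result)
        return result
    if isinstance(k, int) and (k < 1 or k > n):
        raise AnalysisError(f"k={k} invalid for {n} frames")

    link = linkage(data, method="ward")
    if k == "auto":
        k = _auto_k(data, link)
    agglo_labels = fcluster(link, t=k, criterion="maxclust") - 1
    init = np.array([data[agglo_labels == c].mean(axis=0) for c in range(k)])
    km = KMeans(n_clusters=k, init=init, n_init=1, tol=1e-6, max_iter=500,
                random_state=seed)
    labels = km.fit_predict(data)
    occupancy = np.bincount(labels, minlength=k) / n
    result = ClusterResult(labels=labels, occupancy=occupancy,
                           centroids=km.cluster_centers_,
                           representative_frame=np.zeros(k, dtype=int),
                           k=k, seed=seed)
    result.representative_frame = representative_configuration(poses, result)
    return result


def representative_configuration(poses: PoseMatrix,
                                 result: ClusterResult) -> np.ndarray:
    """Member frame closest to each K-means centroid (ties → lowest index)."""
    reps = np.zeros(result.k, dtype=int)
    for c in range(result.k):
        members = np.flatnonzero(result.labels == c)
        if members.size == 0:
            raise AnalysisError(f"cluster {c} is empty")
        dists = np.linalg.norm(
            poses.coordinates[members] - result.centroids[c], axis=1)
        # np.argmin returns the first minimum, i.e. the lowest frame index
        reps[c] = members[int(np.argmin(dists))]
    return reps
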