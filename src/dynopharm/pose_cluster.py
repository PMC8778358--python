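"""Consensus analysis of docking poses.

Poses produced by several search-algorithm/scoring-function combinations are
compared by in-place heavy-atom RMSD (no re-superposition: all poses live in
one receptor frame), clustered by complete-linkage hierarchical clustering cut
at a diameter threshold (default 2.0 Å, so every pair inside a subcluster is
mutually below the cutoff), and the most populated subcluster's medoid is
reported as the consensus binding mode. Scores follow the docking-energy
convention: lower is better.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_model import AtomRecord, ConformerRecord, read_sdf, write_sdf

__all__ = [
    "Pose",
    "PoseSet",
    "ClusterResult",
    "pose_rmsd",
    "rmsd_matrix",
    "hierarchical_cluster",
    "representative",
    "consensus_binding_mode",
    "ConsensusReport",
    "read_poses",
    "write_poses",
]


@dataclass
class Pose:
    """One docked ligand pose in the common receptor frame."""

    label: str
    atoms: list[AtomRecord]
    score: float | None = None

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for a in self.atoms if a.element != "H"]
        return np.array(pts, dtype=float)


@dataclass
class PoseSet:
    poses: list[Pose]

    def __post_init__(self) -> None:
        if self.poses:
            n0 = len(self.poses[0].atoms)
            names0 = [a.name for a in self.poses[0].atoms]
            for p in self.poses[1:]:
                if len(p.atoms) != n0 or [a.name for a in p.atoms] != names0:
                    raise ValueError(
                        f"pose {p.label!r} does not share atom count/order with "
                        f"{self.poses[0].label!r}")

    def __len__(self) -> int:
        return len(self.poses)

    def __getitem__(self, i: int) -> Pose:
        return self.poses[i]


def pose_rmsd(a: Pose, b: Pose) -> float:
    """Heavy-atom RMSD between two poses without re-superposition."""
    ca = a.heavy_coords()
    cb = b.heavy_coords()
    if ca.shape != cb.shape:
        raise ValueError(f"atom-count mismatch: {ca.shape[0]} vs {cb.shape[0]}")
    return float(np.sqrt(((ca - cb) ** 2).sum() / len(ca)))


def rmsd_matrix(poses: PoseSet) -> np.ndarray:
    """Symmetric zero-diagonal matrix of pairwise pose RMSDs."""
    if len(poses) < 2:
        raise ValueError("need at least 2 poses")
    coords = np.stack([p.heavy_coords() for p in poses.poses])  # (P, N, 3)
    diff = coords[:, None, :, :] - coords[None, :, :, :]
    mat = np.sqrt((diff ** 2).sum(axis=(2, 3)) / coords.shape[1])
    np.fill_diagonal(mat, 0.0)
    return mat


@dataclass
class ClusterResult:
    rmsd_matrix: np.ndarray
    cutoff: float
    clusters: list[list[int]]
    representatives: list[int] = field(default_factory=list)

    def largest(self) -> int:
        """Index into ``clusters`` of the largest cluster (ties -> first)."""
        sizes = [len(c) for c in self.clusters]
        return int(np.argmax(sizes))


def hierarchical_cluster(matrix: np.ndarray, cutoff: float = 2.0,
                         link: str = "complete") -> ClusterResult:
    """Complete-linkage clustering cut so every cluster diameter is < cutoff.

    Complete linkage is the only criterion for which "subcluster members are
    mutually within the cutoff" holds by construction; the tree is cut just
    below the cutoff so the bound is strict.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if link != "complete":
        raise ValueError("only complete linkage is supported")
    n = matrix.shape[0]
    condensed = squareform(matrix, checks=False)
    Z = linkage(condensed, method="complete")
    labels = fcluster(Z, t=np.nextafter(cutoff, 0.0), criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    # deterministic order: by min member index
    ordered = sorted(clusters.values(), key=lambda c: min(c))
    for c in ordered:
        sub = matrix[np.ix_(c, c)]
        if len(c) > 1 and sub.max() >= cutoff:
            raise AssertionError("cluster diameter exceeds cutoff")  # pragma: no cover
    result = ClusterResult(rmsd_matrix=matrix, cutoff=cutoff, clusters=ordered)
    result.representatives = [representative(c, matrix) for c in ordered]
    return result


def representative(cluster: list[int], matrix: np.ndarray,
                   scores: list[float | None] | None = None) -> int:
    """Medoid of a cluster: minimal mean RMSD to the other members.

    Ties break by best (lowest) score when scores are given, then lowest index.
    """
    if not cluster:
        raise ValueError("cluster is empty")
    if len(cluster) == 1:
        return cluster[0]
    matrix = np.asarray(matrix)
    sub = matrix[np.ix_(cluster, cluster)]
    means = sub.sum(axis=1) / (len(cluster) - 1)
    best = None
    for pos, idx in enumerate(cluster):
        score = scores[idx] if scores is not None and scores[idx] is not None else np.inf
        key = (round(float(means[pos]), 12), score, idx)
        if best is None or key < best[0]:
            best = (key, idx)
    return best[1]


@dataclass
class ConsensusReport:
    """Largest-subcluster summary: the consensus binding mode."""

    cluster_result: ClusterResult
    largest_cluster: list[int]
    representative_index: int
    representative_label: str
    reference_rmsd: float | None = None

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cluster_result.cutoff,
            "n_poses": int(self.cluster_result.rmsd_matrix.shape[0]),
            "n_clusters": len(self.cluster_result.clusters),
            "cluster_sizes": [len(c) for c in self.cluster_result.clusters],
            "largest_cluster": list(self.largest_cluster),
            "representative_index": self.representative_index,
            "representative_label": self.representative_label,
            "reference_rmsd": self.reference_rmsd,
        }


def consensus_binding_mode(poses: PoseSet, cutoff: float = 2.0,
                           reference: Pose | None = None) -> ConsensusReport:
    """Cluster the pose set and report the largest subcluster's medoid.

    Size ties between clusters break toward the better (lower) mean score;
    if a reference pose is given, its RMSD to the representative is reported.
    """
    matrix = rmsd_matrix(poses)
    result = hierarchical_cluster(matrix, cutoff=cutoff)
    scores = [p.score for p in poses.poses]
    sizes = [len(c) for c in result.clusters]
    max_size = max(sizes)
    candidates = [i for i, s in enumerate(sizes) if s == max_size]
    if len(candidates) > 1:
        def mean_score(ci: int) -> float:
            vals = [scores[i] for i in result.clusters[ci] if scores[i] is not None]
            return float(np.mean(vals)) if vals else np.inf
        candidates.sort(key=lambda ci: (mean_score(ci), ci))
    chosen = candidates[0]
    rep = representative(result.clusters[chosen], matrix, scores)
    result.representatives[chosen] = rep
    ref_rmsd = None
    if reference is not None:
        ref_rmsd = pose_rmsd(poses[rep], reference)
    return ConsensusReport(cluster_result=result,
                           largest_cluster=result.clusters[chosen],
                           representative_index=rep,
                           representative_label=poses[rep].label,
                           reference_rmsd=ref_rmsd)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_poses(path: str | Path) -> PoseSet:
    """Read poses from SDF (label = record title, score from a SCORE field)."""
    poses = []
    for conf, fields in read_sdf(path):
        score = float(fields["SCORE"]) if "SCORE" in fields else None
        poses.append(Pose(label=conf.name, atoms=conf.atoms, score=score))
    return PoseSet(poses)


def write_poses(path: str | Path, poses: PoseSet) -> None:
    confs = [ConformerRecord(name=p.label, atoms=p.atoms) for p in poses.poses]
    fields = [{"SCORE": f"{p.score:.4f}"} if p.score is not None else {}
              for p in poses.poses]
    write_sdf(path, confs, data_fields=fields)


def cluster_report_frames(report: ConsensusReport, labels: list[str]) -> pd.DataFrame:
    """Per-pose cluster assignment table for CSV export."""
    rows = []
    for ci, members in enumerate(report.cluster_result.clusters):
        for m in members:
            rows.append({"pose": labels[m], "cluster": ci,
                         "is_representative": m == report.cluster_result.representatives[ci],
                         "in_largest": m in report.largest_cluster})
    return pd.DataFrame(rows).sort_values("pose").reset_index(drop=True)


def save_cluster_report(report: ConsensusReport, labels: list[str], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "clusters.json").write_text(json.dumps(report.to_dict(), indent=2))
    cluster_report_frames(report, labels).to_csv(out / "clusters.csv", index=False)
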