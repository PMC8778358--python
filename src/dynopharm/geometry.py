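"""Rigid-body fitting and small vector-geometry helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch_fit", "apply_transform", "superposed_rmsd", "best_fit_plane"]


def kabsch_fit(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid fit of ``mobile`` onto ``target`` (SVD Kabsch).

    Returns (R, t) with R a proper rotation so that ``mobile @ R.T + t``
    minimizes the summed squared deviation from ``target``. Both inputs are
    (n, 3) with matched rows, n >= 1.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("kabsch_fit needs two matched (n, 3) arrays")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ np.asarray(R).T + np.asarray(t)


def superposed_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """RMSD after optimal rigid superposition."""
    R, t = kabsch_fit(mobile, target)
    diff = apply_transform(mobile, R, t) - target
    return float(np.sqrt((diff ** 2).sum() / len(target)))


def best_fit_plane(points: np.ndarray):
    """Least-squares plane through ``points``.

    Returns (centroid, unit normal, rms deviation of points from the plane).
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, s, Vt = np.linalg.svd(pts - centroid)
    normal = Vt[-1]
    rms = float(np.sqrt((s[-1] ** 2) / len(pts))) if len(pts) >= 3 else 0.0
    return centroid, normal / np.linalg.norm(normal), rms
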