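"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives its quantity from first principles (naive all-pairs
scans, greedy agglomeration, exhaustive assignment enumeration, quaternion
superposition) without sharing code paths with the library implementations
it checks.
"""

from itertools import combinations, permutations

import numpy as np
from scipy.spatial.transform import Rotation

from dynopharm.interactions import get_typing
from dynopharm.pharmacophore import annotate_conformer_features


def _norm(a):
    return float(np.linalg.norm(a))


def _hbond_angle_ok(frame, donor, hs, acceptor, min_angle):
    if not hs:
        return True
    angles = []
    for h in hs:
        v1 = frame[donor] - frame[h]
        v2 = frame[acceptor] - frame[h]
        c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angles.append(np.degrees(np.arccos(np.clip(c, -1, 1))))
    return max(angles) >= min_angle


def brute_hbond_pairs(frame, topo, crit):
    """{(ligand atom, protein atom, distance rounded)} by naive all-pairs scan."""
    t = get_typing(topo)
    lig_d = dict(t.ligand_donors)
    prot_d = dict(t.protein_donors)
    out = set()
    for li in sorted(set(lig_d) | set(t.ligand_acceptors)):
        for pi in sorted(set(prot_d) | set(t.protein_acceptors)):
            d = _norm(frame[li] - frame[pi])
            if d >= crit.hbond_max_da:
                continue
            ok = False
            if li in lig_d and pi in set(t.protein_acceptors):
                ok = ok or _hbond_angle_ok(frame, li, lig_d[li], pi,
                                           crit.hbond_min_donor_angle)
            if li in set(t.ligand_acceptors) and pi in prot_d:
                ok = ok or _hbond_angle_ok(frame, pi, prot_d[pi], li,
                                           crit.hbond_min_donor_angle)
            if ok:
                out.add((li, pi, round(d, 6)))
    return out


def brute_hydrophobic(frame, topo, crit):
    """{(residue_key, ligand atom, protein atom, distance)} closest per residue."""
    t = get_typing(topo)
    per_res = {}
    for li in t.ligand_apolar:
        for pi in t.protein_apolar:
            d = _norm(frame[li] - frame[pi])
            if d >= crit.hydrophobic_max:
                continue
            key = topo.atoms[pi].residue_key
            if key not in per_res or d < per_res[key][2]:
                per_res[key] = (li, pi, d)
    return {(k, li, pi, round(d, 6)) for k, (li, pi, d) in per_res.items()}


def _plane(points):
    c = points.mean(axis=0)
    _u, s, vt = np.linalg.svd(points - c)
    return c, vt[-1] / np.linalg.norm(vt[-1]), float(np.sqrt(s[-1] ** 2 / len(points)))


def brute_pistack(frame, topo, crit):
    """{(residue_key, ligand ring, distance)} by naive ring-pair scan."""
    t = get_typing(topo)
    out = set()
    for lring in t.ligand_rings:
        lc, ln, lrms = _plane(frame[list(lring)])
        if lrms > 0.3:
            continue
        for pring in t.protein_rings:
            pc, pn, prms = _plane(frame[list(pring)])
            if prms > 0.3:
                continue
            d = _norm(lc - pc)
            if d >= crit.pistack_max_centroid:
                continue
            ang = np.degrees(np.arccos(np.clip(abs(np.dot(ln, pn)), 0, 1)))
            if not (ang <= crit.pistack_max_angle_dev
                    or ang >= 90 - crit.pistack_max_angle_dev):
                continue
            v = pc - lc
            off1 = np.linalg.norm(v - np.dot(v, ln) * ln)
            off2 = np.linalg.norm(v - np.dot(v, pn) * pn)
            if min(off1, off2) > crit.pistack_max_offset:
                continue
            out.add((topo.atoms[pring[0]].residue_key, lring, round(d, 6)))
    return out


def brute_saltbridge(frame, topo, crit):
    """{(residue_key, ligand group, distance)} by naive charged-group scan."""
    t = get_typing(topo)
    out = set()
    for lg, ls in t.ligand_charged:
        lc = frame[list(lg)].mean(axis=0)
        for pg, ps in t.protein_charged:
            if ls * ps >= 0:
                continue
            d = _norm(lc - frame[list(pg)].mean(axis=0))
            if d < crit.saltbridge_max:
                out.add((topo.atoms[pg[0]].residue_key, lg, round(d, 6)))
    return out


def brute_complete_linkage(matrix, cutoff):
    """Greedy agglomerative complete linkage; returns a set of frozensets."""
    matrix = np.asarray(matrix)
    clusters = [{i} for i in range(matrix.shape[0])]
    while True:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            d = max(matrix[i][j] for i in clusters[a] for j in clusters[b])
            if d < cutoff and (best is None or d < best[0]):
                best = (d, a, b)
        if best is None:
            break
        _d, a, b = best
        clusters[a] |= clusters[b]
        del clusters[b]
    return {frozenset(c) for c in clusters}


def brute_medoid(cluster, matrix):
    """Exhaustive mean-RMSD scan; returns the set of tied medoid indices."""
    matrix = np.asarray(matrix)
    means = {i: np.mean([matrix[i][j] for j in cluster if j != i]) if len(cluster) > 1
             else 0.0 for i in cluster}
    lo = min(means.values())
    return {i for i, m in means.items() if abs(m - lo) < 1e-12}


def _fit_rssd(model_pts, conf_pts):
    """Deviations after optimal rigid fit, via scipy's align_vectors."""
    mc = model_pts.mean(axis=0)
    cc = conf_pts.mean(axis=0)
    if len(model_pts) == 1:
        return np.zeros(1)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # collinear 2-point fits
        rot, _ = Rotation.align_vectors(model_pts - mc, conf_pts - cc)
    moved = rot.apply(conf_pts - cc) + mc
    return np.linalg.norm(moved - model_pts, axis=1)


def brute_match(model, conformer, min_match):
    """Exhaustive assignment search; returns (accepted, best matched_count)."""
    positions = model.positions()
    pts = annotate_conformer_features(conformer)
    pt_kinds = [k for k, _ in pts]
    pt_xyz = np.array([p for _, p in pts]) if pts else np.zeros((0, 3))
    compat = [[j for j, k in enumerate(pt_kinds) if k in pos.kinds]
              for pos in positions]
    best = 0
    for size in range(len(positions), max(min_match, 1) - 1, -1):
        for subset in combinations(range(len(positions)), size):
            pools = [compat[i] for i in subset]
            for choice in permutations(range(len(pt_kinds)), size):
                if any(choice[k] not in pools[k] for k in range(size)):
                    continue
                centers = np.array([positions[i].center for i in subset])
                radii = np.array([positions[i].radius for i in subset])
                dev = _fit_rssd(centers, pt_xyz[list(choice)])
                if np.all(dev <= radii + 1e-9):
                    best = max(best, size)
                    break
            if best >= size:
                break
        if best:
            break
    return best >= max(min_match, 1), best


def quaternion_superposed_rmsd(mobile, target):
    """Optimal-superposition RMSD via the Horn quaternion eigenvalue method."""
    P = np.asarray(mobile, float) - np.mean(mobile, axis=0)
    Q = np.asarray(target, float) - np.mean(target, axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K).max()
    msd = ((P ** 2).sum() + (Q ** 2).sum() - 2 * lam) / len(P)
    return float(np.sqrt(max(msd, 0.0)))
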