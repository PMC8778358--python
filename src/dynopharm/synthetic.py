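"""Deterministic, seeded generators for toy pockets, trajectories, pose sets
and conformer libraries.

Everything here is geometric scaffolding, not physics: the pocket is a
minimal arrangement of standard-residue fragments (hydrogen-bond partners, an
aromatic ring, apolar carbons, a Lys/Glu charge pair) around a small ligand
whose fragments can be toggled in or out of detection range frame by frame
with planted per-frame probabilities. "Off" places the partner at the
relevant cutoff + 2 Å so thermal jitter cannot flip an interaction across the
boundary, keeping planted probabilities exact. All randomness flows from a
single ``numpy.random.default_rng(seed)`` so fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_model import AtomRecord, ConformerRecord, Topology, Trajectory
from .pose_cluster import Pose, PoseSet
from .pharmacophore import PharmacophoreModel

__all__ = [
    "PlantSpec",
    "PoseSetSpec",
    "make_pocket",
    "plantable_interactions",
    "make_trajectory",
    "make_pose_set",
    "default_pose_spec",
    "make_conformer_library",
    "default_plant_spec",
]

ResidueKey = tuple[str, int, str]


@dataclass
class PlantSpec:
    """Which interactions to plant, at what per-frame probability.

    ``interactions`` entries are (residue_key, itype, p) where p is either a
    per-frame Bernoulli probability in [0, 1] or an explicit collection of
    frame indices in which the interaction is present. Handles not listed
    stay in their base ("on") geometry. ``bridge_probability`` optionally
    toggles the Lys38-Glu52 protein-protein salt bridge.
    """

    interactions: list[tuple[ResidueKey, str, object]]
    n_frames: int
    jitter_sigma: float = 0.03
    seed: int = 0
    bridge_probability: object | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for rkey, itype, p in self.interactions:
            if isinstance(p, (int, float)) and not (0.0 <= float(p) <= 1.0):
                raise ValueError(f"probability {p} for {rkey}/{itype} outside [0,1]")


@dataclass
class PoseSetSpec:
    """Planted pose modes: list of (mode offset 3-vector, count, jitter Å)."""

    modes: list[tuple[Sequence[float], int, float]]
    seed: int = 0

    def __post_init__(self) -> None:
        for _off, count, _j in self.modes:
            if count < 1:
                raise ValueError("mode counts must be >= 1")


# ---------------------------------------------------------------------------
# Pocket construction
# ---------------------------------------------------------------------------

def _hexagon(center, radius=1.39, z=0.0):
    pts = []
    for k in range(6):
        ang = np.radians(60 * k)
        pts.append([center[0] + radius * np.cos(ang),
                    center[1] + radius * np.sin(ang), z])
    return np.array(pts)


def _build_pocket():
    """Atoms, bonds, charges and plant handles of the toy pocket."""
    atoms_spec = []  # (name, element, resname, resnum, chain, xyz)

    def res(resname, resnum, entries):
        for name, element, xyz in entries:
            atoms_spec.append((name, element, resname, resnum, "A", np.array(xyz, float)))

    # PHE 20: aromatic ring stacked over the ligand ring (+z)
    ring20 = _hexagon((0.0, 0.0), z=3.8)
    phe_names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    phe_ring_order = [ring20[0], ring20[1], ring20[5], ring20[2], ring20[4], ring20[3]]
    res("PHE", 20, [(n, "C", p) for n, p in zip(phe_names, phe_ring_order)]
        + [("CB", "C", [2.6, 0.0, 4.6]), ("CA", "C", [3.6, 0.8, 5.4]),
           ("N", "N", [3.4, 2.0, 6.1]), ("C", "C", [5.0, 0.5, 5.6]),
           ("O", "O", [5.9, 1.3, 5.9])])
    # LYS 38: charged NZ near the GLU 52 carboxylate (-y)
    res("LYS", 38, [("NZ", "N", [0.0, -13.0, -2.0]),
                    ("CA", "C", [0.0, -16.0, -2.5]), ("N", "N", [0.0, -16.8, -1.4]),
                    ("C", "C", [1.2, -16.4, -3.3]), ("O", "O", [1.4, -17.6, -3.5])])
    # GLU 52: carboxylate facing the ligand ammonium (-y)
    res("GLU", 52, [("CD", "C", [0.8, -10.5, 0.0]),
                    ("OE1", "O", [0.0, -10.5, 1.1]), ("OE2", "O", [0.0, -10.5, -1.1]),
                    ("CA", "C", [1.5, -13.2, 0.5]), ("N", "N", [1.3, -14.2, 1.4]),
                    ("C", "C", [2.9, -13.4, -0.1]), ("O", "O", [3.9, -13.9, 0.5])])
    # GLU 83: backbone carbonyl accepting from the ligand amine (+x)
    res("GLU", 83, [("O", "O", [8.9, 0.0, 0.0]), ("C", "C", [9.8, 0.8, 0.3]),
                    ("CA", "C", [11.2, 0.5, 0.1]), ("N", "N", [11.9, 1.6, 0.5])])
    # LEU 85: backbone amide donating to the ligand carbonyl (-x)
    res("LEU", 85, [("N", "N", [-8.9, 0.0, 0.0]), ("CA", "C", [-9.7, -1.1, 0.2]),
                    ("C", "C", [-11.1, -0.8, 0.1]), ("O", "O", [-11.9, -1.7, 0.3])])
    # LEU 135: apolar side chain near the ligand methyl (+y)
    res("LEU", 135, [("CD1", "C", [0.0, 9.6, 0.0]), ("CG", "C", [0.0, 10.9, 0.8]),
                     ("CD2", "C", [1.1, 11.0, -0.6]), ("CB", "C", [-0.5, 11.9, 1.5]),
                     ("CA", "C", [-0.3, 13.0, 1.0]), ("N", "N", [-0.5, 13.8, 2.1]),
                     ("C", "C", [0.5, 13.9, 0.0]), ("O", "O", [0.6, 15.1, 0.2])])

    n_protein = len(atoms_spec)

    # Ligand: aromatic ring at the origin, a methyl, an amine N, a carbonyl O
    # and an ammonium N+, each facing its planted partner residue.
    ringL = _hexagon((0.0, 0.0), z=0.0)
    lig_entries = [(f"C{i + 1}", "C", ringL[i]) for i in range(6)]
    lig_entries += [("C7", "C", [0.0, 6.0, 0.0]),
                    ("N1", "N", [6.0, 0.0, 0.0]),
                    ("O1", "O", [-6.0, 0.0, 0.0]),
                    ("N2", "N", [0.0, -7.0, 0.0])]
    for name, element, xyz in lig_entries:
        atoms_spec.append((name, element, "LIG", 1, "L", np.array(xyz, float)))

    atoms = [AtomRecord(index=i, element=e, name=n, residue_name=rn,
                        residue_number=rs, chain=ch, coords=xyz)
             for i, (n, e, rn, rs, ch, xyz) in enumerate(atoms_spec)]
    ring_idx = list(range(n_protein, n_protein + 6))
    bonds = {(ring_idx[k], ring_idx[(k + 1) % 6]) for k in range(6)}
    ligand = set(range(n_protein, len(atoms)))
    n2_idx = n_protein + 9
    charges = {n2_idx: +1}
    topo = Topology(atoms=atoms, bonds={(min(i, j), max(i, j)) for i, j in bonds},
                    ligand_selection=ligand, formal_charges=charges)

    idx = {(a.chain, a.residue_number, a.name): a.index for a in atoms}
    # handle: (residue_key, itype) -> (fragment indices, partner point, on distance, off distance)
    handles = {
        (("A", 83, "GLU"), "hbond"): ([idx[("L", 1, "N1")]], np.array([8.9, 0.0, 0.0]), 2.9, 6.1),
        (("A", 85, "LEU"), "hbond"): ([idx[("L", 1, "O1")]], np.array([-8.9, 0.0, 0.0]), 2.9, 6.1),
        (("A", 20, "PHE"), "pi_stack"): (ring_idx, np.array([0.0, 0.0, 3.8]), 3.8, 7.5),
        (("A", 135, "LEU"), "hydrophobic"): ([idx[("L", 1, "C7")]], np.array([0.0, 9.6, 0.0]), 3.6, 6.0),
        (("A", 52, "GLU"), "salt_bridge"): ([idx[("L", 1, "N2")]], np.array([0.0, -10.5, 0.0]), 3.5, 7.5),
    }
    bridge_handle = ([idx[("A", 38, "NZ")]], np.array([0.0, -10.5, 0.0]), 3.2, 7.5)
    return topo, handles, bridge_handle


def make_pocket() -> tuple[Topology, np.ndarray]:
    """Toy binding pocket with all planted interactions in the "on" state."""
    topo, _handles, _bridge = _build_pocket()
    return topo, topo.coords_array()


def plantable_interactions() -> list[tuple[ResidueKey, str]]:
    """The (residue_key, itype) handles :func:`make_trajectory` can toggle."""
    _topo, handles, _bridge = _build_pocket()
    return sorted(handles)


def _off_displacement(frame, fragment, partner, off_distance):
    anchor = frame[fragment].mean(axis=0)
    direction = anchor - partner
    norm = np.linalg.norm(direction)
    current = norm
    return direction / norm * (off_distance - current)


def _present(p, frame_index: int, rng) -> bool:
    if isinstance(p, (int, float, np.floating)):
        return bool(rng.random() < float(p))
    return frame_index in p


def make_trajectory(spec: PlantSpec) -> Trajectory:
    """Synthesize a trajectory with planted per-frame interaction presence.

    Listed handles are toggled each frame; when "off" their ligand fragment
    is displaced along the partner axis so the pair distance equals the
    detector cutoff + 2 Å. Gaussian thermal jitter (``jitter_sigma`` per
    axis) is then added to every atom. Handles not listed stay on.
    """
    topo, handles, bridge_handle = _build_pocket()
    base = topo.coords_array()
    for rkey, itype, _p in spec.interactions:
        if (rkey, itype) not in handles:
            raise ValueError(
                f"no plantable handle for {rkey}/{itype}; available: "
                f"{sorted(handles)}")
    rng = np.random.default_rng(spec.seed)
    frames = np.empty((spec.n_frames, topo.n_atoms, 3))
    for f in range(spec.n_frames):
        coords = base.copy()
        for rkey, itype, p in spec.interactions:
            fragment, partner, _on, off = handles[(rkey, itype)]
            if not _present(p, f, rng):
                coords[fragment] += _off_displacement(base, fragment, partner, off)
        if spec.bridge_probability is not None:
            fragment, partner, _on, off = bridge_handle
            if not _present(spec.bridge_probability, f, rng):
                coords[fragment] += _off_displacement(base, fragment, partner, off)
        if spec.jitter_sigma > 0:
            coords += rng.normal(0.0, spec.jitter_sigma, coords.shape)
        frames[f] = coords
    return Trajectory(topology=topo, frames=frames, frame_spacing=10.0)


def default_plant_spec(n_frames: int = 2000, seed: int = 0) -> PlantSpec:
    """Planted occurrence probabilities emulating a stable inhibitor complex.

    The hinge hydrogen bonds are nearly constitutive (0.99 and 0.97), ring
    stacking intermittent (0.38), the apolar contact frequent (0.63) and the
    charge pair occasional (0.21) — the occupancy regime reported for
    kinase-inhibitor trajectories of this kind.
    """
    return PlantSpec(
        interactions=[
            (("A", 85, "LEU"), "hbond", 0.99),
            (("A", 83, "GLU"), "hbond", 0.97),
            (("A", 20, "PHE"), "pi_stack", 0.38),
            (("A", 135, "LEU"), "hydrophobic", 0.63),
            (("A", 52, "GLU"), "salt_bridge", 0.21),
        ],
        n_frames=n_frames, seed=seed, bridge_probability=0.5)


# ---------------------------------------------------------------------------
# Pose sets
# ---------------------------------------------------------------------------

_ALGORITHMS = "XSO"        # search algorithms
_SCORING = "mMpP"          # scoring functions


def _labels(n: int) -> list[str]:
    if n == 96:
        return [f"{sc}{alg}-{run}" for alg in _ALGORITHMS for sc in _SCORING
                for run in range(1, 9)]
    return [f"pose-{i + 1}" for i in range(n)]


def make_pose_set(spec: PoseSetSpec) -> PoseSet:
    """Poses jittered around planted modes, labelled combo/rank style.

    Each pose is the pocket ligand rigidly translated to its mode offset plus
    a Gaussian displacement whose RMS magnitude is the mode's jitter (so a
    pair of same-mode poses has RMSD ~ jitter * sqrt(2), well inside a 2 Å
    clustering cutoff at the default 0.3 Å). Scores (lower =
    better) favor mode 0, so the dominant planted mode also carries the best
    scores. 96 poses get the 12-combination x 8-run label scheme.
    """
    topo, _h, _b = _build_pocket()
    lig_idx = sorted(topo.ligand_selection)
    base_atoms = [topo.atoms[i] for i in lig_idx]
    rng = np.random.default_rng(spec.seed)
    mode_of = []
    for mi, (_off, count, _j) in enumerate(spec.modes):
        mode_of += [mi] * count
    mode_of = np.array(mode_of)
    rng.shuffle(mode_of)
    labels = _labels(len(mode_of))
    poses = []
    for pi, mi in enumerate(mode_of):
        off, _count, jitter = spec.modes[mi]
        shift = np.asarray(off, float) + rng.normal(0.0, jitter / np.sqrt(3), 3)
        atoms = []
        for k, a in enumerate(base_atoms):
            atoms.append(AtomRecord(index=k, element=a.element, name=a.name,
                                    residue_name=a.residue_name,
                                    residue_number=a.residue_number, chain=a.chain,
                                    coords=a.coords + shift))
        score = -150.0 + 12.0 * mi + float(rng.normal(0.0, 1.0))
        poses.append(Pose(label=labels[pi], atoms=atoms, score=score))
    return PoseSet(poses)


def default_pose_spec(seed: int = 0) -> PoseSetSpec:
    """96 poses (12 combos x 8 runs): 60 around the dominant mode, 36 around
    an alternative mode 10 Å away, 0.3 Å jitter."""
    return PoseSetSpec(modes=[((0.0, 0.0, 0.0), 60, 0.3),
                              ((10.0, 0.0, 0.0), 36, 0.3)], seed=seed)


# ---------------------------------------------------------------------------
# Conformer libraries
# ---------------------------------------------------------------------------

def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _uniform_ball(rng, radius: float) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return v * radius * rng.random() ** (1 / 3)


def make_conformer_library(n: int, model: PharmacophoreModel,
                           hit_fraction: float, seed: int = 0
                           ) -> list[ConformerRecord]:
    """Library with planted hits and guaranteed decoys.

    Hits carry one feature point per model position (within 0.4 x radius of
    the center, kind drawn from the position's allowed kinds) and are then
    rigidly scrambled — matching is invariant to that. Decoys carry only
    min_match - 1 feature points at random locations, so they can never reach
    the match minimum regardless of geometry. Names record ground truth
    (HIT*/DEC* prefixes); one dummy carbon atom sits at every feature point
    so volumes and RMSDs are computable.
    """
    if not (0.0 <= hit_fraction <= 1.0):
        raise ValueError("hit_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_hits = int(round(n * hit_fraction))
    positions = model.positions()
    library: list[ConformerRecord] = []
    for i in range(n):
        is_hit = i < n_hits
        if is_hit:
            pts = []
            for pos in positions:
                kind = sorted(pos.kinds)[rng.integers(len(pos.kinds))]
                pts.append((kind, pos.center + _uniform_ball(rng, 0.4 * pos.radius)))
        else:
            k = max(1, model.min_match - 1)
            kinds_pool = sorted({f.kind for f in model.features}) or ["Hyd"]
            pts = [(kinds_pool[rng.integers(len(kinds_pool))],
                    rng.uniform(-4.0, 4.0, 3)) for _ in range(k)]
        R = _random_rotation(rng)
        t = rng.uniform(-5.0, 5.0, 3)
        pts = [(kind, R @ p + t) for kind, p in pts]
        atoms = [AtomRecord(index=j, element="C", name=f"C{j + 1}",
                            residue_name="LIG", residue_number=1, chain="L",
                            coords=p.copy())
                 for j, (_k, p) in enumerate(pts)]
        tag = "HIT" if is_hit else "DEC"
        name = f"{tag}{i:03d}_c1"
        library.append(ConformerRecord(name=name, atoms=atoms, bonds=set(),
                                       feature_points=pts,
                                       compound=f"{tag}{i:03d}"))
    return library
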