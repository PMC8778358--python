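"""Geometric detection of noncovalent protein-ligand interactions in a frame.

Four detectors (hydrogen bond, hydrophobic, pi-stacking, salt bridge) plus an
aggregator. The numeric defaults follow the published defaults of the PLIP
profiler, the standard tool for this kind of contact analysis: detectors fire
on strict "<" distance cutoffs and ">=" angle minima, so tightening a cutoff
can only remove events.

Donor/acceptor/apolar/aromatic/charged typing comes from residue template
tables for the twenty standard amino acids and from connectivity rules for
ligand atoms. Structures without explicit hydrogens are supported: hydrogen
bonds then fall back to the heavy-atom donor-acceptor distance criterion with
no angle test, and a ligand N/O whose role cannot be resolved is recorded
with ``ligand_role="either"``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core_model import Topology
from .geometry import best_fit_plane

__all__ = [
    "GeometricCriteria",
    "InteractionEvent",
    "InteractionTyping",
    "get_typing",
    "detect_hbonds",
    "detect_hydrophobic",
    "detect_pistack",
    "detect_saltbridge",
    "detect_frame",
    "saltbridge_between",
    "events_to_dataframe",
]

ITYPES = ("hbond", "hydrophobic", "pi_stack", "salt_bridge", "pi_cation")


@dataclass
class GeometricCriteria:
    """Distance/angle cutoffs (Å, degrees) for the detectors."""

    hbond_max_da: float = 4.1
    hbond_min_donor_angle: float = 100.0
    hydrophobic_max: float = 4.0
    pistack_max_centroid: float = 5.5
    pistack_max_angle_dev: float = 30.0
    pistack_max_offset: float = 2.0
    saltbridge_max: float = 5.5
    pication_max: float = 6.0

    def __post_init__(self) -> None:
        for key, val in asdict(self).items():
            if val <= 0:
                raise ValueError(f"{key} must be positive, got {val}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeometricCriteria":
        return cls(**d)


@dataclass
class InteractionEvent:
    """One detected contact in one frame.

    ``residue_key`` identifies the protein residue; ``anchor`` is the
    ligand-side geometric anchor (atom position, ring centroid, or charged
    group centroid) used downstream for pharmacophore placement.
    """

    frame_index: int
    itype: str
    residue_key: tuple[str, int, str]
    ligand_atoms: frozenset[int]
    protein_atoms: frozenset[int]
    distance: float
    angle: float | None = None
    ligand_role: str | None = None  # hbond only: donor | acceptor | either
    anchor: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.itype not in ITYPES:
            raise ValueError(f"unknown interaction type {self.itype!r}")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


# ---------------------------------------------------------------------------
# Residue templates (standard amino acids)
# ---------------------------------------------------------------------------

_BACKBONE_DONOR = "N"      # except proline
_BACKBONE_ACCEPTORS = ("O", "OXT")

_SC_DONORS = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "ASN": ["ND2"],
    "GLN": ["NE2"], "HIS": ["ND1", "NE2"], "LYS": ["NZ"],
    "ARG": ["NE", "NH1", "NH2"], "TRP": ["NE1"],
}
_SC_ACCEPTORS = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "ASN": ["OD1"],
    "GLN": ["OE1"], "HIS": ["ND1", "NE2"], "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
}
# Side-chain carbons with no heteroatom neighbor (hydrophobic-capable).
_SC_APOLAR = {
    "ALA": ["CB"], "VAL": ["CB", "CG1", "CG2"],
    "LEU": ["CB", "CG", "CD1", "CD2"], "ILE": ["CB", "CG1", "CG2", "CD1"],
    "MET": ["CB"], "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2"],
    "TRP": ["CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"],
    "PRO": ["CB", "CG"], "LYS": ["CB", "CG", "CD"], "ARG": ["CB", "CG"],
    "GLU": ["CB", "CG"], "GLN": ["CB", "CG"], "ASP": ["CB"], "ASN": ["CB"],
    "THR": ["CG2"], "HIS": ["CB"],
}
_SC_RINGS = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]],
}
_SC_CHARGED = {
    "LYS": (["NZ"], +1),
    "ARG": (["CZ", "NH1", "NH2"], +1),
    "ASP": (["OD1", "OD2"], -1),
    "GLU": (["OE1", "OE2"], -1),
}


# ---------------------------------------------------------------------------
# Typing
# ---------------------------------------------------------------------------

@dataclass
class InteractionTyping:
    """Frame-independent atom typing derived once per topology."""

    # (heavy index, tuple of explicit-H indices, may_lack_role_info)
    protein_donors: list[tuple[int, tuple[int, ...]]] = field(default_factory=list)
    protein_acceptors: list[int] = field(default_factory=list)
    ligand_donors: list[tuple[int, tuple[int, ...]]] = field(default_factory=list)
    ligand_acceptors: list[int] = field(default_factory=list)
    protein_apolar: list[int] = field(default_factory=list)
    ligand_apolar: list[int] = field(default_factory=list)
    protein_rings: list[tuple[int, ...]] = field(default_factory=list)
    ligand_rings: list[tuple[int, ...]] = field(default_factory=list)
    # (atom index tuple, sign)
    protein_charged: list[tuple[tuple[int, ...], int]] = field(default_factory=list)
    ligand_charged: list[tuple[tuple[int, ...], int]] = field(default_factory=list)
    ligand_has_h: bool = False


def _bonded_h(topology: Topology, idx: int) -> tuple[int, ...]:
    return tuple(j for j in topology.neighbors(idx)
                 if topology.atoms[j].element == "H")


def _ligand_ring_candidates(topology: Topology, lig: Sequence[int]) -> list[tuple[int, ...]]:
    g = nx.Graph()
    g.add_nodes_from(lig)
    ligset = set(lig)
    g.add_edges_from((i, j) for i, j in topology.bonds if i in ligset and j in ligset)
    rings = []
    for cyc in nx.cycle_basis(g):
        if 5 <= len(cyc) <= 7 and all(topology.atoms[i].element in ("C", "N", "O", "S")
                                      for i in cyc):
            rings.append(tuple(sorted(cyc)))
    return rings


def get_typing(topology: Topology) -> InteractionTyping:
    """Derive donor/acceptor/apolar/ring/charged typing for a topology."""
    t = InteractionTyping()
    lig = sorted(topology.ligand_selection)
    ligset = set(lig)
    atoms = topology.atoms
    t.ligand_has_h = any(atoms[i].element == "H" for i in lig)

    by_residue = topology.residues()
    for rkey, indices in by_residue.items():
        if all(i in ligset for i in indices):
            continue
        resname = rkey[2]
        names = {atoms[i].name: i for i in indices}
        # donors: backbone N plus side-chain templates
        donor_names = [] if resname == "PRO" else [_BACKBONE_DONOR]
        donor_names += _SC_DONORS.get(resname, [])
        for nm in donor_names:
            if nm in names:
                i = names[nm]
                t.protein_donors.append((i, _bonded_h(topology, i)))
        acceptor_names = list(_BACKBONE_ACCEPTORS) + _SC_ACCEPTORS.get(resname, [])
        for nm in acceptor_names:
            if nm in names:
                t.protein_acceptors.append(names[nm])
        for nm in _SC_APOLAR.get(resname, []):
            if nm in names:
                t.protein_apolar.append(names[nm])
        for ring in _SC_RINGS.get(resname, []):
            if all(nm in names for nm in ring):
                t.protein_rings.append(tuple(names[nm] for nm in ring))
        if resname in _SC_CHARGED:
            group_names, sign = _SC_CHARGED[resname]
            present = tuple(names[nm] for nm in group_names if nm in names)
            if present:
                t.protein_charged.append((present, sign))

    # --- ligand side: connectivity rules ---
    for i in lig:
        a = atoms[i]
        nbrs = topology.neighbors(i)
        nbr_elems = [atoms[j].element for j in nbrs]
        charge = topology.formal_charge(i)
        if a.element in ("N", "O"):
            hs = _bonded_h(topology, i)
            heavy_deg = sum(1 for e in nbr_elems if e != "H")
            if t.ligand_has_h:
                if hs:
                    t.ligand_donors.append((i, hs))
            else:
                # heavy-atom fallback: any N/O may donate
                t.ligand_donors.append((i, ()))
            quaternary_n = a.element == "N" and (heavy_deg + len(hs)) >= 4
            positive_n = a.element == "N" and charge > 0
            if not (quaternary_n or positive_n):
                t.ligand_acceptors.append(i)
        elif a.element == "C":
            if all(e in ("C", "H") for e in nbr_elems):
                t.ligand_apolar.append(i)
        if charge != 0:
            t.ligand_charged.append(((i,), 1 if charge > 0 else -1))

    t.ligand_rings = _ligand_ring_candidates(topology, lig)
    return t


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _donor_angle_ok(frame: np.ndarray, donor: int, hs: tuple[int, ...],
                    acceptor: int, min_angle: float) -> tuple[bool, float | None]:
    """Angle test at the donor hydrogen (D-H...A >= min_angle), if H exists."""
    if not hs:
        return True, None
    best = max(_angle_deg(frame[donor], frame[h], frame[acceptor]) for h in hs)
    return best >= min_angle, best


def detect_hbonds(frame: np.ndarray, topology: Topology,
                  criteria: GeometricCriteria | None = None, *,
                  typing: InteractionTyping | None = None,
                  frame_index: int = 0) -> list[InteractionEvent]:
    """Hydrogen bonds between ligand and protein N/O atoms.

    Fires when the donor-acceptor heavy-atom distance is below the cutoff
    and, where the donor carries explicit hydrogens, the D-H...A angle at the
    hydrogen meets the minimum. One event per heavy-atom pair; the ligand
    role is resolved from whichever side can donate/accept.
    """
    criteria = criteria or GeometricCriteria()
    typing = typing or get_typing(topology)
    atoms = topology.atoms
    events: list[InteractionEvent] = []

    lig_donor_h = {i: hs for i, hs in typing.ligand_donors}
    prot_donor_h = {i: hs for i, hs in typing.protein_donors}
    lig_polar = sorted(set(lig_donor_h) | set(typing.ligand_acceptors))
    prot_polar = sorted(set(prot_donor_h) | set(typing.protein_acceptors))
    prot_acc = set(typing.protein_acceptors)
    lig_acc = set(typing.ligand_acceptors)

    for li in lig_polar:
        for pi in prot_polar:
            d = float(np.linalg.norm(frame[li] - frame[pi]))
            if not d < criteria.hbond_max_da:
                continue
            roles = []
            angle: float | None = None
            if li in lig_donor_h and pi in prot_acc:
                ok, ang = _donor_angle_ok(frame, li, lig_donor_h[li], pi,
                                          criteria.hbond_min_donor_angle)
                if ok:
                    roles.append("donor")
                    angle = ang if ang is not None else angle
            if li in lig_acc and pi in prot_donor_h:
                ok, ang = _donor_angle_ok(frame, pi, prot_donor_h[pi], li,
                                          criteria.hbond_min_donor_angle)
                if ok:
                    roles.append("acceptor")
                    angle = ang if ang is not None else angle
            if not roles:
                continue
            role = roles[0] if len(roles) == 1 else "either"
            events.append(InteractionEvent(
                frame_index=frame_index, itype="hbond",
                residue_key=atoms[pi].residue_key,
                ligand_atoms=frozenset({li}), protein_atoms=frozenset({pi}),
                distance=d, angle=angle, ligand_role=role,
                anchor=frame[li].copy()))
    return events


def detect_hydrophobic(frame: np.ndarray, topology: Topology,
                       criteria: GeometricCriteria | None = None, *,
                       typing: InteractionTyping | None = None,
                       frame_index: int = 0) -> list[InteractionEvent]:
    """Apolar-carbon contacts, collapsed to one event (closest pair) per residue."""
    criteria = criteria or GeometricCriteria()
    typing = typing or get_typing(topology)
    atoms = topology.atoms
    best: dict[tuple, tuple[float, int, int]] = {}
    if typing.ligand_apolar and typing.protein_apolar:
        lc = frame[typing.ligand_apolar]
        pc = frame[typing.protein_apolar]
        dmat = np.linalg.norm(lc[:, None, :] - pc[None, :, :], axis=2)
        for a, b in zip(*np.nonzero(dmat < criteria.hydrophobic_max)):
            li = typing.ligand_apolar[a]
            pi = typing.protein_apolar[b]
            key = atoms[pi].residue_key
            d = float(dmat[a, b])
            if key not in best or d < best[key][0]:
                best[key] = (d, li, pi)
    return [InteractionEvent(frame_index=frame_index, itype="hydrophobic",
                             residue_key=key,
                             ligand_atoms=frozenset({li}),
                             protein_atoms=frozenset({pi}),
                             distance=d, anchor=frame[li].copy())
            for key, (d, li, pi) in sorted(best.items())]


def _ring_geometry(frame: np.ndarray, ring: tuple[int, ...], planarity_rms: float = 0.3):
    """Centroid and normal of a ring, or None if not planar enough."""
    pts = frame[list(ring)]
    centroid, normal, rms = best_fit_plane(pts)
    if rms > planarity_rms:
        return None
    return centroid, normal


def detect_pistack(frame: np.ndarray, topology: Topology,
                   criteria: GeometricCriteria | None = None, *,
                   typing: InteractionTyping | None = None,
                   frame_index: int = 0) -> list[InteractionEvent]:
    """Parallel or T-shaped ring stacking between ligand and protein rings.

    Requires centroid distance below the cutoff, interplanar angle within the
    allowed deviation of 0 (parallel) or 90 degrees (T-shaped), and an
    in-plane centroid offset at or below the offset cutoff (minimum of the
    two ring-plane projections). Ligand rings must be planar (<= 0.3 Å RMS
    from the best-fit plane) to count as aromatic.
    """
    criteria = criteria or GeometricCriteria()
    typing = typing or get_typing(topology)
    atoms = topology.atoms
    events: list[InteractionEvent] = []
    for lring in typing.ligand_rings:
        lg = _ring_geometry(frame, lring)
        if lg is None:
            continue
        lc, ln = lg
        for pring in typing.protein_rings:
            pg = _ring_geometry(frame, pring)
            if pg is None:
                continue
            pc, pn = pg
            d = float(np.linalg.norm(lc - pc))
            if not d < criteria.pistack_max_centroid:
                continue
            cosang = abs(float(np.dot(ln, pn)))
            angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
            parallel = angle <= criteria.pistack_max_angle_dev
            tshape = angle >= 90.0 - criteria.pistack_max_angle_dev
            if not (parallel or tshape):
                continue
            v = pc - lc
            off_l = float(np.linalg.norm(v - np.dot(v, ln) * ln))
            off_p = float(np.linalg.norm(-v - np.dot(-v, pn) * pn))
            if min(off_l, off_p) > criteria.pistack_max_offset:
                continue
            events.append(InteractionEvent(
                frame_index=frame_index, itype="pi_stack",
                residue_key=atoms[pring[0]].residue_key,
                ligand_atoms=frozenset(lring), protein_atoms=frozenset(pring),
                distance=d, angle=angle, anchor=lc.copy()))
    return events


def _group_centroid(frame: np.ndarray, indices: tuple[int, ...]) -> np.ndarray:
    return frame[list(indices)].mean(axis=0)


def detect_saltbridge(frame: np.ndarray, topology: Topology,
                      criteria: GeometricCriteria | None = None, *,
                      typing: InteractionTyping | None = None,
                      frame_index: int = 0) -> list[InteractionEvent]:
    """Opposite-sign charged-group centroids within the cutoff (ligand-protein)."""
    criteria = criteria or GeometricCriteria()
    typing = typing or get_typing(topology)
    atoms = topology.atoms
    events: list[InteractionEvent] = []
    for lgroup, lsign in typing.ligand_charged:
        lc = _group_centroid(frame, lgroup)
        for pgroup, psign in typing.protein_charged:
            if lsign * psign >= 0:
                continue
            pc = _group_centroid(frame, pgroup)
            d = float(np.linalg.norm(lc - pc))
            if d < criteria.saltbridge_max:
                events.append(InteractionEvent(
                    frame_index=frame_index, itype="salt_bridge",
                    residue_key=atoms[pgroup[0]].residue_key,
                    ligand_atoms=frozenset(lgroup), protein_atoms=frozenset(pgroup),
                    distance=d, anchor=lc.copy()))
    return events


def detect_frame(frame: np.ndarray, topology: Topology,
                 criteria: GeometricCriteria | None = None, *,
                 typing: InteractionTyping | None = None,
                 frame_index: int = 0) -> list[InteractionEvent]:
    """Union of all four detectors for one frame, stamped with frame_index."""
    criteria = criteria or GeometricCriteria()
    typing = typing or get_typing(topology)
    kw = dict(typing=typing, frame_index=frame_index)
    return (detect_hbonds(frame, topology, criteria, **kw)
            + detect_hydrophobic(frame, topology, criteria, **kw)
            + detect_pistack(frame, topology, criteria, **kw)
            + detect_saltbridge(frame, topology, criteria, **kw))


def saltbridge_between(frame: np.ndarray, topology: Topology,
                       resA: tuple[str, int, str], resB: tuple[str, int, str],
                       criteria: GeometricCriteria | None = None) -> InteractionEvent | None:
    """Salt bridge between two protein residues (template charged groups)."""
    criteria = criteria or GeometricCriteria()
    residues = topology.residues()
    groups = []
    for rkey in (resA, resB):
        if rkey not in residues:
            raise ValueError(f"residue {rkey} not found in topology")
        resname = rkey[2]
        if resname not in _SC_CHARGED:
            raise ValueError(f"residue {rkey} carries no charged-group template")
        names = {topology.atoms[i].name: i for i in residues[rkey]}
        group_names, sign = _SC_CHARGED[resname]
        present = tuple(names[nm] for nm in group_names if nm in names)
        if not present:
            raise ValueError(f"residue {rkey} is missing its charged-group atoms")
        groups.append((present, sign))
    (ga, sa), (gb, sb) = groups
    if sa * sb >= 0:
        return None
    d = float(np.linalg.norm(_group_centroid(frame, ga) - _group_centroid(frame, gb)))
    if d < criteria.saltbridge_max:
        return InteractionEvent(frame_index=0, itype="salt_bridge", residue_key=resB,
                                ligand_atoms=frozenset(ga), protein_atoms=frozenset(gb),
                                distance=d)
    return None


def events_to_dataframe(events: Iterable[InteractionEvent]) -> pd.DataFrame:
    """Tabulate events for CSV export."""
    rows = [{"frame": e.frame_index, "itype": e.itype, "chain": e.residue_key[0],
             "resnum": e.residue_key[1], "resname": e.residue_key[2],
             "distance": e.distance, "angle": e.angle}
            for e in events]
    return pd.DataFrame(rows, columns=["frame", "itype", "chain", "resnum",
                                       "resname", "distance", "angle"])
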