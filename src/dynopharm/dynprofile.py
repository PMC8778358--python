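"""Trajectory-level analytics.

Dynamic noncovalent interaction profiles (per-residue, per-type occurrence
counts over frames), backbone RMSD series, per-residue C-alpha RMSF, and
salt-bridge prevalence between residue pairs.

Occurrence counts frames in which a (residue, interaction-type) cell shows at
least one event — event multiplicity within a frame does not matter, matching
the convention of reporting "conformations out of 15,000". Percentages are
rounded half-away-from-zero to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .core_model import Topology, Trajectory
from .geometry import apply_transform, kabsch_fit
from .interactions import (GeometricCriteria, detect_frame, get_typing,
                           saltbridge_between)

__all__ = [
    "InteractionProfile",
    "SeriesResult",
    "profile_trajectory",
    "occurrence_percent",
    "relevant_interactions",
    "backbone_rmsd_series",
    "rmsf_per_residue",
    "salt_bridge_prevalence",
    "profile_heatmap_export",
    "profile_to_dataframe",
]

_BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class InteractionProfile:
    """Frames-with-event counts per (residue_key, itype) cell."""

    total_frames: int
    counts: dict[tuple[tuple[str, int, str], str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_frames < 0:
            raise ValueError("total_frames must be non-negative")
        for cell, c in self.counts.items():
            if not (0 <= c <= self.total_frames):
                raise ValueError(f"count {c} for {cell} outside [0, {self.total_frames}]")

    def percent(self, residue_key, itype) -> float:
        return occurrence_percent(self.counts.get((residue_key, itype), 0),
                                  self.total_frames)


@dataclass
class SeriesResult:
    """Per-frame (RMSD) or per-residue (RMSF) series in Å."""

    values: np.ndarray
    reference: str
    labels: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("series values must be non-negative")


def profile_trajectory(traj: Trajectory,
                       criteria: GeometricCriteria | None = None) -> InteractionProfile:
    """Detect interactions frame by frame and count per-cell presence."""
    if not traj.topology.ligand_selection:
        raise ValueError("topology has an empty ligand selection")
    criteria = criteria or GeometricCriteria()
    typing = get_typing(traj.topology)
    counts: dict[tuple, int] = {}
    for f in range(traj.n_frames):
        events = detect_frame(traj.frames[f], traj.topology, criteria,
                              typing=typing, frame_index=f)
        present = {(e.residue_key, e.itype) for e in events}
        for cell in present:
            counts[cell] = counts.get(cell, 0) + 1
    return InteractionProfile(total_frames=traj.n_frames, counts=counts)


def occurrence_percent(count: int, total_frames: int) -> float:
    """Percent of frames, rounded half-away-from-zero to 2 decimals."""
    if total_frames <= 0:
        raise ValueError("total_frames must be positive")
    if not (0 <= count <= total_frames):
        raise ValueError(f"count {count} outside [0, {total_frames}]")
    pct = Decimal(100 * count) / Decimal(total_frames)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def relevant_interactions(profile: InteractionProfile,
                          threshold_percent: float = 20.0):
    """Cells occurring strictly more than the threshold, sorted by percent desc.

    Returns [(residue_key, itype, percent), ...]. The strict ">" mirrors the
    relevance rule that an interaction counts only above 20% of simulation
    time.
    """
    out = []
    for (rkey, itype), count in profile.counts.items():
        pct = occurrence_percent(count, profile.total_frames)
        if pct > threshold_percent:
            out.append((rkey, itype, pct))
    out.sort(key=lambda x: (-x[2], x[0], x[1]))
    return out


def _backbone_indices(topology: Topology) -> list[int]:
    lig = topology.ligand_selection
    indices = []
    for rkey, atom_ids in topology.residues().items():
        if all(i in lig for i in atom_ids):
            continue
        names = {topology.atoms[i].name: i for i in atom_ids}
        missing = [nm for nm in _BACKBONE_NAMES if nm not in names]
        if missing:
            raise ValueError(f"residue {rkey} is missing backbone atoms {missing}")
        indices.extend(names[nm] for nm in _BACKBONE_NAMES)
    if not indices:
        raise ValueError("no protein backbone atoms found")
    return indices


def backbone_rmsd_series(traj: Trajectory, reference_frame: int = 0,
                         superpose: bool = True) -> SeriesResult:
    """Backbone (N, CA, C, O) RMSD of every frame to a reference frame.

    Each frame is first optimally superposed on the reference over the
    backbone atoms (least-squares rigid fit), unless ``superpose=False``.
    """
    bb = _backbone_indices(traj.topology)
    ref = traj.frames[reference_frame][bb]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        cur = traj.frames[f][bb]
        if superpose:
            R, t = kabsch_fit(cur, ref)
            cur = apply_transform(cur, R, t)
        values[f] = np.sqrt(((cur - ref) ** 2).sum() / len(bb))
    return SeriesResult(values=values, reference=f"frame {reference_frame} backbone")


def rmsf_per_residue(traj: Trajectory, superpose: bool = True) -> SeriesResult:
    """C-alpha RMSF about the time-average structure.

    Frames are superposed on the time-average backbone by a two-pass
    iterative fit (align to first frame, average, re-align to the average,
    re-average); RMSF_i = sqrt(mean_t |r_i(t) - <r_i>|^2) for each CA.
    """
    topo = traj.topology
    lig = topo.ligand_selection
    ca_ids = []
    ca_keys = []
    for rkey, atom_ids in topo.residues().items():
        if all(i in lig for i in atom_ids):
            continue
        names = {topo.atoms[i].name: i for i in atom_ids}
        if "CA" not in names:
            raise ValueError(f"residue {rkey} is missing its CA atom")
        ca_ids.append(names["CA"])
        ca_keys.append(rkey)
    bb = _backbone_indices(topo)

    frames = traj.frames.copy()
    if superpose:
        ref = frames[0][bb]
        for _pass in range(2):
            for f in range(traj.n_frames):
                R, t = kabsch_fit(frames[f][bb], ref)
                frames[f] = apply_transform(frames[f], R, t)
            ref = frames[:, bb, :].mean(axis=0)
    mean_pos = frames[:, ca_ids, :].mean(axis=0)
    disp = frames[:, ca_ids, :] - mean_pos[None, :, :]
    rmsf = np.sqrt((disp ** 2).sum(axis=2).mean(axis=0))
    return SeriesResult(values=rmsf, reference="time-average structure",
                        labels=ca_keys)


def salt_bridge_prevalence(traj: Trajectory, resA: tuple[str, int, str],
                           resB: tuple[str, int, str],
                           criteria: GeometricCriteria | None = None) -> float:
    """Percent of frames with a salt bridge between two charged residues."""
    criteria = criteria or GeometricCriteria()
    hits = 0
    for f in range(traj.n_frames):
        if saltbridge_between(traj.frames[f], traj.topology, resA, resB, criteria):
            hits += 1
    return occurrence_percent(hits, traj.n_frames)


def profile_to_dataframe(profile: InteractionProfile) -> pd.DataFrame:
    """Long-format table: chain, resnum, resname, itype, count, percent."""
    rows = []
    for (rkey, itype), count in sorted(profile.counts.items()):
        rows.append({"chain": rkey[0], "resnum": rkey[1], "resname": rkey[2],
                     "itype": itype, "count": count,
                     "total_frames": profile.total_frames,
                     "percent": occurrence_percent(count, profile.total_frames)})
    return pd.DataFrame(rows, columns=["chain", "resnum", "resname", "itype",
                                       "count", "total_frames", "percent"])


def profile_heatmap_export(profiles: list[InteractionProfile],
                           system_names: list[str] | None = None,
                           min_occurrence: float = 20.0) -> pd.DataFrame:
    """Residues x (system, itype) occurrence table, heatmap-style.

    Rows are kept only when at least one cell exceeds ``min_occurrence``
    (strict >), matching the convention of showing only residues with
    occurrence above 20%.
    """
    if system_names is None:
        system_names = [f"system{i + 1}" for i in range(len(profiles))]
    if len(system_names) != len(profiles):
        raise ValueError("one system name per profile required")
    data: dict[tuple, dict] = {}
    columns: list[tuple[str, str]] = []
    for name, prof in zip(system_names, profiles):
        for (rkey, itype), count in prof.counts.items():
            col = (name, itype)
            if col not in columns:
                columns.append(col)
            data.setdefault(rkey, {})[col] = occurrence_percent(count, prof.total_frames)
    rows = sorted(data)
    table = pd.DataFrame(
        [[data[r].get(c, 0.0) for c in columns] for r in rows],
        index=pd.Index([f"{r[0]}:{r[1]}:{r[2]}" for r in rows], name="residue"),
        columns=pd.MultiIndex.from_tuples(columns, names=["system", "itype"]),
    )
    if table.empty:
        return table
    keep = (table > min_occurrence).any(axis=1)
    return table.loc[keep]
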