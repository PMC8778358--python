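"""3D pharmacophore building, serialization, matching and screening.

A pharmacophore is a set of typed spheres (hydrogen-bond acceptor HBA,
donor HBD, aromatic Aro, hydrophobic Hyd) with centers and tolerance radii.
Two features may be co-located (one position satisfiable by either kind,
counted once toward the match minimum). Models are built from
high-occurrence cells of a dynamic interaction profile, serialized as
Pharmit-style JSON, and matched against conformer feature points by an
exhaustive rigid-assignment search with distance-compatibility pruning.

Screening applies the published filter order: conformers whose van der Waals
molecular volume exceeds the ceiling (default 270 Å^3) are eliminated before
matching, and compounds need at least ``min_match`` positionally distinct
elements (default 6) to count as hits.

The packaged :data:`REFERENCE_ELEMENTS` list reproduces the eight-element
CK1-epsilon inhibitor pharmacophore layout (HBA + HBD1 at the hinge/adenine
region, HBD2 nearby, a co-located Aro1/Hyd1 dual at the phosphate region,
a co-located Hyd2/Aro2 dual in the buried region, and Hyd3 at the aliphatic
lysine contact). Its coordinates are synthetic: the source study published
the element types and their triangular arrangement, not coordinates, so the
packaged geometry is a constructed stand-in with realistic spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import ConformerRecord, Trajectory, VDW_RADII
from .geometry import apply_transform, kabsch_fit
from .interactions import GeometricCriteria, detect_frame, get_typing
from .pose_cluster import Pose

__all__ = [
    "PharmacophoreFeature",
    "PharmacophoreModel",
    "MatchResult",
    "ScreenReport",
    "build_features",
    "add_colocated",
    "assemble_reference_model",
    "submodel",
    "write_model",
    "read_model",
    "annotate_conformer_features",
    "match",
    "molecular_volume",
    "screen",
    "pose_agreement",
    "REFERENCE_ELEMENTS",
]

KINDS = ("HBA", "HBD", "Aro", "Hyd")

_PHARMIT_NAMES = {"HBA": "HydrogenAcceptor", "HBD": "HydrogenDonor",
                  "Aro": "Aromatic", "Hyd": "Hydrophobic"}
_PHARMIT_KINDS = {v: k for k, v in _PHARMIT_NAMES.items()}


@dataclass
class PharmacophoreFeature:
    """One typed sphere: kind, center (Å) and tolerance radius (Å)."""

    name: str
    kind: str
    center: np.ndarray
    radius: float = 1.0
    colocation_group: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("feature center must be a 3-vector")
        if self.radius <= 0:
            raise ValueError("feature radius must be positive")

    def __eq__(self, other) -> bool:
        return (isinstance(other, PharmacophoreFeature)
                and self.name == other.name and self.kind == other.kind
                and np.allclose(self.center, other.center)
                and self.radius == other.radius
                and self.colocation_group == other.colocation_group)


@dataclass
class PharmacophoreModel:
    """Feature list plus the minimum number of positions a match must cover."""

    features: list[PharmacophoreFeature] = field(default_factory=list)
    min_match: int = 6
    provenance: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise ValueError("duplicate feature names")
        for group, members in self._groups_by_id().items():
            centers = np.array([m.center for m in members])
            if not np.allclose(centers, centers[0], atol=1e-9):
                raise ValueError(f"colocation group {group!r} members differ in center")

    def __eq__(self, other) -> bool:
        return (isinstance(other, PharmacophoreModel)
                and self.features == other.features
                and self.min_match == other.min_match
                and self.provenance == other.provenance)

    def _groups_by_id(self) -> dict[str, list[PharmacophoreFeature]]:
        out: dict[str, list[PharmacophoreFeature]] = {}
        for f in self.features:
            if f.colocation_group:
                out.setdefault(f.colocation_group, []).append(f)
        return out

    def feature(self, name: str) -> PharmacophoreFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"unknown feature {name!r}")

    def positions(self) -> list["_Position"]:
        """Positionally distinct elements: colocation groups collapsed."""
        seen_groups = set()
        out = []
        for f in self.features:
            if f.colocation_group:
                if f.colocation_group in seen_groups:
                    continue
                seen_groups.add(f.colocation_group)
                members = [g for g in self.features
                           if g.colocation_group == f.colocation_group]
                out.append(_Position(name=f.colocation_group,
                                     kinds=frozenset(m.kind for m in members),
                                     center=f.center,
                                     radius=max(m.radius for m in members)))
            else:
                out.append(_Position(name=f.name, kinds=frozenset({f.kind}),
                                     center=f.center, radius=f.radius))
        return out

    @property
    def n_positions(self) -> int:
        return len(self.positions())


@dataclass(frozen=True)
class _Position:
    name: str
    kinds: frozenset
    center: np.ndarray
    radius: float


@dataclass
class MatchResult:
    """Accepted assignment of model positions to conformer feature points."""

    assignment: dict[str, int]            # position name -> conformer point index
    transform: tuple[np.ndarray, np.ndarray]  # (R, t) mapping conformer -> model frame
    deviations: dict[str, float]          # position name -> residual (Å)
    matched_count: int

    @property
    def total_deviation(self) -> float:
        return float(sum(self.deviations.values()))


# ---------------------------------------------------------------------------
# Building from dynamic profiles
# ---------------------------------------------------------------------------

def build_features(profile, traj: Trajectory, threshold: float = 20.0,
                   criteria: GeometricCriteria | None = None,
                   radius: float = 1.0,
                   merge_radius: float = 1.5) -> list[PharmacophoreFeature]:
    """Derive features from interaction cells above the occurrence threshold.

    Hydrogen-bond cells map to HBA (ligand accepts) or HBD (ligand donates),
    pi-stacking to Aro, hydrophobic to Hyd; centers are the mean ligand-side
    anchor over qualifying frames. Hydrophobic cells whose anchors lie within
    ``merge_radius`` of each other collapse into one Hyd feature, since
    several residues often pack against one ligand moiety.

    The threshold applies strictly ("> threshold percent of frames"). Events
    are re-detected from ``traj`` to recover anchor geometry; ``profile`` must
    have been computed over the same trajectory (frame counts must agree).
    """
    from .dynprofile import occurrence_percent  # local import avoids a cycle

    if profile.total_frames != traj.n_frames:
        raise ValueError("profile and trajectory disagree on frame count")
    criteria = criteria or GeometricCriteria()
    typing = get_typing(traj.topology)

    # cell -> {frame -> [anchors]}; hbond cells are split by ligand role
    anchors: dict[tuple, dict[int, list[np.ndarray]]] = {}
    for f in range(traj.n_frames):
        for e in detect_frame(traj.frames[f], traj.topology, criteria,
                              typing=typing, frame_index=f):
            if e.anchor is None:
                continue
            if e.itype == "hbond":
                roles = ("donor", "acceptor") if e.ligand_role == "either" else (e.ligand_role,)
                keys = [(e.residue_key, "hbond", r) for r in roles]
            else:
                keys = [(e.residue_key, e.itype, None)]
            for key in keys:
                anchors.setdefault(key, {}).setdefault(f, []).append(e.anchor)

    kind_of = {("hbond", "donor"): "HBD", ("hbond", "acceptor"): "HBA",
               ("pi_stack", None): "Aro", ("hydrophobic", None): "Hyd",
               ("salt_bridge", None): None}  # salt bridges carry no sphere kind
    candidates = []  # (kind, percent, center, cell)
    for (rkey, itype, role), per_frame in anchors.items():
        pct = occurrence_percent(len(per_frame), traj.n_frames)
        if pct <= threshold:
            continue
        kind = kind_of.get((itype, role))
        if kind is None:
            continue
        frame_means = np.array([np.mean(alist, axis=0) for alist in per_frame.values()])
        center = frame_means.mean(axis=0)
        candidates.append((kind, pct, center, (rkey, itype, role)))

    candidates.sort(key=lambda c: (-c[1], c[3]))
    features: list[PharmacophoreFeature] = []
    counters = {k: 0 for k in KINDS}
    # merge hydrophobic anchors that describe the same ligand moiety
    hyd_groups: list[dict] = []
    for kind, pct, center, cell in candidates:
        if kind == "Hyd":
            placed = False
            for g in hyd_groups:
                if np.linalg.norm(center - g["center"]) <= merge_radius:
                    g["members"].append((pct, center, cell))
                    weights = np.array([m[0] for m in g["members"]])
                    pts = np.array([m[1] for m in g["members"]])
                    g["center"] = (pts * weights[:, None]).sum(axis=0) / weights.sum()
                    placed = True
                    break
            if not placed:
                hyd_groups.append({"center": center, "members": [(pct, center, cell)]})
        else:
            counters[kind] += 1
            name = f"{kind}{counters[kind]}"
            features.append(PharmacophoreFeature(name=name, kind=kind,
                                                 center=center, radius=radius))
            features[-1]._provenance = [cell]  # attached for the caller
    for g in hyd_groups:
        counters["Hyd"] += 1
        name = f"Hyd{counters['Hyd']}"
        feat = PharmacophoreFeature(name=name, kind="Hyd", center=g["center"],
                                    radius=radius)
        feat._provenance = [m[2] for m in g["members"]]
        features.append(feat)
    return features


def build_model(profile, traj: Trajectory, threshold: float = 20.0,
                min_match: int = 6, **kwargs) -> PharmacophoreModel:
    """Convenience wrapper: build features and wrap them in a model."""
    feats = build_features(profile, traj, threshold=threshold, **kwargs)
    provenance = {}
    for f in feats:
        cells = getattr(f, "_provenance", None)
        provenance[f.name] = ([(list(rk), it, role) for rk, it, role in cells]
                              if cells else "manual")
    min_match = min(min_match, max(1, len(feats)))
    return PharmacophoreModel(features=feats, min_match=min_match,
                              provenance=provenance)


def add_colocated(model: PharmacophoreModel, feature_name: str,
                  new_kind: str) -> PharmacophoreModel:
    """Append a feature of ``new_kind`` co-located with an existing feature.

    The pair shares a colocation group: matching counts the position once and
    either kind satisfies it.
    """
    base = model.feature(feature_name)
    if base.colocation_group is not None:
        raise ValueError(f"group already exists for feature {feature_name!r}")
    if new_kind not in KINDS:
        raise ValueError(f"unknown feature kind {new_kind!r}")
    existing = {f.name for f in model.features}
    i = 1
    while f"{new_kind}{i}" in existing:
        i += 1
    twin_name = f"{new_kind}{i}"
    group = f"{feature_name}/{twin_name}"
    new_features = []
    for f in model.features:
        nf = PharmacophoreFeature(f.name, f.kind, f.center.copy(), f.radius,
                                  group if f.name == feature_name else f.colocation_group)
        new_features.append(nf)
    new_features.append(PharmacophoreFeature(twin_name, new_kind, base.center.copy(),
                                             base.radius, group))
    prov = dict(model.provenance)
    prov[twin_name] = "manual"
    return PharmacophoreModel(features=new_features, min_match=model.min_match,
                              provenance=prov)


# Synthetic stand-in coordinates for the published eight-element model:
# element kinds, co-locations and the triangular adenine/phosphate/buried
# arrangement follow the study; the coordinates themselves are constructed.
REFERENCE_ELEMENTS: list[dict] = [
    {"name": "HBA1", "kind": "HBA", "center": [0.0, 0.0, 0.0], "radius": 1.0},
    {"name": "HBD1", "kind": "HBD", "center": [1.9, 1.3, 0.2], "radius": 1.0},
    {"name": "HBD2", "kind": "HBD", "center": [-1.6, 2.1, 0.6], "radius": 1.0},
    {"name": "Aro1", "kind": "Aro", "center": [6.4, -3.1, 1.1], "radius": 1.1},
    {"name": "Hyd1", "kind": "Hyd", "colocate_with": "Aro1"},
    {"name": "Hyd2", "kind": "Hyd", "center": [-4.1, -3.4, -0.6], "radius": 1.0},
    {"name": "Aro2", "kind": "Aro", "colocate_with": "Hyd2"},
    {"name": "Hyd3", "kind": "Hyd", "center": [-1.9, -5.6, 1.4], "radius": 1.0},
]


def assemble_reference_model(spec: list[dict] | None = None,
                             min_match: int = 6) -> PharmacophoreModel:
    """Assemble a model from a declarative element list.

    Each entry names a kind and either a center+radius or a
    ``colocate_with`` reference to an earlier element. The default spec is
    the packaged eight-element reference layout.
    """
    if spec is None:
        spec = REFERENCE_ELEMENTS
    features: list[PharmacophoreFeature] = []
    names = set()
    for entry in spec:
        name = entry["name"]
        if name in names:
            raise ValueError(f"duplicate feature name {name!r}")
        names.add(name)
        if "colocate_with" in entry:
            base_name = entry["colocate_with"]
            base = next((f for f in features if f.name == base_name), None)
            if base is None:
                raise ValueError(f"colocate_with references unknown feature {base_name!r}")
            group = f"{base_name}/{name}"
            base.colocation_group = group
            features.append(PharmacophoreFeature(name=name, kind=entry["kind"],
                                                 center=base.center.copy(),
                                                 radius=base.radius,
                                                 colocation_group=group))
        else:
            features.append(PharmacophoreFeature(name=name, kind=entry["kind"],
                                                 center=np.array(entry["center"], float),
                                                 radius=float(entry.get("radius", 1.0))))
    provenance = {f.name: "manual" for f in features}
    model = PharmacophoreModel(features=features, min_match=min_match,
                               provenance=provenance)
    if model.features and min_match > model.n_positions:
        raise ValueError("min_match exceeds the number of distinct positions")
    return model


def submodel(model: PharmacophoreModel, drop: list[str],
             min_match: int | None = None) -> PharmacophoreModel:
    """Model minus the named features; colocation groups are dropped whole."""
    for name in drop:
        model.feature(name)  # raises on unknown name
    drop_set = set(drop)
    groups_to_drop = {model.feature(n).colocation_group for n in drop
                      if model.feature(n).colocation_group}
    kept = [f for f in model.features
            if f.name not in drop_set and f.colocation_group not in groups_to_drop]
    prov = {f.name: model.provenance.get(f.name, "manual") for f in kept}
    return PharmacophoreModel(
        features=[PharmacophoreFeature(f.name, f.kind, f.center.copy(), f.radius,
                                       f.colocation_group) for f in kept],
        min_match=model.min_match if min_match is None else min_match,
        provenance=prov)


# ---------------------------------------------------------------------------
# JSON serialization (Pharmit-style points list)
# ---------------------------------------------------------------------------

def write_model(model: PharmacophoreModel, path: str | Path) -> None:
    points = []
    for f in model.features:
        points.append({
            "name": _PHARMIT_NAMES[f.kind],
            "label": f.name,
            "x": float(f.center[0]), "y": float(f.center[1]), "z": float(f.center[2]),
            "radius": f.radius,
            "enabled": True,
            "colocation": f.colocation_group,
        })
    doc = {"points": points, "minMatch": model.min_match,
           "provenance": model.provenance}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_model(path: str | Path) -> PharmacophoreModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed pharmacophore JSON: {exc}") from exc
    features = []
    for p in doc.get("points", []):
        if p["name"] not in _PHARMIT_KINDS:
            raise ValueError(f"unknown feature kind string {p['name']!r}")
        features.append(PharmacophoreFeature(
            name=p.get("label", p["name"]), kind=_PHARMIT_KINDS[p["name"]],
            center=np.array([p["x"], p["y"], p["z"]], float),
            radius=float(p.get("radius", 1.0)),
            colocation_group=p.get("colocation")))
    prov_raw = doc.get("provenance", {})
    provenance = {}
    for k, v in prov_raw.items():
        if isinstance(v, list):
            provenance[k] = [(list(rk), it, role) for rk, it, role in v]
        else:
            provenance[k] = v
    return PharmacophoreModel(features=features,
                              min_match=int(doc.get("minMatch", 6)),
                              provenance=provenance)


# ---------------------------------------------------------------------------
# Conformer feature perception
# ---------------------------------------------------------------------------

def annotate_conformer_features(conformer: ConformerRecord) -> list[tuple[str, np.ndarray]]:
    """Feature points of a conformer: HBD/HBA atoms, Aro ring centroids,
    Hyd apolar-carbon group centroids. Pre-annotated points pass through."""
    if conformer.feature_points is not None:
        return list(conformer.feature_points)
    topo = conformer.as_topology()
    typing = get_typing(topo)
    coords = topo.coords_array()
    points: list[tuple[str, np.ndarray]] = []
    for i, _hs in typing.ligand_donors:
        points.append(("HBD", coords[i].copy()))
    for i in typing.ligand_acceptors:
        points.append(("HBA", coords[i].copy()))
    for ring in typing.ligand_rings:
        pts = coords[list(ring)]
        from .geometry import best_fit_plane
        centroid, _n, rms = best_fit_plane(pts)
        if rms <= 0.3:
            points.append(("Aro", centroid))
    # hydrophobic groups: connected components of apolar carbons
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(typing.ligand_apolar)
    apolar = set(typing.ligand_apolar)
    g.add_edges_from((i, j) for i, j in topo.bonds if i in apolar and j in apolar)
    for comp in nx.connected_components(g):
        points.append(("Hyd", coords[sorted(comp)].mean(axis=0)))
    return points


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _evaluate(model_pts: np.ndarray, conf_pts: np.ndarray, radii: np.ndarray):
    """Rigid-fit conf_pts onto model_pts; return (ok, deviations, R, t)."""
    R, t = kabsch_fit(conf_pts, model_pts)
    moved = apply_transform(conf_pts, R, t)
    dev = np.linalg.norm(moved - model_pts, axis=1)
    return bool(np.all(dev <= radii + 1e-9)), dev, R, t


def match(model: PharmacophoreModel, conformer: ConformerRecord,
          min_match: int | None = None) -> MatchResult | None:
    """Best rigid assignment of model positions to conformer feature points.

    Searches all injective assignments of positionally distinct elements to
    kind-compatible conformer points (pruned by pairwise distance
    compatibility), evaluates each candidate of sufficient size by a
    least-squares rigid fit, and accepts it when every residual is within the
    feature radius. Among accepted assignments the largest wins; ties break
    toward the lowest total deviation. Returns None when nothing reaches
    ``min_match``.
    """
    positions = model.positions()
    if not positions:
        return None
    need = model.min_match if min_match is None else min_match
    need = max(need, 1)
    pts = annotate_conformer_features(conformer)
    if not pts:
        return None
    pt_kinds = [k for k, _ in pts]
    pt_xyz = np.array([p for _, p in pts])
    compat = [[j for j, k in enumerate(pt_kinds) if k in pos.kinds]
              for pos in positions]
    n_pos = len(positions)
    best: dict = {"count": need - 1, "dev": np.inf, "result": None}

    def recurse(i: int, assigned: list[tuple[int, int]], used: set[int]):
        remaining = n_pos - i
        if len(assigned) + remaining < best["count"]:
            return
        if i == n_pos:
            k = len(assigned)
            if k < need or k < 2:
                # a 1-point "fit" is degenerate; require >= 2 pairs (need >= 1
                # with a single position still evaluates below)
                if not (k == 1 and need == 1):
                    return
            pos_idx = [a for a, _ in assigned]
            pt_idx = [b for _, b in assigned]
            centers = np.array([positions[a].center for a in pos_idx])
            radii = np.array([positions[a].radius for a in pos_idx])
            if k == 1:
                # translation-only fit
                t = centers[0] - pt_xyz[pt_idx[0]]
                R = np.eye(3)
                dev = np.zeros(1)
                ok = True
            else:
                ok, dev, R, t = _evaluate(centers, pt_xyz[pt_idx], radii)
            if not ok:
                return
            total = float(dev.sum())
            if k > best["count"] or (k == best["count"] and total < best["dev"]):
                best["count"] = k
                best["dev"] = total
                best["result"] = MatchResult(
                    assignment={positions[a].name: b for (a, b) in assigned},
                    transform=(R, t),
                    deviations={positions[a].name: float(d)
                                for (a, _), d in zip(assigned, dev)},
                    matched_count=k)
            return
        # skip this position
        recurse(i + 1, assigned, used)
        # or assign a compatible unused point, pruned by pairwise distances
        ci = positions[i].center
        ri = positions[i].radius
        for j in compat[i]:
            if j in used:
                continue
            feasible = True
            for (a, b) in assigned:
                dm = np.linalg.norm(ci - positions[a].center)
                dp = np.linalg.norm(pt_xyz[j] - pt_xyz[b])
                if abs(dm - dp) > ri + positions[a].radius + 1e-9:
                    feasible = False
                    break
            if feasible:
                used.add(j)
                assigned.append((i, j))
                recurse(i + 1, assigned, used)
                assigned.pop()
                used.remove(j)

    recurse(0, [], set())
    return best["result"]


# ---------------------------------------------------------------------------
# Filters and screening
# ---------------------------------------------------------------------------

def _signed_surface_distance(points: np.ndarray, coords: np.ndarray,
                             radii: np.ndarray) -> np.ndarray:
    """min over atoms of (|p - c_a| - r_a); negative = inside the union."""
    out = np.full(len(points), np.inf)
    for center, r in zip(coords, radii):
        d = np.linalg.norm(points - center, axis=1) - r
        np.minimum(out, d, out=out)
    return out


def molecular_volume(conformer: ConformerRecord, grid_spacing: float = 0.2) -> float:
    """van der Waals molecular volume (Å^3) by grid counting.

    Voxels whose centers lie clearly inside (outside) the union of atomic
    vdW spheres count fully (not at all); voxels straddling the surface are
    refined by a 4x4x4 sub-grid, so the estimate converges fast in the grid
    spacing.
    """
    coords = conformer.coords_array()
    radii = []
    for a in conformer.atoms:
        r = VDW_RADII.get(a.element)
        if r is None:
            raise ValueError(f"no van der Waals radius for element {a.element!r}")
        radii.append(r)
    radii = np.array(radii)
    h = grid_spacing
    rmax = radii.max()
    lo = coords.min(axis=0) - rmax - h
    hi = coords.max(axis=0) + rmax + h
    axes = [np.arange(lo[d], hi[d] + h, h) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    sd = _signed_surface_distance(grid, coords, radii)
    half_diag = h * np.sqrt(3) / 2
    n_inside = int(np.count_nonzero(sd <= -half_diag))
    boundary = grid[np.abs(sd) < half_diag]
    frac = 0.0
    if len(boundary):
        sub = 4
        offs = (np.arange(sub) + 0.5) / sub - 0.5  # sub-centers in voxel units
        ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
        sub_offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()]) * h
        pts = (boundary[:, None, :] + sub_offsets[None, :, :]).reshape(-1, 3)
        sub_sd = _signed_surface_distance(pts, coords, radii)
        frac = float(np.count_nonzero(sub_sd <= 0.0)) / sub ** 3
    return (n_inside + frac) * h ** 3


@dataclass
class ScreenEntry:
    name: str
    compound: str
    volume: float
    status: str                    # "hit" | "no_match" | "volume"
    matched_count: int = 0
    match: MatchResult | None = None


@dataclass
class ScreenReport:
    entries: list[ScreenEntry]
    volume_max: float
    min_match: int

    @property
    def hits(self) -> list[ScreenEntry]:
        return [e for e in self.entries if e.status == "hit"]

    @property
    def hit_compounds(self) -> set[str]:
        return {e.compound for e in self.hits}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"conformer": e.name, "compound": e.compound,
                 "volume": round(e.volume, 3), "status": e.status,
                 "matched_count": e.matched_count,
                 "total_deviation": (round(e.match.total_deviation, 4)
                                     if e.match else None)}
                for e in self.entries]
        return pd.DataFrame(rows, columns=["conformer", "compound", "volume",
                                           "status", "matched_count",
                                           "total_deviation"])

    def to_dict(self) -> dict:
        return {"volume_max": self.volume_max, "min_match": self.min_match,
                "n_conformers": len(self.entries),
                "n_hits": len(self.hits),
                "hit_compounds": sorted(self.hit_compounds),
                "entries": self.to_dataframe().to_dict(orient="records")}


def screen(library: list[ConformerRecord], model: PharmacophoreModel,
           volume_max: float = 270.0, min_match: int = 6,
           grid_spacing: float = 0.2) -> ScreenReport:
    """Volume-filter then pharmacophore-match a conformer library.

    Conformers with volume strictly greater than ``volume_max`` are
    eliminated before matching (reason "volume"). A compound is a hit when
    any of its conformers matches at least ``min_match`` positions.
    """
    entries = []
    for conf in library:
        vol = molecular_volume(conf, grid_spacing=grid_spacing)
        if vol > volume_max:
            entries.append(ScreenEntry(conf.name, conf.compound, vol, "volume"))
            continue
        res = match(model, conf, min_match=min_match)
        if res is None:
            entries.append(ScreenEntry(conf.name, conf.compound, vol, "no_match"))
        else:
            entries.append(ScreenEntry(conf.name, conf.compound, vol, "hit",
                                       matched_count=res.matched_count, match=res))
    return ScreenReport(entries=entries, volume_max=volume_max, min_match=min_match)


def pose_agreement(docked: Pose, matched: MatchResult,
                   conformer: ConformerRecord,
                   threshold: float = 1.5) -> tuple[float, bool]:
    """Heavy-atom RMSD between the pharmacophore-placed conformer and a
    docked pose (no re-fit); selected iff RMSD is strictly below threshold."""
    R, t = matched.transform
    placed = apply_transform(conformer.coords_array(), R, t)
    docked_heavy = [a for a in docked.atoms if a.element != "H"]
    conf_heavy = [i for i, a in enumerate(conformer.atoms) if a.element != "H"]
    if len(docked_heavy) != len(conf_heavy):
        raise ValueError("docked pose and conformer differ in heavy-atom count")
    d = np.array([a.coords for a in docked_heavy])
    c = placed[conf_heavy]
    rmsd = float(np.sqrt(((d - c) ** 2).sum() / len(d)))
    return rmsd, rmsd < threshold
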