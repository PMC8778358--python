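import json

import numpy as np
import pytest

from dynopharm.core_model import AtomRecord, ConformerRecord
from dynopharm.dynprofile import profile_trajectory
from dynopharm.pharmacophore import (add_colocated, annotate_conformer_features,
                                     assemble_reference_model, build_features,
                                     build_model, match, molecular_volume,
                                     pose_agreement, read_model, screen,
                                     submodel, write_model)
from dynopharm.pose_cluster import Pose
from dynopharm.synthetic import (PlantSpec, make_conformer_library,
                                 make_trajectory)
from conftest import random_rigid_transform
from oracles import brute_match


# ---------------------------------------------------------------------------
# Reference model assembly / colocation / submodel
# ---------------------------------------------------------------------------

def test_reference_model_has_eight_elements(ref_model):
    assert len(ref_model.features) == 8
    kinds = sorted(f.kind for f in ref_model.features)
    assert kinds == ["Aro", "Aro", "HBA", "HBD", "HBD", "Hyd", "Hyd", "Hyd"]
    assert ref_model.n_positions == 6
    assert ref_model.min_match == 6
    groups = {f.colocation_group for f in ref_model.features if f.colocation_group}
    assert len(groups) == 2  # Aro1/Hyd1 and Hyd2/Aro2 duals


def test_assemble_empty_and_duplicate():
    assert assemble_reference_model([], min_match=0).features == []
    with pytest.raises(ValueError, match="duplicate"):
        assemble_reference_model([
            {"name": "A", "kind": "Hyd", "center": [0, 0, 0]},
            {"name": "A", "kind": "Aro", "center": [1, 0, 0]},
        ], min_match=1)


def test_add_colocated():
    model = assemble_reference_model([
        {"name": "Aro1", "kind": "Aro", "center": [0, 0, 0]},
        {"name": "HBA1", "kind": "HBA", "center": [3, 0, 0]},
    ], min_match=2)
    model2 = add_colocated(model, "Aro1", "Hyd")
    assert len(model2.features) == 3
    twin = model2.feature("Hyd1")
    assert twin.colocation_group == model2.feature("Aro1").colocation_group
    np.testing.assert_allclose(twin.center, [0, 0, 0])
    assert model2.n_positions == 2
    with pytest.raises(ValueError, match="group already exists"):
        add_colocated(model2, "Aro1", "HBD")


def test_colocated_group_counts_once():
    """A conformer satisfying both members of a dual gains exactly one count
    over a conformer satisfying neither."""
    model = assemble_reference_model([
        {"name": "HBA1", "kind": "HBA", "center": [0, 0, 0]},
        {"name": "HBD1", "kind": "HBD", "center": [4, 0, 0]},
        {"name": "Aro1", "kind": "Aro", "center": [2, 3, 0]},
        {"name": "Hyd1", "kind": "Hyd", "colocate_with": "Aro1"},
    ], min_match=2)
    pts_without = [("HBA", np.zeros(3)), ("HBD", np.array([4.0, 0, 0]))]
    pts_with = pts_without + [("Aro", np.array([2.0, 3, 0])),
                              ("Hyd", np.array([2.0, 3, 0]))]
    atoms = [AtomRecord(0, "C", "C1", "LIG", 1, "L", np.zeros(3))]
    c0 = ConformerRecord(name="a", atoms=atoms, feature_points=pts_without)
    c1 = ConformerRecord(name="b", atoms=atoms, feature_points=pts_with)
    m0 = match(model, c0, min_match=2)
    m1 = match(model, c1, min_match=2)
    assert m1.matched_count == m0.matched_count + 1


def test_submodel_drops_groups_whole(ref_model):
    sub = submodel(ref_model, ["Aro1"])  # drags the co-located Hyd1 along
    assert len(sub.features) == 6
    assert {f.name for f in sub.features} == {"HBA1", "HBD1", "HBD2", "Hyd2",
                                              "Aro2", "Hyd3"}
    assert submodel(ref_model, []) == ref_model
    empty = submodel(ref_model, [f.name for f in ref_model.features])
    assert empty.features == []
    atoms = [AtomRecord(0, "C", "C1", "LIG", 1, "L", np.zeros(3))]
    conf = ConformerRecord(name="x", atoms=atoms,
                           feature_points=[("Hyd", np.zeros(3))])
    assert match(empty, conf) is None
    with pytest.raises(KeyError):
        submodel(ref_model, ["NoSuch"])


def test_removing_features_never_decreases_matchability(ref_model):
    """Dropping a model position cannot lower the matched count against the
    remaining positions."""
    lib = make_conformer_library(6, ref_model, hit_fraction=0.5, seed=21)
    sub = submodel(ref_model, ["Hyd3"], min_match=1)
    for conf in lib:
        full = match(ref_model, conf, min_match=1)
        reduced = match(sub, conf, min_match=1)
        full_rest = 0
        if full is not None:
            full_rest = sum(1 for k in full.assignment if k != "Hyd3")
        got = reduced.matched_count if reduced is not None else 0
        assert got >= full_rest


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------

def test_model_json_round_trip(tmp_path, ref_model):
    path = tmp_path / "model.json"
    write_model(ref_model, path)
    assert read_model(path) == ref_model
    doc = json.loads(path.read_text())
    assert {p["name"] for p in doc["points"]} <= {
        "HydrogenAcceptor", "HydrogenDonor", "Aromatic", "Hydrophobic"}
    assert doc["minMatch"] == 6


def test_model_json_unknown_kind(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text(json.dumps({"points": [
        {"name": "Magnetic", "x": 0, "y": 0, "z": 0, "radius": 1.0}]}))
    with pytest.raises(ValueError, match="unknown feature kind"):
        read_model(path)
    path.write_text("{not json")
    with pytest.raises(ValueError, match="malformed"):
        read_model(path)


# ---------------------------------------------------------------------------
# Feature perception
# ---------------------------------------------------------------------------

def _benzene():
    atoms = []
    for k in range(6):
        ang = np.radians(60 * k)
        atoms.append(AtomRecord(k, "C", f"C{k+1}", "LIG", 1, "L",
                                np.array([1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0])))
    bonds = {(k, (k + 1) % 6) for k in range(6)}
    return ConformerRecord(name="benzene", atoms=atoms,
                           bonds={(min(i, j), max(i, j)) for i, j in bonds})


def test_annotate_benzene():
    pts = annotate_conformer_features(_benzene())
    kinds = sorted(k for k, _ in pts)
    assert kinds == ["Aro", "Hyd"]  # ring centroid + one apolar-carbon group
    aro = next(p for k, p in pts if k == "Aro")
    np.testing.assert_allclose(aro, [0, 0, 0], atol=1e-9)


def test_annotate_methanol():
    atoms = [AtomRecord(0, "C", "C1", "LIG", 1, "L", np.zeros(3)),
             AtomRecord(1, "O", "O1", "LIG", 1, "L", np.array([1.43, 0, 0])),
             AtomRecord(2, "H", "H1", "LIG", 1, "L", np.array([1.8, 0.9, 0]))]
    conf = ConformerRecord(name="methanol", atoms=atoms, bonds={(0, 1), (1, 2)})
    pts = annotate_conformer_features(conf)
    kinds = sorted(k for k, _ in pts)
    assert kinds == ["HBA", "HBD"]
    for _k, p in pts:
        np.testing.assert_allclose(p, [1.43, 0, 0], atol=1e-9)


def test_annotate_pass_through():
    atoms = [AtomRecord(0, "C", "C1", "LIG", 1, "L", np.zeros(3))]
    given = [("Aro", np.array([1.0, 2.0, 3.0]))]
    conf = ConformerRecord(name="x", atoms=atoms, feature_points=given)
    out = annotate_conformer_features(conf)
    assert [(k, tuple(p)) for k, p in out] == [("Aro", (1.0, 2.0, 3.0))]


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _exact_conformer(model, rng=None):
    """Feature points exactly at the model centers (optionally transformed)."""
    pts = [(sorted(pos.kinds)[0], pos.center.copy()) for pos in model.positions()]
    if rng is not None:
        R, t = random_rigid_transform(rng)
        pts = [(k, R @ p + t) for k, p in pts]
    atoms = [AtomRecord(i, "C", f"C{i+1}", "LIG", 1, "L", p.copy())
             for i, (_k, p) in enumerate(pts)]
    return ConformerRecord(name="exact", atoms=atoms, feature_points=pts)


def test_match_exact_conformer(ref_model):
    res = match(ref_model, _exact_conformer(ref_model))
    assert res is not None
    assert res.matched_count == 6
    assert all(d <= 1e-9 for d in res.deviations.values())


def test_match_threshold(ref_model):
    """Only 5 satisfiable positions with min_match 6 is a miss."""
    conf = _exact_conformer(ref_model)
    conf5 = ConformerRecord(name="five", atoms=conf.atoms[:5],
                            feature_points=conf.feature_points[:5])
    assert match(ref_model, conf5, min_match=6) is None
    res = match(ref_model, conf5, min_match=5)
    assert res is not None and res.matched_count == 5


def test_match_rigid_invariance(ref_model):
    rng = np.random.default_rng(17)
    for _ in range(5):
        conf = _exact_conformer(ref_model, rng)
        res = match(ref_model, conf)
        assert res is not None and res.matched_count == 6
        assert all(d <= 1e-6 for d in res.deviations.values())


def test_match_agrees_with_brute_force_oracle():
    """Accept/reject and matched_count equal an exhaustive assignment search
    on randomized small instances."""
    rng = np.random.default_rng(23)
    kinds = ["HBA", "HBD", "Aro", "Hyd"]
    agree = 0
    for trial in range(20):
        n_pos = int(rng.integers(3, 6))
        spec = [{"name": f"F{i}", "kind": kinds[rng.integers(4)],
                 "center": rng.uniform(-4, 4, 3).tolist(),
                 "radius": float(rng.uniform(0.6, 1.4))} for i in range(n_pos)]
        min_match = int(rng.integers(2, n_pos + 1))
        model = assemble_reference_model(spec, min_match=min_match)
        n_pts = int(rng.integers(2, 8))
        pts = [(kinds[rng.integers(4)], rng.uniform(-5, 5, 3))
               for _ in range(n_pts)]
        if trial % 2 == 0 and n_pts >= n_pos:
            # half the trials embed a true match
            R, t = random_rigid_transform(rng)
            for i in range(n_pos):
                pts[i] = (sorted(model.positions()[i].kinds)[0],
                          R @ model.positions()[i].center + t)
        atoms = [AtomRecord(i, "C", f"C{i+1}", "LIG", 1, "L", p.copy())
                 for i, (_k, p) in enumerate(pts)]
        conf = ConformerRecord(name=f"t{trial}", atoms=atoms, feature_points=pts)
        res = match(model, conf, min_match=min_match)
        accepted = res is not None
        count = res.matched_count if res else 0
        o_accept, o_count = brute_match(model, conf, min_match)
        assert accepted == o_accept
        if accepted:
            assert count == o_count
        agree += 1
    assert agree == 20


# ---------------------------------------------------------------------------
# Volume
# ---------------------------------------------------------------------------

def _carbon(i, xyz):
    return AtomRecord(i, "C", f"C{i+1}", "LIG", 1, "L", np.array(xyz, float))


def test_volume_single_sphere():
    conf = ConformerRecord(name="c", atoms=[_carbon(0, (0.3, -0.2, 0.9))])
    exact = 4 / 3 * np.pi * 1.7 ** 3
    assert molecular_volume(conf) == pytest.approx(exact, rel=0.02)


def test_volume_disjoint_and_coincident():
    one = molecular_volume(ConformerRecord(name="a", atoms=[_carbon(0, (0, 0, 0))]))
    two = molecular_volume(ConformerRecord(
        name="b", atoms=[_carbon(0, (0, 0, 0)), _carbon(1, (10, 0, 0))]))
    assert two == pytest.approx(2 * one, rel=0.01)
    dup = molecular_volume(ConformerRecord(
        name="c", atoms=[_carbon(0, (0, 0, 0)), _carbon(1, (0, 0, 0))]))
    assert dup == pytest.approx(one, rel=1e-6)


def test_volume_grid_convergence():
    rng = np.random.default_rng(3)
    atoms = [_carbon(i, rng.uniform(-2, 2, 3)) for i in range(5)]
    conf = ConformerRecord(name="blob", atoms=atoms)
    v2 = molecular_volume(conf, grid_spacing=0.2)
    v1 = molecular_volume(conf, grid_spacing=0.1)
    assert abs(v2 - v1) / v1 <= 0.005


def test_volume_unknown_element():
    atoms = [AtomRecord(0, "FE", "FE1", "LIG", 1, "L", np.zeros(3))]
    with pytest.raises(ValueError, match="van der Waals"):
        molecular_volume(ConformerRecord(name="fe", atoms=atoms))


# ---------------------------------------------------------------------------
# Screening and pose agreement
# ---------------------------------------------------------------------------

def test_screen_planted_hits(ref_model):
    lib = make_conformer_library(10, ref_model, hit_fraction=0.1, seed=2)
    report = screen(lib, ref_model)
    assert len(report.hits) == 1
    assert report.hit_compounds == {"HIT000"}
    assert {e.status for e in report.entries} <= {"hit", "no_match"}


def test_screen_volume_filter_precedes_matching(ref_model):
    conf = _exact_conformer(ref_model)
    # a big slab of carbons: volume far beyond the ceiling, yet a perfect match
    rng = np.random.default_rng(0)
    big_atoms = list(conf.atoms)
    k = len(big_atoms)
    for x in np.arange(0, 12, 1.7):
        for y in np.arange(0, 6, 1.7):
            big_atoms.append(_carbon(k, (x, y, 8.0)))
            k += 1
    big = ConformerRecord(name="big", atoms=big_atoms,
                          feature_points=conf.feature_points)
    report = screen([big], ref_model)
    assert report.entries[0].status == "volume"
    assert report.entries[0].volume > 270.0
    assert report.entries[0].match is None


def test_pose_agreement_boundaries(ref_model):
    conf = _exact_conformer(ref_model)
    res = match(ref_model, conf)
    docked = Pose(label="d", atoms=[a.copy() for a in conf.atoms])
    rmsd, selected = pose_agreement(docked, res, conf)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert selected
    # shifted 5.2 Å: the discard regime
    far = Pose(label="f", atoms=[AtomRecord(a.index, a.element, a.name,
                                            a.residue_name, a.residue_number,
                                            a.chain, a.coords + [5.2, 0, 0])
                                 for a in conf.atoms])
    rmsd, selected = pose_agreement(far, res, conf)
    assert rmsd == pytest.approx(5.2, abs=1e-9)
    assert not selected
    # exactly at the boundary: strict "<" rejects
    edge = Pose(label="e", atoms=[AtomRecord(a.index, a.element, a.name,
                                             a.residue_name, a.residue_number,
                                             a.chain, a.coords + [1.5, 0, 0])
                                  for a in conf.atoms])
    rmsd, selected = pose_agreement(edge, res, conf)
    assert rmsd == pytest.approx(1.5, abs=1e-12)
    assert not selected


# ---------------------------------------------------------------------------
# Building from trajectories
# ---------------------------------------------------------------------------

def test_build_single_planted_donor_hbond():
    """One ligand-donor hydrogen bond at 95% gives a single HBD feature at
    the donor atom's mean position."""
    spec = PlantSpec(interactions=[
        (("A", 83, "GLU"), "hbond", 0.95),
        (("A", 85, "LEU"), "hbond", 0.0),
        (("A", 20, "PHE"), "pi_stack", 0.0),
        (("A", 135, "LEU"), "hydrophobic", 0.0),
        (("A", 52, "GLU"), "salt_bridge", 0.0),
    ], n_frames=300, seed=13)
    traj = make_trajectory(spec)
    feats = build_features(profile_trajectory(traj), traj)
    assert [f.kind for f in feats] == ["HBD"]
    np.testing.assert_allclose(feats[0].center, [6.0, 0.0, 0.0], atol=0.05)


def test_build_merges_hydrophobic_and_keeps_aromatic(small_traj):
    model = build_model(profile_trajectory(small_traj), small_traj)
    kinds = [f.kind for f in model.features]
    assert kinds.count("Aro") == 1
    assert kinds.count("HBA") == 1 and kinds.count("HBD") >= 1
    # the ring's stacking and its packing contact resolve to co-positioned
    # Aro + Hyd centers (the dual-element situation)
    aro = next(f for f in model.features if f.kind == "Aro")
    hyds = [f for f in model.features if f.kind == "Hyd"]
    assert any(np.linalg.norm(h.center - aro.center) < 0.5 for h in hyds)


def test_build_feature_center_recovery_across_seeds():
    """Planted anchor positions are recovered within 0.2 Å over 10 seeds."""
    expected = {"HBD": np.array([6.0, 0.0, 0.0]),    # ligand amine
                "HBA": np.array([-6.0, 0.0, 0.0]),   # ligand carbonyl
                "Aro": np.array([0.0, 0.0, 0.0])}    # ring centroid
    for seed in range(10):
        spec = PlantSpec(interactions=[
            (("A", 83, "GLU"), "hbond", 0.9),
            (("A", 85, "LEU"), "hbond", 0.9),
            (("A", 20, "PHE"), "pi_stack", 0.4),
            (("A", 135, "LEU"), "hydrophobic", 0.6),
            (("A", 52, "GLU"), "salt_bridge", 0.0),
        ], n_frames=400, seed=seed)
        traj = make_trajectory(spec)
        feats = build_features(profile_trajectory(traj), traj)
        by_kind = {}
        for f in feats:
            by_kind.setdefault(f.kind, []).append(f)
        for kind, target in expected.items():
            centers = [f.center for f in by_kind[kind]]
            assert min(np.linalg.norm(c - target) for c in centers) < 0.2


def test_build_empty_when_nothing_relevant():
    spec = PlantSpec(interactions=[
        (("A", 83, "GLU"), "hbond", 0.05),
        (("A", 85, "LEU"), "hbond", 0.0),
        (("A", 20, "PHE"), "pi_stack", 0.0),
        (("A", 135, "LEU"), "hydrophobic", 0.0),
        (("A", 52, "GLU"), "salt_bridge", 0.0),
    ], n_frames=50, seed=1)
    traj = make_trajectory(spec)
    feats = build_features(profile_trajectory(traj), traj)
    assert feats == []
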