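# dynopharm

Dynamic noncovalent interaction profiling, pharmacophore generation and
virtual screening for structure-based drug discovery.

In target-based screening campaigns against kinases such as CK1ε, the binding
mode of an inhibitor is rarely a single static picture: hydrogen bonds to the
hinge persist in nearly every trajectory frame while ring stacking and
hydrophobic packing come and go. `dynopharm` implements the post-docking /
post-MD half of such a campaign:

- **Interaction detection** — geometric detectors for hydrogen bonds,
  hydrophobic contacts, π-stacking (parallel and T-shaped) and salt bridges,
  frame by frame, with PLIP-style default cutoffs and template/connectivity
  atom typing that works with or without explicit hydrogens.
- **Dynamic interaction profiles** — per-residue, per-type *occurrence*
  tables: the fraction of trajectory frames in which a contact is present at
  least once, `occ(r, τ) = 100 · |{t : contact (r, τ) in frame t}| / T`,
  rounded half-away-from-zero to two decimals.
- **Dynamic pharmacophores** — interactions occurring in **> 20 %** of frames
  become typed spheres (HBA / HBD / Aro / Hyd) centered on the mean
  ligand-side anchor, with co-located dual elements (one position, either
  kind, counted once) and Pharmit-style JSON serialization.
- **Screening** — conformers with van der Waals volume **> 270 Å³** are
  eliminated, then an exhaustive rigid-assignment matcher requires at least
  `min_match` (default 6) positionally distinct elements, every residual
  within the feature radius after a least-squares rigid fit. A
  pharmacophore-placed conformer can be compared with a docked pose
  (selected when heavy-atom RMSD **< 1.5 Å**, no re-fit).
- **Consensus docking analysis** — pairwise in-place heavy-atom RMSD,
  complete-linkage hierarchical clustering cut at **2.0 Å** (every subcluster
  pair mutually below the cutoff), largest-subcluster medoid as the consensus
  binding mode.
- **Trajectory analytics** — backbone RMSD series (Kabsch superposition),
  per-residue Cα RMSF about the iteratively superposed time average, and
  salt-bridge prevalence for residue pairs such as Lys38–Glu52.

A fully seeded synthetic module (`dynopharm.synthetic`) generates toy
pockets, trajectories with planted per-frame interaction probabilities, pose
sets with planted binding modes, and conformer libraries with known hits —
every fixture the test-suite needs, no downloads.

## Worked example

```python
from dynopharm.dynprofile import (profile_trajectory, relevant_interactions,
                                  salt_bridge_prevalence)
from dynopharm.pharmacophore import build_model, screen
from dynopharm.synthetic import (default_plant_spec, make_trajectory,
                                 make_conformer_library)

traj = make_trajectory(default_plant_spec(n_frames=2000, seed=42))
profile = profile_trajectory(traj)
for rkey, itype, pct in relevant_interactions(profile, threshold_percent=20.0):
    print(f"{rkey[2]}{rkey[1]:>3} {itype:<12} {pct:6.2f}%")

model = build_model(profile, traj, threshold=20.0, min_match=6)
print("features:", ", ".join(f"{f.name}({f.kind})" for f in model.features))

library = make_conformer_library(50, model, hit_fraction=0.1, seed=42)
report = screen(library, model, volume_max=270.0, min_match=6)
print(f"hits: {sorted(report.hit_compounds)} of {len(library)} conformers")
print(f"Lys38-Glu52 bridge prevalence: "
      f"{salt_bridge_prevalence(traj, ('A',38,'LYS'), ('A',52,'GLU')):.2f}%")
```

prints

```
LEU 85 hbond         99.05%
GLU 83 hbond         96.05%
LEU135 hydrophobic   61.25%
PHE 20 hydrophobic   37.65%
PHE 20 pi_stack      37.65%
GLU 52 hbond         21.30%
GLU 52 salt_bridge   21.30%
features: HBA1(HBA), HBD1(HBD), Aro1(Aro), HBD2(HBD), Hyd1(Hyd), Hyd2(Hyd)
hits: ['HIT000', 'HIT001', 'HIT002', 'HIT003', 'HIT004'] of 50 conformers
Lys38-Glu52 bridge prevalence: 51.10%
```

The profile recovers the planted occupancy regime (hinge hydrogen bonds
nearly constitutive at ~99 % and ~96 %, stacking intermittent, the charge
pair just over the relevance threshold); only the cells above 20 % become
pharmacophore features, the ring's stacking and packing contacts resolving to
co-positioned Aro + Hyd centers; screening the 50-conformer library returns
exactly the five planted hits.

## Command line

The `dynopharm` console script wires the pipeline end to end, one
subcommand per stage, each writing its outputs plus a JSON run manifest:

```sh
dynopharm simulate      --out sim --seed 3
dynopharm profile       --traj sim/trajectory.pdb --topology sim/pocket.pdb --out prof
dynopharm build-model   --traj sim/trajectory.pdb --topology sim/pocket.pdb --out model
dynopharm screen        --library sim/library.sdf --model model/model.json --out hits
dynopharm cluster-poses --poses sim/poses.sdf --out clusters
dynopharm traj-metrics  --traj sim/trajectory.pdb --topology sim/pocket.pdb --out metrics
dynopharm saltbridge    --traj sim/trajectory.pdb --topology sim/pocket.pdb \
                        --res-a A:38:LYS --res-b A:52:GLU --out bridge
```

Formats: multi-model PDB for structures/trajectories, SDF V2000 for poses and
conformer libraries (scores and feature points in data fields), Pharmit-style
JSON for pharmacophores, CSV for profiles and series.

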