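# Methods

## Scope and model

`dynopharm` treats a protein–ligand complex as a fixed topology (atoms,
bonds, ligand membership, formal charges) plus per-frame Cartesian
coordinates in Å. All analyses are geometric: no force field, no energies.
The pipeline is

1. detect noncovalent contacts per frame,
2. aggregate them into a per-residue, per-type *occurrence* profile,
3. convert high-occurrence cells into a 3D pharmacophore,
4. screen conformer libraries against that pharmacophore,

with consensus clustering of docking poses and backbone RMSD / Cα RMSF /
salt-bridge analytics alongside.

## Interaction detectors

Contacts are detected independently per frame from distances and angles
only, so every detector is exactly invariant under global rigid motion.
Boundary conventions are fixed for testability: distance cutoffs are strict
(`<`), angle minima are inclusive (`≥`), so tightening any cutoff can only
remove events.

| criterion | default | meaning |
|---|---|---|
| `hbond_max_da` | 4.1 Å | donor–acceptor heavy-atom distance |
| `hbond_min_donor_angle` | 100° | D–H···A angle at the hydrogen, when H is explicit |
| `hydrophobic_max` | 4.0 Å | apolar-carbon pair distance |
| `pistack_max_centroid` | 5.5 Å | ring-centroid distance |
| `pistack_max_angle_dev` | 30° | interplanar deviation from 0° (parallel) or 90° (T) |
| `pistack_max_offset` | 2.0 Å | in-plane centroid offset (min of the two ring projections) |
| `saltbridge_max` | 5.5 Å | charged-group centroid distance |
| `pication_max` | 6.0 Å | reserved for the π–cation type |

The defaults mirror the published defaults of the PLIP profiler, the
standard tool for this kind of contact analysis; all are configurable per
run. The `pi_cation` type is declared in the vocabulary but has no detector;
the frame aggregator is the union of the four implemented detectors.

**Atom typing.** Protein atoms are typed by template tables for the twenty
standard residues (backbone N donor except proline, backbone O/OXT acceptor;
side-chain donors/acceptors; apolar side-chain carbons; His/Phe/Tyr/Trp
rings; Lys/Arg cationic and Asp/Glu anionic groups). Ligand atoms are typed
from connectivity: a carbon is apolar when it has no N/O/S/P neighbor; N/O
with a bound hydrogen donate; N/O accept unless quaternary or positively
charged; rings come from the bond-graph cycle basis (sizes 5–7) and count
as aromatic in a frame when their atoms lie within 0.3 Å RMS of the best-fit
plane. Charged ligand groups are the atoms with nonzero formal charge.

**Hydrogen-free structures.** Toy fixtures and many deposited structures
carry no hydrogens. Detection then falls back to the heavy-atom
donor–acceptor distance with no angle test, and any ligand N/O may donate.
The ligand's role in a hydrogen bond (needed to decide HBA vs HBD features)
is resolved from the protein partner's template role — a backbone carbonyl
can only accept, so the ligand must be donating. When both sides could play
either role the event is recorded with role `either` and contributes to both
acceptor and donor tallies during pharmacophore building.

**Deduplication.** Hydrophobic contacts collapse to one event per residue
per frame (the closest atom pair); hydrogen bonds keep one event per heavy
pair. Occurrence counting (below) further collapses to presence/absence per
(residue, type) cell per frame.

## Occurrence profiles

For trajectory frames t = 1…T, a cell (residue r, type τ) scores the number
of frames with ≥ 1 qualifying event; event multiplicity within a frame is
deliberately ignored, since occupancy is reported as "conformations out of
T". Percentages are 100·count/T rounded half-away-from-zero to two
decimals (`decimal` arithmetic, no binary-float rounding artifacts).
*Relevant* interactions are those strictly above the threshold (default
20 % of simulation time).

## Trajectory metrics

- **Backbone RMSD**: each frame is superposed on the reference frame
  (default: first frame, configurable) over N/CA/C/O by a least-squares
  rigid fit (SVD Kabsch with determinant correction), then the RMSD over
  those atoms is taken. The tests cross-check the fit against an independent
  Horn quaternion superposition to 10⁻⁶ Å.
- **Cα RMSF**: frames are aligned to the time-average backbone by a two-pass
  iterative fit (align to frame 0, average, re-align to the average,
  re-average), then RMSF_i = √⟨|r_i(t) − ⟨r_i⟩|²⟩ per Cα. Superposition can
  be disabled for closed-form checks (isotropic jitter of σ per axis gives
  RMSF = σ√3).
- **Salt-bridge prevalence**: the percent of frames in which the
  template-charged groups of two named residues sit within the salt-bridge
  cutoff.

## Pose consensus clustering

Poses from multiple search-algorithm/scoring-function combinations share one
receptor frame, so pose–pose RMSD is computed over heavy atoms **without**
re-superposition and without symmetry-equivalent atom remapping (poses come
from one engine run on one input molecule; automorphism handling is a
possible extension). Clustering is complete-linkage hierarchical clustering
(scipy) cut just below the cutoff (default 2.0 Å): complete linkage is the
only criterion that guarantees, by construction, that every pair inside a
subcluster is mutually below the cutoff, which is the property the consensus
analysis relies on. The representative is the medoid (minimum mean RMSD to
the other members), ties broken by best docking score (lower = better), then
lowest index; size ties between clusters break toward the better mean score.

## Pharmacophores

**Building.** Every relevant cell maps to a feature: ligand-donor hydrogen
bonds → HBD, ligand-acceptor → HBA, π-stacking → Aro, hydrophobic → Hyd
(salt-bridge cells carry no sphere type in this feature vocabulary). The
center is the mean, over qualifying frames, of the ligand-side anchor (donor
or acceptor atom, ring centroid, or the closest apolar carbon). Hydrophobic
cells whose anchors lie within a merge radius (default 1.5 Å) collapse into
one Hyd feature with an occurrence-weighted center, because several residues
typically pack against one ligand moiety. The default feature radius is
1.0 Å (per-feature configurable); tolerances of that order are the common
choice in interactive pharmacophore tools.

**Co-location and min_match.** Two features may share one position
(`colocation_group`): either kind satisfies the position and it counts once
toward the match minimum. Counting duals once avoids double-weighting a
single spatial constraint. Consequence worth noting: an 8-element model with
two duals has 6 distinct positions, so `min_match = 6` demands *all*
positions; a submodel that drops a dual whole (e.g. removing its aromatic
member removes the partner too) has 5 positions and needs an explicit
`min_match` override to be satisfiable. Which variant a screen should use is
a campaign decision, so it is exposed as a parameter everywhere.

**Matching.** Conformer feature points are either supplied (pre-annotated
libraries) or perceived with the same typing rules as the detectors. The
matcher searches all injective assignments of model positions to
kind-compatible points, pruned by pairwise distance compatibility
(|Δmodel − Δconformer| ≤ r_i + r_j, a necessary condition for any rigid fit
to land both pairs inside their radii). Each candidate of sufficient size is
evaluated by a least-squares rigid fit of the assigned points onto the
position centers and accepted when every residual is ≤ its radius (with a
10⁻⁹ slack for float noise). The largest accepted assignment wins; ties
break toward the lowest total deviation. A single-pair assignment is fitted
by translation only. The search is exhaustive, so it agrees with a
brute-force enumeration on every instance; with ≤ 10 positions and ≤ 20
points it runs in milliseconds.

**Volume filter.** The van der Waals molecular volume uses Bondi radii on a
regular grid (default 0.2 Å): voxels clearly inside/outside the sphere union
(center beyond half the voxel diagonal from the surface) count fully,
boundary voxels are refined on a 4×4×4 sub-grid. The estimate is within
~0.2 % of the analytic single-sphere volume at the default spacing and
changes ≤ 0.5 % when the spacing halves. Screening eliminates conformers
with volume strictly greater than the ceiling (default 270 Å³, the size
restriction of a kinase catalytic site) *before* matching — the cheaper
filter runs first. Pose agreement applies the match transform to the
conformer and selects when the heavy-atom RMSD to the docked pose is
strictly below 1.5 Å, with no re-fit.

**Reference model.** `assemble_reference_model()` packages the published
eight-element inhibitor pharmacophore layout (HBA + 2 HBD at the
hinge/adenine region, an Aro/Hyd dual at the phosphate region, a Hyd/Aro
dual in the buried region, and a third Hyd at the aliphatic lysine contact).
Its coordinates are synthetic: the source describes the element types,
co-locations and triangular arrangement but not coordinates, so the
packaged geometry is a constructed stand-in with realistic spacing.

## Synthetic data

The generator builds a minimal pocket — six standard-residue fragments
(hinge donor and acceptor backbones, a Phe-like ring, a Leu-like apolar side
chain, a Lys/Glu charge pair) around a ten-atom ligand whose fragments each
face one partner — and toggles each planted interaction per frame: "on"
keeps the base geometry, "off" displaces the ligand fragment along the
partner axis to the detector cutoff + 2 Å, so Gaussian thermal jitter
(default σ = 0.03 Å per axis) can never flip a contact across its boundary
and planted Bernoulli probabilities are exact. Pose sets place rigid copies
of the ligand around planted modes (jitter = RMS displacement magnitude, so
same-mode pose pairs sit well inside a 2 Å cutoff at the default 0.3 Å) with
the 12-combination × 8-run label scheme at 96 poses; the dominant mode also
receives the best scores. Conformer libraries plant hits (one point per
model position, within 0.4 × radius, rigidly scrambled) and decoys that
carry only `min_match − 1` feature points and therefore cannot match
regardless of geometry. All randomness flows from one
`numpy.random.default_rng(seed)`, making every fixture bit-reproducible.

The default planted probabilities (hinge hydrogen bonds 0.99/0.97, stacking
0.38, hydrophobic 0.63, charge pair 0.21, inter-residue bridge 0.5) emulate
the occupancy regime of a stable kinase–inhibitor complex: near-constitutive
hinge anchoring with intermittent peripheral contacts.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: solvent, conformational strain, correlated
motions, realistic protein flexibility (only isotropic jitter), chemistry
(decoys are not valid molecules; fragments are not bonded into one ligand),
protonation equilibria, and the tautomer/conformer enumeration a production
library would need. Tests demonstrate that the *measurement machinery* is
correct and calibrated, not that the pipeline's biological conclusions
transfer.

## Problem sizes

The test-suite and acceptance script run at desk scale, chosen so the full
suite completes in about a minute: 50 randomized instances per oracle
comparison, planted-probability recovery over 10 seeds × 2 000 frames
(checked within 3 binomial standard errors of the mean), 96-pose sets over
5 seeds, 50-conformer libraries over 3 seeds. Production-scale inputs
(15 000-frame trajectories, tens of thousands of conformers) use the same
code paths; profiling cost is linear in frames (~0.3 ms/frame on the toy
pocket).

## Known limitations

- No π–cation, halogen-bond, water-bridge or metal-coordination detectors.
- Protein typing covers the 20 standard residues only; modified residues
  need ligand-style connectivity input.
- PDB parsing handles ATOM/HETATM/MODEL/ENDMDL/CONECT with element and
  charge columns; no insertion codes, altlocs or multi-character chains.
- `pose_rmsd` requires identical atom ordering (no graph-automorphism
  matching).
- The matcher's exhaustive search is exponential in model size; it is meant
  for pharmacophores of ≤ ~10 positions, the practical regime.
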