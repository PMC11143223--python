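# Methods

## Scope and model of the data

`kinalysis` analyses the *outputs* of docking and molecular-dynamics pipelines
for kinase–inhibitor systems — structures and frame series as PDB text, docking
scores and interaction annotations as delimited tables, externally computed
energy series as plain numbers. It computes no force-field energies, docking
scores or folding ΔΔG values itself; those are inputs.

Coordinates are in Å, right-handed, taken as stored. No periodic-boundary
handling is performed: trajectories are expected to be imaged, whole-molecule
snapshots. All user-facing residue numbers are in the original (crystal)
numbering; `ResidueMap` translates to and from renumbered-from-1 MD schemes
(the packaged CSF1R map is a uniform offset of 548, i.e. residue 606 ↔ 58).

## Distance-profile analysis (Δd, ΔΔd)

For every protein residue, the distance from the residue's *backbone point* to
the *protein center* is averaged over a frame window:

- backbone point: geometric centroid of N, CA, C, O (default), or the
  α-carbon alone (`residue_point_rule="CA"`);
- protein center: mass-weighted mean of protein heavy atoms (default) or the
  unweighted centroid, recomputed per frame; hetero atoms and hydrogens never
  contribute;
- window: the last 40 % of frames by default (the equilibrated tail — e.g. the
  last 800 of 2000 snapshots), overridable.

Binding-induced change is Δd = d(bound) − d(free) per residue; negative values
mean the residue moved toward the center. The impact of a mutation on
ligand-binding response is ΔΔd = Δd(mutant) − Δd(wild type), labelled

| |ΔΔd| | label |
|---|---|
| ≤ 1.5 Å | unaffected |
| > 1.5 Å and ≤ 2.0 Å | slight |
| > 2.0 Å | significant |

Both comparisons are strict: exactly 1.5 Å is unaffected and exactly 2.0 Å is
slight. The thresholds sit between the length scale of a hydrogen bond (~2 Å)
and of a hydrophobic contact (~4 Å), i.e. the displacement at which a residue
can plausibly gain or lose an interaction. Whether the center is mass-weighted
or geometric is not critical for globular systems; mass weighting is the
default and both inputs must use the same rule before profiles are compared.

Replicate trajectories are averaged as if their windows were concatenated:
the replicate-mean profile is the mean of means, and the pooled variance is
the mean within-replicate variance plus the variance of the replicate means
(exact for equal-length windows; asserted exactly in the tests).

## DFG-state classification

Two α-carbon distances diagnose the kinase conformational state:
d1 from the HRD-motif aspartate (CSF1R 783) to the DFG phenylalanine (797),
and d2 from the conserved αC-helix glutamate (633) to the same phenylalanine.

- d1 < d2 → inactive (DFG-out); d1 > d2 → active (DFG-in); exact equality is
  reported as `boundary` rather than guessed.
- Within the inactive state, d1 < 7.2 Å **and** d2 > 9.0 Å (both strict) is
  the classical DFG-out geometry; any other inactive geometry is
  `nonclassical_out`.
- d2 > 10.5 Å raises the αC-out flag. The flag is an independent annotation,
  not a class of its own: a classical DFG-out structure (e.g. d1 = 7.07,
  d2 = 10.55) is simultaneously αC-out, and the package reports both facts
  rather than forcing a single label.

Classification operates on window-mean distances (the values a results table
prints), not on per-frame majority votes; `dfg_distances` on a trajectory
returns the mean ± SD over the window.

## Geometric interaction detection

The detectors make explicit, configurable criteria out of what structure
viewers apply implicitly:

- **Ring perception.** Protein aromatic rings come from atom-name templates
  (PHE/TYR 6-ring, TRP fused 5- and 6-rings, HIS 5-ring). Ligand rings are
  perceived from a heavy-atom bond graph (pair distance ≤ 1.6 Å, suited to
  inputs without connectivity records) via minimum cycle basis, keeping 5- and
  6-cycles planar to within 0.3 Å. Planarity plus ring size stands in for
  aromaticity — adequate for idealized and docked small molecules, wrong for
  saturated near-planar rings (a known limitation).
- **π–π stack**: centroid–centroid distance ≤ 5.5 Å, interplanar angle ≤ 30°,
  lateral offset ≤ 2.5 Å. The lateral offset is the smaller of the two
  components of the centroid displacement perpendicular to either normal,
  which keeps detection symmetric in the two rings.
- **π–T shape**: centroid–centroid distance ≤ 6.0 Å, interplanar angle
  60–90°. Centroid-to-centroid (not centroid-to-edge) distance is used, and
  angles are folded to [0°, 90°].
- **Hydrogen bond**: donor (N/O) to acceptor (N/O) distance in [2.0, 3.5] Å;
  when the donor hydrogen is present, D–H···A angle ≥ 120° as well. Docked
  poses often lack hydrogens, so the distance-only fallback is applied (and
  logged) when no hydrogen sits within 1.3 Å of the donor.
- **Halogen bond**: carbon-bound F/Cl/Br/I to O/N/S acceptor, X···A ≤ 3.5 Å,
  C–X···A angle ≥ 140°.

All gates are strict pure predicates of the geometry, so perturbing a pose
across a threshold flips detection exactly there; all detectors are invariant
under global rigid motion. Records may carry a nominal π-energy annotation as
metadata only; no energy model is computed.

## Cohort statistics

Group means are plain arithmetic means of docking scores (reported at four
decimals). The affinity cut-off is the mean over all ligands, or an explicit
value — the packaged reference cut-off (−10.0871 kcal/mol) is supplied as a
constant because the direct mean of the packaged 31 scores is −10.0729 and a
published cut-off need not be recomputable from a published table. "Passing"
the cut-off means a score strictly more negative than it (no packaged score
equals the cut-off, so the boundary choice is inert for the reference data).
Residue-contact frequency rows count ligands with any matching
(residue, kind) annotation, split by group and cut-off side.

The folding-stability rule labels an alanine-scan ΔΔG stabilizing in
[−5, −0.75] kcal/mol, destabilizing strictly above +1 kcal/mol, neutral
otherwise. Energy-series comparison is a two-sample Student's t-test
(equal-variance by default, Welch by flag) at α = 0.05 on externally computed
series.

## Synthetic systems and what they do (not) show

The toy kinase lays N/CA/C/O backbones on a smooth helical curve spanning
residues 540–800, overrides the three diagnostic Cα positions so the realized
d1/d2 match their targets to 1e-6 Å, and attaches a planar TRP-like 6-ring at
residue 550. Ligand poses are ideal aromatic hexagons placed at an exact
centroid distance / interplanar angle / lateral offset from the site ring.
Trajectories add a planted radial displacement (per-residue, outward from the
protein center) and isotropic per-atom Gaussian noise (default SD 0.3 Å over
800 frames, the scale of a converged, well-behaved simulation tail).
Docking cohorts draw scores from Normal(−10, 1) kcal/mol with a planted
−1.5 kcal/mol bonus for ligands annotated with the chosen residue contact
(contact probability 0.4 / 0.3 for the two groups).

The generators are pure functions of their specs (seed included) and always
emit the ground truth next to the data. They deliberately omit everything a
force field would add: no Ramachandran realism, no correlated fluctuations, no
solvent. Recovery results on these systems therefore demonstrate that the
*analysis chain* is correct and sensitive at the stated noise level — not that
real MD noise (which is temporally and spatially correlated) would behave
identically. A mutant-only 3.0 Å planted shift on residues 603–609 under
0.3 Å noise and an 800-frame window is recovered exactly (the expected margin
is m − 2σ/√n ≫ 2.0 Å); shrinking the margin toward the threshold will produce
boundary misses, as it should.

## Numerical choices

- Superposition is least-squares (Kabsch); degenerate (collinear or < 3-point)
  inputs are rejected rather than silently resolved. RMSD series fit each
  frame to the first frame by default over backbone atoms N, CA, C, O.
- RMSF aligns frames to the window-mean structure with a single pass (mean of
  raw frames → align → re-mean), for determinism.
- Masses are standard atomic masses by element; an unknown element falls back
  to unit mass with a warning.
- SDs use the population convention (ddof = 0) so replicate pooling is exact.
- PDB coordinates round-trip at the format's three decimals; alternate
  locations other than blank/'A' are dropped with a logged count; insertion
  codes are rejected.
- The RMSD stability threshold (3.0 Å) only flags frames in the report; the
  package does not interpret a trajectory as "stable" or "unstable".

## Known limitations

- Single-character chain IDs, PDB v3.3 fixed columns only; no mmCIF, no
  binary trajectory formats (convert upstream).
- Aromaticity is geometric (planarity + ring size), not electronic.
- Interaction criteria reproduce common viewer defaults, not any specific
  program's output; per-ligand annotation fixtures shipped with the package
  are a synthetic assignment consistent with published marginal counts (see
  `kinalysis.fixtures`).
- The impact-call thresholds are fixed geometric cut-offs; no statistical test
  is attached to per-residue differences.
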