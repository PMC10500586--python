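# Methods

This note documents the models and procedures implemented in `ensemblevs`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducibility.

## Scope and inputs

The package covers the *post-simulation* and *triage* stages of an
ensemble-based virtual-screening workflow. Docking scores, MM-GBSA component
energies and ADME predictions are **inputs** (per-compound tables); receptor
trajectories are inputs as multi-model PDB (or generated synthetically).
Force-field evaluation, docking, MD integration and ADME prediction models
are out of scope by design.

## Trajectory metrics

**Superposition.** RMSD uses least-squares rigid superposition (Kabsch, via
SVD of the 3×3 cross-covariance). The returned rotation is always proper;
reflection is corrected by flipping the smallest singular direction. RMSD is
evaluated from the actual residuals of the fitted coordinates rather than
the trace identity, which keeps exact zeros at ~1e-12 instead of the ~1e-8
cancellation floor of the closed form. Inputs with fewer than three points
or collinear geometry raise a degeneracy error — the rotation is not
identifiable there.

**Ligand RMSD** is a binding-pose RMSD: frames are fitted on the protein
alpha-carbons and deviation is measured over ligand heavy atoms, i.e.
ligand movement in the receptor frame. **RMSF** is taken about the mean
structure with a two-pass alignment (fit to frame 0, average, re-fit to the
mean); the fit selection may exclude mobile tails while still reporting
them. This satisfies the identity
Σ_residues RMSF² = ⟨Σ_atoms |Δr|²⟩ under the common alignment.

**Convergence** is a two-window drift test: the series is converged when
the means of the last and penultimate windows differ by at most
`drift_tol` (default 0.3 Å; default window = last 25 % of frames). Visual
"flat plot" judgements have no standard quantitative form; the two-window
rule is the simplest monotone surrogate and both knobs are exposed. The
trajectory segment over which summary means are taken is likewise a
parameter rather than a hard-coded choice.

## Conformational ensemble

The pairwise backbone RMSD matrix (batched Kabsch over all frame pairs;
pair-for-pair equal to the scalar routine) feeds average-linkage
agglomerative clustering cut at a **2 Å merge distance**. Abundances are
fractions of all clustered frames; clusters under the **2 % abundance
floor** are dropped from reports only — assignments keep every frame, so
abundances always sum to 1 pre-floor. The floor is applied at reporting
time (whether it should apply before or after merging is not specified
anywhere authoritative; reporting-time flooring never changes the tree).
Each cluster is represented by its **centroid frame** — the member with the
most same-cluster neighbors within a cutoff that defaults to the merge
cutoff. All tie-breaks (cluster labelling, centroid selection) resolve to
the lowest frame index, making runs reproducible. The workflow clusters the
last half of frames by default, mirroring the practice of discarding the
equilibration-dominated first part.

**Elastic-network modes.** An anisotropic network model on the
alpha-carbons with uniform unit springs inside a 15 Å cutoff (a
conventional ANM default; the upstream tool's setting is undocumented).
The 3N×3N Hessian is assembled from −(d dᵀ)/|d|² blocks and
eigendecomposed; the rigid-body modes (6 for any non-collinear network, 5
for a dimer) are identified by a relative 1e-8 eigenvalue tolerance and
discarded; the lowest 10 nontrivial modes are reported, eigenvalues
ascending, eigenvectors orthonormal. A disconnected network at the chosen
cutoff is an error instructing a larger cutoff. A finite-difference Hessian
of the explicit harmonic energy serves as an independent check in the tests.

## Dynamic network model

Nodes are residues (alpha-carbon positions) plus one ligand node (geometric
center of ligand heavy atoms; all ligand heavy atoms are used for
contacts). An edge exists where the minimum heavy-atom distance between two
nodes is ≤ **4.5 Å in ≥ 75 %** of frames (inclusive thresholds);
sequence-adjacent residues (|i−j| ≤ 1) are excluded to avoid trivial
backbone edges (configurable).

Correlations use the **normalized displacement covariance** with the vector
dot-product convention,

    C_ij = ⟨Δr_i · Δr_j⟩ / sqrt(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩),

computed after superposing all frames onto the mean structure (two-pass, on
alpha-carbons), Δr being the node displacement from its trajectory mean.
This is the established definition for this family of network models; the
scalar-product alternative would only change |C| marginally for isotropic
motion. Zero-variance nodes are flagged and their correlations set to 0.

Edge weights are `w_ij = −log |C_ij|` in **natural log**; the base only
rescales all weights uniformly and therefore leaves optimal paths and
communities invariant (recorded in the graph metadata). Edges with
|C| < 1e-6 are dropped with a warning instead of carrying effectively
infinite weight.

**Communities** come from a Girvan–Newman sweep: repeatedly remove the edge
of highest betweenness (betweenness computed with w as distance; ties break
to the lexicographically smallest edge), recording each level at which the
component count grows. The returned partition is the level maximizing
modularity, computed with |C| as the edge strength; exact ties prefer the
coarser level, so a uniform complete graph stays one community.
**Critical nodes** are the endpoints of inter-community edges (the node
convention is reported, not edge pairs — published counts are ambiguous on
this and the definition is stated here for that reason). **Optimal paths**
are minimum-total-weight paths (Dijkstra); among equal-weight optima the
lexicographically smallest node sequence is returned; disconnected
endpoints yield an explicit no-path result. Path overlap between two
systems counts shared interior residues (source and target excluded) and
the fraction of the reference path's interior that is shared.

## Interaction profiler

Geometric criteria are data (an editable config), not code, since the
upstream tool's internals are proprietary; the defaults are standard
literature values: hydrogen bond = donor–acceptor heavy-atom distance
≤ 3.5 Å **and** ≥ 120° at the donor between its bonded antecedent and the
acceptor (toy atoms carry no hydrogens, so the antecedent stands in for the
H direction); hydrophobic = apolar-carbon pair ≤ 4.0 Å; ionic = opposite
formal charges ≤ 4.0 Å; water bridge = one water within hydrogen-bond
distance of a polar protein atom and a polar ligand atom simultaneously.
Aromatic stacking and cation-π are folded into hydrophobic/ionic — the toy
atoms have no ring perception.

Event granularity: hydrogen bonds and ionic contacts count per qualifying
atom pair; hydrophobic contacts per (residue, ligand atom); water bridges
per (residue, water). The interaction fraction is events/frames, so
simultaneous contacts accumulate and fractions may exceed 1. The **30 %**
reporting threshold applies to the fraction summed over categories by
default (a per-category switch exists; the authoritative choice is
unstated upstream).

## Screening pipeline

`mmgbsa_total` accepts either representation — the state-energy difference
ΔG = E_complex − E_receptor − E_ligand, or the component sum
VDW + SUR + GBELE + ΔE_conf(receptor) + ΔE_conf(ligand) — and errors if
both are supplied and disagree beyond 1e-6 kcal/mol.

Drug-likeness **stars** count properties outside a user-editable range
table defaulting to the four Lipinski bounds (MW ≤ 500, HBD ≤ 5,
HBA ≤ 10, logP ≤ 5); the proprietary 24-property reference-range model it
replaces is structurally the same mechanism. Properties missing from a
record are skipped rather than penalized.

The **cascade** applies conjunctive gates in a configurable order (docking
≤ reference score; stars ≤ 1; MM-GBSA ≤ reference total; GI absorption
high; BBB permeant; zero PAINS and Brenk alerts). Comparisons use ≤ on
signed kcal/mol so the reference compound passes its own cutoffs; gate
order affects only the recorded first failure, never the surviving set.
CYP-inhibition flags are carried as annotations, not gates — the original
triage did not filter on them.

**Selectivity deltas** are Δ = score_receptor − original score per
compound; crystal ligands, which have no "original" screened score, are
referenced to their best (most negative) score across the receptor columns
— their native receptor. Column averages are taken over the screened
compounds and rounded half away from zero to one decimal, matching printed
conventions. In the bundled table the recomputed MOR score-column average
is −7.1 while the published table prints −7.2 (inconsistent with its own
column entries); the MOR score average is therefore computed but not used
as a reference value anywhere. The delta-column averages (1.8, 1.3, 2.4)
reproduce exactly.

**Scaffold clustering** uses hashed path fingerprints (RDKit, 2048 bits)
and Tanimoto similarity with average-linkage clustering cut at
1 − similarity_cutoff (default cutoff 0.7 — tight enough to separate
scaffolds, loose enough to merge homologs). The proprietary pharmacophore
fingerprint it stands in for differs in the descriptor, not the clustering
logic, which is what the pipeline preserves. Unparseable structures are
flagged and excluded (cluster id −1).

## Synthetic-data generator

The generator is first-class, tested code; it defines the conditions under
which every recovery claim is made.

**Geometry.** The receptor is an idealized alpha-helix of labelled points:
alpha-carbons at exactly 3.8 Å spacing (radius 2.3 Å, 100° twist, rise
solved from the spacing), plus side-chain pseudo-atoms packing toward the
i+3/i+4 turn so the deep i±3/i±4 contacts of a real helix exist — that
gives the contact network a realistic banded topology that survives the
planted motion. Residues cycle through an 8-residue chemical motif so
donors, acceptors and both charge signs are present; the ligand is a
compact blob against the outer face of an anchor residue (guaranteed within
4.5 Å of ≥ 3 residues); optional waters sit in a shell around the ligand so
water-bridge detection is exercisable.

**Substates.** Conformers are smooth low-rank deformations (sinusoidal
displacement fields along orthogonal axes) scaled iteratively to a
requested superposed CA-RMSD separation (default 5 Å — comfortably beyond
the 2 Å merge cutoff), with occupancies sampled per frame. Defaults mirror
the reference system's two abundant conformations at 75 %/25 %.

**Correlation blocks.** Each block carries a scalar latent per frame; the
displacement pattern within a block is a zero-mean sign profile (half the
residues +1, half −1 along a per-block axis) scaled by the coupling
(default 0.9 Å), plus isotropic per-atom noise (default 0.1 Å). The
zero-mean pattern is deliberate: a uniform per-block translation is largely
absorbed by the rigid superposition that precedes correlation analysis, and
its residuals are *anticorrelated across blocks* regardless of the planted
independence — internal (zero-mean) patterns survive superposition with
within-block |C| ≈ 0.95 and between-block |C| ≈ 0.3 (the remainder being
rotation-fit leakage). The ligand and waters ride with a designated block
at full amplitude.

**What the generator does not emulate:** side-chain chemistry and rotamers,
membrane and solvent physics, force-field energetics, anharmonic or
diffusive dynamics, realistic secondary-structure diversity. Passing
recovery tests therefore demonstrates that the *analysis chain* is correct
under its stated assumptions (separable substates, block-structured
internal motion, persistent contacts), not that it would resolve arbitrary
real-data ensembles.

**Screening tables** plant per-gate pass/fail outcomes by Bernoulli draws
per compound, placing values on the corresponding side of the planted
cutoffs (−8.6 / −90.2 kcal/mol defaults); MM-GBSA components are a
Dirichlet split of the planted total minus small conformational terms, so
the component sum is exact by construction. All generation is driven by a
single seeded stream per call; identical seeds give bit-identical outputs.

## Problem sizes and determinism

The recovery analyses run on toy systems chosen to make their statistics
stable: 24–30 residues, 300 frames for correlation/community recovery
(sample correlation noise ~1/√300 keeps spurious |C| well under planted
levels), 1000 frames for occupancy recovery (binomial sd ~1.4 % against
the ±5 % band). Oracle-equivalence checks use exhaustive enumeration on
graphs of ≤ 12 nodes (100 seeds) and O(n²) distance scans on 10-residue
toys. Every stochastic step takes an explicit integer seed; reruns of the
pipeline with the same configuration produce byte-identical outputs.

## Known limitations

* PDB round trips quantize coordinates to 1e-3 Å and do not preserve
  chemical roles — ground truth travels in a JSON sidecar.
* Girvan–Newman recomputes edge betweenness after every removal; fine for
  receptor-sized graphs (hundreds of nodes), not for thousands.
* Suboptimal-path ensembles, secondary-structure assignment and
  mutagenesis-database cross-referencing are not implemented.
* The interaction profiler's criteria are distance/angle heuristics on
  labelled points; they are not a substitute for chemistry-aware
  fingerprinting on real structures.
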