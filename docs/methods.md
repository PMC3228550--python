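# Methods

## The prediction problem

Most B-cell epitopes are conformational: the antigen residues an antibody
binds are close in space but scattered along the sequence, so they can only
be recognised from a folded 3D structure. `epitopepatch` frames the task as
binary classification of antigen **surface residues** (relative
accessibility above 5%). Each surface residue is represented by its local
spatial neighbourhood — a *patch* — and a voting ensemble of random forests
decides whether the patch centre is an epitope residue.

## Geometry and labelling

All residue-level geometry reduces to one primitive: the distance between
two residues is the **minimal Euclidean distance between any pair of their
heavy atoms**. Hydrogens are removed at parse time, alternate locations
resolve to the highest-occupancy conformer, selenomethionine maps to
methionine, and multi-model entries contribute model 1 only.

Given an antigen–antibody complex, an antigen residue is labelled
**epitope** when its distance to any antibody residue is strictly below
4 Å. The inequality is strict on both sides: a contact at exactly 4.000 Å
is a non-epitope. For unbound antigens, labels cannot be derived
geometrically and are read from a plain-text annotation file; the package
deliberately does not guess a bound→unbound mapping.

Interior residues (RASA ≤ 5%) are never patch centres and never training
instances, but they do receive distances and annotations for diagnostics.

## Solvent accessibility

SASA uses a deterministic Shrake–Rupley implementation: each atom's sphere
(van der Waals radius + 1.4 Å probe) is sampled with a 960-point Fibonacci
lattice and a point counts as accessible when outside every other
probe-expanded atom sphere. The point lattice is oriented in the
molecule's principal-axis frame (signs fixed by third moments), which
makes the estimate exactly invariant under rigid-body motion of the input
coordinates while staying fully deterministic. Per-residue SASA sums the
residue's atoms; by default only antigen chains form the molecular system,
so accessibility describes the free antigen rather than the complex.

Relative accessibility divides by the fully-exposed (Gly-X-Gly) reference
area of the residue type. The package ships the theoretical maximal-ASA
table of Tien et al. (2013) as a replaceable text resource; with a
different reference table the surface/interior split can shift slightly
for borderline residues.

At 960 points the discretisation quantum is ≈ 0.13 Å² per point on a
carbon sphere; per-residue agreement with a 4000-point run is within 3%
or 0.5 Å², whichever is larger.

## Patches

The patch of a surface residue contains the residue itself plus its n−1
nearest antigen neighbours by minimal heavy-atom distance, sorted
ascending, with ties broken by residue identity so feature vectors are
reproducible. Two neighbour pools are supported:

* **surface** patch — only surface residues are eligible neighbours;
* **thick** patch (default) — all antigen residues are eligible, so buried
  neighbours that pack beneath a site contribute. Because the candidate
  pool is a superset, a thick patch never reaches farther than the surface
  patch of the same centre.

The default patch size is n = 20 (sizes 12–20 are supported); the patch
size counts the central residue, so a patch carries 19 neighbours.

## Features: 7 values per patch residue

Each patch residue contributes, in fixed order: `[rasa, conservation,
ard, composition, ss_helix, ss_sheet, ss_coil]`, giving a 7·n vector per
patch (central residue first, then neighbours by ascending distance).

* **rasa** — relative accessibility as above.
* **conservation** — from the chain's PSSM (PSI-BLAST ASCII format,
  consumed as an input, never produced by running BLAST): with M the
  PSSM score of the position's own residue type and B the BLOSUM62
  diagonal entry for that type, the score is |M − B| when M < B and 0
  otherwise. Zero means "as conserved as expected or more"; larger values
  mean less conserved.
* **ard** — the adjacent-residue-distance weight. With d_i the distance of
  neighbour i to the centre and p_i = 1/d_i, neighbour i receives
  S(x_i) = p_i / Σ_j p_j. The n−1 weights sum to one and decrease strictly
  with distance, encoding that nearer neighbours matter more. The central
  residue's own slot is 0: the formula is defined over neighbours and 1/d
  is singular at d = 0, and the sentinel keeps the vector length at 7·n.
* **composition** — the fraction of the patch sharing the residue's
  amino-acid type. This is the one-dimensional per-residue reading of
  patch amino-acid composition; a 20-dimensional patch-level variant would
  change the vector layout and is intentionally not the default.
* **ss_\*** — one-hot 3-state secondary structure, order (helix, sheet,
  coil). DSSP files are the preferred source (8→3 collapse: H/G/I helix,
  E/B sheet, else coil); without a DSSP file a φ/ψ-window heuristic is
  used and logged — it is a documented approximation, not a DSSP
  re-implementation.

A per-residue **contact number** (count of other Cα atoms within 10 Å) can
be appended as an eighth slot for comparison experiments; it is off by
default because the thick patch already encodes packing.

## Imbalance strategy and classifier

Epitope residues are a small minority of surface residues. Rather than
reweighting, the ensemble balances by subsampling: the negative set A⁻ is
sampled n_sub times down to |A⁺| (without replacement within a subset,
independently across subsets), each balanced subset (sample ∪ A⁺) trains
one random forest, and a query instance receives one binary vote per
forest. The default n_sub = round(|A⁻|/|A⁺|) makes the expected negative
coverage approximate the full negative set. The default decision cutoff is
half the sub-classifiers, with ties at exactly half counting as positive;
sweeping the integer cutoff from 0 to n_sub+1 yields the ROC curve,
including both degenerate endpoints.

Forests use deliberately small, classic defaults — 10 trees,
⌊log2(m)⌋+1 candidate features per split, unlimited depth — all
overridable. One master seed deterministically spawns the subsample and
per-forest seeds, so (data, seed, parameters) fully determine every vote.

## Evaluation

Cross-validation partitions **by structure**: each fold holds out one
antigen entirely, so no residue of a test structure reaches training. Per
structure the package reports the confusion table at the default cutoff,
SN, SP, ACC, precision, recall, F, and the vote-sweep AUC (trapezoidal,
equivalent to the tie-corrected rank statistic). The headline number is
the unweighted mean of per-structure AUCs; a pooled-residue AUC over
votes/n_sub is emitted alongside for transparency. Metrics with a zero
denominator are reported as NaN, never silently as 0. Test structures with
single-class labels are skipped for AUC with a warning.

The distance-contrast statistics compare epitope and non-epitope patches
in two views: mean adjacent distance grouped by the central residue's
amino-acid type, and mean distance of the kth-nearest neighbour per rank
k. Each view gets a closed-form paired t-test (pairs = types, pairs =
ranks). The rank-paired view is useful descriptively, but its "pairs"
share the same patches and therefore a common random offset, which makes
the test anti-conservative on small cohorts at any sample size; the
type-paired view uses disjoint patch subsets per pair and is well
calibrated. Statistical claims about class separation should therefore
rest on the type-paired test, and that is what the package's own
acceptance checks assert; both statistics are always reported.

## Synthetic fixtures

The generator produces complete, parseable inputs (PDB, DSSP-format, PSSM
ASCII, label annotations, a JSON manifest) with no downloads, designed so
its statistical properties — not its physics — match what the pipeline
needs to be tested against:

* the antigen is a self-avoiding Cα walk (step 3.8 Å, minimum separation
  3.7 Å) confined to a sphere sized at 95 Å³ per residue, dense enough
  that a realistic minority of residues is buried; each residue carries an
  N/CA/C/O/CB template with small placement jitter;
* epitope residues are sampled **uniformly among surface residues**, so
  with no planted signal epitope and non-epitope patch centres are
  exchangeable and their distance distributions indistinguishable — a
  contiguous "most protruding site" selection would bias epitope patches
  sparse even with no signal;
* the antibody chain places one collinear 5-atom residue along the
  clearest approach direction of each epitope residue at 3.2–3.8 Å.
  Where no direction is clear, the few blocking residues are nudged
  outward ("carving"); identical sham carving is applied at an equal
  number of random non-epitope surface residues so the perturbation
  cannot separate the classes. Every fixture is verified by round-tripping
  through the PDB writer/parser and the 4 Å labeller: the recovered
  epitope set must equal the designated set exactly, with clearance
  margins (≥ 4.05 Å for non-designated residues) that coordinate rounding
  cannot flip;
* the **distance shift** (default 0.5 Å where a signal is wanted) dilates
  space locally around each epitope centre (Gaussian kernel, σ = 7 Å,
  strength shift/3.9), raising the mean adjacent distance of
  epitope-centred patches by approximately the configured amount;
* the **conservation signal** makes every epitope position non-conserved
  in the generated PSSM (own-type score 2–6 below the BLOSUM62 diagonal)
  against a 10% non-conserved background among non-epitope positions, so
  the planted signal is clearly learnable but not a literal label copy;
* secondary-structure truth cycles through all DSSP code classes and is
  emitted as a DSSP-format file, exercising the reader path.

What the fixtures do **not** emulate: real side-chain geometry and
chemistry, sequence-dependent structure, antibody shape, evolutionary
correlation structure in PSSMs, or the bound/unbound coordinate
differences of real benchmarks. Passing tests therefore demonstrate that
the pipeline is internally correct and can recover signals of the planted
kind — not that it attains any particular accuracy on real antigens.

## Problem sizes used by the checks

The packaged verification uses 60-residue antigens with 8-residue epitope
sites: cross-validation cohorts of 8 structures (~480 patch instances,
~13% positive), a 16-structure cohort for the shifted distance contrast
(sized for the power of a 20-way type pairing), and 20 independent seeds
for permutation and null calibrations. These sizes are the package's
choice of a small but statistically meaningful study; all of them are
parameters of the public API and scale up freely.

## Known limitations

* The bound→unbound label transfer of real benchmark studies is out of
  scope; unbound evaluation requires externally supplied annotations.
* The φ/ψ fallback secondary-structure assigner is a coarse heuristic;
  supply DSSP files where fidelity matters.
* mmCIF input, biological-assembly expansion and symmetry mates are not
  supported.
* With fewer negatives than positives the ensemble degrades to a single
  unbalanced training set (with a warning) rather than inverting the
  subsampling.
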