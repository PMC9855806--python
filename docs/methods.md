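# Methods

This note records the models, conventions and numerical choices behind
`hemevox`, including the points where the underlying procedure is open to
interpretation and a specific convention had to be fixed.

## Site extraction

Structure files are read with gemmi; only the first model is used and
hydrogens are dropped, so all geometry is heavy-atom.  Alternate locations
are resolved per (chain, residue, atom name): the record with the largest
occupancy wins, and at equal occupancy the lexicographically smallest
altloc identifier wins — which reduces to "keep altloc A" in the common
A/B half-occupancy case and makes the operation deterministic and
idempotent for every input.

Four filters gate a site into the dataset:

* **Skeleton completeness.** All 25 heavy atoms of the Fe–porphyrin core
  (FE; NA–ND; C1A–C4A … C4D; CHA–CHD) must be present exactly once.
* **Axial coordination.** At least one amino-acid residue or water needs
  an atom within 3.1 Å of the iron.  The boundary is read inclusively
  (≤ 3.1 Å); this choice is invisible in practice (bond lengths are not
  poised at the cutoff) but makes the operation exactly testable.
* **Heme coverage ≥ 0.6.** "Coverage" is not a uniquely defined quantity;
  here it is the fraction of heme heavy atoms with at least one
  host-protein atom within a contact cutoff (default 5 Å, configurable).
  This proxy is monotone in the cutoff, equals 0 for an isolated cofactor
  and 1 for a fully buried one, and is isolated behind a single function
  so an alternative definition can be swapped in.
* **Sequence redundancy.** A greedy pass in input order drops any chain
  whose global pairwise identity to an already-kept chain exceeds the
  threshold (25, 60, 80 or 99.99 % are the standard operating points).
  Identity is computed from a Needleman–Wunsch alignment (match +1,
  mismatch −1, gap open −2, extend −0.5) as identities over the shorter
  sequence length.  The kept set provably contains no pair above the
  threshold; the greedy order-dependence is the price of determinism.

## Function labelling

The cascade is a pure function of the annotation tables: (1) EC number on
the axial-ligand chain — first digit 1 means oxidoreductase, any other
digit leaves the modelled label set; (2) otherwise the first matching GO
concept in the order oxygen-binding, oxidoreductase activity, electron
transfer activity, transcription, heme transport; (3) otherwise the first
matching entry keyword in the order hemophore, electron transfer,
oxygen-binding, oxidoreductase, heme extraction, signaling protein,
nitrophorin, heme transport; (4) otherwise a description naming
cytochrome P460 means oxidoreductase; (5) otherwise — or with no axial
ligand — unclassified.  Matching is case-insensitive substring matching
against a small synonym table (e.g. "oxygen carrier" counts as
oxygen-binding), because annotation vocabularies name concepts
inconsistently.  Priority lives entirely in the fixed rule lists, so
permuting the input annotation lists never changes the result.

Two curated overrides encode known biochemistry: dehaloperoxidases are
dual-function regardless of cascade outcome, and myoglobin entries whose
cascade result includes oxidoreductase activity gain oxygen binding.

Label vectors place oxidoreductase first, oxygen-binding second and (in
the three-label scheme) electron transfer third.  Any predicted vector
that matches no class — most importantly the all-zero vector — decodes to
the catch-all outcome "Others", which appears as an extra confusion-matrix
column and counts as a false negative of the observed class.

## Heme frame and voxelization

The frame is built from the four methine bridge carbons: origin at their
barycenter; z along the normal of their least-squares plane, with the sign
chosen so CHA→CHB→CHC→CHD winds counterclockwise seen from +z; x along
the projection of CHA→CHC onto the plane; y = z × x.  The direction
conventions (which end of CHA–CHC, which side of the plane) are fixed
choices — any consistent convention gives voxel grids that are identical
across rigid motions of the same site, which is the property that matters
and which the tests verify to 1e−9.  Degenerate methine configurations
(collinear or coincident) raise rather than produce an arbitrary frame.

Voxels are binary, with one channel per element C/N/O/S; other elements
contribute nothing.  A voxel is occupied when an atom **center** falls in
its half-open cube [low, high) — deterministic, oracle-checkable, and
every atom lands in exactly one voxel.  A van-der-Waals-overlap variant
(atom sphere intersects the voxel cube) is available behind
``mode="vdw"`` for sensitivity checks.  The default inclusion cube is
24 Å / 1 Å (24³ grid); the 17 Å variant is the same code path with
``edge=17``.

## The classifier

The network follows the published layer table: Conv(2×2×2) → 64 channels,
Conv(2×2×2, padded) → 128, BatchNorm, Conv(2×2×2) → 128, ReLU, BatchNorm,
MaxPool(2, stride 2), Flatten, Dense 128, ReLU, Dropout 0.4, Dense 64,
BatchNorm, ReLU, Dense 2-or-3, Sigmoid.  The middle convolution uses
symmetric padding of one plane per side, the only choice that reproduces
the published intermediate sizes (21³ → 22³ → 21³ → 10³ and a flattened
width of 128,000 for a 22-point input edge).  A 24-point input (the
literal 24 Å / 1 Å grid) flows through the same stack with sizes
23/24/23/11 and a flattened width of 170,368; both configurations are
supported, and the published-size configuration uses 22 points.

Everything is implemented in NumPy: convolutions as im2col matrix
products in float32, batch norm with biased batch variance and running
statistics (momentum 0.1, eps 1e−5), inverted dropout, He fan-in
initialization, plain SGD (learning rate 0.01, batch 32) on binary
cross-entropy summed over labels, computed from logits for stability.
Max-pool gradients are routed to a single (first) maximum per window;
with ReLU zero-plateaus upstream, ties inside pooling windows are common
and distributing the gradient to all tied entries measurably biases the
gradient (this was caught by the numerical-gradient check, which the test
suite runs in float64).  All randomness — initialization, epoch shuffles,
dropout masks, fold assignment — flows from integer seeds, and training
is bit-reproducible for a fixed seed.

The epoch count is configurable (no early stopping); the default of 100
is generous for datasets of a few hundred samples.  Sigmoid outputs are
thresholded at 0.5, the standard operating point for multi-label binary
cross-entropy heads.  Cross-validation is stratified five-fold with a
seeded shuffle, so every class appears in every fold (sizes differ by at
most one per class); each sample is predicted exactly once, by the model
that held it out.

Reported quantities: per-fold and combined confusion counts over the
class list plus "Others"; row-normalized matrices as mean ± sd over
folds; Sacc per fold; and per-class accuracy, recall, precision and
specificity with the one-vs-rest TP/FP/FN/TN convention, averaging over
folds and excluding (and counting) folds where a ratio is 0/0.

## Occlusion analysis

Occlusion reuses the trained fold models unchanged — batch-norm
statistics stay frozen, on the view that the masked inputs should be
scored by the model as trained, not by a partially re-adapted one.  Voxel
membership in the discarded region is decided by voxel-center
coordinates, matching the voxelization convention, so at r = 0 the masked
grid is bitwise identical to the original and the curve necessarily
starts at the unoccluded Sacc.  Retained volumes are (edge−2r)³ for
outside discarding and edge³−(2r)³ for inside discarding, and with 1 Å
voxels the kept-voxel count equals the retained volume exactly.  The
default sweep is integer r from 0 to 11 Å.

## Cavity vectors

The cavity lattice is the set of integer multiples of the grid spacing
(default 1 Å) within 8.5 Å of the iron, enumerated lexicographically over
the bounding cube — 2553 points at the defaults.  The lattice lives in
the heme frame and is anchored on each site's own iron, so the i-th
component of every cavity vector refers to the same physical location
relative to the cofactor and vectors are comparable element-wise without
any structure superposition.  A point is protein (0) when it lies within
the element's van-der-Waals radius (C 1.70, N 1.55, O 1.52, S 1.80 Å,
carbon-like fallback) plus a configurable padding (default 0) of any
host-protein heavy atom; there is no isolated-point cleanup.  Because the
occlusion radii are a convention, absolute d̄ values are comparable
within one parameterization but not across tools; the statistic's
structure (0 for singletons and identical groups, growing with shape
heterogeneity, maximal for mixtures of distinct prototypes) is what the
tests pin down.

## Synthetic data

The generator emulates the geometric situation the classifier faces: an
idealized planar porphyrin (4-fold symmetric, methine radius 3.42 Å,
pyrrole N 2.05 Å) in a uniformly random pose, a proximal histidine
nitrogen 2.1 Å below the iron, and 240 protein-like atoms in a 6–11 Å
shell with a realistic element mix (62 % C, 17 % N, 19 % O, 2 % S) and
0.25 Å positional jitter.  Class identity is carried purely by geometry:
OB-like sites keep a 55° distal cone empty; OR-like sites pack 35 % of
their atoms (O/N-rich) into a distal ball; ET-like sites clear both 35°
axial cones and concentrate half their atoms into an equatorial band;
OBOR-like sites combine a narrower 30° cone with an off-axis polar crowd.
A single ``motif_strength`` knob scales all motifs; at 0 the classes are
drawn from one distribution and no classifier can beat chance.  Crowd
atoms are kept at least 3.3 Å from the iron so no motif ever adds a
spurious axial ligand.

What the generator does *not* emulate: covalent backbone connectivity,
rotamer statistics, propionate and vinyl substituents, solvent, or any
sequence signal.  Passing the recovery experiment therefore shows that
the pipeline can learn and localize geometric class signal end to end —
not that real heme-protein classes are this separable.  Accordingly the
generator makes no attempt to mimic the real-data score levels.

## Experiment sizes

The recovery experiment used by the tests runs five-fold cross-validation
on 30 sites per class for OB/OR/ET-like classes, voxelized at 3 Å
(8-point grid edge) with the full 64/128/128 channel widths, trained for
12 epochs — sizes chosen so a complete run takes about a minute on one
CPU core while training loss has plateaued.  Three generator seeds are
averaged for the recovery bound (mean Sacc ≥ 0.9); a motif-strength-0 run
must stay below 0.6.  At these sizes the observed scores are ≈ 0.98 with
motifs on and ≈ 0.13 with motifs off (most chance-level predictions
decode to "Others").

## Known limitations

* The NumPy trainer is two orders of magnitude slower than a GPU
  framework; full-resolution (24³) training on PDB-scale datasets is
  out of desk-scale reach, though the code path is identical.
* The coverage proxy and the cavity occlusion radii are conventions;
  absolute thresholds (0.6) and absolute d̄ values inherit that.
* The greedy redundancy filter is order-dependent and not a maximum
  independent set.
* Real annotation tables are messier than the synonym table; the cascade
  is only as good as its inputs, and misassigned functions propagate into
  training labels.
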