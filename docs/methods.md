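# Methods

This note documents the models, conventions and numerical choices behind
`branchkit`'s analyses, and what the synthetic test bed does and does not
establish about real data.

## Structure model

Structures are parsed with gemmi into a flat atom table (chain, residue
number + insertion code, residue name, atom name, element, xyz in Å,
occupancy, altloc). Only the first MODEL block of multi-model files is read;
deposited branch-junction models are single-model, and averaging conformers
would be wrong for geometry. Alternate conformers are collapsed to the
highest-occupancy one, ties broken by the alphabetically first altloc id, so
downstream geometry always sees a single conformer. Residue numbering is
taken verbatim from the file; coordinates are Å throughout; polymer atoms
are identified by the ATOM record flag, falling back to the chemical
component tables for files that lack it.

A chain→subunit mapping (small text format: `LABEL CHAIN [START-END]`)
partitions the polymer atoms into labelled subunits. Labels encode roles:
`M1..Mn` mother-filament actins, `D1..Dn` daughter actins, `ARP2`, `ARP3`,
`ARPC1..ARPC5` the complex. The mapping validator enforces unique labels and
disjoint chain/range claims, so subunit assignment is a partition by
construction. Optional residue ranges let a user exclude ligands deposited
on polymer chains. Mappings for deposited accessions are user-supplied
config files, not hard-coded: chain naming differs between depositions and
should be checked against each entry's annotations.

## Branch angle

The filament axis is deliberately the *line between two reference atoms* —
the Cα of residue 269 (actin's Met269, which sits near the filament's
central axis) of the terminal subunits — rather than a fitted helical axis.
Two points define the line exactly and make the measurement auditable: the
result records the four atom identities used. A least-squares line through
all subunit centroids is available as an alternative estimator but is never
the default, because it measures something slightly different (it is exact
only when the subunit centroids are themselves on-axis).

The angle is arccos of the dot product of the two unit vectors, clamped to
[−1, 1] before arccos so floating-point edge cases cannot produce NaN.
Vectors are oriented by label order (M1→M8, D1→D3, pointed-end→barbed-end);
the result carries both θ ∈ [0°, 180°] and its complement 180° − θ so an
orientation-convention flip can never silently report the complement.
Reports print one decimal degree; JSON keeps full precision.

Accuracy under coordinate noise: with the default generator geometry
(mother span 7 × 27.5 Å = 192.5 Å, daughter span 2 × 27.5 Å = 55 Å) and
0.5 Å per-coordinate Gaussian noise, the daughter's short baseline dominates
the error; the mean absolute recovery error over a seeded batch is ≈ 0.6°
(per-draw standard deviation ≈ 0.8°, dominated by the 55 Å daughter span).
The tests therefore assert the batch mean is below 1°, not every single
draw.

## Superposition and RMSD

Superposition is the Kabsch algorithm via SVD of the 3×3 covariance of the
centred point sets, with the smallest singular direction sign-flipped
whenever the naive solution would be a reflection — proper rotations only,
since mirror images of proteins are unphysical. Inputs with fewer than three
points, or whose centred coordinates are (near-)collinear (second singular
value ≤ 1e−9 relative), raise a degeneracy error instead of returning an
arbitrary in-plane rotation. The test suite cross-checks RMSDs against an
independently implemented quaternion-eigenvalue (Horn) method to 1e−9.

All RMSDs use paired Cα atoms only. Pairing modes:

* `residue_number` (default): intersection of (residue number, insertion
  code) keys — right for model pairs that share numbering by construction;
* `sequence_alignment`: global alignment of the residue-name sequences
  (Biopython PairwiseAligner, match 1, mismatch 0, gap open −0.5, extend
  −0.1) — for references with independent numbering.

Per-subunit RMSD superposes the pair on its own paired Cα atoms and reports
the post-fit value over **all** common pairs; an optional iterative pruning
flag (drop pairs beyond 2× the current RMSD, refit, repeat) mimics
alignment tools that trim divergent loops, and is off by default because the
untrimmed value is the reproducible one.

The anchored RMSD matrix compares two conformations of the same assembly:
for each anchor subunit, one transform is computed from that subunit's pairs
alone and applied to the whole model; entry (anchor, target) is the target
subunit's Cα RMSD under that transform. For rigid-subcomplex motions each
row's minimum falls on its own diagonal, and blocks of jointly small
off-diagonal entries identify subunits moving as one rigid body.

## Contacts

The contact rule is Cα–Cα distance strictly below the cutoff (default
10 Å), cross-group only. "Strictly" matters at the boundary: pairs at
exactly the cutoff are excluded and counted separately, so the semantics are
unambiguous. The k-d-tree-accelerated query is tested for exact equality
with an O(n·m) brute-force reference. Distances are Euclidean on raw
coordinates — no symmetry expansion, no periodicity. The contact-zone rule
(atoms of a subunit within 5.5 Å, inclusive, of that subunit's contacting
Cα atoms) converts residue-level contacts into atom sets for export or
surface colouring; zone membership at exactly the radius is included.
Nothing is special-cased: named interface features (e.g. an ArpC1 protrusion
helix reaching the mother filament) must emerge from the same rule and can
be inspected in the per-residue pair list.

## Surface area

Shrake–Rupley with a deterministic golden-spiral (Fibonacci) sphere lattice:
no RNG, so SASA is bit-stable run to run. Per-atom area is the accessible
fraction of `n_points` test points times 4π(r + probe)². Neighbour pruning
uses a k-d tree with radius r_i + r_max. Defaults: probe 1.5 Å (the
interface-burial convention for these models; 1.4 Å water is a parameter
away), 960 points (within 1% of the 4000-point value on a 500-atom cluster;
single-sphere area is exact to ≈ 0.2% at 960 points).

Radii are an explicit, named, swappable set — default `element-single`:
C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20, Se 1.90, fallback 1.80 Å.
Hydrogens are used if the file contains them and never added; hydrogen
placement is a modelling step outside this package's scope.

Buried area reports all three SASA totals plus both conventions: `full_sum`
= SASA(A) + SASA(B) − SASA(A∪B) and `half_sum` = full_sum/2. The default
report is `half_sum` (the per-side average, matching what interactive
visualization tools print as "buried area"), but because published numbers
do not always state their convention, both values always travel together.
Tests validate the implementation against the closed-form two-sphere
spherical-cap area and against an independent external implementation
(biotite) with identical radii, probe and point count.

## Synthetic models

The generator emulates the *geometry* of a branch junction, not its
chemistry: a toy monomer is a seeded uniform cloud of Cα pseudo-atoms in a
ball (default 50 atoms, 14 Å radius) with one designated reference atom —
Cα of residue 269 — exactly at the local origin, mirroring the on-axis role
of actin's Met269. Filaments repeat the monomer under a rise/twist screw
along +z (defaults 27.5 Å and −166.7° per subunit, chosen to resemble
canonical F-actin; they are generator defaults, not measured values). The
daughter filament is built in its own frame and rotated by the prescribed
branch angle about an axis perpendicular to the mother axis through the
attachment subunit's reference atom, then offset laterally — so the
constructed axes subtend exactly θ and the reference atoms are exactly
on-axis. Seven blob subunits labelled as the complex are placed on a ring
around the junction so contact and buried-area stages have a complex group.
Noise is i.i.d. per-coordinate Gaussian with a mandatory seed; σ = 0 is the
identity.

What passing on synthetic models shows: the measurement machinery is
correct — angles are recovered exactly from exact inputs and degrade as
expected under noise, contact sets match geometry, SASA matches analytic
and external references. What it does not show: correctness of any
particular chain mapping for a deposited model, robustness to real modelling
artefacts (missing residues, alternate conformers beyond the collapse rule,
ligands), or agreement with published values for real structures — those
checks live in the deposited-model tests and run only where the published
files are available locally.

## Pipeline determinism and sizes

The full-analysis report is JSON with a schema version and provenance block
(input SHA-256, parameter echo, package version). No stage draws random
numbers, so re-running a config reproduces the report byte-for-byte. Default
problem sizes (18 subunits × 50 atoms, 960 SASA points) keep the complete
pipeline around a second on one CPU; the acceptance script's noise batch
uses 20 draws, enough to put the batch-mean angle error estimate well inside
its 1° bound.
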