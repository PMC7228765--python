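# Methods

## Distance correlation between domain motions

For each domain, a per-frame positional vector series is built from its Cα
atoms. Two modes are provided: `concatenated` (default) stacks all m domain
Cα coordinates into an n × 3m series — the literal reading of "positions of
the Cα atoms" — while `centroid` reduces each frame to the unweighted Cα
centroid (n × 3). Both are exposed because either is a defensible reduction
of domain motion; results are labeled with the mode used.

Between two series the distance covariance is the biased V-statistic

v(A, B) = (1/n²) Σᵢⱼ aᵢⱼ bᵢⱼ,

with aᵢⱼ the double-centered inter-frame Euclidean distance matrix. The
coefficient reported is DiCC = v(A,B)/√(v(A,A)·v(B,B)) — note this is the
*squared* distance correlation of the common statistical convention (no
additional square root is taken); the 1/n² normalization is used as is,
without the unbiased U-statistic correction. Both choices are deliberate:
the quantity is implemented exactly in the form in which it is conventionally
reported for MD domain-motion analysis, so values are comparable with that
literature. Consequences worth knowing:

- DiCC(A, A) = 1 identically; matrix diagonals are set to 1 by construction.
- The V-statistic is non-negative but biased upward at finite n: two
  independent stationary 3-D series of 500–1000 frames typically show
  DiCC ≈ 0.05–0.15, not 0. Comparisons should therefore be made at fixed n.
- DiCC is invariant under translation, proper rotation, and uniform scaling
  of either series.

Degenerate (constant) series raise an error rather than returning 0; a
silent 0 would corrupt the ranking of matrix entries. The most correlated
domain pair (largest off-diagonal entry) is reported alongside the matrix;
ties break lexicographically for determinism.

### Superposition and RMSD

Frames are superposed by least-squares rigid (Kabsch) fit — computed via
SVD with a guaranteed proper rotation — on the whole-protein Cα selection,
reference frame 0 by default (the analysis depends only on frame order, and
a mean-structure reference is a configurable alternative). RMSD series use
the backbone selection {N, CA, C, O} against the reference frame without
per-frame re-fitting, so the reported series reflects drift from the
reference after a single alignment. Fewer than 3 selected atoms, or a
collinear configuration, is a degenerate fit and raises an error. The
post-fit RMSD is measured from the applied transform directly rather than
from the SVD residual, which loses precision to cancellation for near-exact
rigid motions.

One consequence of whole-protein superposition: motion that is common to
every domain (e.g. a shared translation) is absorbed into the fit and
removed. Only *internal* concerted motion — anti-phase or differential
domain displacements — survives alignment, which is the physically
meaningful signal.

Replica averaging is the element-wise mean of per-replica DiCC matrices
with identical domain label order (three independent replicas per model is
the typical design).

## Synthetic trajectories

The generator stands in for equilibrated production MD. Each of K domains
is a rigid cloud of one Cα per residue (clouds ≥ 20 Å apart, residues
numbered contiguously per domain). Frame t displaces domain k rigidly by

u_k(t) = λ_k · s(t) + η_k(t),

with s a shared latent 3-vector process and η_k independent per-domain
processes. Both default to a discrete mean-reverting (AR(1)) process,
x_{t+1} = (1 − θ)x_t + ε, θ = 0.1 per frame, step SD 1.0 Å (latent) and
0.5 Å (noise) — stationary, like an equilibrated run, so DiCC estimates
stabilize with n; a random-walk option mimics drifting trajectories.
Default conditions are K = 4 domains × 25 residues, 1000 frames, loadings
(0.9, 0.7, 0.5, 0.3) giving a realistic spread of couplings. A "locked"
pair (emulating an engineered inter-domain disulfide) shares one fully
common displacement (loading 1 on a pair-specific latent, private noise
shared), so its DiCC is 1 before jitter and it ranks first in the matrix.
Optional per-frame global rigid motion (random rotation + translation) is
removable by superposition, and optional per-atom Gaussian jitter models
uncorrelated fluctuation. Seeds are mandatory and all draws come from
independent child streams, so toggling one stage (e.g. global motion) never
shifts another stage's draws.

What the generator does *not* emulate: internal domain deformation,
rotational domain motion, anharmonic transitions, solvent/membrane
coupling, or any real protein geometry. Passing tests therefore demonstrate
that the estimator recovers known translational coupling structure, not
that any particular biological trajectory has a given DiCC.

## Peptide and disulfide mass arithmetic

Atomic monoisotopic masses are fixed module constants (H 1.007825,
C 12.000000, ¹³C 13.003355, D 2.014102, N 14.003074, O 15.994915,
S 31.972071; proton 1.007276 Da), sufficient for 4-decimal m/z
reproduction. A peptide's composition is the sum of residue compositions
plus one water plus modification deltas. Shipped modifications:
carbamidomethyl (+C₂H₃NO, +57.0215 Da) and its heavy form
(+¹³C₂HD₂NO, +61.0407 Da, a +4.0193 Da shift), both cysteine-targeted;
deltas derive from the isotope table rather than being hard-coded.
Enriched labels are treated as isotopically pure — at 98–99 atom %
reagent purity the error is below the precision used anywhere downstream.

Disulfide formation removes exactly 2 H. ETD cleavage of the S–S bond is
modeled with the even-electron thiol fragment at peptide mass + 1.00783 Da
and the sulfanyl radical at the bare peptide mass; both role assignments
are returned since either peptide can take either part.

Isotope envelopes are aggregated isotopologues: per-element natural
abundance vectors convolved count times at unit nominal-mass spacing (no
fine structure), truncated to `max_peaks` (default 6, capturing > 99% of
these peptides' intensity), renormalized, with peak k placed at
monoisotopic m/z + k · 1.00336/z. Fine structure is irrelevant at the
10 ppm matching tolerance used downstream.

## Protection-fraction quantification

The labeling order (heavy on free cysteines, reduce, light on freed
cysteines) means the light-labeled fraction of a site is its
disulfide-protected fraction f. The by-eye "linear combination of control
spectra" is formalized as non-negative least squares on the union of the
light and heavy envelope grids: controls are normalized to unit total
intensity (making the weight ratio a molar-fraction proxy and the result
invariant to any uniform intensity rescaling), and
f = w_L / (w_L + w_H).

Numerical choices:

- **Peak matching** is globally greedy by ppm distance (default tolerance
  10 ppm): candidate (expected, observed) pairs are processed nearest
  first, each observed centroid used at most once, unmatched positions
  zero-filled.
- **Grid-slot merging.** The light (k+4)-th isotopologue lies only ~5–6 ppm
  from the heavy k-th peak at the charges used here (the +4.0193 Da label
  shift is close to, but not exactly, 4 isotope spacings). Peaks that close
  are a single centroid to any instrument and matcher, so grid positions
  within the matching tolerance collapse into one slot whose light/heavy
  template values are the sums; the linear model then accounts for the
  overlap exactly. The spectrum generator merges generated peaks at the
  same resolution. Without this, nearest-peak assignment between two slots
  5 ppm apart under 3 ppm jitter is unstable and can corrupt f by ~0.1.
- The residual norm reported is the L1 residual over total observed
  intensity — the fraction of signal the two-component model leaves
  unexplained, a sanity check against interferences.

The spectrum generator mixes the two envelopes at a stated f, applies
Gaussian m/z jitter (3 ppm SD default), multiplicative intensity noise
(CV 2% default), and decoy peaks kept ≥ 50 ppm from any expected position.
Under these defaults, recovery is exact to 10⁻⁸ without noise and within
±0.02 with noise across f ∈ [0, 1]. The generator does not model
chromatographic integration, detector saturation, deamidation or other
real interferences, so recovery accuracy on real spectra depends on those
being handled upstream.

## Trajectory I/O

Multi-model PDB is the interchange format (read/write through biotite,
3-decimal Å fixed columns, metadata exact on round trip). Residue numbers
are taken verbatim from the file — domain definitions quote the protein's
own numbering — and overlapping residue intervals merge on construction.
Models disagreeing in atom count are rejected; unparsable coordinate
fields report their line number; residue numbers above 9999 cannot be
written in fixed columns and are refused. Insertion codes and altlocs are
out of scope (first altloc wins with a warning). Binary trajectory formats
can be adapted behind the same `Trajectory` contract.

## Problem sizes

Default analyses run on 1000-frame, ~100-atom synthetic systems, where a
full DiCC matrix takes well under a second; the test suite's brute-force
oracles (O(n²) loops, exhaustive isotopologue enumeration, rotation grid
search) run on reduced sizes (n = 50–60 frames, 5-point clouds) chosen so
each oracle remains exact while completing in seconds.

## Known limitations

- The DiCC value depends on the vector-series mode (concatenated vs
  centroid) and on n through the V-statistic bias; the package reports the
  mode and n rather than claiming a canonical value.
- Domain motion in the generator is translational only.
- No significance testing of DiCC differences (a permutation test is a
  natural extension point).
- Quantification assumes exactly one targetable cysteine per peptide;
  multi-cysteine peptides would need site-resolved fragment evidence,
  which is out of scope.
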