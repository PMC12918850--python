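# Methods

## Fold comparison model

A protofilament fold is represented by one rung: an ordered chain of
residues in canonical 2N4R tau numbering with backbone coordinates in Å
(Cα mandatory; N, C, O optional). Comparing two folds requires a
*residue correspondence*, a strictly monotone pairing partitioned into
segments — maximal runs in which both residue numbers advance by one per
step. Two construction routes exist:

- **By numbering (default).** Residues sharing a canonical number are
  paired regardless of amino-acid identity, so point mutants (I305 vs
  S305) stay paired and splicing differences (3R folds lacking the R2
  repeat, residues 275–305) simply leave numbers unpaired. Numbering is
  unambiguous where a shared scheme exists, which is why it is the
  default over heuristic alignment.
- **By sequence.** Global Needleman–Wunsch with affine gaps (Gotoh
  recursion), BLOSUM62 scoring, defaults gap-open 12 / gap-extend 1.
  The open penalty is deliberately large relative to BLOSUM62 mismatch
  scores so that biologically meaningful block gaps (splicing) emerge
  instead of scattered single gaps. Traceback tie-breaks are fixed
  (diagonal, then vertical) so alignments are reproducible. The scoring
  parameters are a package choice; no reference values exist for them.

**Window RMSD.** For every window of `w ≥ min_window` consecutive pairs
inside one segment, the paired backbone atoms are superposed
independently by the Kabsch algorithm (SVD route; the determinant
correction restricts to proper rotations, so mirror-image folds cannot
score as similar) and the residual RMSD is stored. Per-window fitting is
the essential design decision: conserved motifs whose orientation
relative to the rest of the fold has rotated score near zero locally,
which a single global superposition cannot reveal. With `n` paired
residues in one segment this costs `O(n²)` windows of `O(w)` work each —
a ~100-residue rung takes well under a second.

**Localized RMSD** is the unweighted arithmetic mean over all admissible
windows. All windows count equally regardless of length: short windows
are many but individually noisy, long windows few but global; an
unweighted mean is the simplest summary and the one the ranking uses.
Library ranking sorts ascending by localized RMSD with deterministic
label tie-breaks; members sharing no admissible window are reported as
incomparable rather than dropped.

Defaults: `min_window = 3` (the smallest window with a non-trivial rigid
fit), atom set `CA` (published inter-fold values are Cα RMSDs; N/C/O can
be added per call). Heat-maps plot window start residue (x) against
window length (y), colour = RMSD on a fixed linear scale from 0; the
axes convention and colour scale are recorded in a sidecar JSON next to
the PNG/SVG.

## Helical geometry and the synthetic generator

Filament symmetry is parameterized by rise `h` (Å/rung, > 0) and signed
twist `ω` (deg/rung; negative = left-handed, the tau convention). The
crossover distance — the axial length of a 180° rotation of the ribbon —
satisfies `crossover = 180 h / |ω|`. The fixture geometries use the
4.8 Å cross-β rise with 600 Å and 750 Å crossovers (twist −1.44 and
−1.152 °/rung), the regimes relevant to patient-derived 4R tau
filaments.

`make_serpentine_rung` produces the default rung: a planar Cα trace of
100 residues (numbering from 273) meandering through antiparallel
strands with 3.8 Å Cα–Cα spacing and 4.8 Å inter-strand gaps. It mimics
the footprint of an amyloid cross-section but is geometric only — bond
lengths, angles and side chains are not modelled, so tests built on it
validate the comparison machinery, not stereochemistry. `build_filament`
stacks exact rigid copies (optional seeded Gaussian jitter);
`perturb_region` displaces a residue range along one seeded random
direction with a cosine taper normalized so the peak displacement equals
the requested amplitude exactly, giving a sharp ground truth for
localization tests. What passing these tests shows: the window machinery
detects and localizes known deformations and recovers known symmetry.
What they cannot show: behaviour on real backbone geometry, altloc/occupancy
edge cases in real depositions, or the empirical inter-fold RMSD values
of published structures — those need the deposited models themselves.

`estimate_helical_params` takes the helical axis as the first principal
component of the per-rung Cα centroids. The centroids of a helical stack
lie on the axis by construction, so this estimator is exact even for
short stacks whose rung cross-section (~76 Å for the default rung) is
wider than their axial extent — a regime where a principal component of
*all* Cα coordinates would pick an in-plane direction instead. For a
single-chain structure (no centroids to fit), all-Cα PCA is the
fallback. Rise is the mean axial centroid spacing with the axis oriented
to make it positive; twist is the mean rotation angle of the optimal
adjacent-rung superposition projected on that axis, which fixes the
handedness sign.

## ThT kinetics

Curves are fluorescence (RFU) vs time (hours; minutes converted on
load). Background is the mean of the first five raw readings, subtracted
once (double subtraction is an error); the raw maximum is retained for
QC. The model is the Gompertz sigmoid

    y(t) = A exp(−exp(−(t − t_i)/B))

with amplitude `A` (RFU), inflection time `t_i` (h) and time constant
`B` (h); `k_app = 1/B` (h⁻¹) is the apparent elongation rate and
`t½ = t_i − B ln(ln 2) ≈ t_i + 0.3665 B` the half-amplitude time.
Aggregation propensity is `1/t½`, by default from the fitted closed form
(an observed-curve interpolation mode exists; on clean sigmoids the two
agree to within one sampling interval). Fits use Levenberg–Marquardt
(lmfit `leastsq`) initialized at `A₀ = max signal`, `t_i₀ =` time of
steepest observed increase, `B₀ = (time span)/10`; MSE is the residual
sum of squares over the number of points, and non-convergence is
reported explicitly, never silently.

QC discards a well if its raw maximum is below 50 RFU **or** its fit MSE
exceeds one sample standard deviation of the per-well signal maxima
within the condition group — either defect alone suffices, since both
patterns indicate failed wells (bubbles), and requiring both would keep
a high-signal bubble well. The threshold scope (per condition group) and
scale factor are configurable because the rule compares an MSE
(squared RFU) against an RFU spread: with highly reproducible replicates
the cut tightens sharply, which is visible in simulation when replicate
maxima barely vary. Groups of one skip the MSE criterion with a warning.
Group summaries report mean ± sd of `k_app` and propensity per
condition; inferential statistics between conditions are out of scope.

The simulator reproduces the standard plate design — 5-minute sampling
over 24 h (289 points), 9 replicate wells per condition, additive
Gaussian noise, optional baseline — with one child seed stream per well,
so replicate sets are reproducible and wells independent. At 2% noise
the median relative error of recovered `k_app` over 100 wells is ~1.5%,
comfortably inside the 5% design envelope for the assay.

## Numerical choices

- Kabsch via SVD with determinant correction; coincident/collinear
  windows return the well-defined optimal residual even though the
  rotation is then non-unique. Verified in tests against scipy's
  `Rotation.align_vectors` and a quaternion-grid + local-refine search.
- Window RMSDs are symmetric in the two folds and invariant under rigid
  motions of either input to 1e-9; coordinate round trips through
  PDB/mmCIF are exact to the 1e-3 Å format precision.
- Altlocs keep the highest-occupancy conformer; insertion codes are
  rejected outright (absent from filament depositions); residue numbers
  are never silently remapped.
- Degenerate inputs raise informative errors rather than propagate NaNs:
  empty correspondences, ranges with unpaired residues, all-zero ThT
  curves, non-positive half-times, single-rung parameter estimation.

## Problem sizes

Tests and the acceptance script run on 24–100-residue rungs (≤ 4851
windows per comparison), 2–9-rung filaments, and 100-replicate kinetic
recovery at 289 points per curve — sizes chosen to exercise every code
path at interactive speed while matching the assay's real sampling
design.

## Known limitations

- Deposited-model comparisons require the published coordinate files
  (locally cached or downloadable); the package ships no third-party
  coordinates, so those checks are inert without them.
- Correspondences are sequence-space only; no structure-based or
  flexible alignment, and only pairwise (no multiple) comparison.
- The localized-RMSD mean weights all windows equally; a length-weighted
  variant would emphasize global agreement more strongly.
- Fixtures are Cα-geometric; results on them do not certify behaviour on
  full-backbone stereochemistry.
- The Gompertz model describes sigmoidal growth empirically; it is not a
  mechanistic nucleation–elongation rate law.
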