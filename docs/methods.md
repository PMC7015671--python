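# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `mtrecon`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted that the code does not measure.

## The lattice model

Microtubules are treated as ideal N-protofilament (PF), S-start monomer
helices. A lateral step from one PF column to the next is the screw
operation

    twist = handedness · 360°/N,    rise = S·a/N,

with *a* the monomer spacing along a PF (default 40.95 Å, giving the
~82 Å tubulin dimer repeat) and S = 3 for microtubules. Defaults:
left-handed lateral twist (handedness −1), zero PF skew (no
supertwist), cylinder radius 110 Å to monomer centers. All of these are
`LatticeSpec` fields; tests run a reduced radius (80 Å) so a 64-96 px
box at 4 Å/voxel contains the decorated lattice.

Applying the screw N times equals a pure translation by S·a (one full
turn). Because S is odd, that closure translation is an odd number of
monomers: the monomer screw is therefore *not* a symmetry of any
per-dimer property (motor/tail decoration, α vs β identity). This is
the α/β ambiguity of monomer-lattice averaging; it is inherent to the
geometry, and the seam — realized here as one column with swapped α/β
register — breaks the symmetry further. Consequences are noted under
*Symmetrization* below.

The stack is z-centered so that a column-0 dimer midpoint sits exactly
at z = 0. This makes the per-dimer anchor points used by protofilament
extraction coincide with lattice sites instead of falling between them.

## Synthetic data

**Volumes.** Specimens are sums of isotropic Gaussian blobs: α- and
β-tubulin (distinguishable amplitudes 1.0/0.8 so the dimer repeat and
seam are visible in density), one motor blob per dimer at radius +30 Å
(amplitude 1.2, σ 10 Å) and optionally one tail blob at +55 Å
(amplitude 0.9, σ 9 Å), with independent Bernoulli occupancies recorded
as ground truth. Blob parameters are free `DensitySpec` fields; the
defaults were chosen so that one projected tail blob is detectable by an
ideal matched filter at footprint SNR 0.5 with ~3% error — comparable
in spirit to the real contrast of a small disordered domain against an
MT.

**Segments.** Filaments lie in the ice plane (tilt 90° with optional
jitter). Overlapping segments are extracted every 80 Å; since the ideal
lattice is an exact helix, a window translated by Δz equals the
canonical volume spun by Δz/rise · twist, so each segment is a
projection of one volume at an advanced rot angle with known shifts.
`floor((L − box)/spacing) + 1` segments per filament of length L.

**Noise and CTF.** SNR is defined as clean-signal variance over noise
variance *inside the projected MT footprint* — the quantity alignment
quality actually depends on; Gaussian white noise is scaled per segment
to meet it (the generators do not model ice gradients or detector
statistics). The optional CTF is a radial phase-contrast transfer
function (defocus + amplitude contrast at 300 kV), with no astigmatism
or envelope: synthetic data carries known truth, so the CTF only needs
to be a realistic sign-flipping modulation.

**Assay datasets.** Michaelis–Menten rates with multiplicative Gaussian
noise; velocity samples from 1-2 component Gaussian mixtures;
exponential run lengths right-censored at the observation window, with
per-record censoring flags; linear force-vs-overlap data with Gaussian
noise on uniformly drawn overlaps; two-compartment cell images
(elliptical cell, inner spindle ellipse, corner background ROIs) with
per-pixel Gaussian noise. Generating parameters in tests and in the
acceptance script are the study's published values (kcat 7.1 s⁻¹ / Km
680 nM; velocities 7 nm/s, and 24/41 nm/s at 60/40; run length 8 µm
censored at 25 µm; slopes 4.0 and 0.6 pN/µm; spindle:cytoplasm ratio
2.39). All generators are bitwise-reproducible under a fixed seed.

## Conventions

Euler angles are ZYZ (rot, tilt, psi), degrees, rotating the reference
into the image frame: R = Rz(psi)·Ry(tilt)·Rz(rot). Maps are cubic,
indexed [ix, iy, iz], origin at the geometric box center; projection
integrates along z after rotation and in-plane shift (Å); shifts move
image content in the +axis direction. Interpolation is trilinear
throughout. On disk: MRC2014 mode 2 with x fastest, tables as a minimal
single-loop STAR dialect or TSV.

## Reconstruction

**Matching.** Exhaustive normalized cross-correlation against a gallery
of reference projections (rot grid at tilt ≈ 90°, optional psi list),
shifts searched on the integer pixel grid by FFT cross-correlation with
parabolic sub-pixel refinement; ties go to the lowest gallery index.
NCC was chosen over likelihood weighting because it is exact, fast, and
directly testable against a brute-force oracle.

**Back-projection.** Real-space smearing of each un-shifted image along
its beam direction, accumulated with per-voxel hit-count normalization.
By default each image is first ramp-filtered along the in-plane
direction perpendicular to the projected filament axis — the standard
filtered-back-projection weighting for the parallel-beam geometry that
tilt ≈ 90° segments form about the helix axis. Without it the 1/|k|
weighting of plain back-projection visibly blurs reconstructions and
fails reasonable fidelity bounds; `filter="none"` gives the unweighted
adjoint. Voxels with no interpolation weight are flagged, not silently
zeroed.

**Helical parameter estimation.** Grid search of (twist, rise)
maximizing the real-space correlation between the map and its
screw-transformed copy inside a cylindrical mask (axial margin ≥ the
rise search bound), with parabolic refinement about the grid optimum.
Degenerate surfaces (variation < 1e-3, the interpolation noise level)
return the guess with a flag; optima on the search edge are flagged.
Within the IHRSR loop the search runs on the *symmetrized* volume: the
raw back-projection of a desk-scale view set carries streak artifacts
that bias the self-correlation surface, while symmetrization retains
the true lattice signal (measured: estimates on raw 21-view
back-projections err by ~0.5° and hit range bounds; on symmetrized
volumes they recover the generating twist within one grid step).

**Symmetrization.** The mean of the k = 0..N−1 screw copies. Axial
translations are wrapped into the *dimer* repeat (2a) — a pure
dimer-repeat translation is a lattice symmetry, whereas wrapping by the
start repeat (3a) would swap the α/β register. Interpolation makes the
noise-variance reduction slightly stronger than the nominal 1/N (each
interpolated copy also smooths); the test suite checks the measured
reduction against an oracle that measures the per-copy interpolation
factor on independent noise.

**PF-number sorting.** Best NCC per segment against 13/14/15-PF
reference galleries, then a per-filament majority vote (a filament is
one MT, so its segments pool evidence); ties are left unassigned. The
segment-vs-filament aggregation level is our choice; it is flagged as
such here.

**Alignment smoothing.** Per filament, degree-≤2 polynomial fits of
unwrapped rot and both shift components against axial position;
residuals beyond 3 robust standard deviations (1.4826·MAD) are replaced
by a refit that excludes them. Filaments with fewer than degree+2
segments pass through unchanged.

## Protofilament refinement

A soft wedge mask (raised-cosine crossfade, default 5° half-width; hard
edges ring under interpolation) isolates one PF; the N masks partition
the annulus exactly. Subtraction projects the complement-masked
symmetrized volume once per target PF — mathematically equivalent under
the linear projector to rotating-and-subtracting a PF-deleted volume
N−1 times, without double-counting overlapping wedges. One particle per
PF per 80 Å segment (≈ one dimer repeat) is re-centered on that PF's
dimer anchor; its initial alignment composes the MT alignment with the
j-th screw transform (rot + j·twist), the sub-pixel re-centering
remainder becoming the particle shift.

**Local refinement** is a constrained grid search about the initial
alignment. Rotating a single PF about its own axis changes its
projection by less than interpolation noise (measured NCC differences
~1e-4 across ±4°), so rot is effectively unidentifiable for an isolated
PF at this scale; the search therefore accepts a move only for an NCC
gain above that noise (1e-4) and otherwise keeps the smallest
perturbation, which keeps truth-initialized alignments exactly in place
while still recovering genuine shift errors.

**Focused classification** reduces each particle to a matched-filter
statistic — the dot product with the projection, at the particle's own
fixed alignment, of the focus-masked consensus volume — and alternates
hard assignment against per-class means of that statistic (1D k-means,
deterministic). Two designs that look natural fail measurably and are
documented to save the next implementer the detour: 2D image-space
class means cannot separate occupancy because particles view the
lattice from many azimuths (~57% accuracy at SNR 0.5, 50% occupancy);
per-class 3D mean volumes feed each particle's own noise back into its
assignment (self-correlation bias) and stall at the initialization.
Scoring against the class-neutral consensus removes the bias, and
optional per-site score pooling — different segments of a filament view
the same physical dimer from different azimuths — averages away both
noise and the residual occupancy signal of neighboring sites that
projects into the focus footprint (that contamination alone caps
single-view accuracy at ~86% even without noise). With pooling, site
accuracy at SNR 0.5 and 50% occupancy is 100% in the test conditions,
against an ideal matched-filter bound of ~97% per single view. Class
fractions are reported so a retention-style cut (e.g. keeping the
majority class) can be applied downstream.

## Validation

FSC is the per-shell normalized complex correlation of the two
half-maps' Fourier coefficients; global resolution is the first
downward crossing of 0.143, linearly interpolated between shells, with
explicit saturation (never crosses) and undefined (never reaches)
flags. Half-sets are split BY FILAMENT, never by segment: 80 Å-spaced
segments overlap and share noise, so segment-level splits inflate FSC.
B-factor sharpening scales amplitudes by exp(−B·s²/4) and preserves
phases exactly; the display convention of the pipeline is B = −200 Å²
(sharpening). Local resolution slides a Hann-tapered windowed FSC
(default threshold 0.5, appropriate to small-window statistics; the
global 0.143 criterion is not valid in tiny windows) and interpolates
between window centers.

## Assay fitters

All fitters are deterministic given their seed and invariant to record
order.

* Michaelis–Menten: Levenberg–Marquardt on v = kcat·S/(Km+S),
  initialized from the Hanes–Woolf linearization; SEs from the fit
  covariance; flat rate profiles flag Km as unidentifiable instead of
  returning an arbitrary number.
* Gaussian mixture: EM on raw samples (not histogram bins — bin-free
  MLE is better defined; the likelihood trace is exposed and is
  non-decreasing). Deterministic quantile initialization; a variance
  floor (1e-6 of the sample SD) guards collapse and flags it. Model
  selection between k = 1 and 2 by BIC; equal-component fits collapse
  to k = 1.
* Censored exponential: closed-form MLE, mean = (Σ all lengths)/(#
  uncensored); half-length = mean·ln 2. All-censored input is an error
  (the mean is unbounded). Conditions where runs exceed the observation
  window are therefore reported as non-quantifiable rather than fitted.
* Force per overlap: ordinary least squares, intercept free by default
  (plateau-force data show nonzero intercepts; origin constraint is a
  flag), with a seeded pair-resampling bootstrap percentile CI
  (default 1000 replicates).
* Spindle:cytoplasm ratio: (mean_spindle − mean_bg)/(mean_cyto −
  mean_bg) with cytoplasm = cell minus spindle; a cytoplasm signal at
  or below background is flagged undefined.

## Problem sizes

The test suite and acceptance script run at sizes chosen to exercise
every stage with meaningful statistics on a single CPU: 64-96 px boxes
at 4 Å/voxel, MT radius 80 Å, 1-12 filaments of 0.9-1.2 µm, galleries
at 4-6° steps, 8 ATPase concentrations, n = 149-200 single-molecule
records, 30 sliding events, 1000 bootstrap replicates. The 19,128 × 14
= 267,792 particle bookkeeping is checked exactly at the metadata
level.

## Known limitations

* The generators model one canonical volume per filament viewed under
  the exact screw; real filaments present a different dimer per
  segment, bent lattices, and non-white ice noise.
* Per-dimer decorations are not monomer-screw invariant (odd-start
  closure), so symmetrized motor/tail density is azimuthally smeared —
  as in real monomer-lattice MT averaging; seam-register search and α/β
  assignment are out of scope.
* The seam is a single swapped column, not a full 3-start closure
  model.
* Supertwisted (nonzero-skew) lattices are representable in
  `LatticeSpec` but not exercised by tests; helical parameter search
  assumes skew 0.
* The run-length recovery check at n = 200 carries a ~7% standard
  error against a ±10% acceptance band; the test asserts the median
  over five replicate datasets for this reason.
* No per-particle CTF refinement, no likelihood-weighted
  reconstruction, no GPU path.
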