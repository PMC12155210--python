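# Methods

This note documents the models, numerical choices and limitations behind
`avcalc`.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The cylindrical valve ROI

The aortic valve is modelled as an oblique cylinder in scanner mm space,
described by eight parameters: a unit normal (μx, μy, μz), an origin
(x₀, y₀, z₀) at the cylinder's center of mass, radius r and height h.
An idealized parametric shape (rather than a free-form segmentation) is used
deliberately: it cannot "leak" along image boundaries toward coronary
calcium, it admits clean mathematical sub-division for regional analysis,
and it can be adjusted smoothly (grow r, shift the origin) if a reader wants
to revise an automated result.

**Frame fitting.** Disk annotations are rescaled by the voxel spacing and
PCA-decomposed; PC3 (least variance) is the disk normal.  The covariance
eigen-problem leaves the normal's sign free, but the expansion below is
asymmetric, so the sign matters.  Convention: PC3 points toward the scanner
superior (+z) axis and "above" the disk means superior (toward the aortic
root), exposed as the `superior_is_above` config flag.  PC2 is recomputed as
PC3 × PC1 so every frame is exactly orthonormal (unit tests enforce 1e-8).

**Disk→cylinder expansion.** The valve radius is the largest in-plane
distance from the *annotated center point* (not the PCA centroid — the two
differ for asymmetric disks, and the annotated center is what a reader
chose as "the valve's center") to any disk voxel.  The ROI contains every
voxel whose center satisfies, in frame coordinates about the PCA centroid,

    x'² + y'² < (r_disk + Δr)²   and   −dB < z' < dA

with defaults Δr = 2 mm, dA = 10 mm, dB = 30 mm (h = 40 mm, in the size
range of replacement valves).  Both inequalities are strict, evaluated at
voxel centers; half-voxel effects are absorbed by the stated tolerances
rather than by fuzzing the rule.  Cylinders that overrun the grid are
clipped with a logged warning, never silently.

**Mask→parameters.** The origin is the unweighted centroid of member-voxel
centers.  The axis starts from the maximal-variance principal direction
(valid while h > r·√3; for the valve ROI h/r ≥ 1.8) and is then refined by
fitting a line through the centroids of interior axial slabs — slab
centroids of an ideal cylinder lie exactly on the axis, so the fit is
insensitive to the shrinking PCA eigen-gap at r → 22 mm.  The two end
regions (15% of the span each) are excluded because the end caps cut those
slabs asymmetrically.  Height comes from the axial second moment
(var(z') = h²/12 for a uniform cylinder) and radius from volume matching
(count · voxel volume = π r² h); both are accurate to a few hundredths of a
millimetre on 1 mm grids (measured by the acceptance script).  When a
7-parameter prediction is reconstructed, the height is split symmetrically
(h/2 above and below the origin) because the center of mass of an ideal
cylinder lies at mid-height.

**Coordinate conventions.** Voxel indices are 0-based, (x, y, z) order with
z superior; physical positions are voxel centers, `pos = origin + idx ·
spacing`.  The isotropic crop grid shares the acquisition origin, so mapping
parameters between spaces is a pure translation by the crop offset; radius
and height are mm quantities and space-invariant.

## Calcium scoring

Standard clinical Agatston criteria: candidate voxels are ≥ 130 HU inside
the ROI; per-axial-slice 2D components (8-neighbour) below 1 mm² are
discarded (7 voxels at 0.4 × 0.4 mm, the smallest n with n·sx·sy ≥ 1);
surviving components are grouped into 3D lesions by 26-neighbour
connectivity.  The 2D/3D connectivity choices follow the usual
calcium-scoring convention.  Each slice-component contributes
area × weight, weight 1/2/3/4 for max HU in [130,200)/[200,300)/[300,400)/
≥ 400.  Scores are computed on native slices (2.5–3 mm) with no
slice-increment rescaling, and always on the acquisition-space volume —
never on the isotropic resample, whose interpolation would blur lesion
boundaries.

Volume and mass are restricted to voxels of qualifying lesions (not all
≥ 130 HU voxels) so the four metrics describe the same objects; a
consequence tested explicitly is Agatston = 0 ⇒ volume = mass = 0.  The
mass calibration factor is scanner-specific and not knowable here; it is a
config value with placeholder default 0.001.  A lesion is *valid* for the
lesion count when its individual Agatston score strictly exceeds 10,
suppressing noise specks.

Severity uses the guideline bins {0, 1–800, 800–1200, 1200–2000, 2000+}
(upper-inclusive edges, so a score of exactly 2000 is "1200–2000", matching
the strict > 2000 severe rule), severe-likely thresholds > 2000 (men) /
> 1200 (women), severe-unlikely < 1600 / < 800, and optional conservative
thresholds 1500 / 900.  Unknown sex yields a bin but no flags.

## Sub-ROI decomposition

Three independent splits of the cylinder, each in thirds: concentric shells
A–C at radius fractions 1/3 and 2/3 (equal radius fractions, not equal
areas — the outer shell deliberately covers more area since wall-adjacent
calcium dominates); axial slabs D (top, aortic-root side) to F (bottom,
cusp side); and sectors G–I bounded by rays from the axis through the three
projected anchor points (G flanked by RAPA and PALA, H by PALA–LARA, I by
LARA–RAPA).  Rays-through-anchors is the default (`sector_mode:
anchor_rays`); a bisector mode (sectors centered on anchors) is available
since the annotation convention admits either reading.  Intervals are
half-open and boundary voxels go to the lower region, making the 27 crossed
regions an exact partition (tested for disjointness and completeness).
Without anchors only the 9 shell × slab regions are emitted.

Volume scores are additive across regions.  Agatston is not when a lesion
straddles a boundary (its per-component area and max-HU terms change); this
is inherent to the score and is logged, not corrected.

## Noise QC and preprocessing

Noise is the standard deviation of sub-130-HU voxels (excluding candidate
calcium) inside an externally supplied descending-aorta mask: > 36 HU flags
slice-wise 3×3 median denoising — well suited to the 1-voxel streaks of
photon starvation — and > 45 HU excludes the case.  The filter is applied to
the whole volume before any calcium detection, and uniformly whenever the
rule fires.  Organ segmentation itself (descending aorta, heart sac) is out
of scope: masks are accepted as inputs, with a largest-soft-tissue-component
bounding-box fallback for phantoms.

Model inputs are windowed to [−300, 100] HU, rescaled to [0, 1], resampled
to 1 mm isotropic voxels (linear; nearest for masks) and cropped to a fixed
window (176 × 176 × 128 at full scale) centered on the heart bounding box,
padded with the volume minimum where the window over-reaches.  The crop
offset is recorded so predictions map back exactly (round-trip identity is
tested at 1e-6 mm).

## The three-branch network

A 3D encoder–decoder with additive skips.  Encoder widths double per level;
the full-size preset (176×176×128 input, widths 16–256) produces the
256-channel 11×11×8 latent; the desk preset (64³ input, stem average-pool to
32³, widths 8/16/32) is what the tests train.  Branch-2 applies adaptive
average pooling to the encoder bottom (a length-`C` descriptor), then
FullyConnected → LeakyReLU → LayerNorm → Dropout → FullyConnected → tanh to
7 outputs.  Targets share the [−1, 1] scale: normal components are already
unit-bounded, origins are normalized over the crop extent, and the radius is
rescaled by r' = 2(r/40) − 1.  The decoder convolves at the coarse level and
then upsamples (rather than convolving at the fine level), which costs a
little boundary sharpness on an ROI that is smooth by construction and
saves most of the decoder FLOPs — relevant because the whole network runs
on a hand-written numpy autodiff engine (no GPU framework is assumed
anywhere).

**Branch-3 differentiability.** A binary reconstructed cylinder admits no
gradients, so branch-3 renders a soft membership
σ(k(r − ρ(x))) · σ(k(h/2 − |z'(x)|)) with sharpness k = 50 /mm; thresholded
at 0.5 it matches the exact voxelizer (Dice ≥ 0.995 on a 64³ grid, tested),
and its gradient with respect to each parameter is verified against finite
differences.  The branch-3 grid is the input grid strided by 2 (a pure
compute saving; the soft boundary is several voxels wide at k = 50 anyway).

**Loss.** α·Dice(seg) + β·MSE(origin) + Δ·MSE(normal, radius) +
γ·Dice_recon, defaults all 1/4.  Zeroing a weight removes that branch
entirely, which is how ablation configurations (branch-1 only;
branch-2+3 only) are expressed.  Origin MSE is computed on normalized
coordinates; during training branch-3 uses the regressed origin (the CoM is
not usefully differentiable), while at inference the origin is the
unweighted center of mass of the 0.5-thresholded branch-1 segmentation —
the CoM linkage, which the tests show recovers origins to well under a
voxel on ideal masks and under 1 mm after desk training.  An empty
segmentation falls back to the regressed origin with a warning flag.

**Optimization.** Adam (lr 2e-3, cosine decay to 0.2e-3, global-norm
gradient clip at 5) with a small-variance initialization of the regression
output layer so tanh outputs start near zero; these choices are unstated in
any reference and were fixed for stability, all overridable in
`TrainConfig`.  Splits are 65/15/20 by seeded permutation with
floor/floor/remainder rounding (an explicit `split_counts` override exists
because other roundings are defensible).  Augmentation is on-the-fly
Gaussian noise, mean 0 / std 0.1 on the [0, 1] intensity scale;
displacement augmentation is omitted (it would require offline relabeling
of origins for negligible benefit).  The reference protocol is batch 8 for
600 epochs at full size; the desk preset used by the acceptance run is
36 phantoms, batch 4, 30 epochs at 64³ — sized so a complete training fits
comfortably in a single-CPU session while still demonstrating the CoM
linkage (validation reconstruction Dice ≈ 0.89 and origin error < 1 mm in
the acceptance runs, against bounds of 0.6 and 3 mm).

**Evaluation suite.** For any predicted/truth cylinder pair the package
reports mask Dice, Hausdorff distance (via exact Euclidean distance
transforms with physical sampling), radius absolute difference, origin
Euclidean distance and normal cosine similarity.

## Synthetic phantoms

Phantoms emulate the statistical and geometric structure of a coned-down
CTCS exam, not its visual appearance: a 96×96×26 grid at 0.7×0.7×2.5 mm
(in the reported acquisition range), soft-tissue background (~35 HU) with
smooth shading, a heart-like ellipsoid, an ascending-aorta tube with a
bright wall running along the cylinder axis above the valve plane (the
anatomy cue that makes localization and radius regression learnable), a
ventricular blood pool below it, an annulus ring at the plane (110 HU —
dense but deliberately sub-threshold), and a descending-aorta tube for QC.
The valve plane sits 10 mm above the cylinder's center of mass, consistent
with the dA/dB split.  Truth cylinders have r ∈ [16, 22] mm, h = 40 mm,
tilt ≤ 12° from superior and a few millimetres of positional jitter —
anatomically plausible variation that keeps the learning task honest
without making it unsolvable at desk scale.

Calcifications are clipped Gaussians (σ = r_blob/1.5) with peaks in
[130, 1000] HU, giving smooth partial-volume-like edges so the ≥ 130 HU and
≥ 1 mm² rules are exercised at genuine boundaries.  Inside-flagged blobs
must satisfy the cylinder membership rule; distractor blobs must keep their
≥ 130 HU core clear of the ROI (validated at generation; a dedicated test
confirms distractors never contribute).  Streak artifacts are 1-voxel
chords with random orientation and ± amplitude; because the line geometry
is a pure function of the seed, a bisection sweep
(`calibrate_streak_amplitude`) pins the aorta-noise statistic to any target,
which is how the tests place phantoms precisely in the denoise (36–45 HU]
and exclude (> 45 HU) bands.  Every phantom carries an expected score
report computed from the rendered image by the scoring module itself, so
"truth" and "measured" can never drift apart silently; the independent
check against scoring bugs is the separate scalar oracle suite.

Cohort generation targets requested severity-bin proportions by
largest-remainder allocation and adds blobs from a calibrated size ladder,
re-measuring the actual rendered score after each addition and capping
increments near bin edges so cases land in their intended bins.

What phantom tests do **not** show: robustness to real-scanner noise
spectra, beam hardening, motion, anatomical variation (bicuspid valves,
mitral annular calcium nearby), or annotation variability.  Passing them
demonstrates that the geometry, scoring arithmetic, QC logic and learning
machinery are correct, and that the multi-task design (CoM linkage
included) can recover known cylinders from images — not clinical
performance.

## Degenerate inputs and tie-breaks

Collinear/coincident disk voxels raise a geometry error; a cylinder radius
below half the in-plane spacing voxelizes to an empty mask with a warning;
an empty mask has no origin (error) — except the inference path, which
falls back to the regressed origin.  Partition boundary values go to the
lower interval; on-axis voxels (undefined angle) go to the alphabetically
first sector.  Agatston bins are upper-inclusive.  Normals within 1e-3 of
unit length are silently normalized, anything further off is an error.

## Known limitations

* The scalar mass calibration is a placeholder; absolute mass scores are
  only comparable within a fixed calibration.
* The axis estimator assumes h > r·√3 (true for the 40 mm valve ROI); for
  squat cylinders the principal-moment gap closes and recovery degrades.
* The desk-scale network shares the architecture contract but not the
  capacity of the full-size configuration; its weights are not meant for
  real images.
* DICOM reading supports single-orientation axial series with uniform
  slice gaps; anything else is rejected rather than resampled.
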