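# Methods

`spectplan` implements an automated planning chain for unsealed-source
(Y-90 microsphere) liver therapy: atlas-based CT organ segmentation,
rigid SPECT–CT registration driven by a narrow-band signed-distance metric,
and absorbed-dose computation by dose-point-kernel convolution.  This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic phantoms do and do not establish.

## Coordinate conventions

All images live on axis-aligned grids; the physical position of voxel
`(i, j, k)` is `origin + index * spacing` in millimetres, and data axis `a`
carries spacing component `a`.  Physical mm space is the common frame between
CT (~0.7–2 mm voxels) and SPECT (3.2–4.6 mm cubic voxels).  Rigid transforms
use intrinsic Z·Y·X Euler angles in degrees (matrix `Rz·Ry·Rx`), translations
in mm, and an explicit rotation centre; a point maps as
`p' = R (p − c) + c + t`.  Displacement fields are dense per-voxel 3-vectors
in mm on the fixed-image grid, mapping fixed-space points to moving-space
points (`warped(x) = moving(x + d(x))`).  Oblique DICOM orientations are out
of scope and must be resampled upstream; keeping the grids axis-aligned keeps
every geometric operation transparent.

## CT preprocessing

Two steps precede deformable registration:

- **Perona–Malik anisotropic diffusion** with conductance
  `g(s) = exp(−(s/K)²)`, explicit six-neighbour flux updates in normalized
  voxel units, time step 0.0625 (the 3D stability bound `1/(2·2³)`),
  5 iterations.  `K` is expressed in units of the image's median gradient
  magnitude (default multiplier 3.0) so one setting behaves comparably across
  HU ranges.  The flux form conserves the intensity sum exactly and never
  expands the intensity extrema.
- **Histogram matching** to compensate HU calibration differences between
  scanners: seven interior quantiles of a 1024-bin histogram are aligned by a
  monotone piecewise-linear map, with voxels at or below the image mean
  excluded from quantile estimation so the air background does not dominate.
  Matching is applied on every run and can be disabled in the configuration.

## Diffeomorphic demons segmentation

Atlas segmentation reduces delineation to registration: a pre-contoured
template CT is deformably registered to the subject and its binary structures
are warped through the resulting field.  The registration is a diffeomorphic
demons scheme:

- **Force** (classical, fixed-image gradient):
  `u = s · (f − m) · ∇f / (|∇f|² + (f − m)²)`, zeroed where the denominator
  falls below 1e-9.  `s` is the force step (default 2).  The sign follows
  from the field convention above: where the warped moving image is darker
  than a rising fixed edge the displacement must grow along the fixed
  gradient.
- **Log-domain accumulation**: updates are added to a stationary velocity
  field, which is smoothed each iteration (`sigma_field` = 1 voxel); the
  per-iteration update is smoothed separately (`sigma_update` = 0.2 voxel)
  and its magnitude capped at `step` voxels.  Both sigmas are in voxels at
  the current pyramid level.
- **Exponential** by scaling and squaring: scale the velocity by `2^-n` so
  its maximum magnitude is below half a voxel, then compose the field with
  itself `n` times (trilinear interpolation, edge-clamped).  This keeps the
  mapping invertible in practice: composing `exp(v)` with `exp(−v)` leaves
  sub-half-voxel residuals on smooth fields.
- **Multiresolution**: three levels with downsampling factors 4/2/1
  (Gaussian presmoothing of `factor/2` voxels before striding) and 50/40/30
  iterations.  Velocities are upsampled between levels by trilinear
  interpolation; mm units make the values resolution-independent.

Masks are warped with linear interpolation and thresholded at 0.5.  Where
independently warped structures overlap, the voxel goes to the structure with
the largest pre-threshold value (ties to the first listed).  A structure that
comes back empty raises a warning rather than an error.  The subject is the
fixed image, so the field pulls atlas labels directly onto the subject grid
with no field inversion.

## Narrow-band rigid SPECT–CT registration

A Tc-99m MAA SPECT shows essentially one feature — nonuniform uptake confined
to the liver — so intensity-constancy assumptions behind mutual information
are unreliable; the liver *shape* is the only information shared with CT.
The registration encodes the CT liver contour as a signed Euclidean distance
map (negative inside) and restricts attention to the narrow band
`|d| ≤ 10 mm`.  Band voxels carry the weight `w(d) = exp(−d²/(2σ²))` with
`σ = width/3`, peaking on the contour and decayed to `exp(−4.5) ≈ 0.011` at
the band edge.  The cost of a candidate CT→SPECT transform is the negated
Pearson correlation (NCC) between those weights and the SPECT
gradient-magnitude image sampled at the mapped band voxels: it is minimal
when the SPECT gradient ridge lies on the zero level set, invariant to affine
rescaling of SPECT intensities, and — because the band is a transition zone
rather than a hard edge — tolerant of one-voxel errors in the liver
segmentation.  Voxels mapping outside the SPECT extent sample as zero
gradient, keeping the objective smooth as the band slides off the field of
view; fewer than 100 band voxels inside the extent is an overlap error.

The optimizer is a regular-step gradient descent over the 6-vector
(rx, ry, rz, tx, ty, tz): central finite differences (step 2 mm ≈ half a
SPECT voxel, which averages over trilinear-interpolation kinks), a move of
the current step length along the normalized negative gradient, step
relaxation by 0.5 whenever the direction reverses, and termination when the
step falls below 0.01 or after 200 iterations, returning the best-seen
parameters.  Rotation degrees and translation mm are weighted 1:1 in the
scaled parameter space (`rotation_scale` = 1): one degree moves a
liver-surface point by roughly one millimetre at this anatomy's scale.  The
rotation centre is the liver centroid.

**Capture range.**  The band (±10 mm) plus the blurred SPECT ridge carries no
information more than ~2 cm from alignment, while restart analysis samples
initial displacements up to 30 mm per axis (52 mm diagonal).  A single
sharp-scale descent therefore stalls or falls into spurious minima from far
corners.  The registration consequently runs a coarse-to-fine cascade of the
same metric and optimizer with SPECT presmoothing of 4, 2, then 1 voxels:
heavier smoothing widens the ridge (and the capture basin) at the cost of a
curvature-dependent ridge shift (∝ σ²) that would bias rotations by several
degrees if kept, so the final stage always uses the sharp one-voxel setting.
Coarse stages stop at step lengths of 0.5 and 0.1 since they only need to
reach the next stage's basin.  On the default phantom this converges to one
solution (spreads ≲ 0.1 mm / 0.1°) from every corner of the restart range.

A Mattes-style mutual-information baseline (64-bin joint histogram over a
seeded random sample of CT voxels, same optimizer) is included solely as the
comparison arm for convergence analysis.

## Dosimetry

Y-90 microsphere implants decay in place, so a single-time-point activity map
convolved with a radionuclide-specific dose-point kernel gives the absorbed
dose.  Kernel tables are radial CSV profiles (`radius_mm,value`); voxelization
samples the table at each voxel-centre radius of an odd, centred cubic grid
(log-linear interpolation, zero beyond support).  Convolution is zero-padded
FFT (`scipy.signal.fftconvolve`, no circular wrap), performed on the
SPECT-native cubic grid — matching the kernel to the activity resolution and
avoiding a ~250× larger CT-grid convolution — and the dose is then resampled
onto the CT grid through the rigid registration transform.  Activity values
are treated as relative; absolute calibration (counts → Bq) is one scalar in
the configuration.  Energy bookkeeping holds to 0.1%: integrated dose equals
integrated activity times the kernel sum for interior sources.

The repository ships a synthetic exponential-falloff test kernel
(`exp(−r/2.5 mm)`, 11 mm support, mimicking the Y-90 beta range) so the
dosimetry chain is testable without external data; it is labelled synthetic
and is not a measured Y-90 kernel.  Real Monte-Carlo kernels use the same CSV
schema.

Per structure the package reports cumulative DVHs (fraction of voxels with
dose ≥ each edge) and summary statistics: min/max/mean, D95 (the largest dose
still covering ≥95% of the volume, an order statistic of the voxel multiset)
and V20 (volume fraction ≥ 20 Gy, the critical-structure check).

## Validation instruments

- **Dice similarity coefficient** `DSC = 2|A∩B|/(|A|+|B|)`, the primary
  overlap score with 0.7 as the conventional good-match threshold; the
  Jaccard index `|A∩B|/|A∪B|` is reported alongside (the two are sometimes
  conflated in the literature; both are logged to avoid ambiguity).
- **Surface distances**: surfaces are extracted as a mask minus its one-voxel
  erosion; each test-surface voxel is assigned its Euclidean distance to the
  reference surface via the reference's distance transform — the quantity
  rendered as a 0–5 mm colour wash in 3D reviews.
- **Convergence analysis**: registration accuracy without ground truth.  The
  registration is restarted from `n` (default 20) random initial
  displacements (uniform, ±30 mm / ±5° per axis, seeded) and the
  per-parameter range (max − min) of the final transforms is the accuracy
  measure.  Failed restarts are tabulated and excluded from ranges.

## Synthetic phantoms

The phantom module is the test bed standing in for patient data.  The CT
atlas rasterizes analytic shapes at 2×2×2.5 mm on a 128×128×60 grid: a
soft-tissue body ellipsoid (40 HU), a liver as the union of two overlapping
ellipsoids (60 HU, ~1.1 L — the hepatomegaly range typical of
radioembolization patients), two kidneys (45 HU, ~11 cm long axis), a spinal
cord cylinder (30 HU) inside a vertebral bone shell (700 HU), air at
−1000 HU, and additive Gaussian HU noise (σ = 10).  Masks are the noise-free
analytic shapes, pairwise disjoint.  `organ_scale` shrinks the anatomy for
fast test phantoms.

Subjects are derived by a known diffeomorphic deformation: Gaussian-smoothed
white-noise vector fields (kernel σ = 20 mm) rescaled to a maximum norm of
8 mm and exponentiated; the Jacobian determinant is verified positive
(regenerating with larger smoothness on the rare failure).  The returned
ground-truth field uses the same convention the registration must recover.

SPECT volumes place activity only inside the liver: a base level plus 2–4
Gaussian hot spots (amplitudes 2–4× base, σ 8–15 mm) centred at least 10 mm
inside the boundary — the nonuniform uptake that defeats mutual information
while keeping the organ surface the dominant edge.  The activity is resampled
through the inverse of a known rigid pose onto a cubic 4 mm grid (co-centred
with the CT, padded 32 mm), blurred with an 8 mm FWHM system response, scaled
to 200 expected counts in the hottest voxel, and Poisson-sampled.  Every
generator is a pure function of (spec, seed).

**What the phantoms do not emulate**: reconstruction artifacts, attenuation
and scatter, respiratory motion, real inter-patient anatomical variability
(the deformations are smooth random fields, not anatomy), HU heterogeneity
within organs, and MAA biological breakdown.  Passing phantom tests therefore
establishes the internal consistency and numerical correctness of the chain
— ground-truth deformations recovered, known poses found from arbitrary
starts, dose conserved — not clinical segmentation accuracy, which only
patient studies with expert contours can measure.

## Problem sizes and determinism

The default study sizes (983k-voxel CT, 20 restarts, three demons levels of
50/40/30 iterations) run the full restart analysis in minutes on one core;
unit tests use reduced phantoms (`organ_scale` 0.55–0.8 on 48³–72³ grids)
that preserve the topology.  Every stochastic component (phantom noise,
deformations, hot spots, restart sampling, MI voxel sampling) draws from an
explicit seed, and the registration and demons loops contain no randomness,
so all pipelines are bit-reproducible for fixed inputs.

## Known limitations

- Axis-aligned grids only; no DICOM series assembly or oblique support.
- The demons force is the fixed-gradient (Thirion) variant; symmetric and
  inverse-consistent variants are out of scope.
- The narrow-band metric's band weighting (Gaussian bump, σ = width/3) is one
  consistent realization of matching a gradient ridge to a contour; other
  readings (correlation against |d| or a band indicator) would change the
  objective's shape near the optimum.
- Dosimetry ignores tissue heterogeneity and uses a single calibration
  scalar; no Monte-Carlo transport.
- Kidneys are the hardest structures for single-modality demons on real data
  (small, low contrast); the phantom's high-contrast kidneys do not probe
  that failure mode.
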