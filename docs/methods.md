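# Methods

## The registration model

All geometry is physical: voxel `i` of a volume sits at
`origin + i·spacing` (mm), and every transform, metric and distance is
computed in mm. This matters because the data the pipeline targets have
strongly anisotropic voxels (CT ≈ 1.37×1.37×2.5 mm, MR ≈ 1.9×1.9×6 mm);
voxel-space distances would weight the axes arbitrarily. Only
axis-aligned volumes are supported; a NIfTI/MetaImage header carrying a
rotated or flipped direction matrix is rejected at read time rather than
silently mishandled.

A transform chain maps fixed-domain (CT) points into the moving (MR)
domain — the resampling direction: the registered image is produced by
reading the moving image at the mapped position of each fixed voxel.

**Rigid stage.** r(p) = R(p−c) + c + t with R = R_z R_y R_x (X applied
first; the order is a convention, fixed here because small clinical
rotations nearly commute), c the fixed-image centre, t in mm.

**Elastic stage.** T(p) = r(p) + u(r(p)): the displacement field is
defined in the rigidly-mapped frame. u is a tensor-product cubic
B-spline on a uniform control grid; grid spacing is 8 fixed-image voxels
(converted to mm with the fixed spacing), and the grid covers the
rigidly-mapped fixed domain plus a one-control-point margin so the full
4×4×4 support exists everywhere it is evaluated. The field is C² by
construction; a single-level grid is used (no multi-level refinement).

## The similarity measure and its gradient

NMI = (H_F + H_M)/H_FM with entropies in nats from a 32-bin joint
histogram; NMI lies in [1, 2] (1 at independence, 2 for identical
discretizations). Binning ranges are robust percentiles (0.5–99.5) of
each volume, fixed per resolution level.

Two histogram windows exist deliberately:

* **nearest** — plain binning on both axes. Used for analysis and for
  exact statements: identical discretized images give exactly 2.0,
  relabelling the moving intensity classes (the multimodality property)
  leaves the value exactly unchanged. Any smoothing window breaks both
  statements (β³(0) = 2/3 spreads mass off the diagonal), which is why
  a single window cannot serve both roles.
* **parzen** — cubic B-spline window on the moving axis, linear on the
  fixed axis: the standard differentiable construction. The moving
  intensity is read through a prefiltered cubic interpolant, so
  ∂NMI/∂θ is available in closed form for the six rigid parameters
  (including the (I + ∇u) factor when an FFD is present) and for every
  FFD coefficient. The test suite verifies the analytic gradient
  against central finite differences to 1e-3 relative on twenty seeded
  cases.

Each iteration draws fresh uniform random sample positions in the fixed
domain (5000 rigid / 4096 elastic by default). Samples mapping outside
the moving volume are skipped; the metric is declared invalid when more
than 80% are lost. Intensities outside the binning range are clipped
(their window derivative is zero on the flat clip piece).

## Optimization

Steepest ascent on NMI with the decaying gain step(k) = a/(A+k+1)^α per
level. Two update rules, chosen for the distinct failure modes of the
two stages:

* **Rigid**: the 6-vector gradient is rescaled (rotations by the
  fixed-image half-diagonal so one unit moves corner voxels comparably
  to a translation), normalized to unit length, and stepped — the step
  is then a parameter-space distance in mm. With only six well-excited
  parameters this converges robustly; the terminal jitter equals the
  final step (&lt; 0.5 mm with the defaults).
* **Elastic**: the coefficient update is step(k)·g/‖g₀‖∞, where g₀ is
  the level's first-iteration gradient. Normalizing every iteration to
  full step length (as in the rigid stage) forces thousands of weakly
  constrained control points to take full-length steps through sampling
  noise and random-walks them far from zero; scaling by the initial
  gradient keeps the update self-limiting — near-converged or
  uninformative coefficients move proportionally less. When the grid
  has more control points than the per-iteration budget (default 5000),
  a random subset is updated each iteration.

Initialization: translation from intensity centre-of-mass alignment,
rotations zero, FFD zero.

The default `RegistrationConfig()` is the clinical whole-body protocol:
rigid levels 16/8/4/2/1 and elastic levels 8/4/4/2/2 with iteration
ladder 4096/2048/1024/512/256 (7936 per stage), a = 4000 (rigid) and
2000/7000/20000/20000/30000 (elastic), A = 50, α = 0.6/0.602, 32 bins,
8-voxel grid spacing. Those settings are sized for ~512×512×350 CT
volumes. `RegistrationConfig.compact()` is the package's choice for the
64³ phantom experiments: rigid levels 4/2/1 (300/150/80 iterations,
gains sized so the first step is about one coarse voxel), and a single
full-resolution elastic level (400 iterations, a = 2.5). A 64³ volume
is already at the scale of a clinical coarse level; in development,
adding coarser elastic levels measurably degraded small structures
(brain Dice fell from ≈0.89 to ≈0.75 through over-deformation that the
fine level could not fully undo — the same over-deformation effect that
motivates keeping the elastic pyramid shallow at clinical scale).

Pyramid levels are Gaussian-smoothed (σ = factor/2 voxels) and
subsampled; factor 1 returns the original image. Interim resampled
volumes use linear interpolation, the final output cubic (orders 1/3);
labels always nearest-neighbour when resampled as images.

## Evaluation metrics

Overlap and overlay-error figures are exact voxel counts on the fixed
grid: TO = |S∩T|/|T|, DC = 2|S∩T|/(|S|+|T|), JC = |S∩T|/|S∪T|,
FN = |T∖S|/|T|, FP = |S∖T|/|S|, VS = 2(|S|−|T|)/(|S|+|T|). VS is
*signed* — a negative value means the source region is smaller than the
target. Dice bands: &lt;0.2 poor, 0.2–0.4 fair, 0.6–0.8 good, 0.8–1.0
excellent; the conventionally unlabelled 0.4–0.6 band is reported as
"moderate".

Surface measures operate on boundary voxels — mask voxels with at least
one face-adjacent (6-connectivity) outside neighbour, the array border
counting as outside. The Euclidean distance transform of the target
boundary is computed in mm (anisotropic spacing respected) and sampled
at source-boundary voxel centres: DE is the mean, HD the maximum. HD is
directed (source→target) as defined; a symmetric variant is available
as max(HD_{S→T}, HD_{T→S}). Tests verify both against an exhaustive
all-pairs oracle on masks up to 12³.

Label transfer into the fixed grid: the default interpolates a per-code
indicator channel linearly and takes the arg-max code, which places
region boundaries with sub-voxel accuracy; plain nearest-neighbour
pulling is available (`method="nearest"`). The choice matters at coarse
grids — see the discretization note below.

Landmark error is the Euclidean mm distance between paired named
points, either raw (pre-registration misalignment) or after mapping the
fixed-space point through the recovered chain (registration error);
both readings are supported because either protocol is defensible when
landmarks were identified independently on both modalities.

Cohort statistics follow box-whisker conventions: quartiles by linear
interpolation (stated in the table metadata because quartiles depend on
the convention), outliers beyond 1.5·IQR from the quartiles, whiskers
the extrema after outlier removal, and the 95% median notch
Δ = 1.57·IQR/√n (the McGill rule). Regions missing from some cases
enter their cohort row with reduced n, never silently.

## The phantom: what it emulates, and what it does not

Each case is a stylized whole body on a 64³, (3, 3, 4) mm grid: trunk
with a subcutaneous fat shell, head with a ~6 mm skull shell, neck,
two arms; spherical brain, ellipsoidal lungs, kidneys and liver, a
vertebra-modulated spine and pelvis. Tissue classes carry CT values in
Hounsfield units (air −1000, lung −800, fat −100, soft ~40, bone ~700)
and MR values from a deliberately non-monotone remap (fat and brain
bright, bone dark), so no affine CT↔MR intensity relation exists — the
regime NMI is designed for. A smooth shared "texture" field (±60 HU in
soft tissue) stands in for visceral heterogeneity; without it, interior
deformation would be invisible to any intensity metric, because one
32-bin histogram bin spans ~60 HU of the CT range. The MR rendering
lives on a coarser 48³ (4, 4, 5.33) mm grid and is degraded by a smooth
multiplicative bias field (±8%) and Gaussian noise.

The ground-truth chain is drawn per seed: a random 8 mm translation
with ~2° rotations, plus a smooth random FFD whose coefficients are
bounded at 6 mm — checked against the injectivity limit of 0.4× the
control spacing. The truth is expressed in the same FFD
parameterization the registrar optimizes, deliberately: a recovery
failure then isolates the optimizer rather than model mismatch. The MR
side is rendered through the numerically inverted truth chain, so
applying the truth to the CT-space landmarks reproduces the MR-space
landmarks exactly (a test asserts this to machine precision).

What the phantom does **not** model: anatomical realism (no XCAT-style
detail), respiratory or articulated arm motion, metal artifacts,
MR-specific distortions beyond bias and noise, or segmentation error —
clinical labels come from fallible manual/semi-automatic segmentation,
phantom labels are exact. Passing the recovery experiment therefore
demonstrates that the optimizer recovers deformations the model class
can represent under realistic contrast conditions; it does not predict
clinical accuracy, where segmentation uncertainty and
out-of-model motion dominate.

### Discretization ceiling on phantom Dice

With binary labels on the coarse MR grid, transferred labels localize
region boundaries with a normal-direction error e_n of roughly
0.4–1 mm; for a region of effective radius R this caps Dice at about
1 − 3e_n/(2R). For the phantom kidneys (R ≈ 14 mm) and brain
(R ≈ 19 mm) the ceiling is ≈0.93–0.96 even under the *exact*
ground-truth chain — measured truth-chain Dice across seeds is
0.92–0.96 for those organs and ≥0.97 for body and lungs. The
sub-voxel indicator-argmax transfer is the default precisely because
plain nearest-neighbour pulling roughly doubles e_n and costs ~0.1
Dice on kidney-sized regions. Test bounds on truth-chain
self-consistency reflect these ceilings (≥0.95 body/lungs, ≥0.90
brain/kidneys, DE ≤ 1 voxel).

## Numerical choices and degenerate inputs

* Entropy terms use 0·log 0 = 0; a single-occupied-cell histogram
  returns the defined degenerate NMI value 2.
* The histogram's moving-axis bin coordinate is mapped to [1, B−3] so
  the 4-tap window always fits; partition of unity then conserves
  histogram mass exactly (tested to 1e-6 of the sample count).
* Out-of-volume reads during resampling take the moving-image minimum
  (air) unless configured otherwise.
* Transform files store every float at full precision (`%.17g`);
  round-tripping a chain reproduces its mapping to &lt;1e-9 mm and
  seeded reruns are byte-identical.
* All randomness flows from explicit seeds through
  `numpy.random.Generator`; phantom synthesis, sampling and
  control-point subsetting use separated seed sequences so components
  stay decoupled.
* Empty-denominator metrics raise named errors (`UndefinedMetricError`)
  rather than returning NaN silently; regions absent from one side of a
  case produce flagged records.

## Known limitations

* No inverse-chain computation is offered (CT→MR deformation would need
  a separate registration or a numeric field inversion; the phantom's
  private inversion handles only synthesis-scale fields).
* No regularization term (bending energy) — the optimizer relies on the
  gain schedule and the B-spline's intrinsic smoothness, so aggressive
  schedules can over-deform, as the compact-schedule development
  history shows.
* Single binary region per label code; no fractional or multi-label
  overlap generalizations.
* The full clinical schedule is untested at clinical volume sizes here
  (no such data ships with the package); it reproduces the published
  parameter table exactly and runs, but its wall-clock cost at
  512×512×350 is hours on one CPU.
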