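# Methods

## The registration model

Registration is posed variationally on binary (or probability) masks of the
hyperechogenic structures rather than on raw intensities.  For a reference
mask R (the later surgical stage) and template mask T (the earlier, higher
quality stage), the method seeks a map φ from reference world coordinates
to template world coordinates minimizing

    J(φ) = D(R, T∘φ) + α · S(u),
    D    = ½ ∫ (T(φ(x)) − R(x))² dx,
    S(u) = ∫ μ/4 Σ_{j,k} (∂ⱼuₖ + ∂ₖuⱼ)² + λ/2 (div u)² dx,

where u is only the nonparametric part of the displacement: the parametric
(rigid) bulk motion is never penalized.  SSD is appropriate because both
images are masks of the same structures — a mono-modal problem by
construction.  The elastic potential is discretized with mm-scaled central
differences (one-sided at the boundary, Neumann-style); its gradient is the
exact adjoint of the same stencil, verified in the tests by inner-product
identities and finite differences.

Everything follows the discretize-then-optimize paradigm: each term is
written down on a fixed voxel grid (values weighted by the voxel volume, so
objectives are comparable across pyramid levels) and the resulting
finite-dimensional problem is handed to the optimizer.

### Optimization and stopping

The optimizer is an own l-BFGS (memory 10, two-loop recursion) with Armijo
backtracking, which guarantees a non-increasing objective log — a property
the test suite asserts on every run.  Convergence is declared when the three
local criteria hold jointly,

    |J_k − J_{k−1}| < min_progress · (1 + |J₀|)
    ‖∇J_k‖          < min_gradient · (1 + |J₀|)
    ‖step‖_∞        < min_step,

or when the relative gradient ‖∇J_k‖/‖∇J₀‖ falls below `rel_gradient`, or
when the line search can no longer find descent.  All four tolerances
default to 0.001 and the iteration cap to 100.  The joint convention is the
one used by the variational-registration frameworks this formulation
follows; requiring any single criterion alone turned out to terminate the
elastic stage long before the objective flattened (a progress of 0.1 % of
J₀ per iteration is routine mid-descent).  Hitting the iteration cap is
reported as non-converged.

### Stages and scales

* **Parametric.**  Both masks are Gaussian-softened (σ = 1.5 voxels by
  default) — a hard binary mask has an SSD gradient that vanishes almost
  everywhere — and moved one pyramid level coarse (smooth with σ = 1 fine
  voxel, subsample by 2; node-centered, so world geometry is preserved).
  Stage one optimizes the 3 translation parameters from the tracker-based
  initial guess; stage two all 6 rigid parameters (intrinsic XYZ Euler
  angles about the reference volume's world center, which decouples
  rotation from translation).  Internally the angle parameters are scaled
  by a lever arm (half the volume diagonal) so that translations and
  rotations see comparable gradients.
* **Nonparametric.**  Levels 3 → 2 → 1 of the pyramid; at each level u
  lives on the level's node grid in mm and is prolonged trilinearly to the
  next finer level (mm values need no rescaling).  The template is sampled
  at φ_rigid(x) + u(x) with trilinear interpolation; outside the grid the
  interpolant decays linearly to 0 (background), which keeps the objective
  continuous at the boundary.  The analytic SSD gradient interpolates the
  precomputed world-frame template gradient at the mapped points.
* **Output.**  The chain is serialized as [rigid, field] with the field
  re-indexed so that applying the chain reproduces φ exactly at grid nodes;
  the stored deformed template is produced by resampling through that very
  chain, so chain and artifact can never disagree.

Defaults: α = 0.03, μ = 1, λ = 0 (none of the three has a published value;
α was calibrated once so that the synthetic-field recovery property holds,
and all are exposed in `RegistrationConfig`).

## Segmentation

The network is a compact 3D U-Net: two resolution steps, two conv(3³) +
batch-norm + ReLU blocks per level, max-pool down, transposed-conv(2³) up
with skip concatenation, dropout 0.4 before each convolution of the
synthesis path only, 16 base channels doubling per step, and a 1³ output
convolution.  It is implemented directly in numpy with hand-written
backpropagation (im2col-free shifted-GEMM convolutions, Adam); the full
backward pass is checked against numerical differentiation in float64.

Patches follow the core-plus-context convention: the labelled core
(default (30,30,30)) is surrounded by an (8,8,8) border on every side, so
the network input is 46³ while only the core is predicted and stitched —
tiling therefore produces no seams.  Inputs not divisible by 2^steps are
reflect-padded internally and cropped back.  Volumes are z-scored before
tiling.  Training draws class-balanced patches (half the core centers on
mask voxels; the sheets occupy < 5 % of the volume, so uniform sampling
would starve the foreground) and minimizes voxel-wise binary cross-entropy
(soft Dice by flag); every `val_interval` iterations the mean Jaccard index
over a fixed set of validation patches is recorded and the best checkpoint
kept.  An optional early stop ends training once a requested validation
Jaccard is reached.  All randomness (initialization, sampling, dropout) is
seeded, and being pure numpy, runs are bit-reproducible on a fixed BLAS.

Defaults follow the published operating point (patch (30,30,30), padding
(8,8,8), batch 15, learning rate 10⁻³, 75 validation samples every 100
iterations); the test suite exercises a scaled-down configuration (12³
cores, 4-voxel borders, batch 4, 48³ volumes) chosen as the smallest
problem on which the capacity and stitching properties are meaningful.

## The synthetic phantom

The generator emulates exactly the features the method depends on, and no
more:

* **Geometry** — 64³ voxels at 0.5 mm isotropic (a 32 mm field of view);
  three curved sheets (graphs of random low-order trigonometric height
  functions, one per axis orientation) thickened to 1.5 mm: sulci/falx
  analogues that cross and form corners.
* **Intensity** — structure mean 180, background mean 60, multiplied by
  right-skewed speckle (1−s) + s·Exp(1) with s = 0.3, lightly smoothed.
  Only the hyper/hypo-echogenic contrast matters to a mask-driven method;
  no acoustic simulation (shadowing, probe geometry) is attempted.
* **Landmarks** — sampled from the top-decile curvature voxels of the mask
  with a 3 mm margin from the volume border, mirroring how annotators pick
  distinctive corners of sulci inside the well-imaged overlap.  On a flat
  sheet patch tangential correspondence is genuinely ambiguous (the
  aperture problem), so featureless landmarks would measure an error no
  mask-driven — or human — method could resolve.
* **Deformations** — `random_smooth_field` draws low-order global modes
  (constant, linear, bilinear, half-period sine) scaled to a chosen peak
  magnitude: brain shift seen through a 32 mm window is organ-scale
  coherent motion, not voxel-scale noise.  `deform_phantom` maps landmarks
  through the exact analytic motion and pushes the volume forward through
  the motion's inverse (closed-form for rigid, fixed-point for fields), so
  returned landmarks are the exact ground-truth correspondence.
* **Resection** — a sphere whose interior drops to background and whose
  1.5 mm shell turns bright; the shell is deliberately left out of the
  ground-truth mask because resection cavities are precisely the false
  positives that confound mask-based registration on real data.

What passing tests therefore show: the engine recovers rigid and smooth
elastic motions of sheet-like structures under speckle, with landmark
errors evaluated at identifiable corners.  What they cannot show: behavior
under real acoustic artefacts, shadowing, blood products, probe pressure,
or anatomy whose structures vanish between stages.

## Evaluation choices

* TRE is ‖chain(reference landmark) − other landmark‖ in mm; reports carry
  per-point distances and mean/std/min/max.
* Correspondence-restricted Dice labels predicted components with
  26-connectivity and discards those sharing no voxel with the manual mask
  (thin diagonal sheets make 6-connectivity fragment).
* Capture range: trials start from random pure translations of each probed
  magnitude (so the initial mean TRE equals the offset); a trial succeeds
  if the final mean TRE is at most max(1 voxel, 1.5 × the unperturbed
  run's result).  The returned range is the largest offset with ≥ 80 %
  successes, cut at the first failing offset; if every probed offset
  passes the result is flagged censored.

## Numerical notes and limitations

* World convention is a single fixed LPS mm frame (ITK's native one);
  voxel indices are 0-based, node-centered.
* Intensities are stored float32; objectives accumulate in float64.
* The fixed-point field inversion assumes displacement gradients below 1
  (smooth, moderate fields) — adequate here, not for folding deformations.
* Masks leaving the field of view read as background; structures that
  genuinely exit the volume (or are resected) contribute an error floor no
  algorithm can remove, which is why phantom landmarks keep a border
  margin.
* The elastic stage can slightly perturb an already-exact rigid alignment
  by fitting interpolation noise (≈ 0.1 mm at 0.5 mm voxels); on genuinely
  deformed pairs it improves on the parametric stage throughout the test
  suite.
* Timings are logged for information but never asserted.
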