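# Methods

This note describes the models, algorithms and numerical choices behind
`fetalmsp`, and what the synthetic phantom experiments do and do not show.

## Problem and overall design

The mid-sagittal plane (MSP) of the fetal head is the standard view for
first-trimester biometry (nuchal translucency, nasal bone). Given a 3D
ultrasound volume resampled on a Cartesian voxel grid, the system finds the
MSP fully automatically in two stages:

1. **Seed point.** A cascade of four 2D networks locates the head centre
   (a dark central structure, the diencephalon): a U-net-with-ASPP
   segmentation network on the sagittal view gives the in-plane position, two
   single-box detection networks on the axial and coronal views give the
   left–right position, and two further segmentation passes refine both.
2. **Plane mask.** An 80-voxel cube (desk scale: 32) cropped around the seed
   is mapped by a 3D generator network to a soft plane mask — MSP detection
   treated as filtration rather than plane classification. The generator is
   trained adversarially: a critic scores two-channel *combined* inputs
   (mask ⊙ volume, volume), and the generator loss mixes the adversarial
   term with a voxelwise cross-entropy to the ground-truth mask:

   L_G = −(1−w)·E[C(x′)] + w·L_ce,
   L_C = E[C(x′)] − E[C(y′)] + λ·E[(‖∇_{x̂′} C(x̂′)‖₂ − 1)²],

   with w = 0.8, λ = 10, x̂ = αy + (1−α)x, α ~ U(0,1) per sample. Both
   networks are updated alternately (one step each) with Adam
   (lr 10⁻⁴, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸, batch 8).
3. **Post-processing.** The soft mask is reduced to plane coefficients by
   weighted total least squares; the 2D MSP image is resampled along the
   plane through a rigid map M = TR from the initial axis-aligned sagittal
   grid.

## Coordinate and plane conventions

* 0-based voxel indices; axis 0 is left–right, so a well-aligned MSP has a
  normal dominated by axis 0. Sagittal slices are `volume[i]`, axial slices
  fix axis 2, coronal slices fix axis 1.
* A plane is stored as a coefficient 4-vector (a,b,c,d) of ax+by+cz+d = 0,
  normalized to unit 4-norm with the first nonzero normal component
  positive. All coefficient-space metrics assume this convention; without
  it the coefficient distance is not well defined.
* Obliquity is parameterized by two angles applied to the sagittal plane
  through the seed: θ_axi (a rotation about the volume z-axis — the tilt
  seen on axial slices) followed by θ_cor (about the y-axis — seen on
  coronal slices). Rotation-axis naming in anatomy-to-volume
  mappings is genuinely ambiguous across the field; the
  convention here is self-consistent and exactly invertible
  (`angles_from_plane ∘ plane_from_angles = id` for |θ| < 90°).
* Plane metrics (included angle, coefficient distance, yaw, roll) are
  evaluated on **seed-centred** coefficients — the labelling convention
  places the origin at the seed point, which keeps d of comparable scale to
  the normal components.

## Evaluation metrics

For normalized 4-vectors v₁, v₂: included angle θ = arccos|v₁·v₂|;
coefficient distance d = ‖v₁−v₂‖₂ (so d² = 2(1−cosθ) identically);
yaw = arctan(b/a) and roll = arctan(−c/√(a²+b²)), reported as absolute
differences between methods. The absolute dot product makes antipodal
representations of one plane compare as identical. Cohort agreement between
two measurement arms uses the paired-difference mean, SD, t-based 95% CI,
Pearson r, a paired t-test, and Bland–Altman bias with ±1.96·SD limits of
agreement; a zero-variance difference reports p as not-applicable rather
than NaN. Cross-validation folds are compared by one-way ANOVA per metric.

## Network architectures

**Generator** — a symmetric 3D autoencoder: four stride-2 4³ convolutions
(desk-scale channels 8/16/32/32), two dense layers through a latent vector
(desk scale 128), four stride-2 4³ transposed convolutions, leaky-ReLU
(slope 0.2) activations and a sigmoid output. Each convolution is followed
by batch normalization — a stabilization detail the architecture leaves
open; without it the bottlenecked autoencoder
converges to an input-independent "mean mask" at this learning rate. The
final bias is initialized to the logit of the sparse-mask base rate. The
full-scale configuration (channels 16/32/64/64, latent 200) is the default
`GeneratorConfig`.

**Critic** — four stride-1 3³ convolutions with one 2× max-pooling per
layer and a dense head; the output is a latent vector (not a scalar) passed
through a sigmoid, and every expectation over the critic reduces that
vector by its mean. This reduction is the single largest interpretation
choice in the loss (a latent-vector critic inside scalar expectations);
the gradient penalty is likewise taken through the reduced scalar. The
pooling is applied at the start of each layer (pool → conv → leaky ReLU),
which halves the grid every convolution runs on; with one pooling per layer
either order yields the same output resolution, and this order makes CPU
training of the full protocol tractable. No normalization layers are used
in the critic (they would couple samples and invalidate the per-sample
gradient penalty). The critic's channel widths mirror the generator
encoder.

**Seed cascade** — segmentation: a depth-2 2D U-net (base 8 channels) with
an ASPP bottleneck (parallel 3³ dilated convolutions at rates 1/2/4 fused
by a 1×1 convolution), trained with Adam (lr 10⁻³, batch 10) on binary
cross-entropy against the diencephalon label; detection: three stride-2
convolutions and two dense layers emitting (objectness, cx, cy, w, h)
through sigmoids (boxes intrinsically clamped to the slice), trained with
SGD (lr 0.01, momentum 0.9, weight decay 5·10⁻⁴, batch 5) on cross-entropy
plus Huber loss (box terms masked to head-containing slices). Training
slices per phantom: the three slices through the seed per view plus two
off-centre negatives.

## Differentiation engine

No deep-learning framework is part of the dependency set; the networks run
on a small reverse-mode automatic-differentiation engine over numpy
(`fetalmsp.autodiff`). Every primitive's vector–Jacobian product is itself
composed of engine primitives, so gradients can be differentiated again —
required because the critic update differentiates the gradient-penalty term
(a gradient of a gradient norm) with respect to the critic weights.
Convolutions are im2col gathers plus a matmul; transposed convolutions a
matmul plus the adjoint scatter; both directions are described by a cached
`GatherPlan` of strided block slices. Gradient correctness (first and
second order) is pinned to finite differences in the test suite.

## Synthetic phantom

Clinical first-trimester volume datasets of this kind are private, so the
package generates head-like phantoms with known ground truth: an ellipsoidal bright shell
(radii ≈ 0.30–0.36 of the smallest dimension) around a mid-intensity
interior; a dark central blob (radius 0.09·min-dim) at the seed point;
paired bright internal features mirror-symmetric about the ground-truth
plane; on-plane features (a bright nasal-tip analogue and a dark nuchal
band — on the plane so they do not break its symmetry); and a nose-like
protrusion outside the shell whose side along axis 2 encodes left/right
head orientation, making flip alignment learnable. The plane passes
through the seed with θ_axi, θ_cor drawn uniformly within ±30° (the
clinical inclusion baseline). The volume is Gaussian-blurred (σ = 1) and
multiplied by unit-mean gamma speckle; `noise_level` is the variance of
that multiplier, default 0.1 — a moderate B-mode-like degradation. Ground
truth masks are rasterized at half-thickness 0.5 voxel (a one-voxel-thick
digital plane).

What the phantom does **not** emulate: ray-dependent shadowing and probe
geometry, anisotropic voxels, fuzzy tissue boundaries, inter-subject
anatomical variability, or any quantitative match to clinical image
statistics. Passing phantom tests therefore demonstrates that the
implementation of the method is correct and that the pipeline recovers
planted symmetry planes under speckle — not clinical-grade accuracy.

## Problem sizes and numerical choices

* Desk-scale experiments run at 32³ voxels with the narrow network widths
  above; cohort sizes are 150–200 training phantoms with 50 held out, the
  adversarial stage trained for 30 epochs at batch 8. These sizes were
  chosen so the full protocol — phantom synthesis, both training stages and
  evaluation — completes on a single CPU core.
* Plane fitting thresholds the soft mask at 0.5 (falling back to 0.25 and
  0.1, then to the side²-strongest voxels, for timid masks) and weights
  voxels by mask value in the total-least-squares fit; the fitted normal is
  the smallest principal axis of the weighted centred scatter. Collinear
  support (second singular value ≈ 0) is rejected.
* Cross-entropy clips predictions to [10⁻⁷, 1−10⁻⁷]; the gradient-penalty
  norm adds 10⁻¹² inside the square root; arccos arguments are clamped to
  [−1, 1].
* The ±30° exclusion boundary is inclusive. Cross-validation uses a seeded
  permutation with a striped near-equal partition (for n = 218 and five
  folds: 174–175 train / 43–44 test).
* Every stochastic component (phantom synthesis, fold assignment, batch
  order, interpolation weights α, weight initialization) draws from a
  `numpy` generator derived from a single run seed; repeated runs are
  bit-identical.

## Known limitations

* The critic's final sigmoid bounds the Wasserstein surrogate; it is kept
  as specified even though it weakens the adversarial signal (the
  cross-entropy term, w = 0.8, dominates training in practice).
* At desk scale the seed cascade localises the head centre to ~0.3 voxel
  median on held-out speckled phantoms. The mask generator's plane
  orientation is the weak point of the scaled protocol: after 30 epochs
  (750 optimizer steps at the fixed learning rate 10⁻⁴) the median
  plane-to-plane angle on held-out phantoms is ~9–12°, with the error
  concentrated on strongly oblique cases (|θ| > 15°) — the network is still
  regressing extreme orientations toward the mean. The in-plane offset is
  already sub-voxel (median ~0.2 voxel), and doubling the training length
  brings the angle median to ~6° and falling, so the limitation is the
  optimization budget of the scaled protocol rather than the method. Clinical-grade
  sub-degree accuracy on real data cannot be demonstrated without a
  clinical cohort.
* Geometry is voxel-based; physical spacing is metadata only.
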