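# Methods

## Problem and model

`lungreg` aligns a fixed volume F and a moving volume M (inhale/exhale lung
CT being the motivating setting) by estimating a dense deformation
y(x) = x + u(x) that minimizes

    L(F, M, y) = D(F, M∘y) + α R(y) + β B(y) + γ V(y) + δ K(y).

* **D — normalized gradient fields (NGF).** Breathing changes tissue density,
  so intensity constancy fails between inhale and exhale; NGF compares local
  gradient *orientation* instead of intensity. Per voxel,
  `1 − ⟨∇M∘y, ∇F⟩²_ε / (‖∇M∘y‖²_ε ‖∇F‖²_ε)` with
  `⟨f,g⟩_ε = Σ f_j g_j + ε²`; the integrand lies in [0, 1]. The edge
  parameter ε (default 1, CT-appropriate) suppresses noise gradients; a
  heuristic `ε = ν · mean‖∇I‖` (noise level ν) is provided. When a lung mask
  is available, D is averaged over the mask support only; all other terms are
  evaluated on the full grid (only the distance term is mask-restricted).
* **R — curvature regularizer.** Mean over interior voxels of
  `Σ_j (Δu_j)²` with the 7-point Laplacian stencil in voxel units. Affine
  maps have zero curvature, so the term penalizes bending, not scaling or
  translation.
* **V — volume-change control (VCC).** `ψ` applied voxelwise to
  `det∇y`: `ψ(z) = (z−1)²/z` for `z ≥ t`, continued for `z < t` by its C¹
  linear extension `(1 − 1/t²) z + 2(1−t)/t`. The penalty is minimal at
  z = 1 (no volume change), symmetric under z ↔ 1/z on its smooth branch,
  and a barrier against folding (det ≤ 0). The barrier is *raised* over the
  multilevel schedule: t = 0.2 on the coarsest level, halved per finer level
  (0.2, 0.1, 0.05 for three levels). A hard variant ((z−1)²/z with +∞ for
  z ≤ 0) and the parametric log-barrier extension are also provided; note
  the log-barrier's branch point is z = 1/t², so its schedule *increases* t
  over time, and ψ̃_t(1) = 0 only holds for t ≥ 1.
* **B — mask alignment.** ½ · mean over voxels of the squared channel-wise
  difference between the fixed one-hot lobe mask and the *linearly* warped
  moving one-hot mask (linear warping yields probabilistic boundary values
  and a smoother loss than nearest-neighbour).
* **K — keypoints.** Mean squared Euclidean distance in mm² between moving
  keypoints and the displaced fixed keypoints y(k_F). Deliberately
  unnormalized by image size, which is why its weight is large relative to
  the mean-based image terms.

Default weights: α = 10, β = 1, γ = 0.01, δ = 1e7 (δ = 0 on the coarsest
level so it can focus on coarse alignment), ε = 1.

Discretization choice: every ∫…dx is a **mean over the voxel set**, not a
sum times voxel volume, so a single weight set remains comparable across
pyramid levels and grid sizes.

## Multilevel scheme

Images are Gaussian-smoothed (σ = 1 voxel per halving, edge-replicated) and
downsampled by 2^(L−1) for the coarsest of L levels. Per level, the moving
image is first warped **at full resolution** with the composition of all
preceding level fields, then both images are downsampled and the level solver
estimates a residual displacement; that residual is prolonged (linear
upsampling; voxel-unit components scaled by the shape ratio so physical
displacement is preserved) and composed functionally:
`u_new(x) = u_fine(x) + u_coarse(x + u_fine(x))` — the coarse field applied
after the fine refinement, since the solver saw a moving image already
carrying the coarse warp. Lobe masks are warped nearest-neighbour at full
resolution and subsampled; keypoints stay in full-resolution mm coordinates,
with the level loss chaining the level field through the frozen coarse field.

## Solvers

* **Instance solver** — minimizes L directly over the displacement field of
  one pair with Adam (step 0.01 on voxel-unit displacements), starting from
  u = 0 and returning the best-loss iterate (robust to overshoot). Default
  per-level budgets are 400/200/100 iterations coarse→fine.
* **Displacement-regression network** — a 3-level 3D U-Net (3³ convolutions
  + instance norm + ReLU; 2³ average pooling; 2³ transposed-convolution
  upsampling with half the filters; 1³ head to 3 components; zero padding
  keeps spatial shape; Xavier-uniform initialization). Levels are trained
  progressively with Adam at 1e-3: coarsest first (δ = 0), each finer model
  initialized from the previous level's parameters while the frozen coarser
  models supply the initial composed field (recomputed by the frozen models
  each pass). Inference needs images only; masks/keypoints are training-time
  inputs. Batch size is 1 (one 3D pair per step).

All differentiable machinery runs on a small NumPy reverse-mode autodiff
engine written for this package (`lungreg.autodiff`); its gradients are
verified against central finite differences in the test suite, both per
primitive and through the full loss.

## Synthetic phantoms

The generator emulates the features the method actually exploits: an
ellipsoidal "lung" partitioned into five lobe-like compartments (nearest of
five seeds under a smoothly warped metric), ≥ 20 bright tubes of radius 1–3
voxels as vessel analogues, ≥ 50 keypoints on tube centerlines, and a known
smooth fold-free ground-truth deformation (Gaussian-smoothed tapered noise,
rescaled to a requested maximum displacement and redrawn until
min det∇y > 0.1). Default study conditions: 64³ voxels at 1 mm spacing,
8-voxel maximum displacement, a multiplicative intensity shift of 0.8 plus
additive noise (σ = 2) on the exhale image to defeat intensity constancy.
The fixed image is the *deformed* copy (F = I∘y, M = I), so keypoint pairs
kM = y(kF) are exact without field inversion; fixed keypoints are re-detected
on the warped tubes. Everything is deterministic per seed.

What the phantoms do **not** model: sliding motion at the pleura, CT
reconstruction artefacts, dose-dependent noise differences, or anatomically
realistic airway/vessel trees. Passing the recovery tests shows the loss,
composition and solver machinery behave as designed — it does not certify
clinical registration accuracy.

## Evaluation

Dice `2|X∩Y|/(|X|+|Y|)` per lobe; average symmetric surface distance and
symmetric Hausdorff distance over 6-connected boundary voxels at voxel-center
coordinates in mm (no subvoxel meshing); landmark TRE in mm (plain
distances, not squared); folding fraction = proportion of voxels with
det∇y ≤ 0 (counting singular voxels as folded), with determinant histograms.
Percentiles interpolate linearly between order statistics. A Dice30 helper
summarizes the worst 30 % of cases.

## Numerical choices

* Displacements are stored in voxel units of their own grid; mm conversions
  happen only at keypoint/TRE boundaries.
* Out-of-domain samples are clamped to the boundary (edge replication);
  clamped coordinates also receive zero coordinate-gradient.
* Image gradients for NGF are spacing-aware central differences (one-sided
  at faces); the Laplacian and Jacobian act in voxel units, so the identity
  map has det 1 under anisotropic spacing.
* ψ is applied to the voxelwise determinant map without subvoxel quadrature.
* Composition order is coarse-after-fine (see Multilevel scheme).
* Prolongation samples stride-aligned source coordinates (target index j
  maps to source j/ratio), matching the subsampling convention of the
  pyramid, and clamps at the far face.

## Test-suite problem sizes

The recovery experiment runs one 64³ pair with the default iteration
budgets. The ablation suites use 32³ pairs over 5 seeds: the VCC ablation
uses aggressive conditions (8-voxel displacement at smoothness 6, 100
keypoints carrying 2 mm detection noise — emulating automatically detected
correspondences with 1–2 mm residual error — and a deepened fine-level
budget) because weakly converged, noise-free solves produce essentially no
folding under either setting; the keypoint ablation uses 6-voxel pairs; the
level-count ablation uses 12-voxel displacements where a single-level solve
is prone to local minima. The network smoke test trains the coarsest level
of a base-8-filter model on ten 32³ pairs for three epochs. Folding in the
VCC ablation is measured inside the lung mask: the one-sided difference
stencils at the clamped domain faces generate boundary det artefacts that
are unrelated to the penalty being tested.

## Known limitations

* The instance solver's Adam updates are per-voxel sign-normalized, which
  converges slowly on globally coherent modes (e.g. a pure translation)
  when no keypoints or masks supply coherent gradients; the multilevel
  scheme and multi-scale image content mitigate this. Second-order or
  parameter-space (network) solvers do not share the issue.
* No inverse fields, no diffeomorphic scaling-and-squaring integration, no
  affine prealignment (inputs are assumed prealigned), axis-aligned grids
  only.
* The hard ψ variant is non-differentiable and only used for reporting.
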