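# Methods

## Problem setting

Image-guided adaptive radiotherapy of abdominal/pelvic tumors benefits from
frequent diagnostic-quality fan-beam CT, but repeated scanning at normal
tube current adds radiation dose. Scanning at ~1/10 tube current (24 mA vs
233 mA at 120 kV; effective dose 0.71 mSv vs 7.28 mSv via the 0.015
mSv/(mGy·cm) adult abdominal tissue weighting factor) produces images
degraded by photon-starvation noise and streak artifacts. This package
restores such low-dose CT (LDCT) slices toward normal-dose quality (NDCT)
using *unpaired* training data — the two dose levels are acquired in
different treatment fractions, so no pixel-aligned pairs exist.

## Model

Two generators and two patch discriminators are trained jointly:
G_A: LDCT→NDCT, G_B: NDCT→LDCT, with D_B judging real/synthetic NDCT and
D_A judging real/synthetic LDCT. The total generator objective is

    L = L_adv(G_A, D_B) + L_adv(G_B, D_A) + λ_cyc·L_cyc + λ_iden·L_iden

where L_cyc is the L1 cycle-consistency penalty on A→B→A and B→A→B round
trips and L_iden the L1 identity penalty (each generator applied to its own
target domain). λ_cyc = 20 and λ_iden = 0.5 by default.

**Adversarial variant.** The objective is printed in logistic (min–max)
form in the source literature of this family, but least-squares adversarial
loss is the de-facto stabilizer for cycle-consistent translation; both are
implemented (`gan_loss: lsgan | log`, default `lsgan`, the log form in its
non-saturating generator version).

**Generator.** Each generator runs two branches in parallel on a
single-channel slice in [0, 1]:

* *noise branch* — 7×7 stride-1 stem (64 ch), two 3×3 stride-2
  downsamplers (64, 128 ch), nine 3×3 residual blocks
  (reflection-padded conv → instance norm → ReLU → conv → instance norm,
  identity skip), two 3×3 stride-2 transposed-conv upsamplers (256, 128
  ch), 7×7 stride-1 head to one channel — its output n̂ is the predicted
  noise map;
* *content branch* — a skip-connected encoder–decoder: 4×4 stride-2 stem,
  up to seven down units (LeakyReLU 0.2 → 4×4 stride-2 conv → instance
  norm; channel ladder 64, 128, 256, 512, 512, 512, 512, 512), mirrored
  transposed-conv up units with skip concatenation, 4×4 stride-2
  transposed-conv head to one channel (the content prediction ĉ).

The *fusion head* reconstructs the output as a 1×1 convolution over
concat(x − n̂, ĉ). Its two weights are initialized to (1, 0) with zero
bias, so a freshly built generator is an exact pass-through of the
noise-corrected input — and since n̂ ≈ 0 under the Gaussian weight
initialization (std 0.02), the generator starts as a near-identity map.
This is the content-noise *complementary* reading of the dual-branch
design: the residual branch explains the noise, the content branch the
anatomy, and training only has to refine a map that already preserves the
patient. It also makes the branch ablations exact: zeroing the content
fusion weight leaves a pure residual noise-subtracting predictor, zeroing
the noise weight a pure skip-connected content predictor. Without the
identity start, a from-scratch generator needs on the order of 10⁴
adversarial steps before its output error drops below the ~20 HU total
error of a typical low-dose slice — far more optimization than a
desk-scale run performs.

No output nonlinearity is applied; outputs are clipped to [0, 1] only when
slices are assembled at inference.

**Discriminator.** The 70×70-receptive-field patch discriminator: 4×4
convolutions with strides 2, 2, 2, 1, 1 and channels 64, 128, 256, 512, 1;
instance norm on all but the first layer; LeakyReLU 0.2. A 256×256 input
yields a 30×30 score map.

**Instance normalization** carries no affine parameters and no running
statistics, so training- and evaluation-mode forwards are identical and
batch composition cannot leak between samples.

**Width scaling.** All channel counts scale linearly with `base_channels`
(default 64 = the published architecture). The content-branch depth is
capped at log₂(patch)−1 so the bottleneck never collapses below 1×1; the
innermost encoder unit skips instance norm (1×1 spatial statistics are
degenerate).

## Preprocessing

HU slices map to the unit interval by I_nor = (I_HU + 1000)/2800 — the
window [−1000, 1800] HU, equivalently window level 400 / window width
2800 — with out-of-window values clipped (lossy, documented; the inverse
I_HU = I_nor·2800 − 1000 is exact inside the window). Training draws
random fully-in-bounds square crops per slice, each independently rotated
by k·90° and flipped with probability ½ per axis ("random rotation" is
read as right-angle rotation; arbitrary angles would need interpolation).
Domain-A and domain-B patches always come from independently chosen slices
— no pairing is assumed or exploited. Slices are 2-D throughout; no
volumetric network is used.

## Training loop

Adam (β₁ = 0.5, β₂ = 0.999) at base rate 2·10⁻⁴, constant for the first
150 of 250 epochs then linearly decayed to exactly zero; mini-batch 4.
Within an iteration the generators update first (on the four-term loss),
then both discriminators, which draw their fake inputs from a replay pool
of 50 previously generated images (probability ½ of swapping; size 0
disables it). Iterations per epoch default to ⌈max(|A|, |B|)/batch⌉ times
`patches_per_slice` (default 1; the scaled test suite uses 4 so that an
epoch visits roughly every disjoint 64×64 patch of its 128×128 slices
once). A single master seed derives independent streams for each network's
initialization, patch sampling and the replay pool via seed-sequence
spawning; runs are bit-reproducible on fixed hardware and thread settings.
A non-finite loss aborts with a diagnostic checkpoint.

## Inference

Full slices are restored by sliding a tile (default 256, stride 128 = 50 %
overlap) over the normalized slice, pushing each tile through G_A, and
averaging overlapping outputs — uniformly by default, or with a Gaussian
center-weighted profile (σ = tile/4, floored at 10⁻³ so coverage never
vanishes). The final tile position per axis is clamped into bounds rather
than padded, so the network only ever sees real image content. The
assembled slice is clipped to [0, 1] and de-normalized; geometry (spacing,
origin, orientation, slice count) is copied from the input.

## Evaluation metrics

* MAE = (1/m)Σ|Xᵢ−Yᵢ|, MSE = (1/m)Σ|Xᵢ−Yᵢ|²; Y is the reference.
* PSNR = 10·log₁₀(MAX²/MSE) dB. MAX is the reference-image maximum by
  default or a fixed 2800 HU range by flag; identical images report a +∞
  sentinel. (A dimensionally inconsistent historical variant
  20·log₁₀(MAX/MSE) is available as `as_printed` for auditability only.)
* SSIM with C1 = (0.01L)², C2 = (0.03L)²: windowed mode (default)
  averages the SSIM formula over 11×11 Gaussian-weighted windows
  (σ = 1.5); global mode evaluates it once from whole-image moments.
* DSC = 2|A∩B|/(|A|+|B|); both-empty masks define DSC = 1.
* HD95: 95th percentile of the pooled directed surface-to-surface
  distances (both directions — symmetric by construction; some tools
  instead take the max of per-direction percentiles). Surfaces are
  face-connectivity boundary voxels; distances in mm via voxel spacing.
  Computed in 3-D over the volume.
* Equal-variance two-sample t test (two-sided) for table-style summaries.
* Effective dose = DLP × 0.015 mSv/(mGy·cm).

## Synthetic phantom and dose simulator

The phantom emulates an axial abdominal/pelvic section on a fixed ~50 cm
field of view (in-plane spacing 0.9765·512/side mm, slice thickness 3 mm):
body ellipse with subcutaneous fat ring (−100 HU), soft tissue (+40),
vertebral body and femoral heads (+700), urine-filled bladder (+10),
rectum with optional gas pocket (−1000); air background exactly −1000 HU.
Per-phantom tissue means jitter by N(0, 8²) HU and a smoothed
Gaussian-field texture (σ = 10 HU, correlation ≈ 2 px) is added inside the
body; anatomy drifts ±5 % across slices of a stack.

Dose degradation follows tube-current physics: HU → linear attenuation at
a single effective energy (μ_water = 0.19 cm⁻¹ at 120 kV), parallel-beam
Radon projection (180 angles), Poisson sampling of the transmitted
intensity I₀·f·exp(−line integral) plus Gaussian electronic noise
(σ_e = 5 counts), a one-count photon-starvation floor, log transform and
ramp-filtered back-projection. f is the tube-current ratio: 1 for the
NDCT analog, 24/233 for the LDCT analog. I₀ = 2·10⁷ counts/bin was
calibrated once so the f = 1 reconstruction's soft-tissue noise (measured
against the noiseless FBP of the same phantom) is ≈10 HU at the default
256 grid — a diagnostic-quality analog; the LDCT analog then carries
≈√(233/24) ≈ 3.1× that noise, with visibly streaky (spatially correlated)
texture.

What the simulator does *not* model: fan-beam/helical geometry, scatter,
beam hardening, bowtie filtration, spectral effects, metal, and anatomy
beyond piecewise ellipses. Passing tests therefore demonstrate the
pipeline's correctness and the direction of restoration gains under
Poisson/FBP noise, not clinical performance on patient scans.

## Scaled study sizes

The test suite and the acceptance script run the full pipeline at desk
scale, chosen once: 128×128 phantoms (16 unpaired slices per domain),
64×64 patches, 30 epochs with the decay starting at epoch 15,
`base_channels` 8, `patches_per_slice` 4, batch 4; evaluation on 8
held-out phantoms with paired clean/low-dose volumes. At this scale the
low-dose analog carries ~17 HU mean absolute error against the clean
phantom (~14 HU of which is the FBP discretization floor common to every
reconstruction), and a training run comprises only ~500 optimizer steps —
three orders of magnitude fewer than the full-scale protocol. The
end-to-end comparison (restored vs low-dose, against the clean phantom)
is reported as measured.

## Numerical choices

* The tensor engine works in float32 (float64 for gradient checks);
  convolution gradients use exact kernel-position scatter/gather.
* Instance-norm ε = 10⁻⁵; Adam ε = 10⁻⁸.
* Patch sampling reflect-pads slices smaller than the patch and records
  the padding; positions are uniform over in-bounds placements.
* Tile weights: uniform, or Gaussian floored at 10⁻³; accumulation checks
  full coverage before dividing.
* HU outside the normalization window are preserved by I/O and clipped
  only in preprocessing.
* DICOM series are validated for consistent orientation and pixel spacing
  (the offending slice is named), sorted by position along the slice
  normal, and rescaled by slope/intercept per the DICOM standard — the
  stored-pixel convention is not specified by the study design and
  follows the standard.

## Known limitations

* The restoration quality achievable at desk scale is bounded by the
  small number of optimizer steps such a run performs. With the
  identity-initialized fusion the generator
  trains stably toward a faithful pass-through (no brightness bias,
  cycle/identity losses falling monotonically), but the *adversarial*
  pressure that produces actual noise removal does not engage within a
  few hundred to a few thousand optimizer steps: the cycle term (weight
  20) favors preserving noise, since the reverse generator would have to
  re-synthesize it to close the round trip, and overcoming that requires
  the long adversarial schedule of the full protocol. At desk scale the
  restored images therefore approach — but do not surpass — the low-dose
  input's fidelity to the clean phantom, and the end-to-end numbers
  reported by the acceptance script document exactly that. Magnitudes of
  the full-scale study (e.g. MAE 34.3 → 20.3 HU on patient data) are out
  of reach by design.
* The "standard normal" weight initialization mentioned for the published
  experiment is honored as a config option (`init_std: 1.0`) but defaults
  to 0.02: unit-variance Gaussians destabilize adversarial training, and
  the phrase is presumed an imprecision.
* SSIM's window mode and intensity scale for the published tables are
  unspecified; reports record which convention produced each number.
* Checkpoints store raw parameter arrays plus a config snapshot
  (versioned); they are not portable to other tensor frameworks.
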