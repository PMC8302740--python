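# Methods

`qcbct` measures volumetric bone mineral density (BMD, mg/cm³) from dental
cone-beam CT (CBCT). CBCT voxel intensities are arbitrary — spatially
non-uniform and nonlinearly related to attenuation — so a phantom
calibration alone cannot convert them to BMD the way it converts
multi-detector CT (MDCT) Hounsfield units to quantitative CT (QCT). The
package implements the full measurement chain: phantom-based linear
calibration, landmark registration and anatomy masking, a hybrid
intensity-mapping network (cycle-consistent adversarial pair followed by a
two-channel U-Net), and an agreement-metric suite, all exercisable
end-to-end on synthetic paired phantoms.

## The measurement model

**Calibration.** A phantom with three calcium-hydroxyapatite inserts (0,
100, 200 mg/cm³) is imaged in each modality. Density is regressed on the
three insert ROI mean intensities by ordinary least squares (density as
the response, so the fitted line is applied directly voxelwise). Using all
three inserts rather than an exact two-point line yields an RMS residual,
a useful linearity QC number: it is ~0 for the CT side and visibly nonzero
for the CBCT side. Applying the CBCT-side line to a CBCT volume gives the
CAL_CBCT baseline — the best a linear correction can do. Voxels equal to
the background sentinel (−1000) pass through calibration unchanged so that
masked-out background never acquires a fabricated BMD. The insert ROI
radius is configurable (default: the full insert radius; the pipeline uses
4 voxels to avoid rim partial-volume voxels).

**Registration and grid harmonization.** Paired CT/CBCT volumes are
aligned from six dental landmarks (lateral-incisor vertices, first-premolar
buccal cusps, first-molar distobuccal cusps) by the closed-form
least-squares rigid fit (Kabsch/SVD). Coordinates are 0-based voxel indices
times voxel spacing; the moving volume is resampled trilinearly onto the
fixed grid (out-of-field voxels = −1000), then center-cropped and
bilinearly resized per axial slice to the network geometry (the reference
protocol crops 559×559×200 and resizes to 256×256×200; grid sizes are
arguments throughout). Masks are resampled with nearest-neighbour
interpolation so they stay binary.

**Anatomy masks.** Per axial slice: a local range filter (max−min in a
window, default 3×3) marks intensity edges; the edge map is binarized at a
threshold expressed as a fraction of the slice dynamic range (default
0.10); a 4-connected border flood fill converts the closed edge band into
the filled anatomy region; a morphological opening (disk, default radius 2)
then removes small noise blobs. Two deliberate details: the opening runs
*after* the fill because a 3×3 range filter produces an edge band only
~2 px thick, which no disk opening of radius ≥ 1 would survive; and the
filled region is eroded by the filter half-width ((w−1)/2 px) because the
range band provably extends that far beyond the true boundary, so the
erosion recenters the mask on the edge. The 0.10 threshold is ≈5σ of the
9-sample noise range at a noise level of 2 % of the dynamic range, which
keeps pure-background binarization negligible. Both volumes of a pair are
multiplied by the *intersection* of their masks and everything outside is
set to −1000 HU exactly; masking is idempotent.

**Networks.** Intensities are normalized from a fixed window
[−1000, 3000] to [−1, 1] before entering any network (the same window sets
the PSNR MAX and SSIM stabilizers, L = 4000 in intensity units, L = 2 on
the normalized scale). The mapping model has two parts:

* a cycle-consistent adversarial pair — two ResNet generators (7×7 stem,
  two stride-2 3×3 downsamplings, nine residual blocks, two transposed-conv
  upsamplings, 7×7 head with tanh; batch norm + ReLU) translating
  CBCT→QCT and QCT→CBCT, and two 70×70-receptive-field patch
  discriminators (4×4 convs, three stride-2 + two stride-1 stages, batch
  norm + leaky ReLU 0.2, scalar score map);
* a two-channel U-Net taking (CBCT, generator output) and producing the
  final BMD image: four resolution levels with skip concatenation, double
  3×3 conv + batch norm + ReLU blocks, max-pool down, transposed-conv up,
  linear 3×3 head.

Batch normalization (not the instance normalization common in translation
nets) is used throughout, as in the reference architecture. Per-level
channel widths default to 64→128→256→512 and are configurable; the
reduced-scale protocol below uses base 8.

**Losses.**

    L_ADV(G) = mean(D(real)²) + mean((D(G(x)) − 1)²)
    L_CYC    = |G_yx(G_xy(x)) − x| + |G_xy(G_yx(y)) − y|     (means)
    L_GAN    = L_ADV(G_xy) + L_ADV(G_yx) + λ·L_CYC,          λ = 10
    L_UNet   = (1−α)·MAD + α·(1 − SSIM),                     α = 0.6

The published composite L_ADV mixes the real and fake terms in one
expression; taken literally as a discriminator objective it would train D
with inverted labels, and inside the generator objective the D(real)² term
has no generator gradient. Optimization therefore uses the standard
least-squares split — D minimizes (D(real)−1)² + D(fake)², G minimizes
(D(fake)−1)², whose generator gradient is identical to the composite's —
while the composite is always computed and logged verbatim
(`total_gan_loss` in the history). A config flag `adv_loss=composite` trains
the discriminator on the literal composite instead, for anyone who wants
the literal composite form end to end. SSIM inside L_UNet (and in the metric suite)
is the *global* single-window form over in-mask pixels — one mean,
variance and covariance per image, C1 = (0.01 L)², C2 = (0.03 L)² — not a
sliding-window average; its analytic gradient is implemented in closed
form and verified against finite differences. The U-Net loss is restricted
to the anatomy mask so the empty background cannot dominate MAD.

**Training.** Two stages, strictly sequential: the adversarial pair is
trained on aligned (paired) batches, then frozen; the generator output is
synthesized for every slice and the U-Net trained on the two-channel
input. Published defaults: Adam (β₁ = 0.9, β₂ = 0.999), batch 8, 200
epochs per stage; generator learning rate 2·10⁻⁴ held for the first 100
epochs then decayed linearly to zero; U-Net learning rate 1·10⁻⁴. "Momentum
0.9" is interpreted as Adam β₁. All randomness (init, shuffling) flows
from one seed; training is bitwise reproducible. After each stage the
batch-norm running statistics are recomputed as the exact average of the
batch statistics over the training set (cumulative-average momentum), so
eval-mode inference does not depend on the incidental final-epoch batches.

**Inference feature statistics.** By default the translation networks
normalize each batch-norm layer by the statistics of the single slice
being mapped (per-image statistics), the usual convention for
image-translation models; it is deterministic, leaves network state
untouched, and is robust when the test-scan intensity distribution drifts
from the training scans (different phantom, different scanning session).
`feature_stats="running"` switches to the frozen running averages.

**Metrics.** MAD, PSNR (= 20·log₁₀(MAX/√MSE), MAX defaulting to the
4000-unit window width), global SSIM, NCC (Pearson-style normalized
cross-correlation), SNU (spread max−min of *per-ROI mean* BMD over
rectangular reference ROIs — the per-voxel-extremes reading of SNU would be
noise-dominated), the slope of the OLS regression of test on reference
voxel intensities, Bland–Altman bias ± 1.96 SD of voxelwise differences,
and dental-arch profiles (bilinear sampling at equal arc length along a
polyline, Pearson r). All metrics are computed over in-mask voxels only —
the −1000 sentinel would otherwise dominate every error measure. Per-slice
values aggregate into maxilla (first 81 of 200 slices, scaled
proportionally for other counts) and mandible regions as mean ± SD, with
two-tailed paired t-tests between methods. Published comparison tables are
rounded to 2 decimals, half-up.

## The synthetic data generator

The generator emulates the two-skull-phantom study design: a jaw-like
piecewise-constant BMD phantom (acrylic/soft-tissue head ≈30, trabecular
150–260, cortical 850–1000, teeth 1100–1350, optional metal 2800 mg/cm³)
whose compartment positions and values jitter per seed, so the training
phantom (no metal) and test phantom (with metal restorations) have
different anatomy; a linear CT scanner model (HU = 0.9·BMD + 30); and a
CBCT degradation applied in a fixed order — power-law nonlinearity on the
window-normalized intensity (γ = 0.7), gain 1.3, offset +80 HU,
multiplicative low-frequency shading rescaled exactly to [1−a, 1+a]
(a = 0.15, Gaussian correlation scale 12 voxels), additive streaks through
the metal/tooth centers (2 streaks, ±150 HU, Gaussian cross-profile), and
white noise (σ = 20 HU). The identity degradation is an exact fixed point.
These defaults are the package's standard study conditions; they produce a
calibration-only baseline that is clearly degraded (slope well below 1,
MAD of tens of mg/cm³) yet leave the mapping learnable at reduced scale.

What the generator does *not* emulate: projection-domain physics (scatter,
beam-hardening cupping computed through a sinogram), anatomical texture
inside compartments, registration error between the paired volumes, and
scanner blur. Passing the end-to-end check therefore shows that the
pipeline learns to invert a realistic class of intensity corruptions on
anatomy it has not seen — not that it reaches clinical accuracy on real
scanners; the published full-scale results are the reference for that.

## Reduced-scale end-to-end protocol

The full published schedule (800 training pairs at 256×256, 200+200
epochs) is far beyond a desktop CPU. The package's standard reduced run —
used by the demo, the acceptance script and the end-to-end test — is: 64
training slices and 16 held-out test slices at 64×64, translation networks
at base width 8 (nine residual blocks kept) and the restoration U-Net at
base width 16 — the U-Net carries the accuracy budget at this scale, so it
gets the capacity — batch 8, 5 Cycle-GAN epochs then 15 U-Net epochs.
Because this is ~100× fewer optimizer steps than the published schedule,
the reduced protocol scales the Adam learning rates up (Cycle-GAN 1·10⁻³,
U-Net 2·10⁻³); the published values remain the `TrainConfig` defaults. The
run takes a few minutes on one CPU core and ends with the hybrid output
beating the CAL_CBCT baseline in MAD and in |slope − 1| on the held-out
phantom.

## Numerical choices and edge cases

* All computation is float64 numpy; convolutions are im2col/col2im over
  BLAS matmuls; every layer's analytic gradient is tested against central
  finite differences.
* PSNR of identical images returns +inf (logged sentinel); NCC and slope
  raise on constant inputs; empty masks, degenerate calibration fits
  (equal insert means), collinear landmarks, crops larger than the volume
  and mismatched shapes raise `ValueError`.
* Overlapping phantom compartments resolve last-listed-wins; calibration
  inserts must be disjoint and strictly increasing in density.
* Rotation fits are proper (det = +1) by the sign-corrected SVD; reflections
  cannot be returned.
* Bland–Altman is computed per voxel over the masked region; plots
  subsample to ≤10⁵ points.
* Rounding for table reproduction is decimal half-up at 2 decimals,
  matching the published formatting.

## Known limitations

* The NN engine is CPU-only and unbatched across processes; it is meant
  for correctness and reduced-scale experiments, not production training.
* Cycle-GAN training uses strictly aligned paired batches (the reference
  protocol trained on paired data); unpaired shuffling is not implemented.
* The mask builder is 2D per axial slice; a stack with anatomy open at the
  slice border will not be filled.
* Four cells of the published improvement table cannot be reproduced from
  the published per-method means by any direction convention (they were
  evidently derived from unrounded values); `qcbct.benchmark` lists them
  explicitly and the strict reproduction test reports them rather than
  hiding them.
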