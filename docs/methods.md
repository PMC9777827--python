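# Methods

`follikit` quantifies ovarian ultrasound images in three stages: segment the
ovary, segment the follicles, then size / filter / count the follicles. This
note records the models, the defaults and why, the numerical choices, and the
limits of what the synthetic phantoms can demonstrate.

## Harmonic convolution

Every encoder (and, symmetrically, decoder) convolution is *harmonic*: instead
of learning a free f×f spatial kernel, the layer learns weights
w[d, n, u, v] that linearly combine the responses of a **fixed** orthonormal
2-D DCT-II filter bank γ(u,v). The bank kernel for frequency pair (u, v) at
pixel (i, j) is

    γ_{u,v}(i,j) = sqrt(β_u/f) · sqrt(β_v/f) · cos(π(i+½)u/f) · cos(π(j+½)v/f),

with β₀ = 1 and β_{u>0} = 2. With this normalization the f² flattened kernels
are orthonormal (their Gram matrix is the identity to < 1e-10), the (0,0)
kernel is the constant 1/f, and the bank is a deterministic function of f
alone. The scaling is sometimes written without the square roots in the
harmonic-networks literature; the square-root (orthonormal) form is used here
because it is the only reading that yields an orthonormal, well-conditioned
basis. All f² frequencies are kept, including the DC component.

Because the output is linear in both the weights and the bank responses, the
layer is implemented by collapsing weights and bank into one effective kernel
K[d,c] = Σ_{u,v} w[d,c,u,v]·γ(u,v) and running a single stride-1, zero-padded
convolution. Tests verify this equals the direct triple-loop sum over
channels and frequencies to ~1e-15. Gradients flow only through the weights
and bias; the bank is frozen. Weights use fan-in-scaled (He) normal
initialization — appropriate precisely because the bank is orthonormal, so
the effective kernel variance equals the weight variance.

## Harmonic attention (HA)

A squeeze-and-excitation-style channel gate: global average pooling produces
per-channel statistics T′ (C×1×1); two 1×1 harmonic convolutions W0 (C→C/r,
ReLU) and W1 (C/r→C, sigmoid) produce attention values a ∈ (0,1)^C; the block
returns O = a⊙T + T (channel-wise scaling, broadcast over space, plus a
residual add). Consequences tested: output shape equals input shape, O lies
between T and 2T for non-negative T, and zero weights give exactly O = 1.5·T.
A formulation that multiplies T by the pooled statistics directly (rather than
by the attention values) would bypass the gate entirely and is treated as a
typographical slip in the source literature.

A 1×1 DCT basis is the scalar 1, so the two 1×1 harmonic convolutions are
plain learned channel mixings; they are routed through the harmonic layer for
uniformity. Defaults: reduction r = 16, clamped so the bottleneck keeps at
least 4 channels and always divides C (`effective_reduction`); biases are
included. Neither r nor the bias choice is fixed by the source description.

## Network

Five-level encoder–decoder with skip connections (input sizes must be
divisible by 16):

- level 1: harmonic conv → BN → ReLU, then an ERFNet-style 1-D factorized
  pair (3×1 conv and 1×3 conv, each BN+ReLU);
- level 2: the same plus an HA block (placed last in the level);
- levels 3–5: harmonic conv → BN → ReLU plus HA;
- 2×2 max pooling between encoder levels; channel width doubles per level
  (base 64 at full scale; 8 for desk-scale runs);
- decoder: 2×2 stride-2 transposed conv, concatenation with the same-level
  encoder features, harmonic conv → BN → ReLU, the 1-D factorized pair at
  levels 1–2 (mirroring the encoder), and HA where the encoder level had one;
  final 1×1 conv with sigmoid, thresholded at 0.5.

The head bias is initialized from a configurable foreground prior
(`head_prior`): 0.5 (bias 0, neutral) by default, and the approximate
foreground coverage rate for rare-object targets — the follicle stage uses
0.05, the order of magnitude of follicle coverage in an ovarian frame. This
is the focal-loss prior-initialization convention: starting the sigmoid at
the class prior keeps early gradients from being dominated by the background
sea. For the ovary stage (~25–30 % foreground) a neutral head trains
fastest, so no prior is applied there.

Open points decided here: the decoder mirrors the encoder's harmonic
convolutions (the source specifies the encoder only); channel widths follow
the conventional U-Net doubling; HA sits after the factorized pair in level 2.
`use_ha=False` swaps every HA block for the identity, giving the baseline
(BL) model for ablations. Ovary and follicle segmentation are two
independently trained instances of the same architecture.

The tensor engine underneath is a compact reverse-mode autodiff over numpy
(`follikit.nn`): broadcast arithmetic, matmul, reductions, ReLU / sigmoid /
log, concatenation, stride-1 convolution via sliding-window einsum (BLAS),
2×2 max pooling and 2×2 stride-2 transposed convolution, with BatchNorm
composed from primitives and Adam as the optimizer. Every convolutional op is
checked against central finite differences.

## Losses

Pixel-mean reductions throughout; predictions clipped to [1e-7, 1−1e-7]
before logarithms. Focal loss −y(1−p)^γ log p − (1−y)p^γ log(1−p) with
γ = 2.0 by default (the conventional value; the source does not state γ);
focal reduces exactly to BCE at γ = 0. The default compound objective is
L = L_BCE + η·L_F with η = 0.6. Selectable variants for ablation: `bce`,
`dice` (1 − soft-Dice, smoothing 1.0), `bce+dice`, `bce+focal`. Closed forms
frozen in tests: y=1, p=0.5, γ=2 gives 0.25·ln2 for focal and 1.15·ln2 for
the compound loss.

## Training

Published recipe, all exposed in `TrainConfig`: input 384×384 (desk-scale
override allowed, must be divisible by 16), intensities in [0,1], Adam with
β₁ = 0.5, β₂ = 0.999, lr 2e-4, batch 4, up to 50 epochs, augmentation by
rotations uniform in ±15° (bilinear for images, nearest for masks) and
horizontal flips with probability 0.5. The learning rate is halved (decay
factor 0.5 — unstated in the source, configurable) when validation Dice fails
to improve for 2 consecutive epochs; the best-validation-Dice weights are
restored at the end. Training is bit-reproducible under a fixed seed.

## Quantification

Connected components at 8-connectivity (configurable); per component the
equivalent-ellipse major/minor axis lengths (normalized second central
moments, via `skimage.regionprops`) are averaged and multiplied by the pixel
spacing to give the diameter in mm — the mask analogue of averaging a
follicle's two largest orthogonal diameters. Moment-based diameters of
rasterized disks are within one pixel-spacing of truth for radii ≥ 10 px
(tested). The recruitable filter keeps 2 mm ≤ d ≤ 10 mm (inclusive) and is
applied to **both** ground-truth and predicted masks before matching, since
the exclusion step operates on both images. Matching is one-to-one greedy by
descending pairwise Dice with deterministic tie-breaks; a prediction counts
as correct only at Dice strictly > 0.5. Precision = correct/detected,
recall = correct/real; zero denominators yield a flagged 0. In the chained
pipeline the predicted follicle mask is intersected with the predicted ovary
mask first (flag `restrict_to_ovary`), suppressing extra-ovarian false
positives.

## Phantoms

The generator emulates the *appearance hierarchy* of transvaginal B-mode
ovary images, not their physics: a smooth echogenic background field
(Gaussian-filtered noise around level ~0.6), one hypoechoic elliptical ovary
(background × 0.45), and anechoic elliptical follicles (level 0.04) fully
inside the ovary, pairwise separated by ≥ 2 px; multiplicative speckle as the
squared magnitude of low-pass-filtered complex Gaussian noise (unit mean, the
fully-developed-speckle approximation); optional vertical shadow bands and
contrast compression. Default canvas 384 px at 0.1 mm/px (38.4 mm field of
view, accommodating 2–28 mm follicles); the desk-scale configuration is 96 px
at 0.4 mm/px — the same field of view at coarser resolution. Follicle
diameters are sampled log-uniformly (many small antral follicles, few
dominant ones), truncated to what fits inside the sampled ovary, and avoid a
±0.3 mm guard band around the 2 and 10 mm recruitable bounds so the
ground-truth antral count is unambiguous under ≤ 1 px diameter-measurement
error — the synthetic analogue of an annotation protocol that excludes
borderline calls. Every scene is bit-reproducible from its seed, and datasets
ship a manifest sufficient for exact regeneration.

What passing on phantoms does **not** show: phantoms have sharp follicle
boundaries, a single convex ovary, no acoustic attenuation model, no fan-beam
geometry, no adjacent anechoic structures (vessels, cysts, bowel), and no
inter-annotator ambiguity. Scores on phantoms are therefore an upper bound on
what the same pipeline would achieve on clinical TVUS data; the phantom suite
verifies the machinery (architecture, losses, training, quantification
arithmetic), not clinical performance.

## Problem sizes for the built-in acceptance run

`scripts/acceptance.py` trains both segmentation targets at base width 8 on
200 phantoms of 96×96 px for 10 epochs with the recipe above and evaluates on
40 held-out phantoms — sizes chosen so the whole run completes on a single
CPU core in well under half an hour while still exercising every stage at
realistic class imbalance. The counting-arithmetic section feeds the
published per-method count rows (correct / detected / real follicles over a
141-image test set) through the same precision/recall code used by
`counting_report`.

## Known limitations

- CPU-only, float64 throughout: full-scale (384 px, base width 64, 50-epoch)
  training is possible but slow; the package is tuned for desk-scale
  verification and method study.
- The greedy Dice matching is not guaranteed optimal for pathological overlap
  patterns (it is for all tested configurations; an optimal assignment would
  need the Hungarian algorithm on the Dice matrix).
- Axis lines in the overlay rendering are axis-aligned rather than rotated to
  the measured ellipse orientation.
- Phantom realism limits above.
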