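# Methods

`fluidcam` quantifies retinal fluid in OCT C-scans from the *explanation*
of a classifier rather than from a segmentation network: a binary
per-pathology CNN flags each B-scan, class-activation maps localize the
evidence, classical post-processing sharpens the maps into fluid masks,
and voxel arithmetic turns masks into volumes. This note records the
models, the parameters that matter, and the choices made where the design
was open.

## Pipeline

For each slice of a C-scan:

1. optional despeckling (the "denoised" path) or the raw slice (the
   "noisy" path);
2. binary classification; slices whose pathology-present softmax score
   exceeds 0.5 **strictly** continue;
3. a CAM heat map for the positive class, computed at the classifier's
   input resolution, min-max normalized to [0, 1];
4. Otsu binarization of the heat map; for the ensemble technique, five
   binarized maps are fused by a >= 3-of-5 pixel majority;
5. nearest-neighbor resize of the binary map back to the original B-scan
   grid (thresholds in step 6 are defined on scanner intensities, so all
   pixel counting happens at scanner resolution);
6. refinement: seeded region growing or selective thresholding for IRF
   and SRF; for PED — a layer detachment, not a dark pocket — both
   refiners are unsuitable and the raw CAM mask is used;
7. volume: every mask pixel is a cuboid `dx*dy*dz` (defaults
   11.7 x 47.2 x 2.0 um^3 = 1104.48 um^3), summed over the C-scan and
   reported in mm^3.

Evaluation uses Jaccard/IoU and Dice (`Dice = 2J/(1+J)`), computed on the
stacked 3-D masks per scan and aggregated as mean plus *population*
standard deviation per (pathology, technique, refiner). Two empty masks
score overlap 1 by convention (configurable). Treatment response: a scan
pair is "Responder" when volume drops by strictly more than 10%.

## Classifier

A residual-inception network: stem (two 3x3 convolutions, max pool),
then `n_a` Inception-A blocks, Reduction-A, `n_b` Inception-B blocks,
Reduction-B, `n_c` Inception-C blocks, global average pooling, dropout
(p = 0.2) and a 2-way softmax head. Each block is a set of parallel
conv branches, concatenated, projected by a linear 1x1 convolution, and
added back to the input scaled by 0.2 before a ReLU. Presets:

| preset   | blocks (A,B,C) | input | widths (stem/branch) | lr     | params |
|----------|----------------|-------|----------------------|--------|--------|
| standard | 10, 20, 10     | 450   | 64 / 48              | 1e-4   | ~2.7 M |
| small    | 8, 7, 4        | 450   | 64 / 48              | 1e-4   | ~1.5 M |
| tiny     | 1, 1, 1        | 64    | 8 / 8                | 3e-3   | ~10 k  |

The reduced block counts alone bring `small` to ~0.54x the parameters of
`standard`, mirroring the published halving; exact parameter counts of
the reference architectures are not reproduced (branch widths inside the
small variant were never published, so widths are shared across presets).
The `tiny` preset exists for desk-scale training and tests.

Training: Adam on categorical cross entropy (natural log, predictions
clamped to [1e-7, 1]), seeded shuffling and dropout, per-epoch loss and
accuracy logged. Images are bilinearly resized to the input size,
standardized per image (zero mean, unit variance — without this the
tiny model trains an order of magnitude slower on speckled input), and
replicated to 3 channels. Initialization is seeded He-normal;
`set_weights` accepts externally pretrained weights, but nothing is
downloaded.

The whole network stack (convolutions via im2col, pooling, blocks,
backprop, Adam) is implemented in NumPy inside `fluidcam.nn`; every
composite layer is gradient-checked against central differences in the
test suite.

## CAM techniques

All five weight the channels `A^k` of the final convolutional stage
(the last Inception-C output — the standard "last conv layer" choice)
and produce `ReLU(sum_k w_k A^k)`, bilinearly upsampled and min-max
normalized. Degenerate conventions: an all-zero map stays all-zero; a
flat positive map normalizes to ones.

- **Grad-CAM**: `w_k = mean_ij dy_c/dA^k_ij`. Since only GAP and a
  linear layer sit above the target stage, the gradient is exactly
  `W[c,k]/(hw)`; the protocol exposes it analytically.
- **Grad-CAM++**: per-pixel
  `alpha = d2 / (2 d2 + (sum_ab A_ab) d3)`, `w_k = sum alpha*ReLU(d1)`.
  Models may expose true higher derivatives; otherwise the score is
  treated as locally linear (`d2 = d3 = 0`), for which `alpha -> 1/2`
  wherever the first derivative is nonzero and 0 where everything
  vanishes (the 0/0 guard).
- **Score-CAM** (gradient-free): each activation map, upsampled and
  normalized, masks the input; `w` is the channel softmax of the score
  gain of the masked input over an all-zero baseline.
- **Ablation-CAM**: `w_k = (y_c - y_c^(k))/y_c` with channel `k` zeroed;
  weights forced to 0 when `|y_c| < 1e-12`.
- **Self-Matching-CAM**: the cited formulation was not available, so the
  contract is fixed here as: `w_k` = cosine similarity between the
  normalized upsampled activation map and the normalized input image.

Otsu binarization quantizes [0, 1] into 256 uniform bins, maximizes
between-class variance, breaks ties toward the smallest threshold, keeps
strictly greater levels, and maps a constant heat map to an all-false
mask. Every kernel is checked against an independent naive-loop oracle
at 1e-6 and Otsu against exhaustive threshold search.

## Post-processing

- **Seeded region growing**: connected components of the CAM mask yield
  seeds (rounded centroids, snapped into the component when the blob is
  non-convex). Breadth-first growth admits a neighbor when its intensity
  differs by strictly less than the threshold (default 15) from the
  originating **seed** pixel (default) or from the adjoining region
  pixel (`reference="neighbor"` — provided because the prose rule "the
  seed pixel and the corresponding neighboring pixel" is ambiguous).
  Connectivity 8 by default, regions from multiple seeds unioned. With
  seed reference, the result is monotone in the threshold.
- **Selective thresholding**: the image is masked by the CAM mask and
  only pixels in the band [20, 50] (inclusive) survive. The band low end
  is 20 even though the histogram spike of fluid interiors is described
  at 25-50; the applied band is what the procedure prescribes, and both
  ends are configurable.

## Despeckler

A gated convolution-deconvolution structure: 5 encoder convolutions
(3x3, widths 32/64/128/256/256 by default — kernel sizes, widths and the
MSE loss are this package's choices; only the topology is prescribed),
a mirrored deconvolution decoder, and one learnable gate per skip. The
gate `g` (sigmoid-parameterized, hence in [0, 1] by construction) sends
`g*e` over the skip and `(1-g)*e` down the encoder; all-zero gates
reduce the decoder to the bottleneck path. Decoder depth mirrors the
encoder. Trained with Adam on speckled/clean pairs from the phantom.

## Phantom generator

The synthetic C-scan emulates what the pipeline actually exploits, not
retinal anatomy: a dark vitreous (intensity 5), a bright ILM band (peak
190), a mid-gray retinal slab (120), a very bright RPE band (220), a
choroid (90), and elliptical lesions with per-pixel interior intensities
drawn uniformly from [25, 50] — IRF inside the slab, SRF resting on the
RPE, PED straddling an RPE drawn as a detachment bump. Speckle is
i.i.d. multiplicative gamma noise with shape k = 4 and scale 1/k (unit
mean, so brightness is preserved and the lesion band stays meaningful);
the result is clipped to [0, 255] and quantized. Everything is a pure
function of the seed.

What the phantom does **not** model: A-scan interferometry, depth-
dependent attenuation, vessel shadows, motion artifacts, realistic
lesion morphology (an open question — fluid-pocket shape statistics were
never published). Tests passing on phantoms therefore demonstrate the
pipeline's mechanics (gating, mapping, thresholding, arithmetic), not
clinical accuracy.

## Problem sizes and seeds

Desk-scale defaults keep every check cheap: phantoms are 128 x 256 x 32
(configurable up to scanner sizes of 1024 x 512 x 200); the trained model
in tests is the tiny preset on 200 slices for 20 epochs; the denoiser
property tests use 3 encoder layers at widths (8, 12, 16) on 64 x 64
slices; volume recovery uses 20 C-scans of 16 slices. Stochastic
properties (training accuracy, PSNR gain) are asserted over 3 seeds with
majority pass. In the end-to-end volume-recovery check the refiners read
the noise-free render — the role an ideal despeckler plays in the
denoised path — because multiplicative speckle deliberately pushes
lesion pixels out of the [20, 50] band; thresholding speckled input is
exactly the failure the denoising stage exists to prevent.

## Known limitations

- CAM localization on the tiny model is coarse (B-scan IoU ~0.04-0.06 on
  phantoms), comparable in order to published B-scan-level CAM overlap;
  the refiners, not the raw maps, carry the volumetry.
- The analytic-gradient protocol relies on the GAP + linear head; models
  with nonlinear heads must provide their own gradients (the CAM
  functions accept any object implementing the small protocol).
- `standard`/`small` presets are buildable and parameter-counted but not
  trained anywhere at full input size in the tests.
- Published volume tables carry no units; volumes here are reported in
  mm^3, under which the published cohort means (~0.15-0.62) are
  anatomically plausible.
- B-scan-level overlap is computed over ground-truth-positive slices;
  whether published B-scan aggregates include negative slices is
  unstated.
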