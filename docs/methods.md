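# Methods

## The model

LeafFusionNet classifies leaf images into plant-disease categories by
fusing three feature streams:

1. **Gabor texture stream.** The input image is passed through a fixed bank
   of Gabor kernels

   g(x, y) = exp(−½ (x_θ² + γ² y_θ²)/σ²) · cos(2π x_θ/λ + ψ),
   x_θ = x cos θ + y sin θ, y_θ = −x sin θ + y cos θ,

   applied depthwise (each kernel to each channel independently,
   cross-correlation, zero "same" padding) at orientations
   θ_k = kπ/n for k = 0 … n−1 (n = 8 by default).  The kernels are
   constants — the layer contributes zero trainable parameters — and act as
   an explicit orientation/frequency prior for lesion boundaries, streaks
   and mottling.  The original channels are concatenated ahead of the
   filtered ones (`passthrough`), so colour information survives.
   A three-block CNN (3×3 conv → ReLU → 2×2 max-pool, widths 32/64/128)
   reduces the texture-enhanced image to a feature map F3; global average
   pooling (GAP) of F3 gives the CNN feature vector.

2. **ViT stream.** The original image, resized to a square grid, is cut
   into non-overlapping patches, linearly embedded, given a class token and
   learned position embeddings, and processed by pre-norm transformer
   encoder blocks whose heads compute softmax(QKᵀ/√d_k)V.  The class-token
   vector after the final LayerNorm is the global-context feature.

3. **LeafTAM stream.** Sequential dual attention on F3: a channel gate
   a = σ(W₂·ReLU(W₁·z)) (z the per-channel spatial mean; bias-free
   bottleneck MLP with reduction ratio r), giving F′ = F ⊙ a, then a
   spatial gate M_s = σ(conv₇ₓ₇(mean_c F′)) giving F″ = F′ ⊙ M_s.  Both
   gates lie strictly in (0, 1).  GAP(F″) is the TAM feature vector, and
   F″ is the Grad-CAM target layer.

The three pooled vectors are concatenated without rescaling —
Z = concat(CNN, ViT, TAM) — and classified by
Dense(512)+ReLU → BatchNorm → Dropout → Dense(256)+ReLU → BatchNorm →
Dropout → Dense(K) → softmax.  Training minimises sparse categorical
cross-entropy −log p_y (log-sum-exp stabilised on logits).

## Backend

No deep-learning framework is used: the package carries a compact
reverse-mode automatic-differentiation engine over numpy arrays
(`leaffusionnet.nn`), with hand-written vector–Jacobian products for every
primitive (dense/conv/pool/softmax/normalisation).  Analytic gradients are
validated against central finite differences through the entire network —
convolution, attention, batch norm, LeafTAM — to ~1e−10 in float64.
Parameters are float32; Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−7) is the
optimizer.  Weight init: truncated normal (std 0.02) for dense/embedding
layers, Kaiming-uniform for convolutions, zero biases; all seeded.

### BatchNorm inference statistics

The classification-head features of near-duplicate images have
cross-sample variance orders of magnitude below the feature scale
(~1e−5 here).  An exponential-moving-average estimate of BatchNorm
statistics is then dominated by estimation noise under weight drift, and
inference-mode accuracy collapses even while batch-statistics accuracy is
high.  The package therefore recalibrates BatchNorm before each
validation pass and at the end of training: exact first and second moments
of each BN input are accumulated over up to 512 training images with
frozen weights (batches of 32) and installed as the inference statistics
(the "precise BN" approach).  This is deterministic and resume-safe.

## Training protocol

`TrainConfig` defaults follow the reference protocol: Adam lr 1e−4,
batch 16, up to 50 epochs, early stopping on validation loss with
patience 5 (min_delta 0), best-weights restoration, a best-model
checkpoint on every validation-loss improvement, and an every-epoch
checkpoint holding model weights, optimizer state, history and a config
hash.  All per-epoch randomness (shuffling, augmentation, dropout) derives
from `SeedSequence([seed, epoch, stream])`, so resuming from the epoch
checkpoint replays the identical stream: on a single thread the resumed
run is bit-identical to the uninterrupted one, which the tests assert.

Data protocol: class-per-folder trees are indexed in sorted order;
splitting is two-stage stratified sampling (per class: round(n·0.2) to
test, then round(rem·0.2) to validation ⇒ 64/16/20 overall, every split
non-empty per class for n ≥ 3).  Preprocessing: decode → scale to [0, 1] →
bilinear resize; normalisation precedes augmentation (a choice —
equivalent up to interpolation linearity).  Augmentation (train only,
before the Gabor and ViT stages): horizontal flip p = 0.5, rotation
uniform in ±10 % of a turn (±36°; the "up to 10 %" convention of common
augmentation layers, configurable in degrees), centre zoom in
[0.9, 1.1], bilinear with reflection fill.

## Synthetic study conditions

The generator draws a green elliptical leaf blade with venation on a brown
background and paints one of four textures: none (`healthy`), dark discs of
radius 3–6 px (`spots`), oriented sinusoidal bands of wavelength 8 px near
30° (`streaks`), or low-frequency blotches from a coarse Gaussian field
(`mottle`).  All diseased classes share the same necrotic colour, blend
weight and lesion area fraction (≈14 % of the blade), so the classes are
separable only through the spatial arrangement of lesion tissue — the
orientation/frequency statistics the Gabor pathway is designed for — and
not through colour histograms or lesion totals.  Additive Gaussian pixel
noise (`noise_level`, default 0.08) plus ±8 % illumination jitter set the
difficulty; a linear probe on 8-orientation Gabor energies separates
`streaks` from `healthy` essentially perfectly at the default noise and
degrades monotonically as noise grows.  Exact lesion masks are emitted for
every image, which is what makes the Grad-CAM localisation property
quantifiable.

The toy study conditions: 200 generated images per class at 64×64
(4 classes), split 64/16/20; tiny geometry (CNN widths 8/16/32, ViT
depth 2, d_model 64, 2 heads, patch 16; head 512/256; r = 16 clamped).
The toy Gabor bank uses two wavelengths, λ ∈ {4, 8}, spanning the spot and
streak scales — the multi-frequency configuration the method motivates
(different symptom scales need different frequencies) — with the
per-kernel zero-mean option enabled: at σ = 2 the λ = 8 kernels carry a DC
gain of ≈4.5, which would make their output channels an order of magnitude
larger than the passthrough channels and condition the first convolution
badly; subtracting the mean makes them genuinely band-pass and
scale-matched.  Full-scale defaults remain a single λ = 4 with raw
(non-zero-mean) kernels.  The toy optimiser runs at lr 2e−3 for up to 16
epochs (patience 5): the reference 1e−4 is tuned for fine-tuning a
pretrained ViT on ~54 k images, while these from-scratch runs on ~800
images need a larger step.  Problem sizes (512 training images, ≤512
calibration samples, 40 Grad-CAM images) were chosen so the full study
runs in minutes on one CPU core.

What passing on this data does and does not show: the synthetic classes
isolate texture as the only class signal, so they exercise the Gabor,
attention and fusion machinery and the claim that texture priors help a
small CNN under limited training; they do not emulate photographic leaves
(specularities, pose, background clutter, disease-colour correlations),
so no accuracy number here transfers to PlantVillage or field images.

## Grad-CAM

Standard construction on the LeafTAM output F″ (selectable to F3):
back-propagate the pre-softmax logit of the target class to F″, average
the gradient spatially into channel weights α_c, form
ReLU(Σ_c α_c F″_c), min–max normalise (an all-constant raw map is defined
as all zeros, which makes the zero-gradient case testable), and bilinearly
upsample to the input size.  Logits rather than probabilities are
differentiated so confident predictions do not shrink the signal.
Overlays alpha-blend a jet colormap (α = 0.4) over the input.

## Numerical choices and degenerate cases

- Gabor kernels are not normalised (the analytic form has no normaliser);
  an optional per-kernel zero-mean flag exists, off by default at full
  scale and on in the toy profile (see above).  The learnability *oracle*
  uses zero-mean kernels with σ = λ/2, since DC response otherwise swamps
  orientation contrast.
- Precision/recall/F1 return 0 with a per-class `degenerate` flag when a
  denominator is empty.  Macro-AUC skips absent classes with a warning;
  micro-AUC rejects single-class inputs.
- Stratified allocation uses round-half-even with clamping that keeps all
  three splits non-empty per class.
- Max-pool ties route the gradient to the first maximal element.
- Dropout is inverted (scaling at train time); BatchNorm ε = 1e−5.
- `fuse` concatenates streams without per-stream normalisation; scale
  imbalance is absorbed by the first dense layer.

## Known limitations

- Grad-CAM on the LeafTAM output can collapse to an empty map for some
  trained models: because GAP(F3) and GAP(F″) are strongly correlated
  streams (F″ is a gated version of F3), the classification head may
  assign the TAM stream a net-negative weight for a class and carry the
  positive evidence through the CNN/ViT streams; the gradient-weighted sum
  is then non-positive everywhere and the ReLU yields the all-zero map.
  When this happens, lesion-localisation rates drop sharply even though
  accuracy is unaffected.  Grad-CAM on F3 — which captures the total
  derivative through both the direct and the attention pathway — localises
  lesions reliably across seeds and is available via the ``layer``
  argument / ``--layer`` flag.

- The numpy backend is single-threaded and CPU-bound; the full-scale
  profile (224×224, widths 32/64/128, ViT-depth 6) is architecturally
  supported and shape-tested but not trained here.
- The ViT is trained from scratch; `VitBranch.load_pretrained` accepts a
  geometry-matched npz checkpoint but no specific public checkpoint is
  bundled or tested.
- Batch statistics recalibration assumes the calibration subset fits in
  memory and represents the training distribution (true here by
  construction).
- The resume guarantee is bit-exact only in single-threaded execution;
  multi-threaded BLAS may reorder reductions.
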