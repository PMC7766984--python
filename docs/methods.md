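# Methods

This note records the model, the defaults, and the judgement calls behind
`medfuse`, in the spirit of a package methods appendix. It states no
empirical result the test suite or `scripts/acceptance.py` do not compute.

## Problem setting

Two registered 2-D views of the same slice: a structural grayscale image
`a` (MRI-like, sharp anatomy) and a functional RGB image (PET/SPECT-like,
smooth activity rendered through a flow colormap). The goal is one RGB
image keeping the functional color coding with structural detail folded
into its luminance. All images are `[0, 1]` floats; integer inputs are
divided by their max code value at read time.

## Color handling

RGB↔YIQ is a fixed 3×3 linear map. The default is the signed NTSC matrix
(luma row `0.299, 0.587, 0.114`; chroma rows sum to zero). An all-positive
variant (`matrix="paper-literal"`, with `0.144` as the blue luma
coefficient) is kept for comparison; it does not separate chroma and is
never the default. The inverse is computed numerically from the forward
matrix, never hard-coded. Clamping to `[0, 1]` happens only at RGB
write-out; chroma is never clamped in YIQ space, which is what makes the
chroma pass-through property exact (verified to 1e−6 through a full
round trip).

## Fuzzy enhancement (IFP)

Per image, with observed extrema `g_min`, `g_max`:

- non-membership `ν(g) = (g_max − g)/(g_max − g_min)`,
- enhanced image `ξ = 1 − ν^λ`,
- membership `µ = [(g − g_min)/(g_max − g_min)]^λ` (the mirror of `ν^λ`;
  the source formulation leaves µ undefined — this is our choice),
- entropy `E(λ) = mean 2µξ/(µ² + ξ²)`, with `0/0` pixels contributing 0.

λ is the `E`-argmax over the grid `{200, 300, 400, 500, 600, 700, 800}`;
ties break toward the smallest λ. Constant images cannot be fuzzified
(division by zero); they pass through unchanged with a warning flag rather
than raising mid-pipeline. With exponents of order 10², `ξ` is close to a
soft threshold just above `g_min`: IFP suppresses background and saturates
tissue, which is the intended "remove redundancy, keep salient features"
behavior. `ν + ξ = 1` holds bitwise in IEEE double (round-to-even absorbs
the rounding of `1 − ν`), and the tests assert it exactly.

## Network

Encoder: `C1` (1→16) → `CIDN1` (16→16) → `CIDN2` (32→16, input is the
concatenation of the two previous outputs — the single feature-reuse
layer) → `CIDN3` (16→16). The stack handed to fusion is
`concat(CIDN2, CIDN3)` = 32 maps, implementing the reading that the reuse
layer feeds both its successor and the fusion stage. Decoder: `D1` (32→16),
`D2` (16→8) SeLU-activated, `D3` (8→1) with a logistic output so decoded
images are valid Bernoulli means for the cross-entropy loss. All kernels
are 3×3, stride 1, zero same-padding, so any input ≥ 8×8 keeps its shape.
Channel widths are configurable; these defaults are ours (the source never
states widths).

SeLU uses the canonical self-normalizing constants
λ_s = 1.0507009873554805, α_s = 1.6732632423543772 (the printed form drops
λ_s from the negative branch and leaves α unspecified; both are
configurable). Initialization is seeded LeCun-normal
(std = 1/√fan_in), the standard choice for self-normalizing nets.

No deep-learning framework is used: convolutions are im2col + BLAS
matmuls, and the backward pass is derived by hand (including the SSIM
gradient, see below). The full analytic gradient is checked against
central finite differences in the test suite (worst relative error
~1e−8 at h = 1e−6).

## Fusion rule

Each source stack is reduced to a scalar saliency `s_i = Σ_j |tr φ_i^j|`
(diagonal sum; for rectangular maps the main diagonal of length
`min(M, N)`). Weights are `w_i = s_i / Σ s_i` — one global scalar per
source, since a trace is one number per map; a spatially varying weight
field is not derivable from traces. Absolute values keep weights
non-negative under SeLU features whose traces can be negative;
`signed_traces=True` restores the literal signed sum. All-zero saliencies
fall back to uniform `1/k`. Fusion is the per-map convex combination, so
fused responses are bounded by the per-pixel min/max over sources and the
operation is permutation-equivariant; the decoder input width equals the
encoder output width (no cross-source channel concatenation). A `mean`
strategy (uniform weights) is included as the addition-rule baseline.

## Training

Autoencoder objective on single images, fusion bypassed:

    L = α · CE(I, O) + β · (1 − SSIM(I, O)),   α = 500, β = 1.

CE is the per-pixel **mean** binary cross entropy (the literal sum would
make α image-size dependent); outputs are clamped to `[1e−7, 1 − 1e−7]`
for log safety. β is our choice (unstated in the source); the `α = 500`
default is read as the loss weight — the enhancement λ the source prefers
is also 500, and the two are independently configurable. Optimizer: Adam
with default moments (the source does not name one); learning rate
`0.95^epoch · 5e−4`, batch 32, 10 epochs, all seeded, so runs are bit
reproducible on one machine. Training runs in float32; returned weights
are float64.

The SSIM gradient: local Gaussian statistics are valid-mode correlations
with a symmetric kernel, whose adjoint is full-mode convolution with the
same kernel. With `u = µ_O`, `v = K∗O²`, `w = K∗(I·O)` the chain rule
gives a closed form used directly, verified against finite differences.

Note the scale of the desk run: 200 images / batch 32 × 10 epochs is only
70 optimizer steps (the full-scale regime is 80,000 images, 25,000 steps).
It suffices here because the mixed loss's optimum is the identity map and
the corpus is smooth; held-out reconstruction SSIM ≥ 0.9 is reached and
asserted by the acceptance tests, with the loss plateau equal to α times
the mean binary entropy of the targets (the irreducible CE term).

## Metrics

All metrics operate on `[0, 1]` grayscale images; color fusions are scored
on their Y channel against the structural image and the functional luma.

- **EN**: Shannon entropy (bits) of the 256-bin histogram. The literal
  pixel-value normalization (values divided by M·N) is not a probability
  distribution and is kept only behind `literal=True`.
- **CE**: symmetric divergence `Σ p log(p/q) + Σ q log(q/p)` (natural log)
  between 256-bin histograms, smoothed by 1e−12 per bin;
  `CE = 0.7·D(a:f) + 0.3·D(b:f)`. The 0.7/0.3 split is the surveyed
  35-of-50 physician preference for structural information.
- **RMSE**: `0.5·RMSE(a,f) + 0.5·RMSE(b,f)`.
- **AG**: mean of `sqrt((Δx² + Δy²)/2)` with forward differences,
  boundary row/column excluded.
- **SSIM**: 11×11 Gaussian window (σ = 1.5), `c1 = 0.01²`, `c2 = 0.03²`,
  `c3 = c2/2` (product form ≡ the two-term form), dynamic range 1,
  valid windows only — numerically identical to
  `skimage.metrics.structural_similarity(gaussian_weights=True,
  use_sample_covariance=False)`, which the tests cross-check.
- **Q0 family**: universal image quality index over 8×8 sliding windows,
  step 1. Windows with variance below 1e−12 in either operand are
  undefined and skipped. Saliency is local variance; λ(ω) its normalized
  share; Qw weights windows by `max(s_a, s_b)` normalized over valid
  windows; Qe mixes Qw on intensity and gradient-magnitude images with
  exponent α = 0.5 (negative Qw floored at 0 before exponentiation;
  α exactly 0 or 1 collapses without flooring).
- **FMI**: mutual information (bits, 64-bin joint histograms) between
  gradient-magnitude images, fused-vs-a plus fused-vs-b, unnormalized.
  DCT/wavelet features are out of scope.
- **VIF**: pixel-domain formulation, 4 Gaussian scales (window
  `2^(5−s)+1`, σ = window/5, reflect boundary, 2× downsampling between
  scales), per-window variance decomposition with noise variance
  σ_n² = 2 on the [0, 255] scale. The source gives no formulas; this
  standard construction is pinned by the identity `vif(x, x) = 1 ± 1e−6`.

Every windowed metric is equality-tested (1e−9) against a pure-Python
nested-loop oracle on small images.

## Synthetic data

`make_pair` draws a seeded ellipse geometry (head ellipse, skull ring at
scale 0.90, 3–5 inner tissue ellipses), renders the structural phantom as
piecewise-constant regions plus band-limited Gaussian-filtered texture
(amplitude 0.08), and the functional companion as 2–5 Gaussian activity
blobs (widths 5–12 % of the field, masked to the tissue support,
peak-normalized) through a black→blue→green→yellow→red colormap. The two
share one geometry, so registration holds by construction.
`make_training_corpus` mixes oriented ramps, random ellipses and smoothed
noise, min-max stretched, giving broad histograms (mean EN > 4 bits).
Default desk scale is 64×64 with n = 200 so training and tests finish in
minutes on one CPU.

What the generator does **not** emulate: MR/PET physics (k-space,
attenuation, partial volume), noise statistics of real scanners,
pathology, or misregistration. A green test therefore establishes the
correctness and stability of the algorithmic pipeline, not clinical
fusion quality.

## Degenerate inputs and tie-breaks

Constant images: IFP passes them through with a warning; EN is 0; Q0-type
metrics have no valid windows and return NaN. λ ties break to the smallest
grid value. All-zero trace saliency → uniform weights. Images smaller than
a metric's window raise rather than silently truncating.

## Known limitations

- One scalar fusion weight per source; no spatially adaptive weighting.
- 70 optimizer steps at desk scale: adequate for smooth synthetic corpora,
  not a substitute for full-scale training on natural images.
- Metrics on strongly enhanced inputs (λ ≈ 10²) score the fused luma
  against the raw sources, so SSIM/Qw are structurally low on phantoms
  with large uniform backgrounds; this is a property of the pipeline
  design, not a bug in the metrics.
- VIF and FMI defaults (feature choice, bins, σ_n²) follow the common
  conventions but cannot be validated against the source numerically.
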