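# Methods

`sparsefuse` fuses a co-registered CT/MRI pair into a single grayscale
image by convolutional-sparse cartoon–texture decomposition, and ships the
evaluation machinery that goes with the task: five standard fusion-quality
metrics and a Friedman/Nemenyi rank analysis over method-score tables.
This note records the model, the parameters that matter, the numerical
choices, and what the synthetic phantoms do and do not establish.

## Pipeline model

All images are 2-D float arrays in [0, 1] (8- and 16-bit rasters are
scaled by their container's bit depth on load; RGB collapses by Rec. 601
luminance; working size defaults to 256 × 256 with bilinear resampling).
The pipeline has five stages.

**1. Contrast enhancement.** A per-pixel illumination map `A` is estimated
from the brightness estimate `R = clip(img, ε, 1)` by minimising

    Σ (A − R)² + φ Σ_{d∈{h,v}} Z_d · (∇_d A)² / (|∇_d R| + ε)

— a quadratic relaxation of an edge-aware total-variation prior, solved as
one sparse SPD linear system (direct LU factorisation). The directional
weights `Z_d = 1 / (|Σ_window ∇_d R| + κ)` are large on flat regions and
small across coherent edges, so illumination may jump at structure
boundaries. The enhanced image blends the input with a synthetically
exposed copy: `W·img + (1 − W)·f(img, k)` with `W = A^ϕ` and the
beta–gamma camera response `f(img, k) = img^(k^a)·exp(b(1 − k^a))`
(a = −0.3293, b = 1.1258). The exposure ratio `k ∈ [1, 7]` maximises the
intensity entropy of the under-exposed pixels (`W < 0.5`) by
golden-section search (30 iterations; deterministic). Defaults: ϕ = 0.5,
φ = 10⁻³, κ = ε = 10⁻³, gradient-window half-width 2. Well-exposed images
pass through nearly unchanged (`W → 1`); enhancement is applied to both
modalities.

**2. Edge maps.** Sobel gradients of the *enhanced* images (true
convolution, symmetric padding) and their magnitude. The gradient maps are
diagnostic/exportable; the decomposition itself targets the enhanced
image, and the gradient information re-enters through the gradient-based
quality metrics.

**3. Cartoon–texture decomposition.** Each enhanced image is decomposed
over a fixed overcomplete dictionary of 8 × 8 2-D DCT atoms sorted by
radial frequency: the 8 lowest-frequency atoms (including DC) form the
cartoon bank, the 16 highest-frequency zero-mean atoms the texture bank.
A deterministic analytic dictionary was chosen over a learned one so that
builds need no training data and every result is bit-reproducible; an
externally learned bank can be supplied through `FilterBank` (with flat
binary import/export). The coefficient stacks minimise

    ½‖img − Σ h_cu∗φ_cu − Σ h_tu∗φ_tu‖² + ν_c Σ‖φ_cu‖₁ + ν_t Σ‖φ_tu‖₁

by block alternation (cartoon stack, then texture stack), each block
solved by ADMM. Convolutions are circular so the ADMM coefficient update
is exact in the frequency domain: the per-frequency normal matrix is a
rank-one perturbation of ρI and Sherman–Morrison gives a closed form. The
image is edge-tapered (4-pixel cosine ramp toward a blurred copy) before
the periodic solve to suppress wrap-around edges. Defaults: ν_c = 0.01,
ν_t = 0.005 (texture penalised less, since its atoms carry less energy
per unit coefficient), ρ = 1, ≤100 inner ADMM iterations, ≤10 block
alternations, tolerance 10⁻⁴ on residuals and relative objective change.
The objective evaluated at the sparse iterates is non-increasing across
block alternations up to the subproblem tolerance.

A post-solve *expansion* step re-admits coefficients the l1 penalty
zeroed: for every filter and 8 × 8 tile with no active coefficients, the
normalised correlation between the reconstruction residual and the
filter's correlation response is computed over the tile; where it reaches
the similarity threshold τ (default 0.8) the tile is unlocked, and the
enlarged support is refined by gradient steps on the plain least-squares
term with step 1/L (L = max over frequencies of Σ_u |ĥ_u|², an upper
bound on the operator norm), so the reconstruction error cannot increase.
The correlation-over-tiles form is this package's concrete definition of
residual-similarity expansion; τ = 1 disables the step.

**4. Fusion rule.** Per component j ∈ {c, t} and source n, the activity
`ζ_j^n(p,q) = Σ_u |φ_{j,u}^n(p,q)|` is window-averaged over
(2m_j + 1)² neighbourhoods (defaults m_c = 2, m_t = 1: the cartoon map is
smoothed harder because it varies slowly, while texture activity is
spatially precise; smoothing also buys robustness to slight
misregistration). The choose-max rule copies, per pixel, the *entire*
coefficient vector (all U_j filters at once) from the source with the
larger smoothed activity — per-vector rather than per-filter selection
keeps the local representation coherent. Ties go to the CT source by
default (deterministic).

**5. Reconstruction.** The fused image is the synthesis
`Σ h_cu∗φ^f_cu + Σ h_tu∗φ^f_tu`, clipped to [0, 1].

The whole pipeline is deterministic: two runs with the same configuration
produce bit-identical output (asserted in the tests and the acceptance
script).

## Quality metrics

* **MI** — I(a;f) + I(b;f), 256-level histograms, base-2 logs, 0·log 0 = 0.
  Quantization is `floor(v·255 + 0.5)`.
* **EN** — Shannon entropy of the fused histogram, ∈ [0, 8] bits.
* **FMI** — features are Sobel magnitudes; over every stride-1 3 × 3
  window, each feature patch is binarized at its own mean and
  `I(m,i)/(S_m+S_i) + I(m,j)/(S_m+S_j)` is averaged over windows where
  both denominators are positive. The two-level quantization is
  deliberate: with 9 samples per window, a fine quantization saturates the
  empirical MI estimator (I ≈ S for *any* pair), destroying the metric's
  discrimination; the binary form keeps FMI(a,a,a) = 1 exact while
  independent noise scores near 0. Images whose features are everywhere
  uninformative (constant images) score 0 and are flagged.
* **Qabf** — Xydeas–Petrovic edge transfer: relative Sobel
  strength/orientation preservation through the standard sigmoids
  (Γ_g = 0.9994, k_g = −15, σ_g = 0.5; Γ_α = 0.9879, k_α = −22,
  σ_α = 0.8), weighted by gradient strength to the power T = 1.
  Convention: where the fused gradient vanishes but a source gradient does
  not, preservation is exactly 0 (rather than the sigmoid's small positive
  floor), so a constant fused image scores exactly 0; a 10⁻¹⁰ tolerance
  absorbs convolution round-off on flat regions.
* **VIF** — pixel-domain multi-scale visual information fidelity (scalar
  Gaussian scale mixture, 4 dyadic scales, Gaussian windows of size
  17/9/5/3 with σ = size/5, noise variance 2), averaged over the two
  sources. Identical images score 1 (to ~10⁻⁷, set by the internal
  variance floor); scales whose window no longer fits the downsampled
  image are skipped, so very small inputs are scored from the finer scales
  only; a reference with no usable information scores 1 by convention.
  VIF may legitimately exceed 1 when the fused image is sharper than a
  source.

Every metric is checked against an independent nested-loop implementation
at 32 px to 10⁻⁹.

## Rank statistics

Scores are ranked within each (dataset, metric) block, rank 1 = best,
ties averaged (all five metrics are higher-better). The omnibus test is
the tie-corrected Friedman chi-square with k − 1 degrees of freedom
(cross-checked against `scipy.stats.friedmanchisquare` and, at tiny
sizes, an exhaustive within-block permutation null). The post-hoc Nemenyi
critical difference uses an embedded table of infinite-df
Studentized-range values divided by √2 (α ∈ {0.05, 0.10}, k ≤ 20;
verified against `scipy.stats.studentized_range`). The shipped benchmark
table (10 methods × 30 blocks = 6 dataset pairs × 5 metrics) yields
CD = 2.4734, Friedman p ≈ 5·10⁻²², mean rank 1.0 for the proposed method,
and a gap of 1.83 to the next-best method (CNN) — smaller than one CD,
i.e. not statistically significant at α = 0.05.

## Phantoms: what they emulate and what they don't

`make_pair` generates registered CT-like/MRI-like pairs on a shared
elliptical skull geometry: the CT channel has a bright bone ring
(intensity 0.9 on a 0.05 background) with a low-contrast interior; the
MRI channel has the same ring dark (0.15) and a high-contrast interior of
smooth tissue blobs, band-limited texture (amplitude 0.25) and a few
bright lesions. Gaussian noise σ = 0.01 is added to both; all randomness
comes from one seeded generator. Default size 256 matches the pipeline's
standard working size.

The phantoms reproduce the *complementarity* of the two modalities (hard
structure in one channel, soft-tissue detail in the other, exact
registration) — which is what the fusion rule and the metrics exercise.
They do not reproduce anatomy, partial-volume effects, modality-specific
noise statistics, bias fields, or misregistration; passing tests
therefore establish the correctness of the algorithms, not clinical
image quality on real scanner data.

## Problem sizes and numerical conventions

* Unit tests run at 16–64 px; solver properties at 64 px; the end-to-end
  test fuses a 256 × 256 pair (≈ 13 s single-threaded). The acceptance
  script uses 256 px for metric identities, 64 px for solver
  diagnostics and 128 px for the end-to-end quantities — sizes chosen so
  the full recomputation stays fast while the 256-px path is still
  exercised in the suite.
* Monotonicity of the block objective is asserted with relative slack
  10⁻⁶ (the subproblems are solved to tolerance, not exactly).
* Degenerate inputs: zero images decompose to zero stacks with objective
  0; constant fused images score MI = EN = Qabf = 0; `evaluate_pair`
  flags the conventions it applied.
* Save/load round trip is lossy only through 8-bit quantization
  (≤ 1/255 per pixel, round-half-up).

## Known limitations

* The DCT frequency split is a fixed proxy for learned morphological
  dictionaries; signals whose "texture" is oscillatory in one axis only
  sit near the cartoon/texture boundary and can land in either component.
* Circular convolutions (required for the exact frequency-domain ADMM
  step) interact with the edge taper: the outermost ~4 pixels of the
  decomposition target are slightly blended.
* The Friedman/Nemenyi analysis treats the 30 dataset-metric cells as
  independent blocks, as is conventional for this kind of benchmark
  table; metrics computed on the same fused image are in truth
  correlated.
* Only pairwise fusion is supported, and no registration is performed.
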