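# Methods

## Scope and intent

`pathae` implements a feature-learning and classification pipeline for
large tissue images whose classes are defined by the spatial distribution
of locally similar motifs, together with a synthetic generator that
reproduces exactly that situation at desk scale. Everything below — model
equations, defaults, problem sizes, numerical choices — describes what the
package actually computes; the test suite and `scripts/acceptance.py`
measure every empirical number quoted here.

## Sparse convolutional autoencoder

One stage maps an (H, W, C) input through a same-padded convolution
(filter size f, F filters), a sigmoid, and 2×2 max pooling to an
(H/2, W/2, F) encoding with activations in (0, 1); the decoder copies each
encoding value into a 2×2 block (no pooling switches are stored), applies
a same-padded deconvolution with filters of the same size, and a sigmoid.
The training objective is `L = R + λ_s·S` with

- `R = Σ_i (x_i^out − x_i^in)²` summed over all input nodes, and
- `S`: at each spatial position of the encoding, the F activations are
  normalized to proportions r_j and `−Σ_j r_j ln r_j` (natural log,
  `0·ln 0 := 0`) is accumulated over positions; zero-total positions
  contribute zero.

Entropy is normalized **per spatial position across filters** rather than
per image across all encoding nodes: the per-position reading is what
makes S a *local* sparsity pressure (each position should respond through
few filters) and keeps S's extremes interpretable (0 at one-hot,
`ln F` per position at uniform). The sigmoid nonlinearity is used on both
encode and decode paths because the entropy term requires nonnegative
bounded activations and the reconstruction must live in [0, 1].

Gradients are exact analytic backpropagation (verified against central
finite differences at 1e-6 tolerance in the test suite); optimization is
Adam (lr 1e-3 default, standard moment decays). Weight initialization is
fan-in-scaled uniform, seeded. λ_s defaults to 1e-3 — small enough not to
harm reconstruction, large enough that a 10× increase measurably reduces
S (≈ 450 vs ≈ 585 nats mean per-image in the paired experiment).

Stacking is greedy: stage k trains on the frozen encodings of stage k−1;
earlier weights are bit-identical before and after later training (hash-
checked). Default stack for three stages: filter sizes 7, 5, 3 with
16, 24, 32 filters.

**Stage training length matters.** With too few Adam steps (~100), stages
2–3 reconstruct their nearly-constant inputs from the bias alone and the
deep encoding becomes input-independent (inter-image amplitude decays
~0.12 → 0.02 → 0.005 through the stack); no classifier can then work. The
reference experiments use 600 steps per stage, after which the stage-3
encoding retains clear inter-image signal. Pre-training uses 32 px patches
of the training images: the filters are local, so the patch only needs to
exceed the stack's receptive field.

## RISA

Filters C (k×n) over flattened n-dim patches, fixed binary pooling H
(g×k; consecutive non-overlapping groups, default group size 2 so filters
pair up). Second-layer output `p_i = sqrt(Σ_m H_im (C x)_m²)` — the
Euclidean norm of each group's responses, positively homogeneous and
invariant to within-group rotations. The learning objective is

    Σ_t ( (1/N) ‖Cᵀ C x⁽ᵗ⁾ − x⁽ᵗ⁾‖² + λ Σ_i p_i(x⁽ᵗ⁾) ),

with N the batch size. The reconstruction term is written `CᵀC x − x`
(the standard linear-autoencoder form); with C as k×n this is the only
type-consistent reading of the two-layer reconstruction. Only C is
trained (Adam, analytic gradient, ε = 1e-12 guard at p = 0); H is fixed.
Used convolutionally, C slides over the image with stride 1.

## Classifier variants

Three pipelines share a softmax head trained by cross-entropy + Adam:
*direct* (two conv+pool blocks for 64 px inputs, one block fewer/more per
halving/doubling of input size, trained jointly), *ae* and *risa* (frozen
pretrained extractor, head only). Pretrained extractors stay frozen during
supervised training — the pre-training rationale is precisely that
features are reusable and the supervised pass stays cheap; a `fine_tune`
flag exists but is unimplemented and raises. Argmax ties in evaluation
resolve to the lowest class index. Class names default to (TRU, PP, PI).

## Tiled multi-reduction classifier

Tiles are encoded independently (zero padding per tile; values within
~f/2 px of seams differ from a whole-image encoding — measured and
bounded in the tests) and reassembled. The encoded map is partitioned
into G×G subpanes; one shared dense map (sigmoid) reduces each subpane to
d_r values; a final linear layer + softmax gives class probabilities.
Desk defaults G=8, d_r=24, 64 px tiles on 256 px inputs; the full-scale
regime (2048 px, G=16) is reachable through the same fields.

**Conditioning.** Desk-scale stage-3 encodings carry their informative
variation at ~1e-3 amplitude on top of a large constant spatial pattern.
`train_reduction` therefore standardizes each subpane feature dimension
(z-score over the training set) during optimization and afterwards folds
the affine transform into the shared dense weights and bias — an exact
reparameterization: the saved classifier is the plain architecture above
and consumes raw encodings. An optional decoupled weight decay exists
(default 0; the reference experiments do not use it).

## Synthetic generator

The generator emulates one specific premise: classes share local
appearance and differ in spatial arrangement.

- **Motifs**: m=8 px stamps — stripes, ring/target patterns, blobs —
  colored as stain absorption (green absorbed most, so motifs read
  purple on the pink background). One seeded bank is shared by all
  classes of a dataset.
- **Background**: eosin-like base color (0.91, 0.76, 0.84) plus smoothed
  Gaussian noise with 0.05 peak amplitude — non-constant but class-free.
- **Placement** (all with the same expected count, density 0.004 /px²):
  uniform = homogeneous Poisson; clustered = Neyman–Scott (parent Poisson,
  mean 6 offspring at Gaussian σ = 12 px); graded = linear intensity ramp
  via thinning. Overlapping motifs composite by per-pixel maximum of ink,
  then darken the background multiplicatively — order-independent and
  never leaving [0, 1]. Coordinates are row-major, origin top-left,
  half-open.
- **Local indistinguishability**: at the defaults, the distribution of
  8×8-patch mean intensities is statistically indistinguishable between
  the uniform and clustered classes (two-sample KS p ≥ 0.02 across ten
  pilot seeds, typically ≫ 0.1), while the index of dispersion of motif
  counts differs by ≥ 2×. The graded class genuinely widens the patch-mean
  distribution (its local rate varies), so local near-chance behavior is
  asserted through the classifier experiment rather than the KS pair.

What the generator does **not** model: real nucleus/stroma morphology,
stain variation between slides, scanner artifacts, or any measured
morphological difference between actual transcriptome subtypes. Passing
tests therefore demonstrate that the architecture can read spatial
distribution when local appearance is shared — not that it reaches any
particular accuracy on real whole-slide images.

## Reference experiments and problem sizes

All experiments are seeded end to end; every random stream derives from
the experiment seed.

- **Context-size experiment**: 3 placement classes, 80 images/class at
  256 px (80/20 stratified split), one shared stack (7/5/3 px filters,
  16/24/32 filters, 600 steps/stage, λ_s = 1e-3), then a fresh reducer per
  context size (32, 128, 256 px; 4 random crops per image below full
  size; G scales with the encoded map, d_r = 24, 400 Adam steps at
  lr 1e-2). Seed 1 measures 35.9 / 80.7 / 97.9 % — near-chance at motif
  scale, near-perfect at full context; other seeds measured 90–100 % at
  256 px (the test split is only 48 images, so single misclassifications
  move the estimate by ~2 points). These sizes are a deliberate desk-scale
  choice: with 40 images/class the reducer memorizes (train 100 %,
  test 75 %).
- **Sparsity effect**: same seed/architecture trained with λ_s = 0 vs
  1e-2 on 50 images; the penalized stage ends with strictly smaller mean
  encoding entropy.
- **Reconstruction gain**: a trained single stage reaches a held-out mean
  R about 25× smaller than its initialization (ratio ≈ 0.04, bound 0.2).
- **Motif recovery**: with one stripe motif at 85 % mixture weight, random
  16 px patches are encoded once through a trained single stage; for every
  (position, filter) node the 100 highest-activating patches are averaged
  and the average's darkness is correlated with the motif's ink at the
  node's receptive-field center (±1 px alignment). Best node: Pearson
  0.64–0.67 across pilot seeds. Position-locked ranking is what preserves
  phase; ranking by a position-pooled filter score blurs stripes out.

## Numerical choices

- Natural logarithms throughout; entropy guard ε = 1e-12 (sigmoid
  activations never actually reach 0).
- Max-pool gradient shares ties equally (ties have measure zero for
  continuous inputs but keep finite-difference checks exact).
- Same padding for even filter sizes pads (f−1)//2 before and f//2 after.
- Seeds passed to NumPy generators are kept below 2³¹; nested streams use
  `SeedSequence` hashing.
- Checkpoints are HDF5 with a format version checked on load; images are
  8-bit PNG/TIFF normalized by 255.

## Known limitations

- Determinism is promised per backend/BLAS build, not across builds.
- Tile seams use zero padding (tiles are independent); seam halos are
  bounded but present.
- The RISA classifier path materializes stride-1 patch features; for
  large inputs this is memory-heavy and the variant is intended for small
  (≤ 64 px) inputs, matching how it is compared against the others.
- `fine_tune` for pretrained extractors is declared but not implemented.
- The full whole-slide regime (2048 px inputs, hundreds of thousands of
  slices) is architecturally supported but not exercised by the tests.
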