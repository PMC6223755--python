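# pathae

Sparse convolutional autoencoders and a tiled multi-reduction classifier
for recognizing image classes that are defined not by their local texture
but by the **spatial distribution** of locally similar motifs — the
situation faced when classifying tumor tissue into molecular subtypes
(e.g. the lung adenocarcinoma transcriptome subtypes TRU, PP and PI) from
stained histopathology: the cell-scale structures look alike across
subtypes, and only their arrangement over a wide tissue area separates the
classes.

The package is pure NumPy/SciPy: all forward passes, analytic gradients
and the Adam optimizer are implemented here, with no deep-learning
framework dependency.

## The model

**Sparse convolutional autoencoder.** One stage encodes an H×W×C image by
a same-padded convolution, sigmoid nonlinearity and 2×2 max pooling, and
decodes by copy-unpooling each value into a 2×2 block, a deconvolution
with filters of the same size, and a sigmoid. Training minimizes

    L = R + λ_s · S,
    R = Σ_i (x_i^output − x_i^input)²,
    S = Σ_positions Σ_j (− r_j ln r_j),

where, at each spatial position of the encoding map, r_j is filter j's
output intensity relative to the total over all filters. R is the
reconstruction error; S is the information entropy of the encoding layer,
which pushes every position to respond through few filters. Stages are
stacked greedily: each stage is trained, then frozen, and the next stage
trains on its encodings.

**RISA** (reconstruction independent subspace analysis). A two-layer
alternative with learned filters C (k×n) and a fixed binary group-pooling
matrix H (g×k). The second-layer output

    p_i(x; C, H) = sqrt( Σ_m H_im (Σ_j C_mj x_j)² )

is invariant to rotations inside each filter group. C is learned by
minimizing Σ_t ( (1/N)‖CᵀC x⁽ᵗ⁾ − x⁽ᵗ⁾‖² + λ Σ_i p_i(x⁽ᵗ⁾) ).

**Classifier variants.** Three pipelines: a *direct* classifier (conv +
pool blocks trained jointly with a softmax head), an *AE-pretrained*
classifier and a *RISA-pretrained* classifier (frozen unsupervised
extractor + trainable softmax head), all trained with softmax
cross-entropy and Adam and evaluated by confusion matrices.

**Tiled multi-reduction classifier.** Large images are split into
non-overlapping tiles; each tile passes through the frozen three-stage
encoder; the tile encodings are concatenated back into one feature map,
partitioned into a G×G grid of subpanes, and a *single shared* dense map
reduces every subpane to d_r nodes (a non-overlapping windowed
convolution); a final dense layer maps the G·G·d_r values to one node per
class. Because the reduction layers see the whole arrangement of local
features, the network can separate classes that differ only in spatial
distribution — and its accuracy grows with input context size.

**Synthetic data.** A built-in generator renders labeled images whose
classes share one bank of cell-scale motifs (blobs, stripes, ring/target
patterns on an eosin-pink background) and differ only in the point process
placing them: homogeneous Poisson (uniform), Neyman–Scott (clustered) or a
linear intensity ramp (graded). Small patches are statistically
indistinguishable between classes; whole images are separable. This makes
the context-size claim testable without any external imagery.

## Worked example

The central experiment — accuracy of the multi-reduction classifier as a
function of input context size on three placement-only classes:

```python
from pathae import context_size_experiment

res = context_size_experiment(seed=1)
print(res["accuracy"])
```

which prints (seed 1):

```
{32: 35.94, 128: 80.73, 256: 97.92}
```

At 32 px — roughly the motif scale — the classifier is near the 33.3 %
chance level for three classes: single patches carry almost no class
information. At 128 px the placement pattern starts to be visible (80.7 %),
and with the full 256 px context the tiled reduction network separates the
three placement processes almost perfectly (97.9 % on 48 held-out images).
The experiment pre-trains a 7×7/5×5/3×3 three-stage sparse autoencoder
stack (16/24/32 filters) on unlabeled patches, freezes it, and trains only
the reduction layers per context size.

The same pipeline is scriptable from the shell:

```bash
pathae gen-data --classes 3 --n 30 --size 64 --seed 7 --out data/
pathae pretrain --data data/ --ckpt stack.h5 --stages 7x16,5x24,3x32
pathae train-reduce --data data/ --ckpt stack.h5 --out-ckpt model.h5 --grid 2
pathae predict --ckpt model.h5 --image data/0/0.png
```

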