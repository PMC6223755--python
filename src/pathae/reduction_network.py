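"""Tiled multi-reduction classifier for large images.

A large image is divided into non-overlapping square tiles; every tile is
encoded by a frozen, greedily pre-trained convolutional autoencoder stack;
the tile encodings are concatenated back into one feature map in tile
positions.  That map is partitioned into a G x G grid of subpanes, and a
*single shared* dense map (sigmoid) reduces each subpane to d_r output
nodes — equivalently a convolution with window and stride equal to the
subpane size, without overlap.  A final dense layer reduces the G*G*d_r
values to one node per class, followed by softmax.

Because the per-tile features only see local motifs while the reduction
layers see their arrangement across the whole image, this architecture can
separate classes that differ in the spatial *distribution* of locally
similar structures.  ``context_size_experiment`` measures exactly that on
synthetic data: accuracy as a function of input context size.

Desk-scale defaults are 256 px inputs, 64 px tiles, G=8, d_r=24; the
full-scale regime (2048 px inputs, G=16) is reachable through the same
configuration fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, DataError, ShapeError, sigmoid, softmax, uniform_fanin_init
from .conv_autoencoder import (
    ConvAEStage,
    FeatureMap,
    StageConfig,
    TrainConfig,
    stack_encode,
    train_stack,
)
from .synthetic_data import ClassSpec, LabeledDataset, generate_dataset

__all__ = [
    "TileGrid",
    "ReductionClassifier",
    "ReductionConfig",
    "tile_image",
    "encode_tiles",
    "subpane_reduce",
    "reduction_forward",
    "train_reduction",
    "context_size_experiment",
]


@dataclass(frozen=True)
class TileGrid:
    """Non-overlapping exact cover of an image by square tiles."""

    tile_size: int
    rows: int
    cols: int
    coords: list[tuple[int, int, int, int]]  # half-open (r0, r1, c0, c1)


@dataclass
class ReductionClassifier:
    """Shared subpane reducer plus final class layer."""

    G: int = 8
    d_r: int = 24
    n_classes: int = 3
    tile_size: int = 64
    shared_weights: np.ndarray | None = None  # (subpane_flat_dim, d_r)
    shared_bias: np.ndarray | None = None  # (d_r,)
    final_weights: np.ndarray | None = None  # (G*G*d_r, n_classes)
    final_bias: np.ndarray | None = None  # (n_classes,)


@dataclass(frozen=True)
class ReductionConfig:
    G: int = 8
    d_r: int = 24
    n_classes: int = 3
    tile_size: int = 64
    seed: int = 0
    #: decoupled L2 weight decay on the two dense maps' weights; the reducer
    #: has far more parameters than a desk-scale run has images, so a little
    #: shrinkage steers it toward spatially shared statistics instead of
    #: memorization
    weight_decay: float = 0.0


def tile_image(img: np.ndarray, tile_size: int) -> TileGrid:
    """Row-major, non-overlapping, exactly covering tile grid."""
    H, W = np.asarray(img).shape[:2]
    if H % tile_size or W % tile_size:
        raise ShapeError(f"image {H}x{W} not divisible by tile size {tile_size}")
    rows, cols = H // tile_size, W // tile_size
    coords = [
        (r * tile_size, (r + 1) * tile_size, c * tile_size, (c + 1) * tile_size)
        for r in range(rows)
        for c in range(cols)
    ]
    return TileGrid(tile_size=tile_size, rows=rows, cols=cols, coords=coords)


def encode_tiles(img: np.ndarray, grid: TileGrid, stages: list[ConvAEStage]) -> FeatureMap:
    """Encode each tile independently and reassemble in tile positions.

    Tiles are padded with zeros inside their own convolutions, so values
    near tile seams can differ from a whole-image encoding; tiles are
    treated as individual and independent.
    """
    img = np.asarray(img, dtype=float)
    k = len(stages)
    if grid.tile_size % (2**k):
        raise ShapeError(f"tile size {grid.tile_size} not divisible by 2^{k}")
    ts_out = grid.tile_size // (2**k)
    F = stages[-1].n_filters if stages else img.shape[2]
    out = np.zeros((grid.rows * ts_out, grid.cols * ts_out, F))
    for (r0, r1, c0, c1) in grid.coords:
        enc = stack_encode(img[r0:r1, c0:c1], stages).values
        ro, co = (r0 // grid.tile_size) * ts_out, (c0 // grid.tile_size) * ts_out
        out[ro : ro + ts_out, co : co + ts_out] = enc
    return FeatureMap(out)


def _subpane_matrix(z: np.ndarray, G: int) -> np.ndarray:
    """(G*G, subpane_flat_dim) rows in row-major subpane order."""
    H, W, F = z.shape
    if H % G or W % G:
        raise ShapeError(f"feature map {H}x{W} not divisible into {G}x{G} subpanes")
    h, w = H // G, W // G
    return z.reshape(G, h, G, w, F).transpose(0, 2, 1, 3, 4).reshape(G * G, h * w * F)


def subpane_reduce(z, rc: ReductionClassifier) -> np.ndarray:
    """Apply the single shared dense map (sigmoid) to every subpane."""
    za = z.values if isinstance(z, FeatureMap) else np.asarray(z, dtype=float)
    sub = _subpane_matrix(za, rc.G)
    a = sigmoid(sub @ rc.shared_weights + rc.shared_bias)
    return a.reshape(rc.G, rc.G, rc.d_r)


def reduction_forward(img: np.ndarray, stages: list[ConvAEStage], rc: ReductionClassifier) -> np.ndarray:
    """tile -> encode -> shared subpane reduction -> final dense -> softmax."""
    grid = tile_image(img, rc.tile_size)
    z = encode_tiles(img, grid, stages)
    a = subpane_reduce(z, rc)
    logits = a.ravel() @ rc.final_weights + rc.final_bias
    return softmax(logits)


def _init_reducer(rc_cfg: ReductionConfig, subpane_flat_dim: int) -> ReductionClassifier:
    rng = np.random.default_rng(rc_cfg.seed)
    G, d_r, K = rc_cfg.G, rc_cfg.d_r, rc_cfg.n_classes
    return ReductionClassifier(
        G=G, d_r=d_r, n_classes=K, tile_size=rc_cfg.tile_size,
        shared_weights=uniform_fanin_init(rng, (subpane_flat_dim, d_r), subpane_flat_dim),
        shared_bias=np.zeros(d_r),
        final_weights=uniform_fanin_init(rng, (G * G * d_r, K), G * G * d_r),
        final_bias=np.zeros(K),
    )


def train_reduction(data: LabeledDataset, stages: list[ConvAEStage], rc_cfg: ReductionConfig,
                    cfg: TrainConfig):
    """Train the reducer on frozen stack encodings (softmax CE + Adam).

    Tile encodings are computed once up front; autoencoder weights are
    never touched.  Returns (ReductionClassifier, per-step loss history).
    """
    train_imgs, train_labels = data.train
    if len(train_imgs) == 0:
        raise DataError("empty training split")
    label_map = {c: i for i, c in enumerate(sorted(set(data.labels)))}
    y = np.array([label_map[c] for c in train_labels])
    subs = []
    for im in train_imgs:
        grid = tile_image(im, rc_cfg.tile_size)
        z = encode_tiles(im, grid, stages).values
        subs.append(_subpane_matrix(z, rc_cfg.G))
    E = np.stack(subs)  # (n, G*G, D)
    # Standardize subpane features over the training set to condition the
    # optimization: the encodings ride on a large constant spatial pattern
    # with small informative variation.  The affine transform is folded back
    # into the shared dense weights afterwards, so the trained classifier is
    # exactly the architecture reduction_forward expects.
    mu = E.reshape(-1, E.shape[2]).mean(axis=0)
    sig = np.maximum(E.reshape(-1, E.shape[2]).std(axis=0), 1e-8)
    E = (E - mu) / sig
    rc = _init_reducer(rc_cfg, E.shape[2])
    params = {
        "Wsh": rc.shared_weights, "bsh": rc.shared_bias,
        "Wf": rc.final_weights, "bf": rc.final_bias,
    }
    opt = Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    n = len(train_imgs)
    bs = min(cfg.batch_size, n)
    history = []
    for _ in range(cfg.steps):
        idx = rng.choice(n, size=bs, replace=False)
        Eb, yb = E[idx], y[idx]
        A = sigmoid(Eb @ rc.shared_weights + rc.shared_bias)  # (B, G*G, d_r)
        flat = A.reshape(bs, -1)
        logits = flat @ rc.final_weights + rc.final_bias
        zmax = logits.max(axis=1, keepdims=True)
        logp = logits - zmax - np.log(np.exp(logits - zmax).sum(axis=1, keepdims=True))
        loss = float(-logp[np.arange(bs), yb].mean())
        probs = np.exp(logp)
        dlogits = probs
        dlogits[np.arange(bs), yb] -= 1.0
        dlogits /= bs
        dflat = dlogits @ rc.final_weights.T
        dA = dflat.reshape(A.shape) * A * (1.0 - A)
        grads = {
            "Wf": flat.T @ dlogits,
            "bf": dlogits.sum(axis=0),
            "Wsh": np.einsum("bsd,bsr->dr", Eb, dA, optimize=True),
            "bsh": dA.sum(axis=(0, 1)),
        }
        opt.step(grads)
        if rc_cfg.weight_decay:
            rc.shared_weights *= 1.0 - cfg.learning_rate * rc_cfg.weight_decay
            rc.final_weights *= 1.0 - cfg.learning_rate * rc_cfg.weight_decay
        history.append(loss)
    # fold the standardization into the shared dense map so that
    # W' x + b' == W (x - mu)/sig + b for raw subpane features x
    rc.shared_weights = rc.shared_weights / sig[:, None]
    rc.shared_bias = rc.shared_bias - mu @ rc.shared_weights
    return rc, history


# ---------------------------------------------------------------------------
# Context-size experiment
# ---------------------------------------------------------------------------


def default_class_specs(n_motifs: int = 4, density: float = 0.004) -> list[ClassSpec]:
    """Three classes with an identical motif mixture, differing only in
    placement: uniform, clustered, graded."""
    mix = tuple([1.0 / n_motifs] * n_motifs)
    return [
        ClassSpec(class_id=0, placement="uniform", density=density, motif_mix=mix),
        ClassSpec(class_id=1, placement="clustered", density=density, motif_mix=mix,
                  cluster_radius=12.0, children=6.0),
        ClassSpec(class_id=2, placement="graded", density=density, motif_mix=mix,
                  direction=0.0),
    ]


def _crops(images, labels, size: int, n_crops: int, rng: np.random.Generator):
    out_imgs, out_labels = [], []
    for im, lab in zip(images, labels):
        H, W = im.shape[:2]
        if size == H and size == W:
            out_imgs.append(im)
            out_labels.append(lab)
            continue
        for _ in range(n_crops):
            r = int(rng.integers(0, H - size + 1))
            c = int(rng.integers(0, W - size + 1))
            out_imgs.append(im[r : r + size, c : c + size])
            out_labels.append(lab)
    return out_imgs, out_labels


def _accuracy(rc, stages, images, labels, label_map) -> float:
    correct = 0
    for im, lab in zip(images, labels):
        p = reduction_forward(im, stages, rc)
        correct += int(np.argmax(p) == label_map[lab])
    return 100.0 * correct / len(images)


def context_size_experiment(
    seed: int,
    sizes: tuple[int, ...] = (32, 128, 256),
    n_per_class: int = 80,
    full_size: int = 256,
    stage_cfgs: tuple[StageConfig, ...] = (
        StageConfig(7, 16), StageConfig(5, 24), StageConfig(3, 32)
    ),
    pretrain_steps: int = 600,
    reduce_steps: int = 400,
    n_crops: int = 4,
    d_r: int = 24,
) -> dict:
    """Accuracy of the multi-reduction classifier vs input context size.

    Three synthetic classes share motif bank and mixture and differ only in
    placement.  One three-stage stack is pre-trained on patches of the
    training images and frozen; for every context size a fresh reducer is
    trained on crops of that size (the full images at ``full_size``) and
    evaluated on the test split.  Returns per-size accuracies plus the
    experiment's inputs for inspection.
    """
    seed = int(seed) % (2**31)
    specs = default_class_specs()
    data = generate_dataset(specs, n_per_class=n_per_class, size=full_size, seed=seed)
    train_imgs, train_labels = data.train
    test_imgs, test_labels = data.test
    label_map = {c: i for i, c in enumerate(sorted(set(data.labels)))}

    # unsupervised pre-training on 32 px patches of the training images;
    # the filters are local, so the patch only needs to exceed the stack's
    # receptive field, and small patches keep desk-scale runs fast
    rng = np.random.default_rng(seed + 1)
    patches = []
    for _ in range(200):
        im = train_imgs[int(rng.integers(len(train_imgs)))]
        r = int(rng.integers(0, im.shape[0] - 32 + 1))
        c = int(rng.integers(0, im.shape[1] - 32 + 1))
        patches.append(im[r : r + 32, c : c + 32])
    stack_cfg = TrainConfig(learning_rate=3e-3, batch_size=16, steps=pretrain_steps,
                            lambda_s=1e-3, seed=seed + 2)
    stages = train_stack(patches, list(stage_cfgs), stack_cfg)

    k = len(stages)
    results: dict[int, float] = {}
    for size in sizes:
        crop_rng = np.random.default_rng(seed + 3 + size)
        tr_imgs, tr_labels = _crops(train_imgs, train_labels, size, n_crops, crop_rng)
        te_imgs, te_labels = _crops(test_imgs, test_labels, size, n_crops, crop_rng)
        enc_spatial = size // (2**k)
        G = max(1, enc_spatial // 4)
        rc_cfg = ReductionConfig(G=G, d_r=d_r, n_classes=len(label_map),
                                 tile_size=min(64, size), seed=seed + 5)
        sub_ds = LabeledDataset(
            images=tr_imgs + te_imgs,
            labels=tr_labels + te_labels,
            split={"train": list(range(len(tr_imgs))),
                   "test": list(range(len(tr_imgs), len(tr_imgs) + len(te_imgs)))},
            seed=seed,
        )
        rc, _ = train_reduction(sub_ds, stages, rc_cfg, TrainConfig(
            learning_rate=1e-2, batch_size=16, steps=reduce_steps, seed=seed + 7))
        results[size] = _accuracy(rc, stages, te_imgs, te_labels, label_map)

    return {
        "sizes": list(sizes),
        "accuracy": results,
        "n_train_images": len(train_imgs),
        "n_test_images": len(test_imgs),
        "stages": stages,
        "dataset": data,
    }
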