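"""The three classifier variants and their evaluation.

- ``direct``: convolution + pooling blocks trained jointly with a softmax
  head on the classification loss (features follow optimal classification).
- ``ae``: a greedily pre-trained convolutional autoencoder stack, frozen,
  with a trainable softmax head on the flattened encoding.
- ``risa``: a pre-trained RISA filter bank applied convolutionally
  (stride-1 sliding window over the image), frozen, with a trainable
  softmax head on the pooled group features.

All heads are trained with softmax cross-entropy and Adam.  Pre-trained
extractors stay frozen during head training by default; a ``fine_tune``
flag exists but is off (pre-training is the point: features are reusable
and supervised training stays cheap).

Evaluation produces a confusion matrix (rows = true class, columns =
predicted) with percent accuracy; argmax ties resolve to the lowest class
index.  Default class names follow the three lung adenocarcinoma
transcriptome subtypes TRU, PP, PI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._nn import (
    Adam,
    ConfigError,
    DataError,
    ShapeError,
    conv2d_same,
    conv2d_same_backward,
    log_softmax,
    maxpool2,
    maxpool2_backward,
    sigmoid,
    softmax,
    uniform_fanin_init,
)
from .conv_autoencoder import ConvAEStage, TrainConfig, stack_encode
from .risa import RISAModel, risa_forward

__all__ = [
    "DEFAULT_CLASS_NAMES",
    "SoftmaxHead",
    "HeadConfig",
    "ConfusionMatrix",
    "VariantClassifier",
    "softmax_cross_entropy",
    "build_variant",
    "forward",
    "train_classifier",
    "evaluate_confusion",
    "variant_comparison_report",
]

DEFAULT_CLASS_NAMES = ("TRU", "PP", "PI")


@dataclass
class SoftmaxHead:
    weights: np.ndarray  # (feature_dim, n_classes)
    bias: np.ndarray  # (n_classes,)
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES


@dataclass(frozen=True)
class HeadConfig:
    input_size: int
    n_classes: int = 3
    filter_size: int = 5
    n_filters: int = 16
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    seed: int = 0
    fine_tune: bool = False


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (n_classes, n_classes) ints, rows true / cols predicted
    totals: np.ndarray  # per-class true counts
    accuracy: float  # percent

    def __post_init__(self):
        total = self.counts.sum()
        if total and abs(self.accuracy - 100.0 * np.trace(self.counts) / total) > 1e-9:
            raise ValueError("accuracy must equal 100 * trace / total")


@dataclass
class _ConvBlock:
    filters: np.ndarray  # (f, f, C_in, F)
    bias: np.ndarray  # (F,)


@dataclass
class VariantClassifier:
    kind: str  # "direct" | "ae" | "risa"
    input_size: int
    head: SoftmaxHead
    blocks: list[_ConvBlock] = field(default_factory=list)  # direct only
    stages: list[ConvAEStage] | None = None  # ae only
    risa: RISAModel | None = None  # risa only
    fine_tune: bool = False


def softmax_cross_entropy(logits: np.ndarray, true_class: int) -> float:
    """-ln p_true under softmax(logits); stable for large logits."""
    logits = np.asarray(logits, dtype=float)
    if not 0 <= true_class < logits.shape[-1]:
        raise IndexError(f"class {true_class} out of range for {logits.shape[-1]} classes")
    return float(-log_softmax(logits)[true_class])


def _n_blocks(input_size: int) -> int:
    # two conv+pool blocks at 64x64, one more per doubling, at least one
    return max(1, 2 + int(round(np.log2(input_size / 64))))


def build_variant(kind: str, pretrained=None, head_cfg: HeadConfig | None = None) -> VariantClassifier:
    """Assemble one of the three pipeline variants."""
    if head_cfg is None:
        raise ConfigError("head_cfg is required")
    rng = np.random.default_rng(head_cfg.seed)
    size, K = head_cfg.input_size, head_cfg.n_classes
    if kind == "direct":
        nb = _n_blocks(size)
        blocks, cin, s = [], 3, size
        for _ in range(nb):
            f, F = head_cfg.filter_size, head_cfg.n_filters
            blocks.append(
                _ConvBlock(
                    filters=uniform_fanin_init(rng, (f, f, cin, F), f * f * cin),
                    bias=np.zeros(F),
                )
            )
            cin, s = F, s // 2
        feat_dim = s * s * cin
        extractor: dict = {"blocks": blocks}
    elif kind == "ae":
        if not pretrained:
            raise ConfigError("ae variant needs a pre-trained stage list")
        stages = list(pretrained)
        s = size // (2 ** len(stages))
        feat_dim = s * s * stages[-1].n_filters
        extractor = {"stages": stages}
    elif kind == "risa":
        if pretrained is None:
            raise ConfigError("risa variant needs a pre-trained RISAModel")
        n = pretrained.C.shape[1]
        pf = int(round(np.sqrt(n / 3)))
        if pf * pf * 3 != n:
            raise ConfigError(f"RISA patch dim {n} is not a square RGB patch")
        g = pretrained.H.shape[0]
        pos = (size - pf + 1) ** 2
        feat_dim = pos * g
        extractor = {"risa": pretrained}
    else:
        raise ConfigError(f"unknown variant kind {kind!r}")
    head = SoftmaxHead(
        weights=uniform_fanin_init(rng, (feat_dim, K), feat_dim),
        bias=np.zeros(K),
        class_names=head_cfg.class_names[:K],
    )
    return VariantClassifier(
        kind=kind, input_size=size, head=head, fine_tune=head_cfg.fine_tune, **extractor
    )


# ---------------------------------------------------------------------------
# Feature extraction and forward pass
# ---------------------------------------------------------------------------


def _direct_forward_batch(model: VariantClassifier, xb: np.ndarray, want_cache=False):
    cache = []
    cur = xb
    for blk in model.blocks:
        a = sigmoid(conv2d_same(cur, blk.filters, blk.bias))
        pooled = maxpool2(a)
        cache.append((cur, a, pooled))
        cur = pooled
    feats = cur.reshape(cur.shape[0], -1)
    return (feats, cache) if want_cache else feats


def _risa_patches(img: np.ndarray, pf: int) -> np.ndarray:
    win = np.lib.stride_tricks.sliding_window_view(img, (pf, pf), axis=(0, 1))
    # (H-pf+1, W-pf+1, 3, pf, pf) -> (positions, pf*pf*3) in (row, col, chan) order
    win = win.transpose(0, 1, 3, 4, 2)
    return win.reshape(-1, pf * pf * 3)


def extract_features(model: VariantClassifier, images: list[np.ndarray]) -> np.ndarray:
    """Frozen-extractor features, one row per image."""
    if model.kind == "direct":
        return _direct_forward_batch(model, np.stack(images))
    if model.kind == "ae":
        return np.stack([stack_encode(im, model.stages).values.ravel() for im in images])
    pf = int(round(np.sqrt(model.risa.C.shape[1] / 3)))
    out = []
    for im in images:
        p = risa_forward(_risa_patches(np.asarray(im, dtype=float), pf), model.risa)
        out.append(p.ravel())
    return np.stack(out)


def forward(model: VariantClassifier, image: np.ndarray) -> np.ndarray:
    """Class probabilities for one image; sums to 1."""
    feats = extract_features(model, [np.asarray(image, dtype=float)])
    logits = feats @ model.head.weights + model.head.bias
    return softmax(logits)[0]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _ce_batch(feats: np.ndarray, labels: np.ndarray, head: SoftmaxHead):
    logits = feats @ head.weights + head.bias
    logp = log_softmax(logits, axis=1)
    loss = float(-logp[np.arange(len(labels)), labels].mean())
    dlogits = softmax(logits, axis=1)
    dlogits[np.arange(len(labels)), labels] -= 1.0
    dlogits /= len(labels)
    return loss, dlogits


def train_classifier(model: VariantClassifier, data, cfg: TrainConfig):
    """Adam on softmax cross-entropy; returns (model, per-step loss history).

    ae/risa extractors stay frozen (features are computed once up front);
    the direct variant backpropagates through its convolution blocks.
    """
    train_imgs, train_labels = data.train
    labels = np.asarray(train_labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise DataError("training data must contain at least 2 classes")
    # labels may be arbitrary ints; map onto head output indices
    label_map = {c: i for i, c in enumerate(sorted(classes))}
    y = np.array([label_map[c] for c in labels])
    rng = np.random.default_rng(cfg.seed)
    n = len(train_imgs)
    bs = min(cfg.batch_size, n)
    history: list[float] = []

    if model.kind in ("ae", "risa") and not model.fine_tune:
        feats = extract_features(model, [np.asarray(im, dtype=float) for im in train_imgs])
        params = {"W": model.head.weights, "b": model.head.bias}
        opt = Adam(params, lr=cfg.learning_rate)
        for _ in range(cfg.steps):
            idx = rng.choice(n, size=bs, replace=False)
            loss, dlogits = _ce_batch(feats[idx], y[idx], model.head)
            opt.step({"W": feats[idx].T @ dlogits, "b": dlogits.sum(axis=0)})
            history.append(loss)
        return model, history

    if model.kind != "direct":
        raise ConfigError("fine-tuning pre-trained extractors is not implemented")

    stack = np.stack([np.asarray(im, dtype=float) for im in train_imgs])
    params = {"W": model.head.weights, "b": model.head.bias}
    for i, blk in enumerate(model.blocks):
        params[f"f{i}"] = blk.filters
        params[f"c{i}"] = blk.bias
    opt = Adam(params, lr=cfg.learning_rate)
    for _ in range(cfg.steps):
        idx = rng.choice(n, size=bs, replace=False)
        xb = stack[idx]
        feats, cache = _direct_forward_batch(model, xb, want_cache=True)
        loss, dlogits = _ce_batch(feats, y[idx], model.head)
        grads = {"W": feats.T @ dlogits, "b": dlogits.sum(axis=0)}
        dcur = (dlogits @ model.head.weights.T).reshape(cache[-1][2].shape)
        for i in range(len(model.blocks) - 1, -1, -1):
            cur, a, pooled = cache[i]
            da = maxpool2_backward(a, pooled, dcur)
            de = da * a * (1.0 - a)
            dW, db, dcur = conv2d_same_backward(cur, model.blocks[i].filters, de)
            grads[f"f{i}"], grads[f"c{i}"] = dW, db
        opt.step(grads)
        history.append(loss)
    return model, history


def evaluate_confusion(model: VariantClassifier, data) -> ConfusionMatrix:
    """Confusion matrix on the test split; argmax ties go to the lowest index."""
    test_imgs, test_labels = data.test
    if len(test_imgs) == 0:
        raise DataError("empty test split")
    classes = sorted(set(data.labels)) if hasattr(data, "labels") else sorted(set(test_labels))
    label_map = {c: i for i, c in enumerate(classes)}
    K = model.head.bias.shape[0]
    counts = np.zeros((K, K), dtype=int)
    feats = extract_features(model, [np.asarray(im, dtype=float) for im in test_imgs])
    logits = feats @ model.head.weights + model.head.bias
    preds = np.argmax(logits, axis=1)  # first max wins -> lowest class index
    for lab, pred in zip(test_labels, preds):
        counts[label_map[lab], pred] += 1
    total = counts.sum()
    return ConfusionMatrix(
        counts=counts,
        totals=counts.sum(axis=1),
        accuracy=100.0 * np.trace(counts) / total,
    )


def variant_comparison_report(
    make_dataset,
    variants: tuple[str, ...] = ("direct", "ae", "risa"),
    filter_sizes: tuple[int, ...] = (3, 4, 5),
    input_sizes: tuple[int, ...] = (32, 64),
    pretrained_factory=None,
    cfg: TrainConfig | None = None,
) -> list[dict]:
    """Accuracy grid over variants x filter sizes x input sizes.

    ``make_dataset(input_size)`` supplies a LabeledDataset per input size;
    ``pretrained_factory(kind, input_size, filter_size, dataset)`` supplies
    the frozen extractor for the ae/risa variants.  Returns one record per
    combination with the percent test accuracy.
    """
    cfg = cfg or TrainConfig()
    rows = []
    for size in input_sizes:
        ds = make_dataset(size)
        for fsz in filter_sizes:
            for kind in variants:
                pre = None
                if kind in ("ae", "risa"):
                    if pretrained_factory is None:
                        continue
                    pre = pretrained_factory(kind, size, fsz, ds)
                hc = HeadConfig(input_size=size, filter_size=fsz, seed=cfg.seed,
                                n_classes=len(set(ds.labels)))
                model = build_variant(kind, pretrained=pre, head_cfg=hc)
                model, _ = train_classifier(model, ds, cfg)
                cm = evaluate_confusion(model, ds)
                rows.append(
                    {"variant": kind, "input_size": size, "filter_size": fsz,
                     "accuracy": cm.accuracy}
                )
    return rows
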