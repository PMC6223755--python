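"""Single-stage convolutional autoencoders with an information-entropy
sparsity penalty, and greedy stacked pre-training.

Model
-----
One stage encodes an (H, W, C) input by a same-padded convolution, sigmoid
nonlinearity and 2x2 max pooling, giving an (H/2, W/2, F) feature map of
activations in (0, 1).  Decoding unpools each value into a 2x2 block (plain
copying, no pooling switches), applies a same-padded deconvolution with
filters of the same size, and a sigmoid.

The training objective is

    L = R + lambda_s * S

where R is the summed squared reconstruction error over all input nodes and
S is the information entropy of the encoding activations: at every spatial
position of the encoding map the F filter intensities are normalized to
r_j (relative to their total summation) and -sum_j r_j ln r_j is
accumulated, in nats, with 0 ln 0 := 0.  Minimizing S pushes each position
to respond through few filters, a sparsity pressure on the code.

Stacked stages are trained greedily: stage 1 on raw images, then frozen;
stage k trains on the frozen encodings of stage k-1.  Optimization is Adam
throughout; gradients are exact analytic backpropagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import (
    Adam,
    DataError,
    ShapeError,
    conv2d_same,
    conv2d_same_backward,
    maxpool2,
    maxpool2_backward,
    sigmoid,
    uniform_fanin_init,
    unpool2,
    unpool2_backward,
)

__all__ = [
    "FeatureMap",
    "ConvAEStage",
    "StageConfig",
    "LossBreakdown",
    "TrainConfig",
    "init_stage",
    "encode_stage",
    "decode_stage",
    "reconstruction_loss",
    "sparsity_entropy",
    "total_loss",
    "train_stage",
    "train_stack",
    "stack_encode",
]

_EPS = 1e-12


@dataclass(frozen=True)
class FeatureMap:
    """Grid of nonnegative encoding activations, shape (H', W', F)."""

    values: np.ndarray

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ShapeError("FeatureMap values must be (H', W', F)")
        if self.values.min() < 0:
            raise ValueError("FeatureMap activations must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)


@dataclass
class ConvAEStage:
    """One autoencoder stage: learned filters plus structural config."""

    filter_size: int
    n_filters: int
    in_channels: int
    encode_filters: np.ndarray  # (f, f, C_in, F)
    encode_bias: np.ndarray  # (F,)
    decode_filters: np.ndarray  # (f, f, F, C_in)
    decode_bias: np.ndarray  # (C_in,)
    pool: int = 2  # fixed 2x2 max pooling


@dataclass(frozen=True)
class StageConfig:
    filter_size: int
    n_filters: int


@dataclass(frozen=True)
class LossBreakdown:
    """The optimization function L = R + lambda_s * S and its parts."""

    R: float
    S: float
    lambda_s: float
    L: float
    N: int  # input node count
    M: int  # encoding node count

    def __post_init__(self):
        if abs(self.L - (self.R + self.lambda_s * self.S)) > 1e-9:
            raise ValueError("L must equal R + lambda_s * S")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 16
    steps: int = 200
    lambda_s: float = 1e-3
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.lambda_s < 0:
            raise ValueError("lambda_s must be >= 0")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")


def init_stage(filter_size: int, n_filters: int, in_channels: int, seed: int) -> ConvAEStage:
    """Seeded fan-in-scaled uniform initialization of one stage."""
    rng = np.random.default_rng(seed)
    f = filter_size
    fan_enc = f * f * in_channels
    fan_dec = f * f * n_filters
    return ConvAEStage(
        filter_size=f,
        n_filters=n_filters,
        in_channels=in_channels,
        encode_filters=uniform_fanin_init(rng, (f, f, in_channels, n_filters), fan_enc),
        encode_bias=np.zeros(n_filters),
        decode_filters=uniform_fanin_init(rng, (f, f, n_filters, in_channels), fan_dec),
        decode_bias=np.zeros(in_channels),
    )


def _as_array(x) -> np.ndarray:
    return x.values if isinstance(x, FeatureMap) else np.asarray(x, dtype=float)


def encode_stage(x, stage: ConvAEStage) -> FeatureMap:
    """conv -> sigmoid -> 2x2 max pool.  Output spatial dims are halved."""
    xa = _as_array(x)
    H, W = xa.shape[:2]
    if H % 2 or W % 2:
        raise ShapeError(f"input spatial dims must be even, got {H}x{W}")
    a = sigmoid(conv2d_same(xa[None], stage.encode_filters, stage.encode_bias))
    return FeatureMap(maxpool2(a)[0])


def decode_stage(z, stage: ConvAEStage) -> np.ndarray:
    """2x2 copy-unpool -> deconv (same filter size) -> sigmoid."""
    za = _as_array(z)
    u = unpool2(za[None])
    y = sigmoid(conv2d_same(u, stage.decode_filters, stage.decode_bias))
    return y[0]


def reconstruction_loss(x_in: np.ndarray, x_out: np.ndarray) -> float:
    """R: sum over all nodes of squared input/output differences."""
    x_in, x_out = np.asarray(x_in, dtype=float), np.asarray(x_out, dtype=float)
    if x_in.shape != x_out.shape:
        raise ShapeError(f"shape mismatch {x_in.shape} vs {x_out.shape}")
    d = x_out - x_in
    return float(np.sum(d * d))


def sparsity_entropy(z) -> float:
    """S: per-position entropy of normalized filter intensities, in nats.

    Positions whose total activation is zero contribute zero.
    """
    za = _as_array(z)
    if za.min() < 0:
        raise ValueError("activations must be nonnegative")
    tot = za.sum(axis=-1, keepdims=True)
    r = np.divide(za, tot, out=np.zeros_like(za), where=tot > 0)
    term = np.where(r > 0, -r * np.log(np.maximum(r, _EPS)), 0.0)
    return float(term.sum())


def total_loss(x_in, x_out, z, lambda_s: float) -> LossBreakdown:
    if lambda_s < 0:
        raise ValueError("lambda_s must be >= 0")
    R = reconstruction_loss(x_in, x_out)
    S = sparsity_entropy(z)
    za = _as_array(z)
    return LossBreakdown(
        R=R, S=S, lambda_s=lambda_s, L=R + lambda_s * S,
        N=int(np.asarray(x_in).size), M=int(za.size),
    )


# ---------------------------------------------------------------------------
# Training (analytic backprop through the full stage)
# ---------------------------------------------------------------------------


def _entropy_batch_and_grad(z: np.ndarray) -> tuple[float, np.ndarray]:
    """Entropy summed over batch x positions, and dS/dz.

    For a position with total T > 0 and r_j = z_j / T:
        dS/dz_j = (-ln r_j - S_pos) / T.
    """
    tot = z.sum(axis=-1, keepdims=True)
    safe = np.maximum(tot, _EPS)
    r = z / safe
    logr = np.log(np.maximum(r, _EPS))
    s_pos = -(r * logr).sum(axis=-1, keepdims=True)
    S = float(np.where(tot[..., 0] > 0, s_pos[..., 0], 0.0).sum())
    dz = np.where(tot > 0, (-logr - s_pos) / safe, 0.0)
    return S, dz


def _stage_forward(xb: np.ndarray, st: ConvAEStage):
    e = conv2d_same(xb, st.encode_filters, st.encode_bias)
    a = sigmoid(e)
    z = maxpool2(a)
    u = unpool2(z)
    d = conv2d_same(u, st.decode_filters, st.decode_bias)
    y = sigmoid(d)
    return a, z, u, y


def _stage_loss_and_grads(xb: np.ndarray, st: ConvAEStage, lambda_s: float):
    """Total L, (R, S), and gradients w.r.t. all four parameter arrays."""
    a, z, u, y = _stage_forward(xb, st)
    diff = y - xb
    R = float(np.sum(diff * diff))
    S, dS_dz = _entropy_batch_and_grad(z)
    L = R + lambda_s * S

    dy = 2.0 * diff
    dd = dy * y * (1.0 - y)
    dWd, dbd, du = conv2d_same_backward(u, st.decode_filters, dd)
    dz = unpool2_backward(du) + lambda_s * dS_dz
    da = maxpool2_backward(a, z, dz)
    de = da * a * (1.0 - a)
    dWe, dbe, _ = conv2d_same_backward(xb, st.encode_filters, de)
    grads = {
        "encode_filters": dWe,
        "encode_bias": dbe,
        "decode_filters": dWd,
        "decode_bias": dbd,
    }
    return L, R, S, grads


def _stack_images(data) -> list[np.ndarray]:
    if hasattr(data, "train"):
        imgs = data.train[0]
    else:
        imgs = list(data)
    if len(imgs) == 0:
        raise DataError("no training images supplied")
    return [_as_array(im) for im in imgs]


def train_stage(data, stage_cfg: StageConfig, cfg: TrainConfig):
    """Minimize L = R + lambda_s S over one stage by Adam.

    Returns the trained stage and a per-step history of (L, R, S), each
    expressed as a mean per image of the minibatch.
    """
    imgs = _stack_images(data)
    H, W, C = imgs[0].shape
    if H % 2 or W % 2:
        raise ShapeError("image spatial dims must be divisible by 2")
    stack = np.stack(imgs)
    rng = np.random.default_rng(cfg.seed)
    st = init_stage(stage_cfg.filter_size, stage_cfg.n_filters, C, seed=int(rng.integers(2**31)))
    params = {
        "encode_filters": st.encode_filters,
        "encode_bias": st.encode_bias,
        "decode_filters": st.decode_filters,
        "decode_bias": st.decode_bias,
    }
    opt = Adam(params, lr=cfg.learning_rate)
    history = []
    n = len(imgs)
    bs = min(cfg.batch_size, n)
    for _ in range(cfg.steps):
        idx = rng.choice(n, size=bs, replace=False)
        xb = stack[idx]
        L, R, S, grads = _stage_loss_and_grads(xb, st, cfg.lambda_s)
        opt.step(grads)
        history.append((L / bs, R / bs, S / bs))
    return st, history


def train_stack(data, stage_cfgs: list[StageConfig], cfg: TrainConfig) -> list[ConvAEStage]:
    """Greedy layer-wise pre-training; each stage is frozen once trained."""
    if len(stage_cfgs) < 1:
        raise ValueError("need at least one stage config")
    imgs = _stack_images(data)
    stages: list[ConvAEStage] = []
    current = imgs
    for k, scfg in enumerate(stage_cfgs):
        H, W = current[0].shape[:2]
        if H % 2 or W % 2:
            raise ShapeError(
                f"stage {k + 1} input {H}x{W} not divisible by 2; "
                "image dims must be divisible by 2^n_stages"
            )
        sub = TrainConfig(
            learning_rate=cfg.learning_rate, batch_size=cfg.batch_size, steps=cfg.steps,
            lambda_s=cfg.lambda_s, seed=cfg.seed + k, optimizer=cfg.optimizer,
        )
        st, _ = train_stage(current, scfg, sub)
        stages.append(st)
        current = [encode_stage(x, st).values for x in current]
    return stages


def stack_encode(x, stages: list[ConvAEStage]) -> FeatureMap:
    """Sequential application of encode_stage; identity for an empty stack."""
    cur = _as_array(x)
    for st in stages:
        cur = encode_stage(cur, st).values
    return FeatureMap(cur)


# ---------------------------------------------------------------------------
# Reference experiments
# ---------------------------------------------------------------------------


def sparsity_effect_experiment(seed: int, n_images: int = 50, image_size: int = 32,
                               steps: int = 200, lambda_large: float = 1e-2) -> dict:
    """Paired seeded runs with and without the entropy penalty.

    Trains the same single-stage architecture from the same seed on the
    same synthetic images, once with lambda_s = 0 and once with a penalty
    ten times the package default, and reports the mean per-image encoding
    entropy S of each trained stage.  The penalized run should end sparser
    (smaller S).
    """
    from .reduction_network import default_class_specs
    from .synthetic_data import generate_dataset

    seed = int(seed) % (2**31)
    n_per_class = max(5, int(np.ceil(n_images / (3 * 0.8))))  # 80% land in train
    data = generate_dataset(default_class_specs(), n_per_class, image_size, seed=seed)
    imgs = data.train[0][:n_images]
    out = {}
    for name, lam in (("unpenalized", 0.0), ("penalized", lambda_large)):
        st, _ = train_stage(imgs, StageConfig(5, 16),
                            TrainConfig(learning_rate=3e-3, batch_size=16, steps=steps,
                                        lambda_s=lam, seed=seed + 11))
        out[name] = float(np.mean([sparsity_entropy(encode_stage(x, st)) for x in imgs]))
    out["n_images"] = len(imgs)
    return out


def reconstruction_training_experiment(seed: int, image_size: int = 32, steps: int = 300) -> dict:
    """Held-out reconstruction error of a trained stage vs its initialization.

    Returns mean per-image R on the test split at initialization and after
    training, plus their ratio (trained / initial).
    """
    from .reduction_network import default_class_specs
    from .synthetic_data import generate_dataset

    seed = int(seed) % (2**31)
    data = generate_dataset(default_class_specs(), 20, image_size, seed=seed)
    train_imgs, test_imgs = data.train[0], data.test[0]
    cfg = TrainConfig(learning_rate=3e-3, batch_size=16, steps=steps,
                      lambda_s=1e-3, seed=seed + 11)
    trained, _ = train_stage(train_imgs, StageConfig(5, 16), cfg)
    # same init path train_stage takes before any update
    rng = np.random.default_rng(cfg.seed)
    initial = init_stage(5, 16, 3, seed=int(rng.integers(2**31)))

    def mean_r(stage):
        return float(np.mean([
            reconstruction_loss(x, decode_stage(encode_stage(x, stage), stage))
            for x in test_imgs
        ]))

    r0, r1 = mean_r(initial), mean_r(trained)
    return {"initial_R": r0, "trained_R": r1, "ratio": r1 / r0,
            "n_test_images": len(test_imgs)}
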