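"""Reconstruction independent subspace analysis (RISA).

A two-layer network over flattened patches x (n-dim): a learned linear
filter bank C (k x n) followed by a fixed binary group-pooling matrix H
(g x k).  The second-layer output is

    p_i(x; C, H) = sqrt( sum_m H_im ( sum_j C_mj x_j )^2 ),

the Euclidean norm of each group's filter responses, which is invariant to
sign flips and rotations inside a group — the source of the model's
(minimal translational) invariance.  Filters are learned by minimizing

    sum_t ( (1/N) || C^T C x^(t) - x^(t) ||^2  +  lambda sum_i p_i(x^(t)) )

over a dataset of N patches: a linear-autoencoder reconstruction term plus
a pooled-feature sparsity penalty.  H is fixed (consecutive, non-
overlapping groups; filters pair up for the default group size 2) and only
C is trained, by Adam with exact analytic gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Adam, ConfigError, DataError, ShapeError, uniform_fanin_init

__all__ = [
    "RISAModel",
    "make_pooling_matrix",
    "risa_forward",
    "risa_objective",
    "train_risa",
]

_EPS = 1e-12


@dataclass
class RISAModel:
    """Learned filter matrix C, fixed pooling matrix H, penalty weight."""

    C: np.ndarray  # (k, n)
    H: np.ndarray  # (g, k) binary
    lam: float
    group_size: int

    def __post_init__(self):
        H = self.H
        if not np.isin(H, (0, 1)).all():
            raise ValueError("H entries must be binary")
        if not (H.sum(axis=0) == 1).all():
            raise ValueError("each filter must belong to exactly one group")
        if not (H.sum(axis=1) == self.group_size).all():
            raise ValueError("each group must contain group_size filters")


def make_pooling_matrix(k: int, group_size: int) -> np.ndarray:
    """Binary (k/group_size, k) matrix of consecutive non-overlapping groups."""
    if group_size < 1 or k % group_size:
        raise ConfigError(f"k={k} not divisible by group_size={group_size}")
    g = k // group_size
    H = np.zeros((g, k))
    for i in range(g):
        H[i, i * group_size : (i + 1) * group_size] = 1.0
    return H


def risa_forward(x: np.ndarray, model: RISAModel) -> np.ndarray:
    """Second-layer output p, one nonnegative value per pooling group.

    Accepts a single flattened patch (n,) or a batch (B, n).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xb = x[None] if single else x
    if xb.shape[1] != model.C.shape[1]:
        raise ShapeError(f"patch dim {xb.shape[1]} != filter dim {model.C.shape[1]}")
    s = xb @ model.C.T  # (B, k) filter responses
    p = np.sqrt(s**2 @ model.H.T)  # (B, g)
    return p[0] if single else p


def risa_objective(batch, model: RISAModel) -> float:
    """Reconstruction + pooled-sparsity objective over a batch of patches."""
    X = _as_batch(batch, model)
    N = X.shape[0]
    Y = X @ model.C.T @ model.C - X
    recon = float(np.sum(Y * Y)) / N
    p = risa_forward(X, model)
    return recon + model.lam * float(p.sum())


def _as_batch(batch, model: RISAModel) -> np.ndarray:
    arrs = [np.asarray(b, dtype=float).ravel() for b in batch]
    if len(arrs) == 0:
        raise DataError("empty patch batch")
    X = np.stack(arrs)
    if X.shape[1] != model.C.shape[1]:
        raise ShapeError(f"patch dim {X.shape[1]} != filter dim {model.C.shape[1]}")
    return X


def _objective_and_grad(X: np.ndarray, model: RISAModel) -> tuple[float, np.ndarray]:
    C, H, lam = model.C, model.H, model.lam
    N = X.shape[0]
    S = X @ C.T  # (B, k)
    Y = S @ C - X  # (B, n) residual of C^T C x - x
    recon = float(np.sum(Y * Y)) / N
    # d/dC of sum_t ||C^T C x - x||^2 = 2 C (X^T Y + Y^T X)
    dC = (2.0 / N) * C @ (X.T @ Y + Y.T @ X)
    P = np.sqrt(S**2 @ H.T)  # (B, g)
    obj = recon + lam * float(P.sum())
    # d sum p / d s_m = s_m / p_{group(m)}
    Pf = np.maximum(P, _EPS) @ H  # (B, k): each filter's group norm
    dS = S / Pf
    dC += lam * dS.T @ X
    return obj, dC


def train_risa(data, k: int, group_size: int, lam: float, cfg) -> tuple[RISAModel, list[float]]:
    """Adam minimization of the RISA objective over C with H fixed.

    ``data`` is a sequence of fixed-size patches (flattened internally);
    ``cfg`` is a conv_autoencoder.TrainConfig.  Returns the trained model
    and the per-step objective history.
    """
    patches = [np.asarray(p, dtype=float).ravel() for p in data]
    if len(patches) == 0:
        raise DataError("no training patches supplied")
    n = patches[0].size
    X = np.stack(patches)
    rng = np.random.default_rng(cfg.seed)
    C = uniform_fanin_init(rng, (k, n), n)
    model = RISAModel(C=C, H=make_pooling_matrix(k, group_size), lam=lam, group_size=group_size)
    opt = Adam({"C": model.C}, lr=cfg.learning_rate)
    history = []
    bs = min(cfg.batch_size, len(patches))
    for _ in range(cfg.steps):
        idx = rng.choice(len(patches), size=bs, replace=False)
        obj, dC = _objective_and_grad(X[idx], model)
        opt.step({"C": dC})
        history.append(obj)
    return model, history
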