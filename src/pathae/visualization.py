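"""Feature visualization: activation-ranked patch averaging and per-filter
response maps.

To see what an encoding node has learned, sample many small patches from
the input imagery, encode each through the frozen stack, rank the patches
by the activation of one chosen node, and average the pixel intensities of
the top k patches.  Because a convolutional node is position-locked, the
top patches agree in motif placement and phase, so the average exposes the
motif (stripe- or target-like local structure) instead of blurring it out.

Response maps render every filter's activation over one image as a
red-to-blue heat map (red low, blue high) next to an input/reconstruction
panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._nn import ShapeError
from .conv_autoencoder import ConvAEStage, decode_stage, encode_stage, stack_encode

__all__ = [
    "PatchRanking",
    "sample_patches",
    "rank_patches",
    "top_k_feature_image",
    "response_maps",
    "save_image_png",
]


@dataclass(frozen=True)
class PatchRanking:
    """Patches with per-patch scores and a descending score order."""

    patches: list[np.ndarray]
    scores: np.ndarray
    order: np.ndarray  # indices, scores descending, ties by lower index

    def __post_init__(self):
        if len(self.patches) != len(self.scores):
            raise ValueError("one score per patch required")


def sample_patches(images, n: int, p: int, seed: int) -> list[np.ndarray]:
    """n random p x p patches with uniform positions over seeded streams."""
    images = [np.asarray(im, dtype=float) for im in images]
    for im in images:
        if im.shape[0] < p or im.shape[1] < p:
            raise ShapeError(f"image {im.shape[:2]} smaller than patch size {p}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        im = images[int(rng.integers(len(images)))]
        r = int(rng.integers(0, im.shape[0] - p + 1))
        c = int(rng.integers(0, im.shape[1] - p + 1))
        out.append(im[r : r + p, c : c + p])
    return out


def _node_score(values: np.ndarray, node) -> float:
    if isinstance(node, (int, np.integer)):
        # convenience mode: one filter, max-pooled over spatial positions
        if not 0 <= node < values.shape[2]:
            raise IndexError(f"filter index {node} out of range")
        return float(values[:, :, node].max())
    r, c, f = node
    if not (0 <= r < values.shape[0] and 0 <= c < values.shape[1] and 0 <= f < values.shape[2]):
        raise IndexError(f"node {node} out of range for encoding shape {values.shape}")
    return float(values[r, c, f])


def rank_patches(patches, stages: list[ConvAEStage], node) -> PatchRanking:
    """Rank patches by one encoding node's activation (descending).

    ``node`` is either a (row, col, filter) coordinate of the final-stage
    encoding, or a bare filter index scored as the max over positions.
    """
    scores = np.array([_node_score(stack_encode(p, stages).values, node) for p in patches])
    order = np.argsort(-scores, kind="stable")
    return PatchRanking(patches=list(patches), scores=scores, order=order)


def top_k_feature_image(patches, stages: list[ConvAEStage], node, k: int) -> np.ndarray:
    """Pixelwise mean of the k patches most activating the chosen node."""
    if k < 1 or k > len(patches):
        raise ValueError(f"k={k} outside 1..{len(patches)}")
    ranking = rank_patches(patches, stages, node)
    top = [ranking.patches[i] for i in ranking.order[:k]]
    return np.mean(top, axis=0)


def motif_recovery_experiment(
    seed: int,
    n_images: int = 12,
    image_size: int = 64,
    n_patches: int = 5000,
    patch_size: int = 16,
    k: int = 100,
    train_steps: int = 300,
) -> dict:
    """Recover a planted dominant motif by top-k patch averaging.

    Renders images where one stripe motif dominates the mixture, trains a
    single autoencoder stage unsupervised, encodes random patches once, and
    for every encoding node (position x filter) averages the k patches
    with the highest activation.  Each average is compared to the planted
    motif by Pearson correlation of its darkness (1 - mean intensity)
    against the motif's ink density, cropping the averaged patch at the
    node's receptive-field center (+-1 px alignment).  Returns the best
    correlation over nodes — the analogue of browsing encoding nodes for
    the one that represents a local structure.
    """
    from .synthetic_data import ClassSpec, make_motif_bank, render_class_image

    seed = int(seed) % (2**31)
    bank = make_motif_bank(8, 4, seed=seed)  # motif 0 is stripe-type
    spec = ClassSpec(class_id=0, placement="uniform", density=0.01,
                     motif_mix=(0.85, 0.05, 0.05, 0.05))
    imgs = [render_class_image(spec, bank, image_size, seed=seed * 100 + i)
            for i in range(n_images)]
    from .conv_autoencoder import StageConfig, TrainConfig, train_stack

    train_patches = sample_patches(imgs, 200, 32, seed=seed + 3)
    stages = train_stack(train_patches, [StageConfig(7, 12)],
                         TrainConfig(learning_rate=3e-3, batch_size=16,
                                     steps=train_steps, lambda_s=1e-3, seed=seed))
    patches = sample_patches(imgs, n_patches, patch_size, seed=seed + 5)
    codes = np.stack([stack_encode(p, stages).values for p in patches])
    motif = bank.motifs[0].mean(axis=2)
    m = motif.shape[0]
    best, best_node = -1.0, None
    H, W, F = codes.shape[1:]
    for f in range(F):
        for r in range(H):
            for c in range(W):
                # receptive-field center of pooled node (r, c) is ~(2r, 2c)
                rr0, cc0 = 2 * r - m // 2, 2 * c - m // 2
                if rr0 < 1 or cc0 < 1 or rr0 + m + 1 > patch_size or cc0 + m + 1 > patch_size:
                    continue
                top = np.argsort(-codes[:, r, c, f], kind="stable")[:k]
                avg = np.mean([patches[i] for i in top], axis=0)
                dark = 1.0 - avg.mean(axis=2)
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        crop = dark[rr0 + dr : rr0 + dr + m, cc0 + dc : cc0 + dc + m]
                        rho = float(np.corrcoef(crop.ravel(), motif.ravel())[0, 1])
                        if rho > best:
                            best, best_node = rho, (r, c, f)
    return {"correlation": best, "node": best_node, "motif": motif,
            "stages": stages, "patches_used": n_patches, "k": k}


def _heatmap_rgb(values: np.ndarray) -> np.ndarray:
    """Map scalar field to an RdBu image: red = low, blue = high signal."""
    from matplotlib import cm

    lo, hi = float(values.min()), float(values.max())
    norm = (values - lo) / (hi - lo) if hi > lo else np.full_like(values, 0.5)
    return np.asarray(cm.RdBu(norm))[..., :3]


def save_image_png(img: np.ndarray, path) -> None:
    from PIL import Image

    arr = (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)
    Image.fromarray(arr).save(str(path))


def response_maps(img: np.ndarray, stage: ConvAEStage, out_dir=None) -> dict:
    """Per-filter activation maps plus an input/output reconstruction panel.

    Returns {"maps": (H/2, W/2, F) activations, "input": img,
    "output": reconstruction}; if ``out_dir`` is given, writes one heat-map
    PNG per filter and the side-by-side reconstruction panel.
    """
    img = np.asarray(img, dtype=float)
    z = encode_stage(img, stage)
    recon = decode_stage(z, stage)
    result = {"maps": z.values, "input": img, "output": recon}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for f in range(z.values.shape[2]):
            save_image_png(_heatmap_rgb(z.values[:, :, f]), out / f"filter_{f:02d}.png")
        panel = np.concatenate([img, np.clip(recon, 0, 1)], axis=1)
        save_image_png(panel, out / "reconstruction.png")
    return result
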