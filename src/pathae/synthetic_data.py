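"""Synthetic labeled texture images for context-size experiments.

Classes are built from a shared bank of small local motifs (cell-blob,
stripe and ring/target stamps, echoing the local structures of cell
boundaries seen in stained tissue) placed on an eosin-like pink background.
Two classes can share the identical motif mixture and differ only in the
*spatial point process* used to place the motifs (uniform, clustered or
graded), so that small patches are statistically indistinguishable between
classes while whole images are separable.  This makes the claim "context
size matters" testable without any external imagery.

Placement processes:

- ``uniform``: homogeneous Poisson with intensity ``density`` per px^2.
- ``clustered``: Neyman-Scott parent/offspring process; parents are Poisson
  with intensity ``density / children``, each parent spawns
  Poisson(``children``) offspring at isotropic Gaussian offsets with
  standard deviation ``cluster_radius``.  Expected total count matches the
  uniform process at equal ``density``.
- ``graded``: inhomogeneous Poisson whose intensity ramps linearly from 0
  to twice the mean along ``direction`` (radians), sampled by thinning.

Motifs composite onto the canvas by per-pixel maximum of their "ink"
(stain absorption) and darken the background multiplicatively, so overlap
order never matters and pixels never wrap outside [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ._nn import DataError, ShapeError

__all__ = [
    "MotifBank",
    "ClassSpec",
    "LabeledDataset",
    "make_motif_bank",
    "render_class_image",
    "generate_dataset",
    "tiny_fixture",
    "placement_dispersion",
]

#: Eosin-like base color of the background (RGB in [0,1]).
BACKGROUND_RGB = (0.91, 0.76, 0.84)
#: Peak amplitude of the smoothed background noise.
BACKGROUND_NOISE_AMPLITUDE = 0.05
#: Fraction of background intensity absorbed where motif ink is at maximum.
INK_STRENGTH = 0.85


@dataclass(frozen=True)
class MotifBank:
    """A fixed bank of small motif stamps shared across classes."""

    motifs: list[np.ndarray]  # each (m, m, 3) ink density in [0,1]
    m: int
    seed: int

    def __post_init__(self):
        for s in self.motifs:
            if s.min() < 0 or s.max() > 1:
                raise ValueError("motif stamp values must lie in [0, 1]")


@dataclass(frozen=True)
class ClassSpec:
    """How one class places motifs: point process + motif mixture."""

    class_id: int
    placement: str  # "uniform" | "clustered" | "graded"
    density: float  # expected motifs per px^2
    motif_mix: tuple[float, ...]
    cluster_radius: float = 12.0
    children: float = 6.0
    direction: float = 0.0  # radians, for "graded"
    color_jitter: float = 0.08

    def __post_init__(self):
        if self.placement not in ("uniform", "clustered", "graded"):
            raise ValueError(f"unknown placement kind {self.placement!r}")
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if abs(sum(self.motif_mix) - 1.0) > 1e-9:
            raise ValueError("motif_mix must sum to 1 within 1e-9")


@dataclass
class LabeledDataset:
    """Balanced labeled images with a stratified 80/20 train/test split."""

    images: list[np.ndarray]
    labels: list[int]
    split: dict[str, list[int]]  # {"train": [...], "test": [...]}
    seed: int

    def __post_init__(self):
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")
        if set(self.split["train"]) & set(self.split["test"]):
            raise ValueError("train and test indices overlap")

    @property
    def train(self) -> tuple[list[np.ndarray], list[int]]:
        idx = self.split["train"]
        return [self.images[i] for i in idx], [self.labels[i] for i in idx]

    @property
    def test(self) -> tuple[list[np.ndarray], list[int]]:
        idx = self.split["test"]
        return [self.images[i] for i in idx], [self.labels[i] for i in idx]


def _subseed(*parts: int) -> int:
    """Stable sub-stream seed below 2^31 derived from integer parts."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Motif stamps
# ---------------------------------------------------------------------------


def _grid(m: int) -> tuple[np.ndarray, np.ndarray]:
    c = (m - 1) / 2.0
    yy, xx = np.mgrid[0:m, 0:m]
    return yy - c, xx - c


def _window(m: int) -> np.ndarray:
    yy, xx = _grid(m)
    r2 = (yy**2 + xx**2) / (0.55 * m / 2) ** 2 / 2
    return np.exp(-r2)


def _stamp_blob(m: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = _grid(m)
    sig = m / rng.uniform(3.5, 5.0)
    disc = np.exp(-(yy**2 + xx**2) / (2 * sig**2))
    return disc


def _stamp_stripe(m: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = _grid(m)
    theta = rng.uniform(0, np.pi)
    period = m / rng.uniform(1.5, 2.5)
    phase = rng.uniform(0, 2 * np.pi)
    wave = 0.5 * (1 + np.sin(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / period + phase))
    return wave * _window(m)


def _stamp_ring(m: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = _grid(m)
    r = np.sqrt(yy**2 + xx**2)
    period = m / rng.uniform(1.8, 2.6)
    wave = 0.5 * (1 + np.cos(2 * np.pi * r / period))
    return wave * _window(m)


# hematoxylin-leaning absorption: green absorbed most so motifs read purple
_CHANNEL_ABSORB = np.array([0.55, 0.95, 0.45])


def make_motif_bank(m: int, n_motifs: int, seed: int) -> MotifBank:
    """Build ``n_motifs`` stamps of edge length ``m``.

    Kinds cycle stripe, ring, blob so any bank with >= 2 motifs contains at
    least one stripe-type and one ring/target-type stamp.
    """
    if m < 4:
        raise ShapeError(f"motif edge length must be >= 4 px, got {m}")
    if n_motifs < 2:
        raise ValueError("need at least 2 motifs")
    rng = np.random.default_rng(seed)
    kinds = [_stamp_stripe, _stamp_ring, _stamp_blob]
    motifs = []
    for i in range(n_motifs):
        mono = kinds[i % 3](m, rng)
        absorb = _CHANNEL_ABSORB * rng.uniform(0.85, 1.0, size=3)
        stamp = np.clip(mono[:, :, None] * absorb[None, None, :], 0.0, 1.0)
        motifs.append(stamp)
    return MotifBank(motifs=motifs, m=m, seed=seed)


# ---------------------------------------------------------------------------
# Point processes (positions are top-left corners in [0, size - m))
# ---------------------------------------------------------------------------


def _positions(spec: ClassSpec, size: int, m: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = 0, size - m
    area = float(size * size)
    if spec.placement == "uniform":
        n = rng.poisson(spec.density * area)
        return rng.uniform(lo, hi, size=(n, 2))
    if spec.placement == "clustered":
        n_par = rng.poisson(spec.density * area / spec.children)
        parents = rng.uniform(lo, hi, size=(n_par, 2))
        pts = []
        for p in parents:
            k = rng.poisson(spec.children)
            off = rng.normal(0.0, spec.cluster_radius, size=(k, 2))
            pts.append(np.clip(p + off, lo, hi))
        return np.vstack(pts) if pts else np.empty((0, 2))
    # graded: thinning with linear ramp along `direction`
    n_cand = rng.poisson(2 * spec.density * area)
    cand = rng.uniform(lo, hi, size=(n_cand, 2))
    d = np.array([np.sin(spec.direction), np.cos(spec.direction)])  # (row, col)
    proj = cand @ d
    lo_p, hi_p = proj.min(initial=0.0), max(proj.max(initial=1.0), 1.0)
    t = (proj - lo_p) / (hi_p - lo_p + 1e-12)
    keep = rng.uniform(size=n_cand) < t
    return cand[keep]


def render_class_image(spec: ClassSpec, bank: MotifBank, size: int, seed: int) -> np.ndarray:
    """Render one (size, size, 3) image in [0,1] for the given class spec."""
    if size < 2 * bank.m:
        raise ShapeError(f"image size {size} must be >= 2x motif size {bank.m}")
    rng = np.random.default_rng(seed)
    base = np.array(BACKGROUND_RGB)
    noise = rng.normal(0.0, 1.0, size=(size, size, 3))
    noise = gaussian_filter(noise, sigma=(3, 3, 0))
    peak = np.abs(noise).max()
    if peak > 0:
        noise *= BACKGROUND_NOISE_AMPLITUDE / peak
    bg = np.clip(base[None, None, :] + noise, 0.0, 1.0)

    mix = np.asarray(spec.motif_mix)
    pos = _positions(spec, size, bank.m, rng)
    ink = np.zeros((size, size, 3))
    m = bank.m
    for r, c in pos:
        r, c = int(r), int(c)
        idx = rng.choice(len(bank.motifs), p=mix)
        jit = 1.0 + spec.color_jitter * rng.uniform(-1, 1, size=3)
        stamp = np.clip(bank.motifs[idx] * jit[None, None, :], 0.0, 1.0)
        region = ink[r : r + m, c : c + m]
        np.maximum(region, stamp, out=region)
    img = bg * (1.0 - INK_STRENGTH * ink)
    return np.clip(img, 0.0, 1.0)


def placement_dispersion(spec: ClassSpec, bank: MotifBank, size: int, seed: int,
                         cell: int = 32) -> float:
    """Index of dispersion (variance/mean) of motif counts in a cell grid.

    A summary of spatial clumping: ~1 for uniform Poisson placement, >1 for
    clustered, >1 for graded (intensity varies across the image).
    """
    rng = np.random.default_rng(seed)
    pos = _positions(spec, size, bank.m, rng)
    g = size // cell
    counts = np.zeros((g, g))
    for r, c in pos:
        counts[min(int(r) // cell, g - 1), min(int(c) // cell, g - 1)] += 1
    mu = counts.mean()
    return float(counts.var() / mu) if mu > 0 else 0.0


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def generate_dataset(
    specs: list[ClassSpec], n_per_class: int, size: int, seed: int
) -> LabeledDataset:
    """Balanced dataset with a deterministic stratified 80/20 split."""
    if len(specs) < 2:
        raise DataError("need at least 2 class specs")
    if n_per_class < 5:
        raise DataError("n_per_class must be >= 5 to allow an 80/20 split")
    bank = make_motif_bank(m=8, n_motifs=len(specs[0].motif_mix), seed=_subseed(seed, 0xB4DC))
    images: list[np.ndarray] = []
    labels: list[int] = []
    train_idx: list[int] = []
    test_idx: list[int] = []
    n_test = max(1, round(0.2 * n_per_class))
    split_rng = np.random.default_rng(_subseed(seed, 0x5EED))
    for spec in specs:
        start = len(images)
        for i in range(n_per_class):
            img = render_class_image(spec, bank, size, seed=_subseed(seed, spec.class_id, i))
            images.append(img)
            labels.append(spec.class_id)
        order = split_rng.permutation(n_per_class) + start
        test_idx.extend(int(j) for j in order[:n_test])
        train_idx.extend(int(j) for j in order[n_test:])
    return LabeledDataset(
        images=images, labels=labels,
        split={"train": sorted(train_idx), "test": sorted(test_idx)}, seed=seed,
    )


def tiny_fixture() -> tuple[np.ndarray, np.ndarray]:
    """Fixed 8x8x3 input/target pair for exact-value loss tests.

    Entries are the simple modular sequences (37*i mod 101)/100 and
    (53*i mod 89)/88 over the flattened index i, so every value can be
    enumerated by hand from this source.
    """
    i = np.arange(192)
    a = ((37 * i) % 101).reshape(8, 8, 3) / 100.0
    b = ((53 * i) % 89).reshape(8, 8, 3) / 88.0
    return a, b
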