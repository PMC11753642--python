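"""Synthetic data with known ground truth for every pipeline stage.

Two generators:

* ``gen_features`` — multiclass Gaussian feature matrices with a planted
  informative subset.  Class means sit at the vertices of a regular simplex
  (all pairwise mean distances equal to ``separation``, in units of the
  within-class standard deviation, which is 1), rotated by a seeded random
  orthonormal matrix so signal spreads across all informative columns, then
  hidden among independent N(0, 1) noise columns by a seeded permutation.
  The informative column indices are returned alongside the data.

* ``gen_images`` — toy "lesion-on-leaf" images: a uniform background, one
  class-specific lesion (shape + color signature) at a seeded random
  position, plus Gaussian pixel noise clipped to [0, 255].  Labels are
  correct by construction.

Everything is fully deterministic under the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .augmentation import LabeledImage

__all__ = [
    "SyntheticFeatureSpec",
    "SyntheticImageSpec",
    "gen_features",
    "gen_images",
]


@dataclass(frozen=True)
class SyntheticFeatureSpec:
    """Study conditions for the planted-subset feature generator.

    Defaults are the reference conditions used throughout the test suite:
    3 balanced classes of 60 samples, 5 informative among 50 total columns,
    class-mean separation of 2 within-class standard deviations.
    """

    n_per_class: int = 60
    k_classes: int = 3
    d_informative: int = 5
    d_noise: int = 45
    separation: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.k_classes < 2:
            raise ValueError("k_classes must be >= 2")
        if min(self.n_per_class, self.d_informative) < 1 or self.d_noise < 0:
            raise ValueError("counts must be positive (d_noise may be 0)")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.d_informative < self.k_classes - 1:
            raise ValueError(
                "d_informative must be >= k_classes - 1 to host a regular simplex"
            )


def _simplex_means(k: int, d: int, separation: float,
                   rng: np.random.Generator) -> np.ndarray:
    """k class-mean vectors in R^d, pairwise distance = separation, randomly
    rotated so every informative coordinate carries signal generically."""
    # regular simplex: centered identity has pairwise vertex distance sqrt(2)
    verts = np.eye(k) - 1.0 / k
    # coordinates in the (k-1)-dim subspace the vertices actually span
    _, _, vt = np.linalg.svd(verts, full_matrices=False)
    coords = verts @ vt[: k - 1].T  # (k, k-1)
    coords *= separation / np.sqrt(2.0)
    means = np.zeros((k, d))
    means[:, : k - 1] = coords
    # seeded random rotation (QR of a Gaussian matrix)
    q, r = np.linalg.qr(rng.normal(size=(d, d)))
    q *= np.sign(np.diag(r))
    return means @ q.T


def gen_features(spec: SyntheticFeatureSpec) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate (X, y, informative_indices).

    X is (k_classes * n_per_class) x (d_informative + d_noise); labels are
    integers 1..K; ``informative_indices`` are the column positions of the
    planted features after the seeded column permutation.
    """
    rng = np.random.default_rng(spec.seed)
    k, n, di, dn = spec.k_classes, spec.n_per_class, spec.d_informative, spec.d_noise
    means = _simplex_means(k, di, spec.separation, rng)
    y = np.repeat(np.arange(1, k + 1), n)
    X_inf = rng.normal(size=(k * n, di)) + means[y - 1]
    X_noise = rng.normal(size=(k * n, dn))
    X = np.hstack([X_inf, X_noise])
    perm = rng.permutation(di + dn)
    X = X[:, perm]
    informative = np.sort(np.argsort(perm)[:di])
    return X, y, informative


# ---------------------------------------------------------------------------
# Toy lesion images
# ---------------------------------------------------------------------------

_DEFAULT_SHAPES = ("disc", "ring", "streak", "disc")
_DEFAULT_COLORS = (
    (190, 60, 40),    # reddish-brown lesion
    (60, 160, 60),    # green mottle
    (70, 70, 190),    # bluish streak
    (210, 190, 60),   # yellow spot
)


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Study conditions for the lesion-image generator: 4 classes of 40
    images, 64 x 64 RGB, pixel noise sd 8, each class a distinct
    (shape, color) lesion signature on a leaf-green background."""

    k_classes: int = 4
    images_per_class: int = 40
    height: int = 64
    width: int = 64
    lesion_shape_per_class: Sequence[str] = _DEFAULT_SHAPES
    lesion_color_per_class: Sequence[Tuple[int, int, int]] = _DEFAULT_COLORS
    background_color: Tuple[int, int, int] = (90, 140, 80)
    lesion_radius: int = 10
    pixel_noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.k_classes < 2 or self.images_per_class < 1:
            raise ValueError("need >= 2 classes and >= 1 image per class")
        if len(self.lesion_shape_per_class) < self.k_classes:
            raise ValueError("one lesion shape per class is required")
        if len(self.lesion_color_per_class) < self.k_classes:
            raise ValueError("one lesion color per class is required")
        sigs = {
            (self.lesion_shape_per_class[c], tuple(self.lesion_color_per_class[c]))
            for c in range(self.k_classes)
        }
        if len(sigs) < self.k_classes:
            raise ValueError("every class needs a distinct (shape, color) signature")
        if 2 * self.lesion_radius + 1 > min(self.height, self.width):
            raise ValueError("lesion larger than canvas")


def _paint_lesion(canvas: np.ndarray, shape: str, color, cy: int, cx: int,
                  radius: int) -> None:
    h, w, _ = canvas.shape
    yy, xx = np.ogrid[:h, :w]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    if shape == "disc":
        mask = d2 <= radius**2
    elif shape == "ring":
        mask = (d2 <= radius**2) & (d2 >= (radius * 0.55) ** 2)
    elif shape == "streak":
        mask = (np.abs((yy - cy) - (xx - cx)) <= max(1, radius // 3)) & (
            d2 <= (2 * radius) ** 2
        )
    else:
        raise ValueError(f"unknown lesion shape {shape!r}")
    canvas[mask] = color


def gen_images(spec: SyntheticImageSpec) -> List[LabeledImage]:
    """Generate k_classes * images_per_class labeled lesion images, class
    by class in label order."""
    rng = np.random.default_rng(spec.seed)
    r = spec.lesion_radius
    images: List[LabeledImage] = []
    for c in range(spec.k_classes):
        shape = spec.lesion_shape_per_class[c]
        color = np.asarray(spec.lesion_color_per_class[c], dtype=float)
        for i in range(spec.images_per_class):
            canvas = np.tile(
                np.asarray(spec.background_color, dtype=float),
                (spec.height, spec.width, 1),
            )
            cy = int(rng.integers(r, spec.height - r))
            cx = int(rng.integers(r, spec.width - r))
            _paint_lesion(canvas, shape, color, cy, cx, r)
            if spec.pixel_noise_sd > 0:
                canvas = canvas + rng.normal(scale=spec.pixel_noise_sd,
                                             size=canvas.shape)
            px = np.clip(canvas, 0, 255).astype(np.uint8)
            images.append(
                LabeledImage(pixels=px, label=f"class{c + 1}",
                             origin=f"synthetic/class{c + 1}/{i:04d}")
            )
    return images
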