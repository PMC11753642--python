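"""Image-to-feature-vector extraction behind a pluggable contract.

Deep backbones (e.g. a fine-tuned DenseNet-201 penultimate pooling layer or
an AlexNet fc layer) participate only through an adapter: anything that maps
a list of images to a fixed-width feature table is a valid extractor.  The
built-in extractor is a deterministic block-statistics descriptor so the
whole pipeline is testable without any pretrained network: the image is cut
into a g x g grid and the per-block, per-channel mean and standard deviation
are emitted (dimension 2 * 3 * g^2 for RGB input).  Remainder rows/columns
on non-divisible image sizes are absorbed by the last block row/column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .augmentation import LabeledImage

logger = logging.getLogger(__name__)

__all__ = [
    "ExtractorSpec",
    "toy_extract",
    "extract_dataset",
    "BlockStatsExtractor",
    "CallableExtractor",
]


@dataclass(frozen=True)
class ExtractorSpec:
    """Named extractor contract: a pure function of (pixels, params) with a
    fixed output dimension."""

    name: str
    output_dim: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.output_dim < 1:
            raise ValueError("output_dim must be positive")


def _block_edges(size: int, g: int) -> np.ndarray:
    """g+1 block boundaries; the last block absorbs the remainder."""
    step = size // g
    if step < 1:
        raise ValueError(f"image side {size} smaller than grid {g}")
    edges = np.arange(g + 1) * step
    edges[-1] = size
    return edges


def toy_extract(img: LabeledImage, grid: int = 4) -> np.ndarray:
    """Block mean/std descriptor of an RGB image: dimension 6 * grid**2.

    Values stay within [0, 255] for 8-bit input (means by averaging, stds
    bounded by half the range).  Grayscale input is rejected: the contract
    is three channels, matching the pipelines this stands in for.
    """
    px = np.asarray(img.pixels)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("channel error: toy_extract requires H x W x 3 input")
    px = px.astype(float)
    rows = _block_edges(px.shape[0], grid)
    cols = _block_edges(px.shape[1], grid)
    feats = np.empty(2 * 3 * grid * grid)
    i = 0
    for r in range(grid):
        for c in range(grid):
            block = px[rows[r]:rows[r + 1], cols[c]:cols[c + 1], :]
            feats[i:i + 3] = block.mean(axis=(0, 1))
            feats[i + 3:i + 6] = block.std(axis=(0, 1))
            i += 6
    return feats


def extract_dataset(
    images: Sequence[LabeledImage],
    spec: Optional[ExtractorSpec] = None,
    extract_fn: Optional[Callable[[LabeledImage], np.ndarray]] = None,
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Apply an extractor image-by-image; returns (X, labels, n_dropped).

    Row i is the extraction of image i (input order preserved); per-image
    failures are logged, the sample dropped, and the drop count reported.
    """
    if extract_fn is None:
        spec = spec or ExtractorSpec("block-stats-g4", 96, {"grid": 4})
        grid = int(spec.params.get("grid", 4))
        extract_fn = lambda im: toy_extract(im, grid=grid)
    rows, labels = [], []
    dropped = 0
    for img in images:
        try:
            rows.append(np.asarray(extract_fn(img), dtype=float))
        except Exception as exc:
            dropped += 1
            logger.warning("dropping image %r: %s", img.origin, exc)
            continue
        labels.append(img.label)
    if not rows:
        return np.empty((0, 0)), np.asarray(labels), dropped
    X = np.vstack(rows)
    return X, np.asarray(labels), dropped


class BlockStatsExtractor(TransformerMixin, BaseEstimator):
    """sklearn transformer over lists of :class:`LabeledImage`.

    ``transform`` returns the n x (6 * grid^2) feature matrix; labels are
    available via :meth:`labels_of`.  Stateless: ``fit`` is a no-op kept for
    pipeline compatibility.
    """

    def __init__(self, grid: int = 4):
        self.grid = grid

    def fit(self, X, y=None):
        self.n_features_out_ = 6 * self.grid * self.grid
        return self

    def transform(self, X: Sequence[LabeledImage]) -> np.ndarray:
        feats, _, dropped = extract_dataset(
            X, extract_fn=lambda im: toy_extract(im, grid=self.grid)
        )
        if dropped:
            raise ValueError(f"{dropped} image(s) failed extraction")
        return feats

    @staticmethod
    def labels_of(X: Sequence[LabeledImage]) -> np.ndarray:
        return np.asarray([im.label for im in X])

    def spec(self) -> ExtractorSpec:
        return ExtractorSpec(
            name=f"block-stats-g{self.grid}",
            output_dim=6 * self.grid * self.grid,
            params={"grid": self.grid},
        )


class CallableExtractor:
    """Adapter wrapping any image -> vector callable as an extractor, e.g. a
    subprocess bridge to an external deep backbone."""

    def __init__(self, fn: Callable[[LabeledImage], np.ndarray], spec: ExtractorSpec):
        self.fn = fn
        self._spec = spec

    def __call__(self, img: LabeledImage) -> np.ndarray:
        out = np.asarray(self.fn(img), dtype=float)
        if out.shape != (self._spec.output_dim,):
            raise ValueError(
                f"extractor {self._spec.name} returned shape {out.shape}, "
                f"expected ({self._spec.output_dim},)"
            )
        return out

    def spec(self) -> ExtractorSpec:
        return self._spec
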