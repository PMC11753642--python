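"""Label-preserving image augmentation: 90-degree rotation and the two
flips, plus dataset expansion.

All three ops are bijections on the pixel grid; the flips are involutions
and rot90 has order 4, so they generate (together with transposition) the
dihedral group of the square.  Nothing here is random.  Rotation is
counter-clockwise (numpy convention); for classification the direction is
immaterial.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledImage",
    "rot90",
    "flip_ud",
    "flip_lr",
    "augment_dataset",
    "expand_to",
    "load_image_dir",
    "save_augmented",
]


@dataclass
class LabeledImage:
    """Pixel grid (H x W or H x W x C, uint8) with a class label and an
    origin tag recording the source file and applied ops."""

    pixels: np.ndarray
    label: object
    origin: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be H x W or H x W x C with H, W >= 1")
        if px.ndim == 3 and px.shape[2] not in (1, 3):
            raise ValueError("channel count must be 1 or 3")
        self.pixels = px

    @property
    def shape(self):
        return self.pixels.shape


def _tagged(img: LabeledImage, op: str, pixels: np.ndarray) -> LabeledImage:
    tag = f"{img.origin}+{op}" if img.origin else op
    return replace(img, pixels=pixels, origin=tag)


def rot90(img: LabeledImage) -> LabeledImage:
    """Rotate 90 degrees counter-clockwise; H x W becomes W x H."""
    return _tagged(img, "rot90", np.rot90(img.pixels, axes=(0, 1)).copy())


def flip_ud(img: LabeledImage) -> LabeledImage:
    """Vertical flip (row order reversed)."""
    return _tagged(img, "flip_ud", np.flip(img.pixels, axis=0).copy())


def flip_lr(img: LabeledImage) -> LabeledImage:
    """Horizontal flip (column order reversed)."""
    return _tagged(img, "flip_lr", np.flip(img.pixels, axis=1).copy())


#: The three augmentation ops applied on top of the identity.
DEFAULT_OPS: Tuple[Tuple[str, Callable[[LabeledImage], LabeledImage]], ...] = (
    ("rot90", rot90),
    ("flip_ud", flip_ud),
    ("flip_lr", flip_lr),
)


def augment_dataset(images: Sequence[LabeledImage], repeat: int = 1,
                    ops=DEFAULT_OPS) -> List[LabeledImage]:
    """Per input image and per repeat, emit the original plus each op's
    output: 4 outputs per image per repeat with the default op set.

    Labels are preserved, so the per-class histogram scales uniformly by
    4 * repeat.
    """
    if repeat < 1:
        raise ValueError("repeat must be >= 1")
    if not ops:
        raise ValueError("op set must be nonempty")
    out: List[LabeledImage] = []
    for _ in range(repeat):
        for img in images:
            out.append(replace(img))
            for _name, op in ops:
                out.append(op(img))
    return out


# The 8 symmetries of the square, composable from the three ops.
_DIHEDRAL: Tuple[Tuple[str, Callable[[LabeledImage], LabeledImage]], ...] = (
    ("identity", lambda im: replace(im)),
    ("rot90", rot90),
    ("rot180", lambda im: rot90(rot90(im))),
    ("rot270", lambda im: rot90(rot90(rot90(im)))),
    ("flip_ud", flip_ud),
    ("flip_lr", flip_lr),
    ("rot90+flip_ud", lambda im: flip_ud(rot90(im))),
    ("rot90+flip_lr", lambda im: flip_lr(rot90(im))),
)


def expand_to(images: Sequence[LabeledImage], target_count: int) -> List[LabeledImage]:
    """Expand to an arbitrary target count by cycling the dihedral-group
    compositions of the three ops over the inputs in a fixed order.

    Published augmented dataset sizes are often not integer multiples of the
    input count; this reaches any target >= len(images) deterministically.
    """
    if target_count < len(images):
        raise ValueError("target_count must be at least the input count")
    out: List[LabeledImage] = []
    rank = 0
    while len(out) < target_count:
        name, op = _DIHEDRAL[rank % len(_DIHEDRAL)]
        for img in images:
            if len(out) >= target_count:
                break
            out.append(op(img))
        rank += 1
    return out


# ---------------------------------------------------------------------------
# Directory I/O (class-per-folder layout)
# ---------------------------------------------------------------------------

_IMAGE_EXTS = {".png", ".jpg", ".jpeg"}


def load_image_dir(root) -> List[LabeledImage]:
    """Read a class-per-folder image tree; unreadable files are skipped with
    a logged warning and counted in the log."""
    import imageio.v3 as iio

    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"image directory not found: {root}")
    images: List[LabeledImage] = []
    skipped = 0
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for f in sorted(class_dir.iterdir()):
            if f.suffix.lower() not in _IMAGE_EXTS:
                continue
            try:
                px = np.asarray(iio.imread(f))
            except Exception as exc:
                skipped += 1
                logger.warning("skipping unreadable image %s: %s", f, exc)
                continue
            images.append(LabeledImage(pixels=px, label=class_dir.name,
                                       origin=str(f.relative_to(root))))
    if skipped:
        logger.warning("skipped %d unreadable image(s) under %s", skipped, root)
    return images


def save_augmented(images: Sequence[LabeledImage], out_root,
                   manifest_name: str = "manifest.csv") -> Path:
    """Write images to a mirrored class-per-folder tree with op-suffixed
    filenames and a CSV manifest (filename, class, source, op)."""
    import imageio.v3 as iio

    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest_path = out_root / manifest_name
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "class", "source", "op"])
        for i, img in enumerate(images):
            cls_dir = out_root / str(img.label)
            cls_dir.mkdir(exist_ok=True)
            source, _, op = img.origin.partition("+")
            stem = Path(source).stem if source else f"img{i:05d}"
            fname = f"{stem}_{op or 'orig'}_{i:05d}.png"
            iio.imwrite(cls_dir / fname, np.asarray(img.pixels, dtype=np.uint8))
            writer.writerow([f"{img.label}/{fname}", img.label, source, op or "identity"])
    return manifest_path
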