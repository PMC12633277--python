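"""Standardized preprocessing, stochastic augmentation, and CV folds.

The canonical input pipeline pads each frame to a square with neutral gray
(RGB 173), resizes to 224 x 224 with bilinear interpolation, and — for
training sets — expands every image into a fixed number of randomized
variants (resized crop, rotation, flips, color jitter, Gaussian blur).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb, rgb2hsv
from skimage.filters import gaussian
from skimage.transform import resize, rotate

from cytocluster.errors import ParameterError, SplitError
from cytocluster.imageio_core import ChannelImage

__all__ = [
    "AugmentationConfig",
    "FoldSplit",
    "pad_to_square",
    "resize_to_standard",
    "augment",
    "make_folds",
]

GRAY_FILL = (173, 173, 173)
STANDARD_SIDE = 224


@dataclass(frozen=True)
class AugmentationConfig:
    """Per-image augmentation policy.

    ``multiplicity`` variants are drawn per input image.  Magnitudes for
    jitter and blur are free parameters of the pipeline; the defaults are
    brightness/contrast/saturation +-20%, hue +-5% of a full turn and blur
    sigma drawn from U[0.1, 2.0].
    """

    multiplicity: int = 5
    crop_scale: tuple[float, float] = (0.8, 1.0)
    rotation_degrees: tuple[float, float] = (0.0, 360.0)
    hflip: bool = True
    vflip: bool = True
    brightness: float = 0.2
    contrast: float = 0.2
    saturation: float = 0.2
    hue: float = 0.05
    blur_sigma: tuple[float, float] = (0.1, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ParameterError("multiplicity must be >= 1")
        lo, hi = self.crop_scale
        if not (0.0 < lo <= hi <= 1.0):
            raise ParameterError("crop_scale must lie within (0, 1]")
        if self.blur_sigma[0] < 0 or self.blur_sigma[1] < self.blur_sigma[0]:
            raise ParameterError("blur_sigma interval must be non-negative")

    @classmethod
    def identity(cls, multiplicity: int = 1) -> "AugmentationConfig":
        """A config under which every augmented image equals the input."""
        return cls(
            multiplicity=multiplicity,
            crop_scale=(1.0, 1.0),
            rotation_degrees=(0.0, 0.0),
            hflip=False,
            vflip=False,
            brightness=0.0,
            contrast=0.0,
            saturation=0.0,
            hue=0.0,
            blur_sigma=(0.0, 0.0),
        )


def pad_to_square(
    img: ChannelImage, fill_rgb: tuple[int, int, int] = GRAY_FILL
) -> ChannelImage:
    """Pad the shorter side with gray so the output is max(h, w) square.

    Content is centered; when the total padding is odd the extra pixel goes
    to the right/bottom.  Original pixel values are never altered.
    """
    h, w = img.height, img.width
    side = max(h, w)
    if h == w:
        return img
    top = (side - h) // 2
    left = (side - w) // 2
    if img.is_rgb:
        out = np.empty((side, side, 3), dtype=np.uint8)
        out[:] = np.asarray(fill_rgb, dtype=np.uint8)
        out[top : top + h, left : left + w, :] = img.pixels
    else:
        out = np.full((side, side), fill_rgb[0], dtype=np.uint8)
        out[top : top + h, left : left + w] = img.pixels
    return ChannelImage(out)


def resize_to_standard(img: ChannelImage, side: int = STANDARD_SIDE) -> ChannelImage:
    """Bilinear resize to ``side x side``, promoting grayscale to RGB."""
    if side < 1:
        raise ParameterError(f"side must be positive, got {side}")
    rgb = img.to_rgb()
    out = resize(
        rgb.pixels.astype(np.float64),
        (side, side, 3),
        order=1,
        anti_aliasing=False,
        preserve_range=True,
    )
    return ChannelImage(np.clip(np.rint(out), 0, 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _random_resized_crop(
    arr: np.ndarray, scale: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    s = rng.uniform(*scale)
    if s >= 1.0:
        return arr
    h, w = arr.shape[:2]
    ch = max(1, int(round(h * np.sqrt(s))))
    cw = max(1, int(round(w * np.sqrt(s))))
    top = int(rng.integers(0, h - ch + 1))
    left = int(rng.integers(0, w - cw + 1))
    crop = arr[top : top + ch, left : left + cw]
    shape = (h, w) + arr.shape[2:]
    return resize(crop, shape, order=1, anti_aliasing=False, preserve_range=True)


def _color_jitter(
    arr: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    # operates on float arrays in [0, 255]; RGB-only ops skipped on grayscale
    if cfg.brightness > 0:
        arr = arr * rng.uniform(1 - cfg.brightness, 1 + cfg.brightness)
    if cfg.contrast > 0:
        f = rng.uniform(1 - cfg.contrast, 1 + cfg.contrast)
        arr = (arr - arr.mean()) * f + arr.mean()
    if arr.ndim == 3:
        if cfg.saturation > 0:
            f = rng.uniform(1 - cfg.saturation, 1 + cfg.saturation)
            gray = arr.mean(axis=2, keepdims=True)
            arr = gray + (arr - gray) * f
        if cfg.hue > 0:
            shift = rng.uniform(-cfg.hue, cfg.hue)
            hsv = rgb2hsv(np.clip(arr, 0, 255) / 255.0)
            hsv[:, :, 0] = (hsv[:, :, 0] + shift) % 1.0
            arr = hsv2rgb(hsv) * 255.0
    return arr


def augment(
    img: ChannelImage, cfg: AugmentationConfig, rng_seed: int | None = None
) -> list[ChannelImage]:
    """Draw ``cfg.multiplicity`` randomized variants of *img*.

    Each variant is an independent draw of crop, rotation, flips, color
    jitter and blur; output dimensions equal the input's.  Fully
    reproducible from ``rng_seed`` (falls back to ``cfg.seed``).
    """
    seed = cfg.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    out: list[ChannelImage] = []
    for _ in range(cfg.multiplicity):
        arr = img.pixels.astype(np.float64)
        arr = _random_resized_crop(arr, cfg.crop_scale, rng)
        lo, hi = cfg.rotation_degrees
        angle = rng.uniform(lo, hi) if hi > lo else lo
        if angle != 0.0:
            arr = rotate(arr, angle, resize=False, order=1, mode="edge",
                         preserve_range=True)
        if cfg.hflip and rng.random() < 0.5:
            arr = arr[:, ::-1]
        if cfg.vflip and rng.random() < 0.5:
            arr = arr[::-1, :]
        arr = _color_jitter(arr, cfg, rng)
        sig = rng.uniform(*cfg.blur_sigma)
        if sig > 0:
            channel_axis = 2 if arr.ndim == 3 else None
            arr = gaussian(arr, sigma=sig, preserve_range=True,
                           channel_axis=channel_axis)
        out.append(ChannelImage(np.clip(np.rint(arr), 0, 255).astype(np.uint8)))
    return out


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldSplit:
    """Stratified k-fold partition: record_id -> fold index in [0, k)."""

    k: int
    assignments: Mapping[str, int]

    def test_ids(self, fold: int) -> list[str]:
        return [r for r, f in self.assignments.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [r for r, f in self.assignments.items() if f != fold]

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.assignments.values():
            sizes[f] += 1
        return sizes

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"record_id": list(self.assignments), "fold": list(self.assignments.values())}
        ).to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FoldSplit":
        df = pd.read_csv(path, dtype={"record_id": str})
        assignments = dict(zip(df["record_id"], df["fold"].astype(int)))
        return cls(k=int(df["fold"].max()) + 1, assignments=assignments)


def make_folds(
    records: Sequence[tuple[str, Hashable]], k: int = 5, seed: int = 0
) -> FoldSplit:
    """Stratified-by-class k-fold assignment, deterministic given *seed*.

    *records* is a sequence of ``(record_id, class_label)`` pairs.  Per
    class, ids are shuffled and dealt round-robin, so per-class fold counts
    differ by at most one.
    """
    if k < 2:
        raise SplitError(f"k must be >= 2, got {k}")
    by_class: dict[Hashable, list[str]] = {}
    for rid, cls in records:
        by_class.setdefault(cls, []).append(rid)
    for cls, ids in by_class.items():
        if len(ids) < k:
            raise SplitError(
                f"class {cls!r} has only {len(ids)} records, need >= k={k}"
            )
        if len(set(ids)) != len(ids):
            raise SplitError(f"duplicate record ids in class {cls!r}")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    for cls in sorted(by_class, key=repr):
        ids = list(by_class[cls])
        rng.shuffle(ids)
        for i, rid in enumerate(ids):
            assignments[rid] = i % k
    return FoldSplit(k=k, assignments=assignments)
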