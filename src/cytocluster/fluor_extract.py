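"""Binary stain-mask extraction from fluorescence channels by HSV ranges.

Hue dialect: the half-degree scale 0-179 (pure green = 60, pure yellow =
30); saturation and value are 0-255.  The default ranges are

* green / CD61: H 35-85, S 100-255, V X-255
* yellow / CD45: H 20-40, S 100-255, V X-255

where ``X`` is the tunable brightness lower bound (default 140).  The two
hue ranges overlap in [35, 40]; a pixel may legitimately belong to both
stain masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_opening
from skimage.color import hsv2rgb, rgb2hsv
from skimage.morphology import disk

from cytocluster.errors import FormatError, ParameterError
from cytocluster.imageio_core import BinaryMask, ChannelImage

__all__ = [
    "HSVRange",
    "StainChannel",
    "DEFAULT_V_LO",
    "green_channel",
    "yellow_channel",
    "rgb_to_hsv255",
    "hsv255_to_rgb",
    "extract_stain_mask",
]

DEFAULT_V_LO = 140


@dataclass(frozen=True)
class HSVRange:
    """Inclusive hue/saturation/value box; ``v_lo`` is the brightness bound X."""

    h_lo: int
    h_hi: int
    s_lo: int
    s_hi: int
    v_lo: int
    v_hi: int

    def __post_init__(self) -> None:
        if not (0 <= self.h_lo <= self.h_hi <= 179):
            raise ParameterError(f"hue bounds out of order/range: {self}")
        if not (0 <= self.s_lo <= self.s_hi <= 255):
            raise ParameterError(f"saturation bounds out of order/range: {self}")
        if not (0 <= self.v_lo <= self.v_hi <= 255):
            raise ParameterError(f"value bounds out of order/range: {self}")

    def contains(self, hsv: np.ndarray) -> np.ndarray:
        """Boolean grid of pixels inside the box (hsv: H x W x 3 uint8)."""
        h, s, v = hsv[:, :, 0], hsv[:, :, 1], hsv[:, :, 2]
        return (
            (h >= self.h_lo) & (h <= self.h_hi)
            & (s >= self.s_lo) & (s <= self.s_hi)
            & (v >= self.v_lo) & (v <= self.v_hi)
        )

    def with_v_lo(self, v_lo: int) -> "HSVRange":
        return HSVRange(self.h_lo, self.h_hi, self.s_lo, self.s_hi, v_lo, self.v_hi)


@dataclass(frozen=True)
class StainChannel:
    """A named fluorescence stain with its HSV extraction range."""

    name: str  # "cd61_green" or "cd45_yellow"
    range: HSVRange


def green_channel(v_lo: int = DEFAULT_V_LO) -> StainChannel:
    """CD61 / platelet stain: green and adjacent hues."""
    return StainChannel("cd61_green", HSVRange(35, 85, 100, 255, v_lo, 255))


def yellow_channel(v_lo: int = DEFAULT_V_LO) -> StainChannel:
    """CD45 / leukocyte stain: yellow and adjacent hues."""
    return StainChannel("cd45_yellow", HSVRange(20, 40, 100, 255, v_lo, 255))


def rgb_to_hsv255(img: ChannelImage) -> ChannelImage:
    """Convert RGB to the 0-179 / 0-255 / 0-255 HSV dialect.

    H = round(hue in degrees / 2) mod 180; V = max(R, G, B); S = 0 where
    V = 0.
    """
    if not img.is_rgb:
        raise FormatError("rgb_to_hsv255 requires a 3-plane RGB image")
    rgb = img.pixels
    hsv = rgb2hsv(rgb)  # floats: h, s in [0, 1]
    h179 = (np.rint(hsv[:, :, 0] * 180.0).astype(np.int32)) % 180
    s255 = np.rint(hsv[:, :, 1] * 255.0).astype(np.int32)
    v255 = rgb.max(axis=2).astype(np.int32)
    out = np.stack([h179, s255, v255], axis=2)
    return ChannelImage(out.astype(np.uint8))


def hsv255_to_rgb(h: int, s: int, v: int) -> tuple[int, int, int]:
    """Single-color inverse of :func:`rgb_to_hsv255` (used by the synthesizer)."""
    rgb = hsv2rgb(np.array([[[h / 180.0, s / 255.0, v / 255.0]]]))[0, 0]
    return tuple(int(x) for x in np.rint(rgb * 255.0))


def extract_stain_mask(
    img: ChannelImage,
    channel: StainChannel,
    apply_morphology: bool = True,
    morph_radius: int = 1,
) -> BinaryMask:
    """Threshold *img* into the channel's HSV box, then despeckle.

    A pixel is selected iff its (H, S, V) lies inclusively inside
    ``channel.range``; one morphological opening with a radius-
    ``morph_radius`` disk removes isolated speckle (set
    ``apply_morphology=False`` for the raw threshold mask, which is
    monotone non-increasing in the brightness bound X).
    """
    hsv = rgb_to_hsv255(img).pixels
    raw = channel.range.contains(hsv)
    if apply_morphology and morph_radius > 0 and raw.any():
        raw = binary_opening(raw, structure=disk(morph_radius))
    return BinaryMask(raw)
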