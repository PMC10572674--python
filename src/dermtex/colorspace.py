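"""Image loading and color-space decomposition.

Dermoscopic images arrive as 8-bit RGB rasters. Texture descriptors operate
on single intensity planes, so every image is decomposed either into one
grayscale plane or into the three channels of a color space whose channels
are only weakly correlated (LAB, HSV or YCbCr). All planes are 8-bit
integer rasters in [0, 255] so that descriptor outputs are bit-exact and
reproducible across runs.

Conventions (fixed so results are deterministic):

* GRAY is BT.601 luma: ``0.299 R + 0.587 G + 0.114 B``.
* YCbCr is full-range BT.601 (JPEG convention, 128 offsets on Cb/Cr), not
  studio swing, so descriptors see the full [0, 255] dynamic range.
* HSV scales hue from [0°, 360°) to [0, 255] and S, V to [0, 255]. Hue is
  treated as an ordinary scalar plane even though it is circular (0 and 255
  are adjacent on the hue wheel); this matches naive per-channel descriptor
  extraction and is a documented approximation.
* LAB uses the sRGB transfer curve with a D65 white point; L* is rescaled
  by 255/100 and a*, b* are offset by +128.

All conversions round half away from zero and clip to [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage import color as skcolor

from .errors import ConfigError, FormatError, InputError, ShapeError, SizeError

__all__ = [
    "ColorSpace",
    "ChannelPlane",
    "load_image",
    "to_planes",
    "PLANE_NAMES",
]

MIN_SIDE = 3

#: BT.601 luma weights, shared by GRAY and the Y channel of YCbCr.
_LUMA = np.array([0.299, 0.587, 0.114])


class ColorSpace(str, Enum):
    """Identifier of a per-channel decomposition. GRAY yields one plane,
    the color spaces yield exactly three, in the order of PLANE_NAMES."""

    GRAY = "GRAY"
    LAB = "LAB"
    HSV = "HSV"
    YCBCR = "YCBCR"


PLANE_NAMES = {
    ColorSpace.GRAY: ("GRAY",),
    ColorSpace.LAB: ("L", "A", "B"),
    ColorSpace.HSV: ("H", "S", "V"),
    ColorSpace.YCBCR: ("Y", "Cb", "Cr"),
}


@dataclass(frozen=True)
class ChannelPlane:
    """A single H×W intensity plane in [0, 255] with its channel name."""

    values: np.ndarray
    name: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _round_u8(x: np.ndarray) -> np.ndarray:
    """Round half away from zero and clip to [0, 255].

    All inputs are non-negative after the channel offsets, so
    ``floor(x + 0.5)`` implements round-half-away-from-zero exactly.
    """
    return np.clip(np.floor(x + 0.5), 0, 255).astype(np.uint8)


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG file as an H×W×3 uint8 raster.

    Grayscale sources are replicated to three identical channels; an alpha
    channel is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            rgb = im.convert("RGB")
            arr = np.asarray(rgb, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise FormatError(f"cannot decode {path} as PNG/JPEG: {exc}") from exc
    _check_image(arr)
    return arr


def _check_image(img: np.ndarray) -> None:
    if img.ndim != 3 or img.shape[2] != 3:
        raise ShapeError(f"expected H×W×3 raster, got shape {img.shape}")
    if img.shape[0] < MIN_SIDE or img.shape[1] < MIN_SIDE:
        raise SizeError(
            f"image of shape {img.shape[:2]} is smaller than {MIN_SIDE}x{MIN_SIDE}"
        )


def to_planes(img: np.ndarray, space: ColorSpace | str) -> list[ChannelPlane]:
    """Decompose an RGB image into ordered intensity planes.

    GRAY yields a single BT.601 luma plane; LAB/HSV/YCBCR yield exactly
    three planes in the fixed channel order of :data:`PLANE_NAMES`.
    """
    _check_image(np.asarray(img))
    img = np.asarray(img, dtype=np.float64)
    try:
        space = ColorSpace(space.upper() if isinstance(space, str) else space)
    except ValueError:
        raise ConfigError(f"unknown color space: {space!r}") from None

    if space is ColorSpace.GRAY:
        gray = img @ _LUMA
        chans = [gray]
    elif space is ColorSpace.YCBCR:
        r, g, b = img[..., 0], img[..., 1], img[..., 2]
        y = img @ _LUMA
        cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
        cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
        chans = [y, cb, cr]
    elif space is ColorSpace.HSV:
        hsv = skcolor.rgb2hsv(img / 255.0)
        chans = [hsv[..., 0] * 255.0, hsv[..., 1] * 255.0, hsv[..., 2] * 255.0]
    else:  # LAB
        lab = skcolor.rgb2lab(img / 255.0)
        chans = [lab[..., 0] * (255.0 / 100.0), lab[..., 1] + 128.0, lab[..., 2] + 128.0]

    names = PLANE_NAMES[space]
    return [ChannelPlane(_round_u8(c), n) for c, n in zip(chans, names)]
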