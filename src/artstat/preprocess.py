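"""Image preprocessing: central-square crop, bicubic resize, CIELAB split.

Every artwork is reduced to a standard representation before any
statistic is computed: the largest central square is cropped, the
square is rescaled to a fixed side length (1024 px by default) with
cubic interpolation, and the sRGB pixels are converted to CIELAB
(D65 white point).  The three CIELAB planes -- L (lightness, 0-100),
a (red-green) and b (blue-yellow) -- are what the estimators consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.color import rgb2lab

from artstat.errors import InvalidInputError

DEFAULT_SIDE = 1024


@dataclass(frozen=True)
class PlaneStack:
    """The three CIELAB planes of one preprocessed image.

    Attributes
    ----------
    L : ndarray
        Lightness plane, values in [0, 100].
    a : ndarray
        Red-green opponent plane.
    b : ndarray
        Blue-yellow opponent plane.
    """

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        if not (self.L.shape == self.a.shape == self.b.shape):
            raise InvalidInputError("L, a, b planes must share one shape")
        if self.L.ndim != 2:
            raise InvalidInputError("planes must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape

    def planes(self) -> dict[str, np.ndarray]:
        return {"L": self.L, "a": self.a, "b": self.b}


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    if img.ndim != 3 or img.shape[2] < 3:
        raise InvalidInputError(f"expected HxWx3 image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise InvalidInputError("empty image")
    return img[:, :, :3]


def crop_central_square(img: np.ndarray) -> np.ndarray:
    """Crop the largest central square from an image.

    Equal margins are removed from the longer axis; when the total
    margin is odd, the extra pixel comes off the trailing (right or
    bottom) side.  Square inputs pass through unchanged, which makes
    the operation idempotent.
    """
    img = _check_rgb(img)
    h, w = img.shape[:2]
    s = min(h, w)
    top = (h - s) // 2
    left = (w - s) // 2
    return img[top : top + s, left : left + s]


def resize_bicubic(img: np.ndarray, target: int = DEFAULT_SIDE) -> np.ndarray:
    """Resize a square image to ``target`` x ``target`` with cubic interpolation.

    Uses a Catmull-Rom-class bicubic kernel with anti-aliasing when
    downsampling.  Cubic interpolation can overshoot, so the result is
    clipped back to the 8-bit range.
    """
    img = _check_rgb(img)
    h, w = img.shape[:2]
    if h != w:
        raise InvalidInputError(f"resize expects a square image, got {h}x{w}")
    if target < 1:
        raise InvalidInputError("target side must be positive")
    if h == target:
        return img.astype(np.uint8, copy=True)
    pil = Image.fromarray(img.astype(np.uint8), mode="RGB")
    out = pil.resize((target, target), resample=Image.Resampling.BICUBIC)
    return np.asarray(out, dtype=np.uint8)


def srgb_to_lab(img: np.ndarray) -> PlaneStack:
    """Convert an 8-bit sRGB image to a CIELAB plane stack (D65 white)."""
    img = _check_rgb(img)
    lab = rgb2lab(img.astype(np.uint8))
    return PlaneStack(
        L=np.ascontiguousarray(lab[:, :, 0]),
        a=np.ascontiguousarray(lab[:, :, 1]),
        b=np.ascontiguousarray(lab[:, :, 2]),
    )


def preprocess_image(img: np.ndarray, side: int = DEFAULT_SIDE) -> PlaneStack:
    """Full preprocessing chain: crop -> resize -> CIELAB split."""
    return srgb_to_lab(resize_bicubic(crop_central_square(img), side))


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF file as an HxWx3 8-bit sRGB array.

    Alpha channels are dropped; greyscale files are broadcast to three
    channels.  No ICC colour management is attempted: pixel values are
    taken as sRGB.
    """
    with Image.open(path) as im:
        im = im.convert("RGB")
        return np.asarray(im, dtype=np.uint8)
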