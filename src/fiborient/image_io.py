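"""Reading and normalizing grayscale micrographs.

Micrographs enter the pipeline as a two-dimensional intensity function
``I(i, j)`` (row ``i``, column ``j``).  Because the gradient-magnitude
threshold ``T`` is expressed on a normalized scale, every image is divided
by its maximum before analysis so that ``T`` is comparable across frames
acquired at different gains or bit depths.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateImageError, ImageFormatError

__all__ = ["GrayImage", "load_image", "normalize_image"]

#: Smallest usable image side, in pixels.
MIN_SIDE = 2


@dataclass(frozen=True)
class GrayImage:
    """A single-channel image with non-negative real intensities.

    Attributes
    ----------
    pixels:
        2-D float array, indexed ``(row, column)``; never modified in place.
    normalized:
        True once the maximum intensity has been scaled to exactly 1.
    """

    pixels: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ImageFormatError(f"expected a 2-D image, got shape {px.shape}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise DegenerateImageError(
                f"image of shape {px.shape} is below the minimum size "
                f"{MIN_SIDE}x{MIN_SIDE}"
            )
        if not np.all(np.isfinite(px)):
            raise ImageFormatError("image contains non-finite intensities")
        if px.min() < 0:
            raise ImageFormatError("image contains negative intensities")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def load_image(path: str | os.PathLike, channel: int | None = None) -> GrayImage:
    """Read a TIFF or PNG micrograph into a :class:`GrayImage`.

    Parameters
    ----------
    path:
        File to read.  TIFF (including 16-bit) is read with :mod:`tifffile`,
        PNG with :mod:`imageio`.
    channel:
        Required for multichannel inputs; selects one plane explicitly.
        There is no silent luminance conversion.

    Raises
    ------
    ImageFormatError
        If the file cannot be read, or is multichannel and ``channel`` was
        not given.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ImageFormatError(f"no such file: {path}")
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise ImageFormatError(f"could not read {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 3:
        if channel is None:
            raise ImageFormatError(
                f"{path} has {arr.shape[-1]} channels; pass an explicit "
                "channel index (no silent luminance conversion)"
            )
        # channel axis is whichever axis is small; prefer the trailing one
        axis = 2 if arr.shape[2] <= 4 else 0
        if not 0 <= channel < arr.shape[axis]:
            raise ImageFormatError(
                f"channel {channel} out of range for shape {arr.shape}"
            )
        arr = np.take(arr, channel, axis=axis)
    elif arr.ndim != 2:
        raise ImageFormatError(f"unsupported image dimensionality {arr.ndim}")

    return GrayImage(pixels=arr.astype(float), normalized=False)


def normalize_image(img: GrayImage, percentile: float | None = None) -> GrayImage:
    """Scale intensities so the image maximum equals 1.

    By default divides by the image maximum.  ``percentile`` (e.g. 99.9)
    switches to a robust normalizer for images with photon-count outliers:
    the given intensity percentile is mapped to 1 and brighter pixels are
    clipped.  The operation is idempotent and preserves the relative
    ordering of intensities (exactly in the default mode; up to clipping in
    percentile mode).

    Raises
    ------
    DegenerateImageError
        If the image is all-zero (there is no structure to analyze).
    """
    px = img.pixels
    if percentile is None:
        scale = px.max()
        if scale == 0:
            raise DegenerateImageError("all-zero image cannot be normalized")
        if img.normalized and scale == 1.0:
            return img
        return replace(img, pixels=px / scale, normalized=True)

    if not 0 < percentile <= 100:
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    scale = np.percentile(px, percentile)
    if scale <= 0:
        raise DegenerateImageError(
            f"percentile {percentile} of the image is not positive"
        )
    out = np.clip(px / scale, 0.0, 1.0)
    if out.max() < 1.0:  # guarantee the invariant max == 1 exactly
        out = out / out.max()
    return replace(img, pixels=out, normalized=True)
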