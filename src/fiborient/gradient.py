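"""Intensity-gradient field at resolution R, with orientation folding.

The gradient at resolution ``R`` is the centered unit difference of ``R x R``
boxcar means:

    S(i, j)  = mean of I over rows i..i+R-1, cols j..j+R-1
    gx(i, j) = (S(i, j+1) - S(i, j-1)) / 2
    gy(i, j) = (S(i+1, j) - S(i-1, j)) / 2

For ``R = 1`` this is the ordinary centered difference on the interior.  The
operator equals the mean of forward unit-step differences taken over its
stencil (the boxcar sums telescope), so "resolution" literally means the
number of pixels over which the intensity change is averaged.  gx and gy
have disjoint pixel supports, which keeps the statistics of the two
components symmetric under 90-degree rotation - important for integer-valued
photon-count noise, whose exact ties otherwise bias the diagonal
orientations.

Orientations are *folded*: a gradient vector and its antiparallel partner
describe the same fiber edge, so raw directions in (-180, 180] degrees are
mapped onto the half-open interval (0, 180] (0 maps to 180).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .errors import ConfigError, ContractError
from .image_io import GrayImage

__all__ = [
    "GradientConfig",
    "GradientField",
    "compute_gradient",
    "fold_angle",
    "orientation_map",
]


@dataclass(frozen=True)
class GradientConfig:
    """Validated (R, T, B) parameter triple.

    R : averaging span in pixels (integer >= 1)
    T : gradient-magnitude threshold on the normalized-intensity scale
    B : angular bin width in degrees; must divide 180
    """

    R: int = 2
    T: float = 0.05
    B: int = 5

    def __post_init__(self):
        if not (isinstance(self.R, (int, np.integer)) and self.R >= 1):
            raise ConfigError(f"R must be an integer >= 1, got {self.R!r}")
        if self.T < 0:
            raise ConfigError(f"T must be >= 0, got {self.T}")
        if not (
            isinstance(self.B, (int, np.integer)) and 1 <= self.B <= 180
        ):
            raise ConfigError(f"B must be an integer in [1, 180], got {self.B!r}")
        if 180 % self.B != 0:
            raise ConfigError(f"B must divide 180, got {self.B}")


@dataclass(frozen=True)
class GradientField:
    """Per-pixel gradient vectors over the valid (border-cropped) region."""

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    theta_raw: np.ndarray  # degrees in (-180, 180], NaN where undefined
    theta_folded: np.ndarray  # degrees in (0, 180], NaN where undefined
    valid_mask: np.ndarray  # True where magnitude > 0
    R: int
    offset: tuple[int, int] = dataclass_field(default=(1, 1))
    """Row/column offset of the valid grid inside the source image."""


def _window_means(I: np.ndarray, R: int) -> np.ndarray:
    """Means of all R x R windows, anchored at the top-left pixel."""
    if R == 1:
        return I
    c = np.zeros((I.shape[0] + 1, I.shape[1] + 1))
    c[1:, 1:] = I.cumsum(axis=0).cumsum(axis=1)
    return (c[R:, R:] - c[:-R, R:] - c[R:, :-R] + c[:-R, :-R]) / (R * R)


def compute_gradient(img: GrayImage, R: int = 1) -> GradientField:
    """Compute the gradient vector field of a normalized image.

    The valid region excludes the border where the averaging stencil leaves
    the image; its shape is ``(height - R - 1, width - R - 1)``.  Pixels with
    exactly zero magnitude carry no orientation (``atan2(0, 0)`` is
    undefined) and are flagged invalid.
    """
    if not img.normalized:
        raise ContractError("compute_gradient requires a normalized image")
    if not (isinstance(R, (int, np.integer)) and R >= 1):
        raise ConfigError(f"R must be an integer >= 1, got {R!r}")
    if R > min(img.height, img.width) - 2:
        raise ConfigError(
            f"R={R} too large for a {img.height}x{img.width} image "
            f"(needs R <= min(height, width) - 2)"
        )

    S = _window_means(img.pixels, R)
    gx = (S[1:-1, 2:] - S[1:-1, :-2]) / 2.0
    gy = (S[2:, 1:-1] - S[:-2, 1:-1]) / 2.0
    magnitude = np.hypot(gx, gy)
    valid = magnitude > 0

    theta_raw = np.full(gx.shape, np.nan)
    theta_raw[valid] = np.degrees(np.arctan2(gy[valid], gx[valid]))
    # atan2 returns [-180, 180]; move -180 onto its identical partner +180
    theta_raw[theta_raw == -180.0] = 180.0

    theta_folded = np.full(gx.shape, np.nan)
    theta_folded[valid] = fold_angle(theta_raw[valid])

    half = (R + 1) // 2
    return GradientField(
        gx=gx,
        gy=gy,
        magnitude=magnitude,
        theta_raw=theta_raw,
        theta_folded=theta_folded,
        valid_mask=valid,
        R=int(R),
        offset=(half, half),
    )


def fold_angle(theta):
    """Fold a direction (degrees) onto the orientation half-plane (0, 180].

    Antiparallel vectors describe the same fiber edge: a bright ridge at 45
    degrees produces gradients at 135 and -45 degrees on its two flanks, and
    both must count as the single orientation 135.  Folding is 180-periodic
    and maps 0 to 180 under the half-open (0, 180] convention.

    Accepts scalars or arrays; rejects non-finite input.
    """
    arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ContractError("fold_angle is undefined for non-finite angles")
    out = np.mod(arr, 180.0)
    out = np.where(out == 0.0, 180.0, out)
    if np.isscalar(theta) or arr.ndim == 0:
        return float(out)
    return out


def orientation_map(field: GradientField, sentinel=np.nan) -> np.ndarray:
    """Raw (unfolded) per-pixel orientations for visualization.

    Returns a copy of ``theta_raw`` with invalid pixels set to ``sentinel``,
    suitable for color-map export.
    """
    out = field.theta_raw.copy()
    out[~field.valid_mask] = sentinel
    return out
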