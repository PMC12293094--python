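"""Thresholding, binning, and the unit-area orientation PDF.

Folded gradient orientations are grouped into half-open angular bins
``(0, B], (B, 2B], ..., (180-B, 180]`` and converted to a per-degree
probability density, so that the area under the histogram is exactly one
regardless of the bin width.  A circular shift that brings the tallest bin
to the center of the scale is available to condition the subsequent model
fit; the shift is recorded so fitted peak centers can be mapped back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, EmptyPDFError
from .gradient import GradientField

__all__ = [
    "OrientationPDF",
    "bin_angles",
    "build_pdf",
    "threshold_from_fraction",
    "shift_pdf",
]


@dataclass(frozen=True)
class OrientationPDF:
    """Binned, unit-area density of folded orientations.

    ``density`` is per-degree: ``sum(density) * bin_width == 1``.
    ``shift`` is the circular shift (degrees) applied to the angular axis;
    0 if none.  Bin labels (edges, centers) always refer to the displayed,
    possibly shifted axis.
    """

    bin_edges: np.ndarray  # length n_bins + 1, from 0 to 180
    counts: np.ndarray
    density: np.ndarray
    bin_width: int
    n_vectors: int
    shift: float = 0.0

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def area(self) -> float:
        return float(self.density.sum() * self.bin_width)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "bin_center": self.bin_centers,
                "count": self.counts,
                "density": self.density,
            }
        ).to_csv(path, index=False)

    def metadata(self) -> dict:
        return {
            "bin_width": int(self.bin_width),
            "n_bins": int(self.n_bins),
            "n_vectors": int(self.n_vectors),
            "shift": float(self.shift),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


def bin_angles(angles: np.ndarray, B: int) -> np.ndarray:
    """Histogram folded angles in (0, 180] into half-open (lo, hi] bins.

    Returns integer counts of length ``180 // B``.  An angle exactly equal
    to a bin's upper edge belongs to that bin; 180 lands in the last bin.
    """
    if 180 % B != 0:
        raise ConfigError(f"B must divide 180, got {B}")
    a = np.asarray(angles, dtype=float)
    if a.size and (a.min() <= 0 or a.max() > 180):
        raise ConfigError("angles must lie in the folded interval (0, 180]")
    n_bins = 180 // B
    idx = np.ceil(a / B).astype(int) - 1
    np.clip(idx, 0, n_bins - 1, out=idx)
    return np.bincount(idx, minlength=n_bins)


def build_pdf(field: GradientField, T: float, B: int) -> OrientationPDF:
    """Threshold gradient vectors and build the unit-area orientation PDF.

    Vectors with ``magnitude < T`` are discarded; surviving folded angles
    are binned into ``180 / B`` half-open bins and counts are converted to
    per-degree density (``counts / (n_vectors * B)``).

    Raises
    ------
    EmptyPDFError
        If no vector survives the threshold.
    """
    if T < 0:
        raise ConfigError(f"T must be >= 0, got {T}")
    keep = field.valid_mask & (field.magnitude >= T)
    angles = field.theta_folded[keep]
    if angles.size == 0:
        raise EmptyPDFError(
            f"no gradient vectors with magnitude >= {T}; nothing to bin"
        )
    counts = bin_angles(angles, B)
    n = int(counts.sum())
    density = counts / (n * B)
    edges = np.arange(0, 181, B, dtype=float)
    return OrientationPDF(
        bin_edges=edges,
        counts=counts,
        density=density,
        bin_width=int(B),
        n_vectors=n,
    )


def threshold_from_fraction(field: GradientField, fraction: float) -> float:
    """Threshold as a fraction of the maximum gradient magnitude.

    ``fraction = 0.10`` (10% of the maximum) keeps the noise sensitivity
    comparable across images acquired at different contrast.
    """
    if not 0 < fraction <= 1:
        raise ConfigError(f"fraction must be in (0, 1], got {fraction}")
    if not field.valid_mask.any():
        raise EmptyPDFError("gradient field has no valid vectors")
    return float(fraction * field.magnitude[field.valid_mask].max())


def shift_pdf(pdf: OrientationPDF, center: float = 90.0) -> OrientationPDF:
    """Circularly rotate the bins so the tallest bin's center lands at
    ``center`` (degrees).

    The density values are unchanged as a multiset, so the unit area is
    preserved; the applied shift (new angle minus old angle) is accumulated
    in ``shift`` so fitted peak positions can be mapped back to the
    unshifted frame.  Ties on the maximum break to the leftmost (smallest
    angle) bin, which makes the operation deterministic.
    """
    i_max = int(np.argmax(pdf.density))  # argmax takes the leftmost maximum
    centers = pdf.bin_centers
    i_target = int(np.argmin(np.abs(centers - center)))
    roll = i_target - i_max
    if roll == 0:
        return pdf
    return replace(
        pdf,
        counts=np.roll(pdf.counts, roll),
        density=np.roll(pdf.density, roll),
        shift=pdf.shift + roll * pdf.bin_width,
    )
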