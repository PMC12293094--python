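"""Synthetic fiber phantoms with known ground truth.

Real fibrous-tissue micrographs suitable for validating the pipeline are
rarely published, so every stage is exercised against generated images
whose true orientation content is known by construction:

* :func:`make_fiber_image` - oriented sinusoidal gratings (one to three
  fiber families), optionally wavy, over a background, with Gaussian or
  photon-count (Poisson) noise.  The intensity gradient of a grating is
  analytically perpendicular to the fiber axis, so a family drawn at
  ``phi`` degrees must appear at ``(phi + 90) mod 180`` in the orientation
  PDF.
* :func:`make_noise_image` - iid noise fields (integer-valued Poisson
  emulating photon counts, or continuous Gaussian).
* :func:`make_dark_count_image` - a smooth, real-valued isotropic texture
  over exact-zero dark plateaus, plus iid Poisson dark counts and a fixed
  calibration bump that pins the maximum gradient magnitude.  This is the
  controlled setting in which integer-count noise produces its hallmark
  exact-tie spikes at 0/45/90/135 degrees at resolution R = 1 while the
  smooth structure provides a uniform angle continuum.
* :func:`sample_orientation_pdf` - angles drawn directly from a known
  Gaussian-plus-pedestal density, for fit validation.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigError
from .gradient import fold_angle
from .image_io import GrayImage
from .orientation_pdf import OrientationPDF, bin_angles

__all__ = [
    "FiberFamily",
    "PhantomSpec",
    "make_fiber_image",
    "make_noise_image",
    "make_dark_count_image",
    "sample_orientation_pdf",
]

MAX_FAMILIES = 3


@dataclass(frozen=True)
class FiberFamily:
    """One family of quasi-parallel fibers.

    orientation : fiber-axis angle in degrees (image frame)
    period      : fringe spacing in pixels (>= 2)
    amplitude   : relative intensity of the family (>= 0)
    waviness    : amplitude, in degrees, of a sinusoidal modulation of the
                  local fiber angle; 0 means straight fibers
    wav_period  : spatial period of the waviness, pixels
    """

    orientation: float
    period: float = 12.0
    amplitude: float = 1.0
    waviness: float = 0.0
    wav_period: float = 64.0

    def __post_init__(self):
        if self.period < 2:
            raise ConfigError(f"period must be >= 2 px, got {self.period}")
        if self.amplitude < 0:
            raise ConfigError(f"amplitude must be >= 0, got {self.amplitude}")
        if not 0 <= self.waviness < 90:
            raise ConfigError(
                f"waviness must be in [0, 90) degrees, got {self.waviness}"
            )

    @property
    def gradient_orientation(self) -> float:
        """Folded orientation at which this family's gradients appear."""
        return fold_angle(self.orientation + 90.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic fiber image."""

    size: tuple = (256, 256)
    families: tuple = ()
    noise_model: dict | None = None  # {"kind": "poisson", "peak": p} or
    # {"kind": "gaussian", "sd": s} or None
    background: float = 0.0
    mixing: str = "additive"  # "additive": patterns sum everywhere;
    # "domains": each pixel shows exactly one family (lamella-like patches)
    seed: int = 0

    def __post_init__(self):
        fams = tuple(
            f if isinstance(f, FiberFamily) else FiberFamily(**f)
            for f in self.families
        )
        if not 1 <= len(fams) <= MAX_FAMILIES:
            raise ConfigError(
                f"need 1..{MAX_FAMILIES} fiber families, got {len(fams)}"
            )
        object.__setattr__(self, "families", fams)
        h, w = self.size
        if h < 2 or w < 2:
            raise ConfigError(f"size must be at least 2x2, got {self.size}")
        if self.background < 0:
            raise ConfigError("background must be >= 0")
        nm = self.noise_model
        if nm is not None:
            kind = nm.get("kind")
            if kind == "poisson":
                if nm.get("peak", 0) <= 0:
                    raise ConfigError("poisson noise needs peak > 0")
            elif kind == "gaussian":
                if nm.get("sd", 0) <= 0:
                    raise ConfigError("gaussian noise needs sd > 0")
            else:
                raise ConfigError(f"unknown noise kind {kind!r}")
        if self.mixing not in ("additive", "domains"):
            raise ConfigError(
                f"mixing must be 'additive' or 'domains', got {self.mixing!r}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size"] = list(self.size)
        d["families"] = [asdict(f) for f in self.families]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["size"] = tuple(d.get("size", (256, 256)))
        d["families"] = tuple(d.get("families", ()))
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def make_fiber_image(spec: PhantomSpec) -> GrayImage:
    """Render a fiber phantom: summed sinusoidal gratings plus background
    and noise, clipped to >= 0 and normalized.

    Each family contributes ``amplitude * (1 + sin(2 pi s / period)) / 2``
    where ``s`` is the coordinate along the family's normal, optionally
    displaced sinusoidally along the fiber axis so the local fiber angle
    oscillates by +- ``waviness`` degrees.

    With ``mixing="additive"`` the family patterns sum everywhere, so at
    pixels where two families both have steep local slope the combined
    gradient points between the two normals.  With ``mixing="domains"``
    each pixel shows exactly one family, chosen by smooth random domains -
    emulating stacked lamellae whose sheets occupy distinct patches of the
    field of view and keeping each family's orientation signature pure.
    """
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    y, x = np.mgrid[0:h, 0:w].astype(float)
    img = np.full((h, w), float(spec.background))

    if spec.mixing == "domains" and len(spec.families) > 1:
        fields = np.stack(
            [
                gaussian_filter(
                    rng.standard_normal((h, w)), max(min(h, w) / 8.0, 2.0)
                )
                for _ in spec.families
            ]
        )
        owner = np.argmax(fields, axis=0)
    else:
        owner = None

    for idx, fam in enumerate(spec.families):
        if fam.amplitude == 0:
            continue
        phi = math.radians(fam.orientation)
        psi = math.radians(fam.orientation + 90.0)
        s = x * math.cos(psi) + y * math.sin(psi)
        if fam.waviness > 0:
            t = x * math.cos(phi) + y * math.sin(phi)
            amp = math.tan(math.radians(fam.waviness)) * fam.wav_period / (2 * math.pi)
            s = s + amp * np.sin(2 * math.pi * t / fam.wav_period)
        pattern = fam.amplitude * 0.5 * (1.0 + np.sin(2 * math.pi * s / fam.period))
        if owner is not None:
            pattern = np.where(owner == idx, pattern, 0.0)
        img += pattern

    nm = spec.noise_model
    if nm is not None:
        if nm["kind"] == "gaussian":
            img = img + rng.normal(0.0, nm["sd"], img.shape)
        else:  # poisson photon counting: scale to the requested peak count
            top = img.max()
            if top <= 0:
                raise ConfigError("poisson noise needs a non-dark image")
            img = rng.poisson(img / top * nm["peak"]).astype(float)
    img = np.clip(img, 0.0, None)
    top = img.max()
    if top == 0:
        raise ConfigError("phantom rendered all-zero; nothing to normalize")
    return GrayImage(pixels=img / top, normalized=True)


def make_noise_image(size, distribution: dict, seed: int = 0) -> GrayImage:
    """An iid noise field: integer-valued Poisson photon counts, or
    continuous Gaussian noise clipped at zero.

    ``distribution`` is ``{"kind": "poisson", "mean": m}`` or
    ``{"kind": "gaussian", "mean": m, "sd": s}``.
    """
    h, w = size
    rng = np.random.default_rng(seed)
    kind = distribution.get("kind")
    if kind == "poisson":
        px = rng.poisson(distribution["mean"], (h, w)).astype(float)
    elif kind == "gaussian":
        px = rng.normal(
            distribution.get("mean", 0.0), distribution["sd"], (h, w)
        )
        px = np.clip(px, 0.0, None)
    else:
        raise ConfigError(f"unknown noise kind {kind!r}")
    return GrayImage(pixels=px, normalized=False)


def _centered_mags(field: np.ndarray) -> np.ndarray:
    fx = (field[1:-1, 2:] - field[1:-1, :-2]) / 2.0
    fy = (field[2:, 1:-1] - field[:-2, 1:-1]) / 2.0
    return np.hypot(fx, fy)


def make_dark_count_image(
    seed: int = 0,
    size: int = 256,
    blob_sigma: float = 6.0,
    dark_fraction: float = 0.5,
    median_gradient: float = 1.0,
    pin_gradient: float = 4.5,
    dark_rate: float = 0.3,
) -> GrayImage:
    """Smooth structure over dark plateaus with integer dark-count noise.

    The frame emulates a photon-counting acquisition of a specimen whose
    bright regions are smooth (signal dominates, intensities effectively
    real-valued) while roughly ``dark_fraction`` of the field of view holds
    no structure and only registers iid Poisson dark counts at
    ``dark_rate`` per pixel.  Because the dark plateaus are exactly zero,
    intensity differences there are integers, and gradient orientations
    collapse onto exact ties at 0, 45, 90 and 135 degrees - the hallmark
    noise spikes of pixel-to-pixel differentiation.  The smooth bright
    texture is isotropic (a Gaussian-filtered random field), providing a
    uniform continuum of orientations against which the spikes stand out.

    A small fixed Gaussian bump pins the maximum gradient magnitude at
    ``pin_gradient`` dark-count units so that a threshold set relative to
    the maximum is reproducible across seeds.

    Returns an unnormalized image in dark-count units.
    """
    rng = np.random.default_rng(seed)
    tex = gaussian_filter(rng.standard_normal((size, size)), blob_sigma)
    field = np.clip(tex - np.quantile(tex, dark_fraction), 0.0, None)
    mags = _centered_mags(field)
    sup = mags[mags > 0]
    sup = sup[sup > 0.02 * sup.max()]
    field *= median_gradient / np.median(sup)
    peak = _centered_mags(field).max()
    if peak > 0.8 * pin_gradient:  # keep the calibration bump on top
        field *= 0.8 * pin_gradient / peak

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    c = size // 2
    r2 = (yy - c) ** 2 + (xx - c) ** 2
    bump = np.exp(-r2 / (2.0 * 3.0**2))
    bump[r2 > (4 * 3.0) ** 2] = 0.0  # compact support: plateaus stay flat
    field += bump * (pin_gradient / _centered_mags(bump).max())

    img = field + rng.poisson(dark_rate, field.shape)
    return GrayImage(pixels=img, normalized=False)


def sample_orientation_pdf(
    a, b, c, d: float, n: int, B: int = 5, seed: int = 0
) -> OrientationPDF:
    """Draw ``n`` folded angles from a known Gaussian-plus-pedestal density
    and bin them exactly as :func:`~fiborient.orientation_pdf.build_pdf`
    would.

    Component weights are the Gaussian areas ``a_k c_k sqrt(2 pi)`` and the
    pedestal weight is ``d * 180``, normalized to a probability vector.
    Gaussian draws are wrapped at the 0/180 seam (folding makes the domain
    circular); the pedestal is uniform on (0, 180].
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    c = np.atleast_1d(np.asarray(c, dtype=float))
    if not (len(a) == len(b) == len(c)):
        raise ConfigError("a, b, c must have equal length")
    if n < 1:
        raise ConfigError("n must be >= 1")
    weights = np.append(a * c * math.sqrt(2 * math.pi), d * 180.0)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ConfigError("weights must be non-negative with positive sum")
    p = weights / weights.sum()

    rng = np.random.default_rng(seed)
    comp = rng.choice(len(p), size=n, p=p)
    angles = np.empty(n)
    ped = comp == len(a)
    angles[ped] = rng.uniform(0.0, 180.0, ped.sum())
    for i in range(len(a)):
        m = comp == i
        angles[m] = rng.normal(b[i], c[i], m.sum())
    angles = fold_angle(np.where(angles == 0.0, 180.0, angles))

    counts = bin_angles(angles, B)
    edges = np.arange(0, 181, B, dtype=float)
    return OrientationPDF(
        bin_edges=edges,
        counts=counts,
        density=counts / (n * B),
        bin_width=int(B),
        n_vectors=int(n),
    )
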