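"""Least-squares fitting of the k-Gaussian-plus-pedestal orientation model.

The orientation PDF of a fibrous texture is modelled as

    PDF(theta) = sum_k  a_k * exp(-(theta - b_k)^2 / (2 c_k^2))  +  d

where ``a_k`` is the height of the k-th Gaussian above the common pedestal
``d``, ``b_k`` the dominant orientation of the k-th fiber family (degrees),
``c_k`` its angular spread (degrees), and ``d`` absorbs the structureless
(noise) fraction of the image.  One Gaussian per dominant fiber direction:
quasi-parallel lamellae need k = 1, interwoven orthogonal families k = 2.

Fitting is performed on the circularly shifted axis (tallest bin moved to
the center of the scale) so that peaks sit away from the 0/180 seam; the
fitted centers are mapped back to the unshifted (0, 180] frame afterwards.
Model order is chosen as the least k whose goodness of fit R^2 reaches the
maximum attained over k = 1..k_max, within a small tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import optimize, stats

from .errors import ConfigError, FitError
from .gradient import fold_angle
from .orientation_pdf import OrientationPDF, shift_pdf

__all__ = [
    "GaussianPedestalModel",
    "evaluate_model",
    "fit_gaussians",
    "r_squared",
    "select_k",
]


@dataclass(frozen=True)
class GaussianPedestalModel:
    """Fitted parameters of the k-Gaussian-plus-pedestal model."""

    k: int
    a: tuple  # heights, per-degree density units
    b: tuple  # centers, degrees, in the unshifted (0, 180] frame
    c: tuple  # widths, degrees
    d: float  # pedestal, per-degree density
    r_squared: float
    ci95: dict = dc_field(default_factory=dict)  # 95% CI half-widths
    shift_applied: float = 0.0  # axis shift used during fitting, degrees
    diagnostics: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.a) == len(self.b) == len(self.c) == self.k):
            raise ConfigError("a, b, c must all have length k")
        if any(ai < 0 for ai in self.a) or self.d < 0:
            raise ConfigError("heights and pedestal must be >= 0")
        if any(ci <= 0 for ci in self.c):
            raise ConfigError("widths must be > 0")

    @property
    def no_dominant_orientation(self) -> bool:
        """True when the tallest component is indistinguishable from zero
        (its height is below twice its 95% CI half-width): the PDF is
        pedestal-only and the image has no preferred orientation."""
        if not self.ci95.get("a"):
            return False
        i = int(np.argmax(self.a))
        return self.a[i] < 2.0 * self.ci95["a"][i]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "a": list(self.a),
            "b": list(self.b),
            "c": list(self.c),
            "d": self.d,
            "r_squared": self.r_squared,
            "ci95": self.ci95,
            "shift_applied": self.shift_applied,
            "diagnostics": self.diagnostics,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_model(model: GaussianPedestalModel, theta) -> np.ndarray | float:
    """Evaluate the fitted density at angle(s) ``theta`` (degrees)."""
    th = np.asarray(theta, dtype=float)
    out = np.full(th.shape, float(model.d))
    for ai, bi, ci in zip(model.a, model.b, model.c):
        out = out + ai * np.exp(-((th - bi) ** 2) / (2.0 * ci**2))
    if np.isscalar(theta) or th.ndim == 0:
        return float(out)
    return out


def r_squared(observed, fitted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    For a least-squares fit whose model contains a free constant (the
    pedestal plays the role of an intercept) this coincides with the square
    of the Pearson correlation between observed and fitted values.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape or obs.size < 2:
        raise ConfigError("observed and fitted must have equal length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ConfigError("R^2 undefined: observed values are constant")
    ss_res = float(np.sum((obs - fit) ** 2))
    return 1.0 - ss_res / ss_tot


def _model_vec(params: np.ndarray, x: np.ndarray, k: int) -> np.ndarray:
    out = np.full(x.shape, params[-1])
    for i in range(k):
        a, b, c = params[3 * i : 3 * i + 3]
        out = out + a * np.exp(-((x - b) ** 2) / (2.0 * c**2))
    return out


def _initial_guesses(x: np.ndarray, y: np.ndarray, k: int, B: int):
    """Peak-based starting point: the k highest local maxima of a 3-bin
    circular moving average of the density."""
    pad = np.concatenate([y[-1:], y, y[:1]])
    smooth = np.convolve(pad, np.ones(3) / 3.0, mode="valid")
    left = np.roll(smooth, 1)
    right = np.roll(smooth, -1)
    is_max = (smooth >= left) & (smooth >= right)
    order = np.argsort(-smooth)
    peaks = [i for i in order if is_max[i]]
    # fall back to the tallest remaining bins if there are too few maxima
    peaks += [i for i in order if i not in peaks]
    d0 = max(float(y.min()), 0.0)
    c0 = max(2.0 * B, 8.0)
    params = []
    for i in peaks[:k]:
        a0 = max(float(smooth[i] - d0), 1e-6)
        params += [a0, float(x[i]), c0]
    return np.array(params + [d0])


def fit_gaussians(
    pdf: OrientationPDF,
    k: int,
    shift_center: float = 90.0,
    n_restarts: int = 5,
    warm_start: GaussianPedestalModel | None = None,
) -> GaussianPedestalModel:
    """Fit the k-Gaussian-plus-pedestal model to an orientation PDF.

    Bounded trust-region least squares against (bin center, density) pairs
    on the shifted axis, with up to ``n_restarts`` perturbed restarts for
    robustness.  Returns parameters with centers mapped back to the
    unshifted frame, the coefficient of determination, and linearized 95%
    confidence half-widths (Jacobian covariance with a t quantile).

    Raises
    ------
    ConfigError
        If ``k`` needs more degrees of freedom than the PDF has bins
        (requires ``n_bins >= 3k + 2``).
    FitError
        If no restart converges; carries best-so-far diagnostics.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    if pdf.n_bins < 3 * k + 2:
        raise ConfigError(
            f"k={k} needs at least {3 * k + 2} bins, PDF has {pdf.n_bins}"
        )

    work = shift_pdf(pdf, center=shift_center)
    x = work.bin_centers
    y = work.density
    B = work.bin_width
    ymax = float(y.max())

    lower = np.array([0.0, -90.0, B / 2.0] * k + [0.0])
    upper = np.array([10.0 * ymax, 270.0, 180.0] * k + [max(ymax, 1e-12)])

    starts = [_initial_guesses(x, y, k, B)]
    if warm_start is not None and warm_start.k == k - 1:
        # embed the (k-1)-component optimum: guarantees the larger model can
        # do at least as well as the smaller one
        prev = []
        for ai, bi, ci in zip(warm_start.a, warm_start.b, warm_start.c):
            prev += [ai, fold_angle(bi + work.shift), ci]
        extra_b = x[int(np.argsort(y - _model_vec(
            np.array(prev + [warm_start.d]), x, k - 1))[-1])]
        prev += [max(ymax * 0.05, 1e-6), float(extra_b), max(2.0 * B, 8.0)]
        starts.append(np.array(prev + [warm_start.d]))
    rng = np.random.default_rng(0)
    while len(starts) < n_restarts:
        p = starts[0].copy()
        p[1::3] += rng.uniform(-30, 30, size=k)  # jitter centers
        p[2::3] *= rng.uniform(0.5, 2.0, size=k)  # jitter widths
        starts.append(p)

    best = None
    failures = []
    for p0 in starts:
        p0 = np.clip(p0, lower + 1e-12, upper - 1e-12)
        try:
            res = optimize.least_squares(
                lambda p: _model_vec(p, x, k) - y,
                p0,
                bounds=(lower, upper),
                method="trf",
                max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - scipy internals
            failures.append(str(exc))
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError(
            f"all {len(starts)} fit attempts failed for k={k}",
            diagnostics={"failures": failures},
        )

    params = best.x
    fitted = _model_vec(params, x, k)
    try:
        r2 = r_squared(y, fitted)
    except ConfigError:
        r2 = float("nan")  # constant observed density: R^2 is undefined

    ci = _linearized_ci(best, y, k)
    a = tuple(float(params[3 * i]) for i in range(k))
    b_shifted = [float(params[3 * i + 1]) for i in range(k)]
    c = tuple(float(params[3 * i + 2]) for i in range(k))
    d = float(params[-1])
    b = tuple(fold_angle(bi - work.shift) for bi in b_shifted)

    return GaussianPedestalModel(
        k=k,
        a=a,
        b=b,
        c=c,
        d=d,
        r_squared=r2,
        ci95=ci,
        shift_applied=float(work.shift),
        diagnostics={
            "nfev": int(best.nfev),
            "cost": float(best.cost),
            "status": int(best.status),
            "b_shifted": b_shifted,
        },
    )


def _linearized_ci(res, y: np.ndarray, k: int) -> dict:
    """95% confidence half-widths from the Jacobian at the optimum."""
    n, p = len(y), len(res.x)
    dof = max(n - p, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = np.linalg.pinv(res.jac.T @ res.jac) * s2
        half = stats.t.ppf(0.975, dof) * np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        half = np.full(p, np.nan)
    return {
        "a": [float(half[3 * i]) for i in range(k)],
        "b": [float(half[3 * i + 1]) for i in range(k)],
        "c": [float(half[3 * i + 2]) for i in range(k)],
        "d": float(half[-1]),
    }


def select_k(
    pdf: OrientationPDF,
    k_max: int = 3,
    eps: float = 0.02,
    shift_center: float = 90.0,
) -> GaussianPedestalModel:
    """Fit k = 1..k_max and return the least k reaching the maximum R^2.

    ``eps`` is the tolerance on "reaching the maximum": the smallest k whose
    R^2 is within ``eps`` of the best R^2 attained wins.  Larger models are
    warm-started from the previous optimum so the attainable R^2 is
    non-decreasing in k.
    """
    if k_max < 1:
        raise ConfigError(f"k_max must be >= 1, got {k_max}")
    models = {}
    failures = {}
    prev = None
    for k in range(1, k_max + 1):
        if pdf.n_bins < 3 * k + 2:
            break
        try:
            m = fit_gaussians(pdf, k, shift_center=shift_center, warm_start=prev)
        except FitError as exc:
            failures[k] = str(exc)
            continue
        models[k] = m
        prev = m
    if not models:
        raise FitError("no model order could be fitted", diagnostics=failures)

    r2s = {k: m.r_squared for k, m in models.items()}
    finite = {k: v for k, v in r2s.items() if np.isfinite(v)}
    if not finite:
        # constant observed density: no order is better than the smallest
        return models[min(models)]
    best = max(finite.values())
    for k in sorted(models):
        if np.isfinite(r2s[k]) and r2s[k] >= best - eps:
            return models[k]
    return models[max(models)]  # pragma: no cover
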