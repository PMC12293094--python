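"""Derived collagen-order metrics from a fitted orientation model.

The fitted parameters condense into a few scalar descriptors of tissue
order: the area under each Gaussian (how much orientation mass is organized
around a dominant direction), the area under the pedestal (the structureless
fraction), their ratio, the angular separation of fiber families, and a
composite peak-height-to-width ratio used to track remodeling over time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .gauss_fit import GaussianPedestalModel

__all__ = [
    "OrderMetrics",
    "gaussian_areas",
    "pedestal_area",
    "area_ratio",
    "peak_separation",
    "healing_panel",
    "order_metrics",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)

#: R^2 above which a single-Gaussian fit counts as very good - used to flag
#: recovered (well-ordered) tissue in longitudinal series.
R2_THRESHOLD = 0.75


@dataclass(frozen=True)
class OrderMetrics:
    """Scalar order descriptors for one fitted model."""

    component_areas: tuple
    total_gaussian_area: float
    pedestal_area: float
    gaussian_to_pedestal_ratio: float  # inf flagged when the pedestal is 0
    peak_separations: dict  # {(i, j): |b_j - b_i| in degrees}; empty for k=1
    gaussian_height: float  # a_1 of the dominant component
    gaussian_width: float  # c_1 of the dominant component
    composite_height_width: float  # (a_1 + d) / c_1
    r_squared: float

    def to_dict(self) -> dict:
        d = {
            "component_areas": list(self.component_areas),
            "total_gaussian_area": self.total_gaussian_area,
            "pedestal_area": self.pedestal_area,
            "gaussian_to_pedestal_ratio": self.gaussian_to_pedestal_ratio,
            "gaussian_height": self.gaussian_height,
            "gaussian_width": self.gaussian_width,
            "composite_height_width": self.composite_height_width,
            "r_squared": self.r_squared,
        }
        d["peak_separations"] = {
            f"{i + 1}-{j + 1}": v for (i, j), v in self.peak_separations.items()
        }
        return d


def gaussian_areas(model: GaussianPedestalModel):
    """Areas under the Gaussian components and their algebraic sum.

    Each component integrates (over the full line) to ``a_k * c_k *
    sqrt(2*pi)``; the exact constant keeps the areas on the same scale as
    the unit PDF area.  Any fixed constant would cancel in the
    Gaussian-to-pedestal ratio.
    """
    areas = tuple(ai * ci * SQRT_2PI for ai, ci in zip(model.a, model.c))
    return areas, float(sum(areas))


def pedestal_area(model: GaussianPedestalModel) -> float:
    """Area under the pedestal over the full 180-degree orientation range."""
    return float(model.d * 180.0)


def area_ratio(model: GaussianPedestalModel) -> float:
    """Total Gaussian area over pedestal area.

    Large values mean orientation mass dominates over the structureless
    (noise) fraction; ``inf`` is returned when the pedestal is exactly zero.
    """
    _, total = gaussian_areas(model)
    ped = pedestal_area(model)
    if ped == 0:
        return float("inf") if total > 0 else float("nan")
    return total / ped


def peak_separation(model: GaussianPedestalModel) -> dict:
    """Pairwise absolute center differences |b_j - b_i| in degrees.

    Plain arithmetic differences (no circular wrap), matching how fiber
    family separations are conventionally quoted.  Empty dict for k = 1
    (not applicable).
    """
    seps = {}
    for i in range(model.k):
        for j in range(i + 1, model.k):
            seps[(i, j)] = abs(model.b[j] - model.b[i])
    return seps


def order_metrics(model: GaussianPedestalModel) -> OrderMetrics:
    """Bundle all scalar order descriptors for one model."""
    comp, total = gaussian_areas(model)
    ped = pedestal_area(model)
    i_dom = int(np.argmax(model.a)) if model.k > 1 else 0
    a1, c1 = model.a[i_dom], model.c[i_dom]
    return OrderMetrics(
        component_areas=comp,
        total_gaussian_area=total,
        pedestal_area=ped,
        gaussian_to_pedestal_ratio=area_ratio(model),
        peak_separations=peak_separation(model),
        gaussian_height=float(a1),
        gaussian_width=float(c1),
        composite_height_width=float((a1 + model.d) / c1),
        r_squared=float(model.r_squared),
    )


def healing_panel(
    models: Sequence[GaussianPedestalModel],
    labels: Sequence[str] | None = None,
    normalize_composite: bool = True,
    r2_threshold: float = R2_THRESHOLD,
) -> pd.DataFrame:
    """Longitudinal order metrics for a time-ordered series of k=1 fits.

    One row per time point with the goodness of fit, Gaussian height ``a``,
    width ``c``, and the composite ``(a + d) / c`` (total model peak height
    over width).  The composite is optionally normalized by the first
    (control) time point.  ``r2_pass`` flags fits whose R^2 clears
    ``r2_threshold``, the conventional bar for a very good single-Gaussian
    fit.

    Raises
    ------
    ConfigError
        If the series is empty or any model has k != 1.
    """
    if len(models) == 0:
        raise ConfigError("healing_panel requires at least one model")
    for m in models:
        if m.k != 1:
            raise ConfigError(
                "healing_panel expects single-Gaussian (k=1) fits, "
                f"got k={m.k}"
            )
    if labels is None:
        labels = [f"t{i}" for i in range(len(models))]
    if len(labels) != len(models):
        raise ConfigError("labels and models must have equal length")

    rows = []
    for lab, m in zip(labels, models):
        comp = (m.a[0] + m.d) / m.c[0]
        rows.append(
            {
                "time_point": lab,
                "r_squared": m.r_squared,
                "gaussian_height": m.a[0],
                "gaussian_width": m.c[0],
                "composite_height_width": comp,
                "r2_pass": bool(m.r_squared >= r2_threshold),
            }
        )
    df = pd.DataFrame(rows)
    if normalize_composite:
        df["composite_height_width"] /= df["composite_height_width"].iloc[0]
    return df
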