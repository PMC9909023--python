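"""Power-law species-area fits in log-log space.

``log S = C + z * log A`` is fitted by ordinary least squares. The slope z is
invariant to the log base and the area unit; the intercept C depends on both
(defaults: base 10, areas converted to cm² upstream so C stays positive for
realistic richness values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InvalidSpecError
from .island_models import IslandModel

__all__ = ["SARPoint", "SARFit", "fit_sar", "fit_model", "mean_slope"]

_M2_TO_CM2 = 1.0e4


@dataclass(frozen=True)
class SARPoint:
    area: float
    richness: int

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise InvalidSpecError("area must be positive")
        if self.richness < 1:
            raise InvalidSpecError("richness must be >= 1")


@dataclass(frozen=True)
class SARFit:
    """OLS fit of log(richness) on log(area)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    ci_low: float
    ci_high: float
    n_points: int
    log_base: float
    area_unit: str


def _coerce_points(points: Sequence) -> tuple[np.ndarray, np.ndarray]:
    areas, richness = [], []
    for p in points:
        if isinstance(p, SARPoint):
            areas.append(p.area)
            richness.append(p.richness)
        else:
            a, s = p
            sp = SARPoint(float(a), int(s))  # validates
            areas.append(sp.area)
            richness.append(sp.richness)
    return np.asarray(areas, dtype=float), np.asarray(richness, dtype=float)


def fit_sar(
    points: Sequence[SARPoint | tuple[float, int]],
    log_base: float = 10.0,
    area_unit: str = "cm2",
) -> SARFit:
    """Fit ``log S = C + z log A`` with a two-sided slope t-test and 95% CI.

    ``area_unit`` is a label recorded on the fit; conversion of the input
    areas is the caller's responsibility (see :func:`fit_model`).
    """
    areas, richness = _coerce_points(points)
    n = areas.size
    if n < 3:
        raise InvalidSpecError(f"need >= 3 points for SAR inference, got {n}")
    if log_base == 10.0:
        la, ls = np.log10(areas), np.log10(richness)
    elif log_base == math.e:
        la, ls = np.log(areas), np.log(richness)
    else:
        la = np.log(areas) / np.log(log_base)
        ls = np.log(richness) / np.log(log_base)
    if np.ptp(la) == 0:
        raise InvalidSpecError("zero variance in log(area); cannot fit a slope")
    res = stats.linregress(la, ls)
    tcrit = stats.t.ppf(0.975, n - 2)
    return SARFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        ci_low=float(res.slope - tcrit * res.stderr),
        ci_high=float(res.slope + tcrit * res.stderr),
        n_points=int(n),
        log_base=float(log_base),
        area_unit=area_unit,
    )


def fit_model(
    model: IslandModel,
    log_base: float = 10.0,
    area_unit: str = "cm2",
    source_unit: str = "m2",
) -> SARFit:
    """Fit one island model's (area, richness) ladder, converting area units."""
    factor = 1.0
    if source_unit == "m2" and area_unit == "cm2":
        factor = _M2_TO_CM2
    elif source_unit == "cm2" and area_unit == "m2":
        factor = 1.0 / _M2_TO_CM2
    elif source_unit != area_unit:
        raise InvalidSpecError(f"unsupported unit conversion {source_unit} -> {area_unit}")
    pts = [(g.area * factor, g.richness) for g in model.groups]
    return fit_sar(pts, log_base=log_base, area_unit=area_unit)


def mean_slope(fits: Sequence[SARFit]) -> float:
    """Arithmetic mean of the z values of several fits."""
    if not fits:
        raise InvalidSpecError("need at least one fit")
    return float(np.mean([f.slope for f in fits]))
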