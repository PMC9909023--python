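"""Random-placement richness expectation and the paired comparison to observations.

The expectation for an island of area ``a`` inside a total area ``A_T``, given
per-species individual totals ``n_i``, is

    E(S) = sum_i [ 1 - (1 - a/A_T)**n_i ]

(each bracket is the probability that at least one of species *i*'s
individuals lands on the island under uniform independent placement). It is
evaluated through ``log1p``/``expm1`` so very large ``n_i`` stay accurate.

``predict_by_class`` stratifies the expectation by abundance class, taking
``n_i`` either as a species' total count over all samples (``reads`` mode) or
as the number of samples it occupies (``incidence`` mode).

``compare_to_coleman`` runs the paired t-test of expectation against
observation, with differences defined as expectation minus observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community_data import (
    ABUNDANT,
    MODERATE,
    RARE,
    AbundanceClassification,
    AbundanceTable,
)
from .errors import EmptyTableError, InvalidSpecError
from .island_models import IslandModel

__all__ = [
    "ColemanPrediction",
    "PairedComparison",
    "coleman_expectation",
    "predict_by_class",
    "predict_for_model",
    "observed_class_richness",
    "compare_to_coleman",
]

_CLASS_ORDER = (ABUNDANT, MODERATE, RARE)


def coleman_expectation(n: Sequence[int] | np.ndarray, island_area: float, total_area: float) -> float:
    """Expected richness on an island under uniform random placement.

    Parameters
    ----------
    n
        Per-species individual totals, all >= 1.
    island_area, total_area
        ``0 <= island_area <= total_area``, ``total_area > 0``.
    """
    n = np.asarray(n, dtype=float)
    if n.size and np.any(n < 1):
        raise InvalidSpecError("all species totals must be >= 1")
    if total_area <= 0:
        raise InvalidSpecError("total_area must be positive")
    if island_area < 0 or island_area > total_area * (1 + 1e-12):
        raise InvalidSpecError("island_area must lie in [0, total_area]")
    f = min(island_area / total_area, 1.0)
    if f == 0.0 or n.size == 0:
        return 0.0
    if f == 1.0:
        return float(n.size)
    # 1 - (1-f)**n == -expm1(n * log1p(-f)), stable for large n
    return float(np.sum(-np.expm1(n * np.log1p(-f))))


@dataclass(frozen=True)
class ColemanPrediction:
    """Class-stratified expectations (and optional observations) per area."""

    frame: pd.DataFrame  # columns: abundance_class, area, class_size, expected, observed
    total_area: float
    n_mode: str

    def expected(self, abundance_class: str, area: float) -> float:
        sel = self.frame[
            (self.frame.abundance_class == abundance_class) & (self.frame.area == area)
        ]
        if sel.empty:
            raise KeyError((abundance_class, area))
        return float(sel.expected.iloc[0])


def _class_totals(
    table: AbundanceTable, classification: AbundanceClassification, n_mode: str
) -> dict[str, np.ndarray]:
    """Per class, the vector of per-species totals n_i (observed species only)."""
    if n_mode == "reads":
        totals = table.taxon_totals()
    elif n_mode == "incidence":
        totals = (table.counts > 0).sum(axis=0)
    else:
        raise InvalidSpecError(f"unknown n_mode {n_mode!r}; expected 'reads' or 'incidence'")
    out: dict[str, list[int]] = {c: [] for c in _CLASS_ORDER}
    for taxon, total in zip(table.taxon_ids, totals):
        if total > 0:
            out[classification.class_of(taxon)].append(int(total))
    return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}


def observed_class_richness(
    group_counts: np.ndarray,
    taxon_ids: Sequence[str],
    classification: AbundanceClassification,
) -> dict[str, int]:
    """Positive-taxon counts of an aggregated group, split by abundance class."""
    out = {c: 0 for c in _CLASS_ORDER}
    for taxon, c in zip(taxon_ids, np.asarray(group_counts)):
        if c > 0:
            out[classification.class_of(taxon)] += 1
    return out


def predict_by_class(
    table: AbundanceTable,
    classification: AbundanceClassification,
    areas: Sequence[float],
    total_area: float,
    n_mode: str = "reads",
    observed: Mapping[tuple[str, float], int] | None = None,
) -> ColemanPrediction:
    """Expectation per abundance class and island area.

    ``observed`` optionally maps ``(class, area)`` to an observed richness to
    attach alongside the expectation. A class with zero observed species gets
    expectation 0 and is flagged in the ``empty_class`` column.
    """
    by_class = _class_totals(table, classification, n_mode)
    rows = []
    for cls in _CLASS_ORDER:
        n = by_class[cls]
        for a in areas:
            rows.append(
                {
                    "abundance_class": cls,
                    "area": float(a),
                    "class_size": int(n.size),
                    "expected": coleman_expectation(n, float(a), total_area),
                    "observed": None if observed is None else observed.get((cls, float(a))),
                    "empty_class": n.size == 0,
                }
            )
    return ColemanPrediction(pd.DataFrame(rows), float(total_area), n_mode)


def predict_for_model(
    table: AbundanceTable,
    classification: AbundanceClassification,
    model: IslandModel,
    total_area: float,
    n_mode: str = "reads",
) -> ColemanPrediction:
    """Predict along one island model's area ladder, attaching its observations."""
    observed: dict[tuple[str, float], int] = {}
    for g in model.groups:
        per_class = observed_class_richness(g.counts, g.taxon_ids, classification)
        for cls, r in per_class.items():
            observed[(cls, float(g.area))] = r
    return predict_by_class(
        table, classification, [g.area for g in model.groups], total_area, n_mode, observed
    )


@dataclass(frozen=True)
class PairedComparison:
    """Paired t-test of expectation vs observation (differences = expected - observed)."""

    label: str
    differences: tuple[float, ...]
    mean_diff: float
    sd_diff: float
    t: float
    df: int
    p: float


def compare_to_coleman(
    observed: Sequence[float], expected: Sequence[float], label: str = ""
) -> PairedComparison:
    """Two-sided paired t-test on ``expected - observed``.

    Degenerate cases: zero spread with a nonzero mean yields an infinite t
    with p = 0 (and a warning); zero spread with zero mean yields t = 0,
    p = 1.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1:
        raise InvalidSpecError("observed and expected must be 1-D vectors of equal length")
    n = obs.size
    if n < 2:
        raise EmptyTableError("need at least 2 paired values")
    d = exp - obs
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            t, p = 0.0, 1.0
        else:
            warnings.warn(
                "zero spread in paired differences with nonzero mean; t is infinite",
                RuntimeWarning,
                stacklevel=2,
            )
            t, p = float(np.sign(mean)) * float("inf"), 0.0
    else:
        t = mean / (sd / np.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PairedComparison(label, tuple(d.tolist()), mean, sd, float(t), df, p)
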