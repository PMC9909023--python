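"""Area-nested island models built by superimposing randomly drawn samples.

An island model is an ordered series of sample groups of increasing size
(default sizes 1..K-1 for K source samples): for each size ``k``, ``k``
distinct samples are drawn uniformly at random and their count vectors and
areas are summed. Draws are independent across group sizes and across models
by default; ``nested=True`` instead takes prefixes of one random sample order
per model, and ``within_replacement=True`` permits repeated members within a
group (doubling their area and counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import stream
from .community_data import AbundanceTable, SampleAreas
from .errors import InvalidSpecError

__all__ = ["IslandGroup", "IslandModel", "build_island_models", "group_richness_points", "models_to_manifest"]


@dataclass(frozen=True)
class IslandGroup:
    """One superimposed group: member samples, summed area, aggregated counts."""

    member_ids: tuple[str, ...]
    area: float
    taxon_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise InvalidSpecError("island group needs at least one member")
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (len(self.taxon_ids),):
            raise InvalidSpecError("aggregated counts do not match taxon IDs")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "member_ids", tuple(self.member_ids))
        object.__setattr__(self, "taxon_ids", tuple(self.taxon_ids))
        self.counts.setflags(write=False)

    @property
    def size(self) -> int:
        return len(self.member_ids)

    @property
    def richness(self) -> int:
        return int(np.count_nonzero(self.counts))


@dataclass(frozen=True)
class IslandModel:
    """An ordered series of island groups of strictly increasing size and area."""

    groups: tuple[IslandGroup, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        sizes = [g.size for g in self.groups]
        areas = [g.area for g in self.groups]
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise InvalidSpecError("group sizes must be strictly increasing")
        if any(b <= a for a, b in zip(areas, areas[1:])):
            raise InvalidSpecError("group areas must be strictly increasing")
        object.__setattr__(self, "groups", tuple(self.groups))

    @property
    def areas(self) -> tuple[float, ...]:
        return tuple(g.area for g in self.groups)


def _make_group(table: AbundanceTable, areas: SampleAreas, members: Sequence[str]) -> IslandGroup:
    idx = [table.sample_index(s) for s in members]
    counts = table.counts[idx].sum(axis=0)
    area = float(sum(areas.area_of(s) for s in members))
    return IslandGroup(tuple(members), area, table.taxon_ids, counts)


def build_island_models(
    table: AbundanceTable,
    areas: SampleAreas,
    n_models: int = 8,
    group_sizes: Sequence[int] | None = None,
    seed: int = 0,
    nested: bool = False,
    within_replacement: bool = False,
) -> list[IslandModel]:
    """Draw ``n_models`` island models from a table of equal-footing samples.

    Parameters
    ----------
    group_sizes
        Sizes of the groups of each model; defaults to ``1..n_samples-1``.
    nested
        Draw one random sample order per model and use its prefixes, so
        smaller groups are subsets of larger ones.
    within_replacement
        Sample group members with replacement (repeat members contribute
        their area and counts once per occurrence).
    """
    areas.check_covers(table)
    if n_models < 1:
        raise InvalidSpecError("n_models must be >= 1")
    if group_sizes is None:
        group_sizes = list(range(1, table.n_samples))
        if not group_sizes:  # single-sample table
            group_sizes = [1]
    group_sizes = [int(k) for k in group_sizes]
    if any(k < 1 for k in group_sizes):
        raise InvalidSpecError("group sizes must be positive")
    if not within_replacement and max(group_sizes) > table.n_samples:
        raise InvalidSpecError(
            f"group size {max(group_sizes)} exceeds the {table.n_samples} available samples"
        )
    rng = stream(seed, "islands")
    sample_ids = np.array(table.sample_ids)
    models = []
    for _ in range(n_models):
        groups = []
        if nested:
            order = rng.permutation(table.n_samples)
            for k in group_sizes:
                members = sample_ids[order[:k]]
                groups.append(_make_group(table, areas, members))
        else:
            for k in group_sizes:
                members = rng.choice(sample_ids, size=k, replace=within_replacement)
                groups.append(_make_group(table, areas, members))
        models.append(IslandModel(tuple(groups), seed=seed))
    return models


def group_richness_points(models: Sequence[IslandModel]) -> list[list[tuple[float, int]]]:
    """Per model, the (area, richness) pair of every group."""
    if not models:
        raise InvalidSpecError("need at least one island model")
    return [[(g.area, g.richness) for g in m.groups] for m in models]


def models_to_manifest(models: Sequence[IslandModel]) -> pd.DataFrame:
    """Flatten models into a manifest frame (model, group, members, area, richness)."""
    rows = []
    for mi, model in enumerate(models, start=1):
        for gi, g in enumerate(model.groups, start=1):
            rows.append(
                {
                    "model": mi,
                    "group": gi,
                    "size": g.size,
                    "members": ",".join(g.member_ids),
                    "area": g.area,
                    "richness": g.richness,
                }
            )
    return pd.DataFrame(rows)
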