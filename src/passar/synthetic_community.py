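"""Synthetic regional pools, passive-sampling ("dart throwing") simulation, random trees.

The simulator provides all test inputs without external data: a regional pool
of species with a long-tailed abundance distribution is generated, and each
individual of species ``i`` independently lands on island ``j`` with
probability ``m_i * a_j / A_T`` (``m_i`` an occupancy multiplier in (0, 1])
or misses every island with the residual probability. With all multipliers at
1, island richness obeys the random-placement expectation
``E(S_j) = sum_i [1 - (1 - a_j/A_T)**n_i]`` by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from skbio import TreeNode

from ._rng import stream
from .beta_diversity import PhyloTree
from .community_data import AbundanceTable
from .errors import InvalidSpecError

__all__ = [
    "PoolSpec",
    "RegionalPool",
    "PlacementSpec",
    "generate_pool",
    "simulate_passive_sampling",
    "random_tree",
    "fisher_alpha",
    "logseries_parameter",
]


def fisher_alpha(n_species: int, total_individuals: int) -> float:
    """Solve Fisher's alpha from ``S = alpha * ln(1 + N/alpha)``."""
    S, N = float(n_species), float(total_individuals)
    if N <= S:
        raise InvalidSpecError("total individuals must exceed species count for a log-series")

    def f(a: float) -> float:
        return a * math.log1p(N / a) - S

    return float(optimize.brentq(f, 1e-9, 1e12))


def logseries_parameter(alpha: float, total_individuals: int) -> float:
    """Log-series parameter ``x = N / (N + alpha)``."""
    if alpha <= 0:
        raise InvalidSpecError("alpha must be positive")
    return total_individuals / (total_individuals + alpha)


@dataclass(frozen=True)
class PoolSpec:
    """Specification of a regional species pool.

    ``sad`` selects the species-abundance distribution: ``"logseries"``
    (parameter ``alpha``; fitted from ``n_species`` / ``total_individuals``
    when omitted) or ``"lognormal"`` (``meanlog`` / ``sdlog``).
    """

    n_species: int
    total_individuals: int
    sad: str = "logseries"
    alpha: float | None = None
    meanlog: float = 0.0
    sdlog: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise InvalidSpecError("n_species must be >= 1")
        if self.total_individuals < self.n_species:
            raise InvalidSpecError("total_individuals must be >= n_species")
        if self.sad not in ("logseries", "lognormal"):
            raise InvalidSpecError(f"unknown SAD {self.sad!r}")
        if self.alpha is not None and self.alpha <= 0:
            raise InvalidSpecError("alpha must be positive")
        if self.sdlog <= 0:
            raise InvalidSpecError("sdlog must be positive")


@dataclass(frozen=True)
class RegionalPool:
    """Taxa with positive integer abundances summing to the pool total."""

    taxon_ids: tuple[str, ...]
    abundances: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=np.int64)
        if a.ndim != 1 or a.size != len(self.taxon_ids):
            raise InvalidSpecError("abundance vector does not match taxon IDs")
        if np.any(a < 1):
            raise InvalidSpecError("every pool species needs abundance >= 1")
        object.__setattr__(self, "abundances", a)
        object.__setattr__(self, "taxon_ids", tuple(self.taxon_ids))
        self.abundances.setflags(write=False)

    @property
    def total_individuals(self) -> int:
        return int(self.abundances.sum())


@dataclass(frozen=True)
class PlacementSpec:
    """Island areas, total regional area, and per-species landing multipliers.

    ``total_area`` may exceed the summed island areas; the slack is
    environment that is never sampled, which keeps every ``a_j / A_T`` a
    proper probability. ``multipliers`` (one per pool species, values in
    (0, 1]) scale a species' landing probability uniformly across islands;
    the default of all ones is the equal-probability null.
    """

    island_areas: tuple[float, ...]
    total_area: float | None = None
    multipliers: tuple[float, ...] | None = None
    sample_ids: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        areas = tuple(float(a) for a in self.island_areas)
        if not areas or any(a <= 0 for a in areas):
            raise InvalidSpecError("island areas must be positive")
        object.__setattr__(self, "island_areas", areas)
        total = sum(areas) if self.total_area is None else float(self.total_area)
        if total < sum(areas) * (1 - 1e-12):
            raise InvalidSpecError("total_area must be >= the summed island areas")
        object.__setattr__(self, "total_area", total)
        if self.multipliers is not None:
            m = tuple(float(v) for v in self.multipliers)
            if any(not (0 < v <= 1) for v in m):
                raise InvalidSpecError("multipliers must lie in (0, 1]")
            object.__setattr__(self, "multipliers", m)
        if self.sample_ids is not None:
            ids = tuple(str(s) for s in self.sample_ids)
            if len(ids) != len(areas):
                raise InvalidSpecError("sample_ids must match island_areas in length")
            object.__setattr__(self, "sample_ids", ids)


def _integerize(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of positive weights to integers >= 1 summing to ``total``."""
    n = weights.size
    if total < n:
        raise InvalidSpecError("total below species count")
    real = weights * (total / weights.sum())
    base = np.floor(real).astype(np.int64)
    short = total - int(base.sum())
    if short:
        frac = real - base
        top = np.argsort(-frac, kind="stable")[:short]
        base[top] += 1
    # guarantee every species at least one individual, borrowing from the largest
    for z in np.flatnonzero(base == 0):
        base[int(np.argmax(base))] -= 1
        base[z] = 1
    return base


def generate_pool(spec: PoolSpec) -> RegionalPool:
    """Draw a regional pool from the configured SAD, hitting the exact total."""
    rng = stream(spec.seed, "pool")
    if spec.sad == "logseries":
        alpha = spec.alpha if spec.alpha is not None else fisher_alpha(
            spec.n_species, spec.total_individuals
        )
        x = logseries_parameter(alpha, spec.total_individuals)
        draws = stats.logser.rvs(x, size=spec.n_species, random_state=rng).astype(float)
    else:
        draws = rng.lognormal(spec.meanlog, spec.sdlog, spec.n_species)
    abundances = _integerize(draws, spec.total_individuals)
    width = max(6, len(str(spec.n_species)))
    ids = tuple(f"sp{i:0{width}d}" for i in range(1, spec.n_species + 1))
    return RegionalPool(ids, abundances)


def simulate_passive_sampling(pool: RegionalPool, placement: PlacementSpec) -> AbundanceTable:
    """Throw every pool individual at the islands; return the island-by-taxon table.

    Implemented as one multinomial draw per species over the ``k`` islands
    plus a "missed" bin — distributionally identical to per-individual
    placement. Deterministic given ``placement.seed``.
    """
    rng = stream(placement.seed, "placement")
    areas = np.asarray(placement.island_areas)
    k = areas.size
    s = len(pool.taxon_ids)
    m = (
        np.ones(s)
        if placement.multipliers is None
        else np.asarray(placement.multipliers, dtype=float)
    )
    if m.size != s:
        raise InvalidSpecError(
            f"{m.size} multipliers for {s} pool species"
        )
    p = np.empty((s, k + 1))
    p[:, :k] = np.outer(m, areas / placement.total_area)
    p[:, k] = np.maximum(1.0 - p[:, :k].sum(axis=1), 0.0)
    draws = rng.multinomial(pool.abundances, p)
    counts = draws[:, :k].T  # islands x species
    ids = placement.sample_ids or tuple(f"s{j}" for j in range(1, k + 1))
    return AbundanceTable(ids, pool.taxon_ids, counts)


def random_tree(taxon_ids: Sequence[str], seed: int = 0) -> PhyloTree:
    """Random rooted, strictly bifurcating tree over the given taxa.

    Built by repeatedly joining two uniformly chosen subtrees; every branch
    gets a length drawn uniformly from (0.1, 1.1). Deterministic given seed.
    """
    ids = [str(t) for t in taxon_ids]
    if len(ids) < 2:
        raise InvalidSpecError("need at least 2 taxa for a tree")
    if len(set(ids)) != len(ids):
        raise InvalidSpecError("taxon IDs must be unique")
    rng = stream(seed, "tree")
    nodes = [TreeNode(name=t) for t in ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = int(min(i, j)), int(max(i, j))
        right = nodes.pop(j)
        left = nodes.pop(i)
        left.length = float(rng.uniform(0.1, 1.1))
        right.length = float(rng.uniform(0.1, 1.1))
        nodes.append(TreeNode(children=[left, right]))
    root = nodes[0]
    root.length = 0.0
    return PhyloTree(root)
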