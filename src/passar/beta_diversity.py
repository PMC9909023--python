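"""Pairwise beta-diversity decomposition and UniFrac distances.

Two families of presence/absence decompositions are supported (Podani-style
replacement / richness-difference partition):

* Jaccard family:  with a shared, b and c unique taxon counts,
  ``D = (b+c)/(a+b+c)``, ``Repl = 2*min(b,c)/(a+b+c)``,
  ``RichDiff = |b-c|/(a+b+c)``, ``Sim = a/(a+b+c)``.
* Sørensen family: the same numerators over ``2a+b+c`` with ``Sim = 2a/(2a+b+c)``.

Each pair's (similarity, replacement, richness-difference) triplet sums to 1.

UniFrac distances are computed on a rooted tree with branch lengths:
unweighted compares the branch length leading to taxa present in exactly one
community against the branch length leading to taxa present in either;
weighted integrates ``length * |p_x - p_y|`` over branches (``p`` = fraction
of a community's individuals descending through the branch), divided in the
normalized variant by ``length * (p_x + p_y)``.
"""

from __future__ import annotations

import io
import itertools
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .community_data import AbundanceTable
from .errors import EmptyTableError, InvalidSpecError, MissingFileError, TaxonTreeMismatchError

__all__ = [
    "JACCARD",
    "SORENSEN",
    "BetaTriplet",
    "DecompositionSummary",
    "PhyloTree",
    "DistanceMatrix",
    "decompose_beta",
    "pairwise_decompose",
    "summarize_decomposition",
    "unweighted_unifrac",
    "weighted_unifrac",
    "unifrac_matrix",
    "read_newick",
    "write_newick",
]

JACCARD = "jaccard"
SORENSEN = "sorensen"
_FAMILIES = (JACCARD, SORENSEN)


# ---------------------------------------------------------------------------
# Replacement / richness-difference partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaTriplet:
    """One sample pair's (similarity, replacement, richness-difference)."""

    pair: tuple[str, str]
    family: str
    similarity: float
    replacement: float
    richness_difference: float

    @property
    def dissimilarity(self) -> float:
        return self.replacement + self.richness_difference


def decompose_beta(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    family: str = JACCARD,
    pair: tuple[str, str] = ("x", "y"),
) -> BetaTriplet:
    """Decompose one pair of communities over a shared taxon universe.

    ``x`` and ``y`` are aligned count (or boolean presence) vectors; counts
    are binarized internally.
    """
    if family not in _FAMILIES:
        raise InvalidSpecError(f"unknown family {family!r}; expected one of {_FAMILIES}")
    px = np.asarray(x) > 0
    py = np.asarray(y) > 0
    if px.shape != py.shape:
        raise InvalidSpecError("presence vectors must share one taxon universe")
    a = int(np.sum(px & py))
    b = int(np.sum(px & ~py))
    c = int(np.sum(~px & py))
    if a + b + c == 0:
        raise EmptyTableError("both communities are empty")
    denom = (a + b + c) if family == JACCARD else (2 * a + b + c)
    sim = (a if family == JACCARD else 2 * a) / denom
    repl = 2 * min(b, c) / denom
    rich = abs(b - c) / denom
    return BetaTriplet(tuple(pair), family, sim, repl, rich)


def pairwise_decompose(table: AbundanceTable, family: str = JACCARD) -> list[BetaTriplet]:
    """All C(n,2) sample-pair triplets of a table, in sample-ID order."""
    out = []
    for i, j in itertools.combinations(range(table.n_samples), 2):
        out.append(
            decompose_beta(
                table.counts[i],
                table.counts[j],
                family,
                pair=(table.sample_ids[i], table.sample_ids[j]),
            )
        )
    return out


@dataclass(frozen=True)
class DecompositionSummary:
    family: str
    n_pairs: int
    mean_similarity: float
    mean_replacement: float
    mean_richness_difference: float
    #: Repl / (Repl + RichDiff) over all pairs, in percent; None when every
    #: pair has zero dissimilarity.
    replacement_contribution_pct: float | None
    richness_difference_contribution_pct: float | None


def summarize_decomposition(triplets: Sequence[BetaTriplet]) -> DecompositionSummary:
    """Component means and percentage contributions aggregated over pairs."""
    if not triplets:
        raise InvalidSpecError("need at least one triplet")
    families = {t.family for t in triplets}
    if len(families) != 1:
        raise InvalidSpecError(f"mixed decomposition families: {sorted(families)}")
    repl = sum(t.replacement for t in triplets)
    rich = sum(t.richness_difference for t in triplets)
    d = repl + rich
    n = len(triplets)
    return DecompositionSummary(
        family=families.pop(),
        n_pairs=n,
        mean_similarity=sum(t.similarity for t in triplets) / n,
        mean_replacement=repl / n,
        mean_richness_difference=rich / n,
        replacement_contribution_pct=None if d == 0 else 100.0 * repl / d,
        richness_difference_contribution_pct=None if d == 0 else 100.0 * rich / d,
    )


def triplets_to_frame(triplets: Sequence[BetaTriplet]) -> pd.DataFrame:
    """Long-format table of triplets (one row per pair) for TSV export."""
    return pd.DataFrame(
        {
            "sample_a": [t.pair[0] for t in triplets],
            "sample_b": [t.pair[1] for t in triplets],
            "family": [t.family for t in triplets],
            "similarity": [t.similarity for t in triplets],
            "replacement": [t.replacement for t in triplets],
            "richness_difference": [t.richness_difference for t in triplets],
            "dissimilarity": [t.dissimilarity for t in triplets],
        }
    )


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhyloTree:
    """A rooted tree with branch lengths whose leaf labels name taxa."""

    root: TreeNode

    def __post_init__(self) -> None:
        names = [t.name for t in self.root.tips()]
        if len(names) != len(set(names)):
            raise InvalidSpecError("tree leaf labels are not unique")
        for node in self.root.traverse(include_self=False):
            if node.length is None:
                raise InvalidSpecError(f"node {node.name!r} has no branch length")
            if node.length < 0:
                raise InvalidSpecError(f"node {node.name!r} has negative branch length")

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.root.tips())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.root.tips())

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.root.write(buf)
        return buf.getvalue().strip()

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        return cls(TreeNode.read(io.StringIO(newick)))


def read_newick(path: str | os.PathLike) -> PhyloTree:
    if not os.path.exists(path):
        raise MissingFileError(str(path))
    with open(path, encoding="utf-8") as fh:
        return PhyloTree.from_newick(fh.read())


def write_newick(tree: PhyloTree, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------

def _as_count_map(x: Mapping[str, float] | None) -> Mapping[str, float]:
    if not isinstance(x, Mapping):
        raise InvalidSpecError("communities must be mappings of taxon -> count")
    return x

def _branch_loads(tree: PhyloTree, x: Mapping[str, float], y: Mapping[str, float]):
    """Yield ``(length, count_below_x, count_below_y)`` per non-root branch."""
    x = {k: v for k, v in _as_count_map(x).items() if v > 0}
    y = {k: v for k, v in _as_count_map(y).items() if v > 0}
    leaves = set(tree.leaf_names)
    for name, label in ((set(x), "x"), (set(y), "y")):
        missing = sorted(name - leaves)
        if missing:
            raise TaxonTreeMismatchError(f"taxa of {label} missing from tree: {missing}")
    if not x or not y:
        raise EmptyTableError("each community must have positive total count")

    below: dict[int, tuple[float, float]] = {}
    branches = []
    for node in tree.root.postorder(include_self=True):
        if node.is_tip():
            cx, cy = float(x.get(node.name, 0.0)), float(y.get(node.name, 0.0))
        else:
            cx = sum(below[id(ch)][0] for ch in node.children)
            cy = sum(below[id(ch)][1] for ch in node.children)
        below[id(node)] = (cx, cy)
        if node is not tree.root:
            branches.append((float(node.length), cx, cy))
    return branches, below[id(tree.root)]


def unweighted_unifrac(tree: PhyloTree, x: Mapping[str, float], y: Mapping[str, float]) -> float:
    """Unweighted UniFrac: unique branch length / covered branch length."""
    branches, _ = _branch_loads(tree, x, y)
    num = sum(L for L, cx, cy in branches if (cx > 0) != (cy > 0))
    den = sum(L for L, cx, cy in branches if cx > 0 or cy > 0)
    if den == 0:
        raise InvalidSpecError("tree has no positive branch length covering the communities")
    return num / den


def weighted_unifrac(
    tree: PhyloTree, x: Mapping[str, float], y: Mapping[str, float], normalized: bool = True
) -> float:
    """Weighted UniFrac; the normalized variant is bounded in [0, 1]."""
    branches, (tot_x, tot_y) = _branch_loads(tree, x, y)
    raw = 0.0
    den = 0.0
    for L, cx, cy in branches:
        px, py = cx / tot_x, cy / tot_y
        raw += L * abs(px - py)
        den += L * (px + py)
    if not normalized:
        return raw
    if den == 0:
        raise InvalidSpecError("tree has no positive branch length covering the communities")
    return raw / den


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a metric label."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise InvalidSpecError("distance matrix shape does not match sample IDs")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise InvalidSpecError("distance matrix must be symmetric with zero diagonal")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.sample_ids), columns=list(self.sample_ids))
        df.index.name = "sample_id"
        return df


def unifrac_matrix(
    tree: PhyloTree,
    table: AbundanceTable,
    metric: str = "unweighted",
    normalized: bool = True,
) -> DistanceMatrix:
    """Pairwise UniFrac distances between all samples of a table."""
    if metric not in ("unweighted", "weighted"):
        raise InvalidSpecError(f"unknown UniFrac metric {metric!r}")
    table.require_positive_samples()
    maps = [
        {t: int(c) for t, c in zip(table.taxon_ids, table.counts[i]) if c > 0}
        for i in range(table.n_samples)
    ]
    n = table.n_samples
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        if metric == "unweighted":
            d = unweighted_unifrac(tree, maps[i], maps[j])
        else:
            d = weighted_unifrac(tree, maps[i], maps[j], normalized=normalized)
        out[i, j] = out[j, i] = d
    label = metric if metric == "unweighted" else ("weighted" if normalized else "weighted-raw")
    return DistanceMatrix(table.sample_ids, out, f"{label}-unifrac")
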