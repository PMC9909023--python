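"""Sample-by-taxon count tables: data model, I/O, alpha diversity, abundance classes.

The :class:`AbundanceTable` is the universal input of the pipeline: a dense
non-negative integer matrix with one row per sample and one column per taxon.
Tables can be read from / written to tab-separated text (taxa as rows by
default, orientation auto-detected from the header corner cell) or a
BIOM-v1-style JSON document.

Alpha diversity follows the usual conventions: richness is the positive-taxon
count, Shannon uses natural logs, Simpson is the Gini–Simpson form
``1 - sum(p**2)``, and ACE is the abundance-based coverage estimator with a
rare-species cutoff of 10 (falling back to Chao1 when the coverage estimate
is zero, i.e. when every rare taxon is a singleton).

Taxa are assigned to abundance classes from their relative abundance over the
grand total of *all* samples combined: strictly above ``abundant_min`` is
abundant, strictly below ``rare_max`` is rare, everything else (including
exact boundary hits) is moderate.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIDError,
    EmptyTableError,
    InvalidSpecError,
    MissingAreaError,
    MissingFileError,
    NegativeCountError,
    NonIntegerCountError,
    UnknownSampleError,
)

__all__ = [
    "ABUNDANT",
    "MODERATE",
    "RARE",
    "AbundanceTable",
    "SampleAreas",
    "ClassThresholds",
    "AbundanceClassification",
    "read_table",
    "write_table",
    "read_areas",
    "write_areas",
    "classify_abundance",
    "alpha_diversity",
    "rank_abundance",
]

ABUNDANT = "abundant"
MODERATE = "moderate"
RARE = "rare"

#: header corner labels that mark a samples-as-rows orientation
_SAMPLE_ROW_CORNERS = {"sample_id", "sampleid", "sample", "samples", "#sampleid"}

_M2_TO_CM2 = 1.0e4
_AREA_UNITS = {"m2": 1.0, "cm2": 1.0 / _M2_TO_CM2}  # factors to m²


def _check_unique(ids: Sequence[str], kind: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise DuplicateIDError(f"duplicate {kind} IDs: {dups}")
    return ids


@dataclass(frozen=True)
class AbundanceTable:
    """A validated sample-by-taxon matrix of non-negative integer counts.

    Parameters
    ----------
    sample_ids, taxon_ids
        Unique identifiers for the rows and columns of ``counts``.
    counts
        Array of shape ``(n_samples, n_taxa)``; coerced to ``int64``.
    """

    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", _check_unique(self.sample_ids, "sample"))
        object.__setattr__(self, "taxon_ids", _check_unique(self.taxon_ids, "taxon"))
        raw = np.asarray(self.counts)
        if raw.ndim != 2 or raw.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise InvalidSpecError(
                f"counts shape {raw.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if raw.size:
            if not np.issubdtype(raw.dtype, np.number):
                raise NonIntegerCountError("counts contain non-numeric values")
            as_float = raw.astype(float)
            if not np.all(np.isfinite(as_float)):
                raise NonIntegerCountError("counts contain non-finite values")
            if np.any(as_float < 0):
                raise NegativeCountError("counts contain negative values")
            if not np.all(as_float == np.floor(as_float)):
                raise NonIntegerCountError("counts contain non-integer values")
        object.__setattr__(self, "counts", raw.astype(np.int64, copy=True))
        self.counts.setflags(write=False)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise UnknownSampleError(sample_id) from None

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_index(sample_id)]

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def taxon_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def require_positive_samples(self) -> None:
        """Raise :class:`EmptyTableError` if any sample has total count 0."""
        totals = self.sample_totals()
        if self.n_samples == 0 or np.any(totals == 0):
            empty = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            raise EmptyTableError(f"samples with zero total count: {empty or 'none'}")

    # -- conversions -------------------------------------------------------
    def to_dataframe(self, taxa_as_rows: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.sample_ids), columns=list(self.taxon_ids))
        if taxa_as_rows:
            df = df.T
            df.index.name = "taxon_id"
        else:
            df.index.name = "sample_id"
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, samples_as_rows: bool = False) -> "AbundanceTable":
        if not samples_as_rows:
            df = df.T
        values = df.to_numpy()
        try:
            numeric = values.astype(float)
        except (TypeError, ValueError):
            raise NonIntegerCountError("table contains non-numeric cells") from None
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), numeric)


@dataclass(frozen=True)
class SampleAreas:
    """Mapping ``sample_id -> habitat area`` with an explicit unit tag."""

    areas: Mapping[str, float]
    unit: str = "m2"

    def __post_init__(self) -> None:
        if self.unit not in _AREA_UNITS:
            raise InvalidSpecError(f"unknown area unit {self.unit!r}; expected one of {sorted(_AREA_UNITS)}")
        clean = {str(k): float(v) for k, v in self.areas.items()}
        if any(v <= 0 or not np.isfinite(v) for v in clean.values()):
            raise InvalidSpecError("all areas must be positive and finite")
        object.__setattr__(self, "areas", clean)

    def area_of(self, sample_id: str) -> float:
        try:
            return self.areas[sample_id]
        except KeyError:
            raise MissingAreaError(sample_id) from None

    def total(self, sample_ids: Sequence[str] | None = None) -> float:
        ids = self.areas.keys() if sample_ids is None else sample_ids
        return float(sum(self.area_of(s) for s in ids))

    def in_unit(self, unit: str) -> "SampleAreas":
        if unit == self.unit:
            return self
        if unit not in _AREA_UNITS:
            raise InvalidSpecError(f"unknown area unit {unit!r}")
        factor = _AREA_UNITS[self.unit] / _AREA_UNITS[unit]
        return SampleAreas({k: v * factor for k, v in self.areas.items()}, unit)

    def check_covers(self, table: AbundanceTable) -> None:
        missing = [s for s in table.sample_ids if s not in self.areas]
        if missing:
            raise MissingAreaError(f"samples without area: {missing}")


@dataclass(frozen=True)
class ClassThresholds:
    """Relative-abundance cutoffs separating abundant / moderate / rare taxa."""

    abundant_min: float = 1.0e-3
    rare_max: float = 1.0e-4

    def __post_init__(self) -> None:
        if not (0.0 < self.rare_max < self.abundant_min < 1.0):
            raise InvalidSpecError(
                f"need 0 < rare_max < abundant_min < 1, got rare_max={self.rare_max}, "
                f"abundant_min={self.abundant_min}"
            )


@dataclass(frozen=True)
class AbundanceClassification:
    """Assignment of every taxon of a table to exactly one abundance class."""

    classes: Mapping[str, str]
    thresholds: ClassThresholds = field(default_factory=ClassThresholds)

    def __post_init__(self) -> None:
        bad = {c for c in self.classes.values() if c not in (ABUNDANT, MODERATE, RARE)}
        if bad:
            raise InvalidSpecError(f"unknown abundance classes: {sorted(bad)}")
        object.__setattr__(self, "classes", dict(self.classes))

    def taxa_in(self, abundance_class: str) -> tuple[str, ...]:
        return tuple(t for t, c in self.classes.items() if c == abundance_class)

    def class_of(self, taxon_id: str) -> str:
        return self.classes[taxon_id]

    def class_sizes(self) -> dict[str, int]:
        sizes = {ABUNDANT: 0, MODERATE: 0, RARE: 0}
        for c in self.classes.values():
            sizes[c] += 1
        return sizes


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_table(path: str | os.PathLike, format: str = "tsv", orientation: str = "auto") -> AbundanceTable:
    """Read a count table from TSV or BIOM-style JSON.

    Parameters
    ----------
    format
        ``"tsv"`` or ``"biom-json"``.
    orientation
        TSV only. ``"auto"`` inspects the header corner cell (a label such as
        ``sample_id`` marks samples-as-rows; anything else, e.g. ``taxon_id``
        or ``#OTU ID``, marks taxa-as-rows). ``"taxa_as_rows"`` /
        ``"samples_as_rows"`` override the detection.
    """
    if not os.path.exists(path):
        raise MissingFileError(str(path))
    if format == "biom-json":
        return _read_biom_json(path)
    if format != "tsv":
        raise InvalidSpecError(f"unknown table format {format!r}")
    if orientation not in ("auto", "taxa_as_rows", "samples_as_rows"):
        raise InvalidSpecError(f"unknown orientation {orientation!r}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "header")  # pandas would silently rename duplicates
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    corner = (df.index.name or "").strip().lower()
    if orientation == "auto":
        samples_as_rows = corner in _SAMPLE_ROW_CORNERS
    else:
        samples_as_rows = orientation == "samples_as_rows"
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        raise NonIntegerCountError(f"non-numeric count cell in {path}") from None
    frame = pd.DataFrame(values, index=df.index, columns=df.columns)
    return AbundanceTable.from_dataframe(frame, samples_as_rows=samples_as_rows)


def write_table(table: AbundanceTable, path: str | os.PathLike, format: str = "tsv") -> None:
    """Write ``table`` so that :func:`read_table` reproduces it exactly."""
    if table.n_taxa == 0 or table.n_samples == 0:
        raise EmptyTableError("refusing to write a table without samples or taxa")
    if format == "tsv":
        df = table.to_dataframe(taxa_as_rows=True)
        df.to_csv(path, sep="\t", index_label="taxon_id")
    elif format == "biom-json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "passar",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [table.n_taxa, table.n_samples],
            "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.T.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
    else:
        raise InvalidSpecError(f"unknown table format {format!r}")


def _read_biom_json(path: str | os.PathLike) -> AbundanceTable:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    taxon_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    n_taxa, n_samples = doc["shape"]
    data = np.zeros((n_taxa, n_samples), dtype=float)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            data[int(i), int(j)] = v
    else:
        data[:, :] = np.asarray(doc["data"], dtype=float)
    return AbundanceTable(tuple(map(str, sample_ids)), tuple(map(str, taxon_ids)), data.T)


def read_areas(path: str | os.PathLike, unit: str = "m2") -> SampleAreas:
    """Read a two-column ``sample_id<TAB>area`` file."""
    if not os.path.exists(path):
        raise MissingFileError(str(path))
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise InvalidSpecError(f"areas file {path} needs two columns (sample_id, area)")
    ids = [str(s) for s in df.iloc[:, 0]]
    _check_unique(ids, "sample")
    return SampleAreas(dict(zip(ids, df.iloc[:, 1].astype(float))), unit)


def write_areas(areas: SampleAreas, path: str | os.PathLike) -> None:
    df = pd.DataFrame({"sample_id": list(areas.areas), "area": list(areas.areas.values())})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Abundance classes
# ---------------------------------------------------------------------------

def classify_abundance(
    table: AbundanceTable, thresholds: ClassThresholds | None = None
) -> AbundanceClassification:
    """Partition taxa into abundant / moderate / rare classes.

    Relative abundance of a taxon is its total count over all samples divided
    by the grand total. Strictly above ``abundant_min`` -> abundant; strictly
    below ``rare_max`` -> rare; otherwise (boundary hits included) -> moderate.
    """
    thresholds = thresholds or ClassThresholds()
    if table.grand_total == 0:
        raise EmptyTableError("cannot classify an all-zero table")
    p = table.taxon_totals() / table.grand_total
    classes = {}
    for taxon, pi in zip(table.taxon_ids, p):
        if pi > thresholds.abundant_min:
            classes[taxon] = ABUNDANT
        elif pi < thresholds.rare_max:
            classes[taxon] = RARE
        else:
            classes[taxon] = MODERATE
    return AbundanceClassification(classes, thresholds)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _gini_simpson(p: np.ndarray) -> float:
    return float(1.0 - (p**2).sum())


def _ace(counts: np.ndarray, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator (Chao & Lee), rare cutoff 10.

    When the sample coverage estimate is zero (all rare taxa are singletons)
    the estimator diverges; Chao1 is returned instead.
    """
    counts = counts[counts > 0]
    s_obs = counts.size
    rare = counts[counts <= rare_threshold]
    s_rare = rare.size
    s_abund = s_obs - s_rare
    n_rare = int(rare.sum())
    if s_rare == 0 or n_rare == 0:
        return float(s_obs)
    f = np.bincount(rare.astype(int), minlength=rare_threshold + 1)
    f1 = int(f[1])
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        f2 = int(f[2]) if len(f) > 2 else 0
        return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))
    i = np.arange(1, rare_threshold + 1)
    sum_i = float((i * (i - 1) * f[1:]).sum())
    gamma = max(
        (s_rare / c_ace) * sum_i / (n_rare * (n_rare - 1.0)) - 1.0 if n_rare > 1 else 0.0,
        0.0,
    )
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma)


def alpha_diversity(table: AbundanceTable, rare_threshold: int = 10) -> pd.DataFrame:
    """Per-sample richness, Shannon (nats), Gini–Simpson and ACE.

    Returns a DataFrame indexed by sample ID with columns
    ``richness, shannon, simpson, ace``.
    """
    table.require_positive_samples()
    rows = []
    for sid in table.sample_ids:
        c = table.sample_counts(sid)
        c = c[c > 0]
        p = c / c.sum()
        rows.append(
            {
                "richness": int(c.size),
                "shannon": _shannon(p),
                "simpson": _gini_simpson(p),
                "ace": _ace(c, rare_threshold),
            }
        )
    df = pd.DataFrame(rows, index=list(table.sample_ids))
    df.index.name = "sample_id"
    return df


def rank_abundance(table: AbundanceTable, sample_id: str) -> pd.DataFrame:
    """Descending relative-abundance ranking of one sample's positive taxa.

    Ties are broken lexicographically by taxon ID. Returns a DataFrame with
    columns ``rank, taxon_id, relative_abundance``; abundances sum to 1.
    """
    c = table.sample_counts(sample_id)
    total = int(c.sum())
    if total == 0:
        raise EmptyTableError(f"sample {sample_id!r} has zero total count")
    order = sorted(
        (i for i in range(table.n_taxa) if c[i] > 0),
        key=lambda i: (-c[i], table.taxon_ids[i]),
    )
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "taxon_id": [table.taxon_ids[i] for i in order],
            "relative_abundance": [c[i] / total for i in order],
        }
    )
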