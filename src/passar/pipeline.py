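"""End-to-end orchestration: simulate-or-load, classify, islands, SAR, null model, beta.

Every stage writes its intermediate as TSV into the configured output
directory; the run report collects the headline numbers and a provenance
block (seed, version, config hash). Given a seed, the whole run is
deterministic — no timestamps enter any artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beta_diversity import (
    JACCARD,
    SORENSEN,
    PhyloTree,
    pairwise_decompose,
    read_newick,
    summarize_decomposition,
    triplets_to_frame,
    unifrac_matrix,
    write_newick,
)
from .coleman import compare_to_coleman, observed_class_richness, predict_by_class
from .community_data import (
    AbundanceTable,
    ClassThresholds,
    SampleAreas,
    alpha_diversity,
    classify_abundance,
    rank_abundance,
    read_areas,
    read_table,
    write_areas,
    write_table,
)
from .errors import ConfigError
from .island_models import build_island_models, models_to_manifest
from .sar_fit import fit_model, mean_slope
from .synthetic_community import (
    PlacementSpec,
    PoolSpec,
    generate_pool,
    random_tree,
    simulate_passive_sampling,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "validate_inputs"]

log = logging.getLogger("passar")

_CLASS_ORDER = ("abundant", "moderate", "rare")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; exactly one of (input paths, simulation) is set."""

    out_dir: str
    seed: int = 0
    # -- inputs (load mode)
    table_path: str | None = None
    areas_path: str | None = None
    tree_path: str | None = None
    area_unit: str = "m2"
    # -- inputs (simulate mode)
    simulate: Mapping[str, Any] | None = None
    # -- analysis parameters
    abundant_min: float = 1.0e-3
    rare_max: float = 1.0e-4
    n_models: int = 8
    group_sizes: tuple[int, ...] | None = None
    nested: bool = False
    within_replacement: bool = False
    coleman_total_area: float | None = None
    n_mode: str = "reads"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        load_mode = self.table_path is not None
        sim_mode = self.simulate is not None
        if load_mode == sim_mode:
            raise ConfigError("provide exactly one of: input table path, simulation spec")
        if load_mode and self.areas_path is None:
            raise ConfigError("loading a table requires an areas file")
        if sim_mode:
            object.__setattr__(self, "simulate", dict(self.simulate))

    @classmethod
    def from_yaml(cls, path: str, **overrides: Any) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        # out_dir is excluded so identical analyses hash identically
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class RunReport:
    """Headline numbers of a run plus provenance; serialized as report.json."""

    sar_slopes: tuple[float, ...]
    mean_slope: float
    coleman_stats: dict[str, dict[str, float]]
    beta_summaries: dict[str, dict[str, float | None]]
    alpha: dict[str, dict[str, float]]
    n_beta_pairs: int
    diagnostics: tuple[str, ...]
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def validate_inputs(
    table: AbundanceTable, areas: SampleAreas, tree: PhyloTree | None = None
) -> list[str]:
    """Cross-check IDs between table, areas and tree; return warnings (no mutation)."""
    diags: list[str] = []
    missing_area = [s for s in table.sample_ids if s not in areas.areas]
    if missing_area:
        diags.append(f"samples without area: {missing_area}")
    extra_area = [s for s in areas.areas if s not in table.sample_ids]
    if extra_area:
        diags.append(f"areas for unknown samples (ignored): {extra_area}")
    if tree is not None:
        leaves = set(tree.leaf_names)
        orphans = [t for t in table.taxon_ids if t not in leaves]
        if orphans:
            shown = orphans[:10]
            diags.append(
                f"{len(orphans)} table taxa missing from tree (first {len(shown)}): {shown}"
            )
        extra_leaves = sorted(leaves - set(table.taxon_ids))
        if extra_leaves:
            diags.append(f"{len(extra_leaves)} tree leaves not in table (ignored)")
    return diags


def _simulate_inputs(config: PipelineConfig, out: str):
    sim = dict(config.simulate or {})
    n_islands = int(sim.pop("n_islands", 8))
    island_area = float(sim.pop("island_area", 0.36))
    total_area = sim.pop("total_area", None)
    make_tree = bool(sim.pop("make_tree", True))
    rare_multiplier = sim.pop("rare_multiplier", None)
    rare_cutoff = int(sim.pop("rare_cutoff", 0))
    sim.setdefault("n_species", 5000)
    sim.setdefault("total_individuals", 50 * int(sim["n_species"]))
    spec = PoolSpec(seed=config.seed, **sim)
    pool = generate_pool(spec)
    multipliers = None
    if rare_multiplier is not None:
        multipliers = np.where(pool.abundances <= rare_cutoff, float(rare_multiplier), 1.0)
    placement = PlacementSpec(
        island_areas=(island_area,) * n_islands,
        total_area=None if total_area is None else float(total_area),
        multipliers=None if multipliers is None else tuple(multipliers),
        seed=config.seed,
    )
    table = simulate_passive_sampling(pool, placement)
    areas = SampleAreas({s: island_area for s in table.sample_ids}, unit=config.area_unit)
    tree = random_tree(table.taxon_ids, seed=config.seed) if make_tree else None

    write_table(table, os.path.join(out, "table.tsv"))
    write_areas(areas, os.path.join(out, "areas.tsv"))
    pd.DataFrame({"taxon_id": pool.taxon_ids, "abundance": pool.abundances}).to_csv(
        os.path.join(out, "pool.tsv"), sep="\t", index=False
    )
    if tree is not None:
        write_newick(tree, os.path.join(out, "tree.nwk"))
    return table, areas, tree


def _load_inputs(config: PipelineConfig):
    table = read_table(config.table_path)
    areas = read_areas(config.areas_path, unit=config.area_unit)
    tree = read_newick(config.tree_path) if config.tree_path else None
    return table, areas, tree


def _coleman_stage(table, areas, classification, models, config: PipelineConfig):
    """Class-stratified expectation vs model-averaged observation, per area rung."""
    total_area = (
        config.coleman_total_area
        if config.coleman_total_area is not None
        else areas.total(table.sample_ids)
    )
    n_groups = len(models[0].groups)
    rows = []
    for gi in range(n_groups):
        area = float(np.mean([m.groups[gi].area for m in models]))
        obs = {c: [] for c in _CLASS_ORDER}
        for m in models:
            g = m.groups[gi]
            per_class = observed_class_richness(g.counts, g.taxon_ids, classification)
            for c in _CLASS_ORDER:
                obs[c].append(per_class[c])
        rows.append((area, {c: float(np.mean(v)) for c, v in obs.items()}))
    areas_ladder = [a for a, _ in rows]
    prediction = predict_by_class(
        table, classification, areas_ladder, total_area, n_mode=config.n_mode
    )
    frame = prediction.frame.copy()
    frame["observed"] = [
        dict(rows)[a][c] for c, a in zip(frame.abundance_class, frame.area)
    ]
    stats = {}
    for c in _CLASS_ORDER:
        sel = frame[frame.abundance_class == c]
        cmp = compare_to_coleman(sel.observed.to_numpy(), sel.expected.to_numpy(), label=c)
        stats[c] = {
            "mean_diff": cmp.mean_diff,
            "sd_diff": cmp.sd_diff,
            "t": cmp.t,
            "df": cmp.df,
            "p": cmp.p,
        }
    return frame, stats, total_area


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order; write intermediates and the final report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = config.out_dir
    os.makedirs(out, exist_ok=True)

    if config.simulate is not None:
        log.info("stage=simulate seed=%d", config.seed)
        table, areas, tree = _simulate_inputs(config, out)
    else:
        log.info("stage=load table=%s", config.table_path)
        table, areas, tree = _load_inputs(config)
    diagnostics = validate_inputs(table, areas, tree)
    for d in diagnostics:
        log.warning("diagnostic: %s", d)

    thresholds = ClassThresholds(config.abundant_min, config.rare_max)
    classification = classify_abundance(table, thresholds)
    pd.DataFrame(
        {"taxon_id": list(classification.classes), "abundance_class": list(classification.classes.values())}
    ).to_csv(os.path.join(out, "classification.tsv"), sep="\t", index=False)

    alpha = alpha_diversity(table)
    alpha.to_csv(os.path.join(out, "alpha_diversity.tsv"), sep="\t")
    ranks = pd.concat(
        [rank_abundance(table, s).assign(sample_id=s) for s in table.sample_ids],
        ignore_index=True,
    )
    ranks.to_csv(os.path.join(out, "rank_abundance.tsv"), sep="\t", index=False)

    log.info("stage=islands n_models=%d", config.n_models)
    models = build_island_models(
        table,
        areas,
        n_models=config.n_models,
        group_sizes=config.group_sizes,
        seed=config.seed,
        nested=config.nested,
        within_replacement=config.within_replacement,
    )
    models_to_manifest(models).to_csv(os.path.join(out, "islands_manifest.tsv"), sep="\t", index=False)

    log.info("stage=sar")
    fits = [fit_model(m, source_unit=areas.unit) for m in models]
    fit_frame = pd.DataFrame(
        {
            "model": np.arange(1, len(fits) + 1),
            "z": [f.slope for f in fits],
            "C": [f.intercept for f in fits],
            "r2": [f.r_squared for f in fits],
            "p": [f.p_value for f in fits],
            "ci_lo": [f.ci_low for f in fits],
            "ci_hi": [f.ci_high for f in fits],
        }
    )
    fit_frame.to_csv(os.path.join(out, "sar_fits.tsv"), sep="\t", index=False)

    log.info("stage=coleman n_mode=%s", config.n_mode)
    coleman_frame, coleman_stats, total_area = _coleman_stage(
        table, areas, classification, models, config
    )
    coleman_frame.to_csv(os.path.join(out, "coleman_comparison.tsv"), sep="\t", index=False)
    pd.DataFrame(coleman_stats).T.rename_axis("abundance_class").to_csv(
        os.path.join(out, "coleman_stats.tsv"), sep="\t"
    )

    log.info("stage=beta")
    beta_summaries = {}
    n_pairs = 0
    for family in (SORENSEN, JACCARD):
        triplets = pairwise_decompose(table, family)
        n_pairs = len(triplets)
        triplets_to_frame(triplets).to_csv(
            os.path.join(out, f"beta_triplets_{family}.tsv"), sep="\t", index=False
        )
        s = summarize_decomposition(triplets)
        beta_summaries[family] = {
            "mean_similarity": s.mean_similarity,
            "mean_replacement": s.mean_replacement,
            "mean_richness_difference": s.mean_richness_difference,
            "replacement_contribution_pct": s.replacement_contribution_pct,
            "richness_difference_contribution_pct": s.richness_difference_contribution_pct,
        }

    if tree is not None:
        log.info("stage=unifrac")
        for metric in ("unweighted", "weighted"):
            dm = unifrac_matrix(tree, table, metric=metric)
            dm.to_dataframe().to_csv(os.path.join(out, f"unifrac_{metric}.tsv"), sep="\t")

    report = RunReport(
        sar_slopes=tuple(f.slope for f in fits),
        mean_slope=mean_slope(fits),
        coleman_stats=coleman_stats,
        beta_summaries=beta_summaries,
        alpha={s: {k: float(v) for k, v in row.items()} for s, row in alpha.iterrows()},
        n_beta_pairs=n_pairs,
        diagnostics=tuple(diagnostics),
        provenance={
            "seed": config.seed,
            "version": __version__,
            "config_hash": config.digest(),
            "coleman_total_area": total_area,
            "n_mode": config.n_mode,
        },
    )
    with open(os.path.join(out, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_summary(report, os.path.join(out, "summary.txt"))
    return report


def _write_summary(report: RunReport, path: str) -> None:
    lines = [
        "passar run summary",
        f"  seed: {report.provenance['seed']}  config: {report.provenance['config_hash']}",
        f"  mean SAR slope over {len(report.sar_slopes)} models: {report.mean_slope:.4f}",
        "  paired expectation-vs-observation (expected - observed):",
    ]
    for cls, st in report.coleman_stats.items():
        lines.append(
            f"    {cls:9s} mean={st['mean_diff']:.4f} sd={st['sd_diff']:.4f} "
            f"t={st['t']:.3f} df={st['df']:.0f} p={st['p']:.4f}"
        )
    for family, s in report.beta_summaries.items():
        pct = s["replacement_contribution_pct"]
        pct_s = "n/a" if pct is None else f"{pct:.1f}%"
        lines.append(f"  {family}: replacement contribution {pct_s} over {report.n_beta_pairs} pairs")
    for d in report.diagnostics:
        lines.append(f"  warning: {d}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
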