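"""One-shot orchestration of the full analysis.

read -> summarise -> heuristic search -> collapse -> consensus ->
bootstrap/Bremer -> character mapping & segment rates -> Gower/PCoA/
heatmap -> time-scaling & record gaps; every stage seeds its own RNG
deterministically from the global seed, so re-running a config reproduces
every output file.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import charevo, chronostrat, consensus, disparity, parsimony
from .matrix import (CharacterMatrix, read_categories_tsv, read_groups_tsv,
                     read_nexus, read_ranges_tsv, write_table_tsv,
                     write_trees_newick)
from .search import SearchConfig, heuristic_search


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31)."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    matrix_path: str
    outdir: str
    categories_path: Optional[str] = None
    groups_path: Optional[str] = None
    ranges_path: Optional[str] = None
    outgroup: Optional[str] = None   # default: first matrix taxon
    search: SearchConfig = field(default_factory=SearchConfig)
    bootstrap_n: int = 100
    bootstrap_replicates: int = 2
    bootstrap_hold: int = 5
    bremer_max_k: int = 3
    policy: str = "acctran"
    epsilon_ma: float = 0.5
    seed: int = 1

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        search = SearchConfig(**raw.pop("search", {}))
        cfg = cls(search=search, **raw)
        cfg.search.seed = derive_seed(cfg.seed, "search")
        return cfg


def run_pipeline(config: PipelineConfig, log=print) -> dict:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    def stage(name):
        log(f"[morphoclad] stage: {name}")

    stage("read")
    matrix = read_nexus(config.matrix_path)
    outgroup = config.outgroup or matrix.taxa[0]
    if outgroup not in matrix.taxa:
        raise ValueError(f"outgroup {outgroup!r} not in matrix")
    categories = (read_categories_tsv(config.categories_path)
                  if config.categories_path else None)
    groups = read_groups_tsv(config.groups_path) if config.groups_path else None
    ranges = read_ranges_tsv(config.ranges_path) if config.ranges_path else None

    stage("summarize")
    s = matrix.summarize()
    summary["matrix"] = {
        "n_taxa": s.n_taxa, "n_characters": s.n_characters,
        "n_cells": s.n_cells, "n_states_total": s.n_states_total,
        "pct_unknown": round(s.pct_unknown, 3),
        "pct_inapplicable": round(s.pct_inapplicable, 3),
        "pct_missing": round(s.pct_missing, 3),
        "pct_polymorphic": round(s.pct_polymorphic, 3),
    }

    stage("search")
    cfg = SearchConfig(
        n_replicates=config.search.n_replicates,
        hold_per_replicate=config.search.hold_per_replicate,
        seed=derive_seed(config.seed, "search"),
        collapse_rule=config.search.collapse_rule,
        max_trees_total=config.search.max_trees_total)
    mpts = heuristic_search(matrix, cfg, outgroup=outgroup)
    write_trees_newick(mpts.trees, out / "mpts.nwk", lengths=True)
    fit = parsimony.ensemble_fit(mpts.trees[0], matrix)
    fit_excl = parsimony.ensemble_fit(mpts.trees[0], matrix,
                                      include_uninformative=False)
    write_table_tsv(fit.to_frame(), out / "character_fit.tsv")
    summary["parsimony"] = {
        "mpt_count": len(mpts), "tree_length": mpts.length,
        "ci": round(fit.ci, 4), "ri": round(fit.ri, 4),
        "ci_informative_only": round(fit_excl.ci, 4),
        "ri_informative_only": round(fit_excl.ri, 4),
        "n_uninformative": sum(1 for f in fit.per_character
                               if not f.informative),
    }

    stage("consensus")
    strict = consensus.strict_consensus(mpts, outgroup=outgroup)
    major = consensus.majority_consensus(mpts, outgroup=outgroup)
    n_internal = sum(1 for n in strict.postorder()
                     if not n.is_leaf and n.parent is not None)
    summary["consensus"] = {"strict_internal_branches": n_internal}

    stage("support")
    boot = consensus.bootstrap_support(
        matrix, n_pseudoreplicates=config.bootstrap_n,
        seed=derive_seed(config.seed, "bootstrap"),
        config=SearchConfig(n_replicates=config.bootstrap_replicates,
                            hold_per_replicate=config.bootstrap_hold,
                            seed=derive_seed(config.seed, "bootstrap")),
        outgroup=outgroup)
    brem = consensus.bremer_support(
        matrix, mpts, max_k=config.bremer_max_k, outgroup=outgroup,
        method="auto",
        config=SearchConfig(seed=derive_seed(config.seed, "bremer"),
                            n_replicates=max(2, cfg.n_replicates // 5),
                            hold_per_replicate=200))
    table = boot
    for b, vals in brem.rows.items():
        table.set(b, **vals)
    annotated = table.annotate(strict)
    write_trees_newick([annotated], out / "strict_consensus.nwk",
                       supports=True)
    write_trees_newick([major], out / "majority_consensus.nwk")
    table.to_frame().to_csv(out / "support.tsv", sep="\t", index=False)
    strict_bips = strict.bipartitions(ref=outgroup)
    high = sum(1 for b in strict_bips
               if (table.get(b, "bootstrap_pct") or 0) > 80)
    summary["support"] = {"n_bootstrap_gt80": high}

    stage("character mapping")
    recs, homoplasy = charevo.optimize_all(strict, matrix, config.policy)
    write_table_tsv(homoplasy, out / "character_transitions.tsv")
    if groups:
        cat_map = categories or {
            c.id: c.category for c in matrix.characters if c.category}
        if cat_map:
            rates = charevo.segment_rates(strict, matrix, groups,
                                          categories=cat_map,
                                          policy=config.policy)
            write_table_tsv(rates.rates, out / "segment_rates.tsv")
            write_table_tsv(rates.category_stats, out / "rate_table.tsv")
            summary["rates"] = {
                "overall_mean_per_group":
                    {g: round(float(v), 4)
                     for g, v in rates.overall_means.items()},
                "policy": config.policy,
            }

    stage("disparity")
    recoded = matrix.recode_for_distance()
    dm = disparity.gower_distance(recoded)
    ord_ = disparity.pcoa(dm)
    order = disparity.base_to_apex_order(strict)
    heat = disparity.similarity_heatmap_export(dm, order)
    write_table_tsv(dm.to_frame(), out / "gower_distance.tsv")
    write_table_tsv(ord_.coordinates, out / "pcoa_coordinates.tsv")
    write_table_tsv(heat, out / "gower_similarity_heatmap.tsv")
    pct12 = float(ord_.proportion_explained[:2].sum() * 100) \
        if len(ord_.proportion_explained) >= 2 else 100.0
    summary["disparity"] = {
        "pct_variance_axes_1_2": round(pct12, 2),
        "pct_variance_axes_1_2_abs_denominator": round(
            float(ord_.proportion_explained_abs[:2].sum() * 100), 2),
        "n_negative_eigenvalues": int((ord_.eigenvalues < 0).sum()),
    }

    if ranges:
        stage("chronostratigraphy")
        ts = chronostrat.timescale(strict, ranges,
                                   epsilon_ma=config.epsilon_ma)
        gaps = chronostrat.record_gaps(ranges)
        write_trees_newick([ts.tree], out / "timescaled.nwk", lengths=True)
        with open(out / "record_gaps.tsv", "w", encoding="utf-8") as fh:
            fh.write("older_ma\tyounger_ma\tduration_myr\n")
            for a, b in gaps:
                fh.write(f"{a:g}\t{b:g}\t{a - b:g}\n")
        summary["chronostrat"] = {
            "root_age_ma": round(ts.root_age(), 3),
            "n_record_gaps": len(gaps),
            "longest_gap_myr": round(max((a - b for a, b in gaps),
                                         default=0.0), 3),
        }

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    stage("done")
    return summary
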