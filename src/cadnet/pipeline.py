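"""End-to-end orchestration: variants -> interactome -> co-expression ->
shortest-path subnetwork -> hubs -> over-representation.

A single :class:`PipelineConfig` (typically loaded from YAML) holds every
threshold of the analysis: per-source confidence cutoffs, the expression
prevalence rule, the MI significance target, the hub fraction and the ORA
alpha.  :func:`run_pipeline` executes the stages in order, writes each
stage's tabular output under ``outdir`` and returns a run manifest with
per-stage row counts; the whole run is deterministic given ``rng_seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .coexpression import calibrate_null, default_n_bins, infer_coexpression
from .enrichment import read_gmt, run_ora, write_enrichment
from .interactome import (
    DEFAULT_THRESHOLDS,
    expressed_genes,
    filter_by_score,
    merge_interactome,
    prune_to_expressed,
    read_scored_edges,
)
from .subnetwork import connected_restriction, shortest_path_edge_union
from .topology import node_topology, non_seed_hubs, select_hubs, write_topology
from .variants import (
    DEFAULT_CONSEQUENCES,
    DEFAULT_P_MAX,
    DEFAULT_TRAITS,
    read_catalog,
    seed_genes,
    select_variants,
    write_seed_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Typed, range-checked configuration for one pipeline run."""

    catalog: str
    expression: str
    edge_files: dict[str, str]  # source name -> path
    gmt_files: list[str]
    outdir: str = "cadnet_out"
    traits: tuple[str, ...] = DEFAULT_TRAITS
    consequences: frozenset[str] = DEFAULT_CONSEQUENCES
    p_max: float = DEFAULT_P_MAX
    score_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    min_tpm: float = 0.0
    min_fraction: float = 0.8
    n_bins: int | None = None
    n_permutations: int = 100_000
    p_target: float = 1e-15
    tail_fraction: float = 0.1
    hub_fraction: float = 0.01
    ora_alpha: float = 0.05
    min_set_size: int = 5
    universe: str = "interactome"  # or "expressed"
    rng_seed: int = 0

    _VALID_KEYS = None  # populated below

    def __post_init__(self) -> None:
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must be in (0, 1)")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if not 0 < self.hub_fraction < 1:
            raise ValueError("hub_fraction must be in (0, 1)")
        if not 0 < self.ora_alpha < 1:
            raise ValueError("ora_alpha must be in (0, 1)")
        if not 0 < self.p_target < 1:
            raise ValueError("p_target must be in (0, 1)")
        if not 0 < self.tail_fraction < 0.5:
            raise ValueError("tail_fraction must be in (0, 0.5)")
        if self.universe not in ("interactome", "expressed"):
            raise ValueError("universe must be 'interactome' or 'expressed'")
        self.consequences = frozenset(self.consequences)
        self.traits = tuple(self.traits)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["consequences"] = sorted(self.consequences)
        d["traits"] = list(self.traits)
        return d


_FIELD_NAMES = {f.name for f in dataclasses.fields(PipelineConfig)}


def validate_config(raw: Mapping[str, Any] | str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a mapping or a YAML file path.

    Unknown keys raise an error that lists the valid keys; out-of-range
    values raise from the dataclass validation naming the bound.
    """
    if isinstance(raw, (str, Path)):
        with open(raw) as fh:
            raw = yaml.safe_load(fh)
    unknown = set(raw) - _FIELD_NAMES
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: "
            f"{sorted(_FIELD_NAMES)}"
        )
    config = PipelineConfig(**raw)
    for path in [config.catalog, config.expression, *config.edge_files.values(),
                 *config.gmt_files]:
        if not Path(path).exists():
            raise FileNotFoundError(f"configured input does not exist: {path}")
    return config


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; write outputs and a JSON manifest under outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "version": __version__,
        "rng_seed": config.rng_seed,
        "stages": {},
    }

    # 1. seed genes from the association catalog
    records = read_catalog(config.catalog)
    selected = select_variants(
        records, config.traits, config.consequences, config.p_max
    )
    seeds = seed_genes(selected)
    write_seed_table(seeds, selected, outdir / "seed_genes.tsv")
    manifest["stages"]["variant_selection"] = {
        "catalog_rows": len(records),
        "selected_variants": len(selected),
        "seed_genes": len(seeds),
    }

    # 2. tissue-specific PPI backbone
    expr = pd.read_csv(config.expression, sep="\t", index_col=0)
    expressed = expressed_genes(expr, config.min_tpm, config.min_fraction)
    raw_edges = []
    for source, path in sorted(config.edge_files.items()):
        raw_edges.extend(read_scored_edges(path, source))
    thresholded = filter_by_score(raw_edges, config.score_thresholds)
    pruned = prune_to_expressed(thresholded, expressed)
    manifest["stages"]["interactome_assembly"] = {
        "raw_edges": len(raw_edges),
        "post_threshold": len(thresholded),
        "expressed_genes": len(expressed),
        "post_pruning": len(pruned),
    }

    # 3. MI co-expression between seeds and all expressed genes
    expr_kept = expr.loc[sorted(set(expr.index) & expressed)]
    calib = calibrate_null(
        expr_kept,
        n_bins=config.n_bins,
        n_permutations=config.n_permutations,
        p_target=config.p_target,
        tail_fraction=config.tail_fraction,
        rng_seed=config.rng_seed,
    )
    coexpr = infer_coexpression(expr_kept, seeds, calib, n_bins=config.n_bins)
    with open(outdir / "mi_calibration.json", "w") as fh:
        json.dump(
            {
                "n_permutations": calib.n_permutations,
                "p_target": calib.p_target,
                "mi_threshold": calib.mi_threshold,
                "tail_intercept": calib.intercept,
                "tail_slope": calib.slope,
                "tail_fraction": calib.tail_fraction,
                "extrapolated": calib.extrapolated,
                "rng_seed": calib.rng_seed,
            },
            fh,
            indent=1,
        )
    pd.DataFrame(
        [
            {
                "seed": e.gene_a if e.gene_a in seeds.genes else e.gene_b,
                "partner": e.gene_b if e.gene_a in seeds.genes else e.gene_a,
                "mi_score": e.score,
            }
            for e in coexpr
        ],
        columns=["seed", "partner", "mi_score"],
    ).to_csv(outdir / "coexpression_edges.tsv", sep="\t", index=False)
    manifest["stages"]["coexpression"] = {
        "mi_threshold": calib.mi_threshold,
        "coexpression_edges": len(coexpr),
    }

    # 4. merged interactome
    interactome = merge_interactome(pruned, coexpr)
    interactome.write(outdir / "interactome_edges.tsv")
    manifest["stages"]["interactome"] = {
        "nodes": len(interactome.nodes),
        "edges": interactome.n_edges,
    }

    # 5. all-shortest-paths subnetwork between seeds
    graph = interactome.to_networkx()
    union = shortest_path_edge_union(graph, seeds)
    sub = connected_restriction(union)
    sub.write(outdir / "subnetwork_nodes.tsv", outdir / "subnetwork_edges.tsv")
    manifest["stages"]["subnetwork"] = {
        "nodes": len(sub.nodes),
        "edges": len(sub.edges),
        "component_report": sub.component_report,
        "skipped_pairs": sub.skipped_pairs,
    }

    # 6. hubs
    topology = node_topology(sub)
    hubs = select_hubs(topology, config.hub_fraction)
    novel = non_seed_hubs(hubs)
    write_topology(topology, hubs, outdir / "node_topology.tsv")
    manifest["stages"]["topology"] = {
        "hubs": len(hubs),
        "non_seed_hubs": [h.gene for h in novel],
    }

    # 7. over-representation of the subnetwork genes
    collections = []
    for path in config.gmt_files:
        collections.extend(read_gmt(path))
    universe = (
        interactome.nodes if config.universe == "interactome" else expressed
    )
    results = run_ora(
        sub.nodes, universe, collections, config.ora_alpha, config.min_set_size
    )
    write_enrichment(results, outdir / "enrichment.tsv")
    manifest["stages"]["enrichment"] = {
        "sets_tested": len(results),
        "significant": sum(r.significant for r in results),
    }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
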