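"""Deterministic synthetic fixtures for every pipeline input.

One :class:`FixtureConfig` drives four generators — expression matrix,
GWAS-catalog table, per-source PPI edge lists, and GMT gene-set
collections — each drawing from its own fixed-offset substream of a single
seed, so any generator can be re-run in isolation and all artifacts are
byte-identical under the same seed.  Ground-truth labels (which catalog
rows pass the filters, which genes share a co-expression module, which
gene sets were planted, which bridge node connects the seeds) are emitted
alongside the data so that every downstream stage can be scored exactly.

Expression is simulated on a latent-factor log scale: members of module m
follow x_g = loading * z_m + eps_g with a shared standard-normal latent
z_m per sample and Gaussian noise eps_g, then exponentiated to a
non-negative, right-skewed TPM-like scale.  A configurable fraction of
genes outside the modules is zeroed in more than 20% of samples to
exercise the expression-prevalence filter.  Seed connectivity is
guaranteed by a star of unscored interactions from one non-seed "bridge"
gene to every seed, mimicking a high-degree connector hub.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSet, write_gmt
from .interactome import GENETIC, PHYSICAL

TARGET_TRAITS = (
    "Coronary artery disease",
    "Coronary heart disease",
    "Ischemic heart disease",
)
DECOY_TRAITS = ("Type 2 diabetes", "Body mass index", "Rheumatoid arthritis")
PASS_CONSEQUENCES = ("missense_variant", "stop_gained")
DECOY_CONSEQUENCES = (
    "intron_variant",
    "synonymous_variant",
    "3_prime_UTR_variant",
    "intergenic_variant",
)

SCORED_SOURCES = ("string", "mentha", "intact")
UNSCORED_SOURCE = "biogrid"

# fixed substream offsets: each generator is independently reproducible
_STREAM_OFFSETS = {"expression": 1, "gwas": 2, "ppi": 3, "gmt": 4}


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module."""

    size: int
    loading: float  # latent-factor loading in [0, 1]
    noise_sd: float


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic fixture.

    Defaults match the analysis conditions: 240 tissue samples, planted
    modules with loading 0.95 and noise SD 0.1 containing the seed genes,
    and score ranges that straddle each source's confidence threshold.
    """

    n_genes: int = 300
    n_samples: int = 240
    n_seed_genes: int = 6
    modules: tuple[ModuleSpec, ...] = (
        ModuleSpec(12, 0.95, 0.1),
        ModuleSpec(12, 0.95, 0.1),
        ModuleSpec(12, 0.0, 1.0),
    )
    n_edges_per_source: Mapping[str, int] = field(
        default_factory=lambda: {
            "string": 400,
            "mentha": 300,
            "intact": 300,
            "biogrid": 200,
        }
    )
    score_range: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "string": (0.4, 1.0),
            "mentha": (0.2, 1.0),
            "intact": (0.2, 1.0),
        }
    )
    n_catalog_rows: int = 60
    fraction_pass_filters: float = 0.2
    planted_sets: tuple[tuple[str, float], ...] = (
        ("PLANTED_SEED_NEIGHBORHOOD", 1.0),
        ("PLANTED_PARTIAL_OVERLAP", 0.5),
    )
    n_decoy_sets: int = 30
    set_size: int = 15
    fraction_unexpressed: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples, self.n_seed_genes) <= 0:
            raise ValueError("n_genes, n_samples and n_seed_genes must be > 0")
        for m in self.modules:
            if m.size <= 0 or not 0 <= m.loading <= 1 or m.noise_sd < 0:
                raise ValueError(f"invalid module spec {m}")
        if not 0 <= self.fraction_pass_filters <= 1:
            raise ValueError("fraction_pass_filters must be in [0, 1]")
        if not 0 <= self.fraction_unexpressed <= 1:
            raise ValueError("fraction_unexpressed must be in [0, 1]")
        for name, frac in self.planted_sets:
            if not 0 <= frac <= 1:
                raise ValueError(f"planted set {name!r}: overlap fraction {frac}")
        for src, (lo, hi) in self.score_range.items():
            if not 0 <= lo <= hi <= 1:
                raise ValueError(f"score_range for {src!r} must be within [0, 1]")
        total = sum(m.size for m in self.modules)
        reserved = max(total, self.n_seed_genes) + 1  # modules + bridge gene
        n_low = int(self.fraction_unexpressed * self.n_genes)
        if reserved + n_low > self.n_genes:
            raise ValueError(
                "n_genes too small for the configured modules, seeds and "
                "unexpressed fraction"
            )

    # --- derived layout -------------------------------------------------
    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed * 8 + _STREAM_OFFSETS[stream])

    @property
    def genes(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    @property
    def module_members(self) -> list[list[str]]:
        out, start = [], 0
        for m in self.modules:
            out.append(self.genes[start : start + m.size])
            start += m.size
        return out

    @property
    def seed_gene_names(self) -> list[str]:
        """Seeds are spread round-robin over the dependent (loading > 0)
        modules so that cross-module seed pairs have no direct
        co-expression edge; any overflow comes from non-module genes."""
        dependent = [
            members
            for spec, members in zip(self.modules, self.module_members)
            if spec.loading > 0
        ]
        names: list[str] = []
        depth = 0
        while len(names) < self.n_seed_genes and any(
            depth < len(m) for m in dependent
        ):
            for members in dependent:
                if depth < len(members) and len(names) < self.n_seed_genes:
                    names.append(members[depth])
            depth += 1
        total = sum(m.size for m in self.modules)
        spare = iter(self.genes[total:])
        while len(names) < self.n_seed_genes:
            names.append(next(spare))
        return names

    @property
    def bridge_gene(self) -> str:
        in_modules = sum(m.size for m in self.modules)
        taken = set(self.seed_gene_names)
        for g in self.genes[in_modules:]:
            if g not in taken:
                return g
        raise ValueError("no gene left outside modules/seeds for the bridge")

    @property
    def unexpressed_genes(self) -> list[str]:
        n_low = int(self.fraction_unexpressed * self.n_genes)
        return self.genes[self.n_genes - n_low :] if n_low else []


def generate_expression(config: FixtureConfig) -> pd.DataFrame:
    """TPM-like genes x samples matrix with planted latent-factor modules."""
    rng = config.rng("expression")
    genes = config.genes
    samples = [f"S{i:03d}" for i in range(1, config.n_samples + 1)]
    log_expr = rng.normal(0.0, 1.0, size=(config.n_genes, config.n_samples))
    start = 0
    for m in config.modules:
        z = rng.normal(0.0, 1.0, size=config.n_samples)
        noise = rng.normal(0.0, m.noise_sd, size=(m.size, config.n_samples))
        log_expr[start : start + m.size] = m.loading * z + noise
        start += m.size
    tpm = np.exp(log_expr)
    low = set(config.unexpressed_genes)
    for i, gene in enumerate(genes):
        if gene in low:
            # zero in >20% of samples, so the prevalence filter drops it
            zero_frac = rng.uniform(0.25, 0.6)
            n_zero = int(round(zero_frac * config.n_samples))
            idx = rng.choice(config.n_samples, size=n_zero, replace=False)
            tpm[i, idx] = 0.0
    return pd.DataFrame(tpm, index=pd.Index(genes, name="gene"), columns=samples)


def generate_gwas_table(config: FixtureConfig) -> tuple[pd.DataFrame, dict]:
    """Catalog-style association rows with a known-passing subset.

    Exactly ``round(fraction_pass_filters * n_catalog_rows)`` rows pass the
    trait/consequence/p-value filters, and their mapped genes cover exactly
    the configured seed genes; every other row deterministically fails at
    least one filter.  Ground truth lists the passing variant IDs and the
    seed genes.
    """
    rng = config.rng("gwas")
    n = config.n_catalog_rows
    k = int(round(config.fraction_pass_filters * n))
    seed_names = config.seed_gene_names

    rows = []
    passing_ids = []
    if k > 0:
        gene_slots: list[list[str]] = [[] for _ in range(k)]
        for j, gene in enumerate(seed_names):
            gene_slots[j % k].append(gene)
        for slot in gene_slots:
            if not slot:
                slot.append(seed_names[int(rng.integers(len(seed_names)))])
        if all(len(s) == 1 for s in gene_slots):
            # make at least one multi-gene mapped field to exercise splitting
            extra = seed_names[int(rng.integers(len(seed_names)))]
            if extra not in gene_slots[0]:
                gene_slots[0].append(extra)
    for i in range(n):
        rsid = f"rs{100000 + i}"
        study = f"GCST90{i % 10:04d}"
        if i < k:
            sep = str(rng.choice([", ", " - ", "; "]))
            rows.append(
                {
                    "SNPS": rsid,
                    "MAPPED_GENE": sep.join(gene_slots[i]),
                    "DISEASE/TRAIT": str(rng.choice(TARGET_TRAITS)),
                    "CONTEXT": str(rng.choice(PASS_CONSEQUENCES)),
                    "P-VALUE": f"{10 ** rng.uniform(-12, -5.05):.3g}",
                    "STUDY ACCESSION": study,
                }
            )
            passing_ids.append(rsid)
        else:
            mode = rng.choice(["trait", "context", "pvalue"])
            trait = str(
                rng.choice(DECOY_TRAITS if mode == "trait" else TARGET_TRAITS)
            )
            context = str(
                rng.choice(DECOY_CONSEQUENCES if mode == "context" else PASS_CONSEQUENCES)
            )
            p = 10 ** rng.uniform(-12, -5.05) if mode != "pvalue" else 10 ** rng.uniform(-5, -1)
            gene = str(rng.choice(config.genes))
            rows.append(
                {
                    "SNPS": rsid,
                    "MAPPED_GENE": gene,
                    "DISEASE/TRAIT": trait,
                    "CONTEXT": context,
                    "P-VALUE": f"{p:.3g}",
                    "STUDY ACCESSION": study,
                }
            )
    order = rng.permutation(n)
    table = pd.DataFrame([rows[i] for i in order])
    truth = {"passing_variants": sorted(passing_ids), "seed_genes": seed_names}
    return table, truth


def _sample_pairs(
    rng: np.random.Generator, genes: Sequence[str], n: int
) -> list[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()
    while len(pairs) < n:
        i, j = rng.integers(0, len(genes), size=2)
        if i == j:
            continue
        a, b = genes[int(i)], genes[int(j)]
        pairs.add((a, b) if a < b else (b, a))
    return sorted(pairs)


def generate_ppi_sources(
    config: FixtureConfig,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Per-source edge tables in each repository's column dialect.

    Scored sources draw uniform scores from their configured range, so a
    range ending at or below the source threshold yields zero surviving
    edges.  The BioGRID-style table is unscored, carries an
    interaction-type column, and additionally contains a star of physical
    interactions from the bridge gene to every seed, guaranteeing that all
    seeds share one post-threshold connected component.
    """
    rng = config.rng("ppi")
    genes = config.genes
    frames: dict[str, pd.DataFrame] = {}
    truth: dict = {"edge_counts": {}, "bridge_gene": config.bridge_gene}

    for source in SCORED_SOURCES:
        n = config.n_edges_per_source.get(source, 0)
        lo, hi = config.score_range.get(source, (0.0, 1.0))
        pairs = _sample_pairs(rng, genes, n)
        scores = rng.uniform(lo, hi, size=len(pairs))
        a_col, b_col, s_col = {
            "string": ("protein1", "protein2", "combined_score"),
            "mentha": ("Gene A", "Gene B", "Score"),
            "intact": ("gene_a", "gene_b", "confidence"),
        }[source]
        frames[source] = pd.DataFrame(
            {
                a_col: [p[0] for p in pairs],
                b_col: [p[1] for p in pairs],
                s_col: [f"{s:.4f}" for s in scores],
            }
        )
        truth["edge_counts"][source] = len(pairs)

    n_bio = config.n_edges_per_source.get(UNSCORED_SOURCE, 0)
    pairs = _sample_pairs(rng, genes, n_bio)
    kinds = [str(rng.choice([PHYSICAL, GENETIC])) for _ in pairs]
    backbone = [
        (min(config.bridge_gene, s), max(config.bridge_gene, s))
        for s in config.seed_gene_names
    ]
    all_pairs = pairs + [p for p in backbone if p not in set(pairs)]
    all_kinds = kinds + [PHYSICAL] * (len(all_pairs) - len(pairs))
    frames[UNSCORED_SOURCE] = pd.DataFrame(
        {
            "Official Symbol Interactor A": [p[0] for p in all_pairs],
            "Official Symbol Interactor B": [p[1] for p in all_pairs],
            "Experimental System Type": all_kinds,
        }
    )
    truth["edge_counts"][UNSCORED_SOURCE] = len(all_pairs)
    truth["backbone_edges"] = [list(p) for p in backbone]
    return frames, truth


def generate_gmt(config: FixtureConfig) -> tuple[list[GeneSet], dict]:
    """Planted and decoy gene sets over the gene universe.

    Planted sets take the configured fraction of their members from the
    seed neighborhood — an ordered list of the seeds themselves, the bridge
    gene and the seeds' module partners, consumed front-first so that a
    high overlap fraction guarantees the seeds are covered; decoy sets are
    uniform draws from the whole universe.
    """
    rng = config.rng("gmt")
    universe = config.genes
    seeds = config.seed_gene_names
    partners = [
        g
        for members in config.module_members
        for g in members
        if g not in set(seeds)
    ]
    neighborhood = seeds + [config.bridge_gene] + partners
    outside = sorted(set(universe) - set(neighborhood))
    sets: list[GeneSet] = []
    for name, frac in config.planted_sets:
        n_in = min(int(round(frac * config.set_size)), len(neighborhood))
        members = neighborhood[:n_in]
        members += list(
            rng.choice(outside, size=config.set_size - n_in, replace=False)
        )
        sets.append(GeneSet(name, "planted", frozenset(members)))
    for i in range(config.n_decoy_sets):
        members = rng.choice(universe, size=config.set_size, replace=False)
        sets.append(GeneSet(f"DECOY_{i:03d}", "decoy", frozenset(members)))
    truth = {
        "planted_sets": {s.name: sorted(s.members) for s in sets[: len(config.planted_sets)]},
        "neighborhood": neighborhood,
    }
    return sets, truth


def write_fixture(config: FixtureConfig, outdir: str | Path) -> dict[str, Path]:
    """Write all four inputs plus ground_truth.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    expr = generate_expression(config)
    paths["expression"] = outdir / "expression.tsv"
    expr.to_csv(paths["expression"], sep="\t", float_format="%.6g")

    catalog, gwas_truth = generate_gwas_table(config)
    paths["catalog"] = outdir / "catalog.tsv"
    catalog.to_csv(paths["catalog"], sep="\t", index=False)

    frames, ppi_truth = generate_ppi_sources(config)
    for source, frame in frames.items():
        paths[source] = outdir / f"{source}.tsv"
        frame.to_csv(paths[source], sep="\t", index=False)

    sets, gmt_truth = generate_gmt(config)
    paths["gmt"] = outdir / "sets.gmt"
    write_gmt(sets, paths["gmt"])

    truth = {
        **gwas_truth,
        **ppi_truth,
        **gmt_truth,
        "module_members": config.module_members,
        "module_loadings": [m.loading for m in config.modules],
        "unexpressed_genes": config.unexpressed_genes,
        "rng_seed": config.rng_seed,
    }
    paths["ground_truth"] = outdir / "ground_truth.json"
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
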