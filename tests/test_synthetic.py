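"""The fixture generators: determinism, ground-truth bookkeeping, planted
statistical structure."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cadnet.coexpression import discretize, mutual_information
from cadnet.enrichment import read_gmt, write_gmt
from cadnet.interactome import filter_by_score, merge_interactome, read_scored_edges
from cadnet.synthetic import (
    FixtureConfig,
    ModuleSpec,
    generate_expression,
    generate_gmt,
    generate_gwas_table,
    generate_ppi_sources,
    write_fixture,
)
from cadnet.variants import read_catalog, seed_genes, select_variants


def _pair_mi(expr: pd.DataFrame, a: str, b: str, n_bins: int = 15) -> float:
    pa = discretize(expr.loc[a].to_numpy(), n_bins)
    pb = discretize(expr.loc[b].to_numpy(), n_bins)
    return mutual_information(pa, pb).mi


def test_fixture_is_byte_identical_under_fixed_seed(tmp_path, fixture_config):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    p1 = write_fixture(fixture_config, d1)
    p2 = write_fixture(fixture_config, d2)
    assert p1.keys() == p2.keys()
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key


def test_invalid_config_dimensions_rejected():
    with pytest.raises(ValueError):
        FixtureConfig(n_genes=0)
    with pytest.raises(ValueError):
        FixtureConfig(fraction_pass_filters=1.5)
    with pytest.raises(ValueError):
        FixtureConfig(modules=(ModuleSpec(10, 1.5, 0.1),))
    with pytest.raises(ValueError):
        # modules + unexpressed tail cannot fit into the gene universe
        FixtureConfig(n_genes=30, modules=(ModuleSpec(29, 0.9, 0.1),))


def test_catalog_pass_fraction_is_exact_and_roundtrips(fixture_dir, fixture_config, ground_truth):
    records = read_catalog(fixture_dir / "catalog.tsv")
    assert len(records) == fixture_config.n_catalog_rows
    selected = select_variants(records)
    expected = round(
        fixture_config.fraction_pass_filters * fixture_config.n_catalog_rows
    )
    assert len(selected) == expected
    assert sorted(r.variant_id for r in selected) == ground_truth["passing_variants"]
    assert seed_genes(selected).genes == set(ground_truth["seed_genes"])


def test_zero_pass_fraction_yields_empty_selection():
    config = FixtureConfig(fraction_pass_filters=0.0)
    table, truth = generate_gwas_table(config)
    assert truth["passing_variants"] == []
    target = {
        "Coronary artery disease",
        "Coronary heart disease",
        "Ischemic heart disease",
    }
    passing = table[
        table["DISEASE/TRAIT"].isin(target)
        & table["CONTEXT"].isin(["missense_variant", "stop_gained"])
        & (table["P-VALUE"].astype(float) < 1e-5)
    ]
    assert passing.empty


def test_high_loading_module_pairs_beat_random_pairs(expression, ground_truth):
    """Every within-module pair's MI exceeds the 95th percentile of MI
    between unrelated gene pairs (loading 0.95, noise 0.1, 240 samples)."""
    rng = np.random.default_rng(7)
    module = ground_truth["module_members"][0]
    free = [
        g
        for g in expression.index
        if not any(g in m for m in ground_truth["module_members"])
        and g not in ground_truth["unexpressed_genes"]
    ]
    null = [
        _pair_mi(expression, *rng.choice(free, size=2, replace=False))
        for _ in range(200)
    ]
    cutoff = np.quantile(null, 0.95)
    for a, b in itertools.combinations(module, 2):
        assert _pair_mi(expression, a, b) > cutoff


def test_zero_loading_module_pairs_look_independent(expression, ground_truth):
    loadings = ground_truth["module_loadings"]
    idx = loadings.index(0.0)
    module = ground_truth["module_members"][idx]
    rng = np.random.default_rng(11)
    free = [
        g
        for g in expression.index
        if not any(g in m for m in ground_truth["module_members"])
        and g not in ground_truth["unexpressed_genes"]
    ]
    null = [
        _pair_mi(expression, *rng.choice(free, size=2, replace=False))
        for _ in range(200)
    ]
    mis = [
        _pair_mi(expression, a, b) for a, b in itertools.combinations(module, 2)
    ]
    assert np.median(mis) < np.quantile(null, 0.95)


def test_unexpressed_genes_are_zero_in_over_20pct(expression, ground_truth):
    for gene in ground_truth["unexpressed_genes"]:
        zero_frac = (expression.loc[gene] == 0).mean()
        assert zero_frac > 0.2


def test_ppi_union_connects_all_seeds_and_counts_match(fixture_dir, ground_truth):
    edges = []
    for source in ("string", "mentha", "intact", "biogrid"):
        source_edges = read_scored_edges(fixture_dir / f"{source}.tsv", source)
        assert len(source_edges) == ground_truth["edge_counts"][source]
        edges.extend(source_edges)
    graph = merge_interactome(filter_by_score(edges)).to_networkx()
    seeds = ground_truth["seed_genes"]
    component = nx.node_connected_component(graph, seeds[0])
    assert set(seeds) <= component


def test_string_score_range_below_threshold_leaves_no_edges(tmp_path):
    config = FixtureConfig(
        score_range={"string": (0.0, 0.7), "mentha": (0.2, 1.0), "intact": (0.2, 1.0)}
    )
    frames, _ = generate_ppi_sources(config)
    path = tmp_path / "string.tsv"
    frames["string"].to_csv(path, sep="\t", index=False)
    kept = filter_by_score(read_scored_edges(path, "string"))
    assert kept == []


def test_gmt_roundtrip_preserves_membership(tmp_path, fixture_config):
    sets, _ = generate_gmt(fixture_config)
    path = tmp_path / "sets.gmt"
    write_gmt(sets, path)
    back = read_gmt(path)
    assert {s.name: s.members for s in back} == {s.name: s.members for s in sets}


def test_expression_matrix_is_tpm_like(expression, fixture_config):
    assert expression.shape == (fixture_config.n_genes, fixture_config.n_samples)
    assert (expression.to_numpy() >= 0).all()
    assert expression.index.is_unique
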