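"""Extraction of the all-shortest-paths subnetwork between seed genes.

For every unordered pair of seed genes in the same component, every edge
lying on at least one minimum-hop path between them is collected; the union
over all pairs is the subnetwork.  Membership of an edge (u, v) on a
shortest s-t path is decided from the two BFS distance maps alone:

    d(s, u) + 1 + d(v, t) == d(s, t)   (in either edge orientation)

so path counts never need to be enumerated.  The search is unweighted —
confidence scores never act as edge weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class Subnetwork:
    """Node/edge subset of the interactome flagged with seed membership."""

    graph: nx.Graph
    seeds: set[str]
    component_report: list[tuple[int, int]] = field(default_factory=list)
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(min(u, v), max(u, v)) for u, v in self.graph.edges}

    def node_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": n, "is_seed": n in self.seeds} for n in sorted(self.graph.nodes)
        ]
        return pd.DataFrame(rows, columns=["gene", "is_seed"])

    def edge_frame(self) -> pd.DataFrame:
        rows = [{"gene_a": a, "gene_b": b} for a, b in sorted(self.edges)]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b"])

    def write(self, node_path: str | Path, edge_path: str | Path) -> None:
        self.node_frame().to_csv(node_path, sep="\t", index=False)
        self.edge_frame().to_csv(edge_path, sep="\t", index=False)


def bfs_distances(graph: nx.Graph, source: str) -> dict[str, int]:
    """Hop distances from ``source``; unreachable nodes are absent."""
    if source not in graph:
        raise KeyError(f"source node {source!r} not in graph")
    return dict(nx.single_source_shortest_path_length(graph, source))


def shortest_path_edge_union(graph: nx.Graph, seeds) -> Subnetwork:
    """Union of all shortest-path edges over every co-component seed pair.

    ``seeds`` may be a :class:`~cadnet.variants.SeedGeneSet` or any iterable
    of gene symbols.  Seed pairs with no connecting path are recorded in
    ``skipped_pairs`` with a warning, not an error.
    """
    gene_iter = getattr(seeds, "genes", seeds)
    present = sorted(set(gene_iter) & set(graph.nodes))
    absent = sorted(set(gene_iter) - set(graph.nodes))
    if absent:
        logger.warning("seeds absent from the interactome, skipped: %s", absent)
    if len(present) < 2:
        raise ValueError("need at least two seed genes present in the graph")

    dist = {s: bfs_distances(graph, s) for s in present}
    kept_edges: set[tuple[str, str]] = set()
    skipped: list[tuple[str, str]] = []
    for s, t in combinations(present, 2):
        ds, dt = dist[s], dist[t]
        if t not in ds:
            skipped.append((s, t))
            continue
        total = ds[t]
        for u, v in graph.edges:
            du_s, dv_s = ds.get(u), ds.get(v)
            if du_s is None or dv_s is None:
                continue
            du_t, dv_t = dt.get(u), dt.get(v)
            if (du_s + 1 + dv_t == total) or (dv_s + 1 + du_t == total):
                kept_edges.add((min(u, v), max(u, v)))
    if skipped:
        logger.warning("%d seed pairs had no connecting path", len(skipped))

    sub = nx.Graph()
    sub.add_edges_from(kept_edges)
    for u, v in kept_edges:
        prov = graph.edges[u, v].get("provenance")
        if prov is not None:
            sub.edges[u, v]["provenance"] = prov
    seed_set = set(present)
    for n in sub.nodes:
        sub.nodes[n]["is_seed"] = n in seed_set
    report = [
        (len(c), len(c & seed_set))
        for c in sorted(nx.connected_components(sub), key=lambda c: -len(c))
    ]
    return Subnetwork(sub, seed_set, component_report=report, skipped_pairs=skipped)


def connected_restriction(sub: Subnetwork) -> Subnetwork:
    """Restrict the union to its most seed-rich connected component.

    Ties on seed count break toward the larger component, then toward the
    component with the lexicographically smallest member.  Dropped
    components stay listed in ``component_report``.
    """
    components = list(nx.connected_components(sub.graph))
    if len(components) <= 1:
        return sub
    best = min(
        components,
        key=lambda c: (-len(c & sub.seeds), -len(c), min(c)),
    )
    dropped = [c for c in components if c is not best]
    logger.info(
        "connected restriction dropped %d components (%d nodes)",
        len(dropped),
        sum(len(c) for c in dropped),
    )
    g = sub.graph.subgraph(best).copy()
    report = [
        (len(c), len(c & sub.seeds))
        for c in sorted(components, key=lambda c: -len(c))
    ]
    return Subnetwork(
        g,
        seeds=sub.seeds & best,
        component_report=report,
        skipped_pairs=list(sub.skipped_pairs),
    )
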