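"""Assembly of a tissue-specific molecular interaction network.

Scored protein-protein interaction edge lists from several public-repository
dialects are read, filtered at per-source confidence thresholds, merged with
unscored genetic/physical interactions, and pruned to the genes expressed in
the tissue of interest.  The expression rule is prevalence-based: a gene
counts as expressed when its TPM exceeds ``min_tpm`` in at least
``min_fraction`` of the samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

PHYSICAL = "physical"
GENETIC = "genetic"
COEXPRESSION = "coexpression"
EDGE_KINDS = (PHYSICAL, GENETIC, COEXPRESSION)

#: Per-source minimum confidence; edges must score STRICTLY above these.
DEFAULT_THRESHOLDS: Mapping[str, float] = {
    "string": 0.7,
    "mentha": 0.5,
    "intact": 0.45,
}

#: Column-name maps for the tabular dialect each repository distributes.
DEFAULT_DIALECTS: Mapping[str, Mapping[str, str]] = {
    "string": {"gene_a": "protein1", "gene_b": "protein2", "score": "combined_score"},
    "mentha": {"gene_a": "Gene A", "gene_b": "Gene B", "score": "Score"},
    "intact": {"gene_a": "gene_a", "gene_b": "gene_b", "score": "confidence"},
    "biogrid": {
        "gene_a": "Official Symbol Interactor A",
        "gene_b": "Official Symbol Interactor B",
        "kind": "Experimental System Type",
    },
}


class ConfigurationError(ValueError):
    """An input file, source name or threshold map is inconsistent."""


@dataclass(frozen=True)
class ScoredEdge:
    """One undirected gene-gene association with provenance.

    Endpoints are stored in lexicographic order so that (a, b) and (b, a)
    denote the same edge.  ``score`` is ``None`` for sources that do not
    provide a confidence score.
    """

    gene_a: str
    gene_b: str
    score: float | None
    source: str
    kind: str = PHYSICAL

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-loop edge on {self.gene_a!r}")
        if self.kind not in EDGE_KINDS:
            raise ValueError(f"unknown edge kind {self.kind!r}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class Interactome:
    """Merged undirected network over gene symbols.

    ``edges`` maps each unordered gene pair to the set of
    ``(source, kind, score)`` provenance tuples supporting it.
    """

    edges: dict[tuple[str, str], frozenset[tuple[str, str, float | None]]] = field(
        default_factory=dict
    )

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for (a, b), prov in self.edges.items():
            g.add_edge(a, b, provenance=prov)
        return g

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), prov in sorted(self.edges.items()):
            sources = sorted({p[0] for p in prov})
            kinds = sorted({p[1] for p in prov})
            scores = [p[2] for p in prov if p[2] is not None]
            rows.append(
                {
                    "gene_a": a,
                    "gene_b": b,
                    "sources": ";".join(sources),
                    "kinds": ";".join(kinds),
                    "max_score": max(scores) if scores else "",
                }
            )
        return pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "sources", "kinds", "max_score"]
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_scored_edges(
    path: str | Path,
    source: str,
    dialect: Mapping[str, str] | None = None,
    default_kind: str = PHYSICAL,
) -> list[ScoredEdge]:
    """Read one repository's edge table into normalized undirected edges.

    ``dialect`` maps the logical fields ``gene_a``/``gene_b`` and optionally
    ``score`` and ``kind`` onto the file's column headers; when omitted the
    source's default dialect is used.  Self-loops are dropped (counted in the
    log); duplicate rows are collapsed silently with a logged count.
    """
    if dialect is None:
        if source not in DEFAULT_DIALECTS:
            raise ConfigurationError(
                f"unknown source {source!r}; known sources: {sorted(DEFAULT_DIALECTS)}"
            )
        dialect = DEFAULT_DIALECTS[source]
    table = pd.read_csv(path, sep="\t", dtype=str)
    for logical in ("gene_a", "gene_b"):
        if dialect[logical] not in table.columns:
            raise ConfigurationError(
                f"{path}: missing column {dialect[logical]!r} for field {logical}"
            )
    score_col = dialect.get("score")
    if score_col is not None and score_col not in table.columns:
        raise ConfigurationError(f"{path}: missing score column {score_col!r}")
    kind_col = dialect.get("kind")

    edges: list[ScoredEdge] = []
    seen: set[tuple] = set()
    n_loops = n_dups = 0
    for idx, row in enumerate(table.itertuples(index=False)):
        rec = dict(zip(table.columns, row))
        a = str(rec[dialect["gene_a"]]).strip().upper()
        b = str(rec[dialect["gene_b"]]).strip().upper()
        if a == b:
            n_loops += 1
            continue
        score = None
        if score_col is not None:
            try:
                score = float(rec[score_col])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: malformed score {rec[score_col]!r} at row {idx}"
                ) from exc
        kind = str(rec[kind_col]).strip() if kind_col is not None else default_kind
        edge = ScoredEdge(a, b, score, source, kind)
        key = (edge.gene_a, edge.gene_b, edge.score, edge.kind)
        if key in seen:
            n_dups += 1
            continue
        seen.add(key)
        edges.append(edge)
    if n_loops:
        logger.info("%s: dropped %d self-loop rows", path, n_loops)
    if n_dups:
        logger.info("%s: collapsed %d duplicate rows", path, n_dups)
    return edges


def filter_by_score(
    edges: Iterable[ScoredEdge],
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
) -> list[ScoredEdge]:
    """Keep scored edges strictly above their source threshold.

    Unscored edges (``score is None``, e.g. BioGRID genetic/physical
    interactions) pass through unconditionally.  A scored edge whose source
    has no threshold entry is a configuration error.
    """
    kept: list[ScoredEdge] = []
    for edge in edges:
        if edge.score is None:
            kept.append(edge)
            continue
        if edge.source not in thresholds:
            raise ConfigurationError(
                f"scored edge from source {edge.source!r} has no threshold entry"
            )
        if edge.score > thresholds[edge.source]:
            kept.append(edge)
    return kept


def expressed_genes(
    expr: pd.DataFrame, min_tpm: float = 0.0, min_fraction: float = 0.8
) -> set[str]:
    """Genes with TPM strictly above ``min_tpm`` in at least
    ``min_fraction`` of samples (inclusive boundary, sample count by ceiling).
    """
    if expr.empty:
        raise ValueError("expression matrix is empty")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    n_samples = expr.shape[1]
    # guard against float fuzz pushing ceil(0.8 * 240) above 192
    needed = math.ceil(min_fraction * n_samples - 1e-9)
    counts = (expr.to_numpy() > min_tpm).sum(axis=1)
    return {g for g, c in zip(expr.index, counts) if c >= needed}


def prune_to_expressed(
    edges: Iterable[ScoredEdge], expressed: set[str]
) -> list[ScoredEdge]:
    """Keep only edges whose both endpoints are expressed in the tissue."""
    return [e for e in edges if e.gene_a in expressed and e.gene_b in expressed]


def merge_interactome(*edge_lists: Sequence[ScoredEdge]) -> Interactome:
    """Union one or more edge lists into a deduplicated interactome.

    Provenance of an unordered pair is the union of its (source, kind, score)
    tuples; the result is invariant to the order of the input lists.
    """
    merged: dict[tuple[str, str], set[tuple[str, str, float | None]]] = {}
    for edges in edge_lists:
        for e in edges:
            merged.setdefault(e.pair, set()).add((e.source, e.kind, e.score))
    return Interactome({pair: frozenset(prov) for pair, prov in merged.items()})
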