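"""Over-representation analysis of gene sets with BH-FDR control.

Each GMT gene set is restricted to the background universe and its overlap
with the query is scored by the upper-tail hypergeometric probability
P(X >= k) with population N, K successes and n draws.  P-values are pooled
across all loaded collections and adjusted by the Benjamini-Hochberg
step-up procedure; a set is called significant when FDR < alpha (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_SET_SIZE = 5


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of one gene set."""

    set_name: str
    universe_size: int
    set_size: int
    query_size: int
    overlap: int
    overlap_genes: frozenset[str]
    p_value: float
    fdr: float = float("nan")
    significant: bool = False


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file (name TAB description TAB member genes...).

    Blank lines are skipped; duplicate members within a line are collapsed.
    A line with fewer than three fields is a parse error naming the line.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "expected name, description and at least one gene"
                )
            name, description, *genes = fields
            members = frozenset(g.strip().upper() for g in genes if g.strip())
            sets.append(GeneSet(name, description, members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def hypergeom_overrep(
    query: set[str], universe: set[str], gene_set: GeneSet
) -> EnrichmentResult:
    """Upper-tail hypergeometric p for the query/set overlap in the universe."""
    if not universe:
        raise ValueError("universe is empty")
    if not query:
        raise ValueError("query is empty")
    stray = query - universe
    if stray:
        logger.warning(
            "%d query genes outside the universe were dropped", len(stray)
        )
    q = query & universe
    members = gene_set.members & universe
    n_universe, n_set, n_query = len(universe), len(members), len(q)
    overlap = q & members
    k = len(overlap)
    p = float(hypergeom.sf(k - 1, n_universe, n_set, n_query))
    return EnrichmentResult(
        set_name=gene_set.name,
        universe_size=n_universe,
        set_size=n_set,
        query_size=n_query,
        overlap=k,
        overlap_genes=frozenset(overlap),
        p_value=min(1.0, max(p, np.nextafter(0, 1))),
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ora(
    query: set[str],
    universe: set[str],
    collections: Sequence[GeneSet],
    alpha: float = DEFAULT_ALPHA,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> list[EnrichmentResult]:
    """Test every gene set and adjust pooled p-values by BH.

    Sets smaller than ``min_set_size`` after universe restriction are
    excluded before testing (and logged).  Results are sorted by FDR, then
    p, then set name; ``significant`` means FDR < alpha strictly.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    tested: list[EnrichmentResult] = []
    n_excluded = 0
    for gs in collections:
        if len(gs.members & universe) < min_set_size:
            n_excluded += 1
            continue
        tested.append(hypergeom_overrep(query, universe, gs))
    if n_excluded:
        logger.info(
            "excluded %d gene sets below min_set_size=%d after universe "
            "restriction",
            n_excluded,
            min_set_size,
        )
    if not tested:
        return []
    fdrs = bh_adjust([r.p_value for r in tested])
    results = [
        EnrichmentResult(
            set_name=r.set_name,
            universe_size=r.universe_size,
            set_size=r.set_size,
            query_size=r.query_size,
            overlap=r.overlap,
            overlap_genes=r.overlap_genes,
            p_value=r.p_value,
            fdr=float(f),
            significant=bool(f < alpha),
        )
        for r, f in zip(tested, fdrs)
    ]
    results.sort(key=lambda r: (r.fdr, r.p_value, r.set_name))
    return results


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    rows = [
        {
            "set_name": r.set_name,
            "universe_size": r.universe_size,
            "set_size": r.set_size,
            "query_size": r.query_size,
            "overlap": r.overlap,
            "p_value": r.p_value,
            "fdr": r.fdr,
            "significant": r.significant,
            "overlap_genes": ";".join(sorted(r.overlap_genes)),
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "universe_size",
            "set_size",
            "query_size",
            "overlap",
            "p_value",
            "fdr",
            "significant",
            "overlap_genes",
        ],
    ).to_csv(path, sep="\t", index=False)
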