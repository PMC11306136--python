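"""Selection of GWAS seed genes from an association-catalog table.

Rows of a GWAS-Catalog-style association file are filtered on trait
(case-insensitive exact match), variant consequence (sequence-ontology
terms; "nonsense" is taken as ``stop_gained``) and association p-value
(strict ``<``).  The unique genes mapped by the surviving variants form
the seed set that anchors the downstream subnetwork extraction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_TRAITS = (
    "Coronary artery disease",
    "Coronary heart disease",
    "Ischemic heart disease",
)
DEFAULT_CONSEQUENCES = frozenset({"missense_variant", "stop_gained"})
DEFAULT_P_MAX = 1e-5

#: Logical field -> GWAS Catalog association-file header.
DEFAULT_CATALOG_COLUMNS: Mapping[str, str] = {
    "variant": "SNPS",
    "gene": "MAPPED_GENE",
    "trait": "DISEASE/TRAIT",
    "context": "CONTEXT",
    "p_value": "P-VALUE",
    "study": "STUDY ACCESSION",
}

#: Separators used in multi-gene mapped-gene fields.
GENE_SEPARATORS = (",", ";", " - ")


class SchemaError(ValueError):
    """A required column is absent from the catalog file."""


@dataclass(frozen=True)
class VariantRecord:
    """One SNP-trait association row."""

    variant_id: str
    mapped_genes: tuple[str, ...]
    trait: str
    context: str
    p_value: float
    study_accession: str = ""


@dataclass
class SeedGeneSet:
    """Deduplicated seed genes with per-gene supporting variants."""

    genes: set[str] = field(default_factory=set)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def _split_genes(raw: str) -> tuple[str, ...]:
    pattern = "|".join(re.escape(s) for s in GENE_SEPARATORS)
    parts = [p.strip().upper() for p in re.split(pattern, raw)]
    return tuple(dict.fromkeys(p for p in parts if p))


def read_catalog(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[VariantRecord]:
    """Parse a GWAS-Catalog-style TSV into variant records.

    Multi-gene mapped fields are split on comma, semicolon and ``" - "``;
    symbols are upper-cased and trimmed.  Rows with an empty gene field are
    dropped with a warning (intergenic mappings cannot seed the network).
    """
    cols = dict(DEFAULT_CATALOG_COLUMNS)
    if dialect:
        cols.update(dialect)
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for logical in ("variant", "gene", "trait", "context", "p_value"):
        if cols[logical] not in table.columns:
            raise SchemaError(f"{path}: missing required column {cols[logical]!r}")
    has_study = cols["study"] in table.columns

    records: list[VariantRecord] = []
    n_dropped = 0
    for idx, row in table.iterrows():
        genes = _split_genes(row[cols["gene"]])
        if not genes:
            n_dropped += 1
            continue
        try:
            p = float(row[cols["p_value"]])
        except ValueError as exc:
            raise ValueError(
                f"{path}: unparseable p-value {row[cols['p_value']]!r} at row {idx}"
            ) from exc
        records.append(
            VariantRecord(
                variant_id=str(row[cols["variant"]]).strip(),
                mapped_genes=genes,
                trait=str(row[cols["trait"]]).strip(),
                context=str(row[cols["context"]]).strip(),
                p_value=p,
                study_accession=str(row[cols["study"]]).strip() if has_study else "",
            )
        )
    if n_dropped:
        logger.warning("%s: dropped %d rows with empty mapped-gene field", path, n_dropped)
    return records


def select_variants(
    records: Iterable[VariantRecord],
    traits: Sequence[str] = DEFAULT_TRAITS,
    consequences: frozenset[str] = DEFAULT_CONSEQUENCES,
    p_max: float = DEFAULT_P_MAX,
) -> list[VariantRecord]:
    """Keep records matching a target trait, consequence class, and p < p_max.

    Trait matching is exact after trimming and case-folding; the p-value
    filter is strict.  Input order is preserved and the operation is
    idempotent.
    """
    if not traits:
        raise ValueError("traits must be non-empty")
    if not 0 < p_max < 1:
        raise ValueError("p_max must be in (0, 1)")
    wanted = {t.strip().casefold() for t in traits}
    kept = [
        r
        for r in records
        if r.trait.strip().casefold() in wanted
        and r.context in consequences
        and r.p_value < p_max
    ]
    if not kept:
        logger.warning("no variants pass the trait/consequence/p-value filters")
    return kept


def seed_genes(selected: Iterable[VariantRecord]) -> SeedGeneSet:
    """Union the mapped genes of the selected variants into a seed set."""
    out = SeedGeneSet()
    for rec in selected:
        for gene in rec.mapped_genes:
            out.genes.add(gene)
            out.provenance.setdefault(gene, set()).add(rec.variant_id)
    return out


def write_seed_table(
    seeds: SeedGeneSet, selected: Sequence[VariantRecord], path: str | Path
) -> None:
    """Write gene / supporting variants / min p-value as TSV."""
    min_p: dict[str, float] = {}
    for rec in selected:
        for gene in rec.mapped_genes:
            min_p[gene] = min(min_p.get(gene, 1.0), rec.p_value)
    rows = [
        {
            "gene": g,
            "variants": ";".join(sorted(seeds.provenance[g])),
            "min_p_value": min_p.get(g, ""),
        }
        for g in sorted(seeds.genes)
    ]
    pd.DataFrame(rows, columns=["gene", "variants", "min_p_value"]).to_csv(
        path, sep="\t", index=False
    )
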