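"""Gene-phenotype / gene-disease association catalogs.

Each catalog mirrors one source export: OMIM, DGA, the GWAS Catalogue and
GWAS Central on the human side, WormBase phenotypes on the worm side.
GWAS-derived rows carry the association p-value of the original study so
they can be filtered at the source's inclusion threshold (e.g. <1e-5 for
the GWAS Catalogue, <1e-10 for GWAS Central); curated OMIM/DGA/WormBase
rows carry none.  Sources are held as separate catalogs and selected by
the user; gene ids are matched as exact case-sensitive strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .orthology import HUMAN, WORM
from .tabular_io import ValidationError, read_table

logger = logging.getLogger(__name__)

SOURCES = {
    "OMIM": HUMAN,
    "DGA": HUMAN,
    "GWAS_CATALOGUE": HUMAN,
    "GWAS_CENTRAL": HUMAN,
    "WORMBASE": WORM,
}


@dataclass(frozen=True)
class PhenotypeTerm:
    source: str
    term_id: str
    label: str

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValidationError(
                f"unknown source {self.source!r}; expected one of {sorted(SOURCES)}"
            )
        if not self.term_id:
            raise ValidationError("empty term id")

    @property
    def species(self) -> str:
        return SOURCES[self.source]


@dataclass
class GeneSetCatalog:
    """Deduplicated (term, gene, optional p) associations from one source."""

    source: str
    associations: dict[PhenotypeTerm, dict[str, float | None]] = field(default_factory=dict)

    @property
    def species(self) -> str:
        return SOURCES[self.source]

    def terms(self) -> list[PhenotypeTerm]:
        return list(self.associations)

    def all_genes(self) -> set[str]:
        genes: set[str] = set()
        for gene_ps in self.associations.values():
            genes.update(gene_ps)
        return genes

    def n_associations(self) -> int:
        return sum(len(g) for g in self.associations.values())

    def term_by_id(self, term_id: str) -> PhenotypeTerm:
        for term in self.associations:
            if term.term_id == term_id:
                return term
        raise KeyError(f"term id {term_id!r} not in {self.source} catalog")


def _add(catalog: GeneSetCatalog, term: PhenotypeTerm, gene: str, p: float | None) -> bool:
    """Insert one association; duplicate (term, gene) keeps the smallest p. Returns True if new."""
    genes = catalog.associations.setdefault(term, {})
    if gene in genes:
        prior = genes[gene]
        if p is not None and (prior is None or p < prior):
            genes[gene] = p
        return False
    genes[gene] = p
    return True


def parse_catalog(path: str | Path, source: str) -> GeneSetCatalog:
    """Load a catalog TSV (columns term_id, label, gene, optional p_value).

    Duplicate (term, gene) rows collapse, keeping the smallest p-value;
    raw and deduplicated row counts are logged.
    """
    if source not in SOURCES:
        raise ValidationError(f"unknown source {source!r}; expected one of {sorted(SOURCES)}")
    table = read_table(path, required=["term_id", "label", "gene"])
    has_p = "p_value" in table.header
    catalog = GeneSetCatalog(source)
    n_rows = 0
    n_dup = 0
    for lineno, row in enumerate(table.rows, start=2):
        n_rows += 1
        if not row["gene"]:
            raise ValidationError(f"{path}, line {lineno}: empty gene id")
        p: float | None = None
        if has_p and row["p_value"] not in ("", "NA"):
            p = float(row["p_value"])
            if not 0.0 < p <= 1.0:
                raise ValidationError(
                    f"{path}, line {lineno}: p_value {row['p_value']} outside (0,1]"
                )
        term = PhenotypeTerm(source, row["term_id"], row["label"])
        if not _add(catalog, term, row["gene"], p):
            n_dup += 1
    logger.info(
        "%s: %d rows, %d duplicate (term,gene) rows collapsed, %d associations kept",
        path, n_rows, n_dup, catalog.n_associations(),
    )
    return catalog


def filter_by_pvalue(
    catalog: GeneSetCatalog, threshold: float, keep_unscored: bool = True
) -> GeneSetCatalog:
    """Keep associations with p strictly below ``threshold``.

    Rows without a p-value (curated sources) are kept unless
    ``keep_unscored=False``.  Idempotent; monotone in the threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError(f"threshold {threshold} outside (0,1]")
    out = GeneSetCatalog(catalog.source)
    for term, genes in catalog.associations.items():
        for gene, p in genes.items():
            if (p is None and keep_unscored) or (p is not None and p < threshold):
                _add(out, term, gene, p)
    return out


def gene_set_for_term(catalog: GeneSetCatalog, term: PhenotypeTerm | str) -> set[str]:
    """Distinct genes associated with a term (by PhenotypeTerm or term_id)."""
    if isinstance(term, str):
        term = catalog.term_by_id(term)
    if term not in catalog.associations:
        labels = sorted(t.label for t in catalog.associations)[:10]
        raise KeyError(
            f"term {term.term_id!r} ({term.label!r}) not in {catalog.source} catalog; "
            f"known labels include {labels}"
        )
    return set(catalog.associations[term])
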