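"""The four composed analysis tools, operating on a probe selection set.

* ``disease2qtl`` — from human disease terms to the worm expression probes
  of their orthologous genes (with LOD profiles when a scan is supplied).
* ``region2disease`` — from a genomic region to the human diseases whose
  gene sets are enriched among the region's genes.
* ``qtl2disease`` — from a probe's QTL peak, via the window of flanking
  probes, to enriched human diseases.
* ``comparepheno`` — from phenotype/disease terms to their cross-species
  phenologs (or, within one species, the closest related terms).

The selection set replaces an interactive cart: an ordered, de-duplicated
list of probe ids with per-probe provenance, serialisable to TSV so CLI
subcommands can hand it to each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .enrichment import PhenologResult, bh_adjust, phenolog_test, _sorted_results
from .genesets import GeneSetCatalog, PhenotypeTerm, gene_set_for_term
from .orthology import HUMAN, WORM, OrthologGroupMap, project_set
from .qtlmap import (
    GenomicRegion,
    Marker,
    ProbeAnnotation,
    QTLScan,
    find_peak,
    flanking_probes,
    region_probes,
)
from .tabular_io import TableFile, read_table, write_table


@dataclass
class SelectionSet:
    """Ordered, de-duplicated probe selection with provenance."""

    probe_ids: list[str] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, probe_id: str, source: str) -> bool:
        """Insert preserving first-insertion order; returns True if new."""
        if probe_id in self.provenance:
            return False
        self.probe_ids.append(probe_id)
        self.provenance[probe_id] = source
        return True

    def extend(self, probe_ids: Iterable[str], source: str) -> int:
        return sum(self.add(p, source) for p in probe_ids)

    def __len__(self) -> int:
        return len(self.probe_ids)

    def to_table(self) -> TableFile:
        return TableFile(
            ["probe_id", "added_by"],
            [{"probe_id": p, "added_by": self.provenance[p]} for p in self.probe_ids],
        )

    def write(self, path: str | Path) -> Path:
        return write_table(self.to_table(), path)

    @classmethod
    def read(cls, path: str | Path) -> "SelectionSet":
        table = read_table(path, required=["probe_id", "added_by"])
        sel = cls()
        for row in table.rows:
            sel.add(row["probe_id"], row["added_by"])
        return sel


def _worm_genes_of_groups(group_ids: Iterable[str], ortho_map: OrthologGroupMap) -> set[str]:
    genes: set[str] = set()
    for gid in group_ids:
        genes.update(g for g in ortho_map.groups[gid] if ortho_map.species_of[g] == WORM)
    return genes


def _probes_of_genes(genes: set[str], annotation: Iterable[ProbeAnnotation]) -> list[ProbeAnnotation]:
    return sorted(
        (p for p in annotation if p.gene_id in genes),
        key=lambda p: (p.chrom, p.midpoint, p.probe_id),
    )


@dataclass
class Disease2QTLResult:
    selection: SelectionSet
    peaks: dict[str, tuple[Marker, float] | None] | None = None
    profiles: TableFile | None = None
    n_genes_without_ortholog: int = 0


def disease2qtl(
    terms: Sequence[PhenotypeTerm | str],
    human_catalog: GeneSetCatalog,
    ortho_map: OrthologGroupMap,
    annotation: Sequence[ProbeAnnotation],
    scan: QTLScan | None = None,
    lod_threshold: float = 0.0,
) -> Disease2QTLResult:
    """Worm probes for the orthologues of a human disease's genes.

    The disease gene sets project to ortholog groups, expand to the worm
    genes of those groups, then to every probe annotated to one of them.
    A term with no orthologous worm genes contributes nothing (warning
    case, not an error).  When a scan is supplied the result also carries
    each selected probe's LOD profile and peak (plot-ready, long format).
    """
    selection = SelectionSet()
    dropped = 0
    for term in terms:
        if isinstance(term, str):
            term = human_catalog.term_by_id(term)
        genes = gene_set_for_term(human_catalog, term)
        proj = project_set(genes, HUMAN, ortho_map)
        dropped += proj.n_dropped
        worm_genes = _worm_genes_of_groups(proj.groups, ortho_map)
        probes = _probes_of_genes(worm_genes, annotation)
        selection.extend((p.probe_id for p in probes), source=f"disease2qtl:{term.term_id}")
    result = Disease2QTLResult(selection, n_genes_without_ortholog=dropped)
    if scan is not None:
        result.peaks = {}
        rows = []
        for probe_id in selection.probe_ids:
            result.peaks[probe_id] = find_peak(scan, probe_id, lod_threshold)
            profile = scan.profile(probe_id)
            for marker, lod in zip(scan.markers, profile):
                rows.append(
                    {
                        "probe_id": probe_id,
                        "marker_id": marker.marker_id,
                        "chrom": marker.chrom,
                        "pos_bp": marker.pos_bp,
                        "lod": "NA" if np.isnan(lod) else f"{lod:.4f}",
                    }
                )
        result.profiles = TableFile(["probe_id", "marker_id", "chrom", "pos_bp", "lod"], rows)
    return result


def _enrich_genes_against_catalogs(
    worm_genes: set[str],
    ortho_map: OrthologGroupMap,
    human_catalogs: Sequence[GeneSetCatalog],
    N_override: int | None,
    adjust: bool,
) -> list[PhenologResult]:
    """Test one worm gene set against every term of every human catalog."""
    results = []
    n_tests = 0
    for catalog in human_catalogs:
        for term in catalog.terms():
            n_tests += 1
            r = phenolog_test(
                worm_genes,
                gene_set_for_term(catalog, term),
                ortho_map,
                N_override=N_override,
                term2=term,
            )
            if r.k >= 1:
                results.append(r)
    results = _sorted_results(results)
    if adjust:
        adjusted = bh_adjust([r.p for r in results], m=n_tests)
        results = [replace(r, p_adjusted=a) for r, a in zip(results, adjusted)]
    return results


def region2disease(
    region: GenomicRegion,
    annotation: Sequence[ProbeAnnotation],
    ortho_map: OrthologGroupMap,
    human_catalogs: Sequence[GeneSetCatalog],
    N_override: int | None = None,
    adjust: bool = True,
) -> list[PhenologResult]:
    """Disease enrichment of the genes annotated in a genomic region.

    Probes overlapping the region collapse to their distinct worm genes
    (genes are the statistical unit; multiple probes per gene count once),
    which are tested against every human term per catalog.  Sorted by
    ascending p across catalogs.
    """
    probe_ids = set(region_probes(region, annotation))
    genes = {p.gene_id for p in annotation if p.probe_id in probe_ids and p.gene_id}
    if not genes:
        return []
    return _enrich_genes_against_catalogs(genes, ortho_map, human_catalogs, N_override, adjust)


def qtl2disease(
    probe_id: str,
    scan: QTLScan,
    lod_threshold: float,
    annotation: Sequence[ProbeAnnotation],
    ortho_map: OrthologGroupMap,
    human_catalogs: Sequence[GeneSetCatalog],
    count_per_side: int = 50,
    N_override: int | None = None,
    adjust: bool = True,
) -> list[PhenologResult]:
    """Disease enrichment around a probe's QTL peak.

    If the probe's best LOD exceeds the threshold, the closest
    ``count_per_side`` probes on each side of the peak marker (plus the
    query probe itself) define the gene set tested against the human
    catalogs; otherwise the result is empty.
    """
    peak = find_peak(scan, probe_id, lod_threshold)
    if peak is None:
        return []
    window = set(flanking_probes(peak[0], annotation, count_per_side))
    window.add(probe_id)  # the query probe's own gene participates
    genes = {p.gene_id for p in annotation if p.probe_id in window and p.gene_id}
    if not genes:
        return []
    return _enrich_genes_against_catalogs(genes, ortho_map, human_catalogs, N_override, adjust)


def comparepheno(
    query_terms: Sequence[PhenotypeTerm],
    worm_catalog: GeneSetCatalog,
    human_catalogs: Sequence[GeneSetCatalog],
    ortho_map: OrthologGroupMap,
    N_override: int | None = None,
    adjust: bool = True,
) -> list[PhenologResult]:
    """Phenologs of the query terms in the opposite species.

    The direction is auto-detected from each query term's source species:
    worm queries sweep the human catalogs, human queries sweep the worm
    catalog.  Results are merged and sorted by ascending p; term1 is
    always the query.  (For within-species neighbours use
    ``enrichment.within_species_sweep``.)
    """
    results = []
    n_tests = 0
    for query in query_terms:
        if query.species == WORM:
            worm_genes = gene_set_for_term(worm_catalog, query)
            for catalog in human_catalogs:
                for term in catalog.terms():
                    n_tests += 1
                    r = phenolog_test(
                        worm_genes,
                        gene_set_for_term(catalog, term),
                        ortho_map,
                        N_override=N_override,
                        term1=query,
                        term2=term,
                    )
                    if r.k >= 1:
                        results.append(r)
        else:
            human_genes = None
            for catalog in human_catalogs:
                if query in catalog.associations:
                    human_genes = gene_set_for_term(catalog, query)
            if human_genes is None:
                raise KeyError(f"query term {query.term_id!r} not in any supplied human catalog")
            for term in worm_catalog.terms():
                n_tests += 1
                r = phenolog_test(
                    gene_set_for_term(worm_catalog, term),
                    human_genes,
                    ortho_map,
                    N_override=N_override,
                    term1=query,
                    term2=term,
                )
                if r.k >= 1:
                    # roles swapped for reporting: term1 stays the query
                    results.append(replace(r, n1=r.n2, n2=r.n1))
    results = _sorted_results(results)
    if adjust:
        adjusted = bh_adjust([r.p for r in results], m=n_tests)
        results = [replace(r, p_adjusted=a) for r, a in zip(results, adjusted)]
    return results
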