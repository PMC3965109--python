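"""The phenolog statistic and its sweeps.

A *phenolog* is a pair of phenotypes in two species whose associated gene
sets share more orthologous genes than expected by chance.  With a shared
background of N ortholog groups, a worm phenotype hitting n1 groups, a
human disease hitting n2, and k groups hit by both, the significance is
the upper tail of the hypergeometric distribution:

    P(X >= k),  X ~ Hypergeometric(N, n1, n2)
              = sum_{i=k}^{min(n1,n2)} C(n1,i) C(N-n1, n2-i) / C(N, n2)

The tail is computed in log space (log-gamma binomials combined by
log-sum-exp) so that values far below the double-precision underflow
threshold remain usable; ``log_hypergeom_tail`` returns the natural log,
``hypergeom_tail`` the probability.

Sweeps run the test all-vs-all (every worm phenotype against every human
disease) or within one species; reported p-values are uncorrected by
default, with Benjamini-Hochberg adjustment over the *full* number of
tests (including non-overlapping pairs, whose p = 1) available on top.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import exp, lgamma, log
from typing import Iterable, Sequence

import numpy as np

from .genesets import GeneSetCatalog, PhenotypeTerm, gene_set_for_term
from .orthology import HUMAN, WORM, OrthologGroupMap, background_size, project_set


@dataclass(frozen=True)
class PhenologResult:
    """One cross-species overlap test, the row format of the output tables."""

    term1: PhenotypeTerm | None  # worm side (or query side within-species)
    term2: PhenotypeTerm | None  # human side (or subject side)
    n1: int
    n2: int
    k: int
    N: int
    p: float
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n1, self.n2) <= self.N and max(self.n1, self.n2) <= self.N):
            raise ValueError(
                f"inconsistent counts n1={self.n1} n2={self.n2} k={self.k} N={self.N}"
            )
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p={self.p} outside (0,1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p - 1e-12:
            raise ValueError("adjusted p below raw p")


def _log_comb(n: int, r: int) -> float:
    return lgamma(n + 1) - lgamma(r + 1) - lgamma(n - r + 1)


def _check_params(N: int, n1: int, n2: int, k: int) -> None:
    for name, v in (("N", N), ("n1", n1), ("n2", n2), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name}={v} must be a non-negative integer")
    if n1 > N or n2 > N:
        raise ValueError(f"n1={n1}, n2={n2} must not exceed N={N}")
    if k > min(n1, n2):
        raise ValueError(f"k={k} exceeds min(n1,n2)={min(n1, n2)}")


def log_hypergeom_tail(N: int, n1: int, n2: int, k: int) -> float:
    """Natural log of P(X >= k) for X ~ Hypergeometric(N, n1, n2).

    The upper tail *includes* k itself.  Accurate far into the underflow
    regime (p ~ 1e-300 and below) because everything stays in log space.
    """
    _check_params(N, n1, n2, k)
    if k == 0:
        return 0.0
    if n1 > n2:
        n1, n2 = n2, n1  # canonical order makes the n1/n2 symmetry exact
    lo = max(k, n2 - (N - n1))  # below lo the complementary draw C(N-n1, n2-i) is impossible
    hi = min(n1, n2)
    if lo > hi:
        raise ValueError(f"empty support: k={k} beyond attainable overlap for N={N},n1={n1},n2={n2}")
    log_den = _log_comb(N, n2)
    terms = np.array(
        [_log_comb(n1, i) + _log_comb(N - n1, n2 - i) for i in range(lo, hi + 1)], dtype=float
    )
    m = terms.max()
    log_num = m + log(np.exp(terms - m).sum())
    return min(log_num - log_den, 0.0)


def hypergeom_tail(N: int, n1: int, n2: int, k: int) -> float:
    """P(X >= k) as a probability (underflows to 0.0 below ~1e-308)."""
    return exp(log_hypergeom_tail(N, n1, n2, k))


def phenolog_test(
    worm_genes: Iterable[str],
    human_genes: Iterable[str],
    ortho_map: OrthologGroupMap,
    N_override: int | None = None,
    term1: PhenotypeTerm | None = None,
    term2: PhenotypeTerm | None = None,
    counting: str = "groups",
) -> PhenologResult:
    """Overlap test of a worm gene set against a human gene set.

    Both sets project to shared ortholog groups; n1, n2 count the groups
    hit on each side (``counting="genes"`` instead counts the projecting
    genes — the two coincide for one-to-one orthology), k the groups hit
    by both.  N is the map's shared-group count unless ``N_override``
    reproduces a literature background.  Empty projections give k=0, p=1.
    """
    if counting not in ("groups", "genes"):
        raise ValueError(f"counting={counting!r}; expected 'groups' or 'genes'")
    worm_genes = set(worm_genes)
    human_genes = set(human_genes)
    proj_w = project_set(worm_genes, WORM, ortho_map)
    proj_h = project_set(human_genes, HUMAN, ortho_map)
    if counting == "groups":
        n1, n2 = len(proj_w.groups), len(proj_h.groups)
    else:
        n1 = len(worm_genes) - proj_w.n_dropped
        n2 = len(human_genes) - proj_h.n_dropped
    k = len(proj_w.groups & proj_h.groups)
    N = background_size(ortho_map) if N_override is None else int(N_override)
    if N_override is not None and N < max(n1, n2):
        raise ValueError(f"N_override={N_override} smaller than max(n1,n2)={max(n1, n2)}")
    p = 1.0 if k == 0 else max(hypergeom_tail(N, n1, n2, k), 5e-324)
    return PhenologResult(term1, term2, n1, n2, k, N, p)


def bh_adjust(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the total number of tests performed, which may exceed the
    number of p-values supplied (untested/omitted pairs count as p = 1 and
    only dilute through the denominator).  Output order matches input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() <= 0.0 or p.max() > 1.0):
        raise ValueError("p-values must lie in (0,1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"total test count m={m} below number of p-values {p.size}")
    if p.size == 0:
        return []
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out.tolist()


def _sorted_results(results: list[PhenologResult]) -> list[PhenologResult]:
    def key(r: PhenologResult):
        t1 = r.term1.term_id if r.term1 else ""
        t2 = r.term2.term_id if r.term2 else ""
        return (r.p, t1, t2)

    return sorted(results, key=key)


def _incidence(catalog: GeneSetCatalog, ortho_map: OrthologGroupMap):
    """Terms, their projected group-id sets, and a term x group 0/1 matrix."""
    group_index = {g: i for i, g in enumerate(sorted(ortho_map.shared_groups))}
    terms = sorted(catalog.terms(), key=lambda t: t.term_id)
    mat = np.zeros((len(terms), len(group_index)), dtype=np.int32)
    projections = []
    for row, term in enumerate(terms):
        proj = project_set(gene_set_for_term(catalog, term), catalog.species, ortho_map)
        projections.append(proj.groups)
        for g in proj.groups:
            mat[row, group_index[g]] = 1
    return terms, projections, mat


def broad_sweep(
    worm_catalog: GeneSetCatalog,
    human_catalog: GeneSetCatalog,
    ortho_map: OrthologGroupMap,
    N_override: int | None = None,
    adjust: bool = True,
) -> list[PhenologResult]:
    """All worm phenotypes vs all human diseases.

    Every (worm term, human term) pair is tested; pairs with k = 0 are
    omitted from the output but still count in the BH denominator (their
    p is 1).  Output is sorted by ascending p, ties broken on term ids.
    """
    if not worm_catalog.terms() or not human_catalog.terms():
        raise ValueError("broad_sweep requires non-empty catalogs on both sides")
    w_terms, _, w_mat = _incidence(worm_catalog, ortho_map)
    h_terms, _, h_mat = _incidence(human_catalog, ortho_map)
    N = background_size(ortho_map) if N_override is None else int(N_override)
    overlap = w_mat @ h_mat.T  # k for every pair, via group incidence
    n1s = w_mat.sum(axis=1)
    n2s = h_mat.sum(axis=1)
    results = []
    for i, j in zip(*np.nonzero(overlap)):
        k = int(overlap[i, j])
        p = max(hypergeom_tail(N, int(n1s[i]), int(n2s[j]), k), 5e-324)
        results.append(
            PhenologResult(w_terms[i], h_terms[j], int(n1s[i]), int(n2s[j]), k, N, p)
        )
    results = _sorted_results(results)
    if adjust:
        m = len(w_terms) * len(h_terms)
        adjusted = bh_adjust([r.p for r in results], m=m)
        results = [replace(r, p_adjusted=a) for r, a in zip(results, adjusted)]
    return results


def within_species_sweep(
    catalog: GeneSetCatalog, query_term: PhenotypeTerm | str, adjust: bool = True
) -> list[PhenologResult]:
    """Overlap of one term's gene set against every other term, same species.

    Counting is in plain gene space with the catalog's distinct genes as
    background (no orthology involved).  Useful to find the closest
    related disease for an input disease.
    """
    if isinstance(query_term, str):
        query_term = catalog.term_by_id(query_term)
    query_genes = gene_set_for_term(catalog, query_term)
    background = catalog.all_genes()
    N = len(background)
    n1 = len(query_genes)
    results = []
    others = [t for t in catalog.terms() if t != query_term]
    for term in others:
        genes = gene_set_for_term(catalog, term)
        k = len(query_genes & genes)
        if k == 0:
            continue
        p = max(hypergeom_tail(N, n1, len(genes), k), 5e-324)
        results.append(PhenologResult(query_term, term, n1, len(genes), k, N, p))
    results = _sorted_results(results)
    if adjust:
        adjusted = bh_adjust([r.p for r in results], m=len(others))
        results = [replace(r, p_adjusted=a) for r, a in zip(results, adjusted)]
    return results
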