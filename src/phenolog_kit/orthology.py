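"""Ortholog-group backgrounds from pairwise worm/human ortholog calls.

Pairwise reciprocal-best-match calls (with a bootstrap support percentage)
are filtered at a minimum bootstrap (default 100%), then flattened into
ortholog *groups*: connected components of the bipartite worm-human gene
graph.  The number of groups containing at least one gene of each species
is the shared background N of the phenolog test.  Gene sets from either
species project into group-id space for cross-species overlap counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx

from .tabular_io import ValidationError, read_table

WORM = "worm"
HUMAN = "human"
_SPECIES = (WORM, HUMAN)


@dataclass(frozen=True)
class OrthologPair:
    worm_gene: str
    human_gene: str
    bootstrap: float

    def __post_init__(self) -> None:
        if not self.worm_gene or not self.human_gene:
            raise ValidationError("ortholog pair with empty gene id")
        if not 0.0 <= self.bootstrap <= 100.0:
            raise ValidationError(
                f"bootstrap {self.bootstrap} for ({self.worm_gene},{self.human_gene}) "
                "outside [0,100]"
            )


@dataclass
class OrthologGroupMap:
    """Partition of retained genes into ortholog groups.

    ``groups`` maps group id -> frozenset of member gene ids; group ids are
    deterministic (lexicographically smallest member).  ``shared_groups``
    are groups with >=1 gene of each species; N = |shared_groups| is the
    phenolog-test background.
    """

    groups: dict[str, frozenset[str]]
    species_of: dict[str, str]
    shared_groups: frozenset[str]
    group_of: dict[str, str]
    n_pairs: int = 0

    @property
    def N(self) -> int:
        return len(self.shared_groups)


class Projection(NamedTuple):
    """Group ids hit by a gene set, plus how many input genes had no group."""

    groups: frozenset[str]
    n_dropped: int


def read_ortholog_pairs(path: str | Path) -> list[OrthologPair]:
    """Read an ortholog TSV with columns worm_gene, human_gene, bootstrap."""
    table = read_table(path, required=["worm_gene", "human_gene", "bootstrap"])
    pairs = []
    seen = set()
    for row in table.rows:
        key = (row["worm_gene"], row["human_gene"])
        if key in seen:
            raise ValidationError(f"{path}: duplicate ortholog pair {key}")
        seen.add(key)
        pairs.append(OrthologPair(key[0], key[1], float(row["bootstrap"])))
    return pairs


def build_groups(pairs: Iterable[OrthologPair], min_bootstrap: float = 100.0) -> OrthologGroupMap:
    """Flatten filtered ortholog pairs into connected-component groups.

    Pairs below ``min_bootstrap`` are discarded.  Remaining pairs are edges
    of a bipartite graph whose connected components become the groups; by
    construction from pairs every component contains both species, so
    every group is shared and N equals the component count.  The partition
    is independent of input pair order.
    """
    if not 0.0 <= min_bootstrap <= 100.0:
        raise ValidationError(f"min_bootstrap {min_bootstrap} outside [0,100]")
    graph = nx.Graph()
    species_of: dict[str, str] = {}
    n_retained = 0
    for p in pairs:
        if p.bootstrap < min_bootstrap:
            continue
        n_retained += 1
        for gene, sp in ((p.worm_gene, WORM), (p.human_gene, HUMAN)):
            prior = species_of.get(gene)
            if prior is not None and prior != sp:
                raise ValidationError(f"gene {gene!r} appears as both {prior} and {sp}")
            species_of[gene] = sp
        graph.add_edge(p.worm_gene, p.human_gene)

    groups: dict[str, frozenset[str]] = {}
    group_of: dict[str, str] = {}
    shared = set()
    for comp in nx.connected_components(graph):
        gid = min(comp)
        members = frozenset(comp)
        groups[gid] = members
        for gene in members:
            group_of[gene] = gid
        if {species_of[g] for g in members} == set(_SPECIES):
            shared.add(gid)
    return OrthologGroupMap(groups, species_of, frozenset(shared), group_of, n_retained)


def project_set(genes: Iterable[str], species: str, ortho_map: OrthologGroupMap) -> Projection:
    """Project a gene set into shared ortholog-group space.

    Genes without a shared ortholog group don't project; their count is
    returned alongside the hit groups.
    """
    if species not in _SPECIES:
        raise ValidationError(f"unknown species tag {species!r}; expected one of {_SPECIES}")
    hit = set()
    dropped = 0
    for gene in set(genes):
        gid = ortho_map.group_of.get(gene)
        if gid is not None and gid in ortho_map.shared_groups and ortho_map.species_of[gene] == species:
            hit.add(gid)
        else:
            dropped += 1
    return Projection(frozenset(hit), dropped)


def background_size(ortho_map: OrthologGroupMap, background: str = "groups") -> int:
    """Background size N of the phenolog test.

    ``background="groups"`` (default) counts shared ortholog groups;
    ``"pairs"`` counts retained ortholog pairs (an alternative convention
    for many-to-many orthology that some published backgrounds use).
    """
    if background == "groups":
        return ortho_map.N
    if background == "pairs":
        return ortho_map.n_pairs
    raise ValidationError(f"unknown background mode {background!r}; expected 'groups' or 'pairs'")
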