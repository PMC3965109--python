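"""Seeded generator of synthetic inputs with planted, recoverable signal.

The generator emulates, at reduced scale, the kinds of data the toolkit
integrates: an ortholog-pair table with bootstrap support, worm-phenotype
and human-disease gene-set catalogs, RIL genotypes as a Markov chain of
biallelic markers along each chromosome, and expression traits with
planted cis-eQTL and a planted trans-eQTL hotspot.

Planted phenologs are constructed exactly: for a planted (n1, n2, k) the
worm term hits n1 distinct ortholog groups, the human term n2, and
exactly k are shared, so the phenolog test recovers the counts with no
sampling slack.  Decoy terms draw gene sets uniformly at random from the
ortholog background.

Each artifact (orthologs, catalogs, genotypes, expression) has its own
random stream derived from the master seed, so regenerating one file
never shifts another.  The same scenario and seed give byte-identical
files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genesets import GeneSetCatalog, PhenotypeTerm, _add
from .orthology import HUMAN, WORM, OrthologGroupMap, OrthologPair, build_groups
from .qtlmap import Marker, ProbeAnnotation
from .tabular_io import MatrixFile, TableFile

# Per-chromosome sizes loosely following the C. elegans karyotype (bp).
DEFAULT_CHROM_LENGTHS = {
    "I": 15_000_000,
    "II": 15_300_000,
    "III": 13_800_000,
    "IV": 17_500_000,
    "V": 20_900_000,
}

_STREAMS = {"orthologs": 0, "catalogs": 1, "genotypes": 2, "expression": 3}


@dataclass
class SyntheticScenario:
    """Parameterisation of the planted-signal test bed.

    Defaults follow the worked phenolog example the toolkit reproduces:
    a background of 4649 shared ortholog groups with one planted
    (n1=16, n2=12, k=3) phenolog among 200 decoy terms per species, and a
    reduced genetical-genomics panel (100 strains, 5 chromosomes x 50
    markers, 500 probes) with cis effects and one trans hotspot of 60
    targets at twice the noise SD.
    """

    seed: int = 0
    N_groups: int = 4649
    planted_phenologs: list[tuple[int, int, int]] = field(default_factory=lambda: [(16, 12, 3)])
    n_decoy_terms_per_species: int = 200
    decoy_set_size_range: tuple[int, int] = (10, 30)
    m2m_extra_fraction: float = 0.0
    low_bootstrap_fraction: float = 0.05
    n_strains: int = 100
    markers_per_chrom: int = 50
    chrom_lengths_bp: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    recomb_prob: float = 0.1
    n_probes: int = 500
    cis_fraction: float = 0.5
    cis_effect: float = 2.0
    hotspot_chrom: str = "V"
    hotspot_n_targets: int = 60
    hotspot_effect: float = 2.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for n1, n2, k in self.planted_phenologs:
            if not 0 <= k <= min(n1, n2) <= self.N_groups or max(n1, n2) > self.N_groups:
                raise ValueError(f"planted phenolog ({n1},{n2},{k}) infeasible for N={self.N_groups}")
        if not 0.0 < self.recomb_prob <= 0.5:
            raise ValueError(f"recomb_prob {self.recomb_prob} outside (0,0.5]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.decoy_set_size_range
        if not 1 <= lo <= hi <= self.N_groups:
            raise ValueError(f"decoy_set_size_range {self.decoy_set_size_range} infeasible")
        if self.hotspot_chrom not in self.chrom_lengths_bp:
            raise ValueError(f"hotspot_chrom {self.hotspot_chrom!r} not in chrom_lengths_bp")

    def rng(self, artifact: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[artifact], self.seed])


def _worm_gene(i: int) -> str:
    return f"ce-g{i:05d}"


def _human_gene(i: int) -> str:
    return f"hs-g{i:05d}"


def gen_ortholog_map(scenario: SyntheticScenario) -> list[OrthologPair]:
    """One-to-one ortholog pairs at bootstrap 100, plus optional extras.

    ``m2m_extra_fraction`` adds that fraction of extra 100%-bootstrap
    edges between random worm/human genes (merging groups, so the shared
    background can only shrink); ``low_bootstrap_fraction`` adds decoy
    pairs of fresh genes at bootstrap < 100 that the default filter
    removes.
    """
    rng = scenario.rng("orthologs")
    n = scenario.N_groups
    pairs = [OrthologPair(_worm_gene(i), _human_gene(i), 100.0) for i in range(n)]
    n_extra = int(round(scenario.m2m_extra_fraction * n))
    seen = {(p.worm_gene, p.human_gene) for p in pairs}
    while n_extra > 0:
        i, j = rng.integers(0, n, size=2)
        key = (_worm_gene(int(i)), _human_gene(int(j)))
        if i != j and key not in seen:
            seen.add(key)
            pairs.append(OrthologPair(*key, 100.0))
            n_extra -= 1
    n_low = int(round(scenario.low_bootstrap_fraction * n))
    for d in range(n_low):
        boot = float(rng.integers(50, 100))
        pairs.append(OrthologPair(f"ce-decoy{d:05d}", f"hs-decoy{d:05d}", boot))
    return pairs


def _gene_of_group(gid: str, species: str, ortho_map: OrthologGroupMap) -> str:
    return min(g for g in ortho_map.groups[gid] if ortho_map.species_of[g] == species)


def gen_catalogs(
    scenario: SyntheticScenario, ortho_map: OrthologGroupMap
) -> tuple[GeneSetCatalog, GeneSetCatalog, dict]:
    """Worm (WORMBASE) and human (OMIM) catalogs with planted phenologs.

    Returns the two catalogs and a ground-truth manifest mapping each
    planted pair to its term ids and exact (n1, n2, k).
    """
    rng = scenario.rng("catalogs")
    group_ids = sorted(ortho_map.shared_groups)
    worm = GeneSetCatalog("WORMBASE")
    human = GeneSetCatalog("OMIM")
    truth: dict = {"planted": []}

    for t, (n1, n2, k) in enumerate(scenario.planted_phenologs):
        chosen = rng.choice(len(group_ids), size=n1 + n2 - k, replace=False)
        groups = [group_ids[i] for i in chosen]
        shared, worm_only, human_only = groups[:k], groups[k : n1], groups[n1:]
        wt = PhenotypeTerm("WORMBASE", f"ce-planted-{t:02d}", f"planted worm phenotype {t}")
        ht = PhenotypeTerm("OMIM", f"hs-planted-{t:02d}", f"planted human disease {t}")
        for gid in shared + worm_only:
            _add(worm, wt, _gene_of_group(gid, WORM, ortho_map), None)
        for gid in shared + human_only:
            _add(human, ht, _gene_of_group(gid, HUMAN, ortho_map), None)
        truth["planted"].append(
            {"worm_term": wt.term_id, "human_term": ht.term_id, "n1": n1, "n2": n2, "k": k}
        )

    lo, hi = scenario.decoy_set_size_range
    for catalog, species, prefix, source in (
        (worm, WORM, "ce-pheno", "WORMBASE"),
        (human, HUMAN, "hs-dis", "OMIM"),
    ):
        for d in range(scenario.n_decoy_terms_per_species):
            size = int(rng.integers(lo, hi + 1))
            chosen = rng.choice(len(group_ids), size=size, replace=False)
            term = PhenotypeTerm(source, f"{prefix}-{d:04d}", f"decoy {species} term {d}")
            for i in chosen:
                _add(catalog, term, _gene_of_group(group_ids[i], species, ortho_map), None)
    return worm, human, truth


def gen_ril_genotypes(scenario: SyntheticScenario) -> tuple[MatrixFile, list[Marker]]:
    """RIL-like biallelic genotypes: per-chromosome two-state Markov chains.

    On each chromosome the first marker is Bernoulli(1/2) over {A, B} and
    each subsequent marker flips with probability ``recomb_prob``; markers
    sit evenly spaced along the chromosome.
    """
    rng = scenario.rng("genotypes")
    m = scenario.markers_per_chrom
    strains = [f"RIL{s:03d}" for s in range(scenario.n_strains)]
    markers: list[Marker] = []
    blocks = []
    for chrom, length in scenario.chrom_lengths_bp.items():
        positions = np.linspace(1, length, m).round().astype(int)
        for j, pos in enumerate(positions):
            markers.append(Marker(chrom, int(pos), f"mk-{chrom}-{j:03d}"))
        first = rng.integers(0, 2, size=(scenario.n_strains, 1))
        flips = (rng.random((scenario.n_strains, m - 1)) < scenario.recomb_prob).astype(int)
        states = np.concatenate([first, flips], axis=1).cumsum(axis=1) % 2
        blocks.append(states)
    states = np.concatenate(blocks, axis=1)
    values = np.where(states == 0, "A", "B").astype(object)
    matrix = MatrixFile(strains, [mk.marker_id for mk in markers], values, label="strain")
    return matrix, markers


def gen_expression(
    scenario: SyntheticScenario, genotypes: MatrixFile, markers: list[Marker]
) -> tuple[MatrixFile, list[ProbeAnnotation], dict]:
    """Expression traits with planted cis effects and one trans hotspot.

    Probes scatter uniformly along the genome (length-weighted chromosome
    choice).  ``hotspot_n_targets`` probes located off the hotspot
    chromosome respond in trans to the hotspot marker (the middle marker
    of ``hotspot_chrom``); of the remainder, ``cis_fraction`` respond in
    cis to the marker nearest their own locus; the rest are pure noise.
    Effects are additive on N(0, noise_sd) noise.

    Returns the trait matrix (probes x strains), the probe annotation and
    a ground-truth manifest (per-probe role and true marker).
    """
    rng = scenario.rng("expression")
    strains = genotypes.row_ids
    n_strains = len(strains)
    x = np.where(np.asarray(genotypes.values, dtype=object) == "B", 1.0, 0.0)  # strains x markers
    marker_index = {mk.marker_id: j for j, mk in enumerate(markers)}

    chroms = list(scenario.chrom_lengths_bp)
    lengths = np.array([scenario.chrom_lengths_bp[c] for c in chroms], dtype=float)
    probe_chrom_idx = rng.choice(len(chroms), size=scenario.n_probes, p=lengths / lengths.sum())
    probe_pos = (rng.random(scenario.n_probes) * (lengths[probe_chrom_idx] - 50)).astype(int) + 1

    by_chrom: dict[str, list[Marker]] = {}
    for mk in markers:
        by_chrom.setdefault(mk.chrom, []).append(mk)

    def nearest_marker(chrom: str, pos: int) -> Marker:
        return min(by_chrom[chrom], key=lambda mk: (abs(mk.pos_bp - pos), mk.pos_bp))

    hs_markers = by_chrom[scenario.hotspot_chrom]
    hotspot = hs_markers[len(hs_markers) // 2]

    annotation: list[ProbeAnnotation] = []
    roles: list[dict] = []
    off_hotspot = [
        i for i in range(scenario.n_probes) if chroms[probe_chrom_idx[i]] != scenario.hotspot_chrom
    ]
    trans_targets = set(off_hotspot[: scenario.hotspot_n_targets])
    if len(trans_targets) < scenario.hotspot_n_targets:
        raise ValueError("not enough off-hotspot probes to place all trans targets")

    Y = rng.normal(0.0, scenario.noise_sd, size=(scenario.n_probes, n_strains))
    for i in range(scenario.n_probes):
        chrom = chroms[probe_chrom_idx[i]]
        pos = int(probe_pos[i])
        pid = f"probe{i:05d}"
        annotation.append(ProbeAnnotation(pid, f"ce-probe-gene{i:05d}", chrom, pos, pos + 49))
        if i in trans_targets:
            Y[i] += scenario.hotspot_effect * x[:, marker_index[hotspot.marker_id]]
            roles.append({"probe_id": pid, "role": "trans", "true_marker": hotspot.marker_id})
        elif rng.random() < scenario.cis_fraction:
            mk = nearest_marker(chrom, pos)
            Y[i] += scenario.cis_effect * x[:, marker_index[mk.marker_id]]
            roles.append({"probe_id": pid, "role": "cis", "true_marker": mk.marker_id})
        else:
            roles.append({"probe_id": pid, "role": "null", "true_marker": ""})

    traits = MatrixFile([r["probe_id"] for r in roles], list(strains), Y, label="probe")
    truth = {"hotspot_marker": hotspot.marker_id, "probes": roles}
    return traits, annotation, truth


def generate_all(scenario: SyntheticScenario):
    """Generate every artifact of a scenario; returns a dict of objects.

    Keys: pairs, ortho_map, worm_catalog, human_catalog, genotypes,
    markers, traits, annotation, truth.
    """
    pairs = gen_ortholog_map(scenario)
    ortho_map = build_groups(pairs, min_bootstrap=100.0)
    worm_catalog, human_catalog, truth_cat = gen_catalogs(scenario, ortho_map)
    genotypes, markers = gen_ril_genotypes(scenario)
    traits, annotation, truth_exp = gen_expression(scenario, genotypes, markers)
    return {
        "pairs": pairs,
        "ortho_map": ortho_map,
        "worm_catalog": worm_catalog,
        "human_catalog": human_catalog,
        "genotypes": genotypes,
        "markers": markers,
        "traits": traits,
        "annotation": annotation,
        "truth": {**truth_cat, **truth_exp},
    }


# --- writers: the on-disk face of a scenario -------------------------------

def pairs_table(pairs: list[OrthologPair]) -> TableFile:
    return TableFile(
        ["worm_gene", "human_gene", "bootstrap"],
        [
            {"worm_gene": p.worm_gene, "human_gene": p.human_gene, "bootstrap": f"{p.bootstrap:g}"}
            for p in pairs
        ],
    )


def catalog_table(catalog: GeneSetCatalog) -> TableFile:
    rows = []
    for term in sorted(catalog.terms(), key=lambda t: t.term_id):
        for gene, p in sorted(catalog.associations[term].items()):
            rows.append(
                {
                    "term_id": term.term_id,
                    "label": term.label,
                    "gene": gene,
                    "p_value": "" if p is None else f"{p:.6g}",
                }
            )
    return TableFile(["term_id", "label", "gene", "p_value"], rows)


def marker_table(markers: list[Marker]) -> TableFile:
    return TableFile(
        ["marker_id", "chrom", "pos_bp"],
        [
            {"marker_id": m.marker_id, "chrom": m.chrom, "pos_bp": str(m.pos_bp)}
            for m in markers
        ],
    )


def annotation_table(annotation: list[ProbeAnnotation]) -> TableFile:
    return TableFile(
        ["probe_id", "gene_id", "chrom", "start_bp", "end_bp"],
        [
            {
                "probe_id": p.probe_id,
                "gene_id": p.gene_id or "",
                "chrom": p.chrom,
                "start_bp": str(p.start_bp),
                "end_bp": str(p.end_bp),
            }
            for p in annotation
        ],
    )


def write_scenario(scenario: SyntheticScenario, out_dir: str | Path) -> dict[str, Path]:
    """Write every artifact of a scenario to a directory, plus the manifest."""
    import json

    from .tabular_io import write_matrix, write_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = generate_all(scenario)
    paths = {
        "orthologs": write_table(pairs_table(data["pairs"]), out / "orthologs.tsv"),
        "worm_catalog": write_table(catalog_table(data["worm_catalog"]), out / "worm_catalog.tsv"),
        "human_catalog": write_table(
            catalog_table(data["human_catalog"]), out / "human_catalog.tsv"
        ),
        "genotypes": write_matrix(data["genotypes"], out / "genotypes.tsv"),
        "markers": write_table(marker_table(data["markers"]), out / "markers.tsv"),
        "traits": write_matrix(data["traits"], out / "traits.tsv"),
        "annotation": write_table(annotation_table(data["annotation"]), out / "annotation.tsv"),
    }
    manifest = out / "truth.json"
    manifest.write_text(json.dumps(data["truth"], indent=1, sort_keys=True) + "\n")
    paths["truth"] = manifest
    return paths
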