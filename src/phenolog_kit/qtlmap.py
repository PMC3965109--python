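"""Single-marker QTL mapping over expression-trait matrices.

Traits (probes x strains) are regressed on biallelic marker genotypes
(strains x markers) one marker at a time.  With RSS0 the total sum of
squares of the trait and RSS1 the residual sum of squares of the
two-genotype group-mean fit over the n strains complete for the pair,

    LOD = (n / 2) * log10(RSS0 / RSS1)

which equals (n/2) * log10(1 / (1 - r^2)) for the point-biserial
correlation r.  A perfect fit (RSS1 = 0) is clamped with RSS1 = eps*RSS0
(eps = 1e-12) so LOD stays finite; a flat trait or a monomorphic marker
scores 0; a pair with fewer than 3 complete strains is recorded missing.

On top of the scan sit peak detection, the flanking-probe window used to
seed disease-enrichment from a QTL, genomic-region queries over probe
annotations, and trans-band (hotspot) counting.  Coordinates are 1-based
inclusive throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .tabular_io import MatrixFile, ValidationError, read_table

LOD_EPS = 1e-12  # RSS1 clamp: perfect fit maps to LOD = (n/2) * 12


@dataclass(frozen=True, order=True)
class Marker:
    chrom: str
    pos_bp: int
    marker_id: str

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValidationError(f"marker {self.marker_id}: pos_bp {self.pos_bp} < 1")


@dataclass(frozen=True)
class ProbeAnnotation:
    probe_id: str
    gene_id: str | None
    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValidationError(
                f"probe {self.probe_id}: start_bp {self.start_bp} > end_bp {self.end_bp}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start_bp + self.end_bp) // 2


@dataclass(frozen=True)
class GenomicRegion:
    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValidationError(f"region start {self.start_bp} > end {self.end_bp}")


@dataclass
class QTLScan:
    """probes x markers matrix of LOD scores (NaN = not computable)."""

    probe_ids: list[str]
    markers: list[Marker]
    lod: np.ndarray

    def __post_init__(self) -> None:
        if self.lod.shape != (len(self.probe_ids), len(self.markers)):
            raise ValidationError("LOD matrix shape does not match probe/marker lists")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.lod, initial=0.0) < 0:
                raise ValidationError("negative LOD score in scan")

    def profile(self, probe_id: str) -> np.ndarray:
        try:
            return self.lod[self.probe_ids.index(probe_id)]
        except ValueError:
            raise KeyError(f"probe {probe_id!r} not in scan") from None


def read_markers(path: str | Path) -> list[Marker]:
    """Marker map TSV: marker_id, chrom, pos_bp."""
    table = read_table(path, required=["marker_id", "chrom", "pos_bp"])
    markers = [Marker(r["chrom"], int(r["pos_bp"]), r["marker_id"]) for r in table.rows]
    ids = [m.marker_id for m in markers]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate marker ids")
    return markers


def read_annotation(path: str | Path) -> list[ProbeAnnotation]:
    """Probe annotation TSV: probe_id, gene_id, chrom, start_bp, end_bp."""
    table = read_table(path, required=["probe_id", "gene_id", "chrom", "start_bp", "end_bp"])
    probes = [
        ProbeAnnotation(
            r["probe_id"], r["gene_id"] or None, r["chrom"], int(r["start_bp"]), int(r["end_bp"])
        )
        for r in table.rows
    ]
    ids = [p.probe_id for p in probes]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate probe ids")
    return probes


def _encode_genotypes(genotypes: MatrixFile) -> np.ndarray:
    """Map a biallelic symbol matrix to {0.0, 1.0} with NaN for missing."""
    if not genotypes.is_symbolic:
        vals = genotypes.values.astype(float)
        classes = np.unique(vals[~np.isnan(vals)])
        if classes.size > 2:
            raise ValidationError(f"genotype matrix has {classes.size} classes; expected 2")
        return (vals == classes.max()).astype(float) if classes.size else vals
    symbols = sorted({v for v in genotypes.values.ravel() if v is not None})
    if len(symbols) > 2:
        raise ValidationError(f"genotype alphabet {symbols} is not biallelic")
    code = {s: float(i) for i, s in enumerate(symbols)}
    out = np.full(genotypes.values.shape, np.nan)
    for sym, val in code.items():
        out[genotypes.values == sym] = val
    return out


def lod_scan(
    traits: MatrixFile, genotypes: MatrixFile, markers: Sequence[Marker] | None = None
) -> QTLScan:
    """Single-marker-regression LOD scan of every probe against every marker.

    ``traits`` is probes x strains, ``genotypes`` strains x markers; the
    two strain id lists are intersected (>= 3 shared strains required).
    Strains missing either the trait or the genotype are dropped pairwise
    per (probe, marker).
    """
    shared = [s for s in traits.col_ids if s in set(genotypes.row_ids)]
    if not shared:
        raise ValidationError("traits and genotypes share no strain ids")
    if len(shared) < 3:
        raise ValidationError(f"only {len(shared)} shared strains; need at least 3")
    t_idx = [traits.col_ids.index(s) for s in shared]
    g_idx = [genotypes.row_ids.index(s) for s in shared]
    Y = traits.values[:, t_idx].astype(float)  # probes x strains
    G = _encode_genotypes(genotypes)[g_idx, :]  # strains x markers

    oy = ~np.isnan(Y)
    og = ~np.isnan(G)
    Y0 = np.where(oy, Y, 0.0)
    G1 = np.where(og, G, 0.0)  # indicator of class-1 among observed
    G0 = np.where(og, 1.0 - G1, 0.0)

    n1 = oy.astype(float) @ G1  # probes x markers: complete strains in class 1
    n0 = oy.astype(float) @ G0
    n = n0 + n1
    s1 = Y0 @ G1
    s0 = Y0 @ G0
    q1 = (Y0**2) @ G1
    q0 = (Y0**2) @ G0

    with np.errstate(divide="ignore", invalid="ignore"):
        rss0 = (q0 + q1) - (s0 + s1) ** 2 / n
        rss1 = (q0 - s0**2 / n0) + (q1 - s1**2 / n1)
        rss0 = np.maximum(rss0, 0.0)  # guard FP cancellation
        rss1 = np.maximum(rss1, 0.0)
        rss1 = np.maximum(rss1, LOD_EPS * rss0)
        lod = (n / 2.0) * np.log10(rss0 / rss1)

    lod = np.where(rss0 <= 0.0, 0.0, lod)  # flat trait: no variance, no signal
    lod = np.where((n0 == 0) | (n1 == 0), 0.0, lod)  # monomorphic marker
    lod = np.where(n < 3, np.nan, lod)
    marker_objs = (
        list(markers)
        if markers is not None
        else [Marker("un", j + 1, mid) for j, mid in enumerate(genotypes.col_ids)]
    )
    if [m.marker_id for m in marker_objs] != list(genotypes.col_ids):
        raise ValidationError("marker table does not match genotype matrix columns")
    return QTLScan(list(traits.row_ids), marker_objs, lod)


def find_peak(
    scan: QTLScan, probe_id: str, lod_threshold: float
) -> tuple[Marker, float] | None:
    """Highest-LOD marker for a probe, if strictly above the threshold.

    Ties go to the smallest (chrom, pos_bp).  Returns None when no marker
    exceeds the threshold.
    """
    profile = scan.profile(probe_id)
    if np.all(np.isnan(profile)):
        return None
    best = np.nanmax(profile)
    if not best > lod_threshold:
        return None
    tied = [scan.markers[j] for j in np.flatnonzero(profile == best)]
    peak = min(tied, key=lambda m: (m.chrom, m.pos_bp))
    return peak, float(best)


def flanking_probes(
    peak_marker: Marker,
    annotation: Iterable[ProbeAnnotation],
    count_per_side: int = 50,
) -> list[str]:
    """Closest probes on both sides of a peak marker, by genomic distance.

    Restricted to the peak's chromosome; probes order by midpoint (ties by
    probe_id).  Up to ``count_per_side`` probes with midpoint strictly
    before the peak position and up to ``count_per_side`` at-or-after are
    returned, in genomic order; fewer available means all are returned.
    """
    on_chrom = sorted(
        (p for p in annotation if p.chrom == peak_marker.chrom),
        key=lambda p: (p.midpoint, p.probe_id),
    )
    left = [p for p in on_chrom if p.midpoint < peak_marker.pos_bp]
    right = [p for p in on_chrom if p.midpoint >= peak_marker.pos_bp]
    window = left[-count_per_side:] + right[:count_per_side]
    return [p.probe_id for p in window]


_REGION_RE = re.compile(r"^(?:[Cc]hr)?([^:]+):(\d+)[-–](\d+)$")


def parse_region(text: str) -> GenomicRegion:
    """Parse "ChrV:15430739-16430739" (or en-dash, or bare "V:...") regions."""
    m = _REGION_RE.match(text.strip())
    if not m:
        raise ValidationError(
            f"cannot parse region {text!r}; expected Chr<NAME>:<start>-<end>"
        )
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start > end:
        raise ValidationError(f"region {text!r}: start {start} > end {end}")
    return GenomicRegion(chrom, start, end)


def region_probes(region: GenomicRegion, annotation: Iterable[ProbeAnnotation]) -> list[str]:
    """Probes whose [start_bp, end_bp] interval overlaps the region (inclusive)."""
    hits = [
        p
        for p in annotation
        if p.chrom == region.chrom and p.start_bp <= region.end_bp and p.end_bp >= region.start_bp
    ]
    hits.sort(key=lambda p: (p.midpoint, p.probe_id))
    return [p.probe_id for p in hits]


def hotspot_counts(
    scan: QTLScan, lod_threshold: float
) -> tuple[dict[str, int], Marker | None]:
    """Per-marker counts of probes whose peak lies at that marker.

    An eQTL hotspot shows up as a marker whose count towers over the rest
    (many traits mapping in trans to one locus).  Returns the counts keyed
    by marker id plus the top marker (None when no probe has a peak).
    """
    counts = {m.marker_id: 0 for m in scan.markers}
    for probe_id in scan.probe_ids:
        peak = find_peak(scan, probe_id, lod_threshold)
        if peak is not None:
            counts[peak[0].marker_id] += 1
    if all(c == 0 for c in counts.values()):
        return counts, None
    by_marker = {m.marker_id: m for m in scan.markers}
    # deterministic argmax: highest count, then genomic order
    top_id = min(
        (mid for mid in counts if counts[mid] == max(counts.values())),
        key=lambda mid: (by_marker[mid].chrom, by_marker[mid].pos_bp),
    )
    return counts, by_marker[top_id]
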