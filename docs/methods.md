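# Methods

## The phenolog test

Let the shared orthology background consist of N ortholog groups — connected
components of the bipartite graph of retained worm–human ortholog pairs that
contain at least one gene of each species. A worm phenotype's gene set
projects to n₁ of those groups, a human disease's to n₂, and k groups are
hit by both. Under the null hypothesis that the two projected sets are
independent uniform draws from the background, the overlap X is
hypergeometric and the reported significance is the inclusive upper tail

    P(X ≥ k) = Σ_{i=k}^{min(n1,n2)} C(n1,i) C(N−n1, n2−i) / C(N, n2).

The tail includes k itself; this convention is what makes the worked
example (N=4649, n₁=16, n₂=12, k=3 → 7.2×10⁻⁶) come out.

Assumptions worth keeping in mind: projections are treated as uniform draws
(no gene-length, annotation-density or study-bias correction), and each
ortholog group counts once however many genes it contains. Counting in
group space is the default (`counting="groups"`); `counting="genes"` counts
the projecting genes instead, and the two coincide on one-to-one
orthologies. Published phenolog tables mix backgrounds from different
database snapshots, so the toolkit accepts an explicit `N_override` to
reproduce a literature background; p-values from unknown snapshots are
otherwise not reproducible and are not targeted numerically.

### Numerics

Each term of the sum is evaluated as log-gamma binomials and the sum is
combined by log-sum-exp, so tails around 1e-243 and far beyond remain
finite and accurate in log space. Arguments are canonicalised (n₁ ≤ n₂)
so the n₁/n₂ symmetry is exact by construction. Exhaustive comparison with
big-integer rational arithmetic over every admissible (N ≤ 40, n₁, n₂, k)
— about 2.6×10⁵ cases — bounds the relative error near 5×10⁻¹⁴, two orders
below the 1e-10 contract; floating-point monotonicity in k and N holds up
to that same accuracy, which is why property tests compare with 1e-10
slack in log space. Probabilities returned out of log space are floored at
the smallest positive double so downstream sorting never sees an exact
zero.

### Sweeps and multiplicity

The broad sweep tests every (worm term, human term) pair; pairs with k=0
are omitted from the output (their p is 1) but kept in the
Benjamini–Hochberg denominator, so adjusted values are computed over the
full m = |worm terms| × |human terms| tests. BH is implemented directly
because the adjustment must accept an external test count m larger than
the list of reported p-values; it is cross-checked against statsmodels
when m equals the list length. Reported p-values are uncorrected by
default, with BH opt-in, and rankings break ties lexicographically on term
ids for determinism.

## LOD scanning

Traits are regressed on one biallelic marker at a time. With RSS₀ the
total sum of squares and RSS₁ the residual sum of squares of the
two-genotype group-mean fit over the n strains complete for the pair,
LOD = (n/2)·log₁₀(RSS₀/RSS₁), equivalently (n/2)·log₁₀(1/(1−r²)) for the
point-biserial correlation r (verified to 1e-9 on random fixtures).
Degenerate cases are made total: a flat trait (RSS₀=0) and a monomorphic
marker both score 0; a perfect fit is clamped with RSS₁ = 1e-12·RSS₀ so a
6-strain perfect split scores exactly 36 rather than infinity; fewer than
3 complete strains for a (probe, marker) pair is recorded missing.
Missing genotypes and trait values are handled by pairwise deletion per
marker. The whole scan is evaluated with indicator-matrix products, so a
500-probe × 250-marker × 100-strain panel takes well under a second.

Peak detection uses a strict ">" threshold and breaks LOD ties toward the
smallest (chromosome, position). The enrichment window around a peak takes
the closest `count_per_side` probes (default 50) on each side of the peak
marker by genomic midpoint distance, restricted to the peak's chromosome;
windows truncate at chromosome ends. Coordinates are 1-based inclusive
throughout, probe order is by integer midpoint with probe-id tie-breaks,
and region queries use inclusive interval overlap.

## Workflows

Genes, not probes, are the statistical unit: when a worm gene carries
several probes the enrichment counts it once, and `qtl2disease` includes
the query probe's own gene in the window's gene set. Multiple human
catalogs are tested separately and concatenated, preserving per-source
identity. Every workflow is a pure function of its inputs — rerunning on
the same files yields byte-identical outputs.

## The synthetic test bed

`SyntheticScenario` generates every input format with planted,
deterministic signal. Defaults describe the study conditions the package
is validated under:

* **Background**: 4649 one-to-one ortholog pairs at 100% bootstrap — the
  background of the worked phenolog example — plus an optional fraction of
  many-to-many edges (default 0) and 5% sub-100% bootstrap decoy pairs
  that the default filter must remove.
* **Catalogs**: one planted phenolog with (n₁, n₂, k) = (16, 12, 3),
  constructed from disjoint group draws so the counts recover exactly, and
  200 decoy terms per species with set sizes uniform on [10, 30],
  representative of curated disease-annotation sets. With these sizes a
  union-bound over the 40 000 decoy pairs puts the chance that some decoy
  outranks the planted pair (p ≈ 7.2×10⁻⁶) at a few percent, so the
  planted pair ranks first in ≳95% of simulated studies — markedly smaller
  decoy sets would make lucky two-gene overlaps more significant than the
  planted signal and is the regime in which phenolog screens genuinely
  lose power.
* **Genotypes**: 100 recombinant-inbred strains, 5 chromosomes with
  C. elegans-like lengths × 50 evenly spaced markers; per chromosome the
  genotype is a two-state Markov chain (first marker Bernoulli(1/2),
  adjacent-marker flip probability 0.1, giving adjacent-marker correlation
  0.8).
* **Expression**: 500 probes placed length-weighted along the genome.
  60 probes off chromosome V respond in trans to the middle marker of
  chromosome V (the planted hotspot); half of the remainder respond in cis
  to the marker nearest their own locus; the rest are pure noise. Effects
  are 2× the unit noise SD, i.e. R² = 0.5 and an expected LOD near 15 at
  n = 100 — comfortably above the LOD 5 working threshold yet small enough
  that peak positions still jitter by a marker.

Each artifact draws from its own seed-derived stream, so regenerating one
file never shifts another, and the same scenario and seed produce
byte-identical files.

What the generator does **not** emulate: linkage-map distortions, genotype
error, array-specific noise (probe effects, batch, heteroscedasticity),
correlated gene-set structure (pathway overlap between real disease
terms), many-to-many orthology by default, and identifier messiness.
Passing the planted-recovery suites therefore demonstrates correctness of
the statistics and plumbing under idealised conditions, not performance on
real catalogs, where annotation bias and correlated terms dominate the
error budget.

## Problem sizes used in validation

Recovery rates are estimated over 100 generated studies for the phenolog
sweep (200×200 terms each) and 100 generated scans for the eQTL suite;
the exhaustive tail validation covers all N ≤ 40; null calibration uses a
50×20-term no-signal sweep (1000 pairs), where the observed rejection
fraction at α = 0.05 stays well below α because the discrete exact test is
conservative. These sizes give binomial standard errors near 2 percentage
points on the recovery rates while keeping the full validation suite
around a minute.

## Known limitations

* Backgrounds from published phenolog tables are snapshot-dependent;
  without the snapshot the printed p-values cannot be regenerated, only
  the structure of the analysis.
* Gene identifiers are matched as exact strings; alias resolution is out
  of scope.
* Single-marker regression does not model multi-QTL traits and the LOD
  threshold is user-supplied; permutation-based thresholds are not
  implemented.
* Cumulative (genome-concatenated) coordinates are not supported; all
  regions are per-chromosome.
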