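# Methods

This note documents the models, parameter choices and numerical
conventions behind `metadepth`, and states explicitly what the
synthetic data can and cannot tell you about real sequencing
experiments.

## The evaluation problem

A shotgun-metagenomics profiling experiment yields, after read
classification and species-level abundance re-estimation, a per-sample
table of species read counts plus an unclassified remainder.  The
package asks one question of such tables: which conclusions —
presence/absence calls, diversity indices, abundance estimates,
between-sample structure, genome reconstruction — survive a reduction
in sequencing depth, and at what depth do they degrade?  Every stage
operates on the count table; classification itself (k-mer matching,
Bayesian read redistribution, database construction) is upstream and
out of scope, represented either by packaged benchmark tables or by the
synthetic classifier model below.

## Detection rule and threshold calibration

A species is *detected* when its read support is ≥ `min_reads`
(default 10) and its relative abundance is ≥ `min_frac` percent
(default 0.1).  Both comparisons are inclusive: an observed frequency
of exactly 0.1% passes, 0.096% does not.  The abundance basis is the
classified species-level read fraction by default; Bracken's
total-read basis is available (`basis="total"`), and the packaged
benchmark column detects the same 15 species on either basis.

The 0.1% default is not arbitrary: sweeping thresholds over the
packaged mock-community benchmark and scoring each against the
declared 20-species composition by F1 = 2TP/(2TP+FP+FN) puts the
maximum (F1 = 0.80: TP 14, FP 1, FN 6) at 0.1%.  Declared species
whose nominal abundance lies below the threshold (the five 0.02%
strains) count as false negatives rather than being excluded — the
threshold is being charged for what it cannot see.  Ties in a sweep
resolve to the smallest threshold.  One caveat is inherited from the
benchmark table itself: it censors estimated abundances below 0.1%, so
confusion counts at sub-0.1% thresholds are carried as recorded values
rather than recomputed (`calibration.sweep_from_counts`), and only the
0.1% and 0.5% rows are recomputable from abundances.

## Subsampling model

Reduced depth is a multivariate hypergeometric draw (without
replacement) over the category vector (species counts + unclassified):
exactly what drawing a random subset of reads from the FASTQ does to
the downstream count table, and distinct from a multinomial draw,
which would resample an infinite pool.  The multinomial is available
(`replace=True`) and is the right choice when sampling *from a
declared composition* rather than from observed reads.

Defaults follow the study design the package evaluates: depth grid
10k / 25k / 50k / 100k / 250k / 500k / 1M reads, 5 replicates per
depth, and a two-sided Student-t interval (df = 4) on the replicate
mean.  The confidence level is a required-explicit parameter with
default 0.99; 0.95 is exercised in tests because both conventions are
common in depth-curve figures.  A t-interval at n = 5 is the minimal
defensible choice; percentile intervals would need far more
replicates.  Replicate seeds derive deterministically from a master
seed and the (depth index, replicate index) pair via
`numpy.random.SeedSequence(entropy, spawn_key)`, so a whole 7 × 5 grid
reproduces from one integer.  Depths above the sample total are
skipped with a warning — depth is never inflated.

## Diversity and agreement

Shannon H = −Σ pᵢ ln pᵢ (natural log) and Pielou J = H/ln S are
computed over the species passing detection, with frequencies
renormalised to sum to one — S, H and J therefore describe the same
species set.  Computing on the raw (unthresholded) species list is
possible by passing the full abundance vector; thresholded is the
default and the documented convention.  Degenerate inputs error
rather than guess: no positive species → undefined H; S = 1 →
undefined J (ln 1 = 0).

Abundance agreement between two profiles is a correlation over the
species union with absences entered as zero (`union_zeros`), because a
reduced sample legitimately loses rare species and that loss is part
of the signal; intersection mode exists for sensitivity checks.  At
least 3 species are required.  Pearson on the percent scale serves
declared-vs-observed comparisons; Spearman serves full-vs-reduced,
where rank stability is the question.

## Beta diversity: ordination and Procrustes

Pairwise dissimilarity defaults to Bray-Curtis on detected-species
relative abundances (Hellinger/Euclidean available).  Ordination is
PCoA (deterministic eigendecomposition; the default for testability)
or NMDS (Kruskal stress-1 by monotone regression, 20 seeded random
starts keeping the best; the convention in published ordination
figures, used by the analysis drivers).  Dimensionality defaults to 2.

Procrustes superimposition centres both configurations, scales each to
unit sum of squares (symmetric mode), and takes the optimal rotation —
reflections permitted — from the SVD of the cross-product.  The
concordance statistic is t = Σσᵢ (the trace of the singular values),
equal to √(1 − m²) where m² is the residual sum of squares.  PROTEST
permutes the rows of one configuration; p = (1 + #{t* ≥ t})/(B + 1)
with B = 999 by default, so the smallest attainable p is 0.001.  The
implementation is checked in tests against scipy's Procrustes
disparity and a brute-force rotation-angle grid search, and the null
calibration of PROTEST is verified empirically (super-uniform at
α = 0.05 across 200 trials).

## Gene recovery

Per species, assembly completeness is summarised as fractions of a
conserved single-copy gene set complete / fragmented / missing
(summing to 1); the reconstructed fraction is complete + fragmented,
and per-sample recovery is its unweighted mean over detected species —
a species detected but absent from the table is an error, never a
silent zero.

The synthetic generator uses the Lander-Waterman model: at mean
coverage c = depth × abundance × read_length / genome_size, each base
is covered with probability 1 − e^(−c).  A gene of `gene_length`
(default 1000 bp) is discretised into ⌈gene_length/read_length⌉
segments (read_length default 125 bp → 8 segments); a gene is complete
when all segments are covered, missing when none is.  Per-species
uniform draws are seeded independently of depth, so recovery is
monotone non-decreasing in depth for a fixed seed — the coupling that
makes "deeper is never worse, seed for seed" a testable invariant.
Genome sizes default to 5 Mb (a typical bacterial genome) and can be
supplied per species; gene count per species defaults to 100.  This
deliberately ignores assembly: no contiguity, repeats, inter-species
k-mer sharing or assembler heuristics, only coverage.  It reproduces
the qualitative depth dependence (abundant tiers recover first;
recovery collapses below ~1× gene coverage) and nothing finer.

## Synthetic classifier output

`simulate_profile` draws `depth` reads multinomially from a declared
composition, then pushes each species' reads through a
misclassification kernel: per true species, a list of (emitted label,
probability) plus an `unclassified_rate` sink, summing to 1.  The
default mock model is the identity kernel with a single leakage
channel, 0.7% of *Escherichia coli* reads emitted as *Shigella
flexneri* — the one systematic false positive the benchmark exhibits,
at its observed magnitude (18% × 0.007 ≈ 0.126%, matching the recorded
0.128%) — and no unclassified reads.  Abundances are read-fraction
abundances; genome-size weighting is deliberately omitted because the
declared compositions being emulated are themselves specified as read
fractions.

`simulate_study` builds multi-sample panels: per sample, a target
detectable richness (the number of species at or above the 0.1%
floor), a depth, and a long-tailed abundance distribution (log-normal
with σ default 1.0; log-series available — neither is privileged by
evidence, both span realistic evenness).  Because a long-tailed draw
pushes part of the community below the detection floor, the community
size is grown iteratively until the detectable count lands within
~10% of the target (cap 60 iterations, closest draw kept); targets up
to 1000 species are feasible by the pigeonhole bound (1000 × 0.1% =
100%).  Species identities are drawn per sample from a shared pool of
300 names so that samples overlap partially; richness targets in the
default panel (4–138) span the range observed across heterogeneous
real matrices (mock, vaccines, feces, food).

**What the simulator does not reproduce.**  Reads are abstract labels:
no sequences, no sequencing error, no read-length effects, no database
content.  Real classifier output differs in ways that matter for some
conclusions: (i) abundance estimation biases are database-driven and
species-specific (the real benchmark shows declared-18% species
estimated anywhere from 11.7% to 25.9%), while the identity kernel is
unbiased — so expected-vs-observed correlations on simulated mocks are
optimistic (~1.0 at 10⁴ reads, against ~0.94 from the recorded
benchmark column); (ii) unclassified fractions in real samples can be
large and composition-dependent, while the default is 0; and (iii) the
default panel's between-sample Bray-Curtis distances are dominated by
abundant, precisely re-estimated species, so the NMDS configuration is
almost invariant under subsampling (Procrustes r ≈ 0.9999 at every
depth) — real surveys show depth-dependent ordination drift that this
panel does not generate.  Passing tests on synthetic data therefore
validate the *machinery* (sampling laws, estimators, statistics,
determinism), not classifier accuracy on any real matrix.

## Numerical conventions

- F1 and diversity values are carried at full double precision;
  comparisons against printed benchmark scores round half-up to the
  printed 2 decimals.
- Percent→count conversion of printed benchmark columns uses half-up
  decimal rounding at the declared sample total, with the unclassified
  count absorbing the remainder; exactness-sensitive detection checks
  use the printed fractions directly.
- Packaged tables are verified against frozen SHA-256 checksums at
  load time; `NP` (below threshold) and `ND` (not declared) sentinels
  are preserved, never coerced to 0.
- All randomness flows through `numpy.random.Generator` seeded by
  explicit integers or `SeedSequence` spawn keys; no global state.
- The pipeline writes a manifest (seed, grids, model parameters, tool
  version) sufficient to reproduce every output byte-for-byte on a
  fixed platform.

## Problem sizes

Defaults were chosen so the full simulated study runs in about a
minute on one core: mock at 2M reads, six panel samples at 1.3-2M
reads, the 7 × 5 subsampling grid, NMDS with 20 starts per (depth,
replicate), PROTEST at 999 permutations, and 100-gene recovery tables.
The test suite uses smaller instances throughout (tiny pools for
exact-law checks, 10⁵-10⁶-read draws for statistical bounds) and runs
in well under a minute.

## Known limitations

- Bray-Curtis on compositional (relative) data inherits the usual
  compositional-data caveats; no log-ratio alternative is provided.
- The NMDS stress returned is scikit-learn's normalised stress-1;
  values from other implementations (e.g. isoMDS variants) can differ
  slightly in convergence behaviour.
- The richness calibration targets *detectable* richness under the
  0.1%/10-read rule at the design depth; at other thresholds the
  panel's richness ladder shifts.
- Confusion counting assumes exact binomial-name matching; no taxonomy
  resolution (synonyms, reclassifications) is attempted.
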