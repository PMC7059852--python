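# metadepth

How far can you cut shotgun-metagenomics sequencing depth before the
answers change?  `metadepth` implements the complete coverage-reduction
evaluation for species-level taxonomic profiles: calibrating a
detection threshold on a staggered mock community, subsampling reads to
emulate shallower sequencing, and measuring what survives — richness,
diversity indices, abundance estimates, community ordination and
(simulated) gene recovery.

It is written for microbiome researchers deciding how many reads per
sample a profiling study actually needs, and for anyone benchmarking a
classifier against a mock community.

## What it computes

**Detection rule.** A species is present in a sample when it is
supported by ≥ 10 reads *and* its relative abundance is ≥ 0.1%
(both inclusive).  The 0.1% operating point is calibrated on the
20-species staggered mock community (ATCC MSA-1003; 5 species at each
of 18%, 1.8%, 0.18% and 0.02%) by maximising

  F1 = 2·TP / (2·TP + FP + FN),

the harmonic mean of precision and recall, appropriate when true
negatives are unknowable.

**Depth reduction.** A lower depth is emulated by drawing a fixed
number of reads without replacement — a multivariate hypergeometric
draw over the species count vector — replicated five times per depth
on the grid 10k, 25k, 50k, 100k, 250k, 500k, 1M reads, with two-sided
Student-t confidence limits (default 99%).

**Alpha diversity.** Observed richness S (species passing detection),
Shannon H = −Σ pᵢ ln pᵢ (nats, over detected species renormalised to
Σpᵢ = 1) and Pielou evenness J = H / ln S.

**Abundance agreement.** Pearson/Spearman correlation between
abundance vectors over the species union (lost species enter at 0):
declared-vs-observed for the mock, and full-vs-reduced per sample.

**Beta diversity.** Bray-Curtis dissimilarities → PCoA or NMDS
(seeded multi-start, Kruskal stress-1) → symmetric Procrustes
superimposition of reduced onto full ordination, with the correlation
statistic t = √(1 − m²) and a PROTEST row-permutation test
(p ≥ 1/1000 at the default 999 permutations).

**Gene recovery.** BUSCO-style completeness tables (complete /
fragmented / missing gene fractions per species); a species'
reconstructed fraction is complete + fragmented, averaged unweighted
over detected species per sample.  A Lander-Waterman simulator
(P(base covered) = 1 − e^(−c) at mean coverage c) generates synthetic
tables to study the depth dependence.

Because the original study's raw reads and reference databases are not
needed, a synthetic module emulates classifier output directly:
multinomial reads from a declared composition pushed through a
misclassification kernel (default: identity plus 0.7% *Escherichia
coli* → *Shigella flexneri* sister-species leakage), and multi-sample
panels with 4–138 detectable species drawn from long-tailed abundance
distributions.

## Worked example

Calibrate the detection threshold on the packaged mock-community
benchmark (estimated abundances of the mock under the broadest
reference database):

```
$ metadepth calibrate
 threshold  tp  fp  fn       f1
     0.001  19 188   1 0.167401
     0.005  19  49   1 0.431818
     0.010  19  32   1 0.535211
     0.050  15   6   5 0.731707
     0.100  14   1   6 0.800000
     0.500  10   0  10 0.666667
best threshold: 0.1%
```

At 0.1%, 14 of 20 declared species are recovered with one false
positive (*Shigella flexneri*, a misclassification sink for
*E. coli* reads) — F1 = 0.80, the maximum of the sweep.  The six
misses are the five 0.02% species, undetectable by construction at
this threshold, plus one 0.18% species observed at 0.096%.

Simulate a mock run, reduce it, and watch the indices:

```
$ metadepth simulate --seed 1 --depth 1000000 -o mock.tsv
$ metadepth diversity mock.tsv
mock    S=16    H=1.9673        J=0.7095
$ metadepth subsample mock.tsv --depth 10000 --seed 1 -o mock10k.tsv
$ metadepth diversity mock10k.tsv
mock10k S=16    H=1.9696        J=0.7104
```

Sixteen species pass detection (15 mock species at or above 0.1% plus
the leakage false positive); Shannon and Pielou barely move between
10⁶ and 10⁴ reads, because both are dominated by the abundant tiers.

The numbered drivers under `analysis/` run the full study on simulated
data (threshold sweep, richness panel, depth curves, abundance
agreement, Procrustes stability, gene recovery) and write their tables
under `results/`; `metadepth run` does the same from a single YAML
config with a reproducibility manifest.  For example,
`analysis/04_abundance_agreement.py` prints mean full-vs-reduced
Spearman ρ rising from 0.987 at 10,000 reads to 0.998 at 1,000,000,
and `analysis/06_gene_recovery.py` shows mean recovery over detected
species falling from 0.949 at full depth (~5M reads) to 0.777 at 1M,
with the 1.8% tier collapsing while the 18% tier stays complete.

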