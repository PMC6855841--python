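# Methods

This note records the models implemented in phylotx, the choices made
where more than one reasonable design existed, and what the synthetic
data can and cannot show about real data.

## Phylostrata and Dollo gene ages

A species tree must be supplied rooted; a basal polytomy is rejected as
the signature of an unrooted newick (no midpoint or outgroup rooting is
attempted). The root→focal ancestor chain defines strata ranked 1
(root) to S (the focal leaf). Internal multifurcations elsewhere are
allowed and handled natively by the containing-leafset test used for
MRCA lookup: the gain node of a focal-containing presence pattern is
the deepest chain node whose descendant leaf set covers all carriers,
which is exactly the pattern's last common ancestor, the unique
minimal-loss single-gain placement under Dollo parsimony (verified
exhaustively in the tests). Numbering follows the convention in which
1 is oldest and S youngest, so that a higher TAI reads as a younger
transcriptome; the age-table writer can emit the flipped numbering for
interoperability with tables that count the other way.

Genes whose orthogroup is absent from the phyletic matrix are an
error; genes with *no* orthogroup at all are focal-specific by
definition and receive stratum S. Species present in the tree but
missing from the matrix are treated as all-absent with a logged
warning, which tolerates partial proteomes at the cost of a
younger-biased age for orthogroups whose only basal carriers are the
missing species.

## Expression processing

* **Low-expression filter.** A gene is kept iff its arithmetic mean
  tpm over *all* samples of both replicates is ≥ the threshold
  (default 0.5 tpm). The boundary case (mean exactly at threshold) is
  retained; only strictly-below genes are removed.
* **Replicate alignment.** A replicate that ran late by Δ hours has
  its timepoint labels shifted back by Δ (which must be an integer
  multiple of the sampling interval); samples whose corrected label
  falls outside the window common to all replicates are dropped and
  logged. The default pipeline applies no shift.
* **Sample dendrogram.** Spearman correlation between all sample
  pairs over genes; the distance between two samples is the Euclidean
  distance between their rows of the correlation matrix; average
  linkage. A zero-variance sample has no defined rank correlation and
  is assigned correlation 0 with a warning. Linkage choice (average)
  is a design decision; the dendrogram is computed on the filtered
  gene set by default.
* **Normalization.** log2(tpm+1) followed by a per-gene z-score
  (population sd). For clustering, the z-score is taken within each
  replicate and replicates are concatenated as extra profile
  dimensions. Zero-variance genes cannot be standardized and are
  excluded with a warning. All normalization arithmetic runs on a
  C-contiguous array so the output is a bit-exact function of the
  values alone, independent of the incoming DataFrame's memory layout
  — without this, bitwise-identical inputs could cluster differently
  at degenerate (duplicate-profile) corners.

## Consensus clustering

The published analyses this package mirrors use a consensus clustering
tool as a black box whose defining behaviours are tight clusters plus
an unassigned remainder; phylotx implements those behaviours as a
transparent, seedable procedure rather than porting any tool:

1. k-means (k-means++, one init per run, recorded seeds) for every k
   in `k_grid` (default 5..15) × `n_base_runs` (default 20) seeds.
   Exactly duplicated profiles are collapsed before fitting (with
   sample weights) so k never exceeds the number of distinct points;
   k-means would otherwise break ties through empty-cluster
   relocation, nondeterministically in effect.
2. The gene×gene co-assignment frequency matrix C.
3. Average linkage on 1−C, cut at height 1−τ (default τ = 0.7);
   candidate clusters are pruned by repeatedly removing the member
   with the lowest mean co-assignment to the rest until all members
   sit at ≥ τ; clusters smaller than `min_cluster_size` (default 10)
   dissolve into the unassigned pool.

Because the cut partitions are nested as τ rises and pruning only
removes members, raising τ does not increase the number of assigned
genes. The whole procedure is deterministic given the run seed.

Replicate robustness is scored by clustering replicate 1 alone,
replicate 2 alone, and the per-timepoint average, then reporting the
pairwise adjusted Rand index over genes assigned in both runs.

## TAI and the reductive hourglass test

TAI is computed on tpm of the filtered ("expressed") gene set — not on
normalized values, since the index weights by expression level — and
separately per replicate. Phases are declared as index sets into each
replicate's sorted timepoints; the default split is 2/4/4
(early/mid/late) for a 10-timepoint course. The test statistic
D = min(early−mid, late−mid) of phase-mean TAI is one-sided in the
hourglass direction. The null permutes the gene→stratum labels,
keeping the expression matrix fixed, which preserves the expression
covariance structure under the hypothesis of no age–expression
association. The empirical p-value is (1 + #{D_perm ≥ D_obs})/(B+1)
with a 1e-12-scale tie tolerance, so a constant-TAI (single-stratum)
transcriptome cleanly yields D = 0, p = 1, and a flagged degenerate
null in which the Gaussian-tail p is reported as undefined rather
than fabricated. The permutation test is exact by construction; its
measured null rejection rate at α = 0.05 matches the discrete
attainable level (10/201 with 200 permutations).

Per-stratum summaries: CV = sample sd / mean (n−1 denominator) of a
gene's tpm across timepoints, computed on values averaged across
replicates; zero-mean genes are excluded with a logged count. Mean
expression by stratum is analogous.

## Fisher exact tests

The 2×2 test is evaluated from the hypergeometric distribution in
exact integer arithmetic: each p-value is a single ratio of integer
sums, so the only rounding is the final float conversion, and
two-sided ties (tables with exactly the observed probability) are
resolved by exact comparison rather than a floating tolerance. This
hand-rolled core exists because (a) the two-sided tie rule should not
depend on a 1e-7 fudge factor and (b) the acceptance checks sweep
every table with total ≤ 60, which needs a per-table cost far below a
general-purpose routine's; scipy's `fisher_exact` serves as an
independent cross-check in the tests, and an exhaustive enumeration
over transposed margins as the oracle. Odds ratio is ad/bc with ∞ when
bc = 0 and ad > 0, NaN for 0/0. Enrichment reports are one-sided
(enrichment direction) with the two-sided value always included, and
BH-adjusted across the (cluster × stratum) family by default; the
universe is all filtered genes, not only cluster-assigned ones.

## Synthetic data

The generator plants every signal the pipeline measures, at the scale
of a desk-top study: a 10-stratum focal lineage with 30 outgroups
spread along the chain; one orthogroup per gene (with a ~10% no-
orthogroup fraction); two replicates of a 10-timepoint course sampled
every 6 h; half of all genes below the 0.5-tpm filter; five planted
co-expression programs of 100 genes each.

* **Dollo patterns.** Gain node drawn from `gain_weights`; every
  branch strictly below the gain loses the family independently with
  probability `loss_prob` (losses inherited), except the gain→focal
  path, where presence is forced. A per-branch Bernoulli is used
  rather than rate×length because the trees carry no meaningful
  branch lengths for this purpose.
* **Cluster programs.** Unit-scale profiles: growth programs that
  shut off sharply at staggered early times, a transient mid pulse,
  and late programs switching on sharply (transitions complete within
  about one sampling interval). Pure time-shifted copies of one
  sigmoid were rejected because per-gene standardization collapses
  them to nearly collinear shapes that no clustering method should be
  expected to separate; the default shapes stay distinct after
  z-scoring, as the sharp, well-separated transcriptional waves they
  emulate do.
* **Background genes.** Unclustered expressed genes follow a
  mean-reverting log-scale trajectory (stationary AR(1), step
  autocorrelation 0.3, stationary sd `background_sigma`, default 0.6
  log2 units) drawn once per gene and shared by both replicates, so
  backgrounds vary in time yet remain mutually near-independent.
  Setting `background_sigma = 0` makes them flat — the configuration
  used when truly unstructured (noise-only) backgrounds are wanted,
  e.g. for clustering-recovery benchmarks. With the default, a
  minority of backgrounds genuinely co-drift and may form small
  clusters; that is intended realism, not an error.
* **Hourglass planting.** The mean of gene *i* at mid-phase
  timepoints is multiplied by 1 + δ·w(age_i), where w maps the oldest
  stratum to +1 and the youngest to −1 linearly; δ > 0 plants an
  hourglass, δ < 0 the inverse, δ = 0 the null. Products that would
  go negative are clipped at 0 with a logged warning.
* **Noise and baselines.** Observed tpm = mean × exp(N(0, σ²))
  (multiplicative log-normal, default σ = 0.2, preserving
  non-negativity). Expressed baselines span ~5–200 tpm
  (log-uniform); the low-expression fraction is placed so its
  *expected* mean stays below 0.4 tpm after the log-normal mean
  inflation.
* **Replicate offset.** Optionally, replicate 2's sample at slot t
  shows the biology of slot t−Δ (edges clamp), emulating a replicate
  that runs slow while keeping its nominal labels.

What the generator does **not** emulate: count noise at low depth,
library-size or composition artifacts in tpm, genes belonging to
several programs, correlated losses across related species, or
annotation error in the membership table. Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
robustness to those real-data pathologies.

## Problem sizes and determinism

Simulation-based checks run at 1,000–2,000 genes, 500 null datasets
for test calibration (200 permutations each) and 100 datasets for
power (1,000 permutations each) — sizes chosen so the whole suite
finishes in about a minute while leaving the binomial margins of the
calibration checks comfortable. Every stochastic component consumes a
single explicit seed; two runs with the same inputs, configuration and
seed produce byte-identical outputs. Seeds derived internally (base
learners, per-replicate permutation streams) come from
`numpy.random.SeedSequence` spawns of the run seed.

## Known limitations

* Dollo parsimony systematically under-ages genes whose basal
  carriers were lost or unsampled; the package quantifies that bias
  on simulations but cannot correct it.
* The consensus scheme's cluster count depends on τ and the k grid;
  no claim is made that any particular count on real data is
  recoverable, only that planted, well-separated programs are.
* The Gaussian-tail hourglass p-value can be extreme (normal fit far
  in the tail); the empirical p-value is bounded below by 1/(B+1) and
  is the one to report.
* `RunConfig.phase_counts` must be chosen by the analyst; the 2/4/4
  default assumes a 10-timepoint course with flanking phases of the
  stated sizes.
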