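# Methods

`chromdyn` analyzes a three-condition chromatin-accessibility time course —
an in vitro baseline and two in vivo time points (early and late metastatic
colonization) — from peak-level fragment counts through trajectory clusters,
candidate target genes, candidate regulator motifs, and context-specific
fitness dependencies from a paired CRISPR dropout screen. This note records
the model, the parameters that matter, the numerical conventions, and what
the synthetic-data generator does and does not emulate.

## Accessibility matrix

Coordinates are 0-based half-open (BED) throughout; any 1-based dialect must
be converted at the reader boundary. The peak universe is the union-merge of
per-sample peak calls (`min_gap = 0`, i.e. overlapping or book-ended
intervals join). Fragment counting is overlap-based: a fragment adds at most
1 to each peak it overlaps by ≥1 bp; per-base insertion-site counting is out
of scope.

Counts are converted to FPKM,

    fpkm(i, j) = count(i, j) / ((length_i / 1e3) * (total_j / 1e6)),

with `total_j` defaulting to the per-sample sum of universe counts
(overrideable via the sample metadata), then quantile-normalized across
samples. Quantile normalization uses the mean sorted profile as reference;
ties within a column receive the mean of the reference values over the ranks
the tie group occupies (the "average" convention).

Peaks are split by pooled coefficient of variation, CV = sd(ddof=1)/mean
across all samples of the normalized FPKM matrix; CV < 10% (or an undefined
CV at zero mean) defines the pseudo-static bin, and the remaining dynamic
peaks are row z-scored (mean 0, sd 1, ddof=1). Normalization happens before
the CV screen; a config flag is not provided because the partition operates
on whichever matrix it is handed. The sample ordination (PCA) runs on
log2(x+1) of the normalized values with peaks centered; component signs are
fixed by making the largest-magnitude loading positive so coordinates are
reproducible.

## Trajectory clustering

Dynamic peaks are summarized as condition-mean z-profiles (a 3-vector),
which neutralizes the unequal replicate structure (3 in vitro / 3 early / 5
late), and clustered by k-means, k = 8 by default, best of `n_init = 50`
k-means++ restarts under one seed. Cluster indices are re-ordered
deterministically (descending early−invitro centroid shift, then descending
late−invitro) so outputs are stable; centroids are recomputed as member
means. A silhouette score is reported as a robustness diagnostic; no
automatic k selection is attempted.

Each centroid gets a trajectory archetype by comparing in vivo points to the
in vitro baseline with a margin `delta = 0.5` z-units: both points up →
pan_gain; early only → early_gain; late only → late_gain; mirrored rules for
losses; otherwise complex. The pan branches are tested first, so a profile
whose early and late points both clear the margin is "pan" even when the
early shift is larger.

## Gene linking

Each gene's basal regulatory domain spans 5 kb upstream to 1 kb downstream
of its TSS (strand-aware), extended toward the nearest flanking basal domain
up to 1 Mb from the TSS and clipped to the chromosome; extensions never
shrink below the gene's own basal window, so basal domains of close
neighbors may overlap. A peak is associated with every gene whose extended
domain contains the peak midpoint (half-open containment; ties are
impossible).

Region filters before enrichment: (i) log2 fold-change of condition-mean
FPKM, in vivo over in vitro, above 1 for either in vivo time point, with a
pseudocount of 1 on both means for bounded behavior at zero; (ii) per-peak
one-way ANOVA across conditions at p < 0.05. ANOVA degenerate cases use
sentinels — zero within-group variance with unequal means reports p = 0; an
all-identical row reports F = 0, p = 1.

Term enrichment reports GREAT's two statistics: a region-based binomial test
(success probability = genomic fraction covered by the union of the term
genes' extended domains; observed = cluster regions whose midpoint lands in
that union) and a gene-based hypergeometric test (population = all modeled
genes; draws = genes associated with the cluster's regions), both
BH-adjusted across terms. Ontologies are not bundled; gene sets arrive as
GMT so synthetic sets can exercise the statistics.

Cluster expression summaries z-score each gene's condition-mean TPM across
conditions (ddof=1) and report the per-cluster, per-condition distribution
as boxplot statistics (median, quartiles, 1.5×IQR whiskers clipped to the
data); a gene linked through several peaks of one cluster counts once.

## Motif analysis

JASPAR count matrices are column-normalized, regularized with a 0.01
pseudocount per cell, and renormalized; the background is uniform unless
supplied. Scanning scores each window by summed log2(p/background) on both
strands; `N` contributes 0. A region is a hit when its best score reaches
0.8 of the maximum achievable score.

Per-cluster differential enrichment uses a signed hypergeometric z: with the
clustered regions as universe, `p_enr = P(X ≥ x)` and `p_dep = P(X ≤ x)` for
the observed hit count; the reported z is the normal quantile of the smaller
tail, positive for enrichment, capped at ±10 against p-value underflow.
Motifs whose best cluster |z| ≥ 6 are the reported regulators. This single
defined statistic replaces an ensemble motif-activity method whose
internals are not reproducible here; what matters downstream — which motifs
clear the display threshold in which cluster — is preserved. TF-expression
concordance correlates a TF's condition-mean expression with a cluster
centroid across conditions; `r ≥ 0.9` flags concordance, and flat or missing
TF profiles are flagged rather than dropped. With three conditions r is
coarse (a cosine in a 2-plane), which is why the default bar is high.

## Dropout screen

Counts-per-million with a 0.5 pseudocount; per-guide log2(final/input) with
replicate pairing when final and input replicate indices match one-to-one
(otherwise each final replicate is compared to the mean input profile); gene
fold-change is the unweighted mean over the gene's guides. Significance uses
a resampled non-targeting null: the null statistic for an m-guide gene is
the mean of m draws (with replacement) from the non-targeting guide
fold-changes, B = 10,000 draws, and `p = (1 + #{null ≤ observed}) / (B+1)`,
one-sided for depletion. The external web service used for the original
screen analysis does not publish its statistic; this null is the package's
own, fully specified replacement and preserves the published decision rule.
BH FDR is computed per arm over targeted genes only (controls excluded). A
gene is a hit in an arm when FDR < 0.05 and log2FC < −1; hits in both arms
are "common", one arm gives the context-specific classes. Mouse pooling is
a generator concern; the analyzer sees one count column per replicate.

## Comparison statistics

Two-sided Fisher exact test with the probability-mass criterion and an exact
conditional-likelihood confidence interval for the odds ratio (sample
`ad/bc` with 0/∞ conventions at zero cells); one-sided hypergeometric set
overlap; per-cluster Pearson correlation of motif z-profiles with pairwise
missing-value dropping (fewer than 3 shared motifs → flagged undefined).
When two peak universes are compared, the documented universe is their
union-merge and "overlap" means ≥1 bp intersection.

## Synthetic-data generator

The generator emulates the study's structure, not its data: 8 planted
trajectory archetypes × 200 peaks plus 800 static peaks laid on a jittered
10-kb lattice over a 25-Mb two-chromosome genome (500-bp peaks), replicates
3/3/5, sequencing depth 2.5e6 in-peak fragments per sample with a lognormal
(sdlog 0.2) per-sample jitter, lognormal peak baselines (sdlog 1).

Counts are negative binomial in the NB1 (linear overdispersion) family:
Var = μ·(1 + φ) with φ = 0.1 by default, realized as a Gamma–Poisson
mixture; φ → 0 recovers Poisson. Two design points follow from the CV<10%
static rule. First, the NB1 family is used because a quadratic-variance
(NB2) family puts a depth-independent floor of √φ on every peak's CV, which
at any appreciable overdispersion leaves the static bin empty — under NB1
the CV shrinks as √((1+φ)/μ), so a static bin exists at realistic depth.
Second, the default depth sits at the upper range of a well-sequenced bulk
library (~1000 fragments per peak) because the CV rule only has resolving
power when counts exceed roughly (1+φ)/0.01 ≈ 110 per peak. Real ATAC-seq
biological replicates are often more dispersed than this; on such data the
static bin shrinks accordingly, and passing recovery tests here demonstrates
correctness of the machinery, not that a 10% CV cut is well-calibrated for
any particular dataset.

Because row z-scoring is affine-invariant, only the standardized shape of an
archetype's condition multipliers matters. The eight default shapes are
placed at equal angular spacing in the replicate-weighted z-profile plane,
anchored at the canonical early-gain trajectory (folds ≈ 3.1–3.5×), giving
adjacent shapes 2.42 z-units of separation in the per-sample metric — the
most separable 8-shape configuration; pairwise separation above ~1.35
z-units is geometrically impossible in the unweighted 3-condition metric, so
recovery quality is intrinsically bounded by the count noise level.

Expression: linked genes' condition-mean log2 TPM follows amplitude (2 log2
units) × concordance (1.0) × the archetype z-trajectory plus condition noise
(sd 0.25) and replicate noise (sd 0.1); unlinked genes are flat; columns are
renormalized to TPM (1e6), which perturbs profiles slightly (per-condition
scale factors), so "perfect concordance" reproduces trajectories to r ≈ 0.99
rather than exactly. Note that for 3-point profiles the correlation of
independent profiles has mean |r| = 2/π ≈ 0.64 (cosine of a uniform angle),
the correct baseline for "no concordance".

Sequences are iid uniform ACGT with one 8-bp consensus motif per archetype
planted in 60% of the archetype's own regions and 5% of all other regions,
random position and strand; PFMs give the consensus base a count of 100, so
the regularized consensus probability is ≈ 0.971 and only exact consensus
windows clear the 0.8 relative-score threshold.

Screen: 78 target genes × 4 guides, 11 positive-control genes × 4 guides,
25 non-targeting guides; day-0 abundances lognormal (sdlog 0.5); planted
effects follow the published hit partition in spirit — 8 in vivo-specific,
3 in vitro-specific, 6 common at log2FC −2, positive controls −3 in both
arms; guide-level fold-changes add N(0, 0.3) around the gene effect;
coverage 400 reads per guide; NB1 dispersion 0.05. Final libraries are
renormalized to fixed depth, so strong depleters shift other guides slightly
upward — the compositional effect real screens have.

Not emulated: read-level data (FASTQ), mouse-read contamination,
GC/mappability bias, peak-calling artifacts, correlated guide efficiencies,
and real ontologies. Recovery results on generator output therefore validate
the statistical machinery and decision rules, not performance on raw
sequencing data.

## Determinism and problem sizes

Every stochastic step takes an explicit seed (one master seed per simulated
study; k-means and the screen null take their own); the pipeline refuses to
run stochastic stages without one. Identical config and inputs give
byte-identical output tables (timings go to `run.log` only). Default
problem sizes — 2,400 peaks, ~1,600 dynamic, ~1,200 genes, 8 motifs, 429
guides — keep a full end-to-end run under ~10 s on one CPU; the sizes are a
deliberate desk-scale choice that leaves the statistics honest (hundreds of
regions per cluster, 400× screen coverage) while allowing many-seed
calibration runs.

## Known limitations

- The archetype annotation is a fixed-margin rule on 3-point profiles; it is
  not a statistical test and has no uncertainty attached.
- The hypergeometric motif z treats regions as exchangeable; GC- or
  length-matched backgrounds are not implemented.
- The screen null resamples non-targeting guides, which carry no
  guide-efficiency variance; p-values for true-null targeted genes are
  slightly anticonservative, but the fold-change arm of the hit rule keeps
  the realized false-hit rate near zero (measured, not assumed).
- Fisher's conditional-likelihood CI and the probability-mass two-sided
  p-value can disagree near ties; both conventions are documented above.
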