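# chromdyn

Temporal chromatin-accessibility trajectory analysis for multi-condition
ATAC-seq time courses, with paired CRISPR dropout-screen hit calling.

Metastatic colonization is a staged process: cells that seed a distant organ
face different stresses early (survival, immune evasion) and late
(outgrowth, matrix remodeling), and their regulatory landscape shifts
accordingly. Given accessibility profiles of the same cells in vitro and at
early and late in vivo time points, `chromdyn` answers four questions:

1. **Which regulatory regions change, and how?** Peak×sample fragment counts
   are FPKM- and quantile-normalized; peaks with coefficient of variation
   below 10% form a pseudo-static bin, and the dynamic remainder is
   z-scored and k-means-clustered (k = 8) into trajectory archetypes —
   early, pan-in-vivo, or late gains and losses.
2. **Which genes do the dynamic regions regulate?** GREAT-style
   basal-plus-extension regulatory domains (5 kb up / 1 kb down of the TSS,
   extended to the nearest neighbor up to 1 Mb) associate peaks to genes by
   midpoint containment; cluster-level gene-set enrichment uses the
   region-based binomial and gene-based hypergeometric tests with BH
   correction, after log2FC > 1 and per-peak ANOVA (p < 0.05) region filters.
3. **Which transcription factors drive each trajectory?** PWM scanning of
   region sequences (log-odds, both strands, 0.8 relative-score threshold)
   feeds a per-cluster signed hypergeometric z; motifs with |z| ≥ 6 are
   reported, and their TFs are checked for expression dynamics that mirror
   the cluster (Pearson r ≥ 0.9 across conditions).
4. **Which of those TFs does the tumor actually need, and where?** A paired
   in vitro / in vivo dropout screen is scored against the day-0 library:
   gene log2 fold-changes, a resampled non-targeting-guide null, BH FDR per
   arm, and the hit rule FDR < 0.05 ∧ log2FC < −1, classifying each gene as
   in vivo-specific, in vitro-specific, common, or neither.

A synthetic-data generator (`chromdyn.simulate`) emits every input the
pipeline consumes — peak universe, counts, gene models, expression, region
sequences, JASPAR motifs, screen counts — with planted ground truth, so the
whole chain is testable without any download. See `docs/methods.md` for the
model details and design choices.

## Worked example

```bash
# generate a complete synthetic study (13 files incl. ground_truth.json)
chromdyn simulate --seed 7 --outdir study/

# run every stage; outputs are byte-identical across reruns
chromdyn all --config config.yaml --outdir out/ --seed 7
```

with `config.yaml` pointing at the generated files:

```yaml
inputs:
  genome: study/genome.txt
  universe: study/universe.bed
  counts: study/counts.tsv
  sample_metadata: study/samples.tsv
  gene_models: study/genes.tsv
  expression: study/expression.tsv
  expression_metadata: study/expression_samples.tsv
  gene_sets: study/gene_sets.gmt
  sequences: study/regions.fasta
  pfms: study/motifs.jaspar
  screen_counts: study/screen_counts.tsv
  screen_metadata: study/screen_samples.tsv
```

`out/` then contains, among others, `partition.tsv` (per-peak CV and
static/dynamic call), `clusters.tsv` and `centroids.tsv` (cluster, archetype
and condition-mean z-profiles), `term_enrichment.tsv`, `motif_enrichment.tsv`
and `screen_results.tsv`. The same run from Python:

```python
import chromdyn as cd

study = cd.simulate_all(cd.SimulationConfig(seed=7))
qn    = cd.quantile_normalize(cd.fpkm(study.counts))
part  = cd.cv_partition(qn, threshold=0.10)
z     = cd.zscore_rows(qn.subset_rows(part.dynamic_ids))
res   = cd.kmeans_cluster(cd.condition_profiles(z), k=8, seed=7, n_init=50)
print(len(part.static_ids), "static peaks;", dict(res.sizes()))
print(res.centroids.round(2))
```

prints (seed 7):

```
697 static peaks; {1: 207, 2: 225, 3: 220, 4: 225, 5: 207, 6: 212, 7: 205, 8: 202}
condition  invitro  early  late
cluster
1            -1.40   1.07  0.20
2            -0.55   1.46 -0.55
3            -1.35  -0.01  0.82
4             0.57   1.00 -0.94
5            -0.59  -1.07  0.99
6             1.40  -0.01 -0.83
7             0.59  -1.52  0.56
8             1.42  -1.08 -0.20
```

i.e. the eight archetype centroids: cluster 2 is the early-gain shape (up
only at the early in vivo point), clusters 1 and 3 are the two pan-in-vivo
gain shapes, 5 is the late gain, and clusters 4, 6, 7, 8 their mirrored
losses. Against the generator's ground truth this clustering reaches an
Adjusted Rand Index of 1.0 (seed 7; ≥ 0.99 across seeds), and each cluster's
archetype annotation matches its planted majority.

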