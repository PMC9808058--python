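# repsig

Promoter repeat-content profiling of gene sets, and survival risk-score
stratification of expression cohorts.

Many regulatory analyses ask two recurring questions about a curated gene set
(for example, ferroptosis-related genes in a cancer cohort):

1. **Which repetitive elements sit in these genes' promoters, and do they
   partition the genes?**  Interspersed repeats — SINEs such as Alu and MIR,
   LINEs such as L1 and L2 — are common in promoters and can shape local
   transcription.
2. **Does a gene signature built from this set stratify patient survival?**

`repsig` implements both analyses as a tested, reusable library with a thin
CLI, plus synthetic-data generators with planted structure so every stage can
be validated end to end without external downloads.

## The model

**Repeat content.**  For each gene, the promoter is the 2 kb window
immediately 5′ of the transcription start site (strand-aware).  Treating each
repeat class *r* as a unigram over this window of exploration of length
*Lₑ*, with *Nᵣ* instances overlapping the promoter and *Lᵣ* total
promoter-clipped base pairs:

```
RC(r) = log10(Nr · Lr / Le)
```

Genes × repeat classes of RC scores form the *weighted matrix* (genes with no
promoter repeat in any analyzed class are dropped and reported; absent
classes get a floor sentinel `log10(1/(2·Le))`, strictly below any attainable
score).  Hierarchical clustering (complete linkage, Manhattan distance)
organises both axes; the pair of classes with the largest RC-column variance
is selected as *discriminative*, and k-means (k = 4) on that pair partitions
the genes into clusters labelled by which selected classes their centroid is
enriched for — e.g. `Alu-related`, `L1-related`, `Alu/L1-related`,
`unrelated`.

**Risk score.**  Given signature genes with coefficients *coefᵢ* (e.g. from a
penalized Cox fit performed elsewhere) and expression *exprᵢₛ*:

```
score(s) = Σ_i coef_i · expr_is
```

Samples are split at the median score into high/low arms and compared with
the Kaplan–Meier product-limit estimator and the two-group log-rank test.
A screening step (per-gene median split + log-rank) finds survival-associated
genes, and a Spearman screen (|ρ| > 0.3, p < 0.05) relates auxiliary features
such as lncRNA expression to the risk score.

## Worked example

Simulate a landscape of 200 genes (four planted groups: Alu-enriched,
L1-enriched, both, neither) and run the repeatome pipeline:

```sh
repsig simulate-repeatome --n-genes 200 --seed 1 --out-dir demo/sim
repsig repeatome --genes demo/sim/genes.bed --repeats demo/sim/repeats.out \
    --seed 1 --out-dir demo/rep
```

which reports (stderr):

```
repeatome: 153 genes, selected LINE/L1+SINE/Alu, clusters
  {'unrelated': 33, 'Alu-related': 79, 'Alu/L1-related': 21, 'L1-related': 20}
```

153 of the 200 genes had at least one promoter repeat and enter the matrix
(`matrix.tsv`; the other 47 are listed in `drop_report.tsv`); column variance
selected the two planted classes; the four k-means clusters recover the
planted groups and are labelled by their centroid enrichment.  Then simulate
a 400-patient cohort whose planted signature gene carries a hazard ratio of 2
between median-split arms, and run the signature pipeline:

```sh
repsig simulate-survival --seed 1 --out-dir demo/simsurv
repsig signature --expression demo/simsurv/expression.tsv \
    --survival demo/simsurv/survival.tsv --model demo/simsurv/model.tsv \
    --features demo/simsurv/features.tsv --out-dir demo/sig
```

```
signature: log-rank chi2=28.833, p=7.89e-08
```

The high-risk arm's KM curve (`km_high.tsv`) lies below the low-risk arm's at
every event time, and `spearman.tsv` shows the one feature simulated with
rank correlation 0.5 to the risk score passing the |ρ| > 0.3 screen while the
19 null features fail it.

The same stages are available as library functions
(`build_matrix`, `select_discriminative_repeats`, `kmeans_partition`,
`screen_survival_genes`, `risk_score`, `km_estimate`, `logrank_test`,
`spearman_screen`) and as scikit-learn-style estimators
(`RepeatPartitioner`, `MedianSplitLogrankScreen`, `RiskScorer`,
`SpearmanScreen`).

## File formats

Genes: BED6 or GFF3 (`gene` features).  Repeats: RepeatMasker `.out` or BED
with `name#class/family` (or a 7th class column).  Matrices/expression/
survival/model/features: TSV.  All readers accept gzip input by extension;
internal coordinates are 0-based half-open.

See `docs/methods.md` for the full model description, parameter defaults,
numerical conventions and limitations.
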