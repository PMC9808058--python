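# Methods

## Promoter repeat-content model

For a gene with transcription start site (TSS) *t* on the + strand, the
promoter is the half-open interval `[t − Le, t)`; on the − strand it is
`[t + 1, t + 1 + Le)`.  `Le` defaults to 2000 bp.  Promoters are clipped at
position 0 and at the contig end when contig lengths are known, but `Le`
stays at the configured window even for clipped promoters so that RC scores
remain comparable across genes; a fully clipped promoter is flagged and its
gene excluded downstream.

Each repeat instance with ≥ 1 bp of overlap contributes its promoter-clipped
length; instances are never merged, so two overlapping same-class elements
count twice (frequency and coverage enter the score separately).  For class
*r* with `Nr` overlapping instances totalling `Lr` clipped bp:

    RC(r) = log10(Nr · Lr / Le)

`Lr` is the *total* clipped length of the class, not the mean instance
length; this keeps an independent frequency effect (doubling the number of
identical hits adds log10(4), not log10(2)).  The logarithm base is 10;
clustering results are invariant to the base.  A class absent from a
promoter has no finite score; in the assembled matrix such cells carry the
floor sentinel

    floor = log10(1 / (2 · Le))

which is strictly below the smallest attainable score `log10(1/Le)` (a
single 1-bp hit), so "no repeat" always ranks below "smallest repeat" while
the matrix stays fully numeric.  Matrix rows are the genes with at least one
hit among the analyzed classes; dropped genes are reported with a reason.
Hits within a promoter are ranked by distance from the hit edge nearest the
TSS (rank 1 = nearest; ties broken by start coordinate, then class and name,
for determinism).

## Clustering and labelling

Pairwise Manhattan (L1) distances are computed over either axis of the
matrix and fed to complete-linkage agglomeration
(`scipy.cluster.hierarchy.linkage`); the resulting tree is exported as
Newick with branch lengths equal to merge-height differences.  Ties between
equal-height merges follow scipy's deterministic nearest-neighbour-chain
order; merge heights are the tested quantity and are tie-independent.

The *discriminative score* of a repeat class is the sample variance of its
RC column (ddof = 1); the top two classes are selected, ties broken
lexicographically.  The column dendrogram is attached to the selection
report so the choice can be audited against the tree structure — variance is
a deliberate, simple operationalisation of "most divergent columns", and an
all-constant matrix is rejected as having no discriminative structure.

k-means (k = 4 by default, 25 restarts, k-means++ initialisation,
`max_iter` 300, deterministic under the seed; `sklearn.cluster.KMeans`) runs
on the matrix restricted to the selected pair; the minimum-inertia solution
is kept.  Clusters receive semantic labels by comparing each centroid
coordinate to the gene-wide median RC of that class; classes whose centroid
exceeds the threshold name the cluster (`Alu-related`, `L1-related`, joint
`Alu/L1-related`, else `unrelated`).  When the matrix carries the floor
sentinel the threshold is additionally held above the floor region at
`floor + log10(2)/2`: centroids below the smallest attainable score can only
arise from averaging absent-class sentinels and therefore denote absence,
even when the gene-wide median itself sits at the floor (which happens
whenever fewer than half the genes carry the class).

## Survival stage

All survival computation is for right-censored data (`time > 0`,
`event ∈ {0, 1}`).  The Kaplan–Meier estimator and the two-group log-rank
test (observed − expected events over pooled event times, hypergeometric
variance, 1-df chi-square) are delegated to lifelines and verified in the
tests against hand product-limit computations and a brute-force log-rank
oracle.

*Screening.*  Each gene's expression is median-dichotomized (values equal to
the median go to "low", the same tie rule used for risk scores) and the two
arms compared by log-rank; genes with fewer than 2 samples in an arm
(constant genes in particular) are excluded with a warning.  The default is
the raw-p screen at α = 0.05; Benjamini–Hochberg adjustment is available via
`correction="BH"` (`scipy.stats.false_discovery_control`).  Screening uses
the median-split log-rank test as the association statistic; coefficient
estimation (penalized Cox) is intentionally out of scope — the risk model's
coefficients are inputs.

*Risk score.*  `score(s) = Σ coef_i · expr_is`, linear and
order-independent; missing model genes are an error naming the genes.
Samples are split at the median score (ties to "low"; all-identical scores
are an error).  The arms are compared by KM curves and the log-rank test.

*Spearman screen.*  Tie-corrected Spearman ρ of each feature against the
risk score with the t-approximation p-value (n − 2 df, `scipy.stats.spearmanr`);
a feature passes when |ρ| > 0.3 **and** p < 0.05, both strict.  Constant
features are skipped with a warning.

## Synthetic data

The generators exist so each stage's planted structure can be recovered and
quantified; they are first-class, tested code.

*Repeat landscape.*  One contig (2 Mb default) divided into equal slots, one
gene (1 kb) per slot placed uniformly at random with a promoter-sized margin
on both sides, strand Bernoulli(½).  Four planted groups — class-A-enriched,
class-B-enriched, both, neither, defaults (0.40, 0.10, 0.10, 0.40) of 200
genes, mirroring the ~59:16:17:56 shape of a four-way repeat partition —
allocated by largest remainder so counts are exact, then shuffled across
slots.  Background insertions are Poisson-scattered genome-wide per class
with lognormal lengths (medians: Alu-like 300 bp, L1-like 900 bp, MIR 130,
L2 250, low-complexity 60; σ = 0.3, minimum 20 bp).  Enriched genes receive
`enrichment_boost` (default 8) extra insertions of their class(es), start
uniform within the promoter (no TSS-distance gradient — the scoring records
order but uses no positional model, so the simplest null-consistent
placement is used), clipped like any other repeat at analysis time.

Default background densities (per kb): SINE/Alu 0.005, LINE/L1 0.0025,
SINE/MIR 0.08, LINE/L2 0.05, Low_complexity 0.06.  The enriched classes'
background is deliberately sparse: because the floor sentinel puts "no hit"
≈ 2.8 log-units below "one 300-bp hit", a dense Alu/L1 background makes the
non-enriched coordinate of every group strongly bimodal and that scatter —
not the planted enrichment — dominates the k-means geometry.  With sparse
enriched-class background, group membership alone determines a promoter's
Alu/L1 content and the four groups are cleanly separable.  This is the main
respect in which the toy landscape is *easier* than a real genome, where Alu
elements are dense near genes; passing recovery tests therefore demonstrate
correctness of the pipeline's mechanics, not that real promoter repeatomes
partition this cleanly.

*Expression/survival cohort.*  Log-scale expression `x_gs ~ Normal(μ_g, σ²)`
(μ_g ~ Normal(5, 1), σ = 1), i.e. log-normal intensities, assumed already
normalized.  Event times are exponential with proportional-hazards rate
`h0 · exp(Σ coef_i (x_is − μ_i))`, `h0 = 0.01` per time unit.  Censoring
times are Uniform(0, c) with c calibrated by root-finding so the expected
censored fraction matches the target (default 0.30; achieved fraction is
logged and lands within ±5 points of the target at n ≥ 200).  The default
signature is a single gene whose coefficient `log(2)/(2·sqrt(2/π))` gives a
hazard ratio of 2 between its median-split arms (the mean gap between the
halves of a unit normal is `2·sqrt(2/π)`).  One auxiliary feature is built
with a requested Spearman correlation (default 0.5) to the true linear
predictor via the Gaussian-copula identity `r = 2·sin(π·ρ_s/6)`; the
remaining features are independent noise.

Each generator draws from `numpy` Generator streams seeded as
`[seed, k]` with a fixed offset `k` per stage (placement/background/boost;
expression/survival/features), so outputs are byte-deterministic under the
config seed and stages do not perturb one another.

## Numerical conventions and degenerate inputs

- Coordinates: 0-based half-open internally; GFF3 (1-based closed) and
  RepeatMasker `.out` (1-based inclusive) shifted on read and restored on
  write.  − strand TSS is `end − 1` of the annotated span.
- Unparseable lines raise errors naming the line number; parseable records
  violating a type invariant (unknown strand, empty span) are skipped with a
  logged warning, since real annotation files contain oddities.
- Matrix TSVs round-trip bit-identically (shortest-repr floats on write,
  `float_precision="round_trip"` on read; the floor sentinel rides in a
  `#floor_value=` header line).  Duplicate gene IDs and empty matrices are
  errors.
- Degenerate inputs rejected with diagnostics: zero surviving genes in
  `build_matrix` (with stage counts), all-constant matrices in selection,
  k < 1 or k > n in k-means, all-identical risk scores, empty log-rank
  groups, non-positive survival times.
- k-means assignment ties and restart selection are handled by scikit-learn
  and are deterministic given `random_state`.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run entirely on synthetic data at
the generators' default scales: 1,000 randomized promoter/repeat layouts for
oracle equivalence (tolerance 1e−12), 50 landscape replicates for selection
recovery and for the enrichment-free null, 2,000 null cohorts (n = 100) for
log-rank calibration, and 100 cohort replicates (n = 400) for
planted-signature and Spearman-screen recovery.  These sizes give binomial
standard errors well below the margins being asserted while keeping a full
run in the low minutes on one CPU.

## Known limitations

- Column variance is one of several defensible "discriminative score"
  definitions; the attached dendrogram lets users audit it.
- The interpretation of `Lr` as total (not mean) clipped length, and
  clipping (not excluding) boundary-spanning repeats, are documented choices
  the oracle mirrors; alternative readings change scores monotonically but
  not the pipeline's structure.
- The synthetic landscape places genes on one contig with regular slots and
  sparse enriched-class background (see above); it makes no attempt to mimic
  chromosomal repeat distribution, GC/isochore structure, or real promoter
  repeat density.
- The survival generator's proportional-hazards form with exponential
  baseline and uniform censoring is the simplest model carrying the planted
  effect; real cohorts violate proportionality and have informative
  censoring.
- Screening uses median-split log-rank rather than univariate Cox; for
  monotone effects the two agree in power ranking, but hazard-ratio
  estimates are out of scope here.
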