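# Methods

`microtopics` implements a topic-model-based integration of multi-omic
gut-microbiome count data: per-omic Latent Dirichlet Allocation (LDA) with
simulation-based selection of the topic count, clustering of topics across
omics into cross-omic topics validated against a multinomial null, topic
interpretation through feature weights and metadata correlations,
topic-driven sample clustering, and per-cluster differential-abundance
testing. This note records the model, the defaults, the numerical choices,
and what the synthetic cohorts used in testing do and do not establish.

## The topic model

Samples play the role of documents and microbial features (16S ASVs,
metagenomic and metatranscriptomic KEGG orthologs, metabolites) the role of
words. For each omic with V features, D samples and K topics:

- θ_d ~ Dir(α) — sample d's topic probabilities (D × K matrix Θ),
- β_k ~ Dir(γ) — topic k's feature probabilities (K × V matrix B),
- each token: z ~ Mult(θ_d), w ~ Mult(β_z).

Inference is collapsed Gibbs sampling: Θ and B are integrated out and each
token's topic is resampled from

    p(z = k) ∝ (n_dk + α)(n_kv + γ) / (n_k + Vγ),

where n_dk, n_kv, n_k are the current topic-count caches. Estimates of θ
and β are posterior means — (n_dk + α)/(N_d + Kα) and (n_kv + γ)/(n_k + Vγ)
— averaged over post-burn-in sweeps with thinning, which is more stable
than a single terminal sample. Topics are never reordered by the sampler;
tests match fitted to true topics by best bipartite cosine assignment.

Defaults: α = 50/K, γ = 0.1, 2000 iterations, 500 burn-in, thinning 10 —
common practice for collapsed Gibbs LDA; all config-exposed. Test- and
script-scale runs use 150–300 iterations with 50–100 burn-in, which the
recovery checks show is sufficient at those problem sizes. The per-sweep
kernel is compiled with numba when available; the pure-Python fallback
consumes the identical pre-generated uniform stream, so both paths give
bit-identical output for a seed. Tokens are expanded from discretized
counts with a per-document cap (default 10⁵) to bound memory.

All-zero samples after discretization carry no tokens; the fitting function
raises by default and drops them with a warning in pipeline mode.

## Normalization and discretization

Size factors are median-of-ratios (RLE): factor of sample d = median over
reference features of count/geometric-mean. The reference set is the
all-positive features; when none exists the fallback uses features positive
in ≥ 90% of samples with geometric means over positive entries only. A
single parameterized median-of-ratios covers what differently-branded
implementations of the same estimator would produce. Counts are then
log2(x+1)-transformed (zeros preserved) and rounded half-to-even — an
unbiased discretization giving the integer table the Gibbs sampler needs
while keeping per-document token loads small.

Normalization is selected by the cohort's own structure: for each candidate
(median-of-ratios, total-sum, none) and each of eight community-ecology
distances (Manhattan, Euclidean, Canberra, Clark, Bray–Curtis, Kulczynski,
quantitative Jaccard = 2B/(1+B), alt-Gower; Canberra/Clark/alt-Gower
averaged over non-double-zero pairs), the ratio of mean within-sibling-pair
distance to mean between-family distance is computed on log-normalized
values; the candidate winning the most metrics is selected, ties broken by
candidate order. Distances are computed on the log scale because that is
the scale entering the model.

## Selecting the number of topics

Posterior-predictive checking: tables are simulated from each candidate
model at the observed per-sample depths and compared with the observed
table on three Pearson correlations — per-sample quantile profiles
(percentiles 1–99, linear interpolation), per-feature quantile profiles,
and the upper triangles of the two feature–feature correlation matrices
(the pairwise-marginal metric, the primary criterion). Metrics are averaged
over 5 simulated tables by default (3 at test scale). The elbow rule:
smallest K whose pairwise-marginal score is within 2% (relative) of its
maximum and whose quantile scores are within 4% of theirs; if no candidate
satisfies all three clauses the pairwise-marginal argmax is used. Constant
features contribute zero entries to the correlation triangle so observed
and simulated tables are compared on a common support.

## Cross-omic topics

Each topic is represented by its attribution vector — its θ column over
the shared samples. Topic similarity is Spearman correlation (average-rank
ties; p from the t approximation with n−2 df). Topics are clustered
hierarchically with average linkage; the candidate cluster count is scored
by the mean within/between ratio (mean intra-cluster pairwise distance over
mean member-to-non-member distance; singletons contribute 0) averaged over
Manhattan, Euclidean and inverse-correlation distances, and the smallest n
within 5% of the minimum score is selected. Known limitation: on strongly
hierarchical data this score decreases monotonically in n (singletons pull
it toward zero), so automatic selection favors the top of the candidate
range; analyses that know the expected cluster count (as the null
validation does by design) should pass it explicitly.

Null validation draws, per replicate, one null table per omic in which each
sample's counts are redrawn from a multinomial at its own total with the
empirical feature distribution of a uniformly chosen *other* sample —
preserving depths and the feature-abundance envelope while destroying
cross-omic coupling. Each null table is renormalized, refit with the same
K/α/γ/iteration settings and seed as the true model, clustered into the
true data's cluster count, and scored by the number of same-cluster topic
pairs with Spearman p < 0.05 (uncorrected by design: the count is a
descriptive statistic compared against its own null ensemble, 15 tables by
default). A topic whose total attribution is ≥ 10× the next topic's and
which defines no features under the interpretation criteria is flagged as
uninformative and can be dropped before clustering (the "dominant topic"
guard; 10× operationalizes an orders-of-magnitude imbalance).

Samples are clustered on their concatenated topic attributions with
inverse-correlation (1 − Pearson r) distance and complete linkage, cut at
2 clusters by default; pairs involving a constant profile get distance 1
with a warning. The sibling co-clustering rate is the fraction of families
with ≥ 2 samples whose members share one cluster.

## Topic interpretation

A feature defines a topic when it passes both: (1) specificity — max
weight across topics exceeds the median by > 1.5 sample SD of its K
weights (K ≥ 2 required); (2) driver — absolute loading above a
percentile cutoff (99 for ~10²–10³-feature omics, 99.9 for ~10⁴-feature
omics) on one of the top K−1 right-singular axes of the column-centered β.
Centering isolates between-topic variation; loadings are thresholded in
absolute value since sign is arbitrary. Survivors are attributed to their
argmax topic. Topic–covariate association is Spearman ρ with pairwise
deletion of missing values, starred at p < 0.05 uncorrected — a screen,
not a confirmatory test.

## Differential testing

Within each sample cluster, case and control samples are compared on
normalized log-scale values (not the discretized model input). Stage 1 is
a shadow-feature screen: the table is extended with one independently
permuted copy of each feature (the permutation drawn once per trial so
real and shadow columns are exchangeable under the null — each carries one
fixed chance association with the labels), and n_runs random forests are
fit to predict phenotype. The forest is an explicit Breiman ensemble —
bootstrap plus random-feature (√p) trees, built as a loop over sklearn
decision trees so each tree's out-of-bag samples are available; regression
trees on the 0/1 labels are used because variance-reduction splits
coincide with Gini splits for binary targets while fitting substantially
faster. Importance is Breiman's mean decrease in out-of-bag accuracy
(per-tree OOB permutation). Each column's Z = mean/SD of importance across
runs; a feature is "important" iff its Z strictly exceeds the best shadow
Z — conservative by exchangeability (flag probability ≈ 1/(V+1) per trial
under the null). The screen is repeated n_repeats times with fresh
shadows, verdicts tallied, and features at or above the 90th percentile of
tallies (linear interpolation, ties included) survive. Stage 2:
two-sided Wilcoxon rank-sum per survivor (exact when both groups ≤ 25 and
tie-free, else normal approximation with tie/continuity correction),
Benjamini–Hochberg within the survivor set, reported at adjusted p < 0.05,
with the sign of the case-minus-control median difference. Defaults are
100 repeats × 100 runs × 500 trees; the reduced profile used in tests and
the acceptance script is 20 × 25 × 100. An all-zero tally vector yields an
empty report, not an error. Because survivors are selected on the same
data that is then tested, reported adjusted p-values are screening-biased;
the calibration this package demonstrates is empirical (see below), not an
analytic FDR guarantee.

## Generalization across datasets

A fitted model induces feature–feature cosine distances between the
K-dimensional β columns. Two models' matrices, restricted to common
features (≥ 5), are compared by a Mantel test: Pearson r of upper
triangles, null from jointly permuting one matrix's rows and columns
(permuting rows alone would break symmetry and is not a valid Mantel
null), one-sided add-one p = (1 + #{null ≥ observed})/(1 + P) for the
concordance alternative, plus a z-score against the null moments. Feature
matching is by exact identifier.

## The synthetic cohort generator

The generator emulates the statistical skeleton the analysis relies on:
sibling-pair families (one case, one control child each), a per-sample
topic vector shared by all omics (each sibling's θ mixes a family-level
Dirichlet draw with an individual draw; weight = sibling_correlation,
default 0.5 — no quantitative sibling-similarity figure exists to
calibrate it, so it is a fixed package choice), per-omic β ~ Dir(γ),
multinomial counts at exact configured depths, covariates that are linear
in θ plus Gaussian noise, and phenotype effects planted by binomial
thinning (log2FC < 0) or Poisson inflation (log2FC > 0) of case-sample
counts, scaling expected counts by exactly 2^log2FC. `shared_theta: false`
draws independent θ per omic — the negative control that destroys exactly
the structure the cross-omic stage detects. One θ is shared across omics,
so the true topic count is global rather than per-omic.

Not emulated: sequencing error, compositional closure artifacts, batch
effects, taxonomy, annotation chemistry, longitudinal repeat sampling.
Passing tests therefore establish that the algorithms recover the
structure they assume when it is present and stay quiet when it is absent
— not that real stool multi-omics satisfies those assumptions.

Default test scale is 15–40 families, V = 20–300 per omic, depths
400–3000, K_true = 3–4. Study scales used by the test suite and
`scripts/acceptance.py` (chosen once as realistic desk-scale cohorts):

- topic recovery: D = 200 samples, V = 50, K = 3, depth 500;
- K selection: D = 60, V = 40, K_true = 3, candidates 2–6, 10–20 replicates;
- cross-omic: 25 families, three omics (V = 60/50/40) at depth 500,
  K_true = 4, 15-table null ensembles;
- differential power: 20 families, V = 40 at depth 3000, a 4-feature
  signature of |log2FC| = 1.5 planted on abundant features
  (expected-frequency ranks 4–8) with alternating signs so the planted
  mass stays balanced and size factors undistorted. The signature is kept
  sparse relative to the 90th-percentile tally cut on purpose: that cut is
  a top-10%-of-features selector, so a signature wider than ~V/10 can
  never be fully recovered — a structural property of the screen worth
  knowing on real data. Fully-null calibration uses 20 families, V = 20 at
  depth 2000;
- Mantel: split halves of a 30-family cohort, 999 permutations; null
  calibration over 200 replicate pairs of random distance matrices.

## Repeated samples per individual

Cross-omic work runs on the samples shared by all omic tables
(lexicographically ordered for reproducibility). When an individual
contributes several stool samples, the package does not collapse them
automatically: the metadata keeps sample and individual identifiers
separate, sibling-pair extraction deduplicates to one sample per
individual (the first in file order), and analyses that require one
observation per individual should subset accordingly. The generator emits
exactly one sample per individual, so the default cohorts are unambiguous.

## Numerical choices and degenerate inputs

- Round-half-to-even throughout discretization (unbiased).
- Accumulated θ/β averages renormalized once at the end of sampling to
  remove floating-point drift before the row-stochastic validation.
- Correlation of anything constant is treated as 0 (metrics) or distance 1
  (sample clustering) with a warning, never NaN.
- Empty survivor sets, K = 1 models in dominance flagging, and log2FC = 0
  plantings are identity/no-op cases, not errors.
- All randomness flows from numpy Generators seeded by the caller; the
  pipeline derives per-stage seeds from the global seed by hashing stage
  names, so stages are independently reproducible.

## Known limitations

- The within/between ratio does not identify the cluster count on strongly
  nested data (above); the gap-statistic family would need a reference
  null to fix this and is out of scope.
- The screen-then-test differential design reuses data; its error control
  is demonstrated empirically on the generator, and holds at the tested
  scales (40+ samples). Much smaller cohorts push the false-discovery
  proportion up, which users should expect on real data too.
- Cross-dataset Mantel comparison requires exact feature-identifier
  overlap; no fuzzy matching of metabolite names is attempted.
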