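# Methods

## Enterotyping model

The pipeline treats each sample as a probability vector over genera and
defines community types as PAM clusters under the square-root base-2
Jensen–Shannon dissimilarity. This follows the canonical enterotyping
protocol: JSD is symmetric, bounded, and its square root is a true metric,
so medoid-based clustering and ordination are well posed. Assumptions worth
stating explicitly:

- Compositions are compared directly; no compositional (log-ratio)
  transform is applied. Enterotypes are by construction dominance
  patterns, which JSD captures well.
- Zeros are structural in count data but undefined in KL terms, so zero
  entries are replaced by a pseudocount (default `1e-6`) and the vector
  renormalised before any divergence is computed. The default is far below
  any observable relative abundance at the simulated depths (2×10⁴–6×10⁴
  reads), so it perturbs distances negligibly; it is configurable.
- All genera enter the distance, including the pooled `unclassified` row
  (dropping it is a flag on `aggregate_to_genus`). A prevalence filter was
  considered and rejected as a default: with ~10²–10³ genera the JSD is
  dominated by the abundant fraction anyway, and silent filtering changes
  the clustering substrate.

### PAM

`pam()` minimises the total distance of every sample to its nearest medoid.
Instances with at most 3 000 candidate medoid subsets are solved exactly by
enumeration; larger instances use the deterministic BUILD + SWAP local
search (greedy seeding, then best-improvement single swaps until
convergence). The split exists because BUILD + SWAP — in any
implementation, including the reference R `cluster::pam` — can stall in a
local optimum even on eight points, and at sizes where the exact optimum
costs microseconds there is no reason to accept that. Above the threshold
the heuristic's objective is still monotonically non-increasing across
swaps and the final labels are exact nearest-medoid assignments. All ties
(equidistant medoids, equal-objective swaps, equal CH across k) break
toward the smallest index or smallest k, so results are bit-reproducible
with no random restarts.

### Cluster-number selection and ordination

The Calinski–Harabasz index is defined for Euclidean coordinates, not
distance matrices. We resolve the ambiguity by embedding the distance
matrix with classical multidimensional scaling (double-centred −½D²,
eigendecomposition, all strictly positive eigenvalues retained) and
evaluating the textbook CH ratio on the embedding; on genuinely Euclidean
distances this reproduces the direct-coordinate CH to numerical precision
(tested). PCoA coordinates come from the same embedding; each axis's sign
is fixed by making its largest-magnitude loading positive, which removes
the eigenvector sign indeterminacy from outputs. Candidate k ranges over
2…min(10, n−1) by default.

## Alpha diversity

Rarefaction draws each sample once, without replacement (multivariate
hypergeometric), to the minimum sample depth by default; single-draw rather
than averaged-over-repeats because the downstream Wilcoxon comparison is
rank-based and a recorded seed keeps the draw reproducible. Estimators:

- Shannon in natural log (a `base` argument gives bits);
- Simpson reported as Gini–Simpson 1 − Σp², the common ecology-toolchain
  convention (raw Σp² behind a flag);
- Chao1 in the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), finite when
  doubletons are absent — sparse samples hit that case routinely;
- ACE with the classical rare/abundant cutoff of 10; when every rare taxon
  is a singleton the coverage estimate is zero and ACE is undefined, so the
  estimator falls back to Chao1 rather than erroring mid-pipeline.

Group comparison is the Wilcoxon rank-sum test: exact enumeration when
n₁+n₂ ≤ 20 without ties, otherwise the normal approximation with tie and
continuity corrections. Clusters are called "comparable" when no index
differs at α = 0.05.

## Association analysis

Contingency tests default to chi-square without continuity correction,
switching to Fisher's exact test when any expected cell drops below 5
(2×2 via the hypergeometric; r×2 tables by exhaustive enumeration of tables
with the observed margins, feasible for totals ≤ 30 — beyond that the
chi-square is kept, since the exact conditional test has no closed
network-free form at that size).

The logistic model is binary — exactly two enterotypes, with the
*Segatella*-dominated cluster coded 1 — rather than multinomial. Fitting is
straight maximum likelihood by IRLS: convergence when the largest score
component falls below 1e-8, Wald standard errors from the inverse observed
information, odds ratios and 95% bounds by exponentiation. Complete or
quasi-complete separation (a covariate level empty in one cluster — e.g. a
sparse partner-count level — sends its coefficient to ±∞) is detected from
diverging coefficients (|β| > 15, odds ratios beyond e¹⁵ being
uninterpretable here) and flagged on the result instead of silently
returning a huge estimate. Sparse levels are deliberately *not* merged; the
flag is the honest output. The default covariate set for the pipeline is
anal sex role + age + BMI; the full behavioural set is available through
`build_design`, with treatment coding against insertive-only, ≤1 partners
and always-condom references.

## Classifier

Features are the union of each enterotype's top-10 genera by within-cluster
mean relative abundance (deterministic order: descending overall mean, then
lexicographic). The 70/30 split is stratified by class — with a ~16-sample
minority class an unstratified 30% test set can lose a class entirely and
leave a pairwise AUC undefined. Oversampling is random duplication with
replacement up to the majority class size, applied to training data only
(a leakage guard asserts test ids never enter the training multiset);
synthetic-minority interpolation was rejected to keep the procedure
deterministic and free of invented structure. The forest (scikit-learn,
`ntree` trees, `mtry` features per split) defaults to ntree = 200,
mtry = 1, which the 5-fold CV grid {100, 200, 500} × {1, 2, 3, ⌊√p⌋}
contains. One-vs-one AUC for classes (a, b) scores the pair's samples by
the renormalised probability p(a)/(p(a)+p(b)) (raw p(a) behind a flag) and
applies the Mann–Whitney rank formulation with ties counted ½; the macro
AUC is the unweighted mean of the three pairwise values. Permutation
importance is the mean macro-AUC drop over seeded column shuffles of the
test matrix.

## Pathway differential testing

Per-pathway Wilcoxon rank-sum between the two clusters, direction from the
median difference. No multiplicity adjustment by default — matching how
such pathway screens are usually reported — with Benjamini–Hochberg a flag
away and recommended; switching `none → bh` can only shrink the
significant set (tested).

## Synthetic generator

The generator emulates the statistical structure the analysis assumes, at
the default scale of a 95-sample cohort:

| parameter | default | meaning |
|---|---|---|
| `n_samples` / `n_genera` | 95 / 120 | cohort and panel size |
| `delta` | 0.35 | dominant-genus mass of each archetype |
| `tail_exponent` | 1.5 | rank-abundance power law of the non-dominant mass |
| `dirichlet_concentration` | 50 | sample-to-sample compositional noise (smaller = noisier) |
| `depth_range` | [20 000, 60 000] | uniform per-sample read depth |
| `cluster_prior` | 52/95 | marginal P(*Segatella*-dominated) |
| `role_probs` | 0.35/0.48/0.17 | insertive/versatile/receptive marginals |
| `or_versatile`, `or_receptive` | 6.1, 1.5 | true odds ratios vs insertive-only |
| `age`, `bmi` | N(31, 8.4), N(20.9, 3.44) | demographic covariates (years, kg/m²) |

Counts are Dirichlet-multinomial: composition ~ Dirichlet(α·archetype),
counts ~ Multinomial(depth, composition). The two archetypes share one
power-law tail over the non-dominant genera but each demotes the rival's
dominant genus to the lowest rank; this concentrates the between-archetype
contrast in the two dominant genera, so `delta` controls separation cleanly
(median between-archetype distance is monotone in it — tested) and the long
tail yields the singletons and doubletons that make Chao1/ACE non-trivial.
Sex role is coupled to cluster through logit P(Segatella) = β₀ +
log(OR_v)·1[versatile] + log(OR_r)·1[receptive], with β₀ calibrated by
bisection so the marginal cluster frequency matches `cluster_prior`; all
other behavioural covariates are drawn independently of cluster, mirroring
the null associations such cohorts typically show for them.

What the generator does **not** emulate: phylogenetic correlation between
genera, overdispersion beyond the Dirichlet, covariation of behavioural
variables with each other or with diet, batch/primer effects, and any
causal path from behaviour to composition other than the single logistic
link. Passing recovery tests therefore show the pipeline is correct and
well-calibrated under its own assumptions — not that those assumptions hold
in any particular cohort.

## Test design and problem sizes

Oracle tests pin every statistical primitive to an independent
implementation: PAM against exhaustive medoid search (200 random instances,
n ≤ 8, k ∈ {2,3}), pairwise AUC against O(n²) concordance counting (100
instances, n ≤ 200), Wilcoxon against full permutation enumeration
(n₁+n₂ ≤ 8), the logistic fit against brute-force likelihood optimisation
(n ≤ 30, 1e-6 in coefficients) and against statsmodels, CH and PCoA against
direct-coordinate computation and scikit-bio. Recovery tests run 50
replicate cohorts at the default scale (k = 2 with ARI ≥ 0.9, drivers
recovered) and 200 replicates of the odds-ratio coverage check at n = 500.

One power note: the classifier's advantage over a permuted-label null is
real but modest (the coupling runs behaviour → cluster → noisy abundances),
and a 29-sample test set gives a single macro-AUC an SE near 0.1. The
null-gap property is therefore asserted on replicate cohorts of n = 300,
where the gap (≈0.13) is resolvable; at n = 95 the same generator yields a
mean gap of only ≈0.05 across replicates. For the same reason the
acceptance script reports the n = 95 macro-AUC averaged over ten resplits.

## Known limitations

- Binary logistic only; a third enterotype would require a multinomial
  model (out of scope).
- No Firth/penalised fallback under separation — the flag is the output.
- The exact conditional test for r×2 tables is enumeration-bound
  (totals ≤ 30).
- Rarefaction is single-draw; diversity values carry that sampling noise.
- PAM above the exact-enumeration threshold is a local search; it inherits
  PAM's usual (small) risk of suboptimal medoids.
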