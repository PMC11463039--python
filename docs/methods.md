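# Methods

This note documents the statistical machinery in `nasonet`: the models and
procedures, the parameters that matter, the design decisions taken where
several constructions were defensible, and what the synthetic benchmarks do
and do not establish about real data.

## Profiles and filtering

Taxon tables are taxa × samples (matching the on-disk TSV). Relative-mode
entries are proportions of the community: a full composition's columns sum
to 1; after taxon filtering a table is a subcomposition and sums to less,
and closure is restored explicitly by `merge_domains_renormalize`.

Retention uses strict inequalities — mean relative abundance (over all
samples, zeros included) strictly above the threshold (1e-4 bacteria, 1e-3
fungi) and prevalence (fraction of samples with nonzero abundance) strictly
above 10%. The mean, rather than a per-sample maximum, is the conventional
reading of an abundance cutoff and is what we commit to; filtering is
idempotent. Diversity indices use natural logarithms throughout (the vegan
convention): Shannon H = −Σ p ln p, Simpson 1 − Σ p², Pielou H/ln S with S
the count of nonzero taxa (undefined, NaN, at S = 1).

## Synthetic cohorts

The generator exists so that every downstream stage has ground truth. Per
group it draws a sparse symmetric precision matrix Ω: a backbone of edges
shared between groups plus a group-private fraction, entry magnitudes
uniform on [0.2, 0.4], a configurable fraction of edges negative. Positive
definiteness comes from diagonal dominance (diagonal = row absolute sum
+ 0.5); the planted interaction sign of an edge is the sign of its partial
correlation, i.e. −sign(Ωᵢⱼ). Latent per-sample log-abundances are
multivariate normal with correlation structure Σ ∝ Ω⁻¹ rescaled to unit
variances and then to `latent_sd` (default 0.5), around baseline means
drawn N(0, `dominance`²) (default 1.5) shared across groups;
`differential_taxa` adds log-fold effects to group 2. Exponentiation,
closure, multinomial sampling at `sequencing_depth` (default 1e5) and
independent per-cell zero inflation (default 0.02) yield the count tables.

Two scales deserve comment. `dominance` (between-taxon spread of baselines)
at 1.5 produces communities where the top-10 taxa typically carry 50–80% of
the mass — the skew regime of real nasal profiles, where the top-10 species
carry ~75%. `latent_sd` (within-group, per-sample spread) at 0.5 places
log-fold-2 planted effects four latent standard deviations apart, the
regime in which the package's recovery benchmarks (clustering ARI ≥ 0.9,
edge AUROC ≥ 0.8) are the designed expectation. Real cohorts show larger
inter-individual spread (log-sd ≈ 1–2); under such spread the same
effect sizes are only partially recoverable by any method, so the benchmark
numbers here measure correctness of the machinery, not field performance.

The model is a conditional-dependence simulation, not population dynamics:
it encodes exactly the partial-correlation structure the inference stage
targets, which gives a clean recovery criterion, but it does not emulate
Lotka–Volterra feedbacks, phylogenetic signal, batch effects, or
compositional mean–variance coupling beyond the multinomial. Zero inflation
is applied after sampling, independently per cell, mimicking dropout
without disturbing the latent covariance.

## WSNF clustering

Each kingdom contributes a sample-similarity matrix S = 1 − BC computed on
its (filtered) relative profile; the Bray–Curtis similarity itself is the
SNF affinity — no scaled-exponential kernel is rebuilt from distances.
Fusion follows the standard SNF cross-diffusion: full kernels row-normalized
with half the mass on the diagonal, sparse k-NN kernels, and iterative
updates P⁽ᵈ⁾ ← S⁽ᵈ⁾ (Σ_{e≠d} w̃ₑ P⁽ᵉ⁾) S⁽ᵈ⁾ᵀ with the richness weights
w_d = p_d/Σp_e renormalized over the other kingdoms, symmetrizing each
step. The fused matrix is the richness-weighted average of the final status
matrices. Kingdoms with weight zero are dropped before diffusion, which
makes the (1, 0)-weight limit coincide exactly with a single-input run; a
single input is returned unchanged. Defaults: 20 iterations, k-NN grid
{5, 10, 15, 20} capped at n/5 — SNF-literature conventions.

The cluster count is the argmax over k ∈ [2, k_max] (k_max = 10; cohort-
scale cluster structure is small) of the eigengap of the normalized graph
Laplacian; an exactly degenerate spectrum (identity or rank-1 fused matrix)
returns k_max with a warning. The k-NN size is chosen by mean silhouette
width of the spectral clustering, with distance 1 − S/max(S) (the fused
matrix is rescaled to unit off-diagonal maximum so the silhouette operates
on a [0, 1] distance); ties go to the smaller k. Spectral clustering is
scikit-learn's normalized spectral clustering with seeded k-means, labels
1-based.

## Ensemble co-occurrence inference

All methods run on the merged (re-closed) multi-kingdom profile of one
group. CLR uses a pseudocount of half the smallest nonzero relative
abundance (0 if the table has no zeros), added before closure; CLR is
invariant to the re-closure itself.

- **COAT**: the CLR sample covariance estimates the basis covariance; each
  off-diagonal entry is shrunk by the adaptive threshold
  λᵢⱼ = soft · √(θ̂ᵢⱼ ln p / n), θ̂ᵢⱼ the empirical variance of the centered
  cross-products, soft = 0.2; the result is reported on the correlation
  scale and its signs carry to the edge-sign vote.
- **Sparse graphical model**: graphical lasso on the CLR correlation over
  100 log-spaced penalties from λ_max down to λ_max/100, selected by StARS
  (20 subsamples of ⌊0.8 n⌋, edge-instability target 0.05, monotonized from
  the sparse end; the path walk stops as soon as the monotonized
  instability exceeds the target, which is exact). Scores are partial
  correlations at the selected penalty; absent pairs score exactly 0.
  Graphical lasso (not Meinshausen–Bühlmann) is the committed estimator.
- **Mutual information**: plug-in MI in nats on equal-frequency
  discretizations, ⌊√n⌋ bins capped at 10; magnitude-only.
- **Bray–Curtis**: 1 − BC between taxon rows (similarity orientation so
  larger = stronger for every member); magnitude-only.

**Significance (ReBoot).** The observed edge score reported per method is
the mean of the statistic over 100 bootstrap resamples of the samples (with
replacement, re-closed). Significance compares the statistic computed on
the original table against a null that shuffles one endpoint taxon across
samples and re-closes every sample — the re-closure keeps the compositional
artifact in the null — with p = (1 + #{|null| ≥ |obs|})/(B + 1), B = 100 by
default. Two deliberate choices here: (i) the p-value comparison uses the
plain observed statistic, not the bootstrap mean, because resampling
duplicates samples and positively biases plug-in statistics such as MI,
which would destroy calibration; (ii) hard-thresholding estimators (COAT,
graphical lasso) are tested through their smooth functionals
(unthresholded CLR correlation; ridge-stabilized empirical partial
correlation), because exact zeros tie with every null draw and pile
p-values at 1. Calibration measured on structure-free compositions:
COAT-correlation and MI p-values are uniform (the CLR is invariant to
re-closure, ranks nearly so); partial-correlation p-values are close to
uniform with a valid tail; Bray–Curtis p-values are conservative on average
with some tail inflation under strong dominance — BC operates on raw
proportions, where the shuffle-and-re-close null carries the compositional
coupling only to first order. Interpret BC-member p-values accordingly; the
Simes merge across the four members buffers the effect.

**Combination.** Per method, |scores| are min–max normalized over all
pairs; the aggregate edge score is their (equal-weight, configurable) mean.
The edge sign is voted by COAT and the graphical model: agreement or a
single nonzero vote decides; a conflict excludes the edge (merged p forced
to 1) under the default policy, or the larger normalized magnitude wins
under the `magnitude` policy. Merged p-values use the weighted Simes rule
min_i (Σw)·p₍ᵢ₎/Σ_{j≤i}w₍ⱼ₎ with equal method weights. Networks keep
sign-defined pairs with merged p below the threshold; both printed presets
(1e-3 and 0.01) are available. Note the interplay with the permutation
floor 1/(B+1): at B = 100 the floor (≈0.0099) sits above 1e-3, so the
strict 1e-3 threshold requires the full 1000-permutation preset; the
reduced-reps preset pairs naturally with 0.01.

## Robustness and keystones

Natural connectivity is λ̄ = ln((1/N) Σᵢ e^{λᵢ}) over the adjacency
eigenvalues (computed with a logsumexp shift; 0 for edgeless or empty
graphs) and strictly increases with every added edge. "Normalized" divides
by N − ln N, the complete graph's value, making remaining-network sizes
comparable; any monotone per-size normalization preserves group-comparison
directions. Robustness uses the unsigned skeleton; signs enter only through
the negative-edge subnetwork (nodes without negative edges dropped).

Random attack removes uniform k-subsets for k = 1..N−1 (the single-node
remainder has connectivity 0 by convention), 1000 repeats by default.
Groups are compared per step with two-sided Wilcoxon rank-sum tests (normal
approximation with tie correction; two identical sample sets short-circuit
to p = 1) and merged by weighted Simes with the larger network's remaining
node count as the step weight. Simes over dependent steps is only
approximately calibrated; the measured type-I rate at α = 0.05 over
replicated same-graph comparisons is of the order of 10%.

IVI combines six node centralities — degree; ClusterRank
10^(−cᵢ)·Σ_{j∈N(i)}(deg j + 1); mean neighbor degree; local H-index
h(i) + Σ_{j∈N(i)} h(j); betweenness; collective influence
(deg i − 1)·Σ_{dist(i,j)=2}(deg j − 1) — each min–max scaled to [1, 100]
(constant components map every node to 100: all equally influential), then
hubness = scaled degree + scaled local H-index, spreading = (scaled
ClusterRank + scaled neighbor connectivity)·(scaled betweenness + scaled
collective influence), and IVI = min–max(hubness · spreading) on [1, 100].

Keystones: nodes are removed cumulatively in descending-IVI order (ties
broken lexicographically), recording normalized natural connectivity at
each prefix; the null repeats the recording under random removal orders.
Per-prefix p = (1 + #{null ≤ targeted})/(M + 1), ties counted
(conservative); the keystone set is the maximal initial prefix significant
at every step (the per-node alternative is not implemented; evaluation
stops one step past the first non-significant prefix, which cannot change
the set). Defaults M = 1000, α = 0.001; M must reach 1/α − 1 or the call
refuses. On an N-node graph the null that removes the top node first ties
with the targeted trajectory, so the first-prefix p cannot fall below
roughly 1/N + 1/(M+1) — keystone tests on small graphs need α chosen with
that floor in mind. A consequence of the maximal-prefix rule on strongly
hub-dominated graphs is that the keystone set can extend well past the hub:
after the hub is gone the targeted order keeps outpacing random orders that
usually still contain it.

## Pipeline and reproducibility

`run_pipeline` derives per-stage seeds from the global seed via
`numpy.random.SeedSequence`, so stages are reproducible in isolation and
rerunning a manifest's echoed config reproduces the outputs. The benchmark
problem sizes used by the test-suite and the acceptance script — cohorts of
p = 30 taxa with n = 500 samples/group for edge recovery, p = 20 with
n = 200 for null calibration, 60 samples/group for clustering, 200–1000
attack and permutation replicates — were chosen as the smallest sizes at
which the stochastic criteria are stable across seeds.

## Known limitations

- The simulator's latent-Gaussian + multinomial model understates real
  inter-individual variability (see above); benchmark recovery rates are
  upper bounds for field data.
- Bray–Curtis ReBoot p-values are approximate (conservative center,
  possible tail inflation under strong dominance).
- Natural connectivity is computed on the unweighted skeleton; edge-weighted
  robustness is out of scope.
- The eigengap rule assumes the fused similarity is approximately block
  structured; on gradient-like cohorts it can return small k with weak
  support — inspect `silhouette_by_k` from `select_k_neighbors`.
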