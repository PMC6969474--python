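# Methods

## The analysis model

The pipeline asks whether the coexpression structure of a focal gene program
is preserved between two experimental conditions measured by bulk RNA-seq.
It deliberately works with *hard-thresholded binary* networks rather than
weighted (soft-threshold) ones: with small per-condition sample sizes the
scientific claim is about whether gene pairs clear a significance bar at all,
not about fine-grained edge weights.

For one condition with `n` samples, all-pairs Pearson correlations
`r_ij` are computed on log2-CPM expression, each with a two-sided p-value from
`t = r * sqrt((n-2)/(1-r^2))` on `n-2` df. An edge exists iff `|r_ij| >= r_min`
(default 0.5) **and** `p_ij <= p_max` (default 0.05), both inclusive.
A useful identity at the default settings: with n = 9 samples, `p <= 0.05`
already forces `|r| >= 0.666`, so the correlation criterion is inactive there;
the test suite asserts this on random data.

Node statistics follow the closed-path-count definitions: connectivity
`k_i = sum_{j != i} a_ij` and clustering coefficient
`c_i = diag(A^3)_i / (k_i^2 - k_i)`, the second factor being the general
quadratic-form denominator `(sum_j a_ij)^2 - sum_j a_ij^2`, which collapses to
`k_i (k_i - 1)` for binary adjacency because `a^2 = a` — an identity the suite
asserts programmatically. `c_i` is reported as missing (NaN) when `k_i <= 1`:
the formula is 0/0 there, and imputing 0 would bias condition means of the
clustering distribution downward in sparse networks.

## Preservation statistic and permutation test

Preservation is summarized by the difference in condition means,
`T_k = mean_k(B) - mean_k(A)` and `T_c = mean_c(B) - mean_c(A)`, where `mean_c`
is taken over genes with defined `c` (and set to 0 when no gene qualifies,
which can occur in permuted near-null networks). This mirrors the
dashed-treatment-mean presentation of the distribution comparison the method
is built around.

Significance comes from pooled sample-label permutation: the `n_A + n_B`
samples are pooled and randomly reassigned to groups of the original sizes,
both networks are rebuilt per permutation, and the two-sided p-value is the
add-one estimator `(1 + #{|T_perm| >= |T_obs|}) / (n_perm + 1)` — never exactly
zero, and exact in size by construction because the null of no condition
effect makes samples exchangeable. Mean connectivity inside the permutation
loop is normalized by the full gene count, counting constant-expression genes
(excluded from correlation) as isolated nodes, so the statistic's denominator
cannot drift between permutations.

## FDR selection and overrepresentation

The DE selection step consumes an upstream per-gene p-value table and applies
Benjamini–Hochberg step-up: reject the `k` smallest p-values where `k` is the
largest rank with `p_(k) <= (k/m) q`. The *implied raw-p cutoff* `(k/m) q` is
reported alongside, because published analyses often quote that number (e.g.
84 rejections among 18,326 tests at q = 0.01 imply a cutoff of 4.6e-05).
Q-values use the standard monotone cumulative-minimum transform. Note that
re-running the full adjustment on q-values is *not* an identity; what is
invariant is (a) the monotonization step on already-monotone input and
(b) the theorem that thresholding q-values at `q` reproduces the step-up
rejection set. The tests assert both.

Overrepresentation of a gene set among the selected genes is the upper-tail
hypergeometric probability `P(X >= x)` with `X ~ Hypergeom(N, K, n)`:
`N` background genes (all tested, optionally restricted to annotated ones),
`K` set members in the background, `n` selected genes, `x` the overlap.
No correction across sets is applied by default (a BH-across-terms option
exists); GO-graph ancestor propagation is out of scope — sets are taken as
listed in the GMT.

## qPCR statistics

ΔCt normalizes the target gene to a stable reference gene per sample;
relative expression is `2^(-ΔΔCt)` with ΔΔCt referenced to the mean control
ΔCt. Group-mean fold changes are geometric (`2^(-mean ΔΔCt)`), which makes the
control group's mean exactly 1 and keeps fold changes multiplicative — the
natural scale of an exponential amplification assay. Amplification efficiency
is fixed at 2 (the method's defining assumption); technical replicates should
be averaged per sample upstream.

The diet/treatment effect on ΔCt uses the Gaussian likelihood-ratio statistic
`n ln(RSS0/RSS1)` (null: common mean; full: group means) against χ²₁. With
2 × 9 samples the χ² reference is an approximation; simulation at the null
shows type-I error within 0.05 ± 0.03, which the suite checks at 500
replicates. Zero residual variance under the full model is rejected as
degenerate rather than reported as infinite evidence.

## Synthetic-data generator

The generator emulates the study design end to end: two conditions of 9
samples, a gene universe (default 18,000) headed by a focal gene set (default
145 genes) that carries planted coexpression modules. Each module `m` has one
latent factor per sample, `f_ms ~ N(0,1)`, and member genes get
`z_gs = sqrt(rho) f_ms + sqrt(1-rho) eps_gs`, giving exact pairwise latent
correlation `rho`; condition B attenuates it to `rho (1 - delta)`. Counts are
negative binomial, `mean = exp(mu_g + sigma_b z_gs) * s_j` with per-gene
baselines `mu_g ~ U(2, 6)` (≈ 7–400 expected counts), per-sample log-normal
size factors (sd 0.1) so CPM normalization is exercised, and dispersion
`phi = 0.1` (variance `mu + phi mu^2`), typical of between-animal bulk RNA-seq.

Two parameters set the signal-to-noise regime and deserve comment. The latent
signal sd `sigma_b = 1.0` (natural-log scale) keeps the observed log-CPM
correlation within ~13% of the planted `rho`, because the NB measurement
noise adds roughly `1/mu + phi` to the log-scale variance. This is a design
requirement of the generator, not a convenience: its purpose is to control
the exact quantity (pairwise correlation) that the network analysis
thresholds. With a much weaker signal the planted `rho` would be a fiction —
attenuated below the n = 9 significance bound of 0.666 before the analysis
ever sees it.

What the generator does *not* emulate: read-level artifacts (GC bias, mapping
noise), batch effects, condition-specific library-size shifts, heavy-tailed
or outlier samples, and correlated modules that overlap. Passing tests
therefore demonstrate correctness of the statistical machinery under a clean
generative model, not robustness to real-data pathologies.

The DE p-value generator plants `Beta(a, 1)` alternatives (default a = 0.05)
in the first `n_true` genes — which overlap the focal set by construction, so
the enrichment stage has a planted positive — among `Uniform(0,1)` nulls. The
qPCR generator draws reference Ct ~ N(20, sd) and target Ct = reference + 5 +
group shift + noise; a +1-cycle shift corresponds to a true fold change 0.5.

## Numerical and design choices

- Correlations are clipped to [−1, 1] before the t-transform; `p = 0` exactly
  at `|r| = 1`. Correlation p-values on the diagonal are NaN by definition.
- Constant-variance genes are excluded from correlation with a warning
  (strict mode raises); missing expression values are rejected outright.
- Thresholds are inclusive (≥, ≤) on both criteria.
- BH uses a stable mergesort so tied p-values resolve deterministically.
- All generators are `numpy.random.default_rng`-seeded and bitwise
  reproducible given the seed.
- Distribution means can be restricted to connected nodes via
  `drop_isolated=True` in the pipeline; the default keeps all genes (isolated
  nodes contribute k = 0 and no defined c), which is the conservative reading
  when the original distribution construction is unspecified.

## Problem sizes in tests and the acceptance script

The Monte-Carlo suites run on a 60-gene focal set with planted modules
(ρ = 0.7–0.8): 100 replicates for the disruption-direction check (δ = 0.85),
100 replicates × 199 permutations for power (δ = 0.9; three modules totalling
45 of 60 genes), and 400 replicates × 199 permutations for test size at δ = 0.
A single planted (20, 0.8) module among 40 background genes caps permutation
power near 0.8 at 9 + 9 samples — all within-module correlations share the
same nine factor draws, so entire replicates fall below the 0.666 edge
threshold together — hence the module-rich design for the power study, which
reaches ≈ 0.97. The acceptance script runs the full pipeline at 4,000 genes
with a 145-gene focal set, 499 permutations.

## Known limitations

- The hard-threshold network is sensitive to the sample size through the
  p-criterion: at n = 9 the effective correlation threshold is 0.666 whatever
  `r_min ≤ 0.666` is set to.
- The permutation test exchanges whole samples; it cannot detect disruption
  patterns that preserve the mean of `k` and `c` while rearranging edges.
- The χ²₁ reference for the qPCR LRT is asymptotic; at very small n an exact
  F-test would be sharper.
- Fisher p-values below ~1e-308 underflow to 0.0 in double precision.
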