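# Methods

## Model and assumptions

`jamss` performs Bayesian variable selection on GWAS summary statistics for a
continuous trait. The underlying data model is the standard multi-SNP linear
regression `y ~ N(Xβ, σ²I_N)` with the trait and the additive genotype
dosages mean-centred (no intercept). Because individual data are unavailable,
inference is carried entirely by the P-vector `z = X'y` and the P×P matrix
`X'X`:

- `z` is reconstructed from the reported marginal effects. Under
  Hardy–Weinberg equilibrium the expected genotype-group counts at allele
  frequency p are `(N(1−p)², 2Np(1−p), Np²)` (kept real-valued — only the
  products `n_g ȳ_g` enter `z`, so rounding would only add error). The
  centred group trait means are the unique solution of the additive marginal
  fit `{ȳ₁−ȳ₀ = β̂, ȳ₂−ȳ₀ = 2β̂, Σ n_g ȳ_g = 0}`, i.e.
  `ȳ₀ = −β̂(n₁+2n₂)/N`, and `z_m = ȳ₁n₁ + 2ȳ₂n₂`. This collapses to
  `z_m = β̂_m · N · 2p(1−p)`, and reproduces `X'y` exactly when the observed
  genotype counts sit exactly at their HWE expectations (asserted against a
  least-squares oracle in the tests).
- `X'X` is a plug-in estimate from a reference genotype panel of the same
  population: the mean-centred reference cross-product scaled by
  `N_study/N_ref`. Missing reference genotypes are mean-imputed per SNP
  before centring (preserves column means). The scaling makes the plug-in
  consistent with the study-scale distribution `z ~ N(X'Xβ, σ²X'X)`.

Within each LD block `X'X = L'L` (upper-triangular Cholesky) and the
triangular system `L'z_L = z` is solved — never an explicit inverse — giving
the whitened model `z_L ~ N(L_γ β_γ, σ² I_P)`. Note the complete block
vector `z_L` is always modelled, whichever SNPs are in `γ`. A
non-positive-definite block is a hard error pointing at LD pruning, not a
silently repaired one: the model genuinely requires a full-rank reference
cross-product, and no block can exceed the reference sample size.

## Priors and marginal likelihood

- Residual variance: `σ² ~ InvGamma(a_σ, b_σ)`, default `0.01, 0.01`
  (weakly informative).
- Effects: g-prior `β_γ | σ² ~ N(0, τσ²(L_γ'L_γ)⁻¹)`. τ defaults to
  `max(P², N)` with P the **total** SNP count across the analysis (applied
  globally, configurable per run).
- Model space: beta-binomial over model size with `(a_ω, b_ω) = (1, 9)` —
  the implied proportion of causal SNPs has prior mean
  `a_ω/(a_ω+b_ω) = 10%`. The same `(a_ω, b_ω)` applies independently in
  every block, so the expected total number of included SNPs is
  `Σ_b P_b/10`, preserving the global prior mean proportion.

Integrating `(β_γ, σ²)` out gives the closed-form log marginal likelihood

    −(p_γ/2)·log(τ+1) − ((2a_σ+P−1)/2)·log(2b_σ + S(γ)),
    S(γ) = ‖z_L‖² − τ/(1+τ)·z_L'L_γ(L_γ'L_γ)⁻¹L_γ'z_L ,

with P the block length. A general normal-inverse-gamma path
(`log_marginal_likelihood_nig`) accepts arbitrary prior means and scale
matrices (e.g. diagonal independence priors for sensitivity analyses) and
reduces exactly to the g-prior expression when `m_γ = 0`,
`Σ_γ = τ(L_γ'L_γ)⁻¹`; the two paths agree to ~1e−13 on random instances.
Model-constant factors that cancel under normalization are retained so that
likelihood values are comparable across code paths.

**Exponent convention.** The S(γ) exponent is `(2a_σ+P−1)/2`, while the
σ²-posterior shape used for effect inference is `a_σ + P/2`; both are
implemented as stated even though they differ by a half — the `P−1`
reflects the degree of freedom absorbed by mean-centring. The literal
integral of the normal-inverse-gamma integrand carries `(2a_σ+P)/2`, so the
quadrature validation evaluates the closed form at `a_σ + 1/2` (whose
exponent equals the literal integral's) against 2-D numerical integration;
this exercises S(γ), the shrinkage factor and the determinant algebra
unchanged, and agrees to ~4e−6 relative (and to machine precision against
the analytic scaled-t ratio).

All scoring is in log space and posteriors normalize per block by
log-sum-exp: S(γ) terms span hundreds of log units. S(γ) itself is computed
through Cholesky/QR solves of small `L_γ'L_γ` systems.

## Posterior inference

**Enumeration.** Per block, every model of dimension ≤ `max_dim` (default 3)
is scored; counting combinations, a 100-SNP block at `max_dim = 3` takes
`1 + C(100,1) + C(100,2) + C(100,3) = 166,751` evaluations. Blocks are
independent, so joint quantities multiply: per-SNP inclusion probabilities
sum model probabilities within the block; the distribution of the number of
signals in a region combines per-block size distributions by convolution.
The prior size distribution over a region uses the same truncated,
renormalized space (size beta-binomial, membership hypergeometric given
size), so Bayes factors

    BF(≥k) = [P(≥k | data)/P(<k | data)] / [P(≥k)/P(<k)]

compare posterior and prior odds under one normalization. Reported rankings
break ties by (probability desc, model size asc, SNP ids lexicographic).

**Stochastic search.** For unbounded model dimension, a Reversible-Jump
Metropolis–Hastings chain proposes one move per iteration: a move type drawn
uniformly among the feasible members of {add, delete, swap}, SNP choices
uniform, swap exchanging an included for an excluded SNP within one block.
Swap preserves all counts, so its proposal is symmetric; add/delete carry
the count correction (e.g. `log[(P−p_γ)/(p_γ+1)]`) plus the change in the
number of feasible move types. The chain starts at the empty model (matching
the sparse prior), discards the first half as burn-in, and thins retained
indicator rows to at most 1e5. Per-block scores are cached by included-set
key, so small-block chains reduce mostly to dictionary lookups (two million
iterations in well under a minute). With the likelihood forced constant the
chain reproduces the beta-binomial prior; against complete enumeration of a
10-SNP block its per-SNP probabilities agree to ~2e−4 after 2×10⁶
iterations. Convergence tooling reports occupancy traces, indicator
autocorrelations and cross-seed probability differences.

**Adjusted effects.** Conditional on a chosen model, the joint posterior of
`(β_γ, σ²)` is normal-inverse-gamma in closed form with
`β̂_γ = (L_γ'L_γ)⁻¹L_γ'z_L` and `s² = ‖z_L − L_γβ̂_γ‖²`. Since the σ² draw
does not depend on β, draws are generated directly (σ² from its
inverse-gamma marginal, then β from the conditional normal) — statistically
identical to iterating the two conditionals as a Gibbs sampler. Credible
intervals are equal-tailed 2.5/97.5 empirical percentiles; their coverage on
self-generated conjugate data is nominal to within Monte-Carlo error.

## Input handling

Summary files are tab-separated (SNP, EA, NEA, MAF, BETA, optional SE, N);
reference panels may be a VCF (dosages from GT, biallelic records), a
PLINK-style additive text export, or a headered numeric matrix. SNPs are
intersected, allele-harmonized onto the reference counted allele (sign and
frequency flip when swapped; strand flips resolved by complement), ordered
by position when coordinates exist, and pruned at MAF ≥ 5% and pairwise
r² ≤ 0.95 (greedy left-to-right). Palindromic A/T and C/G SNPs cannot be
strand-resolved from alleles alone and are dropped by default
(`--keep-ambiguous` overrides). Every dropped SNP is logged with its reason;
analysed + dropped exactly partition the input. Block definitions may come
from a BED file (0-based half-open; SNPs outside any interval become
singleton blocks) or from a built-in contiguous partitioner that cuts where
the maximum between-segment r² drops below a threshold (default 0.01) —
deliberately simpler than haplotype-block recognition algorithms, which
users can still apply upstream via block files.

## Synthetic data generator

The generator emulates the study conditions of the motivating
quantitative-trait setting: cohort n = 15,356; residual SD 0.97 (the scale
of 2-hr glucose); an independently drawn reference panel of 2,674;
per-allele effects 0.065–0.26. Genotypes come either from bootstrapping rows
of a template matrix or from a parametric latent-Gaussian model: one latent
normal per individual with per-block AR or exchangeable correlation
(default AR 0.9), cut at the HWE quantiles of the target allele frequency to
give 0/1/2 dosages. Target frequencies (default U(0.1, 0.4)) are a
deterministic function of the scenario seed, so a study cohort and its
reference panel share one underlying population and differ only by sampling
noise. Traits are sparse linear signals plus Gaussian noise, mean-centred.

What the generator does **not** emulate: empirical haplotype structure
(D′-defined blocks, allele-frequency-dependent LD decay), genotyping error
and missingness patterns, population stratification, or case-control
ascertainment. Passing tests therefore demonstrate correctness of the
machinery and behaviour under controlled LD, not performance guarantees on
any particular real cohort.

## Reference experiments and problem sizes

The experiments in `jamss.experiments` (used by both the test suite and
`scripts/acceptance.py`) run at the following sizes, chosen to make each
check statistically meaningful at desk scale:

- Oracle equivalence: 20 datasets, n = 2,000, P = 30 in 3 blocks; fitted
  quadratic forms agree with the direct genotype computation to ~1e−14 and
  model rankings match the individual-level conjugate analysis exactly.
- Algebraic agreement: 1,000 random g-prior/NIG instances; one quadrature
  validation per run.
- Sampler vs enumeration: one 10-SNP block, full 2¹⁰ enumeration versus
  2×10⁶ RJMCMC iterations.
- Null calibration: 50 zero-effect replicates of the default scenario; mean
  per-SNP posterior probability ≈ 0.001–0.01.
- Signal recovery: 50 replicates, 3 causal SNPs (0.26/0.20/0.13) in
  distinct blocks; mean PPV at rank 3 of the PIP ranking ≈ 0.99.
- Multi-signal Bayes factors: 40 replicates each of 1-signal and 3-signal
  truths; BF(≥2) under one signal ≪ 3, BF(≥2) and BF(≥3) under three
  signals ≫ 100 on average.
- Effect moments: 10⁵ direct draws versus the closed-form means.

## Known limitations

- Continuous traits only: marginal odds ratios from case-control studies are
  outside the model's derivation.
- Reference and study populations must match; LD mis-specification inflates
  S(γ) and dilutes (never manufactures) evidence — noticeably so for strong
  signals with modest reference panels.
- Evidence strength scales with block length P through the S(γ) exponent;
  very small blocks are conservative.
- Per-model (not model-averaged) effect estimates; equal-tailed rather than
  highest-density intervals.
- The enumeration cap assumes few causal SNPs per block; use the stochastic
  search when that is doubtful.
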