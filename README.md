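# jamss — joint Bayesian re-analysis of marginal GWAS summary statistics

GWAS consortia usually publish only one-at-a-time ("marginal") SNP effect
estimates. In a region with linkage disequilibrium (LD) dozens of SNPs then
appear associated, even when one or a few causal variants drive the whole
pattern. `jamss` re-analyses those published marginal effects under **joint
multi-SNP linear models**, using an external reference genotype panel to
supply the LD, and reports which SNP subsets best explain the region —
fine-mapping without access to the individual-level data.

## The model

For a mean-centred continuous trait `y` and centred genotype dosages `X`
(n × P), the sufficient statistic of the joint linear model is `z = X'y`.
Each entry is rebuilt from the reported marginal effect `β̂_m`, allele
frequency `p_m` and sample size `N` under Hardy–Weinberg equilibrium:

    z_m = ȳ_m1 n_m1 + 2 ȳ_m2 n_m2 ,   n_mg = HWE counts,  ȳ_mg = group trait means

`X'X` is estimated from a reference panel, scaled by `N / N_ref`, and
factored per LD block as `X'X = L'L` (Cholesky). Solving `L' z_L = z` whitens
the summaries into an ordinary regression `z_L ~ N(L_γ β_γ, σ² I_P)` over a
model indicator `γ`. A conjugate g-prior `β_γ ~ N(0, τ σ² (L_γ'L_γ)⁻¹)` with
`τ = max(P², N)` and an inverse-gamma prior on σ² integrate out analytically:

    p(z_L | γ) ∝ (τ+1)^(−p_γ/2) (2b_σ + S(γ))^(−(2a_σ+P−1)/2)
    S(γ) = ‖z_L‖² − τ/(1+τ) · z_L' L_γ (L_γ'L_γ)⁻¹ L_γ' z_L

A beta-binomial prior on model size (default Beta(1, 9): causal proportion
centred on 10%) supplies sparsity. Per block, all models up to `max_dim`
SNPs are enumerated exactly — or an add/delete/swap Reversible-Jump MCMC
samples the unrestricted model space. Outputs are per-SNP posterior
inclusion probabilities, ranked models, Bayes factors for "≥ k signals in a
region", and closed-form normal-inverse-gamma posteriors for the adjusted
(multi-SNP) effect sizes.

## Worked example

Simulate a 15,356-person study of a 30-SNP region (three LD blocks, one
causal SNP per block), run the marginal scan, and re-analyse the summaries
with an independent 2,674-person reference panel:

```python
import numpy as np
from jamss import (PriorSpec, SimulationScenario, build_blocks,
                   center_genotype_matrix, enumerate_models, marginal_scan,
                   bayes_factor_min_signals, reconstruct_z, simulate_genotypes,
                   simulate_trait)

scenario = SimulationScenario(
    n_individuals=15_356, block_sizes=(10, 10, 10), within_block_rho=0.9,
    causal={2: 0.26, 14: 0.20, 27: 0.13}, residual_sd=0.97, seed=1)

G, _ = simulate_genotypes(scenario, seed=10)            # study cohort
y = simulate_trait(G, scenario.causal, 0.97, seed=11)   # trait
summaries = marginal_scan(G, y)                         # published statistics
z = reconstruct_z(summaries)                            # rebuild X'y

ref, _ = simulate_genotypes(scenario, n_individuals=2_674, seed=12)
blocks = build_blocks(center_genotype_matrix(ref), z,
                      [s.snp_id for s in summaries], n_study=15_356,
                      boundaries=[(0, 10), (10, 20), (20, 30)])

table = enumerate_models(blocks, PriorSpec())
print(table.snp_probabilities().nlargest(4).round(3))
print("BF(>=3 signals):", round(bayes_factor_min_signals(table, 3), 1))
```

Output:

```
snp14    0.996
snp2     0.865
snp27    0.666
snp24    0.036
Name: posterior_prob, dtype: float64
BF(>=3 signals): 2.0
```

The three causal SNPs receive the top posterior inclusion probabilities,
well separated from every non-causal SNP. The Bayes factor for three or more
distinct signals sits at 2.0 for this particular replicate — evidence for a
third signal at the weakest effect (0.13 per allele) fluctuates from draw to
draw, and averages in the hundreds across replicates (see
`scripts/acceptance.py`), while BF(≥2) is decisive in essentially every run.

The same analysis runs from files on the command line:

```bash
jam simulate scenario.yaml -o sim/
jam enumerate sim/summary_stats.tsv sim/genotypes.tsv -o results/
jam sample    sumstats.tsv ref_panel.vcf --iterations 2000000 -o results/
```

producing `models.tsv`, `snp_probabilities.tsv`, `bayes_factors.tsv`,
`effects.tsv` and a manifest of every dropped SNP.

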