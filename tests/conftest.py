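import numpy as np
import pytest

from jamss import (
    PriorSpec,
    SimulationScenario,
    build_blocks,
    center_genotype_matrix,
    marginal_scan,
    simulate_genotypes,
    simulate_trait,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_930)


@pytest.fixture
def small_study():
    """A small two-block study with exact z = X'y and true X'X (no reference noise)."""
    scenario = SimulationScenario(
        n_individuals=2500,
        block_sizes=(6, 6),
        within_block_rho=0.8,
        causal={1: 0.35, 8: 0.30},
        residual_sd=0.97,
        seed=11,
    )
    G, _ = simulate_genotypes(scenario, seed=101)
    y = simulate_trait(G, scenario.causal, scenario.residual_sd, seed=102)
    Xc = center_genotype_matrix(G)
    yc = y - y.mean()
    z = Xc.T @ yc
    ids = [f"snp{j}" for j in range(G.shape[1])]
    blocks = build_blocks(Xc, z, ids, n_study=G.shape[0], boundaries=[(0, 6), (6, 12)])
    return {"G": G, "y": yc, "z": z, "ids": ids, "blocks": blocks, "bounds": [(0, 6), (6, 12)]}


@pytest.fixture
def default_prior():
    return PriorSpec()
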