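"""Model priors, conjugate marginal likelihoods, enumeration and Bayes factors."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import t as tdist

from jamss.inference import (
    ModelScore,
    PosteriorTable,
    PriorSpec,
    bayes_factor_min_signals,
    enumerate_models,
    log_marginal_likelihood_gprior,
    log_marginal_likelihood_nig,
    log_model_prior,
    prior_region_size_dist,
    snp_inclusion_probabilities,
)
from jamss.ld import build_blocks, cholesky_factor
from jamss.simulate import SimulationScenario, simulate_genotypes
from jamss.experiments import gprior_nig_agreement


class TestModelPrior:
    def test_null_model_closed_form(self):
        from scipy.special import betaln

        for a, b, p in [(1.0, 9.0, 5), (2.0, 3.0, 10)]:
            assert log_model_prior(0, p, a, b) == pytest.approx(
                betaln(a, p + b) - betaln(a, b)
            )

    @pytest.mark.parametrize("p", [3, 8, 12])
    def test_complete_enumeration_sums_to_one(self, p):
        from math import comb

        total = sum(
            comb(p, k) * np.exp(log_model_prior(k, p, 1.0, 9.0)) for k in range(p + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_default_prior_centres_causal_proportion_on_ten_percent(self):
        p = 12
        from math import comb

        ek = sum(
            k * comb(p, k) * np.exp(log_model_prior(k, p, 1.0, 9.0)) for k in range(p + 1)
        )
        assert ek / p == pytest.approx(0.10, abs=1e-12)

    def test_oversized_model_rejected(self):
        with pytest.raises(ValueError):
            log_model_prior(4, 3, 1.0, 9.0)


class TestMarginalLikelihood:
    def test_null_model_formula(self, rng):
        P = 4
        A = rng.normal(size=(P, P))
        L = cholesky_factor(A @ A.T + P * np.eye(P))
        zL = rng.normal(size=P)
        prior = PriorSpec(tau=100.0)
        got = log_marginal_likelihood_gprior(zL, L, np.zeros(P, dtype=bool), prior)
        expected = -0.5 * (2 * 0.01 + P - 1) * np.log(2 * 0.01 + float(zL @ zL))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_single_snp_matches_analytic_scaled_t_ratio(self):
        """With shape shifted by the centring half-power, the single-SNP log BF
        equals the ratio of scaled-t densities that the integral evaluates to."""
        ell, zl, tau, a, b = 1.7, 1.1, 250.0, 0.01, 0.01
        prior = PriorSpec(tau=tau, a_sigma=a + 0.5, b_sigma=b)
        L = np.array([[ell]])
        z = np.array([zl])
        closed = log_marginal_likelihood_gprior(
            z, L, np.array([True]), prior
        ) - log_marginal_likelihood_gprior(z, L, np.array([False]), prior)
        analytic = tdist.logpdf(zl, df=2 * a, scale=np.sqrt(b / a * (tau + 1))) - tdist.logpdf(
            zl, df=2 * a, scale=np.sqrt(b / a)
        )
        assert closed == pytest.approx(analytic, rel=1e-12)

    def test_gprior_equals_nig_with_matching_scale(self):
        res = gprior_nig_agreement(n_instances=200, seed=7)
        assert res["max_rel_discrepancy"] < 1e-10

    def test_nig_huge_variance_reaches_least_squares_limit(self, rng):
        P = 5
        X = rng.normal(size=(50, P))
        A = X.T @ X
        L = cholesky_factor(A)
        zL = rng.normal(size=P) * 3
        prior = PriorSpec(tau=10.0)
        idx = np.array([0, 2])
        mask = np.zeros(P, dtype=bool)
        mask[idx] = True
        huge = 1e12 * np.eye(2)
        val = log_marginal_likelihood_nig(zL, L, mask, np.zeros(2), huge, prior)
        # S(gamma) in the flat-prior limit is the OLS residual quadratic form
        v = L.T @ zL
        fitted = float(v[idx] @ np.linalg.solve(A[np.ix_(idx, idx)], v[idx]))
        s_ols = float(zL @ zL) - fitted
        exponent_term = -0.5 * (2 * prior.a_sigma + P - 1) * np.log(2 * prior.b_sigma + s_ols)
        # determinant terms depend on the huge scale; isolate the S-term
        recovered = val + 0.5 * np.linalg.slogdet(A[np.ix_(idx, idx)] + np.eye(2) / 1e12)[1]
        recovered += 0.5 * np.linalg.slogdet(huge)[1]
        assert recovered == pytest.approx(exponent_term, rel=1e-6)

    def test_nig_degenerate_prior_point_mass_is_finite(self, rng):
        P = 3
        X = rng.normal(size=(30, P))
        L = cholesky_factor(X.T @ X)
        zL = rng.normal(size=P)
        prior = PriorSpec(tau=10.0)
        mask = np.array([True, False, True])
        tiny = 1e-10 * np.eye(2)
        val = log_marginal_likelihood_nig(zL, L, mask, np.array([0.1, -0.2]), tiny, prior)
        assert np.isfinite(val)

    def test_unresolved_tau_is_an_error(self, rng):
        L = np.eye(2)
        with pytest.raises(ValueError, match="tau"):
            log_marginal_likelihood_gprior(np.ones(2), L, np.array([True, False]), PriorSpec())


class TestEnumeration:
    def test_three_snp_block_scores_all_eight_models(self, rng):
        X = rng.normal(size=(100, 3))
        X -= X.mean(0)
        z = rng.normal(size=3)
        blocks = build_blocks(X, z, ["a", "b", "c"], n_study=100, boundaries=[(0, 3)])
        table = enumerate_models(blocks, PriorSpec(max_dim=3))
        assert len(table.block_models[0]) == 8
        assert table.block_probs[0].sum() == pytest.approx(1.0, abs=1e-12)

    def test_pure_noise_prefers_null_model(self):
        wins = 0
        reps = 20
        for r in range(reps):
            scenario = SimulationScenario(
                n_individuals=800, block_sizes=(6,), within_block_rho=0.5,
                causal={}, seed=100 + r,
            )
            rng = np.random.default_rng(200 + r)
            G, _ = simulate_genotypes(scenario, seed=300 + r)
            Xc = G - G.mean(0)
            y = rng.normal(0, 0.97, size=800)
            y -= y.mean()
            z = Xc.T @ y
            blocks = build_blocks(Xc, z, [f"s{i}" for i in range(6)], n_study=800,
                                  boundaries=[(0, 6)])
            table = enumerate_models(blocks, PriorSpec())
            top = table.models_frame().iloc[0]
            wins += int(top["snps"] == ".")
        assert wins / reps > 0.6

    def test_strong_signal_gets_highest_inclusion_probability(self, small_study):
        table = enumerate_models(small_study["blocks"], PriorSpec())
        pips = table.snp_probabilities()
        # the causal SNP tops its own LD block
        assert pips[:6].idxmax() == "snp1"
        assert pips[6:].idxmax() == "snp8"

    def test_sum_of_pips_equals_expected_model_size(self, small_study):
        table = enumerate_models(small_study["blocks"], PriorSpec())
        pips = snp_inclusion_probabilities(table)
        post, _ = table.region_size_distribution()
        e_size = float(np.arange(len(post)) @ post)
        assert pips.sum() == pytest.approx(e_size, abs=1e-10)
        assert ((pips >= 0) & (pips <= 1)).all()

    def test_ranking_tie_break_is_stable(self, small_study):
        df = enumerate_models(small_study["blocks"], PriorSpec()).models_frame()
        assert list(df["rank"]) == list(range(1, len(df) + 1))
        probs = df["posterior_prob"].to_numpy()
        assert np.all(np.diff(probs) <= 1e-15)


def _prior_table(p: int, prior: PriorSpec) -> PosteriorTable:
    """A posterior table whose model probabilities equal the truncated prior."""
    from itertools import combinations

    models, scores = [], []
    for k in range(min(prior.max_dim, p) + 1):
        lp = log_model_prior(k, p, prior.a_omega, prior.b_omega)
        for idx in combinations(range(p), k):
            models.append(ModelScore(idx, tuple(f"s{i}" for i in idx), k, lp, 0.0))
            scores.append(lp)
    scores = np.array(scores)
    norm = logsumexp(scores)
    return PosteriorTable(
        snp_ids=[f"s{i}" for i in range(p)],
        block_snp_ids=[[f"s{i}" for i in range(p)]],
        block_models=[models],
        block_probs=[np.exp(scores - norm)],
        block_log_norm=[float(norm)],
        prior=prior,
    )


class TestBayesFactors:
    def test_posterior_equal_to_prior_gives_unit_bayes_factor(self):
        table = _prior_table(6, PriorSpec(tau=100.0))
        for k in (1, 2, 3):
            assert bayes_factor_min_signals(table, k) == pytest.approx(1.0, abs=1e-10)

    def test_null_dominated_table_shrinks_bf_below_one(self):
        prior = PriorSpec(tau=100.0)
        table = _prior_table(6, prior)
        # move almost all mass onto the empty model
        probs = table.block_probs[0]
        probs[:] = 1e-6 / (len(probs) - 1)
        probs[0] = 1 - 1e-6
        assert bayes_factor_min_signals(table, 1) < 1.0

    def test_infinite_flag_when_no_mass_below_k(self):
        prior = PriorSpec(tau=100.0)
        table = _prior_table(3, prior)
        probs = table.block_probs[0]
        probs[:] = 0.0
        probs[-1] = 1.0  # all mass on a 3-SNP model
        assert bayes_factor_min_signals(table, 1) == np.inf

    def test_region_restriction_uses_hypergeometric_prior(self):
        dist = prior_region_size_dist(10, 4, 1.0, 9.0, max_dim=3)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)
        assert len(dist) == 5


class TestPipsFromTables:
    def test_single_model_table(self):
        prior = PriorSpec(tau=10.0)
        table = _prior_table(3, prior)
        probs = table.block_probs[0]
        probs[:] = 0.0
        # model containing only s1
        for i, m in enumerate(table.block_models[0]):
            if m.gamma == (1,):
                probs[i] = 1.0
        pips = table.snp_probabilities()
        assert pips["s1"] == pytest.approx(1.0)
        assert pips[["s0", "s2"]].sum() == pytest.approx(0.0)

    def test_two_equiprobable_single_snp_models(self):
        prior = PriorSpec(tau=10.0)
        table = _prior_table(2, prior)
        probs = table.block_probs[0]
        probs[:] = 0.0
        for i, m in enumerate(table.block_models[0]):
            if m.size == 1:
                probs[i] = 0.5
        pips = table.snp_probabilities()
        assert pips["s0"] == pytest.approx(0.5)
        assert pips["s1"] == pytest.approx(0.5)
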