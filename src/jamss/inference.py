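"""Bayesian variable selection on whitened summary statistics.

Within each LD block the whitened summary vector behaves as an ordinary
Gaussian regression ``zL ~ N(L_g beta_g, sigma^2 I_P)``.  With a conjugate
normal-inverse-gamma prior on (beta_g, sigma^2) the coefficients integrate out
analytically, giving a closed-form marginal likelihood per model indicator g.
The default effect prior is Zellner's g-prior, ``beta_g ~ N(0, tau sigma^2
(L_g'L_g)^{-1})``, under which the marginal likelihood collapses to

    p(zL | g)  ∝  (tau+1)^(-p_g/2) * (2 b_sigma + S(g))^(-(2 a_sigma + P - 1)/2)
    S(g)       =  ||zL||^2 - tau/(1+tau) * zL' L_g (L_g'L_g)^{-1} L_g' zL ,

and a beta-binomial prior over model size supplies sparsity.  Blocks are
independent, so posteriors multiply across blocks; within a block the
truncated model space (all models up to ``max_dim`` SNPs) is enumerated
exactly and normalized by log-sum-exp.

All scoring is in log space: the S(g) terms routinely span hundreds of log
units.  Model-constant factors that would cancel in normalized posteriors are
retained so likelihood values are comparable across code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import betaln, gammaln, logsumexp
from scipy.stats import hypergeom

from .ld import WhitenedBlock

__all__ = [
    "PriorSpec",
    "ModelScore",
    "PosteriorTable",
    "log_model_prior",
    "log_marginal_likelihood_gprior",
    "log_marginal_likelihood_nig",
    "enumerate_models",
    "snp_inclusion_probabilities",
    "bayes_factor_min_signals",
]


@dataclass(frozen=True)
class PriorSpec:
    """Hyper-parameters of the conjugate model-selection prior.

    Parameters
    ----------
    a_sigma, b_sigma : float
        Inverse-gamma shape/scale on the residual variance; 0.01/0.01 is a
        relatively uninformative default.
    tau : float or None
        g-prior scale.  ``None`` means "resolve to max(P^2, N)" at analysis
        time, with P the total SNP count across all blocks.
    a_omega, b_omega : float
        Beta-binomial hyper-prior on the proportion of truly causal SNPs;
        the (1, 9) default centres that proportion on 10%.
    max_dim : int
        Per-block enumeration cap on model dimension.
    """

    a_sigma: float = 0.01
    b_sigma: float = 0.01
    tau: float | None = None
    a_omega: float = 1.0
    b_omega: float = 9.0
    max_dim: int = 3

    def __post_init__(self) -> None:
        for name in ("a_sigma", "b_sigma", "a_omega", "b_omega"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.max_dim < 1:
            raise ValueError("max_dim must be >= 1")

    def resolve_tau(self, total_p: int, n_study: float) -> "PriorSpec":
        """Fix tau = max(P^2, N) if it was left unset."""
        if self.tau is not None:
            return self
        return replace(self, tau=float(max(total_p**2, n_study)))


@dataclass(frozen=True)
class ModelScore:
    """A scored model: indicator, prior, marginal likelihood, unnormalized posterior."""

    gamma: tuple[int, ...]  # block-local indices of included SNPs
    snp_ids: tuple[str, ...]
    size: int
    log_prior: float
    log_marginal_likelihood: float

    @property
    def log_posterior_unnorm(self) -> float:
        return self.log_prior + self.log_marginal_likelihood


def log_model_prior(k: int, p: int, a_omega: float, b_omega: float) -> float:
    """Log beta-binomial prior mass of one particular model of size k among p SNPs.

    ``log B(k + a, p - k + b) - log B(a, b)``; every model of the same size
    receives this same mass (the expression is per model, not summed over the
    C(p, k) models of that size).
    """
    if not 0 <= k <= p:
        raise ValueError(f"model size {k} outside [0, {p}]")
    return float(betaln(k + a_omega, p - k + b_omega) - betaln(a_omega, b_omega))


def _as_index(gamma, p: int) -> np.ndarray:
    """Accept a model as a boolean inclusion indicator or a tuple of indices.

    Only boolean arrays are read as indicators (length must equal the block
    size); integer sequences are always index lists, avoiding any ambiguity
    for small blocks.
    """
    g = np.asarray(gamma)
    if g.dtype == bool:
        if g.size != p:
            raise ValueError("boolean indicator length must equal block size")
        return np.flatnonzero(g)
    if g.size == 0:
        return np.empty(0, dtype=int)
    idx = g.astype(int)
    if idx.min() < 0 or idx.max() >= p:
        raise ValueError("gamma indices out of range")
    return idx


def _fitted_quadratic(A: np.ndarray, v: np.ndarray, idx: np.ndarray, snp_ids=None) -> float:
    """v_g' (A_gg)^{-1} v_g via Cholesky solves (no explicit inverse)."""
    if idx.size == 0:
        return 0.0
    Agg = A[np.ix_(idx, idx)]
    try:
        c, low = linalg.cho_factor(Agg, lower=False)
    except linalg.LinAlgError as err:
        names = [snp_ids[i] for i in idx] if snp_ids is not None else list(idx)
        raise linalg.LinAlgError(
            f"L_g'L_g singular for SNPs {names}: collinear in the reference panel"
        ) from err
    w = linalg.cho_solve((c, low), v[idx])
    return float(v[idx] @ w)


def log_marginal_likelihood_gprior(
    zL: np.ndarray,
    L: np.ndarray,
    gamma,
    prior: PriorSpec,
    snp_ids: Sequence[str] | None = None,
) -> float:
    """Closed-form log marginal likelihood of one model under the g-prior.

    Uses the identity ``L_g' zL = z_g`` (with A = L'L) so the fitted quadratic
    reduces to ``z_g' (A_gg)^{-1} z_g``, computed by triangular solves.  The
    null model returns ``-((2 a_sigma + P - 1)/2) log(2 b_sigma + ||zL||^2)``.
    """
    if prior.tau is None:
        raise ValueError("tau unset; call PriorSpec.resolve_tau first")
    zL = np.asarray(zL, dtype=float)
    P = zL.shape[0]
    idx = _as_index(gamma, P)
    A = L.T @ L
    v = L.T @ zL
    tau = prior.tau
    fitted = _fitted_quadratic(A, v, idx, snp_ids)
    s_gamma = float(zL @ zL) - tau / (1.0 + tau) * fitted
    if 2.0 * prior.b_sigma + s_gamma <= 0.0:
        raise FloatingPointError(
            f"S(gamma) = {s_gamma} non-positive after rounding: numerical degeneracy"
        )
    return (
        -0.5 * idx.size * np.log(tau + 1.0)
        - 0.5 * (2.0 * prior.a_sigma + P - 1.0) * np.log(2.0 * prior.b_sigma + s_gamma)
    )


def log_marginal_likelihood_nig(
    zL: np.ndarray,
    L: np.ndarray,
    gamma,
    m_gamma: np.ndarray,
    sigma_gamma: np.ndarray,
    prior: PriorSpec,
) -> float:
    """General normal-inverse-gamma log marginal likelihood.

    Supports an arbitrary prior mean ``m_gamma`` and scale matrix
    ``sigma_gamma`` on the included effects (e.g. a diagonal independence
    prior for sensitivity analyses).  With ``m_gamma = 0`` and ``sigma_gamma =
    tau (L_g'L_g)^{-1}`` this reproduces the g-prior fast path exactly.
    """
    zL = np.asarray(zL, dtype=float)
    P = zL.shape[0]
    idx = _as_index(gamma, P)
    base = float(zL @ zL)
    if idx.size == 0:
        s_gamma = base
        log_det_terms = 0.0
    else:
        m = np.zeros(idx.size) if m_gamma is None else np.asarray(m_gamma, dtype=float)
        S = np.atleast_2d(np.asarray(sigma_gamma, dtype=float))
        if m.shape[0] != idx.size or S.shape != (idx.size, idx.size):
            raise ValueError("m_gamma / sigma_gamma dimensions do not match gamma")
        Lg = L[:, idx]
        try:
            cS, lowS = linalg.cho_factor(S, lower=False)
        except linalg.LinAlgError as err:
            raise ValueError("sigma_gamma must be symmetric positive definite") from err
        Sinv = linalg.cho_solve((cS, lowS), np.eye(idx.size))
        K = Lg.T @ Lg + Sinv
        M = Lg.T @ zL + Sinv @ m
        cK, lowK = linalg.cho_factor(K, lower=False)
        C = base + float(m @ (Sinv @ m))
        s_gamma = C - float(M @ linalg.cho_solve((cK, lowK), M))
        log_det_K = 2.0 * np.sum(np.log(np.diag(cK)))
        log_det_S = 2.0 * np.sum(np.log(np.diag(cS)))
        log_det_terms = -0.5 * log_det_K - 0.5 * log_det_S
    if 2.0 * prior.b_sigma + s_gamma <= 0.0:
        raise FloatingPointError(f"S(gamma) = {s_gamma} non-positive: degenerate input")
    return log_det_terms - 0.5 * (2.0 * prior.a_sigma + P - 1.0) * np.log(
        2.0 * prior.b_sigma + s_gamma
    )


# ---------------------------------------------------------------------------
# enumeration


class _BlockScorer:
    """Caches A = L'L and v = L'zL for fast repeated model scoring in one block.

    Because zL solves L' zL = z, v equals the raw z segment; the fitted
    quadratic of any model is then a small positive-definite solve.
    """

    def __init__(self, wb: WhitenedBlock, prior: PriorSpec):
        if prior.tau is None:
            raise ValueError("tau unset; resolve it before scoring")
        self.snp_ids = wb.block.snp_ids
        self.P = wb.block.size
        self.A = wb.block.xtx  # == L'L
        self.v = wb.block.chol_upper.T @ wb.z_whitened
        self.base = float(wb.z_whitened @ wb.z_whitened)
        self.tau = prior.tau
        self.a_sigma = prior.a_sigma
        self.b_sigma = prior.b_sigma
        self.a_omega = prior.a_omega
        self.b_omega = prior.b_omega
        self._shrink = self.tau / (1.0 + self.tau)
        self._exponent = 0.5 * (2.0 * prior.a_sigma + self.P - 1.0)
        self._log_tau1 = np.log(self.tau + 1.0)
        self._prior_by_size = np.array(
            [log_model_prior(k, self.P, self.a_omega, self.b_omega) for k in range(self.P + 1)]
        )
        self._cache: dict[tuple[int, ...], float] = {}

    def log_ml(self, idx: tuple[int, ...]) -> float:
        got = self._cache.get(idx)
        if got is not None:
            return got
        fitted = _fitted_quadratic(self.A, self.v, np.asarray(idx, dtype=int), self.snp_ids)
        s_gamma = self.base - self._shrink * fitted
        val = -0.5 * len(idx) * self._log_tau1 - self._exponent * np.log(
            2.0 * self.b_sigma + s_gamma
        )
        self._cache[idx] = val
        return val

    def log_posterior_unnorm(self, idx: tuple[int, ...]) -> float:
        return self._prior_by_size[len(idx)] + self.log_ml(idx)


@dataclass
class PosteriorTable:
    """Normalized posterior over the enumerated (truncated) model space.

    Blocks are independent: joint model probabilities multiply, per-SNP
    inclusion probabilities and size distributions are computed per block and
    combined by convolution.
    """

    snp_ids: list[str]
    block_snp_ids: list[list[str]]
    block_models: list[list[ModelScore]]
    block_probs: list[np.ndarray]
    block_log_norm: list[float]
    prior: PriorSpec
    normalized: bool = True
    #: log of the estimated joint normalizing constant over the truncated space
    log_normalizing_constant: float = field(init=False)

    def __post_init__(self) -> None:
        self.log_normalizing_constant = float(sum(self.block_log_norm))

    # -- per-SNP summaries ---------------------------------------------------

    def snp_probabilities(self) -> pd.Series:
        if not self.normalized:
            raise ValueError("posterior table is not normalized")
        out = {}
        for ids, models, probs in zip(self.block_snp_ids, self.block_models, self.block_probs):
            pip = np.zeros(len(ids))
            for m, pr in zip(models, probs):
                for j in m.gamma:
                    pip[j] += pr
            for s, v in zip(ids, pip):
                out[s] = min(v, 1.0)
        return pd.Series([out[s] for s in self.snp_ids], index=self.snp_ids, name="posterior_prob")

    # -- size distributions ----------------------------------------------------

    def _block_size_dist(self, b: int, region: set[str] | None) -> np.ndarray:
        """Posterior distribution of the number of included region SNPs in block b."""
        ids = self.block_snp_ids[b]
        members = (
            np.ones(len(ids), dtype=bool)
            if region is None
            else np.array([s in region for s in ids])
        )
        dist = np.zeros(int(members.sum()) + 1)
        for m, pr in zip(self.block_models[b], self.block_probs[b]):
            k = int(sum(members[j] for j in m.gamma))
            dist[k] += pr
        return dist

    def _block_prior_size_dist(self, b: int, region: set[str] | None) -> np.ndarray:
        ids = self.block_snp_ids[b]
        r = len(ids) if region is None else sum(s in region for s in ids)
        return prior_region_size_dist(
            len(ids), r, self.prior.a_omega, self.prior.b_omega, self.prior.max_dim
        )

    def region_size_distribution(self, region: Sequence[str] | None = None):
        """Posterior and prior distributions of the signal count within a region.

        ``region`` is a set of SNP ids (default: every analysed SNP); blocks
        combine by convolution under independence.
        """
        reg = None if region is None else set(region)
        post = np.ones(1)
        pri = np.ones(1)
        for b in range(len(self.block_models)):
            post = np.convolve(post, self._block_size_dist(b, reg))
            pri = np.convolve(pri, self._block_prior_size_dist(b, reg))
        return post, pri

    def models_frame(self) -> pd.DataFrame:
        """All enumerated per-block models, ranked within the joint posterior.

        Probability of a block model is its marginal posterior probability
        (other blocks summed out).  Ties break by size then SNP ids.
        """
        rows = []
        for b, (models, probs) in enumerate(zip(self.block_models, self.block_probs)):
            for m, pr in zip(models, probs):
                rows.append(
                    {
                        "block": b,
                        "snps": ",".join(m.snp_ids) if m.snp_ids else ".",
                        "size": m.size,
                        "log_prior": m.log_prior,
                        "log_marginal_likelihood": m.log_marginal_likelihood,
                        "posterior_prob": pr,
                    }
                )
        df = pd.DataFrame(rows)
        df = df.sort_values(
            by=["posterior_prob", "size", "snps"], ascending=[False, True, True], kind="stable"
        ).reset_index(drop=True)
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        return df


def prior_region_size_dist(
    p: int, r: int, a_omega: float, b_omega: float, max_dim: int | None = None
) -> np.ndarray:
    """Prior distribution of the number of included SNPs among r region members.

    Model size k follows the (optionally dimension-truncated, renormalized)
    beta-binomial; given k, the included set is uniform over subsets, so the
    region count is hypergeometric.
    """
    kmax = p if max_dim is None else min(max_dim, p)
    log_size = np.array(
        [
            gammaln(p + 1) - gammaln(k + 1) - gammaln(p - k + 1)
            + log_model_prior(k, p, a_omega, b_omega)
            for k in range(kmax + 1)
        ]
    )
    size_probs = np.exp(log_size - logsumexp(log_size))
    dist = np.zeros(r + 1)
    for k, pk in enumerate(size_probs):
        j = np.arange(0, min(r, k) + 1)
        dist[j] += pk * hypergeom.pmf(j, p, r, k)
    return dist


def enumerate_models(
    blocks: Sequence[WhitenedBlock], prior: PriorSpec, n_study: float | None = None
) -> PosteriorTable:
    """Exhaustively score every model of dimension <= max_dim in each block.

    The same beta-binomial (a_omega, b_omega) applies independently within
    each block, so the expected total number of included SNPs is
    ``sum_b P_b * a_omega / (a_omega + b_omega)`` — the global prior mean
    proportion is preserved.  Scores normalize per block by log-sum-exp;
    cross-block quantities follow from independence.
    """
    if not blocks:
        raise ValueError("no blocks to analyse")
    total_p = sum(wb.block.size for wb in blocks)
    if n_study is None:
        n_study = blocks[0].block.n_study
    prior = prior.resolve_tau(total_p, n_study)

    block_models: list[list[ModelScore]] = []
    block_probs: list[np.ndarray] = []
    block_lognorm: list[float] = []
    for wb in blocks:
        P = wb.block.size
        if P < 1:
            raise ValueError("empty block")
        scorer = _BlockScorer(wb, prior)
        kmax = min(prior.max_dim, P)
        models = []
        scores = []
        for k in range(kmax + 1):
            lp = log_model_prior(k, P, prior.a_omega, prior.b_omega)
            for idx in combinations(range(P), k):
                ml = scorer.log_ml(idx)
                models.append(
                    ModelScore(
                        gamma=idx,
                        snp_ids=tuple(wb.block.snp_ids[j] for j in idx),
                        size=k,
                        log_prior=lp,
                        log_marginal_likelihood=ml,
                    )
                )
                scores.append(lp + ml)
        scores = np.array(scores)
        lognorm = float(logsumexp(scores))
        block_models.append(models)
        block_probs.append(np.exp(scores - lognorm))
        block_lognorm.append(lognorm)

    return PosteriorTable(
        snp_ids=[s for wb in blocks for s in wb.block.snp_ids],
        block_snp_ids=[list(wb.block.snp_ids) for wb in blocks],
        block_models=block_models,
        block_probs=block_probs,
        block_log_norm=block_lognorm,
        prior=prior,
    )


def snp_inclusion_probabilities(table: PosteriorTable) -> pd.Series:
    """Per-SNP posterior inclusion probability: total mass of models containing it."""
    return table.snp_probabilities()


def bayes_factor_min_signals(table, k: int, region: Sequence[str] | None = None) -> float:
    """Bayes factor for >= k causal SNPs within a region.

    ``BF = [P(>=k | data) / P(<k | data)] / [P(>=k) / P(<k)]`` from the signal
    count distribution within the region (default: all SNPs).  Returns
    ``inf`` when the posterior mass below k is numerically zero.  Accepts any
    object exposing ``region_size_distribution`` (enumeration table or RJMCMC
    summaries).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    post, pri = table.region_size_distribution(region)
    if region is not None and len(set(region)) == 0:
        raise ValueError("empty region")
    post_lt = float(post[:k].sum())
    post_ge = float(post[k:].sum()) if len(post) > k else 0.0
    pri_lt = float(pri[:k].sum())
    pri_ge = float(pri[k:].sum()) if len(pri) > k else 0.0
    if pri_ge == 0.0:
        raise ValueError(f"prior mass of >= {k} signals is zero in this region")
    if post_lt <= 0.0:
        return float("inf")
    return (post_ge / post_lt) / (pri_ge / pri_lt)
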