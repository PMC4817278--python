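"""Reversible-Jump MCMC over model indicators (add/delete/swap moves).

For analyses where exhaustive enumeration is infeasible, or where no cap on
the number of causal SNPs is wanted, the model indicator gamma is sampled by
Metropolis-Hastings using the same unnormalized log posterior as the
enumeration engine (beta-binomial prior x g-prior marginal likelihood, blocks
independent).  One proposal is made per iteration: a move type is drawn
uniformly among the feasible ones of {add, delete, swap}, the SNP choices are
uniform, and swap exchanges an included for an excluded SNP within one block
(a dimension-preserving move with symmetric proposal probability).  The
asymmetric add/delete counts enter the acceptance ratio explicitly.

The chain starts from the empty model (matching the sparse prior); the first
half of the iterations is discarded as burn-in by default, and retained
indicator rows are thinned to a bounded matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import PriorSpec, _BlockScorer, prior_region_size_dist
from .ld import WhitenedBlock

__all__ = [
    "SamplerConfig",
    "IndicatorSamples",
    "propose_move",
    "run_sampler",
    "convergence_report",
]

_ADD, _DELETE, _SWAP = 0, 1, 2


@dataclass(frozen=True)
class SamplerConfig:
    """Run-length and reproducibility settings for the stochastic model search."""

    n_iterations: int = 2_000_000
    burn_in_fraction: float = 0.5
    seed: int = 0
    thinning: int | None = None  # None: auto, keep <= max_retained rows
    max_retained: int = 100_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.burn_in_fraction < 1.0):
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    def resolve_thinning(self) -> int:
        if self.thinning is not None:
            return max(1, self.thinning)
        kept = self.n_iterations - int(self.n_iterations * self.burn_in_fraction)
        return max(1, int(np.ceil(kept / self.max_retained)))


@dataclass
class IndicatorSamples:
    """Retained post-burn-in inclusion indicators and sampler diagnostics."""

    snp_ids: list[str]
    block_snp_ids: list[list[str]]
    indicators: np.ndarray  # retained-iteration x SNP, uint8
    prior: PriorSpec
    acceptance: dict[str, tuple[int, int]]  # move -> (accepted, proposed)
    config: SamplerConfig

    def snp_probabilities(self) -> pd.Series:
        pip = self.indicators.mean(axis=0) if len(self.indicators) else np.zeros(len(self.snp_ids))
        return pd.Series(pip, index=self.snp_ids, name="posterior_prob")

    def region_size_distribution(self, region: Sequence[str] | None = None):
        """Empirical posterior and exact prior distributions of the region signal count.

        The sampler explores the untruncated model space, so the prior size
        distribution is the full (untruncated) beta-binomial, combined across
        blocks by convolution.
        """
        reg = None if region is None else set(region)
        members = np.array([reg is None or s in reg for s in self.snp_ids])
        counts = self.indicators[:, members].sum(axis=1)
        post = np.bincount(counts, minlength=int(members.sum()) + 1) / max(len(counts), 1)
        pri = np.ones(1)
        for ids in self.block_snp_ids:
            r = len(ids) if reg is None else sum(s in reg for s in ids)
            pri = np.convolve(
                pri, prior_region_size_dist(len(ids), r, self.prior.a_omega, self.prior.b_omega)
            )
        return post, pri


def _feasible_moves(p_in: int, P: int, any_swappable: bool) -> list[int]:
    moves = []
    if p_in < P:
        moves.append(_ADD)
    if p_in > 0:
        moves.append(_DELETE)
    if any_swappable:
        moves.append(_SWAP)
    return moves


def propose_move(
    gamma: np.ndarray,
    block_bounds: Sequence[tuple[int, int]],
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Draw one add/delete/swap proposal from the current indicator.

    Returns the proposed indicator and the log proposal ratio
    ``log q(gamma'->gamma) - log q(gamma->gamma')``.  Move types are uniform
    over the feasible set (boundary moves are never drawn); SNP choices are
    uniform; swap operates within a single block and has log ratio 0.
    """
    gamma = np.asarray(gamma, dtype=np.uint8)
    P = gamma.size
    incl = np.flatnonzero(gamma)
    excl = np.flatnonzero(gamma == 0)
    p_in = incl.size

    block_of = np.empty(P, dtype=int)
    n_in_block = []
    for b, (lo, hi) in enumerate(block_bounds):
        block_of[lo:hi] = b
        n_in_block.append(int(gamma[lo:hi].sum()))
    sizes = [hi - lo for lo, hi in block_bounds]
    swappable_blocks = {b for b in range(len(sizes)) if 0 < n_in_block[b] < sizes[b]}

    moves = _feasible_moves(p_in, P, bool(swappable_blocks))
    n_feas = len(moves)
    move = moves[rng.integers(len(moves))]
    new = gamma.copy()

    if move == _ADD:
        j = excl[rng.integers(excl.size)]
        new[j] = 1
        n_feas_new = len(_feasible_moves(p_in + 1, P, _has_swappable(new, block_bounds)))
        log_ratio = (np.log(n_feas) - np.log(n_feas_new)
                     + np.log(P - p_in) - np.log(p_in + 1))
    elif move == _DELETE:
        j = incl[rng.integers(incl.size)]
        new[j] = 0
        n_feas_new = len(_feasible_moves(p_in - 1, P, _has_swappable(new, block_bounds)))
        log_ratio = (np.log(n_feas) - np.log(n_feas_new)
                     + np.log(p_in) - np.log(P - p_in + 1))
    else:  # swap: per-block counts invariant, proposal symmetric
        cand = incl[np.isin(block_of[incl], list(swappable_blocks))]
        i = cand[rng.integers(cand.size)]
        b = block_of[i]
        lo, hi = block_bounds[b]
        excl_b = np.flatnonzero(gamma[lo:hi] == 0) + lo
        j = excl_b[rng.integers(excl_b.size)]
        new[i], new[j] = 0, 1
        log_ratio = 0.0
    return new, float(log_ratio)


def _has_swappable(gamma: np.ndarray, block_bounds) -> bool:
    return any(0 < gamma[lo:hi].sum() < hi - lo for lo, hi in block_bounds)


def run_sampler(
    blocks: Sequence[WhitenedBlock],
    prior: PriorSpec,
    config: SamplerConfig,
) -> IndicatorSamples:
    """Sample model indicators by Metropolis-Hastings; deterministic under seed.

    Per-SNP posterior probabilities are the column means of the retained
    indicator matrix.  Per-block log scores are cached, so on modest blocks
    most iterations reduce to dictionary lookups.
    """
    total_p = sum(wb.block.size for wb in blocks)
    prior = prior.resolve_tau(total_p, blocks[0].block.n_study)
    scorers = [_BlockScorer(wb, prior) for wb in blocks]
    bounds = []
    lo = 0
    for wb in blocks:
        bounds.append((lo, lo + wb.block.size))
        lo += wb.block.size
    sizes = np.array([hi - lo for lo, hi in bounds])
    block_of = np.concatenate([np.full(n, b) for b, n in enumerate(sizes)])

    rng = np.random.default_rng(config.seed)

    # state: global included set, per-block sorted-tuple keys and scores
    incl: set[int] = set()
    n_in_block = np.zeros(len(blocks), dtype=int)
    block_keys: list[tuple[int, ...]] = [() for _ in blocks]
    block_scores = np.array([s.log_posterior_unnorm(()) for s in scorers])
    if not np.all(np.isfinite(block_scores)):
        raise FloatingPointError("non-finite log posterior at initialization")

    n_iter = config.n_iterations
    burn = int(n_iter * config.burn_in_fraction)
    thin = config.resolve_thinning()
    retained = []
    accepted = {"add": 0, "delete": 0, "swap": 0}
    proposed = {"add": 0, "delete": 0, "swap": 0}
    names = {_ADD: "add", _DELETE: "delete", _SWAP: "swap"}

    # buffered uniforms: cheaper than one RNG call per draw
    BUF = 1 << 18
    buf = rng.random(BUF)
    ptr = 0

    def u() -> float:
        nonlocal buf, ptr
        if ptr == BUF:
            buf = rng.random(BUF)
            ptr = 0
        v = buf[ptr]
        ptr += 1
        return v

    incl_list: list[int] = []  # mirrors incl for O(1) uniform sampling
    pos_in_list: dict[int, int] = {}

    def add_to_state(j: int) -> None:
        pos_in_list[j] = len(incl_list)
        incl_list.append(j)
        incl.add(j)
        n_in_block[block_of[j]] += 1

    def del_from_state(j: int) -> None:
        k = pos_in_list.pop(j)
        last = incl_list.pop()
        if last != j:
            incl_list[k] = last
            pos_in_list[last] = k
        incl.remove(j)
        n_in_block[block_of[j]] -= 1

    def block_key(b: int, extra: int | None = None, minus: int | None = None):
        lo, hi = bounds[b]
        mem = [x for x in incl_list if lo <= x < hi and x != minus]
        if extra is not None:
            mem.append(extra)
        return tuple(sorted(x - lo for x in mem))

    P = int(total_p)
    log = np.log
    for it in range(n_iter):
        p_in = len(incl_list)
        swappable = np.flatnonzero((n_in_block > 0) & (n_in_block < sizes))
        moves = _feasible_moves(p_in, P, swappable.size > 0)
        move = moves[int(u() * len(moves))]
        name = names[move]
        proposed[name] += 1

        if move == _ADD:
            # uniform excluded SNP via rejection (inclusion is sparse)
            while True:
                j = int(u() * P)
                if j not in incl:
                    break
            b = block_of[j]
            key_new = block_key(b, extra=j)
            delta = scorers[b].log_posterior_unnorm(key_new) - block_scores[b]
            n_in_block[b] += 1
            feas_new = len(_feasible_moves(p_in + 1, P,
                                           bool(np.any((n_in_block > 0) & (n_in_block < sizes)))))
            n_in_block[b] -= 1
            log_ratio = log(len(moves)) - log(feas_new) + log(P - p_in) - log(p_in + 1)
            if delta + log_ratio >= 0 or u() < np.exp(delta + log_ratio):
                add_to_state(j)
                block_keys[b] = key_new
                block_scores[b] += delta
                accepted[name] += 1
        elif move == _DELETE:
            j = incl_list[int(u() * p_in)]
            b = block_of[j]
            key_new = block_key(b, minus=j)
            delta = scorers[b].log_posterior_unnorm(key_new) - block_scores[b]
            n_in_block[b] -= 1
            feas_new = len(_feasible_moves(p_in - 1, P,
                                           bool(np.any((n_in_block > 0) & (n_in_block < sizes)))))
            n_in_block[b] += 1
            log_ratio = log(len(moves)) - log(feas_new) + log(p_in) - log(P - p_in + 1)
            if delta + log_ratio >= 0 or u() < np.exp(delta + log_ratio):
                del_from_state(j)
                block_keys[b] = key_new
                block_scores[b] += delta
                accepted[name] += 1
        else:
            cand = [x for x in incl_list if block_of[x] in set(swappable)]
            i = cand[int(u() * len(cand))]
            b = block_of[i]
            lo, hi = bounds[b]
            excl_b = [x for x in range(lo, hi) if x not in incl]
            j = excl_b[int(u() * len(excl_b))]
            key_new = block_key(b, extra=j, minus=i)
            delta = scorers[b].log_posterior_unnorm(key_new) - block_scores[b]
            if delta >= 0 or u() < np.exp(delta):
                del_from_state(i)
                add_to_state(j)
                block_keys[b] = key_new
                block_scores[b] += delta
                accepted[name] += 1

        if it >= burn and (it - burn) % thin == 0:
            row = np.zeros(P, dtype=np.uint8)
            row[list(incl)] = 1
            retained.append(row)

    indicators = np.vstack(retained) if retained else np.zeros((0, P), dtype=np.uint8)
    return IndicatorSamples(
        snp_ids=[s for wb in blocks for s in wb.block.snp_ids],
        block_snp_ids=[list(wb.block.snp_ids) for wb in blocks],
        indicators=indicators,
        prior=prior,
        acceptance={m: (accepted[m], proposed[m]) for m in accepted},
        config=config,
    )


def _lag_autocorr(x: np.ndarray, lag: int) -> float:
    x = x.astype(float)
    if x.size <= lag or np.var(x) == 0:
        return float("nan")
    a, b = x[:-lag] - x.mean(), x[lag:] - x.mean()
    return float((a * b).mean() / np.var(x))


def convergence_report(
    samples: IndicatorSamples,
    others: Sequence[IndicatorSamples] = (),
    lags: Sequence[int] = (1, 10, 50),
) -> dict:
    """Mixing diagnostics for the indicator chain.

    Reports per-SNP occupancy, lag-k autocorrelations of the inclusion
    indicators (NaN flags constant columns), per-move acceptance rates, and —
    when replicate chains from other seeds are supplied — the maximum absolute
    per-SNP probability difference across chains.
    """
    if len(samples.indicators) < 2:
        raise ValueError("need at least 2 retained iterations")
    occ = samples.snp_probabilities()
    autocorr = pd.DataFrame(
        {
            f"lag{lag}": [_lag_autocorr(samples.indicators[:, j], lag)
                          for j in range(samples.indicators.shape[1])]
            for lag in lags
        },
        index=samples.snp_ids,
    )
    rates = {
        m: (acc / prop if prop else float("nan"))
        for m, (acc, prop) in samples.acceptance.items()
    }
    report = {
        "occupancy": occ,
        "autocorrelation": autocorr,
        "constant_snps": [s for s, flag in zip(samples.snp_ids, occ.isin([0.0, 1.0])) if flag],
        "acceptance_rates": rates,
        "n_retained": len(samples.indicators),
    }
    if others:
        diffs = [
            float((samples.snp_probabilities() - o.snp_probabilities()).abs().max())
            for o in others
        ]
        report["max_cross_chain_diff"] = max(diffs)
    return report
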