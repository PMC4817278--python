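"""Reconstruction of the sufficient statistic z = X'y from marginal GWAS summaries.

A GWAS typically reports, for each SNP m, only the one-at-a-time (marginal)
regression slope ``beta_hat_m`` of the trait on allele count, together with the
allele frequency ``p_m`` and the study size N.  For a mean-centred trait under
Hardy-Weinberg equilibrium these are enough to rebuild the m-th entry of the
multivariate sufficient statistic z = X'y: the expected genotype-group counts
are (N(1-p)^2, 2Np(1-p), Np^2), the centred group trait means are pinned down
by the marginal slope (additive model) and the zero-mean constraint, and

    z_m = ybar_m1 * n_m1 + 2 * ybar_m2 * n_m2 .

Counts are kept real-valued: only the products n_g * ybar_g enter z, so integer
rounding would inject avoidable error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarginalSummary",
    "GenotypeGroupStats",
    "StrandAmbiguousError",
    "AlleleMismatchError",
    "hwe_genotype_counts",
    "reconstruct_group_means",
    "reconstruct_z",
    "harmonize_alleles",
    "is_strand_ambiguous",
    "read_summary_stats",
    "write_summary_stats",
]

#: allele pairs that are their own reverse complement (strand cannot be resolved)
_PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class StrandAmbiguousError(ValueError):
    """Raised for A/T or C/G SNPs whose strand cannot be resolved from alleles."""


class AlleleMismatchError(ValueError):
    """Raised when reported alleles are incompatible with the reference pair."""


@dataclass(frozen=True)
class MarginalSummary:
    """Per-SNP marginal association summary for a continuous trait.

    Parameters
    ----------
    snp_id : str
        Variant identifier.
    effect_allele : str
        Allele whose count the reported effect refers to.
    other_allele : str
        The non-effect allele.
    maf : float
        Frequency of the effect allele in (0, 1).
    beta_hat : float
        Marginal per-allele effect estimate (trait units per allele).
    se : float or None
        Standard error of ``beta_hat``; optional, unused by the core model.
    n : float
        Study sample size.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    maf: float
    beta_hat: float
    n: float
    se: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.maf < 1.0):
            raise ValueError(
                f"{self.snp_id}: effect-allele frequency must be in (0,1), got {self.maf}"
            )
        if self.n < 2:
            raise ValueError(f"{self.snp_id}: sample size must be >= 2, got {self.n}")
        if not np.isfinite(self.beta_hat):
            raise ValueError(f"{self.snp_id}: beta_hat is not finite")


@dataclass(frozen=True)
class GenotypeGroupStats:
    """Reconstructed genotype-group counts, centred trait means, and z entry."""

    counts: tuple[float, float, float]
    means: tuple[float, float, float]
    z: float


def hwe_genotype_counts(maf: float, n: float) -> tuple[float, float, float]:
    """Expected genotype counts (n0, n1, n2) under Hardy-Weinberg equilibrium.

    Returns real-valued counts ``(n(1-p)^2, 2np(1-p), np^2)``; no rounding is
    applied.  ``maf`` is the frequency of the counted (effect) allele.
    """
    if not (0.0 <= maf <= 1.0):
        raise ValueError(f"allele frequency must lie in [0,1], got {maf}")
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    q = 1.0 - maf
    return (n * q * q, 2.0 * n * maf * q, n * maf * maf)


def reconstruct_group_means(
    beta_hat: float, counts: Sequence[float]
) -> tuple[float, float, float]:
    """Centred per-genotype trait means implied by an additive marginal fit.

    Solves the linear system {ybar1 - ybar0 = beta, ybar2 - ybar0 = 2 beta,
    sum_g n_g ybar_g = 0}, whose unique solution is
    ``ybar0 = -beta (n1 + 2 n2) / N``.
    """
    n0, n1, n2 = counts
    total = n0 + n1 + n2
    if total <= 0:
        raise ValueError("genotype counts sum to zero")
    y0 = -beta_hat * (n1 + 2.0 * n2) / total
    return (y0, y0 + beta_hat, y0 + 2.0 * beta_hat)


def _group_stats(summary: MarginalSummary) -> GenotypeGroupStats:
    counts = hwe_genotype_counts(summary.maf, summary.n)
    means = reconstruct_group_means(summary.beta_hat, counts)
    z = means[1] * counts[1] + 2.0 * means[2] * counts[2]
    return GenotypeGroupStats(counts=counts, means=means, z=z)


def reconstruct_z(summaries: Sequence[MarginalSummary]) -> np.ndarray:
    """Rebuild the vector z = X'y, one entry per SNP.

    All SNPs must share the same study size N (a single-cohort analysis).  The
    result is identical whether genotypes are coded raw 0/1/2 or mean-centred,
    because the trait means are centred.
    """
    if len(summaries) == 0:
        return np.empty(0)
    ns = {float(s.n) for s in summaries}
    if len(ns) != 1:
        raise ValueError(f"inconsistent study sample sizes across SNPs: {sorted(ns)}")
    return np.array([_group_stats(s).z for s in summaries])


def is_strand_ambiguous(allele_a: str, allele_b: str) -> bool:
    """True for palindromic (A/T, C/G) SNPs, which cannot be strand-resolved."""
    return frozenset({allele_a.upper(), allele_b.upper()}) in _PALINDROMIC


def harmonize_alleles(
    summary: MarginalSummary,
    ref_alleles: tuple[str, str],
    allow_ambiguous: bool = False,
) -> MarginalSummary:
    """Orient a summary record onto the reference panel's counted allele.

    ``ref_alleles`` is (counted allele, other allele) in the reference coding.
    If the summary's effect allele already matches the counted allele the
    record is returned unchanged; if the alleles are swapped the effect sign is
    flipped and the frequency replaced by its complement.  Strand flips
    (complementary alleles) are resolved the same way.  Palindromic A/T and C/G
    SNPs raise :class:`StrandAmbiguousError` unless ``allow_ambiguous`` (the
    orientation is then taken at face value).
    """
    ea = summary.effect_allele.upper()
    oa = summary.other_allele.upper()
    if not ea or not oa:
        raise AlleleMismatchError(f"{summary.snp_id}: empty allele label")
    ref_c, ref_o = (a.upper() for a in ref_alleles)

    if is_strand_ambiguous(ea, oa) and not allow_ambiguous:
        raise StrandAmbiguousError(
            f"{summary.snp_id}: palindromic alleles {ea}/{oa} are strand-ambiguous"
        )

    if (ea, oa) == (ref_c, ref_o):
        return summary
    if (ea, oa) == (ref_o, ref_c):
        return replace(summary, effect_allele=ref_c, other_allele=ref_o,
                       beta_hat=-summary.beta_hat, maf=1.0 - summary.maf)
    # try the complementary strand
    cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
    if (cea, coa) == (ref_c, ref_o):
        return replace(summary, effect_allele=ref_c, other_allele=ref_o)
    if (cea, coa) == (ref_o, ref_c):
        return replace(summary, effect_allele=ref_c, other_allele=ref_o,
                       beta_hat=-summary.beta_hat, maf=1.0 - summary.maf)
    raise AlleleMismatchError(
        f"{summary.snp_id}: alleles {ea}/{oa} incompatible with reference {ref_c}/{ref_o}"
    )


def read_summary_stats(path) -> list[MarginalSummary]:
    """Read a tab-separated summary-statistics file.

    Expected header columns: SNP, EA, NEA, MAF, BETA, N and optionally SE.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"SNP", "EA", "NEA", "MAF", "BETA", "N"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary file missing columns: {sorted(missing)}")
    has_se = "SE" in df.columns
    out = []
    for row in df.itertuples(index=False):
        out.append(
            MarginalSummary(
                snp_id=str(row.SNP),
                effect_allele=str(row.EA),
                other_allele=str(row.NEA),
                maf=float(row.MAF),
                beta_hat=float(row.BETA),
                n=float(row.N),
                se=float(row.SE) if has_se and np.isfinite(row.SE) else None,
            )
        )
    return out


def write_summary_stats(summaries: Sequence[MarginalSummary], path) -> None:
    """Write summaries in the tab-separated format read_summary_stats accepts."""
    df = pd.DataFrame(
        {
            "SNP": [s.snp_id for s in summaries],
            "EA": [s.effect_allele for s in summaries],
            "NEA": [s.other_allele for s in summaries],
            "MAF": [s.maf for s in summaries],
            "BETA": [s.beta_hat for s in summaries],
            "SE": [s.se if s.se is not None else np.nan for s in summaries],
            "N": [s.n for s in summaries],
        }
    )
    df.to_csv(path, sep="\t", index=False)
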