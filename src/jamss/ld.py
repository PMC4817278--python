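"""Reference-panel LD: plug-in X'X, block partitioning, Cholesky whitening.

The study genotype matrix X is unobserved; its cross-product is estimated from
an external reference panel of the same population, scaled to the study size:

    X'X  ~=  (N_study / N_ref) * Xref' Xref          (columns mean-centred)

Within each approximately independent block the cross-product is factored as
X'X = L'L with L upper triangular, and the summary vector z is whitened by
solving L' zL = z, turning the multivariate-normal summary likelihood into a
product of independent Gaussians with design matrix L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "LDBlock",
    "WhitenedBlock",
    "NotPositiveDefiniteError",
    "center_genotype_matrix",
    "estimate_xtx",
    "prune_snps",
    "partition_blocks",
    "cholesky_factor",
    "whiten_z",
    "build_blocks",
    "read_reference_matrix",
    "read_reference_vcf",
    "read_block_bed",
]


class NotPositiveDefiniteError(linalg.LinAlgError):
    """Cross-product matrix is not positive definite (collinear SNPs).

    The remedy is stricter LD pruning (lower r2_max), not numerical repair.
    """


@dataclass
class LDBlock:
    """One approximately independent LD block of the analysis.

    Attributes
    ----------
    snp_ids : list of str
        Member SNPs, in genomic order.
    xtx : ndarray
        Study-scaled cross-product estimate, symmetric positive definite.
    chol_upper : ndarray
        Upper-triangular L with ``L.T @ L == xtx``.
    n_ref, n_study : float
        Reference-panel and study sample sizes.
    """

    snp_ids: list[str]
    xtx: np.ndarray
    chol_upper: np.ndarray
    n_ref: float
    n_study: float

    @property
    def size(self) -> int:
        return len(self.snp_ids)


@dataclass
class WhitenedBlock:
    """An LD block paired with its raw and whitened summary statistics."""

    block: LDBlock
    z: np.ndarray
    z_whitened: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.z_whitened = whiten_z(self.block.chol_upper, self.z)


def center_genotype_matrix(genotypes: np.ndarray, snp_ids=None) -> np.ndarray:
    """Mean-centre an (n_ref x P) additive-dosage matrix, column-wise.

    Missing entries (NaN) are mean-imputed per SNP before centring, so imputed
    cells become exactly zero.  A column with no observed genotypes is an
    error.  Zero-variance (monomorphic) columns are allowed here; they are
    expected to be removed by MAF pruning before factorisation.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotype matrix must be 2-dimensional")
    out = G.copy()
    mask = np.isnan(out)
    if mask.any():
        n_obs = (~mask).sum(axis=0)
        bad = np.nonzero(n_obs == 0)[0]
        if bad.size:
            names = [snp_ids[j] if snp_ids is not None else str(j) for j in bad]
            raise ValueError(f"all genotypes missing for SNP(s): {names}")
        col_means = np.nanmean(out, axis=0)
        out[mask] = np.take(col_means, np.nonzero(mask)[1])
    out -= out.mean(axis=0)
    return out


def estimate_xtx(centred_ref: np.ndarray, n_study: float) -> np.ndarray:
    """Study-scaled plug-in cross-product (n_study / n_ref) * Xref'Xref."""
    X = np.asarray(centred_ref, dtype=float)
    n_ref = X.shape[0]
    if n_ref < 2:
        raise ValueError("reference panel needs at least 2 individuals")
    if n_study < 1:
        raise ValueError(f"study size must be >= 1, got {n_study}")
    xtx = (n_study / n_ref) * (X.T @ X)
    return 0.5 * (xtx + xtx.T)  # enforce exact symmetry


def _correlation(centred_ref: np.ndarray) -> np.ndarray:
    sd = centred_ref.std(axis=0)
    sd = np.where(sd > 0, sd, np.inf)  # zero-variance columns correlate with nothing
    R = (centred_ref / sd).T @ (centred_ref / sd) / centred_ref.shape[0]
    return np.clip(R, -1.0, 1.0)


def prune_snps(
    centred_ref: np.ndarray,
    mafs: np.ndarray,
    r2_max: float = 0.95,
    maf_min: float = 0.05,
) -> list[int]:
    """Greedy left-to-right LD and frequency pruning.

    Drops SNPs with minor-allele frequency below ``maf_min``, then scans left
    to right dropping any SNP whose squared correlation with an
    already-retained SNP exceeds ``r2_max``.  Returns retained column indices
    in their original order.
    """
    for name, t in (("r2_max", r2_max), ("maf_min", maf_min)):
        if not (0.0 < t <= 1.0):
            raise ValueError(f"{name} must lie in (0,1], got {t}")
    mafs = np.asarray(mafs, dtype=float)
    minor = np.minimum(mafs, 1.0 - mafs)
    candidates = [j for j in range(centred_ref.shape[1]) if minor[j] >= maf_min]
    R2 = _correlation(centred_ref) ** 2
    retained: list[int] = []
    for j in candidates:
        if all(R2[j, k] <= r2_max for k in retained):
            retained.append(j)
    if not retained:
        import warnings

        warnings.warn("no SNPs retained after pruning", stacklevel=2)
    return retained


def partition_blocks(
    centred_ref: np.ndarray, r2_between_max: float = 0.01
) -> list[tuple[int, int]]:
    """Split position-ordered SNPs into contiguous low-LD blocks.

    A boundary is placed after SNP j when no SNP at or before j has squared
    correlation above ``r2_between_max`` with any SNP after j.  Each block's
    cross-product must admit a Cholesky factorisation; if not, the user is
    pointed to stricter pruning.  Returns half-open (start, stop) index pairs.
    """
    P = centred_ref.shape[1]
    if P == 0:
        return []
    R2 = _correlation(centred_ref) ** 2
    boundaries = []
    start = 0
    for j in range(P - 1):
        if R2[start : j + 1, j + 1 :].max() <= r2_between_max:
            boundaries.append((start, j + 1))
            start = j + 1
    boundaries.append((start, P))
    # fail fast on rank-deficient blocks
    for lo, hi in boundaries:
        xtx = centred_ref[:, lo:hi].T @ centred_ref[:, lo:hi]
        try:
            cholesky_factor(xtx)
        except NotPositiveDefiniteError as err:
            raise NotPositiveDefiniteError(
                f"block [{lo},{hi}) is rank deficient; prune more aggressively "
                f"(lower r2_max) or supply explicit block definitions"
            ) from err
    return boundaries


def cholesky_factor(xtx: np.ndarray) -> np.ndarray:
    """Upper-triangular L with L'L = X'X and positive diagonal.

    Non-positive-definite input is a hard error — the model requires a full
    rank reference cross-product, obtained in practice by LD pruning.
    """
    A = np.asarray(xtx, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("xtx must be square")
    if not np.allclose(A, A.T, rtol=1e-8, atol=1e-10):
        raise ValueError("xtx must be symmetric")
    try:
        return linalg.cholesky(A, lower=False)
    except linalg.LinAlgError as err:
        raise NotPositiveDefiniteError(
            "X'X is not positive definite; prune correlated SNPs (lower r2_max) "
            "or enlarge the reference panel"
        ) from err


def whiten_z(L: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Solve the triangular system L' zL = z (no explicit inverse)."""
    L = np.asarray(L, dtype=float)
    z = np.asarray(z, dtype=float)
    if L.shape[0] != L.shape[1] or L.shape[0] != z.shape[0]:
        raise ValueError("dimension mismatch between L and z")
    if np.any(np.diag(L) == 0):
        raise NotPositiveDefiniteError("singular Cholesky factor (zero diagonal)")
    zL = linalg.solve_triangular(L, z, trans="T", lower=False)
    if not np.all(np.isfinite(zL)):
        raise FloatingPointError("whitened statistics are not finite")
    return zL


def build_blocks(
    centred_ref: np.ndarray,
    z: np.ndarray,
    snp_ids: list[str],
    n_study: float,
    boundaries: list[tuple[int, int]] | None = None,
    r2_between_max: float = 0.01,
) -> list[WhitenedBlock]:
    """Assemble whitened LD blocks from a centred reference and z vector.

    ``boundaries`` (half-open index pairs) override the automatic contiguous
    r²-threshold partition.
    """
    n_ref = centred_ref.shape[0]
    if boundaries is None:
        boundaries = partition_blocks(centred_ref, r2_between_max)
    blocks = []
    for lo, hi in boundaries:
        if hi - lo > n_ref:
            raise ValueError(
                f"block [{lo},{hi}) larger than the reference sample ({n_ref}); "
                "no full-rank cross-product exists"
            )
        xtx = estimate_xtx(centred_ref[:, lo:hi], n_study)
        L = cholesky_factor(xtx)
        blk = LDBlock(
            snp_ids=list(snp_ids[lo:hi]),
            xtx=xtx,
            chol_upper=L,
            n_ref=n_ref,
            n_study=n_study,
        )
        blocks.append(WhitenedBlock(block=blk, z=np.asarray(z[lo:hi], dtype=float)))
    return blocks


# ---------------------------------------------------------------------------
# readers


def read_reference_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a headered numeric dosage matrix (TSV: columns = SNPs, rows = individuals).

    Also accepts PLINK-style additive text exports (e.g. ``--recode A``): any
    leading non-numeric columns (FID, IID, ...) are dropped and ``_<allele>``
    suffixes on SNP column names are stripped.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    numeric = df.select_dtypes(include=[np.number])
    if numeric.shape[1] == 0:
        raise ValueError(f"no numeric dosage columns found in {path}")
    drop = {"FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"}
    keep = [c for c in numeric.columns if c.upper() not in drop]
    ids = [c.rsplit("_", 1)[0] if c.rsplit("_", 1)[-1] in "ACGT" else c for c in keep]
    return numeric[keep].to_numpy(dtype=float), ids


def read_reference_vcf(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read additive dosages from a VCF (GT field; missing calls become NaN).

    Returns (n x P dosage matrix, metadata frame with SNP, CHROM, POS, REF, ALT).
    Multi-allelic records are skipped.
    """
    from cyvcf2 import VCF

    rows, meta = [], []
    for var in VCF(str(path)):
        if len(var.ALT) != 1:
            continue
        gts = np.array(var.gt_types, dtype=float)  # 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
        dos = np.where(gts == 3, 2.0, gts)
        dos[gts == 2] = np.nan
        rows.append(dos)
        meta.append(
            {
                "SNP": var.ID or f"{var.CHROM}:{var.POS}",
                "CHROM": var.CHROM,
                "POS": var.POS,
                "REF": var.REF,
                "ALT": var.ALT[0],
            }
        )
    if not rows:
        raise ValueError(f"no biallelic variants found in {path}")
    return np.vstack(rows).T, pd.DataFrame(meta)


def read_block_bed(path, positions: np.ndarray, chroms=None) -> list[tuple[int, int]]:
    """Map BED intervals (chrom, start, end; 0-based half-open) to SNP index blocks.

    ``positions`` are the panel's 0-based SNP coordinates in analysis order.
    SNPs not covered by any interval each form their own singleton block, so
    the returned boundaries always partition the SNP set.
    """
    bed = pd.read_csv(path, sep="\t", header=None, comment="#").iloc[:, :3]
    bed.columns = ["chrom", "start", "end"]
    positions = np.asarray(positions)
    assigned = np.full(positions.shape[0], -1)
    for i, row in bed.iterrows():
        on_chrom = (
            np.ones(len(positions), dtype=bool)
            if chroms is None
            else np.asarray(chroms) == row.chrom
        )
        hit = on_chrom & (positions >= row.start) & (positions < row.end)
        assigned[hit & (assigned < 0)] = i
    boundaries = []
    j = 0
    while j < len(positions):
        k = j + 1
        while k < len(positions) and assigned[k] == assigned[j] and assigned[j] >= 0:
            k += 1
        boundaries.append((j, k))
        j = k
    return boundaries
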