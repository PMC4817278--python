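"""Reference-panel cross-products, pruning, block partitioning and whitening."""

import numpy as np
import pytest
from scipy import linalg

from jamss.ld import (
    NotPositiveDefiniteError,
    build_blocks,
    center_genotype_matrix,
    cholesky_factor,
    estimate_xtx,
    partition_blocks,
    prune_snps,
    read_block_bed,
    read_reference_matrix,
    whiten_z,
)


class TestCentering:
    def test_simple_column(self):
        out = center_genotype_matrix(np.array([[0.0], [1.0], [2.0]]))
        assert np.allclose(out.ravel(), [-1, 0, 1])

    def test_constant_column_becomes_zero(self):
        out = center_genotype_matrix(np.full((3, 1), 2.0))
        assert np.allclose(out, 0.0)

    def test_missing_entries_mean_imputed_then_centred(self):
        out = center_genotype_matrix(np.array([[0.0], [2.0], [np.nan]]))
        assert np.allclose(sorted(out.ravel()), [-1, 0, 1])
        assert out[2, 0] == pytest.approx(0.0)  # imputed cell sits at the mean

    def test_all_missing_column_names_snp(self):
        with pytest.raises(ValueError, match="rs7"):
            center_genotype_matrix(np.full((3, 1), np.nan), snp_ids=["rs7"])


class TestEstimateXtx:
    def test_scale_factor_one_when_sizes_match(self, rng):
        X = center_genotype_matrix(rng.integers(0, 3, size=(50, 4)).astype(float))
        assert np.allclose(estimate_xtx(X, 50), X.T @ X)

    def test_scalar_case_doubles(self, rng):
        c = rng.normal(size=(30, 1))
        c -= c.mean()
        assert estimate_xtx(c, 60)[0, 0] == pytest.approx(2.0 * float(c.ravel() @ c.ravel()))

    def test_linear_in_study_size(self, rng):
        X = center_genotype_matrix(rng.integers(0, 3, size=(40, 3)).astype(float))
        assert np.allclose(3.0 * estimate_xtx(X, 1000), estimate_xtx(X, 3000))


class TestPrune:
    def test_duplicate_column_dropped(self, rng):
        c = rng.normal(size=100)
        X = np.column_stack([c, c])
        assert prune_snps(X - X.mean(0), np.array([0.3, 0.3])) == [0]

    def test_independent_columns_all_retained(self, rng):
        X = rng.normal(size=(200, 5))
        kept = prune_snps(X - X.mean(0), np.full(5, 0.3))
        assert kept == [0, 1, 2, 3, 4]

    def test_correlated_pair_collapses_third_kept(self, rng):
        a = rng.normal(size=500)
        b = a + 0.1 * rng.normal(size=500)  # r2 > 0.95 with a
        c = rng.normal(size=500)
        X = np.column_stack([a, b, c])
        X -= X.mean(0)
        r_ab = np.corrcoef(a, b)[0, 1] ** 2
        assert r_ab > 0.95
        assert prune_snps(X, np.full(3, 0.3)) == [0, 2]

    def test_low_maf_dropped_with_reason(self, rng):
        X = rng.normal(size=(100, 2))
        kept = prune_snps(X - X.mean(0), np.array([0.03, 0.3]), maf_min=0.05)
        assert kept == [1]

    def test_retained_set_never_violates_threshold(self, rng):
        for _ in range(5):
            base = rng.normal(size=(300, 4))
            mix = rng.uniform(-1, 1, size=(4, 8))
            X = base @ mix + 0.3 * rng.normal(size=(300, 8))
            X -= X.mean(0)
            kept = prune_snps(X, np.full(8, 0.3), r2_max=0.6)
            R2 = np.corrcoef(X[:, kept].T) ** 2
            off = R2[~np.eye(len(kept), dtype=bool)]
            assert np.all(off <= 0.6 + 1e-12)


class TestPartition:
    def test_two_separated_groups(self, rng):
        a = rng.normal(size=(400, 1)) + 0.1 * rng.normal(size=(400, 3))
        b = rng.normal(size=(400, 1)) + 0.1 * rng.normal(size=(400, 3))
        X = np.hstack([a, b])
        X -= X.mean(0)
        bounds = partition_blocks(X, r2_between_max=0.05)
        assert bounds == [(0, 3), (3, 6)]

    def test_independent_snps_one_block_each(self, rng):
        X = rng.normal(size=(500, 4))
        X -= X.mean(0)
        assert partition_blocks(X, r2_between_max=0.01) == [(0, 1), (1, 2), (2, 3), (3, 4)]

    def test_ar_correlation_splits_where_lagged_r2_decays(self, rng):
        n, P, rho = 2000, 12, 0.9
        latent = rng.normal(size=(n, 1))
        cols = [latent.ravel()]
        for _ in range(P - 1):
            cols.append(rho * cols[-1] + np.sqrt(1 - rho**2) * rng.normal(size=n))
        X = np.column_stack(cols)
        X -= X.mean(0)
        bounds = partition_blocks(X, r2_between_max=0.05)
        R2 = np.corrcoef(X.T) ** 2
        for (lo1, hi1), (lo2, hi2) in zip(bounds, bounds[1:]):
            assert R2[lo1:hi1, lo2:hi2].max() <= 0.05


class TestCholeskyWhiten:
    def test_identity(self):
        assert np.allclose(cholesky_factor(np.eye(3)), np.eye(3))
        assert np.allclose(whiten_z(np.eye(3), np.arange(3.0)), np.arange(3.0))

    def test_hand_worked_factor(self):
        L = cholesky_factor(np.array([[4.0, 2.0], [2.0, 5.0]]))
        assert np.allclose(L, [[2, 1], [0, 2]])

    def test_round_trip_random_spd(self, rng):
        A = rng.normal(size=(6, 6))
        spd = A @ A.T + 6 * np.eye(6)
        L = cholesky_factor(spd)
        assert np.allclose(L.T @ L, spd, rtol=1e-10)
        assert np.all(np.diag(L) > 0)
        assert np.allclose(L, np.triu(L))

    def test_not_positive_definite_is_hard_error(self):
        rank1 = np.outer([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(NotPositiveDefiniteError, match="prune"):
            cholesky_factor(rank1)

    def test_whiten_forward_substitution_example(self):
        L = np.array([[2.0, 1.0], [0.0, 2.0]])
        assert np.allclose(whiten_z(L, np.array([2.0, 3.0])), [1.0, 1.0])

    def test_whitened_norm_equals_quadratic_form(self, rng):
        A = rng.normal(size=(5, 5))
        spd = A @ A.T + 5 * np.eye(5)
        z = rng.normal(size=5)
        zL = whiten_z(cholesky_factor(spd), z)
        assert float(zL @ zL) == pytest.approx(float(z @ linalg.solve(spd, z)), rel=1e-8)


def test_blockwise_whitening_matches_full_for_block_diagonal(rng):
    X1 = rng.normal(size=(300, 3))
    X2 = rng.normal(size=(300, 2))
    X1 -= X1.mean(0)
    X2 -= X2.mean(0)
    # orthogonalize the second group against the first: exactly block-diagonal X'X
    X2 -= X1 @ np.linalg.lstsq(X1, X2, rcond=None)[0]
    X = np.hstack([X1, X2])
    z = rng.normal(size=5)
    full = whiten_z(cholesky_factor(X.T @ X), z)
    blocks = build_blocks(X, z, [f"s{i}" for i in range(5)], n_study=300,
                          boundaries=[(0, 3), (3, 5)])
    parts = np.concatenate([wb.z_whitened for wb in blocks])
    assert np.allclose(np.abs(full), np.abs(parts), atol=1e-8)
    assert float(full @ full) == pytest.approx(float(parts @ parts), rel=1e-10)


def test_block_larger_than_reference_rejected(rng):
    X = rng.normal(size=(4, 6))
    X -= X.mean(0)
    with pytest.raises(ValueError, match="reference sample"):
        build_blocks(X, np.zeros(6), [f"s{i}" for i in range(6)], n_study=100,
                     boundaries=[(0, 6)])


def test_reference_matrix_reader_strips_plink_columns(tmp_path):
    path = tmp_path / "ref.raw"
    path.write_text(
        "FID IID rs1_A rs2_G\n" "f1 i1 0 2\n" "f2 i2 1 1\n" "f3 i3 2 0\n"
    )
    mat, ids = read_reference_matrix(path)
    assert ids == ["rs1", "rs2"]
    assert mat.shape == (3, 2)
    assert np.allclose(mat[:, 0], [0, 1, 2])


def test_bed_blocks_partition_all_snps(tmp_path):
    bed = tmp_path / "blocks.bed"
    bed.write_text("chr1\t0\t150\nchr1\t150\t300\n")
    positions = np.array([10, 100, 160, 250, 400])  # last SNP outside all intervals
    bounds = read_block_bed(bed, positions, chroms=np.array(["chr1"] * 5))
    assert bounds == [(0, 2), (2, 4), (4, 5)]
    covered = sorted(i for lo, hi in bounds for i in range(lo, hi))
    assert covered == list(range(5))
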