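"""QC thresholds, normalization law, scaling regression, HVG, PCA."""

import numpy as np
import pytest
import scipy.sparse as sp

from tme.datatypes import CellCovariates
from tme.qc import (
    HvgParams,
    ParameterError,
    QcParams,
    cell_cycle_score,
    log_normalize,
    pca_embed,
    qc_filter,
    regress_and_scale,
    select_hvg,
)
from tme.simulate import ScSimSpec, simulate_sc

from conftest import make_counts, make_norm


def brute_force_qc(dense, mito, min_genes, max_mito, min_gene_mean, scale=1e4):
    """Independent double-loop re-implementation of the QC contract."""
    n_genes, n_cells = dense.shape
    keep_cells = []
    for j in range(n_cells):
        detected = sum(1 for i in range(n_genes) if dense[i, j] > 0)
        mito_sum = sum(dense[i, j] for i in range(n_genes) if mito[i])
        endo_sum = sum(dense[i, j] for i in range(n_genes) if not mito[i])
        ratio = mito_sum / endo_sum if endo_sum > 0 else np.inf
        if detected >= min_genes and ratio <= max_mito:
            keep_cells.append(j)
    keep_genes = []
    for i in range(n_genes):
        vals = []
        for j in keep_cells:
            total = sum(dense[g, j] for g in range(n_genes))
            vals.append(np.log1p(dense[i, j] * scale / total))
        if np.mean(vals) >= min_gene_mean:
            keep_genes.append(i)
    return keep_genes, keep_cells


class TestQcFilter:
    def test_gene_count_threshold_is_strict(self):
        """A cell detecting 299 unique genes is dropped; one at 300 is kept."""
        n_genes = 320
        dense = np.zeros((n_genes, 2), int)
        dense[:299, 0] = 1
        dense[:300, 1] = 1
        counts = make_counts(dense)
        filtered, report = qc_filter(counts, QcParams(min_gene_mean=0.0))
        assert filtered.cells.tolist() == ["c1"]
        assert report["cells_dropped_genes"] == 1

    def test_mito_threshold_is_strict(self):
        n_genes = 301
        dense = np.ones((n_genes, 2), int)
        mito = np.zeros(n_genes, bool)
        mito[-1] = True
        dense[-1, 0] = 30  # mito/endo = 30/300 = 0.1 exactly -> kept
        dense[-1, 1] = 31  # 31/300 > 0.1 -> dropped
        counts = make_counts(dense, mito=mito)
        filtered, report = qc_filter(counts, QcParams(min_gene_mean=0.0))
        assert filtered.cells.tolist() == ["c0"]
        assert report["cells_dropped_mito"] == 1

    def test_matches_brute_force_oracle(self, rng):
        dense = rng.negative_binomial(2, 0.3, size=(40, 25))
        mito = np.zeros(40, bool)
        mito[-3:] = True
        counts = make_counts(dense, mito=mito)
        params = QcParams(min_genes_per_cell=10, max_mito_ratio=0.2, min_gene_mean=0.5)
        filtered, _ = qc_filter(counts, params)
        keep_genes, keep_cells = brute_force_qc(dense, mito, 10, 0.2, 0.5)
        assert filtered.cells.tolist() == [f"c{j}" for j in keep_cells]
        assert filtered.genes.tolist() == [f"g{i}" for i in keep_genes]

    def test_all_cells_removed_is_error(self):
        counts = make_counts(np.ones((5, 3), int))
        with pytest.raises(ValueError, match="every cell"):
            qc_filter(counts, QcParams(min_genes_per_cell=100))

    def test_idempotent_on_filtered_output(self):
        counts, _ = simulate_sc(
            ScSimSpec(n_cell_types=2, cells_per_type=40, n_genes=400, markers_per_type=10, seed=6)
        )
        params = QcParams(min_genes_per_cell=50)
        once, _ = qc_filter(counts, params)
        twice, report = qc_filter(once, params)
        assert twice.n_cells == once.n_cells
        assert twice.n_genes == once.n_genes


class TestLogNormalize:
    def test_zero_count_stays_zero(self):
        counts = make_counts([[0, 2], [5, 3]])
        norm = log_normalize(counts)
        assert norm.matrix[0, 0] == 0.0

    def test_single_count_in_scale_total(self):
        dense = np.zeros((2, 1), int)
        dense[0, 0] = 1
        dense[1, 0] = 9999
        norm = log_normalize(make_counts(dense))
        assert norm.matrix[0, 0] == pytest.approx(np.log(2.0))

    def test_exp_sum_invariant(self, rng):
        """Per cell, sum(e^N - 1) equals the scale factor."""
        dense = rng.integers(0, 20, size=(30, 10))
        dense[0] += 1  # no zero-total cells
        norm = log_normalize(make_counts(dense), scale_factor=1e4)
        sums = np.asarray(np.expm1(norm.matrix.toarray()).sum(axis=0))
        assert np.allclose(sums, 1e4, rtol=1e-6)

    def test_zero_total_cell_rejected(self):
        counts = make_counts([[0, 1], [0, 2]])
        with pytest.raises(ValueError, match="zero total"):
            log_normalize(counts)


class TestCellCycleScore:
    def test_high_set_cells_score_higher(self, rng):
        n_genes, n_cells = 60, 40
        dense = rng.normal(1.0, 0.05, size=(n_genes, n_cells)).clip(0)
        dense[:5, :20] += 2.0  # S-phase genes high in first half
        norm = make_norm(dense)
        score = cell_cycle_score(norm, [f"g{i}" for i in range(5)], seed=0)
        assert score[:20].mean() > score[20:].mean() + 0.3

    def test_identical_sets_give_zero_difference(self, rng):
        dense = rng.random((40, 15))
        norm = make_norm(dense)
        genes = [f"g{i}" for i in range(4)]
        a = cell_cycle_score(norm, genes, seed=1)
        b = cell_cycle_score(norm, genes, seed=1)
        assert np.allclose(a - b, 0.0)

    def test_constant_matrix_scores_zero(self):
        norm = make_norm(np.full((30, 8), 2.0))
        score = cell_cycle_score(norm, ["g0", "g1"], seed=0)
        assert np.allclose(score, 0.0)

    def test_disjoint_gene_set_rejected(self):
        norm = make_norm(np.ones((5, 4)))
        with pytest.raises(ValueError, match="overlap"):
            cell_cycle_score(norm, ["nope"])


def normal_equations_residuals(Y, X):
    """Independent per-gene OLS via explicit normal equations."""
    XtX = X.T @ X
    out = np.empty_like(Y)
    for g in range(Y.shape[1]):
        beta = np.linalg.solve(XtX, X.T @ Y[:, g])
        out[:, g] = Y[:, g] - X @ beta
    return out


class TestRegressAndScale:
    def test_gene_linear_in_covariate_scales_to_zero(self):
        n_cells = 20
        numi = np.linspace(100, 200, n_cells)
        dense = np.vstack([0.01 * numi, np.random.default_rng(1).random(n_cells)])
        norm = make_norm(dense)
        cov = CellCovariates(n_umi=numi, mito_ratio=np.zeros(n_cells))
        scaled = regress_and_scale(norm, cov)
        assert np.allclose(scaled[0], 0.0, atol=1e-8)

    def test_constant_covariates_equal_plain_zscore(self, rng):
        dense = rng.random((10, 15))
        norm = make_norm(dense)
        cov = CellCovariates(n_umi=np.full(15, 500.0), mito_ratio=np.full(15, 0.05))
        scaled = regress_and_scale(norm, cov)
        z = (dense - dense.mean(axis=1, keepdims=True)) / dense.std(axis=1, keepdims=True)
        assert np.allclose(scaled, z, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        n_genes, n_cells = 12, 25
        dense = rng.random((n_genes, n_cells))
        numi = rng.integers(100, 1000, n_cells).astype(float)
        mito = rng.random(n_cells) * 0.1
        ccd = rng.normal(size=n_cells)
        norm = make_norm(dense)
        cov = CellCovariates(n_umi=numi, mito_ratio=mito, s_score=ccd, g2m_score=np.zeros(n_cells))
        scaled = regress_and_scale(norm, cov, clip=np.inf)
        X = np.column_stack([np.ones(n_cells), numi, mito, ccd])
        resid = normal_equations_residuals(dense.T, X)
        expected = ((resid - resid.mean(axis=0)) / resid.std(axis=0)).T
        assert np.allclose(scaled, expected, atol=1e-8)

    def test_constant_gene_scales_to_zero(self):
        dense = np.vstack([np.full(10, 3.0), np.arange(10, dtype=float)])
        scaled = regress_and_scale(make_norm(dense), None)
        assert np.allclose(scaled[0], 0.0)

    def test_values_clipped(self, rng):
        dense = rng.random((5, 30))
        dense[0, 0] = 1e6
        scaled = regress_and_scale(make_norm(dense), None, clip=10.0)
        assert scaled.max() <= 10.0 and scaled.min() >= -10.0


def brute_force_hvg(dense_norm, n_bins, mean_low, mean_high, z_cutoff):
    """Independent binned dispersion z-score computation on dense arrays."""
    C = np.expm1(dense_norm)
    mean = C.mean(axis=1)
    var = C.var(axis=1, ddof=1)
    disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1), 0.0)
    n = len(mean)
    order = np.argsort(mean, kind="stable")
    bins = np.empty(n, int)
    bins[order] = np.arange(n) * n_bins // n
    z = np.zeros(n)
    for b in set(bins):
        m = bins == b
        if m.sum() >= 2 and disp[m].std() > 0:
            z[m] = (disp[m] - disp[m].mean()) / disp[m].std()
    return (mean > mean_low) & (mean <= mean_high) & (z > z_cutoff)


class TestSelectHvg:
    def test_low_mean_gene_excluded_regardless_of_dispersion(self, rng):
        dense = rng.random((40, 30)) + 0.5
        dense[0] = 0.0
        dense[0, 0] = 0.004 * 30  # mean 0.004 < 0.01, dispersion huge
        norm = make_norm(np.log1p(dense * 0))  # rebuild below
        norm = make_norm(np.log1p(dense))
        mask = select_hvg(norm, HvgParams(n_bins=5))
        assert not mask[0]

    def test_identical_genes_yield_no_hvg(self):
        norm = make_norm(np.tile(np.linspace(0.1, 1, 25), (30, 1)))
        mask = select_hvg(norm, HvgParams(mean_low=0.0, mean_high=100, n_bins=5))
        assert mask.sum() == 0

    def test_matches_brute_force_oracle(self, rng):
        dense = np.log1p(rng.gamma(2.0, 1.0, size=(100, 50)))
        norm = make_norm(dense)
        params = HvgParams(mean_low=0.05, mean_high=50.0, dispersion_z_cutoff=0.5, n_bins=10)
        mask = select_hvg(norm, params)
        expected = brute_force_hvg(dense, 10, 0.05, 50.0, 0.5)
        assert (mask == expected).all()

    def test_planted_high_dispersion_recovered(self, rng):
        n_genes, n_cells = 200, 80
        dense = rng.poisson(2.0, size=(n_genes, n_cells)).astype(float)
        # planted genes: same mean (2), much higher variance (0 or 8 at p=1/4)
        dense[:10] = 8.0 * (rng.random((10, n_cells)) < 0.25)
        norm = make_norm(np.log1p(dense))
        mask = select_hvg(norm, HvgParams(mean_low=0.01, mean_high=1e4))
        assert mask[:10].sum() >= 8

    def test_too_few_genes_rejected(self):
        with pytest.raises(ParameterError):
            select_hvg(make_norm(np.ones((5, 4))), HvgParams(n_bins=20))


class TestPcaEmbed:
    def test_rank_two_matrix_has_no_higher_variance(self, rng):
        u = rng.normal(size=(30, 2))
        v = rng.normal(size=(2, 40))
        scaled = (u @ v).T  # genes x cells with rank 2
        emb = pca_embed(scaled, np.ones(scaled.shape[0], bool), n_pcs=5)
        assert emb[:, 2:].var(axis=0).max() < 1e-16

    def test_variance_non_increasing(self, rng):
        scaled = rng.normal(size=(50, 60))
        emb = pca_embed(scaled, np.ones(50, bool), n_pcs=10)
        v = emb.var(axis=0)
        assert (np.diff(v) <= 1e-12).all()

    def test_pairwise_distances_match_dense_eig_oracle(self, rng):
        """Full-rank embedding preserves the distances of an eigendecomposition."""
        scaled = rng.normal(size=(50, 30))
        emb = pca_embed(scaled, np.ones(50, bool), n_pcs=29)
        X = scaled.T - scaled.T.mean(axis=0)
        w, V = np.linalg.eigh(X.T @ X)
        oracle = X @ V[:, ::-1][:, :29]
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(emb), pdist(oracle), atol=1e-6)

    def test_deterministic_sign_convention(self, rng):
        scaled = rng.normal(size=(40, 30))
        a = pca_embed(scaled, np.ones(40, bool), n_pcs=5)
        b = pca_embed(scaled.copy(), np.ones(40, bool), n_pcs=5)
        assert np.array_equal(a, b)

    def test_too_many_pcs_rejected(self, rng):
        with pytest.raises(ParameterError):
            pca_embed(rng.normal(size=(10, 8)), np.ones(10, bool), n_pcs=20)
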