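import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayescor import (
    CountMatrix,
    PRIOR_SCHEMES,
    bayes_correlation_matrix,
    bayes_correlation_pair,
    compute_posterior,
    feature_embedding,
    make_prior,
    pearson_correlation_matrix,
    spearman_correlation_matrix,
)

from conftest import random_count_matrix


def loop_correlations(R, scheme):
    """Pairwise-loop oracle for the all-pairs matrix."""
    belief = compute_posterior(R, make_prior(R, scheme))
    m = R.m
    C = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            C[i, j] = bayes_correlation_pair(belief, i, j)
    return C


class TestToyValues:
    def test_equal_depth_trio_bayes(self, toys):
        toy = toys["equal_depth_trio"]
        C = bayes_correlation_matrix(toy.matrix, "uniform")
        df = C.to_dataframe()
        for (a, b), expected in [((k[0][0], k[0][1]), v)
                                 for k, v in toy.expected.items()
                                 if k[1] == "bayes"]:
            assert round(df.loc[a, b], 3) == expected

    def test_equal_depth_trio_pearson_all_one(self, toys):
        C = pearson_correlation_matrix(toys["equal_depth_trio"].matrix).matrix
        off = C[~np.eye(3, dtype=bool)]
        np.testing.assert_array_equal(off, 1.0)

    def test_depth_contrast_pairs(self, toys):
        toy = toys["depth_contrast_pairs"]
        df = bayes_correlation_matrix(toy.matrix, "uniform").to_dataframe()
        assert round(df.loc["w", "x"], 3) == 0.859
        assert round(df.loc["y", "z"], 3) == 0.948
        # pair measured at the greater depth is closer to 1
        assert df.loc["w", "x"] < df.loc["y", "z"]
        P = pearson_correlation_matrix(toy.matrix).to_dataframe()
        assert P.loc["w", "x"] == 1.0 and P.loc["y", "z"] == 1.0


class TestBayesEngine:
    def test_self_correlation_exactly_one(self, toys):
        R = toys["equal_depth_trio"].matrix
        belief = compute_posterior(R, make_prior(R, "uniform"))
        assert bayes_correlation_pair(belief, 1, 1) == 1.0
        C = bayes_correlation_matrix(R, "uniform").matrix
        assert np.all(np.diag(C) == 1.0)

    def test_index_out_of_range(self, toys):
        R = toys["equal_depth_trio"].matrix
        belief = compute_posterior(R, make_prior(R, "uniform"))
        with pytest.raises(IndexError):
            bayes_correlation_pair(belief, 0, 3)

    def test_single_entity_matrix(self):
        R = CountMatrix([[3.0, 4.0, 5.0]], column_totals=[10.0, 10.0, 10.0])
        C = bayes_correlation_matrix(R, "uniform").matrix
        np.testing.assert_array_equal(C, [[1.0]])

    @pytest.mark.parametrize("scheme", PRIOR_SCHEMES)
    def test_matrix_path_equals_pairwise_loop(self, rng, scheme):
        R = random_count_matrix(rng, m=20, k=5)
        C = bayes_correlation_matrix(R, scheme).matrix
        np.testing.assert_allclose(C, loop_correlations(R, scheme), atol=1e-10)

    def test_block_computation_identical(self, rng):
        R = random_count_matrix(rng, m=17, k=4)
        full = bayes_correlation_matrix(R, "zero_count").matrix
        blocked = bayes_correlation_matrix(R, "zero_count", block_size=5).matrix
        np.testing.assert_allclose(full, blocked, atol=1e-12)

    def test_result_symmetric_and_bounded(self, rng):
        R = random_count_matrix(rng, m=25, k=6)
        C = bayes_correlation_matrix(R, "uniform").matrix
        np.testing.assert_array_equal(C, C.T)
        assert np.all(C >= -1.0) and np.all(C <= 1.0)

    def test_permutation_equivariance(self, rng):
        R = random_count_matrix(rng, m=8, k=5)
        C = bayes_correlation_matrix(R, "zero_count").matrix
        perm = rng.permutation(R.m)
        Rp = CountMatrix(R.counts[perm],
                         entity_ids=[R.entity_ids[i] for i in perm],
                         column_totals=R.column_totals)
        Cp = bayes_correlation_matrix(Rp, "zero_count").matrix
        np.testing.assert_allclose(Cp, C[np.ix_(perm, perm)], atol=1e-12)
        # permuting conditions leaves the correlations unchanged
        cperm = rng.permutation(R.k)
        Rc = CountMatrix(R.counts[:, cperm],
                         entity_ids=R.entity_ids,
                         column_totals=R.column_totals[cperm])
        Cc = bayes_correlation_matrix(Rc, "zero_count").matrix
        np.testing.assert_allclose(Cc, C, atol=1e-12)

    def test_deep_sequencing_drives_bayes_to_pearson(self):
        base = np.array([[1000.0, 1000.0, 10000.0], [100.0, 100.0, 200.0]])
        depths = np.array([1e6, 1e6, 1e6])
        rp = pearson_correlation_matrix(
            CountMatrix(base, column_totals=depths)).matrix[0, 1]
        gaps = []
        for s in (1, 10**2, 10**4):
            R = CountMatrix(base * s, column_totals=depths * s)
            rb = bayes_correlation_matrix(R, "uniform").matrix[0, 1]
            gaps.append(abs(rb - rp))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-4


class TestClassicalBaselines:
    def test_pearson_scale_invariance(self):
        R = CountMatrix([[10, 20, 30], [20, 40, 60]],
                        column_totals=[100.0, 100.0, 100.0])
        C = pearson_correlation_matrix(R).matrix
        np.testing.assert_allclose(C[0, 1], 1.0)

    def test_degenerate_rows_are_nan_with_warning(self):
        R = CountMatrix([[5, 5, 5], [1, 2, 3]], column_totals=[10.0] * 3)
        with pytest.warns(RuntimeWarning, match="zero variance"):
            C = pearson_correlation_matrix(R).matrix
        assert np.isnan(C[0, 1]) and np.isnan(C[0, 0])
        assert C[1, 1] == 1.0

    def test_zero_total_column_rejected(self):
        R = CountMatrix([[0, 1], [0, 2]])
        with pytest.raises(ValueError, match="zero total"):
            pearson_correlation_matrix(R)

    def test_spearman_monotone_and_reversed(self):
        R = CountMatrix([[1, 2, 3, 4], [2, 5, 9, 14], [14, 9, 5, 2]],
                        column_totals=[100.0] * 4)
        C = spearman_correlation_matrix(R).matrix
        np.testing.assert_allclose(C[0, 1], 1.0)
        np.testing.assert_allclose(C[0, 2], -1.0)

    def test_spearman_matches_rank_oracle(self, rng):
        from scipy.stats import rankdata

        R = random_count_matrix(rng, m=10, k=6)
        C = spearman_correlation_matrix(R).matrix
        ranks = np.vstack([rankdata(row) for row in R.fractions])
        oracle = np.corrcoef(ranks)
        np.testing.assert_allclose(C, oracle, atol=1e-12)


class TestKernel:
    def test_embedding_reproduces_toy_matrix(self, toys):
        R = toys["equal_depth_trio"].matrix
        belief = compute_posterior(R, make_prior(R, "uniform"))
        emb = feature_embedding(belief)
        C = bayes_correlation_matrix(R, "uniform").matrix
        np.testing.assert_allclose(emb.gram(), C, atol=1e-12)

    def test_psi_vectors_are_unit_norm(self, rng):
        R = random_count_matrix(rng, m=15, k=4)
        belief = compute_posterior(R, make_prior(R, "zero_count"))
        emb = feature_embedding(belief)
        np.testing.assert_allclose(
            np.einsum("ij,ij->i", emb.psi, emb.psi), 1.0, atol=1e-12)
        # residual coordinate is real: across-variance never exceeds total
        assert np.all(1.0 - np.einsum("ij,ij->i", emb.phi, emb.phi) >= -1e-12)

    @pytest.mark.parametrize("scheme", PRIOR_SCHEMES)
    def test_correlation_matrix_is_psd(self, rng, scheme):
        for _ in range(5):
            R = random_count_matrix(rng, m=15, k=4)
            C = bayes_correlation_matrix(R, scheme).matrix
            eigmin = np.linalg.eigvalsh(C).min()
            assert eigmin >= -1e-8

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 2**20),
        m=st.integers(2, 10),
        k=st.integers(2, 6),
        scheme=st.sampled_from(PRIOR_SCHEMES),
    )
    def test_gram_equals_matrix_property(self, seed, m, k, scheme):
        rng = np.random.default_rng(seed)
        R = random_count_matrix(rng, m=m, k=k)
        C = bayes_correlation_matrix(R, scheme).matrix
        belief = compute_posterior(R, make_prior(R, scheme))
        np.testing.assert_allclose(feature_embedding(belief).gram(), C, atol=1e-10)
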