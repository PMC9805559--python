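import numpy as np
from vaeda import (
    CountMatrix,
    estimate_num_doublets,
    preliminary_knn_scores,
    simulate_doublets,
    subsample_doublets,
)
from vaeda.augment import default_knn_k


def _cm(counts):
    counts = np.asarray(counts, dtype=float)
    n, p = counts.shape
    return CountMatrix(counts, [f"bc{i}" for i in range(n)], [f"g{j}" for j in range(p)])


class TestSimulateDoublets:
    def test_library_size_drawn_from_eligible_multiset(self):
        # rows (2,0), (0,2), (2,2): library sizes {2, 2, 4}.  A doublet of the
        # first two has precursor (2,2); eligible sizes are {2,2,4}; drawing 4
        # must yield the row (2,2).
        X = _cm([[2, 0], [0, 2], [2, 2]])
        sim, parents = simulate_doublets(X, n_sim=200, rng_seed=0)
        libs = sim.counts.sum(axis=1)
        assert set(np.round(libs, 9)) <= {2.0, 4.0}
        pair01 = (parents.min(axis=1) == 0) & (parents.max(axis=1) == 1) & (libs == 4)
        assert pair01.any()
        np.testing.assert_allclose(sim.counts[pair01], np.tile([2.0, 2.0], (pair01.sum(), 1)))

    def test_two_row_matrix_never_pairs_a_cell_with_itself(self):
        X = _cm([[1, 0], [0, 1]])
        _, parents = simulate_doublets(X, n_sim=50, rng_seed=1)
        assert np.all(parents[:, 0] != parents[:, 1])
        assert set(map(tuple, parents)) <= {(0, 1), (1, 0)}

    def test_doublet_library_sizes_match_real_sizes_at_least_larger_parent(self):
        rng = np.random.default_rng(5)
        X = _cm(rng.poisson(3.0, size=(30, 8)) + 1)
        sim, parents = simulate_doublets(X, rng_seed=2)
        real = X.library_sizes
        for row, (i, j) in zip(sim.counts, parents):
            lib = row.sum()
            assert lib >= max(real[i], real[j]) - 1e-9
            assert np.isclose(real, lib, atol=1e-9).any()

    def test_seeded_runs_bit_identical(self):
        X = _cm(np.arange(1, 21).reshape(5, 4))
        a, pa = simulate_doublets(X, rng_seed=11)
        b, pb = simulate_doublets(X, rng_seed=11)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(pa, pb)


class TestPreliminaryKnnScores:
    def test_boundary_scores(self):
        # two tight groups far apart: real cells see only real neighbors etc.
        real = np.zeros((5, 2)) + np.arange(5)[:, None] * 0.01
        sim = np.full((5, 2), 100.0) + np.arange(5)[:, None] * 0.01
        M = np.vstack([real, sim])
        labels = np.repeat([0, 1], 5)
        s = preliminary_knn_scores(M, labels, k=3, n_pcs=2)
        np.testing.assert_array_equal(s[:5], 0.0)
        np.testing.assert_array_equal(s[5:], 1.0)

    def test_line_example(self):
        # real points at 0 and 1, simulated at 10 and 11; k=1
        M = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([0, 0, 1, 1])
        s = preliminary_knn_scores(M, labels, k=1, n_pcs=1)
        np.testing.assert_array_equal(s, [0.0, 0.0, 1.0, 1.0])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        M = rng.normal(size=(40, 6))
        labels = (rng.random(40) < 0.5).astype(int)
        s = preliminary_knn_scores(M, labels, k=5, n_pcs=4)
        perm = rng.permutation(40)
        s_perm = preliminary_knn_scores(M[perm], labels[perm], k=5, n_pcs=4)
        np.testing.assert_allclose(s_perm, s[perm], atol=1e-12)

    def test_default_k_is_sqrt_of_rows(self):
        assert default_knn_k(100) == 10
        assert default_knn_k(101) == 11
        assert default_knn_k(1) == 1


class TestEstimateNumDoublets:
    def test_hand_computed_quantile_and_count(self):
        # simulated scores [.2,.4,.6,.8]: 25% quantile (linear interp) = 0.35;
        # real scores [.1,.4,.5] -> two at or above the cutoff.
        s = np.array([0.1, 0.4, 0.5, 0.2, 0.4, 0.6, 0.8])
        labels = np.array([0, 0, 0, 1, 1, 1, 1])
        assert estimate_num_doublets(s, labels) == 2

    def test_separated_scores_give_zero(self):
        s = np.array([0.0, 0.0, 1.0, 1.0])
        labels = np.array([0, 0, 1, 1])
        assert estimate_num_doublets(s, labels) == 0

    def test_identical_scores_count_every_real_cell(self):
        s = np.full(6, 0.5)
        labels = np.array([0, 0, 0, 0, 1, 1])
        assert estimate_num_doublets(s, labels) == 4

    def test_monotone_in_quantile(self):
        rng = np.random.default_rng(3)
        s = rng.random(50)
        labels = (rng.random(50) < 0.4).astype(int)
        counts = [estimate_num_doublets(s, labels, q) for q in np.linspace(0, 1, 21)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSubsampleDoublets:
    def test_full_subsample_returns_everything(self):
        idx = subsample_doublets(np.array([0.5, 0.1, 0.9]), 3, rng_seed=0)
        np.testing.assert_array_equal(idx, [0, 1, 2])

    def test_degenerate_distribution(self):
        for seed in range(20):
            idx = subsample_doublets(np.array([1.0, 0.0, 0.0]), 1, rng_seed=seed)
            np.testing.assert_array_equal(idx, [0])

    def test_sampling_probability_proportional_to_score(self):
        # scores [3, 1]: P(index 0) = 0.75
        rng = np.random.default_rng(123)
        hits = sum(subsample_doublets(np.array([3.0, 1.0]), 1, rng_seed=rng)[0] == 0 for _ in range(10_000))
        assert abs(hits / 10_000 - 0.75) < 0.02

    def test_zero_score_shortfall_filled_uniformly(self):
        idx = subsample_doublets(np.array([0.0, 2.0, 0.0]), 2, rng_seed=4)
        assert 1 in idx and len(idx) == 2

    def test_seeded_runs_identical(self):
        s = np.random.default_rng(0).random(30)
        a = subsample_doublets(s, 10, rng_seed=9)
        b = subsample_doublets(s, 10, rng_seed=9)
        np.testing.assert_array_equal(a, b)
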