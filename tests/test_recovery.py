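import numpy as np
import pytest
from scipy.optimize import minimize

from cellfuse import (
    DropoutRecovery,
    MultiModalDataset,
    SimulationParams,
    adaptive_similarity,
    fit_masked_nmf,
    guidance_matrix,
    initial_clusters,
    missing_rate,
    recover_matrix,
    recovery_confidence,
    simulate_multimodal,
)
from cellfuse.metrics import ari
from cellfuse.recovery import masked_nmf_objective


class TestInitialClusters:
    def test_recovers_generating_labels(self, small_dataset):
        ds, truth = small_dataset
        labels = initial_clusters(ds, 3, seed=0)
        assert ari(truth.labels, labels) >= 0.9

    def test_deterministic(self, small_dataset):
        ds, _ = small_dataset
        a = initial_clusters(ds, 3, seed=5)
        b = initial_clusters(ds, 3, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_n_equals_k_every_cell_alone(self, rng):
        from cellfuse.io import ModalityMatrix

        vals = rng.uniform(1, 5, (4, 3))
        ds = MultiModalDataset(
            modalities=[ModalityMatrix(vals, ["a", "b", "c"], list("wxyz"), "m")]
        )
        labels = initial_clusters(ds, 4, seed=0)
        assert len(np.unique(labels)) == 4

    def test_k_exceeding_n_rejected(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(ValueError):
            initial_clusters(ds, ds.n_cells + 1, seed=0)


class TestRecoveryConfidence:
    def test_hand_example(self):
        # one gene, cluster values [0, 2, 4]: a=1/3, b=2, v2=8/3 -> c = 0.6
        X = np.array([[0.0, 1.0], [2.0, 1.0], [4.0, 1.0]])
        art = recovery_confidence(X, np.zeros(3, dtype=int))
        assert art.confidence[:, 0] == pytest.approx(0.6)

    def test_degenerate_silent_gene_confidence_zero(self):
        X = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 3.0]])
        art = recovery_confidence(X, np.zeros(3, dtype=int))
        assert np.all(art.confidence[:, 0] == 0.0)

    def test_gene_without_zeros_confidence_one(self):
        X = np.array([[1.0, 1.0], [2.0, 1.0], [3.0, 1.0]])
        art = recovery_confidence(X, np.zeros(3, dtype=int))
        assert np.all(art.confidence[:, 0] == 1.0)

    def test_confidence_bounded_and_broadcast_per_cluster(self, rng):
        X = rng.uniform(0, 3, (20, 6))
        X[X < 1] = 0.0
        labels = np.repeat([0, 1], 10)
        art = recovery_confidence(X, labels)
        assert np.all((art.confidence >= 0) & (art.confidence <= 1))
        for k in (0, 1):
            block = art.confidence[labels == k]
            assert np.all(block == block[0])  # same value for every cell of the cluster


class TestGuidanceMatrix:
    def test_positive_entries_always_trusted(self):
        X = np.array([[5.0, 0.0], [0.0, 1.0]])
        C = np.array([[0.99, 0.99], [0.99, 0.99]])
        G = guidance_matrix(X, C, 0.1)
        assert G[0, 0] == 1 and G[1, 1] == 1

    def test_low_confidence_zero_kept(self):
        X = np.zeros((2, 2))
        C = np.full((2, 2), 0.05)
        assert np.all(guidance_matrix(X, C, 0.1) == 1)

    def test_toy_count_of_recovered_entries(self):
        X = np.array([[0.0, 1.0, 0.0], [2.0, 0.0, 3.0], [0.0, 4.0, 0.0], [5.0, 6.0, 7.0]])
        C = np.where(X == 0, 0.05, 0.9)
        C[0, 0] = 0.5
        C[2, 2] = 0.8  # two zeros at/above threshold -> recover exactly those
        G = guidance_matrix(X, C, 0.1)
        assert (G == 0).sum() == 2
        assert G[0, 0] == 0 and G[2, 2] == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            guidance_matrix(np.zeros((2, 2)), np.zeros((3, 2)), 0.1)

    def test_recovered_count_non_increasing_in_threshold(self, rng):
        X = rng.uniform(0, 2, (30, 20))
        X[X < 0.8] = 0.0
        C = rng.uniform(0, 1, X.shape)
        counts = [
            int((guidance_matrix(X, C, t) == 0).sum()) for t in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestAdaptiveSimilarity:
    def test_rows_sum_to_one_before_symmetrization(self, rng):
        P = rng.normal(size=(20, 4))
        graph = adaptive_similarity(P, 5)
        np.testing.assert_allclose(graph.row_stochastic.sum(axis=1), 1.0, atol=1e-9)

    def test_duplicate_point_dominates_its_row(self, rng):
        P = rng.normal(size=(10, 3))
        P[4] = P[7]  # exact duplicate
        graph = adaptive_similarity(P, 3)
        assert np.argmax(graph.row_stochastic[4]) == 7

    def test_matches_simplex_qp_oracle(self):
        # closed form == argmin sum_j s_j d_j + gamma ||s||^2 on the simplex
        pts = np.array([[0.0, 0.0], [1.0, 0.1], [1.2, -0.2], [3.0, 3.0], [-2.0, 1.5]])
        k = 2
        graph = adaptive_similarity(pts, k)
        d2 = ((pts[None] - pts[:, None]) ** 2).sum(-1)
        for i in range(len(pts)):
            d = np.delete(d2[i], i)
            idx = np.delete(np.arange(len(pts)), i)
            srt = np.sort(d)
            gamma = 0.5 * (k * srt[k] - srt[:k].sum())

            def obj(s):
                return s @ d + gamma * (s @ s)

            cons = [{"type": "eq", "fun": lambda s: s.sum() - 1}]
            res = minimize(obj, np.full(len(d), 1 / len(d)), bounds=[(0, 1)] * len(d),
                           constraints=cons, method="SLSQP", tol=1e-12)
            oracle = np.zeros(len(pts))
            oracle[idx] = res.x
            np.testing.assert_allclose(graph.row_stochastic[i], oracle, atol=1e-6)

    def test_laplacian_structure(self, rng):
        P = rng.normal(size=(15, 3))
        graph = adaptive_similarity(P, 4)
        np.testing.assert_allclose(graph.S, graph.S.T)
        np.testing.assert_allclose(np.diag(graph.laplacian), 1.0)
        # normalized Laplacian is PSD
        w = np.linalg.eigvalsh(graph.laplacian)
        assert w.min() >= -1e-10

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            adaptive_similarity(rng.normal(size=(5, 2)), 5)


def _random_instance(seed, n=30, d=20, zero_frac=0.2):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, (n, d))
    G = (rng.random((n, d)) > zero_frac).astype(float)
    return X, G


class TestMaskedNMF:
    def test_rank_one_exact_recovery(self, rng):
        u, v = rng.uniform(0.5, 2, 25), rng.uniform(0.5, 2, 15)
        X = np.outer(u, v)
        graph = adaptive_similarity(X, 5)
        st = fit_masked_nmf(X, np.ones_like(X), graph, rank=1, lambda1=0, lambda2=0,
                            max_iter=500, tol=0, sim_update_every=None, seed=0)
        assert np.linalg.norm(X - st.P @ st.Q.T) / np.linalg.norm(X) < 1e-3

    def test_iterates_stay_nonnegative(self):
        X, G = _random_instance(1)
        graph = adaptive_similarity(X, 5)
        for it in (1, 3, 10, 50):
            st = fit_masked_nmf(X, G, graph, rank=5, lambda1=0.1, lambda2=0.1,
                                max_iter=it, tol=0, sim_update_every=None, seed=1)
            assert np.all(st.P >= 0) and np.all(st.Q >= 0)

    def test_objective_non_increasing_against_independent_oracle(self):
        # recompute the objective from its formula with explicit loops
        X, G = _random_instance(2)
        graph = adaptive_similarity(X, 5)
        lam1 = lam2 = 0.1
        st = fit_masked_nmf(X, G, graph, rank=5, lambda1=lam1, lambda2=lam2,
                            max_iter=80, tol=0, sim_update_every=None, seed=2)
        L = graph.laplacian
        oracle = masked_nmf_objective(X, G, st.P, st.Q, lam1, lam2, L)
        manual = np.sum((G * (X - st.P @ st.Q.T)) ** 2)
        manual += lam1 * (np.sum(st.P**2) + np.sum(st.Q**2))
        manual += lam2 * np.einsum("ir,ij,jr->", st.P, L, st.P)
        assert oracle == pytest.approx(manual, rel=1e-10)
        tr = np.asarray(st.objective_trace)
        assert np.all(np.diff(tr) <= 1e-9 * (1 + np.abs(tr[:-1])))

    def test_all_zero_matrix_rejected(self):
        graph = adaptive_similarity(np.random.default_rng(0).normal(size=(10, 3)), 3)
        with pytest.raises(ValueError):
            fit_masked_nmf(np.zeros((10, 8)), np.ones((10, 8)), graph, rank=2)


class TestRecoverMatrix:
    def test_full_guidance_is_identity(self, rng):
        X = rng.uniform(0, 2, (10, 6))
        P, Q = rng.uniform(0, 1, (10, 3)), rng.uniform(0, 1, (6, 3))
        np.testing.assert_array_equal(recover_matrix(X, np.ones_like(X), P, Q), X)

    def test_flagged_entries_take_low_rank_value(self, rng):
        X = rng.uniform(0, 2, (10, 6))
        G = np.ones_like(X)
        X[2, 3] = 0.0
        G[2, 3] = 0.0
        P, Q = rng.uniform(0.1, 1, (10, 3)), rng.uniform(0.1, 1, (6, 3))
        rec = recover_matrix(X, G, P, Q)
        assert rec[2, 3] == pytest.approx((P @ Q.T)[2, 3])

    def test_trusted_entries_bit_exact_and_zero_count_drops(self, rng):
        X = rng.uniform(0.5, 2, (8, 5))
        G = np.ones_like(X)
        for i, j in [(0, 0), (3, 2), (7, 4)]:
            X[i, j] = 0.0
            G[i, j] = 0.0
        P, Q = rng.uniform(0.1, 1, (8, 2)), rng.uniform(0.1, 1, (5, 2))
        rec = recover_matrix(X, G, P, Q)
        assert np.all(rec[G == 1] == X[G == 1])  # bit-exact where trusted
        assert (X == 0).sum() - (rec == 0).sum() == 3


class TestMissingRate:
    @pytest.mark.parametrize(
        "X,expected",
        [
            (np.zeros((3, 3)), 1.0),
            (np.ones((3, 3)), 0.0),
        ],
    )
    def test_extremes(self, X, expected):
        assert missing_rate(X) == expected

    def test_direct_count(self, rng):
        X = rng.uniform(1, 2, (4, 5))
        idx = [(0, 0), (1, 2), (2, 4), (3, 3), (0, 4), (1, 1), (2, 2)]
        for i, j in idx:
            X[i, j] = 0.0
        assert missing_rate(X) == pytest.approx(7 / 20)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            missing_rate(np.empty((0, 0)))


class TestDropoutRecoveryEstimator:
    def test_imputation_beats_zero_baseline(self, small_dataset):
        ds, truth = small_dataset
        labels = initial_clusters(ds, 3, seed=1)
        for obs, true, mask in zip(ds.matrices(), truth.true_matrices, truth.dropout_masks):
            rec = DropoutRecovery(rank=20, random_state=0).fit(obs, labels)
            dropped = mask == 1
            rmse_rec = np.sqrt(np.mean((rec.recovered_[dropped] - true[dropped]) ** 2))
            rmse_zero = np.sqrt(np.mean(true[dropped] ** 2))
            assert rmse_rec < rmse_zero
            assert rec.missing_rate_after_ < rec.missing_rate_before_
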