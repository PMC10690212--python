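import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from canonet.datatypes import CanonetError, Phenotype, SimilarityMatrix
from canonet.prune import (
    correlation_to_phenotype,
    netshy_summarize,
    pagerank_scores,
    pca_summarize,
    prune_network,
    summarize,
)
from conftest import make_dataset


def pagerank_power_iteration_oracle(A, alpha=0.85, n_iter=5000):
    """Independent dense power iteration with uniform teleportation and the
    uniform-redistribution convention for dangling (zero-degree) nodes."""
    p = A.shape[0]
    rowsum = A.sum(axis=1)
    M = np.zeros_like(A, dtype=float)
    dangling = rowsum == 0
    M[~dangling] = A[~dangling] / rowsum[~dangling, None]
    x = np.full(p, 1.0 / p)
    u = np.full(p, 1.0 / p)
    for _ in range(n_iter):
        x_new = alpha * (x @ M + x[dangling].sum() * u) + (1 - alpha) * u
        if np.abs(x_new - x).sum() < 1e-15:
            return x_new
        x = x_new
    return x


class TestPagerankScores:
    def test_cycle_graph_is_uniform(self):
        p = 6
        A = np.zeros((p, p))
        for i in range(p):
            A[i, (i + 1) % p] = A[(i + 1) % p, i] = 1.0
        np.testing.assert_allclose(pagerank_scores(A), np.full(p, 1 / p),
                                   atol=1e-9)

    def test_scores_sum_to_one_and_hub_dominates(self):
        # star: node 0 connected to all others
        p = 5
        A = np.zeros((p, p))
        A[0, 1:] = A[1:, 0] = 1.0
        pr = pagerank_scores(A)
        assert pr.sum() == pytest.approx(1.0, abs=1e-9)
        assert pr[0] > pr[1:].max()
        np.testing.assert_allclose(pr[1:], pr[1], atol=1e-9)  # leaf symmetry

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.integers(min_value=3, max_value=20))
    @settings(max_examples=40, deadline=None)
    def test_matches_power_iteration_oracle(self, seed, p):
        rng = np.random.default_rng(seed)
        A = rng.uniform(size=(p, p)) * (rng.uniform(size=(p, p)) < 0.5)
        A = np.triu(A, 1)
        A = A + A.T
        if A.max() == 0:
            A[0, 1] = A[1, 0] = 1.0
        got = pagerank_scores(A)
        oracle = pagerank_power_iteration_oracle(A)
        np.testing.assert_allclose(got, oracle, atol=1e-8)

    def test_all_zero_adjacency_uniform_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            pr = pagerank_scores(np.zeros((4, 4)))
        np.testing.assert_allclose(pr, 0.25)

    def test_invalid_adjacency_errors(self):
        with pytest.raises(CanonetError, match="symmetric"):
            pagerank_scores(np.array([[0.0, 1.0], [0.0, 0.0]]))
        with pytest.raises(CanonetError, match="nonnegative"):
            pagerank_scores(np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(CanonetError, match="2 nodes"):
            pagerank_scores(np.ones((1, 1)))


class TestPcaSummarize:
    def test_rank_one_data_single_component_recovers_latent(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=30)
        X = np.outer(z, [1.0, -2.0, 0.5])
        res = pca_summarize(X)
        assert res.scores.shape[1] == 1  # rank-limited
        assert abs(np.corrcoef(res.scores[:, 0], z)[0, 1]) == pytest.approx(1.0)

    def test_loadings_orthonormal_scores_uncorrelated(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 6))
        res = pca_summarize(X)
        L = res.loadings
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)
        C = res.scores.T @ res.scores
        np.testing.assert_allclose(C - np.diag(np.diag(C)), 0.0, atol=1e-8)

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 5))
        res = pca_summarize(X)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        Xc = Xs - Xs.mean(0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(-evals)
        for c in range(3):
            v = evecs[:, order[c]]
            got = res.loadings[:, c]
            # eigenvectors are sign-ambiguous; compare up to sign
            assert min(np.abs(got - v).max(), np.abs(got + v).max()) < 1e-8
        # variance of PC scores equals the eigenvalues / (n-1)
        np.testing.assert_allclose(res.scores.var(0, ddof=1) * (X.shape[0] - 1),
                                   evals[order][:3], atol=1e-8)

    def test_too_small_inputs_error(self):
        with pytest.raises(CanonetError):
            pca_summarize(np.random.default_rng(3).normal(size=(30, 1)))
        with pytest.raises(CanonetError):
            pca_summarize(np.random.default_rng(3).normal(size=(2, 4)))

    def test_constant_column_errors(self):
        X = np.random.default_rng(4).normal(size=(20, 3))
        X[:, 1] = 5.0
        with pytest.raises(CanonetError, match="zero-variance"):
            pca_summarize(X)


def random_module(seed, n=40, p=6):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    A = rng.uniform(0.1, 1.0, size=(p, p))
    A = np.triu(A, 1)
    A = A + A.T
    return X, A


class TestNetshySummarize:
    def test_zero_adjacency_scores_equal_plain_pca(self):
        X, _ = random_module(5)
        a = netshy_summarize(X, np.zeros((6, 6)))
        b = pca_summarize(X)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-10)

    def test_matches_construct_then_pca_oracle(self):
        X, A = random_module(6)
        res = netshy_summarize(X, A)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        d = A.sum(axis=1)
        Dm = np.diag(1.0 / np.sqrt(d))
        L = np.eye(6) - Dm @ A @ Dm
        from canonet.prune import _pca
        scores, _ = _pca(np.hstack([Xs, Xs @ L]))
        np.testing.assert_allclose(res.scores, scores, atol=1e-10)

    def test_feature_permutation_invariance_of_scores(self):
        X, A = random_module(7)
        perm = np.random.default_rng(8).permutation(6)
        a = netshy_summarize(X, A)
        b = netshy_summarize(X[:, perm], A[np.ix_(perm, perm)])
        np.testing.assert_allclose(np.abs(a.scores), np.abs(b.scores), atol=1e-8)

    def test_shape_mismatch_errors(self):
        X, _ = random_module(9)
        with pytest.raises(CanonetError, match="shape"):
            netshy_summarize(X, np.zeros((4, 4)))

    def test_dispatcher_routes_and_rejects(self):
        X, A = random_module(10)
        assert summarize(X, A, "pca").method == "pca"
        assert summarize(X, A, "netshy").method == "netshy"
        with pytest.raises(CanonetError, match="unknown summarization"):
            summarize(X, A, "umap")


class TestCorrelationToPhenotype:
    def test_single_component_equals_pearson(self):
        rng = np.random.default_rng(11)
        s = rng.normal(size=50)
        y = s + rng.normal(size=50)
        from canonet.datatypes import SummarizationResult
        res = SummarizationResult(scores=s[:, None], loadings=np.ones((1, 1)),
                                  method="pca")
        pheno = Phenotype(values=y, modality="quantitative",
                          subject_ids=[f"S{i}" for i in range(50)])
        rho, pc = correlation_to_phenotype(res, pheno)
        assert pc == 1
        assert rho == pytest.approx(np.corrcoef(s, y)[0, 1])

    def test_picks_component_with_max_absolute_correlation(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=60)
        s1 = rng.normal(size=60)  # noise
        s2 = -y + 0.1 * rng.normal(size=60)  # strongly negative
        from canonet.datatypes import SummarizationResult
        res = SummarizationResult(scores=np.column_stack([s1, s2]),
                                  loadings=np.eye(2), method="pca")
        pheno = Phenotype(values=y, modality="quantitative",
                          subject_ids=[f"S{i}" for i in range(60)])
        rho, pc = correlation_to_phenotype(res, pheno)
        assert pc == 2
        assert rho < -0.9  # signed correlation is preserved

    def test_constant_score_gives_zero(self):
        from canonet.datatypes import SummarizationResult
        res = SummarizationResult(scores=np.ones((10, 1)),
                                  loadings=np.ones((1, 1)), method="pca")
        pheno = Phenotype(values=np.arange(10.0), modality="quantitative",
                          subject_ids=[f"S{i}" for i in range(10)])
        rho, _ = correlation_to_phenotype(res, pheno)
        assert rho == 0.0


def landmark_oracle(rho_pheno, best_scores, m1, m2):
    """Independent enumeration of the pruning landmarks from the per-size
    phenotype correlations and best-PC score vectors."""
    m_star = m1
    for i in range(m1, m2 + 1):
        if abs(rho_pheno[i]) > abs(rho_pheno[m_star]):
            m_star = i
    x = m_star
    for i in range(m_star, m2 + 1):
        r = abs(np.corrcoef(best_scores[m_star], best_scores[i])[0, 1])
        if r > 0.8:
            x = max(x, i)
    m_opt = m_star
    for i in range(m_star, x + 1):
        if abs(rho_pheno[i]) >= 0.9 * abs(rho_pheno[m_star]):
            m_opt = max(m_opt, i)
    return m_star, x, m_opt


def planted_similarity_and_data(seed=13, n=80, p=30, k=6):
    """A module-sized dataset whose first k features share a latent factor
    that also drives the phenotype."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    X = rng.normal(size=(n, p))
    for j in range(k):
        X[:, j] = z + 0.4 * rng.normal(size=n)
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    y = z + 0.4 * rng.normal(size=n)
    data = make_dataset([X], y)
    C = np.abs(np.corrcoef(X, rowvar=False))
    np.fill_diagonal(C, 0.0)
    C = C / C.max()
    C = 0.5 * (C + C.T)
    sim = SimilarityMatrix(matrix=C,
                           feature_index=[("block1", f"block1_f{j}")
                                          for j in range(p)],
                           n_subsamples=1)
    return sim, data


class TestPruneNetwork:
    def test_degenerate_range_collapses_all_landmarks(self):
        sim, data = planted_similarity_and_data()
        pruned = prune_network(np.arange(30), sim, data, m1=8, m2=8,
                               method="pca")
        t = pruned.trace
        assert t.m_star == t.x == t.m_opt == 8
        assert pruned.feature_idx.size == 8

    def test_planted_features_lead_the_ranking(self):
        sim, data = planted_similarity_and_data()
        pruned = prune_network(np.arange(30), sim, data, m1=6, m2=30,
                               method="pca")
        assert set(pruned.trace.ranked_features[:6].tolist()) == set(range(6))
        assert abs(pruned.correlation_to_phenotype) > 0.8

    def test_landmark_ordering_invariants(self):
        sim, data = planted_similarity_and_data(seed=14)
        pruned = prune_network(np.arange(30), sim, data, m1=5, m2=25,
                               method="netshy")
        t = pruned.trace
        assert 5 <= t.m_star <= t.m_opt <= t.x <= 25
        assert pruned.feature_idx.size == t.m_opt
        assert abs(pruned.correlation_to_phenotype) >= \
            0.9 * abs(t.rho_pheno[t.m_star]) - 1e-12

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_landmarks_match_enumeration_oracle(self, seed):
        sim, data = planted_similarity_and_data(seed=seed)
        m1, m2 = 4, 20
        pruned = prune_network(np.arange(30), sim, data, m1=m1, m2=m2,
                               method="pca")
        t = pruned.trace
        # rebuild the per-size best-PC scores from the recorded ranking
        X = data.blocks[0].matrix
        best_scores = {}
        rho = {}
        for i in range(m1, m2 + 1):
            feats = t.ranked_features[:i]
            res = pca_summarize(X[:, feats])
            r, pc = correlation_to_phenotype(res, data.phenotype)
            rho[i] = r
            best_scores[i] = res.scores[:, pc - 1]
        m_star, x, m_opt = landmark_oracle(rho, best_scores, m1, m2)
        assert (t.m_star, t.x, t.m_opt) == (m_star, x, m_opt)

    def test_m2_capped_at_module_size(self):
        sim, data = planted_similarity_and_data()
        pruned = prune_network(np.arange(12), sim, data, m1=4, m2=100,
                               method="pca")
        assert pruned.trace.m2 == 12

    def test_invalid_bounds_error(self):
        sim, data = planted_similarity_and_data()
        with pytest.raises(CanonetError):
            prune_network(np.arange(30), sim, data, m1=1, m2=10)
        with pytest.raises(CanonetError):
            prune_network(np.arange(5), sim, data, m1=10, m2=20)
        with pytest.raises(CanonetError):
            prune_network(np.arange(10), sim, data, m1=8, m2=4)
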