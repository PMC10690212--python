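"""Module summarization (PCA / NetSHy) and PageRank-guided pruning.

A candidate module is pruned by ranking its features with weighted PageRank
on the induced similarity graph and growing the network from size m1 to m2,
tracking the correlation of the best summarization principal component with
the phenotype. Three landmarks are produced: m* (size of maximal |rho| to
phenotype), x (largest size whose summary still correlates > 0.8 with the
m* summary) and m_opt (largest size in [m*, x] retaining >= 90% of the m*
phenotype correlation).
"""

from __future__ import annotations

import logging

import numpy as np
import networkx as nx
from scipy.sparse.csgraph import laplacian as csgraph_laplacian

from .datatypes import (
    CanonetError,
    MultiOmicsDataset,
    Phenotype,
    PrunedModule,
    PruneTrace,
    SimilarityMatrix,
    SummarizationResult,
    warn,
)

logger = logging.getLogger("canonet.prune")

PAGERANK_DAMPING = 0.85
# accuracy target is 1e-9 on the scores; the iteration tolerance is set two
# orders stricter because the solver's stopping rule sums errors over nodes
PAGERANK_TOL = 1e-12
BASE_CORR_THRESHOLD = 0.8
PHENO_RETENTION = 0.9


def pagerank_scores(adjacency: np.ndarray) -> np.ndarray:
    """Weighted PageRank (damping 0.85, tolerance 1e-9); scores sum to 1.

    An all-zero adjacency yields uniform scores with a warning (every node
    is dangling, so teleportation dominates).
    """
    A = np.asarray(adjacency, dtype=float)
    p = A.shape[0]
    if p < 2:
        raise CanonetError("PageRank needs at least 2 nodes")
    if not np.allclose(A, A.T):
        raise CanonetError("adjacency must be symmetric")
    if np.any(A < 0):
        raise CanonetError("adjacency must be nonnegative")
    if A.max() == 0:
        warn("all-zero adjacency; PageRank is uniform")
        return np.full(p, 1.0 / p)
    G = nx.from_numpy_array(A)
    pr = nx.pagerank(G, alpha=PAGERANK_DAMPING, tol=PAGERANK_TOL,
                     max_iter=1000, weight="weight")
    return np.array([pr[i] for i in range(p)])


def _pca(matrix: np.ndarray, n_components: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """PCA of a column-centered matrix via SVD, with a deterministic sign
    convention (largest-|loading| coordinate positive, ties lowest index)."""
    Xc = matrix - matrix.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = max(1, min(n_components, rank))
    loadings = Vt[:k].T
    for c in range(k):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] = -loadings[:, c]
    scores = Xc @ loadings
    return scores, loadings


def _standardize(matrix: np.ndarray) -> np.ndarray:
    sd = matrix.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise CanonetError("module contains a zero-variance feature column")
    return (matrix - matrix.mean(axis=0)) / sd


def pca_summarize(submatrix: np.ndarray) -> SummarizationResult:
    """First three principal components of the column-standardized module
    data (fewer when rank-limited)."""
    X = np.asarray(submatrix, dtype=float)
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise CanonetError("PCA summarization needs >=2 features and >=3 subjects")
    scores, loadings = _pca(_standardize(X))
    return SummarizationResult(scores=scores, loadings=loadings, method="pca")


def netshy_summarize(submatrix: np.ndarray, adjacency: np.ndarray
                     ) -> SummarizationResult:
    """Topology-aware summarization: PCA of [X, X @ L] where L is the
    symmetric normalized graph Laplacian of the module adjacency.

    The Laplacian propagation term injects network-structure information
    into the summary; with an all-zero adjacency it vanishes and the score
    ranking reduces to plain PCA.
    """
    X = _standardize(np.asarray(submatrix, dtype=float))
    A = np.asarray(adjacency, dtype=float)
    if A.shape != (X.shape[1], X.shape[1]):
        raise CanonetError("adjacency shape does not match module width")
    if A.max() > 0:
        L = np.asarray(csgraph_laplacian(A, normed=True))
    else:
        L = np.zeros_like(A)
    scores, loadings = _pca(np.hstack([X, X @ L]))
    return SummarizationResult(scores=scores, loadings=loadings, method="netshy")


def summarize(submatrix: np.ndarray, adjacency: np.ndarray,
              method: str) -> SummarizationResult:
    if method == "pca":
        return pca_summarize(submatrix)
    if method == "netshy":
        return netshy_summarize(submatrix, adjacency)
    raise CanonetError(f"unknown summarization method {method!r}")


def correlation_to_phenotype(scores: SummarizationResult, phenotype: Phenotype
                             ) -> tuple[float, int]:
    """Signed Pearson correlation of the PC maximizing |rho| with the
    phenotype, plus its 1-based index (binary phenotypes are 0/1-coded, so
    this is the point-biserial correlation)."""
    y = phenotype.values.astype(float)
    best_rho, best_pc = 0.0, 1
    for c in range(scores.scores.shape[1]):
        s = scores.scores[:, c]
        if s.std() == 0 or y.std() == 0:
            rho = 0.0
        else:
            rho = float(np.corrcoef(s, y)[0, 1])
        if abs(rho) > abs(best_rho):
            best_rho, best_pc = rho, c + 1
    return best_rho, best_pc


def prune_network(
    module_features: np.ndarray,
    similarity: SimilarityMatrix,
    data: MultiOmicsDataset,
    m1: int = 10,
    m2: int = 100,
    method: str = "netshy",
) -> PrunedModule:
    """PageRank-guided pruning of one candidate module.

    ``module_features`` indexes into the similarity matrix's feature order
    (which must match the dataset's concatenated feature order).
    """
    module_features = np.asarray(module_features, dtype=int)
    size = module_features.size
    if m1 < 2:
        raise CanonetError("m1 must be >= 2")
    if m1 > size:
        raise CanonetError(f"m1={m1} exceeds module size {size}")
    m2 = min(m2, size)
    if m2 < m1:
        raise CanonetError(f"m2={m2} < m1={m1}")

    X_all = np.hstack([b.matrix for b in data.blocks])
    sub_adj = similarity.matrix[np.ix_(module_features, module_features)]
    pr = pagerank_scores(sub_adj)
    order = np.argsort(-pr, kind="stable")  # ties keep original order
    ranked = module_features[order]

    summaries: dict[int, SummarizationResult] = {}
    best_scores: dict[int, np.ndarray] = {}
    rho_pheno: dict[int, float] = {}
    which_pc: dict[int, int] = {}
    for i in range(m1, m2 + 1):
        feats = ranked[:i]
        adj_i = similarity.matrix[np.ix_(feats, feats)]
        summ = summarize(X_all[:, feats], adj_i, method)
        rho, pc = correlation_to_phenotype(summ, data.phenotype)
        summaries[i] = summ
        best_scores[i] = summ.scores[:, pc - 1]
        rho_pheno[i] = rho
        which_pc[i] = pc

    m_star = min(rho_pheno, key=lambda i: (-abs(rho_pheno[i]), i))

    rho_base: dict[int, float] = {}
    for i in range(m_star, m2 + 1):
        a, b = best_scores[m_star], best_scores[i]
        if a.std() == 0 or b.std() == 0:
            rho_base[i] = 0.0
        else:
            rho_base[i] = abs(float(np.corrcoef(a, b)[0, 1]))
    passing = [i for i in range(m_star, m2 + 1) if rho_base[i] > BASE_CORR_THRESHOLD]
    x = max(passing) if passing else m_star

    retained = [i for i in range(m_star, x + 1)
                if abs(rho_pheno[i]) >= PHENO_RETENTION * abs(rho_pheno[m_star])]
    m_opt = max(retained) if retained else m_star

    trace = PruneTrace(m1=m1, m2=m2, ranked_features=ranked,
                       rho_pheno=rho_pheno, rho_base=rho_base,
                       m_star=m_star, x=x, m_opt=m_opt)
    feats = ranked[:m_opt]
    logger.info("pruned module: m*=%d x=%d m_opt=%d (|rho|=%.4f, PC%d)",
                m_star, x, m_opt, abs(rho_pheno[m_opt]), which_pc[m_opt])
    return PrunedModule(
        feature_idx=feats,
        feature_index=[similarity.feature_index[i] for i in feats],
        adjacency=similarity.matrix[np.ix_(feats, feats)],
        summarization=summaries[m_opt],
        correlation_to_phenotype=rho_pheno[m_opt],
        which_pc=which_pc[m_opt],
        trace=trace,
    )
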