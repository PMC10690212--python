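"""Hybrid algorithm for binary phenotypes.

Five stages: (1) phenotype-free sparse multiple CCA to keep features that
are connected across omics blocks; (2) subset each block to that support;
(3) sparse PLS discriminant analysis (SPLSDA) on the concatenated subset,
extracting R sparse latent components; (4) logistic aggregation of the
latent components into one relevance direction; (5) a gamma-weighted convex
combination of the (unit-normalized) CCA weights and SPLSDA-derived feature
weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .datatypes import (
    CanonetError,
    CanonicalWeights,
    MultiOmicsDataset,
    PenaltySpec,
    ScalingScheme,
    warn,
)
from .smcca import l1_l2_project, solve_smcca

logger = logging.getLogger("canonet.binary")

DEFAULT_R = 3
DEFAULT_STAGE1_PENALTY = 0.5  # relaxed, to keep as many features as possible
RIDGE_FALLBACK = 1e-4


@dataclass
class SplsdaModel:
    """Sparse PLS-DA projection: Z maps concatenated features to R scores."""

    projection: np.ndarray  # (p_sub, R)
    latent: np.ndarray  # (n, R) = X_sub @ projection
    n_components: int


@dataclass
class HybridWeights:
    """Per-block weight parts of the hybrid combination."""

    smcca_part: list[np.ndarray]  # unit-normalized W~_t on the full feature set
    splsda_part: list[np.ndarray]  # unit-normalized W*_t on the full feature set
    combined: list[np.ndarray]
    gamma1: float
    gamma2: float
    alpha: np.ndarray


@dataclass
class HybridFit:
    """Everything needed to score new subjects with a fitted hybrid model."""

    weights: CanonicalWeights
    parts: HybridWeights
    support: list[np.ndarray]  # stage-1 surviving feature indices per block
    model: SplsdaModel
    logit_coef: np.ndarray  # alpha (length R)
    logit_intercept: float


def _canonical_sign(w: np.ndarray) -> np.ndarray:
    """Flip so the largest-|entry| coordinate is positive (ties: lowest index)."""
    if not np.any(w):
        return w
    j = int(np.argmax(np.abs(w)))
    return w if w[j] > 0 else -w


def splsda_fit(concatenated: np.ndarray, labels: np.ndarray,
               penalty: float, R: int = DEFAULT_R) -> SplsdaModel:
    """Extract R sparse PLS components against a 0/1 label vector.

    Per component: weight = L1/L2-projection of X_deflated' y, score =
    X_deflated @ weight; X is then deflated by regression on the score
    (PLS1-style, the response is left intact). The reported projection is
    the standard PLS rotation Z = W (P'W)^{-1} of the sparse weight matrix
    W (P holds the X-loadings), so latent = X @ Z reproduces the mutually
    orthogonal component scores from the *original* concatenated matrix.
    Orthogonal latent factors keep the downstream logistic aggregation from
    inflating coefficients on non-predictive components.
    """
    X = np.asarray(concatenated, dtype=float)
    labels = np.asarray(labels, dtype=float)
    classes = np.unique(labels)
    if classes.size < 2:
        raise CanonetError("SPLSDA needs both classes present")
    if not (0.0 < penalty <= 1.0):
        raise CanonetError(f"SPLSDA penalty {penalty} outside (0, 1]")
    if R < 1:
        raise CanonetError("R must be >= 1")
    n, p = X.shape
    rank = min(n - 1, p)
    if R > rank:
        warn(f"R={R} exceeds the data rank; reduced to {rank}")
        R = max(1, rank)
    budget = max(1.0, penalty * np.sqrt(p))
    y = labels - labels.mean()
    Xd = X.copy()
    weights, loadings = [], []
    for _ in range(R):
        v = Xd.T @ y
        w, is_zero = l1_l2_project(v, budget)
        if is_zero:
            warn("SPLSDA deflated covariance vanished; stopping early")
            break
        score = Xd @ w
        ss = float(score @ score)
        if ss == 0:
            warn("SPLSDA produced a zero-variance score; stopping early")
            break
        loading = (Xd.T @ score) / ss
        Xd = Xd - np.outer(score, loading)
        weights.append(w)
        loadings.append(loading)
    if not weights:
        raise CanonetError("SPLSDA extracted no components")
    W = np.column_stack(weights)
    P = np.column_stack(loadings)
    PtW = P.T @ W
    try:
        Z = W @ np.linalg.inv(PtW)
    except np.linalg.LinAlgError:
        Z = W @ np.linalg.pinv(PtW)
    return SplsdaModel(projection=Z, latent=X @ Z, n_components=Z.shape[1])


def _irls_logistic(L: np.ndarray, y: np.ndarray, ridge: float,
                   max_iter: int = 100, tol: float = 1e-10) -> np.ndarray:
    """Ridge-stabilized IRLS for logistic regression with intercept."""
    n, k = L.shape
    D = np.column_stack([np.ones(n), L])
    beta = np.zeros(k + 1)
    pen = np.eye(k + 1) * ridge
    pen[0, 0] = 0.0  # never penalize the intercept
    for _ in range(max_iter):
        eta = np.clip(D @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        Wv = np.maximum(mu * (1 - mu), 1e-10)
        H = (D * Wv[:, None]).T @ D + pen
        g = D.T @ (y - mu) - pen @ beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def aggregate_latent(model: SplsdaModel, labels: np.ndarray,
                     return_intercept: bool = False):
    """Logistic-regression coefficients of labels on the latent components.

    Fit by Newton/IRLS; on separation or non-convergence, refit with a small
    L2 penalty (``RIDGE_FALLBACK``) and log the fallback. The intercept is
    excluded from the returned alpha.
    """
    L = np.asarray(model.latent, dtype=float)
    if not np.all(np.isfinite(L)):
        raise CanonetError("latent factors contain non-finite values")
    y = np.asarray(labels, dtype=float)
    design = sm.add_constant(L, has_constant="add")
    beta = None
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, design).fit(disp=0, maxiter=100)
        if res.mle_retvals.get("converged", False) and np.all(np.isfinite(res.params)) \
                and np.max(np.abs(res.params)) < 1e3:
            beta = np.asarray(res.params)
    except Exception:  # perfect separation raises inside statsmodels
        beta = None
    if beta is None:
        logger.info("logistic aggregation unstable (separation?); "
                    "refitting with L2 penalty %g", RIDGE_FALLBACK)
        beta = _irls_logistic(L, y, RIDGE_FALLBACK)
    alpha = beta[1:]
    if return_intercept:
        return alpha, float(beta[0])
    return alpha


def combine_weights(smcca_part: list[np.ndarray], splsda_part: list[np.ndarray],
                    gamma1: float, gamma2: float) -> list[np.ndarray]:
    """W_t = (g1 * W~_t + g2 * W*_t) / (g1 + g2), per block.

    Both parts are unit-L2 normalized per block (when nonzero) and given a
    deterministic sign before combining, so the result is invariant to class
    relabeling and to joint rescaling of (g1, g2).
    """
    if gamma1 + gamma2 <= 0:
        raise CanonetError("gamma1 + gamma2 must be positive")
    if gamma1 < 0 or gamma2 < 0:
        raise CanonetError("gamma weights must be nonnegative")
    out = []
    for a, b in zip(smcca_part, splsda_part, strict=True):
        if a.shape != b.shape:
            raise CanonetError("per-block weight lengths do not match")
        an = _canonical_sign(a / np.linalg.norm(a)) if np.any(a) else a
        bn = _canonical_sign(b / np.linalg.norm(b)) if np.any(b) else b
        out.append((gamma1 * an + gamma2 * bn) / (gamma1 + gamma2))
    return out


def run_hybrid(
    data: MultiOmicsDataset,
    smcca_penalties: PenaltySpec | None = None,
    splsda_penalty: float = 0.9,
    gamma1: float = 1.0,
    gamma2: float = 1.0,
    R: int = DEFAULT_R,
    scaling: ScalingScheme | None = None,
) -> HybridFit:
    """Run the five-stage hybrid algorithm on a binary-phenotype dataset.

    With a single omics block the phenotype-free CCA stages are skipped and
    the result is the pure SPLSDA path (stage-3/4 weights only).
    """
    if data.phenotype.modality != "binary":
        raise CanonetError("hybrid algorithm requires a binary phenotype")
    T = data.n_blocks
    labels = data.phenotype.values
    if smcca_penalties is None:
        smcca_penalties = PenaltySpec(per_block=[DEFAULT_STAGE1_PENALTY] * T)

    if T > 1:
        if scaling is None:
            scaling = ScalingScheme.unweighted(T, include_phenotype=False)
        # Stage 1: phenotype-free SmCCA keeps cross-connected features
        stage1 = solve_smcca(data, scaling, smcca_penalties, include_phenotype=False)
        support = [np.flatnonzero(np.abs(w) > 0) for w in stage1.per_block]
        for t, s in enumerate(support):
            if s.size == 0:
                raise CanonetError(
                    f"phenotype-free CCA selected zero features in block "
                    f"{data.blocks[t].label!r}; use larger (more relaxed) penalties"
                )
            logger.info("stage 1: block %r kept %d of %d features",
                        data.blocks[t].label, s.size, data.blocks[t].n_features)
        smcca_full = [w.copy() for w in stage1.per_block]
    else:
        support = [np.arange(data.blocks[0].n_features)]
        smcca_full = [np.zeros(data.blocks[0].n_features)]
        gamma1 = 0.0
        gamma2 = 1.0

    # Stage 2-3: subset, concatenate, SPLSDA
    X_sub = np.hstack([data.blocks[t].matrix[:, support[t]] for t in range(T)])
    model = splsda_fit(X_sub, labels, splsda_penalty, R=R)

    # Stage 4: logistic aggregation, W*_t = Z_t @ alpha
    alpha, intercept = aggregate_latent(model, labels, return_intercept=True)
    sizes = [s.size for s in support]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    splsda_full = []
    for t in range(T):
        Zt = model.projection[offsets[t]:offsets[t + 1], :]
        w_star = np.zeros(data.blocks[t].n_features)
        w_star[support[t]] = Zt @ alpha
        splsda_full.append(w_star)

    # Stage 5: normalize and combine; dropped features keep weight 0
    combined = combine_weights(smcca_full, splsda_full, gamma1, gamma2)
    parts = HybridWeights(
        smcca_part=[_canonical_sign(w / np.linalg.norm(w)) if np.any(w) else w
                    for w in smcca_full],
        splsda_part=[_canonical_sign(w / np.linalg.norm(w)) if np.any(w) else w
                     for w in splsda_full],
        combined=combined,
        gamma1=gamma1, gamma2=gamma2, alpha=alpha,
    )
    unit = [w / np.linalg.norm(w) if np.any(w) else w for w in combined]
    weights = CanonicalWeights(per_block=unit, converged=True, objective=np.nan)
    return HybridFit(weights=weights, parts=parts, support=support,
                     model=model, logit_coef=alpha, logit_intercept=intercept)


def predict_proba(fit: HybridFit, blocks: list[np.ndarray]) -> np.ndarray:
    """Class-1 probability for new subjects given per-block matrices."""
    X_sub = np.hstack([blocks[t][:, fit.support[t]] for t in range(len(blocks))])
    latent = X_sub @ fit.model.projection
    eta = np.clip(fit.logit_intercept + latent @ fit.logit_coef, -30, 30)
    return 1.0 / (1.0 + np.exp(-eta))
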