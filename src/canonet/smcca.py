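"""Sparse multiple canonical correlation analysis by block coordinate ascent.

The solver maximizes the weighted sum of pairwise cross-block covariances

    sum_{i<j} a_ij w_i' X_i' X_j w_j  +  sum_i b_i w_i' X_i' Y

over per-block weight vectors w_t subject to ||w_t||_2 = 1 and an L1 budget
||w_t||_1 <= c_t (a LASSO-type constraint inducing feature sparsity). Each
block update is an exact maximization of the objective in w_t with the other
blocks fixed, solved in closed form by soft-thresholding with a bisection on
the threshold, so the objective is non-decreasing across sweeps.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np

from .datatypes import (
    CanonetError,
    CanonicalWeights,
    MultiOmicsDataset,
    PenaltySpec,
    ScalingScheme,
    warn,
)

logger = logging.getLogger("canonet.smcca")

MAX_SWEEPS = 100
TOL = 1e-6


def l1_l2_project(v: np.ndarray, c: float) -> tuple[np.ndarray, bool]:
    """argmax_u v'u  s.t.  ||u||_2 <= 1, ||u||_1 <= c  (c >= 1).

    Solved by soft-thresholding v at delta >= 0 and renormalizing; delta is
    found by bisection so that the L1 constraint is tight (delta = 0 when it
    is inactive). Returns (u, is_zero); a zero input yields the zero vector
    with is_zero=True.
    """
    v = np.asarray(v, dtype=float)
    if c < 1.0:
        raise CanonetError(f"L1 budget c={c} < 1 is infeasible with a unit L2 norm")
    vmax = np.max(np.abs(v)) if v.size else 0.0
    if vmax == 0.0:
        return np.zeros_like(v), True
    u = v / np.linalg.norm(v)
    if np.sum(np.abs(u)) <= c + 1e-12:
        return u, False
    if c == 1.0:
        # the constraint set collapses to signed unit basis vectors
        j = int(np.argmax(np.abs(v)))  # argmax returns the lowest tied index
        u = np.zeros_like(v)
        u[j] = np.sign(v[j])
        return u, False
    lo, hi = 0.0, vmax
    for _ in range(200):
        delta = 0.5 * (lo + hi)
        s = np.sign(v) * np.maximum(np.abs(v) - delta, 0.0)
        nrm = np.linalg.norm(s)
        if nrm == 0.0:
            hi = delta
            continue
        l1 = np.sum(np.abs(s)) / nrm
        if l1 > c:
            lo = delta
        else:
            hi = delta
    s = np.sign(v) * np.maximum(np.abs(v) - hi, 0.0)
    nrm = np.linalg.norm(s)
    if nrm == 0.0:  # degenerate ties at c -> 1 limit
        j = int(np.argmax(np.abs(v)))
        u = np.zeros_like(v)
        u[j] = np.sign(v[j])
        return u, False
    return s / nrm, False


def _pheno_vector(data: MultiOmicsDataset) -> np.ndarray:
    """Phenotype as a standardized column (binary already 0/1-coded)."""
    y = data.phenotype.values.astype(float)
    sd = y.std(ddof=1)
    if sd == 0:
        raise CanonetError("phenotype has zero variance")
    return (y - y.mean()) / sd


class _CrossProducts:
    """Caches X_i' X_j and X_i' y; results are identical with or without
    caching (pure memoization of deterministic products)."""

    def __init__(self, X: list[np.ndarray], y: np.ndarray | None):
        self.X = X
        self.y = y
        self._cross: dict[tuple[int, int], np.ndarray] = {}
        self._xty: dict[int, np.ndarray] = {}

    def cross(self, i: int, j: int) -> np.ndarray:
        key = (i, j)
        if key not in self._cross:
            if (j, i) in self._cross:
                self._cross[key] = self._cross[(j, i)].T
            else:
                self._cross[key] = self.X[i].T @ self.X[j]
        return self._cross[key]

    def xty(self, i: int) -> np.ndarray:
        if i not in self._xty:
            self._xty[i] = self.X[i].T @ self.y
        return self._xty[i]


def _objective(scores: list[np.ndarray], y: np.ndarray | None,
               scaling: ScalingScheme) -> float:
    T = len(scores)
    obj = 0.0
    for i in range(T):
        for j in range(i + 1, T):
            if scaling.between[i, j] != 0:
                obj += scaling.between[i, j] * float(scores[i] @ scores[j])
        if y is not None and scaling.pheno[i] != 0:
            obj += scaling.pheno[i] * float(scores[i] @ y)
    return obj


def objective_value(data: MultiOmicsDataset, weights: CanonicalWeights,
                    scaling: ScalingScheme) -> float:
    """The weighted-sum objective evaluated exactly as written."""
    y = _pheno_vector(data) if np.any(scaling.pheno != 0) else None
    scores = [data.blocks[t].matrix @ weights.per_block[t]
              for t in range(data.n_blocks)]
    return _objective(scores, y, scaling)


def _canonical_signs(w: list[np.ndarray], X: list[np.ndarray],
                     y: np.ndarray | None, scaling: ScalingScheme) -> list[np.ndarray]:
    """Deterministic sign fixing that never degrades the objective.

    Among the sign-flip patterns attaining the maximal objective (within
    1e-9 relative), choose the one that makes each block's largest-|entry|
    coordinate positive, in block order. With phenotype terms present the
    objective generically pins every sign; without them, flipping all blocks
    jointly is always free.
    """
    T = len(w)
    if T > 8:
        return w
    scores = [X[t] @ w[t] for t in range(T)]
    best_obj = -np.inf
    candidates: list[tuple[int, ...]] = []
    for pattern in itertools.product((1, -1), repeat=T):
        obj = _objective([p * s for p, s in zip(pattern, scores)], y, scaling)
        if obj > best_obj + 1e-9 * (1.0 + abs(best_obj)):
            best_obj = obj
            candidates = [pattern]
        elif obj >= best_obj - 1e-9 * (1.0 + abs(best_obj)):
            candidates.append(pattern)

    def preference(pattern: tuple[int, ...]) -> tuple[int, ...]:
        # prefer patterns whose flip makes the dominant coordinate positive
        key = []
        for t, p in enumerate(pattern):
            if np.all(w[t] == 0):
                key.append(0 if p == 1 else 1)
                continue
            j = int(np.argmax(np.abs(w[t])))
            key.append(0 if p * w[t][j] > 0 else 1)
        return tuple(key)

    chosen = min(candidates, key=preference)
    return [p * wt for p, wt in zip(chosen, w)]


def solve_smcca(
    data: MultiOmicsDataset,
    scaling: ScalingScheme,
    penalties: PenaltySpec,
    include_phenotype: bool = True,
    init_seed: int = 0,
) -> CanonicalWeights:
    """Fit sparse multiple CCA weights by block coordinate ascent.

    Blocks are assumed column-standardized. With ``include_phenotype=False``
    all phenotype scaling factors are treated as zero (the phenotype-free
    filtering step of the binary hybrid). Initialization is deterministic:
    w_t proportional to the column sums of X_t' X_t' for the first partner
    block (phenotype cross-products for a single block), then projected.
    """
    T = data.n_blocks
    if len(penalties.per_block) != T:
        raise CanonetError(
            f"{len(penalties.per_block)} penalties given for {T} blocks")
    X = [b.matrix for b in data.blocks]
    p = [b.n_features for b in data.blocks]
    eff_scaling = scaling
    if not include_phenotype:
        eff_scaling = ScalingScheme(between=scaling.between.copy(),
                                    pheno=np.zeros(T))
    use_y = include_phenotype and np.any(eff_scaling.pheno != 0)
    y = _pheno_vector(data) if use_y else None
    cp = _CrossProducts(X, y)
    budgets = [penalties.l1_budget(t, p[t]) for t in range(T)]

    rng = np.random.default_rng(init_seed)
    w: list[np.ndarray] = []
    for t in range(T):
        partner = next((j for j in range(T) if j != t and
                        (eff_scaling.between[t, j] > 0 or T == 1)), None)
        if partner is None and T > 1:
            partner = 0 if t != 0 else 1
        if T == 1 or partner is None:
            v = cp.xty(t) if y is not None else np.ones(p[t])
        else:
            v = cp.cross(t, partner).sum(axis=1)
        if not np.any(v):
            v = rng.standard_normal(p[t])  # randomized fallback, seeded
        wt, _ = l1_l2_project(v, budgets[t])
        w.append(wt)

    prev_obj = -np.inf
    converged = False
    sweeps = 0
    trace: list[float] = []
    for sweeps in range(1, MAX_SWEEPS + 1):
        max_change = 0.0
        for t in range(T):
            grad = np.zeros(p[t])
            for j in range(T):
                if j == t or eff_scaling.between[t, j] == 0:
                    continue
                grad += eff_scaling.between[t, j] * (cp.cross(t, j) @ w[j])
            if y is not None and eff_scaling.pheno[t] != 0:
                grad += eff_scaling.pheno[t] * cp.xty(t)
            new_w, is_zero = l1_l2_project(grad, budgets[t])
            if is_zero:
                # no gradient information: keep the current iterate
                new_w = w[t]
            max_change = max(max_change, float(np.max(np.abs(new_w - w[t]))))
            w[t] = new_w
        scores = [X[t] @ w[t] for t in range(T)]
        obj = _objective(scores, y, eff_scaling)
        logger.debug("sweep %d: objective %.10g (max dw %.3g)", sweeps, obj, max_change)
        if obj < prev_obj - 1e-9 * (1.0 + abs(prev_obj)):
            warn(f"objective decreased at sweep {sweeps} ({prev_obj} -> {obj})")
        prev_obj = obj
        trace.append(obj)
        if max_change < TOL:
            converged = True
            break
    if not converged:
        warn(f"coordinate ascent did not converge in {MAX_SWEEPS} sweeps; "
             "returning best iterate")

    w = _canonical_signs(w, X, y, eff_scaling)
    for t in range(T):
        if not np.any(w[t]):
            warn(f"block {data.blocks[t].label!r} received an all-zero weight vector")
    final_obj = _objective([X[t] @ w[t] for t in range(T)], y, eff_scaling)
    return CanonicalWeights(per_block=w, converged=converged,
                            objective=final_obj, n_iterations=sweeps,
                            objective_trace=trace)


def score_correlations(data: MultiOmicsDataset, weights: CanonicalWeights
                       ) -> dict[tuple[int, int] | int, float]:
    """Pearson correlations of block scores X_t w_t with each other and Y.

    Keys: (i, j) tuples for block pairs (i < j) and bare ints for
    block-phenotype correlations. Zero-variance scores give 0 with a warning.
    """
    T = data.n_blocks
    scores = [data.blocks[t].matrix @ weights.per_block[t] for t in range(T)]
    y = data.phenotype.values.astype(float)
    out: dict[tuple[int, int] | int, float] = {}

    def corr(a: np.ndarray, b: np.ndarray, name: str) -> float:
        if a.std() == 0 or b.std() == 0:
            warn(f"zero-variance score in correlation {name}; reporting 0")
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    for i in range(T):
        for j in range(i + 1, T):
            out[(i, j)] = corr(scores[i], scores[j], f"blocks ({i},{j})")
        out[i] = corr(scores[i], y, f"block {i} vs phenotype")
    return out
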