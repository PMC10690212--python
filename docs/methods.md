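# Methods

This note documents the statistical model implemented by `canonet`, the
default parameters and their rationale, the scope of the synthetic data
generator, the numerical choices that affect results, and known
limitations. It makes no empirical claims beyond what the test suite
computes.

## 1. Model

### 1.1 Sparse multiple CCA (quantitative phenotypes)

Given T column-standardized omics blocks `X_1..X_T` (n subjects,
`p_t` features) and a standardized phenotype vector `y`, the solver finds
one weight vector `w_t` per block maximizing

```
sum_{i<j} a_ij * w_i' X_i' X_j w_j  +  sum_i b_i * w_i' X_i' y
subject to  ||w_t||_2 = 1,  ||w_t||_1 <= c_t
```

where `a_ij >= 0` are between-omics scaling factors, `b_i >= 0` are
omics-phenotype factors, and the L1 budget is `c_t = max(1, l_t * sqrt(p_t))`
for a user-facing penalty `l_t` in (0, 1] (smaller `l_t` = sparser). The
`max(1, .)` clamp exists because `c < 1` is infeasible under a unit L2 norm;
it means very small penalties on very small blocks all collapse to
one-feature solutions.

The problem is solved by block coordinate ascent: with all other blocks
fixed, the optimum for `w_t` is the L1-constrained unit-norm maximizer of a
linear function, computed in closed form by soft-thresholding with the
threshold found by bisection (the penalized-matrix-decomposition update).
Each sweep updates every block once; the objective is recorded per sweep
and is non-decreasing up to floating-point noise (asserted by tests).
Convergence: relative objective change < 1e-6, at most 100 sweeps;
non-convergence returns the best iterate with a warning.

### 1.2 Hybrid algorithm (binary phenotypes)

Canonical correlation against a 0/1 vector underuses class structure, so
binary phenotypes use five stages:

1. **Phenotype-free SmCCA** (all `b_i = 0`) keeps features that are
   connected *across* omics blocks; its weights are `W~_t`.
2. Each block is **subset** to the stage-1 support.
3. **SPLSDA** on the concatenated subset extracts R (default 3) sparse
   latent components: per component, the weight is the L1/L2-projected
   covariance `X_d' y_c` between the deflated matrix and the centered
   labels, and `X` is deflated by regression on the component score
   (PLS1-style; the label vector is not deflated — with X-deflation,
   deflating y too is a mathematical no-op).
4. **Logistic regression** of the labels on the latent components gives
   aggregation coefficients `alpha`; the per-feature SPLSDA weight is
   `W*_t = Z_t alpha`, where `Z` is the PLS rotation (see item 3 of
   "Numerical choices" below).
5. The final weights are the convex combination
   `W_t = (g1 * W~_t + g2 * W*_t) / (g1 + g2)` with both parts unit-L2
   normalized and sign-fixed per block before combining.

With a single omics block, stages 1–2 are skipped (`g1 = 0`): the result is
the pure SPLSDA direction.

### 1.3 Consensus similarity, modules, pruning

- **Similarity**: for each of N subsampling iterations, a feature fraction
  is drawn per block, the model is refit, and the weights are scattered
  back to full length (unsampled features get 0). The similarity matrix is
  the element-wise mean of `|w w'|` over iterations, max-normalized to
  [0, 1], diagonal zeroed. Iteration failures are skipped; > 50% failures
  aborts the run.
- **Modules**: average-linkage hierarchical clustering of
  `D = 1 - similarity`, tree cut at `cut_height`; clusters smaller than
  `m1` are discarded.
- **Pruning**: features of a module are ranked by weighted PageRank
  (damping 0.85) on the module's similarity subgraph. For every size
  `i in [m1, m2]` the top-i subnetwork is summarized (NetSHy or PCA, best
  of the first three PCs by |correlation with phenotype|). Landmarks:
  - `m*`: size with maximal |phenotype correlation| (ties → smallest);
  - `x`: largest size whose best-PC scores still correlate > 0.8 (absolute)
    with the `m*` scores;
  - `m_opt`: largest size in `[m*, x]` retaining ≥ 90% of the `m*`
    phenotype correlation (absolute). The pruned module is the top-`m_opt`
    subnetwork.
- **NetSHy summarization**: PCA of the concatenation `[X_s, X_s L]`, where
  `X_s` is the column-standardized module data and `L` is the symmetric
  normalized graph Laplacian of the module adjacency. The `X_s L` term
  propagates network topology into the summary; with an empty graph it
  vanishes and the scores reduce exactly to plain PCA.

### 1.4 Model selection

- **Quantitative CV loss**: scaled prediction error
  `|trainCC - testCC| / |testCC|` (+inf when `testCC = 0`), where each CC
  is the scaling-weighted mean of pairwise score correlations. Train/test
  CCs are averaged over the K folds first and the loss applied once to the
  averages. Ties break toward smaller penalties.
- **Binary CV**: the full hybrid is refit per fold; held-out subjects are
  scored via the stored PLS rotation and logistic coefficients, and the
  chosen metric (accuracy / AUC / precision / recall / F1) is averaged
  over folds and maximized. Folds are stratified by class.
- **Automated scaling factors**: `a_ij = |cc_ij| / s`, `b_i = 1`, where
  `cc_ij` is a preliminary two-block sparse CCA correlation computed at a
  stringent penalty (l = 0.1) and `s` is the shrinkage factor (default 2).
  An optional nested grid search over phenotype-weight simplexes
  (`candidate_scaling_schemes` + `cv_scaling_search`) is provided for
  quantitative phenotypes.
- **Automated gammas** (binary): `g1 = mean |cc_ij|`, `g2 = 1`, so the CCA
  part contributes in proportion to how correlated the omics blocks
  actually are.

## 2. Defaults and rationale

| parameter | default | rationale |
| --- | --- | --- |
| penalty grid, quantitative | {0.1..0.5} per block | sparse half of the range; 125 combinations for 3 blocks |
| penalty grid, binary | {0.5..0.9} per block + classifier | the hybrid needs a permissive stage-1 filter; 625 combinations for 3 blocks |
| K folds | 5 | standard bias/variance compromise |
| subsample fraction | 0.9 if `p_t` < 300 else 0.7 | small blocks cannot afford losing features; large blocks benefit from more diversity |
| n_subsamples | 100 | enough for a stable consensus at pipeline scale |
| cut_height | 0.995 | similarity values are max-normalized and mostly tiny, so the informative merges happen very close to distance 1; synthetic data with strong planted signal typically needs a lower cut (tests use 0.9) |
| m1, m2 | 10, 100 | minimum interpretable module / maximum reviewable module |
| R (SPLSDA components) | 3 | captures multi-directional class structure without overfitting the logistic aggregation |
| PageRank damping | 0.85 | conventional teleportation constant |
| CoV filter threshold | 0.0 (off) | coefficient-of-variation filtering is only meaningful for positive-scale data (e.g. counts); opt-in |

## 3. Numerical choices

1. **L1/L2 projection.** The constrained maximizer of `v'u` is
   `u = S(v, d) / ||S(v, d)||` with soft-threshold `d` chosen by bisection
   (200 iterations) so that `||u||_1 = c` when the constraint is active; at
   `c = 1` the solution is the single largest-|v| coordinate (lowest index
   on ties). Verified against a grid-search oracle.
2. **Sign convention.** The objective is invariant only to *certain joint*
   sign flips of the weight vectors, not to independent per-block flips.
   After convergence the solver enumerates all 2^T flip patterns, keeps the
   objective-maximal ones, and among those deterministically picks the
   pattern that makes the largest-|entry| coordinate of each block
   positive (earlier blocks take precedence). This yields reproducible
   signs without sacrificing optimality. The hybrid's two weight parts are
   sign-fixed the same way before combining, which makes the combined
   weights invariant (up to sign) to swapping the class labels.
3. **PLS rotation.** SPLSDA reports the projection
   `Z = W (P'W)^{-1}` (`W` sparse weights, `P` X-loadings), so
   `latent = X Z` reproduces the mutually orthogonal component scores from
   the *original* matrix. Without this rotation the latent components are
   correlated and logistic aggregation inflates coefficients on
   non-predictive suppressor components, which measurably degrades
   feature ranking.
4. **Logistic aggregation fallback.** Newton/IRLS via statsmodels; on
   separation, non-convergence, or exploding coefficients (|beta| ≥ 1e3)
   the fit is repeated with a small L2 penalty (1e-4, intercept
   unpenalized) so the hybrid never fails on separable folds.
5. **PageRank tolerance.** The iteration tolerance is 1e-12 because the
   solver's stopping rule sums the error over nodes; this keeps the scores
   within 1e-8 of a dense power-iteration oracle on graphs of ≤ 20 nodes.
6. **Determinism.** All randomness flows from explicit seeds;
   per-iteration subsampling seeds are spawned from the master seed via a
   seed sequence. Identical config + seed produces byte-identical output
   files (asserted by tests); no timestamps are written.
7. **PCA.** Computed by SVD of the centered matrix with a deterministic
   loading-sign convention (largest-|loading| coordinate positive); the
   component count is capped at the numerical rank.

## 4. Synthetic data generator — scope

The generator plants **one** shared Gaussian latent factor: the planted
features of every block are `loading * factor + noise`, the phenotype is a
noisy linear readout (quantitative) or a Bernoulli draw from a logistic
readout (binary), and all other features are independent standard
Gaussians. This is deliberately the *minimal* structure detectable by
sparse multiple CCA. It does not simulate: multiple overlapping modules,
correlated background features, block-specific (phenotype-unrelated)
structure, non-Gaussian marginals, batch effects, or missing data.
Conclusions from the included tests are therefore about correctness of the
algorithms, not about performance on realistic omics data. Planted
features occupy the leading indices of each block by construction, which
makes ground-truth bookkeeping trivial; nothing in the pipeline exploits
feature order.

## 5. Limitations

- The first canonical component only: the solver extracts a single weight
  vector per block; secondary components must be sought by removing the
  first module's features and re-running.
- The scaled prediction error can favor degenerate, maximally sparse
  solutions when the grid contains penalties whose L1 budget collapses to
  the feasibility floor (`l * sqrt(p) <= 1`): a one-feature fit is very
  stable across folds, so `trainCC ≈ testCC` even though the solution is
  uninformative. Grids should avoid penalties at or below `1 / sqrt(p)`
  for the blocks at hand.
- Coordinate ascent guarantees a stationary point, not a global optimum;
  results can depend on initialization (deterministic here).
- Binary CV refits the full hybrid per fold and penalty combination; the
  default 625-combination grid is expensive for large data. Reduce the
  grid or K for exploratory runs.
- Missing values are rejected, not imputed. Subjects must be shared across
  blocks (intersection is taken); features must be complete.
- P-values / significance of module-phenotype correlations are not
  computed; reported correlations are in-sample and optimistically biased
  by the selection procedure. Validate on held-out data.
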