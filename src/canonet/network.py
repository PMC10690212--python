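"""Consensus similarity matrix via feature subsampling, and module detection.

Each subsampling iteration draws a fraction of features per block, refits
the sparse CCA (or the binary hybrid) on the reduced data, and scatters the
resulting canonical weights back into full-length vectors. The similarity
matrix is the average absolute outer product of these weight snapshots,
max-normalized to [0, 1]; modules are found by average-linkage hierarchical
clustering of 1 - similarity cut at a fixed height.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .binary import run_hybrid
from .datatypes import (
    CanonetError,
    ModulePartition,
    MultiOmicsDataset,
    OmicsBlock,
    PenaltySpec,
    Phenotype,
    ScalingScheme,
    SimilarityMatrix,
    warn,
)
from .smcca import solve_smcca

logger = logging.getLogger("canonet.network")


def subsample_features(data: MultiOmicsDataset, fractions: list[float],
                       iteration_seed: int) -> list[np.ndarray]:
    """Per block, floor(fraction * p_t) distinct feature indices drawn
    uniformly without replacement (deterministic given the seed)."""
    rng = np.random.default_rng(iteration_seed)
    out = []
    for t, frac in enumerate(fractions):
        if not (0.0 < frac <= 1.0):
            raise CanonetError(f"subsample fraction {frac} outside (0, 1]")
        p = data.blocks[t].n_features
        size = max(1, int(np.floor(frac * p)))
        if size == 0:
            raise CanonetError(f"subsample of block {t} would be empty")
        if size == p:
            idx = np.arange(p)
        else:
            idx = np.sort(rng.choice(p, size=size, replace=False))
        out.append(idx)
    return out


def accumulate_similarity(weight_snapshots: list[np.ndarray],
                          feature_index: list[tuple[str, str]],
                          n_subsamples: int | None = None) -> SimilarityMatrix:
    """Mean |w w'| over snapshots, max-normalized, zero diagonal.

    Each snapshot must be a full-length concatenated weight vector with
    zeros at features that were not sampled in that iteration.
    """
    if not weight_snapshots:
        raise CanonetError("no weight snapshots to accumulate")
    p = len(feature_index)
    acc = np.zeros((p, p))
    for w in weight_snapshots:
        w = np.asarray(w, dtype=float)
        if w.shape != (p,):
            raise CanonetError("snapshot length does not match feature index")
        acc += np.abs(np.outer(w, w))
    acc /= len(weight_snapshots)
    np.fill_diagonal(acc, 0.0)
    m = acc.max()
    if m > 0:
        acc /= m
    acc = 0.5 * (acc + acc.T)  # enforce exact symmetry against fp drift
    return SimilarityMatrix(matrix=acc, feature_index=feature_index,
                            n_subsamples=n_subsamples or len(weight_snapshots))


def run_subsampling(
    data: MultiOmicsDataset,
    penalties: PenaltySpec,
    scaling: ScalingScheme,
    fractions: list[float],
    n_subsamples: int,
    seed: int,
    mode: str = "quantitative",
    binary_params: dict | None = None,
) -> SimilarityMatrix:
    """Repeat subsample -> fit -> scatter, then aggregate the snapshots.

    Per-iteration seeds are spawned deterministically from the master seed.
    Individual iteration failures are logged and skipped; more than 50%
    failures aborts.
    """
    if n_subsamples < 1:
        raise CanonetError("n_subsamples must be >= 1")
    if mode not in ("quantitative", "binary"):
        raise CanonetError(f"unknown subsampling mode {mode!r}")
    T = data.n_blocks
    p_sizes = [b.n_features for b in data.blocks]
    feature_index = data.feature_index()
    seeds = np.random.SeedSequence(seed).generate_state(n_subsamples)
    snapshots = []
    failures = 0
    for it in range(n_subsamples):
        idx_sets = subsample_features(data, fractions, int(seeds[it]))
        sub_blocks = [data.blocks[t].select_features(idx_sets[t]) for t in range(T)]
        sub_data = MultiOmicsDataset(blocks=sub_blocks, phenotype=data.phenotype)
        try:
            if mode == "quantitative":
                fit = solve_smcca(sub_data, scaling, penalties)
                per_block = fit.per_block
            else:
                params = binary_params or {}
                hybrid = run_hybrid(sub_data, penalties, **params)
                per_block = hybrid.weights.per_block
        except CanonetError as exc:
            failures += 1
            logger.warning("subsample iteration %d failed: %s", it, exc)
            continue
        full = np.zeros(sum(p_sizes))
        offset = 0
        for t in range(T):
            full[offset + idx_sets[t]] = per_block[t]
            offset += p_sizes[t]
        snapshots.append(full)
    if failures > 0.5 * n_subsamples or not snapshots:
        raise CanonetError(
            f"{failures}/{n_subsamples} subsampling iterations failed"
        )
    logger.info("aggregated %d weight snapshots (%d failures)",
                len(snapshots), failures)
    return accumulate_similarity(snapshots, feature_index,
                                 n_subsamples=n_subsamples)


def cluster_modules(similarity: SimilarityMatrix, cut_height: float,
                    min_size: int = 10) -> ModulePartition:
    """Average-linkage clustering of D = 1 - similarity, cut at
    ``cut_height``; clusters below ``min_size`` are discarded."""
    if not (0.0 < cut_height <= 1.0):
        raise CanonetError("cut_height must lie in (0, 1]")
    if min_size < 2:
        raise CanonetError("min_size must be >= 2")
    D = 1.0 - similarity.matrix
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    Z = linkage(condensed, method="average")
    labels = fcluster(Z, t=cut_height, criterion="distance")
    modules = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if members.size >= min_size:
            modules.append(members)
        else:
            logger.info("discarding cluster of size %d (< min_size %d)",
                        members.size, min_size)
    # larger modules first, ties by first member index, for stable numbering
    modules.sort(key=lambda m: (-m.size, int(m[0])))
    if not modules:
        warn("no cluster reached the minimum module size; empty partition")
    return ModulePartition(modules=modules, cut_height=cut_height,
                           linkage="average")
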