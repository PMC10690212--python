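"""Data preprocessing: CoV filtering, covariate regression, center/scale.

The recommended order is: :func:`filter_by_cov` (drop low-variability
features), :func:`regress_out_covariates` (remove clinical effects), then
:func:`center_scale` (restore zero mean / unit variance), and finally
:func:`align_dataset` to restrict all blocks and the phenotype to their
common subjects.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import (
    CanonetError,
    CovariateTable,
    EmptyBlockError,
    MultiOmicsDataset,
    OmicsBlock,
    Phenotype,
    warn,
)

logger = logging.getLogger("canonet.preprocess")


def coefficient_of_variation(matrix: np.ndarray) -> np.ndarray:
    """Per-column CoV = sample sd / |mean|.

    Columns with mean exactly 0 get +inf (informative after centering);
    columns with sd 0 get CoV 0 regardless of mean.
    """
    matrix = np.asarray(matrix, dtype=float)
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    cov = np.empty(matrix.shape[1])
    for j in range(matrix.shape[1]):
        if sd[j] == 0.0:
            cov[j] = 0.0
        elif mean[j] == 0.0:
            cov[j] = np.inf
        else:
            cov[j] = sd[j] / abs(mean[j])
    return cov


def filter_by_cov(block: OmicsBlock, threshold: float) -> OmicsBlock:
    """Keep features whose coefficient of variation is >= ``threshold``.

    Column order is preserved. Features with zero mean are treated as having
    infinite CoV (retained, with a warning); constant features have CoV 0 and
    are removed at any positive threshold.
    """
    if block.n_features < 1:
        raise EmptyBlockError(f"block {block.label!r} has no features")
    if threshold < 0:
        raise CanonetError("CoV threshold must be nonnegative")
    cov = coefficient_of_variation(block.matrix)
    if np.any(np.isinf(cov)):
        zero_mean = [block.feature_names[j] for j in np.flatnonzero(np.isinf(cov))]
        warn(
            f"block {block.label!r}: {len(zero_mean)} feature(s) with mean 0 "
            "treated as infinite CoV and retained"
        )
    keep = np.flatnonzero(cov >= threshold)
    if keep.size == 0:
        raise EmptyBlockError(
            f"CoV filter at threshold {threshold} removed every feature of "
            f"block {block.label!r}"
        )
    dropped = block.n_features - keep.size
    logger.info(
        "CoV filter (threshold %g) on block %r: kept %d of %d features (%d dropped)",
        threshold, block.label, keep.size, block.n_features, dropped,
    )
    return block.select_features(keep)


def regress_out_covariates(block: OmicsBlock, covariates: CovariateTable) -> OmicsBlock:
    """Replace every feature by its OLS residual on the covariates + intercept."""
    if covariates.subject_ids != block.subject_ids:
        raise CanonetError(
            f"covariate subjects do not match block {block.label!r} subjects"
        )
    n = block.n_subjects
    design = np.column_stack([np.ones(n), covariates.matrix])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CanonetError(
            "covariate design (with intercept) is rank deficient; drop "
            "collinear or constant covariates"
        )
    coef, *_ = np.linalg.lstsq(design, block.matrix, rcond=None)
    residuals = block.matrix - design @ coef
    logger.info(
        "regressed %d covariate(s) out of block %r (%d features)",
        covariates.matrix.shape[1], block.label, block.n_features,
    )
    return OmicsBlock(
        label=block.label,
        matrix=residuals,
        feature_names=list(block.feature_names),
        subject_ids=list(block.subject_ids),
    )


def center_scale(block: OmicsBlock) -> OmicsBlock:
    """Standardize each feature to mean 0, sample (n-1) standard deviation 1."""
    sd = block.matrix.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        names = [block.feature_names[j] for j in zero[:5]]
        raise CanonetError(
            f"block {block.label!r} has constant feature(s) {names}; run "
            "filter_by_cov with a positive threshold first"
        )
    standardized = (block.matrix - block.matrix.mean(axis=0)) / sd
    return OmicsBlock(
        label=block.label,
        matrix=standardized,
        feature_names=list(block.feature_names),
        subject_ids=list(block.subject_ids),
    )


def standardize_columns(matrix: np.ndarray) -> np.ndarray:
    """Array-level center/scale used internally on subsampled matrices."""
    matrix = np.asarray(matrix, dtype=float)
    sd = matrix.std(axis=0, ddof=1)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (matrix - matrix.mean(axis=0)) / sd


def align_dataset(blocks: list[OmicsBlock], phenotype: Phenotype) -> MultiOmicsDataset:
    """Restrict all blocks and the phenotype to their common subjects.

    The output subject order follows the first block's ordering restricted to
    the intersection, so it is invariant to row permutations of the other
    inputs.
    """
    if not blocks:
        raise CanonetError("need at least one omics block")
    common = set(blocks[0].subject_ids)
    for b in blocks[1:]:
        common &= set(b.subject_ids)
    common &= set(phenotype.subject_ids)
    if not common:
        raise CanonetError("no subject is shared by all blocks and the phenotype")
    order = [s for s in blocks[0].subject_ids if s in common]
    dropped = len(set(blocks[0].subject_ids) | set(phenotype.subject_ids)) - len(order)
    if dropped:
        logger.info("align_dataset: %d subject(s) dropped, %d retained", dropped, len(order))
    aligned_blocks = []
    for b in blocks:
        pos = {s: i for i, s in enumerate(b.subject_ids)}
        aligned_blocks.append(b.select_subjects(np.array([pos[s] for s in order])))
    ppos = {s: i for i, s in enumerate(phenotype.subject_ids)}
    aligned_pheno = phenotype.select_subjects(np.array([ppos[s] for s in order]))
    return MultiOmicsDataset(blocks=aligned_blocks, phenotype=aligned_pheno)


def preprocess_block(
    block: OmicsBlock,
    cov_threshold: float = 0.0,
    covariates: CovariateTable | None = None,
) -> OmicsBlock:
    """CoV filter -> optional covariate regression -> center/scale."""
    out = filter_by_cov(block, cov_threshold)
    if covariates is not None:
        out = regress_out_covariates(out, covariates)
    # residual columns can be constant only if the feature was covariate-
    # determined; center_scale raises a named error in that case
    return center_scale(out)
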