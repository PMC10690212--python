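"""Delimited-text readers/writers for omics matrices and pipeline artifacts.

All tabular inputs are CSV/TSV with a header row of feature names and a
first column of subject identifiers (the field's usual wide layout).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CanonetError, CovariateTable, OmicsBlock, Phenotype, SimilarityMatrix

logger = logging.getLogger("canonet.io")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df


def check_matrix_schema(df: pd.DataFrame, what: str) -> None:
    """Validate the subjects x features layout before constructing a block."""
    if df.shape[1] == 0:
        raise CanonetError(f"{what}: no feature columns found")
    if df.index.has_duplicates:
        raise CanonetError(f"{what}: duplicate subject identifiers")
    if df.columns.has_duplicates:
        raise CanonetError(f"{what}: duplicate feature names")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise CanonetError(f"{what}: non-numeric columns {non_numeric[:5]}")
    if df.isna().any().any():
        n_bad = int(df.isna().any(axis=1).sum())
        raise CanonetError(
            f"{what}: {n_bad} subject row(s) contain missing values; "
            "missing data is rejected, not imputed"
        )


def read_omics_block(path: str | Path, label: str) -> OmicsBlock:
    df = _read_table(path)
    check_matrix_schema(df, f"omics block {label!r} ({path})")
    logger.info("read block %r: %d subjects x %d features", label, *df.shape)
    return OmicsBlock(
        label=label,
        matrix=df.to_numpy(dtype=float),
        feature_names=[str(c) for c in df.columns],
        subject_ids=[str(i) for i in df.index],
    )


def read_phenotype(path: str | Path, modality: str | None = None) -> Phenotype:
    """Read a two-column (subject, value) phenotype file.

    When ``modality`` is None it is inferred: exactly two distinct values
    (or any non-numeric values) -> binary, otherwise quantitative.
    """
    df = _read_table(path)
    if df.shape[1] != 1:
        raise CanonetError(f"phenotype file {path} must have exactly one value column")
    values = df.iloc[:, 0].to_numpy()
    if modality is None:
        numeric = np.issubdtype(df.iloc[:, 0].dtype, np.number)
        distinct = len(set(values.tolist()))
        if distinct < 2:
            raise CanonetError("phenotype has fewer than 2 distinct values")
        if distinct == 2:
            modality = "binary"
            if numeric:
                logger.info(
                    "numeric phenotype with exactly 2 distinct values treated as "
                    "binary; pass modality='quantitative' to override"
                )
        elif not numeric:
            raise CanonetError(
                "phenotype has >2 distinct non-numeric values; not supported"
            )
        else:
            modality = "quantitative"
    return Phenotype(values=values, modality=modality,
                     subject_ids=[str(i) for i in df.index])


def read_covariates(path: str | Path) -> CovariateTable:
    df = _read_table(path)
    check_matrix_schema(df, f"covariates ({path})")
    return CovariateTable(
        matrix=df.to_numpy(dtype=float),
        names=[str(c) for c in df.columns],
        subject_ids=[str(i) for i in df.index],
    )


def write_omics_block(block: OmicsBlock, path: str | Path) -> None:
    df = pd.DataFrame(block.matrix, index=block.subject_ids, columns=block.feature_names)
    df.to_csv(path, sep="\t" if str(path).endswith((".tsv", ".txt")) else ",")


def write_similarity(sim: SimilarityMatrix, dense_path: str | Path,
                     triplet_path: str | Path | None = None) -> None:
    names = [f"{b}:{f}" for b, f in sim.feature_index]
    pd.DataFrame(sim.matrix, index=names, columns=names).to_csv(dense_path, sep="\t")
    if triplet_path is not None:
        iu = np.triu_indices_from(sim.matrix, k=1)
        mask = sim.matrix[iu] > 0
        rows = pd.DataFrame({
            "feature_a": [names[i] for i in iu[0][mask]],
            "feature_b": [names[j] for j in iu[1][mask]],
            "similarity": sim.matrix[iu][mask],
        })
        rows.to_csv(triplet_path, sep="\t", index=False)
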