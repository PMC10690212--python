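"""Core in-memory containers shared across the pipeline.

The central object is :class:`MultiOmicsDataset`: a list of subject-aligned
omics blocks (subjects x features each) plus a phenotype, which every stage
of the workflow consumes. Canonical weights, similarity matrices, module
partitions and prune traces are the stage outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class CanonetError(ValueError):
    """Base class for user-facing validation errors."""


class EmptyBlockError(CanonetError):
    """Raised when an operation would leave an omics block with no features."""


@dataclass
class OmicsBlock:
    """One omics data type: a subjects x features real matrix.

    Parameters
    ----------
    label : str
        Short tag for the data type, e.g. ``"Gene"`` or ``"miRNA"``.
    matrix : ndarray of shape (n_subjects, n_features)
    feature_names : list of str
        Unique column identifiers.
    subject_ids : list of str
        Unique row identifiers.
    """

    label: str
    matrix: np.ndarray
    feature_names: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise CanonetError(f"block {self.label!r}: matrix must be 2-D")
        n, p = self.matrix.shape
        if n != len(self.subject_ids):
            raise CanonetError(
                f"block {self.label!r}: {n} rows but {len(self.subject_ids)} subject ids"
            )
        if p != len(self.feature_names):
            raise CanonetError(
                f"block {self.label!r}: {p} columns but {len(self.feature_names)} feature names"
            )
        if len(set(self.feature_names)) != p:
            raise CanonetError(f"block {self.label!r}: duplicate feature names")
        if len(set(self.subject_ids)) != n:
            raise CanonetError(f"block {self.label!r}: duplicate subject ids")
        if not np.all(np.isfinite(self.matrix)):
            raise CanonetError(
                f"block {self.label!r}: missing or non-finite values are not supported; "
                "remove or impute them upstream"
            )

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def select_features(self, idx: np.ndarray) -> "OmicsBlock":
        idx = np.asarray(idx, dtype=int)
        return OmicsBlock(
            label=self.label,
            matrix=self.matrix[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            subject_ids=list(self.subject_ids),
        )

    def select_subjects(self, idx: np.ndarray) -> "OmicsBlock":
        idx = np.asarray(idx, dtype=int)
        return OmicsBlock(
            label=self.label,
            matrix=self.matrix[idx, :],
            feature_names=list(self.feature_names),
            subject_ids=[self.subject_ids[i] for i in idx],
        )


@dataclass
class Phenotype:
    """Phenotype of interest: quantitative real values or binary labels.

    Binary phenotypes are coded 0/1 internally with the lexicographically
    smaller original label mapped to 0 (deterministic coding).
    """

    values: np.ndarray
    modality: str  # "quantitative" | "binary"
    subject_ids: list[str]
    labels: tuple | None = None  # original (label0, label1) for binary

    def __post_init__(self) -> None:
        if self.modality not in ("quantitative", "binary"):
            raise CanonetError(f"unknown phenotype modality {self.modality!r}")
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise CanonetError("phenotype values must be a 1-D vector")
        if len(self.values) != len(self.subject_ids):
            raise CanonetError("phenotype length does not match subject ids")
        if self.modality == "binary":
            uniq = sorted(set(self.values.tolist()), key=lambda x: str(x))
            if len(uniq) != 2:
                raise CanonetError(
                    f"binary phenotype must have exactly 2 distinct labels, got {len(uniq)}"
                )
            if self.labels is None:
                self.labels = (uniq[0], uniq[1])
            coded = np.where(self.values == self.labels[1], 1.0, 0.0)
            self.values = coded
        else:
            self.values = self.values.astype(float)
            if not np.all(np.isfinite(self.values)):
                raise CanonetError("quantitative phenotype contains non-finite values")

    def select_subjects(self, idx: np.ndarray) -> "Phenotype":
        idx = np.asarray(idx, dtype=int)
        out = Phenotype.__new__(Phenotype)
        out.values = self.values[idx]
        out.modality = self.modality
        out.subject_ids = [self.subject_ids[i] for i in idx]
        out.labels = self.labels
        return out


@dataclass
class CovariateTable:
    """Subjects x covariates design used by covariate regression."""

    matrix: np.ndarray
    names: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise CanonetError("covariate matrix must be 2-D")
        if self.matrix.shape[1] != len(self.names):
            raise CanonetError("covariate names do not match matrix width")
        if self.matrix.shape[0] != len(self.subject_ids):
            raise CanonetError("covariate subject ids do not match matrix height")


@dataclass
class MultiOmicsDataset:
    """Subject-aligned omics blocks plus phenotype."""

    blocks: list[OmicsBlock]
    phenotype: Phenotype

    def __post_init__(self) -> None:
        ids = self.phenotype.subject_ids
        for b in self.blocks:
            if b.subject_ids != ids:
                raise CanonetError(
                    f"block {b.label!r} subjects are not aligned with the phenotype; "
                    "run align_dataset first"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.phenotype.subject_ids)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def block_labels(self) -> list[str]:
        return [b.label for b in self.blocks]

    def feature_index(self) -> list[tuple[str, str]]:
        """(block label, feature name) for the concatenated feature order."""
        out: list[tuple[str, str]] = []
        for b in self.blocks:
            out.extend((b.label, f) for f in b.feature_names)
        return out

    def select_subjects(self, idx: np.ndarray) -> "MultiOmicsDataset":
        return MultiOmicsDataset(
            blocks=[b.select_subjects(idx) for b in self.blocks],
            phenotype=self.phenotype.select_subjects(idx),
        )


@dataclass
class ScalingScheme:
    """Objective weights: a_{i,j} for block pairs, b_i for block-phenotype.

    ``between[i, j]`` weights the (i, j) between-omics correlation term and
    ``pheno[i]`` the block-i/phenotype term of the sparse multiple CCA
    objective.
    """

    between: np.ndarray  # (T, T) symmetric, diagonal ignored
    pheno: np.ndarray  # (T,)

    def __post_init__(self) -> None:
        self.between = np.asarray(self.between, dtype=float)
        self.pheno = np.asarray(self.pheno, dtype=float)
        T = self.pheno.shape[0]
        if self.between.shape != (T, T):
            raise CanonetError("between-omics scaling table has wrong shape")
        if not np.allclose(self.between, self.between.T):
            raise CanonetError("between-omics scaling table must be symmetric")
        if np.any(self.between < 0) or np.any(self.pheno < 0):
            raise CanonetError("scaling factors must be nonnegative")
        off = self.between[np.triu_indices(T, k=1)]
        if T > 0 and not (np.any(off > 0) or np.any(self.pheno > 0)):
            raise CanonetError("at least one scaling factor must be positive")

    @classmethod
    def unweighted(cls, n_blocks: int, include_phenotype: bool = True) -> "ScalingScheme":
        between = np.ones((n_blocks, n_blocks))
        np.fill_diagonal(between, 0.0)
        pheno = np.ones(n_blocks) if include_phenotype else np.zeros(n_blocks)
        return cls(between=between, pheno=pheno)

    def scaled(self, factor: float) -> "ScalingScheme":
        return ScalingScheme(between=self.between * factor, pheno=self.pheno * factor)


@dataclass
class PenaltySpec:
    """Per-block sparsity levels l_t in (0, 1].

    The L1 budget for block t is c_t = l_t * sqrt(p_t) (clamped below at 1 so
    the unit-L2 constraint stays feasible); l_t = 1 means no active penalty
    for any block, smaller values mean sparser weights.
    """

    per_block: list[float]

    def __post_init__(self) -> None:
        for l in self.per_block:
            if not (0.0 < l <= 1.0):
                raise CanonetError(f"penalty level {l} outside (0, 1]")

    def l1_budget(self, t: int, p_t: int) -> float:
        return max(1.0, self.per_block[t] * np.sqrt(p_t))


@dataclass
class CanonicalWeights:
    """Per-block sparse canonical weight vectors with unit L2 norm."""

    per_block: list[np.ndarray]
    converged: bool
    objective: float
    n_iterations: int = 0
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.per_block = [np.asarray(w, dtype=float) for w in self.per_block]
        for t, w in enumerate(self.per_block):
            nrm = float(np.linalg.norm(w))
            if nrm > 0 and abs(nrm - 1.0) > 1e-8:
                raise CanonetError(f"block {t} weight vector is not unit L2 norm ({nrm})")

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.per_block)


@dataclass
class SimilarityMatrix:
    """Symmetric consensus feature x feature similarity in [0, 1], diagonal 0."""

    matrix: np.ndarray
    feature_index: list[tuple[str, str]]  # (block label, feature name)
    n_subsamples: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        p = self.matrix.shape[0]
        if self.matrix.shape != (p, p) or p != len(self.feature_index):
            raise CanonetError("similarity matrix shape does not match feature index")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise CanonetError("similarity matrix must be symmetric")
        if np.any(self.matrix < 0) or np.any(self.matrix > 1 + 1e-12):
            raise CanonetError("similarity entries must lie in [0, 1]")
        if np.any(np.abs(np.diag(self.matrix)) > 0):
            raise CanonetError("similarity diagonal must be zero")


@dataclass
class ModulePartition:
    """Feature-to-module assignment from cutting the hierarchical tree."""

    modules: list[np.ndarray]  # each: indices into the similarity feature index
    cut_height: float
    linkage: str = "average"

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for m in self.modules:
            s = set(int(i) for i in m)
            if seen & s:
                raise CanonetError("modules must be disjoint")
            seen |= s


@dataclass
class SummarizationResult:
    """Up to 3 principal-component summarization scores for a module."""

    scores: np.ndarray  # (n_subjects, k<=3)
    loadings: np.ndarray  # (n_columns, k<=3)
    method: str  # "pca" | "netshy"


@dataclass
class PruneTrace:
    """Full record of the pruning search over candidate network sizes."""

    m1: int
    m2: int
    ranked_features: np.ndarray  # module-local indices ordered by PageRank
    rho_pheno: dict[int, float]  # size -> signed rho(i, pheno)
    rho_base: dict[int, float]  # size -> |rho(m*, i)|
    m_star: int
    x: int
    m_opt: int

    def __post_init__(self) -> None:
        if not (self.m1 <= self.m_star <= self.m_opt <= self.x <= self.m2):
            raise CanonetError(
                f"prune landmarks out of order: m1={self.m1} m*={self.m_star} "
                f"m_opt={self.m_opt} x={self.x} m2={self.m2}"
            )


@dataclass
class PrunedModule:
    """A phenotype-associated subnetwork after pruning."""

    feature_idx: np.ndarray  # indices into the dataset's concatenated features
    feature_index: list[tuple[str, str]]
    adjacency: np.ndarray  # induced similarity submatrix
    summarization: SummarizationResult
    correlation_to_phenotype: float
    which_pc: int
    trace: PruneTrace

    def __post_init__(self) -> None:
        if len(self.feature_idx) != self.trace.m_opt:
            raise CanonetError("pruned module size does not equal trace m_opt")


def warn(message: str) -> None:
    """Single funnel for runtime warnings so tests can capture them."""
    warnings.warn(message, stacklevel=3)
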