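"""Penalty and scaling-factor selection by K-fold cross-validation.

The quantitative loss is the scaled prediction error
|trainCC - testCC| / |testCC|, which both penalizes train/test discrepancy
and rewards a large held-out canonical correlation. Binary models are scored
by classification metrics (accuracy, AUC, precision, recall, F1) on held-out
folds. Three scaling-factor schemes are provided: manual entry, an automated
pairwise-correlation heuristic with a shrinkage divisor, and a nested CV
grid search.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skmetrics

from .binary import HybridFit, predict_proba, run_hybrid
from .datatypes import (
    CanonetError,
    MultiOmicsDataset,
    PenaltySpec,
    ScalingScheme,
)
from .smcca import score_correlations, solve_smcca

logger = logging.getLogger("canonet.selection")

EVAL_METHODS = ("accuracy", "auc", "precision", "recall", "f1")
STRINGENT_PENALTY = 0.1  # used for the preliminary pairwise correlations


def scaled_prediction_error(trainCC: float, testCC: float) -> float:
    """|trainCC - testCC| / |testCC|; +inf when testCC is 0."""
    if testCC == 0:
        return float("inf")
    return abs(trainCC - testCC) / abs(testCC)


@dataclass
class PenaltyGrid:
    """Cartesian product of per-block (and optional classifier) candidates."""

    per_block: list[list[float]]
    classifier: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.per_block or any(len(c) == 0 for c in self.per_block):
            raise CanonetError("penalty candidate lists must be nonempty")
        if self.classifier is not None and len(self.classifier) == 0:
            raise CanonetError("classifier candidate list must be nonempty")
        for lst in self.per_block + ([self.classifier] if self.classifier else []):
            for l in lst:
                if not (0.0 < l <= 1.0):
                    raise CanonetError(f"penalty candidate {l} outside (0, 1]")

    def combinations(self) -> list[tuple[float, ...]]:
        """Row-major enumeration; classifier candidate is the last element."""
        lists = list(self.per_block)
        if self.classifier is not None:
            lists.append(list(self.classifier))
        return list(itertools.product(*lists))

    @property
    def n_combinations(self) -> int:
        n = 1
        for lst in self.per_block:
            n *= len(lst)
        if self.classifier is not None:
            n *= len(self.classifier)
        return n


def build_penalty_grid(per_block_candidates: list[list[float]],
                       classifier_candidates: list[float] | None = None
                       ) -> PenaltyGrid:
    return PenaltyGrid(per_block=[list(c) for c in per_block_candidates],
                       classifier=list(classifier_candidates)
                       if classifier_candidates is not None else None)


@dataclass
class CVRecord:
    penalties: tuple[float, ...]
    train_cc: float = float("nan")
    test_cc: float = float("nan")
    loss: float = float("nan")
    metric_name: str = "scaled_prediction_error"


@dataclass
class CVResult:
    records: list[CVRecord]
    best: CVRecord
    metric_name: str
    higher_is_better: bool = False


def kfold_split(n: int, K: int, seed: int,
                stratify_labels: np.ndarray | None = None) -> np.ndarray:
    """Deterministic fold assignment (values 0..K-1), sizes differing by <=1.

    With ``stratify_labels`` each class is distributed round-robin across
    folds; an error is raised if some training fold would lose a class.
    """
    if not (2 <= K <= n):
        raise CanonetError(f"K={K} must satisfy 2 <= K <= n={n}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if stratify_labels is None:
        order = rng.permutation(n)
        assignment[order] = np.arange(n) % K
    else:
        labels = np.asarray(stratify_labels)
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            order = rng.permutation(idx.size)
            assignment[idx[order]] = np.arange(idx.size) % K
        for k in range(K):
            train = labels[assignment != k]
            if np.unique(train).size < np.unique(labels).size:
                raise CanonetError(
                    f"a class is absent from the training split of fold {k}; "
                    "use a smaller K"
                )
    return assignment


def weighted_cc(data: MultiOmicsDataset, weights, scaling: ScalingScheme) -> float:
    """Scaling-weighted sum of pairwise score correlations, weights
    normalized to sum to 1."""
    corrs = score_correlations(data, weights)
    T = data.n_blocks
    total_w = 0.0
    acc = 0.0
    for i in range(T):
        for j in range(i + 1, T):
            a = scaling.between[i, j]
            if a > 0:
                acc += a * corrs[(i, j)]
                total_w += a
        b = scaling.pheno[i]
        if b > 0:
            acc += b * corrs[i]
            total_w += b
    if total_w == 0:
        raise CanonetError("all scaling factors are zero")
    return acc / total_w


def _tie_key(rec: CVRecord) -> tuple:
    return rec.penalties


def cv_quantitative(data: MultiOmicsDataset, grid: PenaltyGrid,
                    scaling: ScalingScheme, K: int, seed: int) -> CVResult:
    """K-fold CV over the penalty grid, minimizing the scaled prediction error.

    Per combination: fit on each training split, evaluate the weighted
    canonical correlation on train and test subjects, average each across
    folds, then apply the loss once to the averages. Ties break toward the
    smallest penalties in lexicographic block order.
    """
    if data.phenotype.modality != "quantitative":
        raise CanonetError("cv_quantitative requires a quantitative phenotype")
    if grid.classifier is not None:
        raise CanonetError("classifier candidates are for binary CV only")
    folds = kfold_split(data.n_subjects, K, seed)
    records = []
    for combo in grid.combinations():
        spec = PenaltySpec(per_block=list(combo))
        train_ccs, test_ccs = [], []
        for k in range(K):
            train = data.select_subjects(np.flatnonzero(folds != k))
            test = data.select_subjects(np.flatnonzero(folds == k))
            w = solve_smcca(train, scaling, spec)
            train_ccs.append(weighted_cc(train, w, scaling))
            test_ccs.append(weighted_cc(test, w, scaling))
        rec = CVRecord(penalties=combo,
                       train_cc=float(np.mean(train_ccs)),
                       test_cc=float(np.mean(test_ccs)))
        rec.loss = scaled_prediction_error(rec.train_cc, rec.test_cc)
        records.append(rec)
        logger.debug("CV %s: trainCC %.4f testCC %.4f loss %.4f",
                     combo, rec.train_cc, rec.test_cc, rec.loss)
    best = min(records, key=lambda r: (r.loss, _tie_key(r)))
    return CVResult(records=records, best=best,
                    metric_name="scaled_prediction_error", higher_is_better=False)


def classification_metrics(labels: np.ndarray, scores: np.ndarray
                           ) -> dict[str, float]:
    """Accuracy, AUC, precision, recall and F1 for probability scores.

    AUC is the pairwise-concordance probability with half credit for ties;
    thresholded metrics predict class 1 when the score exceeds 0.5.
    """
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise CanonetError("classification metrics need both classes present")
    pred = (scores > 0.5).astype(float)
    return {
        "accuracy": float(skmetrics.accuracy_score(labels, pred)),
        "auc": float(skmetrics.roc_auc_score(labels, scores)),
        "precision": float(skmetrics.precision_score(labels, pred, zero_division=0)),
        "recall": float(skmetrics.recall_score(labels, pred, zero_division=0)),
        "f1": float(skmetrics.f1_score(labels, pred, zero_division=0)),
    }


def cv_binary(data: MultiOmicsDataset, grid: PenaltyGrid, K: int, seed: int,
              eval_method: str = "auc", gamma1: float = 1.0, gamma2: float = 1.0,
              R: int = 3) -> CVResult:
    """K-fold CV of the full hybrid algorithm, maximizing a classification
    metric on held-out subjects."""
    if data.phenotype.modality != "binary":
        raise CanonetError("cv_binary requires a binary phenotype")
    if eval_method not in EVAL_METHODS:
        raise CanonetError(
            f"unknown eval_method {eval_method!r}; valid: {', '.join(EVAL_METHODS)}"
        )
    T = data.n_blocks
    folds = kfold_split(data.n_subjects, K, seed,
                        stratify_labels=data.phenotype.values)
    records = []
    for combo in grid.combinations():
        if grid.classifier is not None:
            smcca_pen, spls_pen = list(combo[:T]), combo[T]
        else:
            smcca_pen, spls_pen = list(combo), 0.9
        vals = []
        for k in range(K):
            train = data.select_subjects(np.flatnonzero(folds != k))
            test = data.select_subjects(np.flatnonzero(folds == k))
            try:
                fit = run_hybrid(train, PenaltySpec(per_block=smcca_pen),
                                 splsda_penalty=spls_pen, gamma1=gamma1,
                                 gamma2=gamma2, R=R)
            except CanonetError as exc:
                logger.debug("combination %s failed on fold %d: %s", combo, k, exc)
                vals.append(0.0)
                continue
            proba = predict_proba(fit, [b.matrix for b in test.blocks])
            vals.append(classification_metrics(test.phenotype.values, proba)[eval_method])
        rec = CVRecord(penalties=combo, loss=float(np.mean(vals)),
                       metric_name=eval_method)
        records.append(rec)
    best = max(records, key=lambda r: (r.loss, tuple(-p for p in r.penalties)))
    return CVResult(records=records, best=best, metric_name=eval_method,
                    higher_is_better=True)


def auto_scaling_factors(pairwise_cc: np.ndarray, shrinkage: float) -> ScalingScheme:
    """Between-omics factors |cc_ij| / shrinkage; phenotype factors all 1.

    ``pairwise_cc`` is a symmetric (T, T) table of preliminary canonical
    correlations (diagonal ignored). A larger shrinkage down-weights the
    between-omics terms relative to the omics-phenotype terms.
    """
    if shrinkage <= 0:
        raise CanonetError("shrinkage must be positive")
    cc = np.asarray(pairwise_cc, dtype=float)
    if np.any(np.abs(cc) > 1 + 1e-12):
        raise CanonetError("pairwise canonical correlations must lie in [-1, 1]")
    T = cc.shape[0]
    between = np.abs(cc) / shrinkage
    np.fill_diagonal(between, 0.0)
    return ScalingScheme(between=between, pheno=np.ones(T))


def pairwise_preliminary_cc(data: MultiOmicsDataset,
                            penalty: float = STRINGENT_PENALTY) -> np.ndarray:
    """Training canonical correlation for every block pair from a stringent
    two-block sparse CCA fit."""
    T = data.n_blocks
    if T < 2:
        raise CanonetError("need at least 2 blocks for pairwise correlations")
    cc = np.zeros((T, T))
    for i in range(T):
        for j in range(i + 1, T):
            pair = MultiOmicsDataset(blocks=[data.blocks[i], data.blocks[j]],
                                     phenotype=data.phenotype)
            scheme = ScalingScheme(between=np.array([[0.0, 1.0], [1.0, 0.0]]),
                                   pheno=np.zeros(2))
            w = solve_smcca(pair, scheme, PenaltySpec(per_block=[penalty, penalty]),
                            include_phenotype=False)
            corr = score_correlations(pair, w)[(0, 1)]
            cc[i, j] = cc[j, i] = corr
    return cc


def candidate_scaling_schemes(n_blocks: int, step: float = 0.1
                              ) -> list[ScalingScheme]:
    """Simplex grid over phenotype weights (sum 1, step ``step``), with all
    between-omics weights fixed at 1."""
    n_steps = int(round(1.0 / step))
    schemes = []
    between = np.ones((n_blocks, n_blocks))
    np.fill_diagonal(between, 0.0)
    for combo in itertools.product(range(n_steps + 1), repeat=n_blocks):
        if sum(combo) != n_steps:
            continue
        pheno = np.array(combo, dtype=float) * step
        if np.all(pheno == 0):
            continue
        schemes.append(ScalingScheme(between=between.copy(), pheno=pheno))
    return schemes


def cv_scaling_search(data: MultiOmicsDataset,
                      candidate_schemes: list[ScalingScheme],
                      grid: PenaltyGrid, K: int, seed: int
                      ) -> tuple[ScalingScheme, CVRecord, CVResult]:
    """Nested grid search: for each candidate scaling scheme run penalty CV
    and return the scheme (with its best penalties) minimizing the loss."""
    if not candidate_schemes:
        raise CanonetError("need at least one candidate scaling scheme")
    best_scheme, best_result = None, None
    for scheme in candidate_schemes:
        result = cv_quantitative(data, grid, scheme, K, seed)
        if best_result is None or result.best.loss < best_result.best.loss:
            best_scheme, best_result = scheme, result
    return best_scheme, best_result.best, best_result
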