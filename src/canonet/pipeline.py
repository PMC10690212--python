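"""Automated end-to-end pipeline: preprocess, mode detection, heuristics,
cross-validation, subsampling, clustering, pruning and persistence.

All randomness flows from a single master seed in the configuration; the
same configuration and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .binary import run_hybrid
from .datatypes import (
    CanonetError,
    MultiOmicsDataset,
    ModulePartition,
    PenaltySpec,
    Phenotype,
    PrunedModule,
    ScalingScheme,
    SimilarityMatrix,
)
from .io import (
    read_covariates,
    read_omics_block,
    read_phenotype,
    write_similarity,
)
from .network import cluster_modules, run_subsampling
from .preprocess import align_dataset, preprocess_block
from .prune import prune_network
from .selection import (
    CVResult,
    PenaltyGrid,
    auto_scaling_factors,
    build_penalty_grid,
    cv_binary,
    cv_quantitative,
    pairwise_preliminary_cc,
)

logger = logging.getLogger("canonet.pipeline")

SUMMARY_COLUMNS_PREFIX = ["module_index", "size", "pc_correlation_to_phenotype"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run (also serialized to the manifest)."""

    block_paths: list[str] = field(default_factory=list)
    block_labels: list[str] = field(default_factory=list)
    phenotype_path: str = ""
    modality: str | None = None  # override: "quantitative" | "binary"
    covariate_path: str | None = None
    cov_threshold: float = 0.0
    k_folds: int = 5
    n_subsamples: int = 100
    cut_height: float = 0.995
    summarization: str = "netshy"
    between_shrinkage: float = 2.0
    gamma_shrinkage: float | None = None  # binary mode; defaults to between_shrinkage
    m1: int = 10
    m2: int = 100
    eval_method: str = "auc"
    seed: int = 0
    out_dir: str = "canonet_results"
    penalty_grid: list[list[float]] | None = None
    classifier_grid: list[float] | None = None
    subsample_fractions: list[float] | None = None
    edge_threshold: float = 0.0

    def validate(self) -> None:
        if self.k_folds < 2:
            raise CanonetError("k_folds must be >= 2")
        if self.n_subsamples < 1:
            raise CanonetError("n_subsamples must be >= 1")
        if not (0.0 < self.cut_height <= 1.0):
            raise CanonetError("cut_height must lie in (0, 1]")
        if self.summarization not in ("pca", "netshy"):
            raise CanonetError("summarization must be 'pca' or 'netshy'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise CanonetError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunResult:
    config: RunConfig
    mode: str
    scaling: ScalingScheme | None
    gammas: tuple[float, float] | None
    best_penalties: tuple[float, ...]
    cv: CVResult | None
    similarity: SimilarityMatrix
    partition: ModulePartition
    pruned: list[PrunedModule]
    summary: pd.DataFrame


def detect_mode(blocks, phenotype: Phenotype) -> str:
    """One of single-/multi- x quantitative/binary."""
    if not blocks:
        raise CanonetError("need at least one omics block")
    distinct = len(set(np.asarray(phenotype.values).tolist()))
    if distinct < 2:
        raise CanonetError("phenotype has a single distinct value")
    prefix = "single" if len(blocks) == 1 else "multi"
    return f"{prefix}-{phenotype.modality}"


def auto_subsample_fraction(p: int) -> float:
    """0.9 for blocks narrower than 300 features, else 0.7."""
    if p < 1:
        raise CanonetError("feature count must be >= 1")
    return 0.9 if p < 300 else 0.7


def auto_gamma(pairwise_cc: np.ndarray) -> tuple[float, float]:
    """gamma1 = mean |pairwise canonical correlation|, gamma2 = 1."""
    cc = np.asarray(pairwise_cc, dtype=float)
    T = cc.shape[0]
    pairs = [abs(cc[i, j]) for i in range(T) for j in range(i + 1, T)]
    if not pairs:
        raise CanonetError("no block pairs to average")
    return float(np.mean(pairs)), 1.0


def default_grids(mode: str, n_blocks: int) -> PenaltyGrid:
    """Quantitative: 0.1..0.5 per block; binary: 0.5..0.9 per block plus the
    classifier penalty."""
    quant = [round(0.1 * i, 1) for i in range(1, 6)]
    binary = [round(0.1 * i, 1) for i in range(5, 10)]
    if mode.endswith("quantitative"):
        return build_penalty_grid([quant] * n_blocks)
    if mode.endswith("binary"):
        return build_penalty_grid([binary] * n_blocks, binary)
    raise CanonetError(f"unknown mode {mode!r}")


def _load_inputs(config: RunConfig) -> MultiOmicsDataset:
    labels = config.block_labels or [f"block{i + 1}" for i in range(len(config.block_paths))]
    blocks = [read_omics_block(p, lab) for p, lab in zip(config.block_paths, labels)]
    phenotype = read_phenotype(config.phenotype_path, modality=config.modality)
    covariates = read_covariates(config.covariate_path) if config.covariate_path else None
    processed = []
    for b in blocks:
        cov = covariates
        if cov is not None:
            keep = [cov.subject_ids.index(s) for s in b.subject_ids]
            cov = dataclasses.replace(
                cov,
                matrix=cov.matrix[keep],
                subject_ids=[cov.subject_ids[i] for i in keep],
            )
        processed.append(preprocess_block(b, config.cov_threshold, cov))
    return align_dataset(processed, phenotype)


def run_pipeline(config: RunConfig,
                 data: MultiOmicsDataset | None = None) -> RunResult:
    """Execute the full workflow and persist every artifact to out_dir."""
    config.validate()
    if data is None:
        data = _load_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mode = detect_mode(data.blocks, data.phenotype)
    T = data.n_blocks
    logger.info("pipeline mode: %s (%d blocks, %d subjects)", mode, T, data.n_subjects)

    stage = "scaling"
    try:
        scaling: ScalingScheme | None = None
        gammas: tuple[float, float] | None = None
        binary_params: dict = {}
        if mode == "multi-quantitative":
            cc = pairwise_preliminary_cc(data)
            scaling = auto_scaling_factors(cc, config.between_shrinkage)
            logger.info("automated scaling factors (3 dp): between=%s pheno=%s",
                        np.round(scaling.between, 3).tolist(),
                        np.round(scaling.pheno, 3).tolist())
        elif mode == "single-quantitative":
            scaling = ScalingScheme(between=np.zeros((1, 1)), pheno=np.ones(1))
        elif mode == "multi-binary":
            cc = pairwise_preliminary_cc(data)
            shrink = config.gamma_shrinkage or config.between_shrinkage
            stage1_scaling = auto_scaling_factors(cc, shrink)
            g1, g2 = auto_gamma(cc)
            gammas = (g1, g2)
            scaling = stage1_scaling
            binary_params = {"gamma1": g1, "gamma2": g2}
        else:  # single-binary
            gammas = (0.0, 1.0)

        stage = "cross-validation"
        if config.penalty_grid is not None:
            grid = build_penalty_grid(config.penalty_grid, config.classifier_grid)
        else:
            grid = default_grids(mode, T)
        if mode.endswith("quantitative"):
            cv = cv_quantitative(data, grid, scaling, config.k_folds, config.seed)
            best = cv.best.penalties
            penalties = PenaltySpec(per_block=list(best))
        else:
            cv = cv_binary(data, grid, config.k_folds, config.seed,
                           eval_method=config.eval_method,
                           gamma1=gammas[0] if gammas else 1.0,
                           gamma2=gammas[1] if gammas else 1.0)
            best = cv.best.penalties
            if grid.classifier is not None:
                penalties = PenaltySpec(per_block=list(best[:T]))
                binary_params["splsda_penalty"] = best[T]
            else:
                penalties = PenaltySpec(per_block=list(best))
        _write_cv_table(cv, out / "cv_table.tsv")
        logger.info("selected penalties: %s", best)

        stage = "subsampling"
        fractions = config.subsample_fractions or [
            auto_subsample_fraction(b.n_features) for b in data.blocks
        ]
        sub_mode = "binary" if mode.endswith("binary") else "quantitative"
        similarity = run_subsampling(
            data, penalties, scaling or ScalingScheme.unweighted(T),
            fractions, config.n_subsamples, config.seed,
            mode=sub_mode, binary_params=binary_params or None,
        )
        write_similarity(similarity, out / "similarity.tsv",
                         out / "similarity_triplets.tsv")

        stage = "clustering"
        partition = cluster_modules(similarity, config.cut_height,
                                    min_size=config.m1)

        stage = "pruning"
        pruned = []
        for mi, members in enumerate(partition.modules, start=1):
            try:
                pm = prune_network(members, similarity, data,
                                   m1=config.m1, m2=config.m2,
                                   method=config.summarization)
            except CanonetError as exc:
                logger.warning("module %d could not be pruned: %s", mi, exc)
                continue
            pruned.append(pm)
            mod_dir = out / f"module_{mi}"
            _write_module(pm, data, mod_dir)
            export_module_graph(pm, data, config.edge_threshold, mod_dir)

        stage = "summary"
        summary = summary_table(pruned, data.block_labels)
        summary.to_csv(out / "summary_table.tsv", sep="\t", index=False)
        _write_manifest(config, mode, best, out)
    except CanonetError:
        (Path(config.out_dir) / "PARTIAL_RESULTS").write_text(
            f"pipeline aborted during stage: {stage}\n")
        logger.error("pipeline aborted during stage %r", stage)
        raise

    return RunResult(config=config, mode=mode, scaling=scaling, gammas=gammas,
                     best_penalties=best, cv=cv, similarity=similarity,
                     partition=partition, pruned=pruned, summary=summary)


def summary_table(pruned: list[PrunedModule], block_labels: list[str]
                  ) -> pd.DataFrame:
    """Run-level summary: module index, size, best-PC phenotype correlation
    and per-block feature counts (which sum to the size)."""
    rows = []
    for mi, pm in enumerate(pruned, start=1):
        row = {
            "module_index": mi,
            "size": int(len(pm.feature_idx)),
            "pc_correlation_to_phenotype": round(float(pm.correlation_to_phenotype), 5),
        }
        for lab in block_labels:
            row[f"n_{lab}"] = sum(1 for b, _ in pm.feature_index if b == lab)
        rows.append(row)
    cols = SUMMARY_COLUMNS_PREFIX + [f"n_{lab}" for lab in block_labels]
    return pd.DataFrame(rows, columns=cols)


def _write_cv_table(cv: CVResult, path: Path) -> None:
    rows = []
    for rec in cv.records:
        rows.append({
            "penalties": ",".join(f"{p:g}" for p in rec.penalties),
            "train_cc": rec.train_cc,
            "test_cc": rec.test_cc,
            "metric": rec.metric_name,
            "value": rec.loss,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_module(pm: PrunedModule, data: MultiOmicsDataset, mod_dir: Path) -> None:
    mod_dir.mkdir(parents=True, exist_ok=True)
    from .prune import pagerank_scores

    pr = pagerank_scores(pm.adjacency) if len(pm.feature_idx) >= 2 else np.ones(1)
    k = pm.summarization.loadings.shape[1]
    n_feat = len(pm.feature_idx)
    feat_rows = []
    for local, (blab, fname) in enumerate(pm.feature_index):
        row = {"feature": fname, "block": blab, "pagerank": pr[local]}
        for c in range(min(3, k)):
            # NetSHy loadings cover [X, XL]; report the X part per feature
            row[f"loading_pc{c + 1}"] = float(pm.summarization.loadings[local, c]) \
                if local < pm.summarization.loadings.shape[0] else np.nan
        feat_rows.append(row)
    pd.DataFrame(feat_rows).to_csv(mod_dir / "features.tsv", sep="\t", index=False)
    names = [f"{b}:{f}" for b, f in pm.feature_index]
    pd.DataFrame(pm.adjacency, index=names, columns=names).to_csv(
        mod_dir / "adjacency.tsv", sep="\t")
    pd.DataFrame(
        pm.summarization.scores,
        index=data.phenotype.subject_ids,
        columns=[f"PC{c + 1}" for c in range(pm.summarization.scores.shape[1])],
    ).to_csv(mod_dir / "scores.tsv", sep="\t")
    tr = pm.trace
    trace_rows = [{"size": i, "rho_pheno": tr.rho_pheno[i],
                   "rho_base": tr.rho_base.get(i, np.nan)}
                  for i in sorted(tr.rho_pheno)]
    pd.DataFrame(trace_rows).to_csv(mod_dir / "trace.tsv", sep="\t", index=False)
    with open(mod_dir / "trace_landmarks.json", "w") as fh:
        json.dump({"m1": tr.m1, "m2": tr.m2, "m_star": tr.m_star,
                   "x": tr.x, "m_opt": tr.m_opt}, fh, indent=1)


def export_module_graph(pruned: PrunedModule, data: MultiOmicsDataset,
                        edge_threshold: float, out_dir: str | Path) -> None:
    """Edge list (similarity + Pearson r, filtered on |r|) and GraphML with
    node attributes: block, PC loadings, feature-phenotype correlation."""
    if not (0.0 <= edge_threshold < 1.0):
        raise CanonetError("edge threshold must lie in [0, 1)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X_all = np.hstack([b.matrix for b in data.blocks])
    sub = X_all[:, pruned.feature_idx]
    y = data.phenotype.values.astype(float)
    p = sub.shape[1]
    names = [f"{b}:{f}" for b, f in pruned.feature_index]
    corr = np.corrcoef(sub, rowvar=False) if p > 1 else np.ones((1, 1))
    G = nx.Graph()
    k = pruned.summarization.loadings.shape[1]
    for j in range(p):
        rho = float(np.corrcoef(sub[:, j], y)[0, 1]) if y.std() > 0 else 0.0
        attrs = {"block": pruned.feature_index[j][0],
                 "phenotype_correlation": rho}
        for c in range(min(3, k)):
            attrs[f"loading_pc{c + 1}"] = float(pruned.summarization.loadings[j, c])
        G.add_node(names[j], **attrs)
    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            r = float(corr[i, j])
            if abs(r) >= edge_threshold:
                rows.append({"feature_a": names[i], "feature_b": names[j],
                             "similarity": float(pruned.adjacency[i, j]),
                             "pearson_r": r})
                G.add_edge(names[i], names[j],
                           similarity=float(pruned.adjacency[i, j]), pearson_r=r)
    if not rows:
        logger.info("edge filter at %.3g removed every edge; nodes still listed",
                    edge_threshold)
    pd.DataFrame(rows, columns=["feature_a", "feature_b", "similarity",
                                "pearson_r"]).to_csv(
        out_dir / "edges.tsv", sep="\t", index=False)
    nx.write_graphml(G, out_dir / "network.graphml")


def _write_manifest(config: RunConfig, mode: str, best, out: Path) -> None:
    manifest = {
        "software": {"name": "canonet", "version": __version__},
        "mode": mode,
        "selected_penalties": list(best),
        "config": dataclasses.asdict(config),
        "artifacts": sorted(str(p.relative_to(out)) for p in out.rglob("*")
                            if p.is_file()),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
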