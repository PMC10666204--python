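"""End-to-end orchestration: build -> smooth -> pretrain -> classify -> evaluate.

Two entry points:

* :func:`run_pipeline` consumes the standard file formats (edge list TSV,
  annotation TSVs / GAF, OBO ontology) and writes artifacts + an evaluation
  report.
* :func:`run_benchmark` runs the same stages on an in-memory synthetic
  dataset; it is the basis of the package's reproducibility checks.

The three ablation switches reproduce the component study: ``use_pca`` only
(raw features reduced and fed straight to the classifier), ``use_ssl``
without the smoothing filter, and the full PCA + filter + SSL stack.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classifier import ClassifierConfig, DNNClassifier
from .config import RunConfig
from .evaluation import EvalReport, evaluate, make_cv_splits
from .graph import (
    AdjacencyMatrix,
    AttributeMatrix,
    GeneIndex,
    build_adjacency,
    build_go_attributes,
    read_edge_list,
    reduce_dimensions_pca,
)
from . import io as plio
from .ontology import (
    AnnotationTable,
    TermGroupTable,
    filter_terms_by_count,
    parse_obo,
    propagate_annotations,
    read_annotation_tsv,
    read_gaf,
    restrict_to_branch,
    term_group_for_count,
)
from .pretraining import PretrainConfig, pretrain
from .smoothing import FilterConfig, smooth_attributes
from .synthetic import SyntheticDataset

__all__ = ["PipelineInputs", "PipelineResult", "run_pipeline", "run_benchmark", "compute_embeddings", "cross_validate"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineInputs:
    """File inputs for a pipeline run (annotations define the gene universe)."""

    edges: Path
    gene2pheno: Path
    phenotype_obo: Path
    gene2attr: Path
    attr_obo: Path | None = None  # optional GO DAG to propagate attributes over
    gaf_attributes: bool = False  # gene2attr is GAF 2.x rather than 2-column TSV


@dataclass
class PipelineResult:
    report: EvalReport
    index: GeneIndex
    terms: tuple[str, ...]
    groups: TermGroupTable
    embeddings: np.ndarray
    predictions: np.ndarray
    labels: np.ndarray


def compute_embeddings(
    A: AdjacencyMatrix, X: AttributeMatrix, cfg: RunConfig
) -> np.ndarray:
    """Run the unsupervised stages (PCA -> smoothing -> SSL) per the ablation flags."""
    feats = X
    if cfg.ablation.use_pca:
        feats = reduce_dimensions_pca(
            feats, d=cfg.graph.pca_dim, seed=cfg.stage_seed("pca")
        )
    M = feats.X
    if cfg.ablation.use_filter:
        fc = FilterConfig(
            alpha=cfg.filter.alpha, t=cfg.filter.t, laplacian_sign=cfg.filter.laplacian_sign
        )
        M = smooth_attributes(A, _as_attr(M, feats), fc).X
    if cfg.ablation.use_ssl:
        pc = PretrainConfig(
            embed_dim=cfg.ssl.embed_dim,
            k=cfg.ssl.k,
            epochs=cfg.ssl.epochs,
            learning_rate=cfg.ssl.learning_rate,
            reselect_every=cfg.ssl.reselect_every,
            seed=cfg.stage_seed("ssl"),
        )
        _, Z, trace = pretrain(M, pc)
        log.info(
            "pretraining: %d epochs, loss %.3f -> %.3f",
            len(trace), trace[0] if trace else float("nan"),
            trace[-1] if trace else float("nan"),
        )
        return Z
    return M


def _as_attr(M: np.ndarray, like: AttributeMatrix) -> AttributeMatrix:
    return AttributeMatrix(
        X=M,
        columns=tuple(f"c{j}" for j in range(M.shape[1])),
        kind="reduced",
        index=like.index,
    )


def cross_validate(
    Z: np.ndarray,
    Y: np.ndarray,
    index: GeneIndex,
    terms: tuple[str, ...],
    groups: TermGroupTable,
    cfg: RunConfig,
) -> tuple[EvalReport, np.ndarray]:
    """Pooled k-fold CV: train per fold, collect out-of-fold predictions,
    and evaluate the pooled gene x term score matrix once."""
    plan = make_cv_splits(index, folds=cfg.eval.folds, seed=cfg.stage_seed("cv"))
    P = np.zeros_like(Y, dtype=np.float64)
    clf_cfg = ClassifierConfig(
        hidden_sizes=tuple(cfg.clf.hidden_sizes),
        leaky_slope=cfg.clf.leaky_slope,
        batch_size=cfg.clf.batch_size,
        learning_rate=cfg.clf.learning_rate,
        epochs=cfg.clf.epochs,
        patience=cfg.clf.patience,
        seed=cfg.stage_seed("clf"),
    )
    for fold in range(cfg.eval.folds):
        test_genes = plan.test_fold(fold)
        test_idx = np.array([index.position(g) for g in sorted(test_genes)])
        train_idx = np.array([i for i in range(len(index)) if index.gene(i) not in test_genes])
        model = DNNClassifier(clf_cfg).fit(Z[train_idx], Y[train_idx])
        P[test_idx] = model.predict_proba(Z[test_idx])
        log.info("cv fold %d: %d train / %d test genes", fold, len(train_idx), len(test_idx))
    grid = np.round(
        np.arange(0.0, 1.0 + cfg.eval.threshold_grid_step / 2, cfg.eval.threshold_grid_step), 10
    )
    report = evaluate(
        P, Y, terms, groups, grid=grid,
        shared_threshold_fmax=cfg.eval.shared_threshold_fmax,
    )
    return report, P


def _label_matrix(
    table: AnnotationTable, terms: tuple[str, ...], index: GeneIndex
) -> np.ndarray:
    col = {t: j for j, t in enumerate(terms)}
    Y = np.zeros((len(index), len(terms)), dtype=np.float64)
    for g in index.ids:
        for t in table.assignments.get(g, frozenset()):
            if t in col:
                Y[index.position(g), col[t]] = 1.0
    return Y


def run_pipeline(
    cfg: RunConfig, inputs: PipelineInputs, outdir: str | Path | None = None
) -> PipelineResult:
    """Execute the full pipeline from files; optionally write artifacts.

    Stage order: parse + propagate phenotype annotations, restrict to the
    configured branch, filter sparse terms; build the attributed network over
    the annotation-defined gene universe; PCA / smoothing / SSL per the
    ablation flags; pooled cross-validation; evaluation report.
    """
    t_start = time.time()
    fingerprint = cfg.fingerprint()

    dag = parse_obo(inputs.phenotype_obo)
    pheno = read_annotation_tsv(inputs.gene2pheno, dag)
    pheno = propagate_annotations(pheno, dag)
    if cfg.data.branch_root is not None:
        pheno = restrict_to_branch(
            pheno, dag, cfg.data.branch_root, include_root=cfg.data.include_branch_root
        )
    pheno, groups = filter_terms_by_count(pheno, min_genes=cfg.data.min_term_genes)
    terms = tuple(sorted(groups.groups))
    index = GeneIndex(ids=tuple(pheno.gene_ids))
    Y = _label_matrix(pheno, terms, index)

    if inputs.gaf_attributes:
        attrs_table = read_gaf(inputs.gene2attr)
    else:
        attrs_table = read_annotation_tsv(inputs.gene2attr)
    if inputs.attr_obo is not None:
        attr_dag = parse_obo(inputs.attr_obo)
        attrs_table = propagate_annotations(attrs_table, attr_dag)
    X = build_go_attributes(attrs_table, index)

    edges = read_edge_list(inputs.edges, string_scale=cfg.graph.string_scale)
    edges = [(a, b, s) for a, b, s in edges if a in index and b in index]
    A = build_adjacency(edges, index, threshold=cfg.graph.edge_threshold)

    Z = compute_embeddings(A, X, cfg)
    report, P = cross_validate(Z, Y, index, terms, groups, cfg)

    result = PipelineResult(
        report=report, index=index, terms=terms, groups=groups,
        embeddings=Z, predictions=P, labels=Y,
    )
    if outdir is not None:
        outdir = Path(outdir)
        plio.save_matrix(
            outdir / "embeddings", Z, index.ids,
            [f"e{j}" for j in range(Z.shape[1])], "embedding", fingerprint,
        )
        plio.write_predictions_tsv(outdir / "predictions.tsv", P, index.ids, terms)
        plio.write_term_groups_json(outdir / "term_groups.json", dict(groups.groups))
        plio.write_json(
            outdir / "eval_report.json",
            {"fingerprint": fingerprint, **report.to_dict()},
        )
    log.info("pipeline finished in %.1f s", time.time() - t_start)
    return result


def run_benchmark(dataset: SyntheticDataset, cfg: RunConfig) -> PipelineResult:
    """Run the configured stages on an in-memory synthetic dataset."""
    groups = TermGroupTable(
        groups={
            t: term_group_for_count(int(dataset.labels[:, j].sum()))
            for j, t in enumerate(dataset.terms)
        }
    )
    Z = compute_embeddings(dataset.adjacency, dataset.attributes, cfg)
    report, P = cross_validate(
        Z, dataset.labels, dataset.index, dataset.terms, groups, cfg
    )
    return PipelineResult(
        report=report, index=dataset.index, terms=dataset.terms, groups=groups,
        embeddings=Z, predictions=P, labels=dataset.labels,
    )
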