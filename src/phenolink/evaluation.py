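"""CAFA-style evaluation: AUPR and Fmax, macro/micro, per term-size group.

Metrics follow the conventions of the protein/gene annotation-prediction
literature:

* **term AUPR** — area under the precision-recall curve of one term's score
  vector, computed as stepwise average precision over the distinct score
  thresholds (no trapezoidal interpolation, which is optimistic for PR
  curves). Tied scores form a single threshold block.
* **Fmax** — maximum F1 over a decision-threshold grid (0.00, 0.01, ..., 1.00).
* **macro (M-)** — metric computed per term, then averaged (unweighted) over
  terms with at least one test positive.
* **micro (m-)** — the gene x term score matrix is flattened into one vector
  and the metric computed once on it.

Splits: seeded k-fold cross-validation over genes, and a temporal split in
which test genes are those with no annotations at an earlier database
snapshot that gained at least one by a later snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .graph import GeneIndex
from .ontology import AnnotationTable, TermGroupTable, TERM_GROUPS

__all__ = [
    "SplitPlan",
    "EvalReport",
    "term_aupr",
    "fmax_per_term",
    "macro_metrics",
    "micro_metrics",
    "evaluate",
    "make_cv_splits",
    "make_temporal_split",
    "DEFAULT_THRESHOLD_GRID",
]

#: CAFA-convention decision-threshold grid for Fmax.
DEFAULT_THRESHOLD_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)

#: Scope key for metrics over the full label space.
ALL_SCOPE = "All"


@dataclass(frozen=True)
class SplitPlan:
    """A cross-validation or temporal train/test split over genes."""

    kind: str  # "cv" | "temporal"
    fold_of_gene: Mapping[str, int] | None = None  # cv only
    n_folds: int | None = None
    seed: int | None = None
    train_genes: frozenset[str] | None = None  # temporal only
    test_genes: frozenset[str] | None = None
    snapshots: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("cv", "temporal"):
            raise ValueError("kind must be 'cv' or 'temporal'")
        if self.kind == "temporal" and self.train_genes and self.test_genes:
            if self.train_genes & self.test_genes:
                raise ValueError("temporal train and test sets overlap")

    def test_fold(self, fold: int) -> frozenset[str]:
        if self.kind != "cv":
            raise ValueError("test_fold applies to cv plans")
        return frozenset(g for g, f in self.fold_of_gene.items() if f == fold)


@dataclass
class EvalReport:
    """Macro/micro AUPR and Fmax, overall and per term-count group."""

    scopes: dict[str, dict[str, float | None]]
    term_aupr: dict[str, float | None] = field(default_factory=dict)
    threshold_grid: tuple[float, ...] = tuple(DEFAULT_THRESHOLD_GRID)

    def to_dict(self) -> dict:
        return {
            "scopes": self.scopes,
            "term_aupr": self.term_aupr,
            "threshold_grid": list(self.threshold_grid),
        }


def term_aupr(scores: np.ndarray, labels: np.ndarray) -> float | None:
    """Stepwise average precision of one score vector against binary labels.

    Returns ``None`` (the "undefined" sentinel) when there are no positive
    labels — never silently 0. Tied scores are treated as a single threshold
    block, so the result equals brute-force enumeration over distinct cutoffs.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(np.float64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = labels.sum()
    if n_pos == 0:
        return None
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    tp = np.cumsum(y_sorted)
    ranks = np.arange(1, len(scores) + 1)
    # block boundaries: last index of each distinct score
    is_block_end = np.ones(len(scores), dtype=bool)
    is_block_end[:-1] = s_sorted[:-1] != s_sorted[1:]
    precision = tp[is_block_end] / ranks[is_block_end]
    recall = tp[is_block_end] / n_pos
    prev_recall = np.concatenate(([0.0], recall[:-1]))
    return float(np.sum((recall - prev_recall) * precision))


def _f1(tp: float, fp: float, fn: float) -> float:
    if tp + fp == 0 or tp + fn == 0 or tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def fmax_per_term(
    scores: np.ndarray, labels: np.ndarray, grid: np.ndarray = DEFAULT_THRESHOLD_GRID
) -> float | None:
    """Maximum F1 over the threshold grid for one term (None if no positives)."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if not labels.any():
        return None
    best = 0.0
    for tau in grid:
        pred = scores >= tau
        tp = float(np.sum(pred & labels))
        fp = float(np.sum(pred & ~labels))
        fn = float(np.sum(~pred & labels))
        best = max(best, _f1(tp, fp, fn))
    return best


def _scope_columns(
    terms: Sequence[str], groups: TermGroupTable | None
) -> dict[str, np.ndarray]:
    scopes = {ALL_SCOPE: np.arange(len(terms))}
    if groups is not None:
        for g in TERM_GROUPS:
            cols = np.array(
                [j for j, t in enumerate(terms) if groups.groups.get(t) == g], dtype=int
            )
            scopes[g] = cols
    return scopes


def macro_metrics(
    P: np.ndarray,
    Y: np.ndarray,
    terms: Sequence[str],
    groups: TermGroupTable | None = None,
    grid: np.ndarray = DEFAULT_THRESHOLD_GRID,
    shared_threshold_fmax: bool = False,
) -> EvalReport:
    """Per-term AUPR / Fmax averaged over evaluable terms, overall and per group.

    A term is evaluable when it has at least one positive test label; other
    terms are excluded from the averages. ``shared_threshold_fmax=True``
    switches macro-Fmax from the default mean-of-per-term-maxima to the
    single shared threshold maximizing the mean F1.
    """
    P, Y = np.asarray(P, dtype=np.float64), np.asarray(Y)
    if P.shape != Y.shape or P.shape[1] != len(terms):
        raise ValueError("P, Y, and terms are inconsistent")
    auprs = {t: term_aupr(P[:, j], Y[:, j]) for j, t in enumerate(terms)}
    fmaxes = {t: fmax_per_term(P[:, j], Y[:, j], grid) for j, t in enumerate(terms)}
    scopes: dict[str, dict[str, float | None]] = {}
    for scope, cols in _scope_columns(terms, groups).items():
        vals_a = [auprs[terms[j]] for j in cols if auprs[terms[j]] is not None]
        scope_metrics: dict[str, float | None] = {}
        scope_metrics["M-aupr"] = float(np.mean(vals_a)) if vals_a else None
        if shared_threshold_fmax:
            evaluable = [j for j in cols if auprs[terms[j]] is not None]
            if evaluable:
                best = 0.0
                for tau in grid:
                    f1s = []
                    for j in evaluable:
                        pred = P[:, j] >= tau
                        lab = Y[:, j].astype(bool)
                        f1s.append(
                            _f1(
                                float(np.sum(pred & lab)),
                                float(np.sum(pred & ~lab)),
                                float(np.sum(~pred & lab)),
                            )
                        )
                    best = max(best, float(np.mean(f1s)))
                scope_metrics["M-Fmax"] = best
            else:
                scope_metrics["M-Fmax"] = None
        else:
            vals_f = [fmaxes[terms[j]] for j in cols if fmaxes[terms[j]] is not None]
            scope_metrics["M-Fmax"] = float(np.mean(vals_f)) if vals_f else None
        scopes[scope] = scope_metrics
    return EvalReport(scopes=scopes, term_aupr=auprs)


def micro_metrics(
    P: np.ndarray,
    Y: np.ndarray,
    terms: Sequence[str],
    groups: TermGroupTable | None = None,
    grid: np.ndarray = DEFAULT_THRESHOLD_GRID,
) -> EvalReport:
    """Flattened-matrix AUPR / Fmax, overall and per group.

    Within each scope, terms without any positive test label are excluded
    from the flattening so undefined precision-recall cannot pollute the
    micro averages.
    """
    P, Y = np.asarray(P, dtype=np.float64), np.asarray(Y)
    if P.shape != Y.shape or P.shape[1] != len(terms):
        raise ValueError("P, Y, and terms are inconsistent")
    has_pos = np.asarray(Y).sum(axis=0) > 0
    scopes: dict[str, dict[str, float | None]] = {}
    for scope, cols in _scope_columns(terms, groups).items():
        cols = np.array([j for j in cols if has_pos[j]], dtype=int)
        if cols.size == 0:
            scopes[scope] = {"m-aupr": None, "m-Fmax": None}
            continue
        flat_p = P[:, cols].ravel()
        flat_y = Y[:, cols].ravel()
        scopes[scope] = {
            "m-aupr": term_aupr(flat_p, flat_y),
            "m-Fmax": fmax_per_term(flat_p, flat_y, grid),
        }
    return EvalReport(scopes=scopes)


def evaluate(
    P: np.ndarray,
    Y: np.ndarray,
    terms: Sequence[str],
    groups: TermGroupTable | None = None,
    grid: np.ndarray = DEFAULT_THRESHOLD_GRID,
    shared_threshold_fmax: bool = False,
) -> EvalReport:
    """Full report: macro and micro metrics merged per scope."""
    mac = macro_metrics(P, Y, terms, groups, grid, shared_threshold_fmax)
    mic = micro_metrics(P, Y, terms, groups, grid)
    scopes = {
        scope: {**mac.scopes[scope], **mic.scopes[scope]} for scope in mac.scopes
    }
    return EvalReport(scopes=scopes, term_aupr=mac.term_aupr, threshold_grid=tuple(grid))


def make_cv_splits(index: GeneIndex, folds: int = 5, seed: int = 0) -> SplitPlan:
    """Shuffle genes with the seed and deal them round-robin into folds."""
    n = len(index)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"cannot split {n} genes into {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of_gene = {index.gene(int(g)): int(pos % folds) for pos, g in enumerate(order)}
    return SplitPlan(kind="cv", fold_of_gene=fold_of_gene, n_folds=folds, seed=seed)


def make_temporal_split(
    annotations_t0: AnnotationTable,
    annotations_t1: AnnotationTable,
    snapshots: tuple[str, str] = ("t0", "t1"),
) -> SplitPlan:
    """CAFA2-style temporal split.

    Test genes had zero annotations at the earlier snapshot (t0) and gained
    at least one by the later snapshot (t1); training genes are those
    annotated at t0. Genes with no annotations at either time are excluded.
    """
    t0 = {g for g, ts in annotations_t0.assignments.items() if ts}
    t1 = {g for g, ts in annotations_t1.assignments.items() if ts}
    test = frozenset(t1 - t0)
    train = frozenset(t0)
    if not test:
        raise ValueError("temporal split has an empty test set")
    return SplitPlan(
        kind="temporal", train_genes=train, test_genes=test, snapshots=snapshots
    )
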