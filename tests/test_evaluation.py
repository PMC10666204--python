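import numpy as np
import pytest

from phenolink.evaluation import (
    DEFAULT_THRESHOLD_GRID,
    evaluate,
    fmax_per_term,
    macro_metrics,
    make_cv_splits,
    make_temporal_split,
    micro_metrics,
    term_aupr,
)
from phenolink.graph import GeneIndex
from phenolink.ontology import AnnotationTable, TermGroupTable


def brute_force_aupr(scores, labels):
    """Enumerate every distinct score cutoff; sum precision * recall increments."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, float)
    n_pos = labels.sum()
    thresholds = sorted(set(scores), reverse=True)
    aupr, prev_recall = 0.0, 0.0
    for tau in thresholds:
        pred = scores >= tau
        tp = float((pred * labels).sum())
        precision = tp / pred.sum()
        recall = tp / n_pos
        aupr += (recall - prev_recall) * precision
        prev_recall = recall
    return aupr


def brute_force_fmax(scores, labels, grid):
    scores, labels = np.asarray(scores, float), np.asarray(labels, bool)
    best = 0.0
    for tau in grid:
        pred = scores >= tau
        tp = float((pred & labels).sum())
        if tp == 0:
            continue
        p = tp / pred.sum()
        r = tp / labels.sum()
        best = max(best, 2 * p * r / (p + r))
    return best


class TestTermAupr:
    def test_perfect_ranking(self):
        assert term_aupr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_single_positive_ranked_last(self):
        assert term_aupr([0.9, 0.8, 0.7, 0.1], [0, 0, 0, 1]) == pytest.approx(0.25)

    def test_no_positives_is_undefined_sentinel(self):
        assert term_aupr([0.5, 0.2], [0, 0]) is None

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 50))
        scores = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() == 0:
            labels[0] = 1
        assert term_aupr(scores, labels) == pytest.approx(
            brute_force_aupr(scores, labels), abs=1e-12
        )

    def test_agrees_with_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(11)
        for _ in range(10):
            scores = rng.random(30)
            labels = rng.integers(0, 2, size=30)
            if labels.sum() == 0:
                labels[0] = 1
            assert term_aupr(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12
            )


class TestFmax:
    def test_grid_matches_supremum_when_scores_on_grid(self):
        rng = np.random.default_rng(1)
        scores = rng.choice(np.round(np.arange(0, 1.01, 0.01), 2), size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0] = 1
        got = fmax_per_term(scores, labels)
        # supremum over *all* cutoffs: with scores on the grid, the grid covers them
        sup = brute_force_fmax(scores, labels, sorted(set(scores)))
        assert got == pytest.approx(sup, abs=1e-12)

    def test_never_exceeds_continuous_supremum(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            scores = rng.random(25)
            labels = rng.integers(0, 2, size=25)
            labels[0] = 1
            got = fmax_per_term(scores, labels)
            sup = brute_force_fmax(scores, labels, sorted(set(scores)))
            assert got <= sup + 1e-12


def _groups(terms, label):
    return TermGroupTable(groups={t: label for t in terms})


class TestMacroMicro:
    def test_perfect_predictions_score_one_everywhere(self):
        rng = np.random.default_rng(3)
        Y = rng.integers(0, 2, size=(10, 4)).astype(float)
        Y[:, Y.sum(axis=0) == 0] = 1  # every term evaluable
        terms = [f"t{j}" for j in range(4)]
        rep = evaluate(Y, Y, terms, _groups(terms, "11-30"))
        for scope in ("All", "11-30"):
            for metric in ("M-aupr", "M-Fmax", "m-aupr", "m-Fmax"):
                assert rep.scopes[scope][metric] == pytest.approx(1.0)

    def test_macro_aupr_is_unweighted_mean(self):
        # term 1 perfectly ranked (AUPR 1), term 2 single positive at rank 2 (0.5)
        P = np.array([[0.9, 0.9], [0.1, 0.5], [0.2, 0.1]])
        Y = np.array([[1, 1], [0, 0], [0, 0]], dtype=float)
        Y[1, 1] = 1
        Y[0, 1] = 0
        rep = macro_metrics(P, Y, ["a", "b"])
        assert rep.term_aupr["a"] == pytest.approx(1.0)
        assert rep.term_aupr["b"] == pytest.approx(0.5)
        assert rep.scopes["All"]["M-aupr"] == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(3))
    def test_macro_fmax_matches_per_term_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.random((15, 5))
        Y = (rng.random((15, 5)) < 0.3).astype(float)
        Y[0, Y.sum(axis=0) == 0] = 1
        terms = [f"t{j}" for j in range(5)]
        rep = macro_metrics(P, Y, terms)
        expect = np.mean(
            [brute_force_fmax(P[:, j], Y[:, j], DEFAULT_THRESHOLD_GRID) for j in range(5)]
        )
        assert rep.scopes["All"]["M-Fmax"] == pytest.approx(expect, abs=1e-12)

    def test_micro_flat_equivalence(self):
        rng = np.random.default_rng(5)
        P = rng.random((8, 3))
        Y = (rng.random((8, 3)) < 0.4).astype(float)
        Y[0, Y.sum(axis=0) == 0] = 1
        rep = micro_metrics(P, Y, ["a", "b", "c"])
        assert rep.scopes["All"]["m-aupr"] == pytest.approx(
            term_aupr(P.ravel(), Y.ravel()), abs=1e-12
        )

    def test_constant_scores_micro_fmax_closed_form(self):
        # everything predicted at the best threshold: precision = prevalence,
        # recall = 1 -> F1 = 2p/(1+p)
        Y = np.zeros((10, 1))
        Y[:3, 0] = 1  # prevalence 3/10
        P = np.full((10, 1), 0.7)
        rep = micro_metrics(P, Y, ["a"])
        rho = 3 / 10
        assert rep.scopes["All"]["m-Fmax"] == pytest.approx(2 * rho / (1 + rho))

    def test_metrics_invariant_to_gene_permutation(self):
        rng = np.random.default_rng(6)
        P = rng.random((12, 4))
        Y = (rng.random((12, 4)) < 0.3).astype(float)
        Y[0, Y.sum(axis=0) == 0] = 1
        terms = [f"t{j}" for j in range(4)]
        perm = rng.permutation(12)
        r1 = evaluate(P, Y, terms)
        r2 = evaluate(P[perm], Y[perm], terms)
        assert r1.scopes == r2.scopes

    def test_macro_micro_coincide_for_single_term(self):
        rng = np.random.default_rng(7)
        P = rng.random((20, 1))
        Y = (rng.random((20, 1)) < 0.4).astype(float)
        Y[0, 0] = 1
        rep = evaluate(P, Y, ["only"])
        assert rep.scopes["All"]["M-aupr"] == pytest.approx(rep.scopes["All"]["m-aupr"])
        assert rep.scopes["All"]["M-Fmax"] == pytest.approx(rep.scopes["All"]["m-Fmax"])

    def test_group_scopes_use_only_their_columns(self):
        P = np.array([[0.9, 0.1], [0.1, 0.9], [0.5, 0.5]])
        Y = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        groups = TermGroupTable(groups={"a": "11-30", "b": ">300"})
        rep = evaluate(P, Y, ["a", "b"], groups)
        assert rep.scopes["11-30"]["M-aupr"] == pytest.approx(term_aupr(P[:, 0], Y[:, 0]))
        assert rep.scopes[">300"]["M-aupr"] == pytest.approx(term_aupr(P[:, 1], Y[:, 1]))


class TestSplits:
    def test_cv_folds_partition_genes(self):
        index = GeneIndex(ids=tuple(f"g{i}" for i in range(10)))
        plan = make_cv_splits(index, folds=5, seed=0)
        folds = [plan.test_fold(f) for f in range(5)]
        assert all(len(f) == 2 for f in folds)
        assert frozenset().union(*folds) == frozenset(index.ids)
        for a in range(5):
            for b in range(a + 1, 5):
                assert not folds[a] & folds[b]

    def test_cv_seed_determinism(self):
        index = GeneIndex(ids=tuple(f"g{i}" for i in range(100)))
        p1 = make_cv_splits(index, seed=1)
        p2 = make_cv_splits(index, seed=1)
        p3 = make_cv_splits(index, seed=2)
        assert p1.fold_of_gene == p2.fold_of_gene
        assert p1.fold_of_gene != p3.fold_of_gene

    def test_too_few_genes_errors(self):
        with pytest.raises(ValueError):
            make_cv_splits(GeneIndex(ids=("a", "b")), folds=5)

    def test_temporal_split_rules(self):
        t0 = AnnotationTable(
            gene_ids=("g1", "g2"),
            assignments={"g1": frozenset({"t"}), "g2": frozenset({"t"})},
            propagated=True,
        )
        t1 = AnnotationTable(
            gene_ids=("g1", "g2", "g3"),
            assignments={
                "g1": frozenset({"t"}),
                "g2": frozenset({"t", "u"}),
                "g3": frozenset({"t", "u"}),
            },
            propagated=True,
        )
        plan = make_temporal_split(t0, t1)
        assert plan.test_genes == {"g3"}  # zero at t0, >=1 at t1
        assert plan.train_genes == {"g1", "g2"}

    def test_empty_temporal_test_set_errors(self):
        t = AnnotationTable(
            gene_ids=("g1",), assignments={"g1": frozenset({"t"})}, propagated=True
        )
        with pytest.raises(ValueError):
            make_temporal_split(t, t)
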