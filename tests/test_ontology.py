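import numpy as np
import pytest

from phenolink.ontology import (
    AnnotationTable,
    OboParseError,
    OntologyCycleError,
    UnknownTermError,
    filter_terms_by_count,
    parse_obo,
    propagate_annotations,
    read_annotation_tsv,
    read_gaf,
    restrict_to_branch,
    term_group_for_count,
)

from conftest import brute_force_closure, random_annotations, random_dag


MINIMAL_OBO = """\
format-version: 1.2

[Term]
id: A
name: root term

[Term]
id: B
name: child term
is_a: A ! root term
"""


def _table(**assignments):
    return AnnotationTable(
        gene_ids=tuple(assignments),
        assignments={g: frozenset(ts) for g, ts in assignments.items()},
    )


class TestParseObo:
    def test_minimal_ontology(self, tmp_path):
        p = tmp_path / "mini.obo"
        p.write_text(MINIMAL_OBO)
        dag = parse_obo(p)
        assert dag.term_ids == {"A", "B"}
        assert dag.parents == {"B": frozenset({"A"})}
        assert dag.root_ids == {"A"}

    def test_obsolete_terms_are_dropped(self, tmp_path):
        p = tmp_path / "obs.obo"
        p.write_text(
            MINIMAL_OBO + "\n[Term]\nid: C\nname: gone\nis_obsolete: true\n"
        )
        dag = parse_obo(p)
        assert "C" not in dag.term_ids

    def test_alt_id_maps_to_canonical(self, tmp_path):
        p = tmp_path / "alt.obo"
        p.write_text(MINIMAL_OBO.replace("name: child term", "name: child term\nalt_id: B_OLD"))
        dag = parse_obo(p)
        assert dag.canonical("B_OLD") == "B"
        assert dag.canonical("B") == "B"

    def test_cycle_raises_with_cycle_listed(self, tmp_path):
        p = tmp_path / "cyc.obo"
        p.write_text(
            "format-version: 1.2\n\n[Term]\nid: A\nis_a: B\n\n[Term]\nid: B\nis_a: A\n"
        )
        with pytest.raises(OntologyCycleError, match="cycle"):
            parse_obo(p)

    def test_malformed_stanza_names_line(self, tmp_path):
        p = tmp_path / "bad.obo"
        p.write_text("format-version: 1.2\n\n[Term]\nid: A\nthis is not a tag line\n")
        with pytest.raises(OboParseError, match=":5"):
            parse_obo(p)


class TestPropagation:
    def test_chain_closure(self, chain_dag):
        table = _table(g1={"c"})
        out = propagate_annotations(table, chain_dag)
        assert out.assignments["g1"] == {"a", "b", "c"}
        assert out.propagated

    def test_root_annotation_is_fixed_point(self, chain_dag):
        out = propagate_annotations(_table(g1={"a"}), chain_dag)
        assert out.assignments["g1"] == {"a"}

    def test_diamond_matches_transitive_closure_oracle(self, diamond_dag):
        out = propagate_annotations(_table(g1={"d"}), diamond_dag)
        assert out.assignments["g1"] == brute_force_closure(diamond_dag, frozenset({"d"}))
        assert out.assignments["g1"] == {"a", "b", "c", "d"}

    def test_unknown_term_lists_offenders(self, chain_dag):
        with pytest.raises(UnknownTermError, match="zz"):
            propagate_annotations(_table(g1={"c", "zz"}), chain_dag)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_dags_closure_idempotence_and_growth(self, seed):
        rng = np.random.default_rng(seed)
        dag = random_dag(rng, int(rng.integers(4, 15)))
        table = random_annotations(rng, dag, n_genes=6)
        once = propagate_annotations(table, dag)
        for g in table.gene_ids:
            assert once.assignments[g] == brute_force_closure(dag, table.assignments[g])
            assert len(once.assignments[g]) >= len(table.assignments[g])
        twice = propagate_annotations(
            AnnotationTable(once.gene_ids, once.assignments, propagated=False), dag
        )
        assert twice.assignments == once.assignments


class TestBranchRestriction:
    def test_other_branch_removed_and_empty_genes_dropped(self, two_branch_dag):
        table = propagate_annotations(_table(g1={"x2"}, g2={"y1"}), two_branch_dag)
        out = restrict_to_branch(table, two_branch_dag, "R1")
        assert out.assignments["g1"] == {"x1", "x2"}  # R1 itself excluded
        assert "g2" not in out.assignments

    def test_branch_root_kept_when_requested(self, two_branch_dag):
        table = propagate_annotations(_table(g1={"x2"}), two_branch_dag)
        out = restrict_to_branch(table, two_branch_dag, "R1", include_root=True)
        assert "R1" in out.assignments["g1"]

    def test_restrict_to_leaf_keeps_only_leaf(self, two_branch_dag):
        table = propagate_annotations(_table(g1={"x2"}, g2={"x1"}), two_branch_dag)
        # oracle: the descendant set of the leaf is empty, so only the leaf
        # itself (include_root) can survive
        assert two_branch_dag.descendants("x2") == frozenset()
        out = restrict_to_branch(table, two_branch_dag, "x2", include_root=True)
        assert out.assignments == {"g1": frozenset({"x2"})}

    def test_missing_branch_root_errors(self, two_branch_dag):
        with pytest.raises(UnknownTermError):
            restrict_to_branch(_table(g1={"x1"}), two_branch_dag, "nope")


class TestCountFilter:
    @staticmethod
    def _table_with_counts(counts: dict[str, int]) -> AnnotationTable:
        n = max(counts.values())
        genes = [f"g{i}" for i in range(n)]
        assignments = {
            g: frozenset(t for t, c in counts.items() if i < c)
            for i, g in enumerate(genes)
        }
        return AnnotationTable(tuple(genes), assignments, propagated=True)

    def test_count_10_removed_count_11_kept(self):
        table = self._table_with_counts({"rare": 10, "ok": 11})
        out, groups = filter_terms_by_count(table)
        assert "rare" not in out.terms
        assert groups.groups == {"ok": "11-30"}

    @pytest.mark.parametrize(
        "count,group",
        [(30, "11-30"), (31, "31-100"), (100, "31-100"), (101, "101-300"),
         (300, "101-300"), (301, ">300")],
    )
    def test_group_boundaries(self, count, group):
        assert term_group_for_count(count) == group

    def test_boundary_counts_land_in_printed_bins_via_filter(self):
        counts = {f"t{c}": c for c in (30, 31, 100, 101, 300, 301)}
        _, groups = filter_terms_by_count(self._table_with_counts(counts))
        assert groups.groups == {
            "t30": "11-30", "t31": "31-100", "t100": "31-100",
            "t101": "101-300", "t300": "101-300", "t301": ">300",
        }

    def test_orphaned_genes_dropped_but_counts_single_pass(self):
        # 11 genes carry only the rare term -> dropped with it; the counts of
        # the surviving term are not recomputed afterwards
        genes = {f"g{i}": {"rare10"} for i in range(10)}
        genes.update({f"h{i}": {"keep"} for i in range(11)})
        out, groups = filter_terms_by_count(
            AnnotationTable(tuple(genes), {g: frozenset(t) for g, t in genes.items()},
                            propagated=True)
        )
        assert set(out.gene_ids) == {f"h{i}" for i in range(11)}
        assert groups.groups == {"keep": "11-30"}

    def test_all_terms_removed_errors(self):
        with pytest.raises(ValueError, match="empty label space"):
            filter_terms_by_count(self._table_with_counts({"t": 3}))

    def test_groups_partition_surviving_terms(self):
        counts = {f"t{i}": c for i, c in enumerate([11, 25, 50, 150, 400])}
        out, groups = filter_terms_by_count(self._table_with_counts(counts))
        assert set(groups.groups) == out.terms
        assert all(g in ("11-30", "31-100", "101-300", ">300") for g in groups.groups.values())


class TestReaders:
    def test_two_column_tsv(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("g1\tA\ng1\tB\ng2\tA\n")
        table = read_annotation_tsv(p)
        assert table.gene_ids == ("g1", "g2")
        assert table.assignments["g1"] == {"A", "B"}

    def test_gaf_skips_not_qualifier_and_comments(self, tmp_path):
        p = tmp_path / "ann.gaf"
        rows = [
            "!gaf-version: 2.2",
            "DB\tP1\tSYM1\tinvolved_in\tGO:1\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t20200101\tDB",
            "DB\tP1\tSYM1\tNOT|involved_in\tGO:2\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t20200101\tDB",
            "DB\tP2\tSYM2\tinvolved_in\tGO:2\tREF\tEXP\t\tP\t\t\tprotein\ttaxon:9606\t20200101\tDB",
        ]
        p.write_text("\n".join(rows) + "\n")
        table = read_gaf(p)
        assert table.assignments["P1"] == {"GO:1"}
        assert table.assignments["P2"] == {"GO:2"}
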