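import numpy as np
import pytest

from phenolink.ontology import AnnotationTable, OntologyDAG


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """c is_a b is_a a."""
    return OntologyDAG(
        term_ids=frozenset({"a", "b", "c"}),
        parents={"c": frozenset({"b"}), "b": frozenset({"a"})},
    )


@pytest.fixture
def diamond_dag() -> OntologyDAG:
    """d is_a b, d is_a c, b is_a a, c is_a a."""
    return OntologyDAG(
        term_ids=frozenset({"a", "b", "c", "d"}),
        parents={
            "d": frozenset({"b", "c"}),
            "b": frozenset({"a"}),
            "c": frozenset({"a"}),
        },
    )


@pytest.fixture
def two_branch_dag() -> OntologyDAG:
    """Two roots R1, R2 with one leaf each plus a shared-depth chain."""
    return OntologyDAG(
        term_ids=frozenset({"R1", "R2", "x1", "x2", "y1"}),
        parents={
            "x1": frozenset({"R1"}),
            "x2": frozenset({"x1"}),
            "y1": frozenset({"R2"}),
        },
    )


def random_dag(rng: np.random.Generator, n_terms: int) -> OntologyDAG:
    """Random DAG on terms t0..t{n-1}; edges only from higher to lower index."""
    terms = [f"t{i}" for i in range(n_terms)]
    parents: dict[str, frozenset[str]] = {}
    for i in range(1, n_terms):
        k = rng.integers(0, min(i, 3) + 1)
        if k:
            chosen = rng.choice(i, size=k, replace=False)
            parents[terms[i]] = frozenset(terms[j] for j in chosen)
    return OntologyDAG(term_ids=frozenset(terms), parents=parents)


def random_annotations(
    rng: np.random.Generator, dag: OntologyDAG, n_genes: int
) -> AnnotationTable:
    terms = sorted(dag.term_ids)
    genes, assignments = [], {}
    for g in range(n_genes):
        k = rng.integers(1, max(2, len(terms) // 2))
        chosen = rng.choice(len(terms), size=min(k, len(terms)), replace=False)
        name = f"g{g}"
        genes.append(name)
        assignments[name] = frozenset(terms[j] for j in chosen)
    return AnnotationTable(gene_ids=tuple(genes), assignments=assignments)


def brute_force_closure(dag: OntologyDAG, terms: frozenset[str]) -> frozenset[str]:
    """Transitive-closure oracle: repeatedly add direct parents to fixpoint."""
    closed = set(terms)
    changed = True
    while changed:
        changed = False
        for t in list(closed):
            for p in dag.parents.get(t, frozenset()):
                if p not in closed:
                    closed.add(p)
                    changed = True
    return frozenset(closed)
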