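"""Ontology parsing, true-path-rule propagation, and label-space construction.

Gene annotations to an ontology term (HPO phenotype terms, GO terms) imply
annotation to every ancestor of that term — the *true-path-rule*. This module
parses OBO 1.2 ontologies and gene->term annotation tables, propagates
annotations up the ``is_a`` hierarchy, restricts the label space to a single
ontology branch (e.g. the phenotypic-abnormality branch of HPO), removes
sparsely annotated terms, and bins the surviving terms by annotated-gene
count so downstream evaluation can be reported per term-frequency group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "OntologyDAG",
    "AnnotationTable",
    "TermGroupTable",
    "OboParseError",
    "OntologyCycleError",
    "UnknownTermError",
    "TERM_GROUPS",
    "term_group_for_count",
    "parse_obo",
    "read_annotation_tsv",
    "read_gaf",
    "propagate_annotations",
    "restrict_to_branch",
    "filter_terms_by_count",
]


class OboParseError(ValueError):
    """Raised for a malformed OBO stanza; message names the offending line."""


class OntologyCycleError(ValueError):
    """Raised when the is_a graph contains a cycle; message lists the cycle."""


class UnknownTermError(KeyError):
    """Raised when annotations reference terms absent from the ontology."""

    def __init__(self, terms: Iterable[str]):
        self.terms = sorted(terms)
        super().__init__(f"annotations reference unknown terms: {self.terms}")


@dataclass
class OntologyDAG:
    """An is_a hierarchy of ontology terms (child -> parent edges, acyclic)."""

    term_ids: frozenset[str]
    parents: dict[str, frozenset[str]]  # child -> direct is_a parents
    alt_ids: dict[str, str] = field(default_factory=dict)  # alt -> canonical
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for child, pars in self.parents.items():
            bad = ({child} | set(pars)) - self.term_ids
            if bad:
                raise ValueError(f"edge endpoints not in term_ids: {sorted(bad)}")

    @property
    def root_ids(self) -> frozenset[str]:
        return frozenset(t for t in self.term_ids if not self.parents.get(t))

    def canonical(self, term: str) -> str:
        """Map an alt_id to its canonical accession (identity otherwise)."""
        return self.alt_ids.get(term, term)

    def ancestors(self, term: str) -> frozenset[str]:
        """All strict ancestors of ``term`` under the is_a relation."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        if term not in self.term_ids:
            raise UnknownTermError([term])
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.parents.get(p, ()))
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def descendants(self, term: str) -> frozenset[str]:
        """All strict descendants of ``term`` (terms having it as ancestor)."""
        if term not in self.term_ids:
            raise UnknownTermError([term])
        children: dict[str, set[str]] = {t: set() for t in self.term_ids}
        for child, pars in self.parents.items():
            for p in pars:
                children[p].add(child)
        out: set[str] = set()
        stack = list(children[term])
        while stack:
            c = stack.pop()
            if c not in out:
                out.add(c)
                stack.extend(children[c])
        return frozenset(out)


@dataclass(frozen=True)
class AnnotationTable:
    """Gene -> term-set annotation table.

    ``propagated`` records whether every gene's term set is already closed
    under the ancestor relation of its companion ontology.
    """

    gene_ids: tuple[str, ...]
    assignments: Mapping[str, frozenset[str]]
    propagated: bool = False

    def __post_init__(self) -> None:
        if set(self.gene_ids) != set(self.assignments):
            raise ValueError("gene_ids and assignments keys must coincide")

    @property
    def terms(self) -> frozenset[str]:
        out: set[str] = set()
        for ts in self.assignments.values():
            out |= ts
        return frozenset(out)

    def term_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for ts in self.assignments.values():
            for t in ts:
                counts[t] = counts.get(t, 0) + 1
        return counts


#: Term-frequency bins used for grouped evaluation, by annotated-gene count.
TERM_GROUPS = ("11-30", "31-100", "101-300", ">300")


def term_group_for_count(count: int) -> str:
    """Bin a term's annotated-gene count; counts <= 10 have no group."""
    if count <= 10:
        raise ValueError(f"terms with <=10 annotations carry no group (got {count})")
    if count <= 30:
        return "11-30"
    if count <= 100:
        return "31-100"
    if count <= 300:
        return "101-300"
    return ">300"


@dataclass(frozen=True)
class TermGroupTable:
    """Mapping of surviving terms to their annotated-gene-count group."""

    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.groups.values() if g not in TERM_GROUPS}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    def terms_in(self, group: str) -> frozenset[str]:
        return frozenset(t for t, g in self.groups.items() if g == group)


def _prescan_obo(path: Path) -> None:
    """Reject malformed [Term] stanza lines before handing off to the parser."""
    in_term = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            in_term = line == "[Term]"
            if not (line.startswith("[") and line.endswith("]")):
                raise OboParseError(f"{path}:{lineno}: malformed stanza header {raw!r}")
            continue
        if in_term and ":" not in line:
            raise OboParseError(
                f"{path}:{lineno}: malformed tag line in [Term] stanza: {raw!r}"
            )


def parse_obo(path: str | Path) -> OntologyDAG:
    """Parse an OBO 1.2 ontology into an :class:`OntologyDAG`.

    Obsolete terms are dropped, ``alt_id`` accessions are mapped to their
    canonical term, and only ``is_a`` edges are retained. A cyclic is_a graph
    raises :class:`OntologyCycleError` naming one offending cycle.
    """
    path = Path(path)
    _prescan_obo(path)
    try:
        graph = obonet.read_obo(str(path))
    except Exception as exc:  # pragma: no cover - obonet's own diagnostics
        raise OboParseError(f"{path}: {exc}") from exc

    isa = nx.DiGraph()
    isa.add_nodes_from(graph.nodes)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            isa.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(isa):
        cycle = [u for u, _ in nx.find_cycle(isa)]
        raise OntologyCycleError(f"is_a hierarchy contains a cycle: {cycle}")

    alt_ids: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term
    return OntologyDAG(
        term_ids=frozenset(isa.nodes),
        parents={
            t: frozenset(isa.successors(t)) for t in isa.nodes if isa.out_degree(t)
        },
        alt_ids=alt_ids,
    )


def read_annotation_tsv(path: str | Path, dag: OntologyDAG | None = None) -> AnnotationTable:
    """Read a headerless two-column ``gene<TAB>term`` annotation file.

    When ``dag`` is given, alt_id accessions are mapped to canonical ids.
    Gene order follows first appearance in the file.
    """
    genes: list[str] = []
    assignments: dict[str, set[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
        gene, term = parts
        if dag is not None:
            term = dag.canonical(term)
        if gene not in assignments:
            genes.append(gene)
            assignments[gene] = set()
        assignments[gene].add(term)
    return AnnotationTable(
        gene_ids=tuple(genes),
        assignments={g: frozenset(ts) for g, ts in assignments.items()},
    )


def read_gaf(path: str | Path, dag: OntologyDAG | None = None) -> AnnotationTable:
    """Read a GAF 2.1/2.2 association file into an :class:`AnnotationTable`.

    Uses column 2 (DB Object ID) as the gene identifier and column 5 as the
    term accession. Rows whose qualifier contains ``NOT`` are skipped;
    evidence codes are not filtered.
    """
    genes: list[str] = []
    assignments: dict[str, set[str]] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw or raw.startswith("!"):
            continue
        cols = raw.split("\t")
        if len(cols) < 5:
            raise ValueError(f"{path}: GAF row with <5 columns: {raw!r}")
        gene, qualifier, term = cols[1], cols[3], cols[4]
        if "NOT" in qualifier.split("|"):
            continue
        if dag is not None:
            term = dag.canonical(term)
        if gene not in assignments:
            genes.append(gene)
            assignments[gene] = set()
        assignments[gene].add(term)
    return AnnotationTable(
        gene_ids=tuple(genes),
        assignments={g: frozenset(ts) for g, ts in assignments.items()},
    )


def propagate_annotations(table: AnnotationTable, dag: OntologyDAG) -> AnnotationTable:
    """Close every gene's term set under the ancestor relation (true-path-rule)."""
    unknown = table.terms - dag.term_ids
    if unknown:
        raise UnknownTermError(unknown)
    new_assignments: dict[str, frozenset[str]] = {}
    for gene, terms in table.assignments.items():
        closed = set(terms)
        for t in terms:
            closed |= dag.ancestors(t)
        new_assignments[gene] = frozenset(closed)
    return AnnotationTable(
        gene_ids=table.gene_ids, assignments=new_assignments, propagated=True
    )


def restrict_to_branch(
    table: AnnotationTable,
    dag: OntologyDAG,
    branch_root: str,
    include_root: bool = False,
) -> AnnotationTable:
    """Keep only terms inside one ontology branch.

    After propagation the branch root itself annotates every retained gene and
    carries no signal, so it is excluded from the label space by default
    (``include_root=False``). Genes left with no terms are dropped.
    """
    if branch_root not in dag.term_ids:
        raise UnknownTermError([branch_root])
    keep = set(dag.descendants(branch_root))
    if include_root:
        keep.add(branch_root)
    genes: list[str] = []
    assignments: dict[str, frozenset[str]] = {}
    for gene in table.gene_ids:
        terms = frozenset(t for t in table.assignments[gene] if t in keep)
        if terms:
            genes.append(gene)
            assignments[gene] = terms
    return AnnotationTable(
        gene_ids=tuple(genes), assignments=assignments, propagated=table.propagated
    )


def filter_terms_by_count(
    table: AnnotationTable, min_genes: int = 11
) -> tuple[AnnotationTable, TermGroupTable]:
    """Drop terms annotating fewer than ``min_genes`` genes and bin the rest.

    Counts are computed once before removal (single pass): dropping sparse
    terms can orphan genes, but the resulting count changes are deliberately
    not re-iterated. Genes left with empty term sets are dropped.
    """
    counts = table.term_counts()
    surviving = {t for t, c in counts.items() if c >= min_genes}
    if not surviving:
        raise ValueError("empty label space: every term fell below the count filter")
    genes: list[str] = []
    assignments: dict[str, frozenset[str]] = {}
    for gene in table.gene_ids:
        terms = frozenset(t for t in table.assignments[gene] if t in surviving)
        if terms:
            genes.append(gene)
            assignments[gene] = terms
    groups = TermGroupTable(
        groups={t: term_group_for_count(counts[t]) for t in sorted(surviving)}
    )
    filtered = AnnotationTable(
        gene_ids=tuple(genes), assignments=assignments, propagated=table.propagated
    )
    return filtered, groups
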