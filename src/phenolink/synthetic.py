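"""Seeded synthetic benchmark data for the full pipeline.

The generator emulates the statistical premise the method rests on —
functionally related genes interact more, share functional annotations, and
share phenotypes — with the minimal model exhibiting that co-dependence: a
stochastic block model. Genes belong to B functional blocks;

* edges appear within a block with probability ``p_in`` and across blocks
  with ``p_out`` (p_in >> p_out);
* each binary attribute term is tied to one block and is active with a high
  probability (``attr_on``) in its block, a low one (``attr_off``) elsewhere;
* each phenotype term is linked to a subset of blocks: genes in a linked
  block are annotated with probability ``rho_on``, others with ``rho_off``,
  and every annotation cell is flipped with a small noise rate.

A two-snapshot mode hides all annotations of a seeded 10% gene subset at t0,
producing exactly the genes a temporal split must recover as its test set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .graph import AdjacencyMatrix, AttributeMatrix, GeneIndex
from .ontology import AnnotationTable

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_graph", "generate_attributes", "generate_labels", "generate_dataset", "write_fixture_files"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Benchmark-generator parameters (defaults are the standard benchmark)."""

    n: int = 300
    blocks: int = 3
    p_in: float = 0.2
    p_out: float = 0.02
    m_attr: int = 60
    attr_on: float = 0.3
    attr_off: float = 0.05
    q_terms: int = 20
    rho_on: float = 0.6
    rho_off: float = 0.05
    flip_rate: float = 0.02
    hidden_fraction: float = 0.1  # genes hidden at t0 in snapshot mode
    seed: int = 17

    def __post_init__(self) -> None:
        probs = (
            self.p_in, self.p_out, self.attr_on, self.attr_off,
            self.rho_on, self.rho_off, self.flip_rate, self.hidden_fraction,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.blocks < 2:
            raise ValueError("need at least 2 blocks")
        if self.n < self.blocks:
            raise ValueError("need at least one gene per block")


@dataclass(frozen=True)
class SyntheticDataset:
    """A complete synthetic problem instance over one gene universe."""

    index: GeneIndex
    adjacency: AdjacencyMatrix
    attributes: AttributeMatrix
    labels: np.ndarray  # n x q binary
    terms: tuple[str, ...]
    blocks: np.ndarray  # ground-truth block of each gene
    annotations_t0: AnnotationTable | None = None
    annotations_t1: AnnotationTable | None = None
    hidden_genes: frozenset[str] | None = None


def _block_assignment(spec: SyntheticSpec) -> np.ndarray:
    # contiguous, near-equal blocks: sizes differ by at most 1 and sum to n
    sizes = [spec.n // spec.blocks] * spec.blocks
    for b in range(spec.n % spec.blocks):
        sizes[b] += 1
    return np.repeat(np.arange(spec.blocks), sizes)


def generate_graph(spec: SyntheticSpec) -> tuple[AdjacencyMatrix, np.ndarray]:
    """Sample a stochastic block model adjacency; returns (A, block labels)."""
    rng = np.random.default_rng(spec.seed)
    blocks = _block_assignment(spec)
    index = GeneIndex(ids=tuple(f"G{i:04d}" for i in range(spec.n)))
    iu, ju = np.triu_indices(spec.n, k=1)
    p = np.where(blocks[iu] == blocks[ju], spec.p_in, spec.p_out)
    keep = rng.random(p.shape) < p
    rows = np.concatenate([iu[keep], ju[keep]])
    cols = np.concatenate([ju[keep], iu[keep]])
    A = sp.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(spec.n, spec.n), dtype=np.float64
    )
    return AdjacencyMatrix(matrix=A, index=index), blocks


def generate_attributes(spec: SyntheticSpec, blocks: np.ndarray) -> AttributeMatrix:
    """Sample block-correlated binary attributes (one block per attribute term)."""
    rng = np.random.default_rng(spec.seed + 1)
    index = GeneIndex(ids=tuple(f"G{i:04d}" for i in range(len(blocks))))
    attr_block = np.arange(spec.m_attr) % spec.blocks
    p = np.where(
        blocks[:, None] == attr_block[None, :], spec.attr_on, spec.attr_off
    )
    X = (rng.random(p.shape) < p).astype(np.float64)
    cols = tuple(f"ATTR:{j:04d}" for j in range(spec.m_attr))
    return AttributeMatrix(X=X, columns=cols, kind="raw", index=index)


def generate_labels(
    spec: SyntheticSpec, blocks: np.ndarray, snapshots: bool = False
) -> tuple[np.ndarray, tuple[str, ...], AnnotationTable | None, AnnotationTable | None, frozenset[str] | None]:
    """Sample block-linked multi-label phenotype annotations.

    Term j is linked to one or two blocks (deterministic round-robin); genes
    in linked blocks are positive with rho_on, others with rho_off, then
    every cell flips with the noise rate. In snapshot mode the t0 table
    drops all annotations of a seeded ``hidden_fraction`` of genes.
    """
    rng = np.random.default_rng(spec.seed + 2)
    n, q, B = len(blocks), spec.q_terms, spec.blocks
    terms = tuple(f"SYN:{j + 1:07d}" for j in range(q))
    linked: list[set[int]] = []
    for j in range(q):
        s = {j % B}
        if j % 2 == 1:  # every other term spans two blocks
            s.add((j + 1) % B)
        linked.append(s)
    Y = np.zeros((n, q), dtype=np.float64)
    for j in range(q):
        in_linked = np.isin(blocks, list(linked[j]))
        p = np.where(in_linked, spec.rho_on, spec.rho_off)
        col = (rng.random(n) < p).astype(np.float64)
        flip = rng.random(n) < spec.flip_rate
        col = np.where(flip, 1.0 - col, col)
        if col.sum() == 0:  # regenerate a dead column once, then give up
            col = (rng.random(n) < p).astype(np.float64)
            if col.sum() == 0:
                raise RuntimeError(f"term {terms[j]} drew zero positives twice")
        Y[:, j] = col

    if not snapshots:
        return Y, terms, None, None, None

    genes = tuple(f"G{i:04d}" for i in range(n))
    n_hidden = max(1, int(round(spec.hidden_fraction * n)))
    # hide only genes that have >= 1 annotation, so they reappear at t1
    annotated = np.where(Y.sum(axis=1) > 0)[0]
    hidden_idx = rng.choice(annotated, size=min(n_hidden, annotated.size), replace=False)
    hidden = frozenset(genes[i] for i in hidden_idx)

    def table(mask_hidden: bool) -> AnnotationTable:
        gene_list: list[str] = []
        assignments: dict[str, frozenset[str]] = {}
        for i, g in enumerate(genes):
            if mask_hidden and g in hidden:
                continue
            ts = frozenset(terms[j] for j in range(q) if Y[i, j] > 0)
            if ts:
                gene_list.append(g)
                assignments[g] = ts
        return AnnotationTable(
            gene_ids=tuple(gene_list), assignments=assignments, propagated=True
        )

    return Y, terms, table(mask_hidden=True), table(mask_hidden=False), hidden


def generate_dataset(spec: SyntheticSpec = SyntheticSpec(), snapshots: bool = False) -> SyntheticDataset:
    """Generate a full, internally consistent synthetic problem instance."""
    A, blocks = generate_graph(spec)
    X = generate_attributes(spec, blocks)
    Y, terms, t0, t1, hidden = generate_labels(spec, blocks, snapshots=snapshots)
    return SyntheticDataset(
        index=A.index,
        adjacency=A,
        attributes=X,
        labels=Y,
        terms=terms,
        blocks=blocks,
        annotations_t0=t0,
        annotations_t1=t1,
        hidden_genes=hidden,
    )


def write_fixture_files(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as the standard text formats the readers consume.

    Produces a scored edge-list TSV, a gene->attribute TSV, a
    gene->phenotype TSV, and a minimal OBO ontology (a root term with every
    phenotype term as a direct is_a child) so file-based runs exercise the
    real parsers end to end.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    A = dataset.adjacency.matrix.tocoo()
    lines = [
        f"{dataset.index.gene(i)}\t{dataset.index.gene(j)}\t1.0"
        for i, j in zip(A.row, A.col)
        if i < j
    ]
    paths["edges"] = outdir / "edges.tsv"
    paths["edges"].write_text("\n".join(lines) + ("\n" if lines else ""))

    attr_lines = []
    for i, g in enumerate(dataset.index.ids):
        for j, c in enumerate(dataset.attributes.columns):
            if dataset.attributes.X[i, j] > 0:
                attr_lines.append(f"{g}\t{c}")
    paths["gene2attr"] = outdir / "gene2attr.tsv"
    paths["gene2attr"].write_text("\n".join(attr_lines) + "\n")

    pheno_lines = []
    for i, g in enumerate(dataset.index.ids):
        for j, t in enumerate(dataset.terms):
            if dataset.labels[i, j] > 0:
                pheno_lines.append(f"{g}\t{t}")
    paths["gene2pheno"] = outdir / "gene2pheno.tsv"
    paths["gene2pheno"].write_text("\n".join(pheno_lines) + "\n")

    root = "SYN:0000000"
    stanzas = [
        "format-version: 1.2",
        "",
        "[Term]",
        f"id: {root}",
        "name: synthetic phenotype root",
    ]
    for t in dataset.terms:
        stanzas += ["", "[Term]", f"id: {t}", f"name: synthetic term {t}", f"is_a: {root}"]
    paths["obo"] = outdir / "phenotypes.obo"
    paths["obo"].write_text("\n".join(stanzas) + "\n")
    return paths
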