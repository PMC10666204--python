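"""Gene attributed-network construction.

Builds the graph ``G = {V, E, X}``: nodes are genes, edges are confident
protein-protein interactions (combined score >= a threshold, 0.3 by default),
and node attributes are binary GO-annotation indicator vectors, optionally
reduced with PCA. Genes that appear in the annotation tables but not in the
interaction file are kept as isolated nodes; the smoothing filter's implicit
self-loop still lets them carry their own attributes downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .ontology import AnnotationTable

__all__ = [
    "GeneIndex",
    "AdjacencyMatrix",
    "AttributeMatrix",
    "read_edge_list",
    "build_adjacency",
    "build_go_attributes",
    "reduce_dimensions_pca",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneIndex:
    """Ordered gene identifiers with a bidirectional gene<->row map (0-based)."""

    ids: tuple[str, ...]
    _pos: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("gene identifiers must be unique")
        object.__setattr__(self, "_pos", {g: i for i, g in enumerate(self.ids)})

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self._pos

    def position(self, gene: str) -> int:
        return self._pos[gene]

    def gene(self, i: int) -> str:
        return self.ids[i]


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary symmetric adjacency with zero diagonal, paired with a GeneIndex."""

    matrix: sp.csr_matrix
    index: GeneIndex

    def __post_init__(self) -> None:
        A = self.matrix
        n = len(self.index)
        if A.shape != (n, n):
            raise ValueError(f"adjacency shape {A.shape} != ({n}, {n})")
        if A.diagonal().any():
            raise ValueError("adjacency diagonal must be zero")
        if (A != A.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        data = A.data
        if data.size and not np.all((data == 0) | (data == 1)):
            raise ValueError("adjacency entries must be binary")

    @property
    def n(self) -> int:
        return len(self.index)


@dataclass(frozen=True)
class AttributeMatrix:
    """Node attribute matrix X (genes x terms/components), raw or PCA-reduced."""

    X: np.ndarray
    columns: tuple[str, ...]
    kind: str  # "raw" | "reduced"
    index: GeneIndex

    def __post_init__(self) -> None:
        if self.kind not in ("raw", "reduced"):
            raise ValueError("kind must be 'raw' or 'reduced'")
        if self.X.shape != (len(self.index), len(self.columns)):
            raise ValueError("attribute shape does not match index/columns")
        if self.kind == "raw" and self.X.size:
            vals = np.unique(self.X)
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError("raw attribute matrix must be binary")


def read_edge_list(
    path: str | Path, string_scale: bool = False
) -> list[tuple[str, str, float]]:
    """Read a ``gene_a<TAB>gene_b<TAB>score`` edge list.

    ``string_scale=True`` divides raw STRING combined scores (0-1000 integers)
    by 1000 so the core builder only ever sees scores in [0, 1].
    """
    edges: list[tuple[str, str, float]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
        a, b, s = parts
        score = float(s)
        if string_scale:
            score /= 1000.0
        edges.append((a, b, score))
    return edges


def build_adjacency(
    edges: Iterable[tuple[str, str, float]],
    index: GeneIndex,
    threshold: float = 0.3,
) -> AdjacencyMatrix:
    """Threshold a scored edge list into a binary symmetric adjacency matrix.

    An edge is kept iff its score is >= ``threshold`` (scores must already be
    in [0, 1]). Self-edges are ignored; duplicate pairs take the max score.
    """
    n = len(index)
    best: dict[tuple[int, int], float] = {}
    for a, b, score in edges:
        if a not in index or b not in index:
            raise KeyError(f"edge endpoint not in gene index: {(a, b)}")
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"edge score outside [0, 1]: {(a, b, score)}")
        i, j = index.position(a), index.position(b)
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if score > best.get(key, -1.0):
            best[key] = score
    rows, cols = [], []
    for (i, j), score in best.items():
        if score >= threshold:
            rows += [i, j]
            cols += [j, i]
    A = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.float64
    )
    return AdjacencyMatrix(matrix=A, index=index)


def build_go_attributes(
    go_annotations: AnnotationTable, index: GeneIndex
) -> AttributeMatrix:
    """Encode GO annotations as a binary gene x term indicator matrix.

    Columns are the lexicographically sorted union of annotated terms, so the
    matrix is invariant to input-row permutation. Genes without any GO
    annotation keep an all-zero row (logged, not dropped).
    """
    vocab = tuple(sorted(go_annotations.terms))
    col = {t: j for j, t in enumerate(vocab)}
    X = np.zeros((len(index), len(vocab)), dtype=np.float64)
    unannotated = 0
    for i, gene in enumerate(index.ids):
        terms = go_annotations.assignments.get(gene, frozenset())
        if not terms:
            unannotated += 1
            continue
        for t in terms:
            X[i, col[t]] = 1.0
    if unannotated:
        log.info("build_go_attributes: %d genes with zero attributes", unannotated)
    return AttributeMatrix(X=X, columns=vocab, kind="raw", index=index)


def reduce_dimensions_pca(
    attributes: AttributeMatrix, d: int = 1000, seed: int = 0
) -> AttributeMatrix:
    """Project the raw attribute matrix onto its first ``d`` principal components.

    The projection is fit on all rows (the pipeline pretrains transductively on
    the full graph). Output width is min(d, rank of the centered matrix);
    components are ordered by decreasing explained variance, with each
    component's sign fixed so its largest-magnitude loading is positive.
    ``seed`` is recorded for provenance; the full SVD solver is deterministic.
    """
    if d < 1:
        raise ValueError(f"PCA dimension must be >= 1, got {d}")
    X = attributes.X
    n, m = X.shape
    n_comp = min(d, n, m)
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(X)
    # drop numerically-zero components (d above the rank of centered X)
    sv = pca.singular_values_
    tol = max(n, m) * np.finfo(np.float64).eps * (sv[0] if sv.size else 0.0)
    rank = int(np.sum(sv > tol))
    if rank < n_comp:
        log.warning(
            "reduce_dimensions_pca: requested %d components, rank is %d", d, rank
        )
    scores = scores[:, :rank]
    comps = pca.components_[:rank]
    # sign convention: largest-|loading| entry of each component is positive
    flip = np.sign(comps[np.arange(rank), np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    return AttributeMatrix(
        X=scores,
        columns=tuple(f"PC{j + 1}" for j in range(rank)),
        kind="reduced",
        index=attributes.index,
    )
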