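"""Build a gene attributed network from an edge list and annotations.

Simulates a small interactome, writes it to the standard text formats, reads
it back through the real parsers, and reduces the binary attribute matrix
with PCA — the preprocessing every downstream stage consumes.
"""

import tempfile
from pathlib import Path

from phenolink import (
    SyntheticSpec,
    build_adjacency,
    build_go_attributes,
    generate_dataset,
    read_annotation_tsv,
    read_edge_list,
    reduce_dimensions_pca,
    write_fixture_files,
)

workdir = Path(tempfile.mkdtemp())
dataset = generate_dataset(SyntheticSpec(n=100, seed=17))
paths = write_fixture_files(dataset, workdir)

edges = read_edge_list(paths["edges"])
attrs_table = read_annotation_tsv(paths["gene2attr"])
index = dataset.index
A = build_adjacency(edges, index, threshold=0.3)
X = build_go_attributes(attrs_table, index)
X_red = reduce_dimensions_pca(X, d=30, seed=1)

print(f"genes: {len(index)}")
print(f"edges kept at threshold 0.3: {A.matrix.nnz // 2}")
print(f"raw attribute matrix: {X.X.shape}, density {X.X.mean():.3f}")
print(f"PCA-reduced attributes: {X_red.X.shape}")
# The network couples interaction topology with sparse binary annotation
# attributes; PCA compresses the sparse indicators into dense components.
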