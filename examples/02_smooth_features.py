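"""Laplacian feature smoothing: H = I - alpha * L_sym applied t times.

Shows the worked two-node filter and how smoothing shrinks the feature
disagreement between connected genes while preserving graph-constant signal.
"""

import numpy as np
import scipy.sparse as sp

from phenolink import AdjacencyMatrix, GeneIndex, apply_filter, build_filter

# two genes, one edge, alpha = 2/3 -> H = [[2/3, 1/3], [1/3, 2/3]]
pair = AdjacencyMatrix(
    matrix=sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]])),
    index=GeneIndex(ids=("gA", "gB")),
)
H = build_filter(pair, alpha=2 / 3)
print("two-node filter:\n", H.toarray())

# a 10-gene ring: neighbours disagree on a noisy feature; smoothing averages it
n = 10
ring = np.zeros((n, n))
for i in range(n):
    ring[i, (i + 1) % n] = ring[(i + 1) % n, i] = 1
A = AdjacencyMatrix(
    matrix=sp.csr_matrix(ring), index=GeneIndex(tuple(f"g{i}" for i in range(n)))
)
rng = np.random.default_rng(0)
x = np.ones((n, 1)) + rng.normal(0, 0.5, (n, 1))
H = build_filter(A, alpha=2 / 3)
for t in (0, 1, 2, 4):
    sm = apply_filter(H, x, t=t).X
    disagreement = np.abs(np.diff(sm[:, 0], append=sm[0, 0])).mean()
    print(f"t={t}: mean neighbour disagreement {disagreement:.4f}")
# Disagreement falls with t: the filter attenuates high graph frequencies,
# i.e. exactly the components where linked genes disagree.
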