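"""Self-supervised pretraining of a linear gene encoder.

The pretext task: encode smoothed node features with a linear map
``Z = X~ W``, min-max scale each embedding column to [0, 1], compute all
pairwise cosine similarities, and declare the k most-similar unordered gene
pairs positives (label 1) and the k least-similar pairs negatives (label 0).
The encoder is trained with Adam to minimize the binary cross-entropy of the
pair similarities against these self-generated labels; the pair sets are
re-selected as training progresses. Pulling already-similar genes together
and pushing dissimilar ones apart sharpens the cluster structure that the
smoothing filter exposed, which is exactly the structure phenotype labels
follow when functionally related genes share phenotypes.

Because scaling keeps Z non-negative, all cosine similarities lie in [0, 1]
and can be read directly as Bernoulli probabilities in the loss.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .smoothing import SmoothedFeatures

__all__ = [
    "EncoderWeights",
    "PretrainConfig",
    "TrainingPairSet",
    "encode",
    "minmax_scale_columns",
    "cosine_similarity_matrix",
    "select_training_pairs",
    "ssl_loss",
    "init_encoder",
    "pretrain",
]

log = logging.getLogger(__name__)

_CLAMP_EPS = 1e-15


@dataclass
class EncoderWeights:
    """Linear-encoder weight matrix (input dim x embedding dim) plus init record."""

    W: np.ndarray
    init_scheme: str = "uniform(-1/sqrt(d), 1/sqrt(d))"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.W.ndim != 2 or self.W.shape[1] < 1:
            raise ValueError("W must be a d x e matrix with e >= 1")
        if not np.isfinite(self.W).all():
            raise ValueError("encoder weights must be finite")


@dataclass(frozen=True)
class TrainingPairSet:
    """k positive and k negative unordered gene pairs with self-supervision labels."""

    positives: tuple[tuple[int, int], ...]
    negatives: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise ValueError("positive and negative pair counts must match")
        allp = self.positives + self.negatives
        for i, j in allp:
            if i == j:
                raise ValueError(f"self-pair not allowed: {(i, j)}")
            if i > j:
                raise ValueError(f"pairs must be stored as (i < j): {(i, j)}")
        if len(set(allp)) != len(allp):
            raise ValueError("pair sets overlap or contain duplicates")

    @property
    def k(self) -> int:
        return len(self.positives)


@dataclass(frozen=True)
class PretrainConfig:
    """Pretraining hyper-parameters.

    k: number of positive (= negative) pairs; None selects 10 * n_genes.
    embed_dim: embedding width e (2048 mirrors the real-data setting; scale
        it down with the problem).
    reselect_every: epochs between pair re-selections.
    similarity_ceiling: refuse to materialize the dense n x n similarity
        matrix above this many genes.
    """

    embed_dim: int = 2048
    k: int | None = None
    epochs: int = 100
    learning_rate: float = 1e-3
    reselect_every: int = 1
    seed: int = 0
    similarity_ceiling: int = 20_000

    def __post_init__(self) -> None:
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.reselect_every < 1:
            raise ValueError("reselect_every must be >= 1")


def minmax_scale_columns(Y: np.ndarray) -> np.ndarray:
    """Scale each column to [0, 1]; a constant column becomes all zeros."""
    lo = Y.min(axis=0)
    hi = Y.max(axis=0)
    rng = hi - lo
    safe = np.where(rng > 0, rng, 1.0)
    Z = (Y - lo) / safe
    Z[:, rng == 0] = 0.0
    return Z


def encode(Xs: SmoothedFeatures | np.ndarray, weights: EncoderWeights) -> np.ndarray:
    """Embed genes: Z = minmax(X~ W), entries in [0, 1]."""
    X = Xs.X if isinstance(Xs, SmoothedFeatures) else np.asarray(Xs)
    Y = X @ weights.W
    if not np.isfinite(Y).all():
        bad = np.where(~np.isfinite(Y).all(axis=0))[0]
        raise FloatingPointError(f"non-finite embedding columns: {bad.tolist()}")
    return minmax_scale_columns(Y)


def cosine_similarity_matrix(Z: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity of embedding rows.

    All-zero rows get similarity 0 to everything (including themselves);
    this is logged because such genes carry no embedding signal.
    """
    norms = np.linalg.norm(Z, axis=1)
    zero = norms == 0
    if zero.any():
        log.info("cosine_similarity_matrix: %d all-zero rows", int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    U = Z / safe[:, None]
    S = U @ U.T
    np.clip(S, 0.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    return S


def _upper_triangle_order(S: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row/col indices of unordered non-self pairs, sorted by similarity
    descending with lexicographic (i, j) tie-break."""
    n = S.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = S[iu, ju]
    # lexsort: last key is primary. Primary: -similarity; then i, then j ascending.
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order], vals[order]


def select_training_pairs(S: np.ndarray, k: int) -> TrainingPairSet:
    """Pick the top-k most-similar pairs as positives and bottom-k as negatives.

    All unordered non-self pairs are ranked by similarity (descending, ties
    broken by lexicographic (i, j)); positives are the first k of the ranking
    and negatives the last k. Requires 2k <= number of pairs so the two
    windows cannot overlap.
    """
    n = S.shape[0]
    n_pairs = n * (n - 1) // 2
    if k < 1:
        raise ValueError("k must be >= 1")
    if 2 * k > n_pairs:
        raise ValueError(f"2k = {2 * k} exceeds the {n_pairs} available pairs")
    iu, ju, _ = _upper_triangle_order(S)
    pos = tuple((int(iu[r]), int(ju[r])) for r in range(k))
    neg = tuple((int(iu[r]), int(ju[r])) for r in range(n_pairs - k, n_pairs))
    return TrainingPairSet(positives=pos, negatives=neg)


def ssl_loss(S: np.ndarray, pairs: TrainingPairSet) -> float:
    """Summed binary cross-entropy of pair similarities vs pair labels.

    Similarities are clamped to [eps, 1 - eps] (eps = 1e-15) so the loss is
    finite even for saturated pairs.
    """
    total = 0.0
    for (i, j) in pairs.positives:
        s = min(max(S[i, j], _CLAMP_EPS), 1.0 - _CLAMP_EPS)
        total -= math.log(s)
    for (i, j) in pairs.negatives:
        s = min(max(S[i, j], _CLAMP_EPS), 1.0 - _CLAMP_EPS)
        total -= math.log(1.0 - s)
    return total


def init_encoder(d: int, embed_dim: int, seed: int) -> EncoderWeights:
    """Symmetric uniform init scaled by 1/sqrt(d), seeded."""
    rng = np.random.default_rng(seed)
    bound = 1.0 / math.sqrt(max(d, 1))
    W = rng.uniform(-bound, bound, size=(d, embed_dim))
    return EncoderWeights(W=W, seed=seed)


def _loss_and_grad(
    X: np.ndarray, W: np.ndarray, pairs: TrainingPairSet
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss, dL/dW, and the embedding Z for the current weights.

    Backprop runs through the cosine similarity and the linear map; the
    per-column min and max of the scaling step are treated as constants
    (stop-gradient), recomputed at every forward pass.
    """
    Y = X @ W
    lo, hi = Y.min(axis=0), Y.max(axis=0)
    rng_col = hi - lo
    nonconst = rng_col > 0
    safe = np.where(nonconst, rng_col, 1.0)
    Z = (Y - lo) / safe
    Z[:, ~nonconst] = 0.0

    norms = np.linalg.norm(Z, axis=1)
    zero = norms == 0
    nsafe = np.where(zero, 1.0, norms)
    U = Z / nsafe[:, None]

    ii = np.array([i for i, _ in pairs.positives + pairs.negatives], dtype=int)
    jj = np.array([j for _, j in pairs.positives + pairs.negatives], dtype=int)
    yy = np.concatenate([np.ones(pairs.k), np.zeros(pairs.k)])

    s_raw = np.einsum("ij,ij->i", U[ii], U[jj])
    s = np.clip(s_raw, _CLAMP_EPS, 1.0 - _CLAMP_EPS)
    live = ~(zero[ii] | zero[jj])  # zero rows have defined-zero similarity
    s = np.where(live, s, _CLAMP_EPS)
    loss = float(-np.sum(yy * np.log(s) + (1.0 - yy) * np.log(1.0 - s)))

    dl_ds = np.where(live, -(yy / s) + (1.0 - yy) / (1.0 - s), 0.0)
    # d s / d z_i = (u_j - s * u_i) / ||z_i||  (and symmetrically for z_j)
    Gz = np.zeros_like(Z)
    np.add.at(Gz, ii, (dl_ds / nsafe[ii])[:, None] * (U[jj] - s_raw[:, None] * U[ii]))
    np.add.at(Gz, jj, (dl_ds / nsafe[jj])[:, None] * (U[ii] - s_raw[:, None] * U[jj]))

    Gy = Gz / safe
    Gy[:, ~nonconst] = 0.0
    Gw = X.T @ Gy
    return loss, Gw, Z


def pretrain(
    Xs: SmoothedFeatures | np.ndarray, cfg: PretrainConfig
) -> tuple[EncoderWeights, np.ndarray, list[float]]:
    """Train the linear encoder on the pair-similarity pretext task.

    Returns the final weights, the final [0, 1]-scaled embedding matrix, and
    the per-epoch loss trace. Deterministic for a given config (the only
    randomness is the seeded weight init).
    """
    X = Xs.X if isinstance(Xs, SmoothedFeatures) else np.asarray(Xs, dtype=np.float64)
    n, d = X.shape
    if n > cfg.similarity_ceiling:
        raise ValueError(
            f"{n} genes exceeds similarity_ceiling={cfg.similarity_ceiling}; "
            "dense pairwise similarity would not fit — use batched ranking"
        )
    k = cfg.k if cfg.k is not None else 10 * n
    n_pairs = n * (n - 1) // 2
    if 2 * k > n_pairs:
        raise ValueError(f"k={k} too large for {n_pairs} unordered pairs")

    weights = init_encoder(d, cfg.embed_dim, cfg.seed)
    W = weights.W
    trace: list[float] = []

    # Adam state
    m = np.zeros_like(W)
    v = np.zeros_like(W)
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    pairs: TrainingPairSet | None = None
    for epoch in range(cfg.epochs):
        if pairs is None or epoch % cfg.reselect_every == 0:
            Z = encode(X, EncoderWeights(W=W, seed=cfg.seed))
            S = cosine_similarity_matrix(Z)
            pairs = select_training_pairs(S, k)
        loss, Gw, _ = _loss_and_grad(X, W, pairs)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite pretraining loss at epoch {epoch} "
                f"(k={pairs.k}, |W|max={np.abs(W).max():.3g})"
            )
        trace.append(loss)
        m = beta1 * m + (1 - beta1) * Gw
        v = beta2 * v + (1 - beta2) * Gw**2
        mhat = m / (1 - beta1 ** (epoch + 1))
        vhat = v / (1 - beta2 ** (epoch + 1))
        W = W - cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        log.debug("pretrain epoch %d: loss %.4f (k=%d)", epoch, loss, pairs.k)

    final = EncoderWeights(W=W, seed=cfg.seed)
    Z = encode(X, final)
    return final, Z, trace
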