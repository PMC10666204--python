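"""Multi-label phenotype classifier: a feed-forward network on gene embeddings.

Architecture: an input layer, three hidden layers (affine -> batch
normalization -> LeakyReLU), and a sigmoid output layer of one unit per
phenotype term. Training minimizes the multi-label binary cross-entropy

    L = -sum[ y * log(p) + (1 - y) * log(1 - p) ]

averaged over the gene-term entries of each mini-batch, with Adam. Batch
normalization keeps running mean/variance estimates so inference is
batch-independent: predicting a single gene gives the same scores as
predicting it inside any batch.

The classifier is pluggable: anything implementing :class:`PhenotypeScorer`
(``fit`` + ``predict_proba``) can replace the network downstream, which is
how classical baselines (SVM / RF / LR) slot in without being reimplemented
here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

__all__ = ["ClassifierConfig", "PhenotypeScorer", "DNNClassifier", "train_classifier", "predict"]

log = logging.getLogger(__name__)

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@runtime_checkable
class PhenotypeScorer(Protocol):
    """Anything that maps gene embeddings to per-term scores in [0, 1]."""

    def fit(self, Z: np.ndarray, Y: np.ndarray) -> "PhenotypeScorer": ...

    def predict_proba(self, Z: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class ClassifierConfig:
    """Network and optimizer hyper-parameters.

    hidden_sizes: widths of the hidden layers (three by default).
    leaky_slope: negative-side slope of LeakyReLU.
    batch_size / learning_rate: 128 and 1e-3 (Adam).
    epochs: training-epoch cap; early stopping watches a validation split of
        the training genes (``val_fraction``) with the given patience.
    """

    hidden_sizes: tuple[int, ...] = (1024, 512, 512)
    leaky_slope: float = 0.01
    batch_size: int = 128
    learning_rate: float = 1e-3
    epochs: int = 200
    patience: int = 20
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be >= 1")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class _Layer:
    W: np.ndarray
    b: np.ndarray
    gamma: np.ndarray | None = None  # BN scale (hidden layers only)
    beta: np.ndarray | None = None
    run_mean: np.ndarray | None = None
    run_var: np.ndarray | None = None

    def params(self) -> list[np.ndarray]:
        out = [self.W, self.b]
        if self.gamma is not None:
            out += [self.gamma, self.beta]
        return out


class DNNClassifier:
    """Feed-forward multi-label classifier with hand-rolled backprop."""

    def __init__(self, cfg: ClassifierConfig = ClassifierConfig()):
        self.cfg = cfg
        self.layers: list[_Layer] = []
        self.n_terms: int | None = None
        self.loss_trace: list[float] = []

    # -- construction ------------------------------------------------------

    def _build(self, n_in: int, n_out: int) -> None:
        rng = np.random.default_rng(self.cfg.seed)
        dims = [n_in, *self.cfg.hidden_sizes]
        self.layers = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            bound = np.sqrt(6.0 / (d_in + d_out))  # Glorot uniform
            self.layers.append(
                _Layer(
                    W=rng.uniform(-bound, bound, size=(d_in, d_out)),
                    b=np.zeros(d_out),
                    gamma=np.ones(d_out),
                    beta=np.zeros(d_out),
                    run_mean=np.zeros(d_out),
                    run_var=np.ones(d_out),
                )
            )
        bound = np.sqrt(6.0 / (dims[-1] + n_out))
        self.layers.append(
            _Layer(W=rng.uniform(-bound, bound, size=(dims[-1], n_out)), b=np.zeros(n_out))
        )
        self.n_terms = n_out

    # -- forward / backward ------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool) -> tuple[np.ndarray, list[dict]]:
        caches: list[dict] = []
        h = X
        for layer in self.layers[:-1]:
            a = h @ layer.W + layer.b
            if training:
                mu = a.mean(axis=0)
                var = a.var(axis=0)
                layer.run_mean = (1 - _BN_MOMENTUM) * layer.run_mean + _BN_MOMENTUM * mu
                layer.run_var = (1 - _BN_MOMENTUM) * layer.run_var + _BN_MOMENTUM * var
            else:
                mu, var = layer.run_mean, layer.run_var
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            ah = (a - mu) * inv_std
            bn = layer.gamma * ah + layer.beta
            out = _leaky(bn, self.cfg.leaky_slope)
            caches.append(
                {"a": a, "mu": mu, "inv_std": inv_std, "ah": ah, "bn": bn, "out": out}
            )
            h = out
        last = self.layers[-1]
        logits = h @ last.W + last.b
        return logits, caches

    def _backward(
        self, X: np.ndarray, Y: np.ndarray, logits: np.ndarray, caches: list[dict]
    ) -> list[np.ndarray]:
        n_elem = Y.size
        P = _sigmoid(logits)
        dlogits = (P - Y) / n_elem
        grads: list[np.ndarray] = []
        last = self.layers[-1]
        h_prev = caches[-1]["out"] if caches else X
        gW_last = h_prev.T @ dlogits
        gb_last = dlogits.sum(axis=0)
        dh = dlogits @ last.W.T
        layer_grads: list[list[np.ndarray]] = [[gW_last, gb_last]]
        for li in range(len(self.layers) - 2, -1, -1):
            layer = self.layers[li]
            cache = caches[li]
            bn = cache["bn"]
            dbn = dh * np.where(bn > 0, 1.0, self.cfg.leaky_slope)
            ah, inv_std, a, mu = cache["ah"], cache["inv_std"], cache["a"], cache["mu"]
            m = a.shape[0]
            dgamma = (dbn * ah).sum(axis=0)
            dbeta = dbn.sum(axis=0)
            dah = dbn * layer.gamma
            # standard batch-norm backward
            dvar = (dah * (a - mu)).sum(axis=0) * (-0.5) * inv_std**3
            dmu = (-dah * inv_std).sum(axis=0) + dvar * (-2.0 / m) * (a - mu).sum(axis=0)
            da = dah * inv_std + dvar * 2.0 * (a - mu) / m + dmu / m
            h_in = X if li == 0 else caches[li - 1]["out"]
            gW = h_in.T @ da
            gb = da.sum(axis=0)
            dh = da @ layer.W.T
            layer_grads.append([gW, gb, dgamma, dbeta])
        layer_grads.reverse()
        for g in layer_grads:
            grads.extend(g)
        return grads

    @staticmethod
    def _bce(logits: np.ndarray, Y: np.ndarray) -> float:
        # numerically stable mean binary cross-entropy from logits
        return float(
            np.mean(np.maximum(logits, 0) - logits * Y + np.log1p(np.exp(-np.abs(logits))))
        )

    # -- public API --------------------------------------------------------

    def fit(self, Z: np.ndarray, Y: np.ndarray) -> "DNNClassifier":
        """Train on embeddings Z (n x e) and binary labels Y (n x q)."""
        Z = np.asarray(Z, dtype=np.float64)
        Y = np.asarray(Y, dtype=np.float64)
        if not np.isfinite(Z).all():
            raise ValueError("non-finite values in embeddings")
        if Z.shape[0] != Y.shape[0]:
            raise ValueError("Z and Y row counts differ")
        zero_pos = np.where(Y.sum(axis=0) == 0)[0]
        if zero_pos.size:
            log.warning(
                "train_classifier: %d terms have no positive training genes",
                zero_pos.size,
            )
        cfg = self.cfg
        self._build(Z.shape[1], Y.shape[1])
        rng = np.random.default_rng(cfg.seed + 1)

        n = Z.shape[0]
        n_val = int(round(cfg.val_fraction * n))
        use_early = n_val >= 1 and cfg.patience > 0 and n - n_val >= 1
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if not use_early:
            tr_idx = perm
        Ztr, Ytr = Z[tr_idx], Y[tr_idx]

        params = [p for layer in self.layers for p in layer.params()]
        mstate = [np.zeros_like(p) for p in params]
        vstate = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_snapshot: list[np.ndarray] | None = None
        best_stats: list[np.ndarray] | None = None
        stale = 0
        self.loss_trace = []

        for epoch in range(cfg.epochs):
            order = rng.permutation(len(tr_idx))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                logits, caches = self._forward(Ztr[batch], training=True)
                epoch_loss += self._bce(logits, Ytr[batch])
                n_batches += 1
                grads = self._backward(Ztr[batch], Ytr[batch], logits, caches)
                step += 1
                for p, g, ms, vs in zip(params, grads, mstate, vstate):
                    ms *= beta1
                    ms += (1 - beta1) * g
                    vs *= beta2
                    vs += (1 - beta2) * g**2
                    mhat = ms / (1 - beta1**step)
                    vhat = vs / (1 - beta2**step)
                    p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            self.loss_trace.append(epoch_loss / max(n_batches, 1))

            if use_early:
                val_logits, _ = self._forward(Z[val_idx], training=False)
                val_loss = self._bce(val_logits, Y[val_idx])
                if val_loss < best_val - 1e-9:
                    best_val = val_loss
                    best_snapshot = [p.copy() for p in params]
                    best_stats = [
                        s.copy()
                        for layer in self.layers[:-1]
                        for s in (layer.run_mean, layer.run_var)
                    ]
                    stale = 0
                else:
                    stale += 1
                    if stale >= cfg.patience:
                        break
        if use_early and best_snapshot is not None:
            for p, snap in zip(params, best_snapshot):
                p[...] = snap
            it = iter(best_stats)
            for layer in self.layers[:-1]:
                layer.run_mean[...] = next(it)
                layer.run_var[...] = next(it)
        return self

    def predict_proba(self, Z: np.ndarray) -> np.ndarray:
        """Scores in (0, 1) for every gene-term pair, batch-independent."""
        if not self.layers:
            raise RuntimeError("classifier is not trained")
        Z = np.asarray(Z, dtype=np.float64)
        if Z.shape[1] != self.layers[0].W.shape[0]:
            raise ValueError(
                f"embedding width {Z.shape[1]} != model input "
                f"width {self.layers[0].W.shape[0]}"
            )
        logits, _ = self._forward(Z, training=False)
        return _sigmoid(logits)


def train_classifier(
    Z: np.ndarray,
    Y: np.ndarray,
    cfg: ClassifierConfig,
    train_gene_indices: Sequence[int] | np.ndarray,
) -> DNNClassifier:
    """Train a :class:`DNNClassifier` on the given subset of genes."""
    idx = np.asarray(train_gene_indices, dtype=int)
    model = DNNClassifier(cfg)
    return model.fit(Z[idx], np.asarray(Y)[idx])


def predict(model: PhenotypeScorer, Z: np.ndarray) -> np.ndarray:
    """Score all genes with a trained model (thin functional wrapper)."""
    return model.predict_proba(Z)
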