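"""Convolutional classifier over an embedding layer, in pure NumPy.

Architecture: an embedding layer turns the padded token-index sequence
into an (L_max × D) matrix per channel (a lookup, equivalent to one-hot
× W); convolution kernels of heights 2, 3 and 4 — each as wide as the
embedding (D), 128 filters per height — slide vertically with ReLU;
masked global max-pooling per filter concatenates to a 384-vector; a
384-unit fully connected layer and a softmax give the two class
probabilities.  Training minimizes cross-entropy with Adam (base rate
0.001, multiplied by 0.9 each epoch), L2 regularization and batch
size 64.

Three embedding-layer modes are supported:

* ``default`` — one channel, frozen at the pre-trained matrix W;
* ``embedding_training`` — one channel, initialized at W, updated by
  backpropagation;
* ``two_channel`` — two channels both initialized at W, one frozen and
  one trainable; each filter spans both channels, as in RGB images.

Because every embedding row is one of at most 85 vocabulary vectors,
the convolution factorizes through the vocabulary: projecting the
(V × D) matrix once per step and gathering rows by token index gives
the same result as convolving each (L × D) input, at a small fraction
of the arithmetic.  Gradients flow through the same factorization, so
trainable-embedding modes cost no extra full-width matmuls either.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from orivec.segmentation import PAD_INDEX
from orivec.skipgram import EmbeddingMatrix

logger = logging.getLogger(__name__)

MODES = ("default", "embedding_training", "two_channel")


@dataclass
class CNNConfig:
    kernel_heights: tuple[int, ...] = (2, 3, 4)
    filters_per_height: int = 128
    fc_units: int = 384
    l2_strength: float = 1e-4
    learning_rate: float = 0.001
    decay_rate: float = 0.9
    batch_size: int = 64
    epochs: int = 50
    seed: int = 0

    @property
    def pooled_dim(self) -> int:
        """Concatenated max-pool width: filters × number of heights."""
        return self.filters_per_height * len(self.kernel_heights)


@dataclass
class EmbeddingLayerSpec:
    """Per-channel embedding matrices with trainable flags."""

    mode: str
    channels: list[np.ndarray]
    trainable: list[bool]
    vocab: object = None

    @property
    def num_channels(self) -> int:
        return len(self.channels)

    @property
    def dim(self) -> int:
        return self.channels[0].shape[1]

    def lookup(self, idx: np.ndarray) -> list[np.ndarray]:
        """Index lookup per channel — identical to one-hot(idx) @ W."""
        return [W[idx] for W in self.channels]


def build_embedding_layer(W: EmbeddingMatrix, mode: str) -> EmbeddingLayerSpec:
    """Instantiate the embedding layer for one of the three modes."""
    if mode not in MODES:
        raise ValueError(f"unknown embedding mode {mode!r}; expected one of {MODES}")
    base = np.ascontiguousarray(W.W, dtype=np.float64)
    if mode == "default":
        channels, trainable = [base.copy()], [False]
    elif mode == "embedding_training":
        channels, trainable = [base.copy()], [True]
    else:  # two_channel: channel 1 frozen, channel 2 trainable
        channels, trainable = [base.copy(), base.copy()], [False, True]
    return EmbeddingLayerSpec(
        mode=mode, channels=channels, trainable=trainable, vocab=W.vocab
    )


class _Adam:
    """Adam with a per-epoch multiplicative decay of the base rate."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, decay: float):
        self.params = params
        self.lr0 = lr
        self.decay = decay
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.epoch = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        lr = self.lr0 * self.decay**self.epoch
        for k, g in grads.items():
            p = self.params[k]
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= lr * mh / (np.sqrt(vh) + self.eps)


class OriCNN:
    """The convolutional ORI/non-ORI classifier.

    Parameters
    ----------
    embedding : EmbeddingLayerSpec
        Channels and trainable flags (see :func:`build_embedding_layer`).
    l_max : int
        Padded input length; every encoded sequence must fit.
    config : CNNConfig
        Hyper-parameters; the defaults are the reference configuration.
    mask_padding : bool
        When True (default), max-pooling is restricted to windows that
        lie inside the true token length, so appending PAD never changes
        the output.  False reproduces naive unmasked pooling.
    """

    def __init__(
        self,
        embedding: EmbeddingLayerSpec,
        l_max: int,
        config: CNNConfig | None = None,
        mask_padding: bool = True,
    ):
        self.cfg = config or CNNConfig()
        self.emb = embedding
        self.l_max = int(l_max)
        self.mask_padding = mask_padding
        self.history: list[dict] = []
        rng = np.random.default_rng(self.cfg.seed)
        D, C, F = embedding.dim, embedding.num_channels, self.cfg.filters_per_height
        self.K: dict[int, np.ndarray] = {}
        self.bK: dict[int, np.ndarray] = {}
        for h in self.cfg.kernel_heights:
            fan_in = h * C * D
            self.K[h] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(h, C, D, F))
            self.bK[h] = np.zeros(F)
        P = self.cfg.pooled_dim
        self.FC1 = rng.normal(0.0, np.sqrt(2.0 / P), size=(P, self.cfg.fc_units))
        self.b1 = np.zeros(self.cfg.fc_units)
        self.FC2 = rng.normal(
            0.0, np.sqrt(1.0 / self.cfg.fc_units), size=(self.cfg.fc_units, 2)
        )
        self.b2 = np.zeros(2)
        self._opt: _Adam | None = None

    # ------------------------------------------------------------------ #
    # forward / backward
    # ------------------------------------------------------------------ #
    def _project_vocab(self) -> np.ndarray:
        """Σ_c W_c @ K[h][r,c] for all (h, r), concatenated column-wise.

        Returns a (V, Σ_h h·F) matrix; gathering its rows by token index
        reproduces the per-position convolution contributions.
        """
        blocks = []
        for h in self.cfg.kernel_heights:
            for r in range(h):
                acc = self.emb.channels[0] @ self.K[h][r, 0]
                for c in range(1, self.emb.num_channels):
                    acc += self.emb.channels[c] @ self.K[h][r, c]
                blocks.append(acc)
        return np.concatenate(blocks, axis=1)

    def _forward_batch(self, idx: np.ndarray, lens: np.ndarray, want_cache: bool):
        B, L = idx.shape
        F = self.cfg.filters_per_height
        WK = self._project_vocab()
        U = WK[idx]  # (B, L, Σ_h h·F)
        col = 0
        pooled_parts, cache_h = [], []
        for h in self.cfg.kernel_heights:
            T = L - h + 1
            if T < 1:
                raise ValueError(
                    f"padded length {L} is shorter than kernel height {h}"
                )
            pre = np.zeros((B, T, F))
            for r in range(h):
                pre += U[:, r : r + T, col : col + F]
                col += F
            pre += self.bK[h]
            act = np.maximum(pre, 0.0)
            if self.mask_padding:
                valid = np.maximum(lens - h + 1, 1)
                mask = np.arange(T)[None, :] >= valid[:, None]
                act = np.where(mask[:, :, None], -np.inf, act)
            amax = act.argmax(axis=1)  # (B, F)
            pooled = np.take_along_axis(act, amax[:, None, :], axis=1)[:, 0, :]
            pooled = np.maximum(pooled, 0.0)  # all-masked guard cannot occur
            pooled_parts.append(pooled)
            if want_cache:
                pre_at = np.take_along_axis(pre, amax[:, None, :], axis=1)[:, 0, :]
                cache_h.append((h, amax, pre_at, T))
        pooled_cat = np.concatenate(pooled_parts, axis=1)
        hid_pre = pooled_cat @ self.FC1 + self.b1
        hid = np.maximum(hid_pre, 0.0)
        logits = hid @ self.FC2 + self.b2
        zmax = logits.max(axis=1, keepdims=True)
        ez = np.exp(logits - zmax)
        probs = ez / ez.sum(axis=1, keepdims=True)
        if not want_cache:
            return probs
        cache = dict(idx=idx, lens=lens, pooled=pooled_cat, hid=hid,
                     hid_pre=hid_pre, heights=cache_h)
        return probs, cache

    def forward(self, idx: np.ndarray, lens: np.ndarray) -> np.ndarray:
        """Class probability pairs for encoded inputs padded to L_max."""
        idx = np.atleast_2d(np.asarray(idx, dtype=np.int64))
        lens = np.atleast_1d(np.asarray(lens, dtype=np.int64))
        if idx.shape[1] != self.l_max:
            raise ValueError(
                f"input is padded to {idx.shape[1]}, model expects L_max={self.l_max}"
            )
        return self._forward_batch(idx, lens, want_cache=False)

    def _backward_batch(self, probs, cache, y):
        B = probs.shape[0]
        F = self.cfg.filters_per_height
        V = self.emb.channels[0].shape[0]
        l2 = self.cfg.l2_strength
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads = {
            "FC2": cache["hid"].T @ dlogits + l2 * self.FC2,
            "b2": dlogits.sum(axis=0),
        }
        dhid = dlogits @ self.FC2.T
        dhid[cache["hid_pre"] <= 0] = 0.0
        grads["FC1"] = cache["pooled"].T @ dhid + l2 * self.FC1
        grads["b1"] = dhid.sum(axis=0)
        dpooled = dhid @ self.FC1.T
        idx = cache["idx"]
        dW_emb = [
            np.zeros_like(W) if tr else None
            for W, tr in zip(self.emb.channels, self.emb.trainable)
        ]
        off = 0
        for h, amax, pre_at, T in cache["heights"]:
            dp = dpooled[:, off : off + F].copy()
            off += F
            dp[pre_at <= 0] = 0.0  # ReLU at the pooled position
            dpre = np.zeros((B, T, F))
            np.put_along_axis(dpre, amax[:, None, :], dp[:, None, :], axis=1)
            grads[f"bK{h}"] = dpre.sum(axis=(0, 1))
            dK_h = np.empty_like(self.K[h])
            dpre2d = dpre.reshape(B * T, F)
            for r in range(h):
                ids = idx[:, r : r + T].reshape(-1)
                H = sp.csr_matrix(
                    (np.ones(len(ids)), ids, np.arange(len(ids) + 1)),
                    shape=(len(ids), V),
                )
                S = np.asarray((H.T @ dpre2d))  # (V, F) scatter-add by token
                for c in range(self.emb.num_channels):
                    dK_h[r, c] = self.emb.channels[c].T @ S + l2 * self.K[h][r, c]
                    if dW_emb[c] is not None:
                        dW_emb[c] += S @ self.K[h][r, c].T
            grads[f"K{h}"] = dK_h
        for c, dW in enumerate(dW_emb):
            if dW is not None:
                dW[PAD_INDEX] = 0.0  # PAD embedding is never updated
                grads[f"W{c}"] = dW
        return grads

    # ------------------------------------------------------------------ #
    # training
    # ------------------------------------------------------------------ #
    def _param_dict(self) -> dict[str, np.ndarray]:
        params = {"FC1": self.FC1, "b1": self.b1, "FC2": self.FC2, "b2": self.b2}
        for h in self.cfg.kernel_heights:
            params[f"K{h}"] = self.K[h]
            params[f"bK{h}"] = self.bK[h]
        for c, tr in enumerate(self.emb.trainable):
            if tr:
                params[f"W{c}"] = self.emb.channels[c]
        return params

    def fit(
        self,
        encoded: Sequence[np.ndarray],
        labels: Sequence[int],
        rng: np.random.Generator | None = None,
    ) -> "OriCNN":
        """Train on ragged encoded sequences (unpadded index arrays).

        Batches are formed over length-sorted inputs (so padding waste
        stays small) and visited in an order reshuffled each epoch.
        Only trainable channels are updated; the PAD row never is.
        """
        y = np.asarray(labels, dtype=np.int64)
        if len(encoded) == 0:
            raise ValueError("empty training set")
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        rng = rng or np.random.default_rng(self.cfg.seed + 1)
        lens = np.array([len(e) for e in encoded])
        order = np.argsort(lens, kind="stable")
        bs = self.cfg.batch_size
        batches = [order[i : i + bs] for i in range(0, len(order), bs)]
        hmax = max(self.cfg.kernel_heights)
        self._opt = _Adam(self._param_dict(), self.cfg.learning_rate,
                          self.cfg.decay_rate)
        for epoch in range(self.cfg.epochs):
            self._opt.epoch = epoch
            perm = rng.permutation(len(batches))
            tot_loss, tot_correct = 0.0, 0
            for bi in perm:
                sel = batches[bi]
                blen = lens[sel]
                L = max(int(blen.max()), hmax)
                idx = np.zeros((len(sel), L), dtype=np.int64)
                for row, s in enumerate(sel):
                    idx[row, : lens[s]] = encoded[s]
                probs, cache = self._forward_batch(idx, blen, want_cache=True)
                p_true = np.clip(probs[np.arange(len(sel)), y[sel]], 1e-12, None)
                loss = -np.log(p_true).mean()
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch + 1}, batch {bi}"
                    )
                tot_loss += loss * len(sel)
                tot_correct += int((probs.argmax(axis=1) == y[sel]).sum())
                grads = self._backward_batch(probs, cache, y[sel])
                self._opt.step(grads)
            self.history.append(
                {
                    "epoch": epoch + 1,
                    "loss": tot_loss / len(encoded),
                    "train_acc": tot_correct / len(encoded),
                }
            )
        return self

    def predict_proba(
        self, encoded: Sequence[np.ndarray], batch_size: int = 256
    ) -> np.ndarray:
        """Positive/negative probability pairs for ragged encoded inputs."""
        lens = np.array([len(e) for e in encoded])
        hmax = max(self.cfg.kernel_heights)
        out = np.empty((len(encoded), 2))
        order = np.argsort(lens, kind="stable")
        for i in range(0, len(order), batch_size):
            sel = order[i : i + batch_size]
            blen = lens[sel]
            L = max(int(blen.max()), hmax)
            idx = np.zeros((len(sel), L), dtype=np.int64)
            for row, s in enumerate(sel):
                idx[row, : lens[s]] = encoded[s]
            out[sel] = self._forward_batch(idx, blen, want_cache=False)
        return out

    def save(self, path) -> None:
        """Checkpoint all weights plus config and a vocabulary hash."""
        import hashlib

        vocab_hash = ""
        if self.emb.vocab is not None:
            vocab_hash = hashlib.sha256(
                "|".join(self.emb.vocab.index_to_token).encode()
            ).hexdigest()
        arrays = {
            "FC1": self.FC1, "b1": self.b1, "FC2": self.FC2, "b2": self.b2,
            "l_max": np.array(self.l_max), "mode": np.array(self.emb.mode),
            "vocab_hash": np.array(vocab_hash),
        }
        for h in self.cfg.kernel_heights:
            arrays[f"K{h}"] = self.K[h]
            arrays[f"bK{h}"] = self.bK[h]
        for c, W in enumerate(self.emb.channels):
            arrays[f"W{c}"] = W
        np.savez(path, **arrays)


def aggregate_sibling_probs(
    probs: np.ndarray, groups: Sequence[int], aggregation: str = "mean_prob"
) -> tuple[np.ndarray, np.ndarray]:
    """Combine derived-sequence scores into per-parent scores and labels.

    ``mean_prob`` (default) averages the positive-class probability over
    siblings and thresholds at 0.5; ``majority`` takes the majority vote
    of sibling argmax labels (the mean probability is still reported as
    the score, for ROC curves); ``per_derived`` keeps every derived
    sequence as its own unit.  ``groups`` assigns each row of ``probs``
    to its parent record; rows of the same parent must share a group id.
    Parents are returned in order of first appearance.
    """
    groups = np.asarray(groups)
    pos = probs[:, 1]
    if aggregation == "per_derived":
        return pos, (pos > 0.5).astype(int)
    if aggregation not in ("mean_prob", "majority"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    _, first = np.unique(groups, return_index=True)
    uniq = groups[np.sort(first)]
    scores = np.empty(len(uniq))
    labels = np.empty(len(uniq), dtype=int)
    for i, g in enumerate(uniq):
        p = pos[groups == g]
        scores[i] = p.mean()
        if aggregation == "mean_prob":
            labels[i] = int(scores[i] > 0.5)
        else:
            labels[i] = int((p > 0.5).sum() * 2 > len(p))
    return scores, labels
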