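"""Skip-gram word vectors with negative sampling, trained from scratch.

Each tokenized sequence is a sentence; a context word w̃ within a small
window predicts the center word w against k "negative" words drawn from
the unigram^(3/4) distribution.  The distribution is materialized as a
length-M lookup table: the unit interval carries the cumulative word
"lengths" len(w) = count(w)^(3/4) / Σ count^(3/4), is cut into M equal
cells, and each cell stores the word whose interval covers its
midpoint.  For every (w̃, w) pair the objective maximizes

    log σ(v(w̃)·θ(w)) + Σ_{u ∈ NEG(w)} log(1 − σ(v(w̃)·θ(u)))

by plain SGD over input vectors v(·) and output vectors θ(·); the
trained input vectors become the embedding matrix W (PAD row zero).

The per-pair update loop is JIT-compiled with numba; negatives are
pre-drawn per epoch with a seeded Generator so runs are reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from scipy.special import expit

from orivec.segmentation import PAD_INDEX, TokenizedSequence, Vocabulary


@dataclass
class SkipGramConfig:
    """Hyper-parameters of the embedding pre-training.

    dim
        Embedding dimension D (300 by default, the value that worked
        best for this task after a coarse-to-fine search).
    window
        Context radius around the center word (2).
    negatives
        Negative samples drawn per (context, center) prediction (5).
    table_size
        M, the number of equal cells of the sampling table (1000).
    epochs
        Passes over the corpus.  A handful of iterations suffices for
        these tiny (64/84-word) vocabularies; 5 by default.
    lr / lr_min
        SGD rate, decayed linearly from ``lr`` to ``lr_min`` over all
        updates.
    """

    dim: int = 300
    window: int = 2
    negatives: int = 5
    table_size: int = 1000
    epochs: int = 5
    lr: float = 0.025
    lr_min: float = 1e-4
    seed: int = 0


@dataclass
class NegativeSamplingTable:
    """Length-M array of word indices encoding the unigram^(3/4) law."""

    table: np.ndarray
    M: int
    lengths: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.table) != self.M:
            raise ValueError("table size does not match M")


@dataclass
class EmbeddingMatrix:
    """Trained |V|×D input-vector matrix; row 0 (PAD) is all zeros."""

    W: np.ndarray
    vocab: Vocabulary
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.W.shape[0] != len(self.vocab):
            raise ValueError("embedding rows must match vocabulary size (incl. PAD)")
        if not np.all(self.W[PAD_INDEX] == 0):
            raise ValueError("PAD row must be zero")

    @property
    def dim(self) -> int:
        return self.W.shape[1]

    def save_tsv(self, path: str | Path) -> None:
        """token <TAB> D tab-separated values, PAD row omitted."""
        with open(path, "w") as fh:
            for i in range(1, len(self.vocab)):
                vals = "\t".join(f"{x:.8g}" for x in self.W[i])
                fh.write(f"{self.vocab.index_to_token[i]}\t{vals}\n")

    def save_word2vec(self, path: str | Path) -> None:
        """Plain word2vec text format (header line: count dim)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.vocab) - 1} {self.dim}\n")
            for i in range(1, len(self.vocab)):
                vals = " ".join(f"{x:.8g}" for x in self.W[i])
                fh.write(f"{self.vocab.index_to_token[i]} {vals}\n")

    @classmethod
    def load_tsv(cls, path: str | Path, vocab: Vocabulary) -> "EmbeddingMatrix":
        rows = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows[parts[0]] = np.array([float(x) for x in parts[1:]])
        dim = len(next(iter(rows.values())))
        W = np.zeros((len(vocab), dim))
        for tok, vec in rows.items():
            W[vocab[tok]] = vec
        return cls(W=W, vocab=vocab, metadata={"source": str(path)})


def token_counts(corpus: Sequence[TokenizedSequence]) -> Counter:
    c: Counter = Counter()
    for s in corpus:
        c.update(s.tokens)
    return c


def unigram_lengths(counts: Mapping[str, int]) -> dict[str, float]:
    """Word "lengths" len(w) = count(w)^(3/4) / Σ_i count(i)^(3/4)."""
    powered = {w: float(c) ** 0.75 for w, c in counts.items() if c > 0}
    total = sum(powered.values())
    if total == 0:
        raise ValueError("all word counts are zero")
    lengths = {w: p / total for w, p in powered.items()}
    for w in counts:
        lengths.setdefault(w, 0.0)
    return lengths


def build_table(
    lengths: Mapping[str, float], vocab: Vocabulary, M: int = 1000
) -> NegativeSamplingTable:
    """Deterministic M-cell table over the cumulative length intervals.

    Cell n (midpoint (n + 1/2)/M) stores the word whose cumulative
    interval contains that midpoint.  Words are laid out in vocabulary
    index order so the table is reproducible bit-for-bit.
    """
    support = [
        (vocab[w], l) for w, l in sorted(lengths.items(), key=lambda kv: vocab[kv[0]])
        if l > 0
    ]
    if M < len(support):
        raise ValueError(
            f"table size M={M} is smaller than the support ({len(support)} words)"
        )
    total = sum(l for _, l in support)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"lengths must sum to 1 (got {total:.12f})")
    ids = np.array([i for i, _ in support], dtype=np.int32)
    cum = np.cumsum([l for _, l in support])
    mids = (np.arange(M) + 0.5) / M
    cells = ids[np.minimum(np.searchsorted(cum, mids, side="right"), len(ids) - 1)]
    return NegativeSamplingTable(table=cells, M=M, lengths=dict(lengths))


def sample_negatives(
    table: NegativeSamplingTable,
    center: int,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw k negatives uniformly over table cells, excluding the center."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.all(table.table == center):
        raise ValueError(
            "the sampling table contains only the center word; "
            "no valid negative exists"
        )
    draws = table.table[rng.integers(0, table.M, size=k)]
    while np.any(bad := draws == center):
        draws[bad] = table.table[rng.integers(0, table.M, size=int(bad.sum()))]
    return draws


def sgns_probability(
    context_vector: np.ndarray, output_vector: np.ndarray, label: int
) -> float:
    """Observation probability σ(v·θ) for label 1, else 1 − σ(v·θ)."""
    if context_vector.shape != output_vector.shape:
        raise ValueError(
            f"dimension mismatch: {context_vector.shape} vs {output_vector.shape}"
        )
    s = float(expit(np.dot(context_vector, output_vector)))
    return s if label == 1 else 1.0 - s


def sgns_pair_gradient(
    v: np.ndarray, theta: np.ndarray, label: int
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of −log p w.r.t. (v, θ) for one prediction."""
    s = expit(np.dot(v, theta))
    g = s - label  # d(−log p)/d(v·θ)
    return g * theta, g * v


@njit(cache=False)
def _sgns_epoch(V, TH, contexts, centers, negs, lr0, lr_step, step0):  # pragma: no cover
    """One SGD pass over all (context, center) pairs.  Returns total NLL."""
    n_pairs, k = negs.shape
    D = V.shape[1]
    dx = np.empty(D)
    nll = 0.0
    for p in range(n_pairs):
        lr = lr0 - lr_step * (step0 + p)
        ctx = contexts[p]
        for d in range(D):
            dx[d] = 0.0
        for j in range(k + 1):
            if j == 0:
                u = centers[p]
                label = 1.0
            else:
                u = negs[p, j - 1]
                label = 0.0
            z = 0.0
            for d in range(D):
                z += V[ctx, d] * TH[u, d]
            if z >= 0:
                s = 1.0 / (1.0 + np.exp(-z))
                nll += np.log(1.0 + np.exp(-z)) + (1.0 - label) * z
            else:
                e = np.exp(z)
                s = e / (1.0 + e)
                nll += np.log(1.0 + e) - label * z
            g = lr * (label - s)
            for d in range(D):
                dx[d] += g * TH[u, d]
                TH[u, d] += g * V[ctx, d]
        for d in range(D):
            V[ctx, d] += dx[d]
    return nll


def _corpus_pairs(
    corpus: Sequence[TokenizedSequence], vocab: Vocabulary, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """All (context, center) index pairs; windows never cross sentences."""
    contexts, centers = [], []
    for sent in corpus:
        ids = [vocab.token_to_index[t] for t in sent.tokens
               if t in vocab.token_to_index]
        n = len(ids)
        for c in range(n):
            for o in range(-window, window + 1):
                if o == 0:
                    continue
                j = c + o
                if 0 <= j < n:
                    contexts.append(ids[j])
                    centers.append(ids[c])
    if not centers:
        raise ValueError("corpus yields no context pairs")
    return (
        np.asarray(contexts, dtype=np.int64),
        np.asarray(centers, dtype=np.int64),
    )


def train_skipgram(
    corpus: Sequence[TokenizedSequence],
    vocab: Vocabulary,
    config: SkipGramConfig | None = None,
) -> EmbeddingMatrix:
    """Train input vectors on a tokenized corpus; returns the matrix W.

    Input vectors start uniform in [−0.5/D, 0.5/D], output vectors at
    zero.  PAD is never sampled or updated.  The mean per-epoch negative
    log-likelihood is recorded in the metadata; on any corpus with
    repeated co-occurrences it decreases from the first to the last
    epoch.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    cfg = config or SkipGramConfig()
    rng = np.random.default_rng(cfg.seed)

    counts = token_counts(corpus)
    unknown = [t for t in counts if t not in vocab.token_to_index]
    known = {t: c for t, c in counts.items() if t in vocab.token_to_index}
    if not known:
        raise ValueError("no corpus token is in the vocabulary")
    lengths = unigram_lengths(known)
    table = build_table(lengths, vocab, M=cfg.table_size)

    contexts, centers = _corpus_pairs(corpus, vocab, cfg.window)
    n_pairs = len(centers)

    V = np.zeros((len(vocab), cfg.dim))
    V[1:] = rng.uniform(-0.5 / cfg.dim, 0.5 / cfg.dim, size=(len(vocab) - 1, cfg.dim))
    TH = np.zeros_like(V)

    total_steps = cfg.epochs * n_pairs
    lr_step = (cfg.lr - cfg.lr_min) / max(total_steps - 1, 1)
    history = []
    for epoch in range(cfg.epochs):
        # negatives for the center word of every pair, PAD excluded by
        # construction (the table only holds corpus words), center
        # excluded by rejection
        m = rng.integers(0, cfg.table_size, size=(n_pairs, cfg.negatives))
        negs = table.table[m].astype(np.int64)
        while np.any(bad := negs == centers[:, None]):
            ii, jj = np.nonzero(bad)
            negs[ii, jj] = table.table[
                rng.integers(0, cfg.table_size, size=len(ii))
            ].astype(np.int64)
        nll = _sgns_epoch(
            V, TH, contexts, centers, negs, cfg.lr, lr_step, epoch * n_pairs
        )
        if not np.isfinite(nll):
            raise FloatingPointError(f"non-finite loss at epoch {epoch + 1}")
        history.append(nll / n_pairs / (cfg.negatives + 1))

    V[PAD_INDEX] = 0.0
    meta = {
        "epochs": cfg.epochs,
        "seed": cfg.seed,
        "mode": vocab.mode,
        "window": cfg.window,
        "negatives": cfg.negatives,
        "loss_history": history,
        "skipped_token_types": len(unknown),
    }
    return EmbeddingMatrix(W=V, vocab=vocab, metadata=meta)


def project_2d(
    emb: EmbeddingMatrix, method: str = "tsne", seed: int = 0
) -> dict[str, tuple[float, float]]:
    """2-D t-SNE projection of the non-PAD rows, for visual inspection.

    Coordinates are stochastic across seeds — the embedding itself is
    only defined up to rotation, and t-SNE adds its own run-to-run
    variation — so only neighborhood structure is meaningful.
    """
    if method != "tsne":
        raise ValueError(f"unknown projection method {method!r}")
    X = emb.W[1:]
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 non-PAD rows to project")
    from sklearn.manifold import TSNE

    perplexity = min(30.0, (n - 1) / 3.0)
    coords = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="random"
    ).fit_transform(X)
    return {
        emb.vocab.index_to_token[i + 1]: (float(x), float(y))
        for i, (x, y) in enumerate(coords)
    }
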