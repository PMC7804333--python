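"""Trinucleotide tokenization of DNA sequences.

Two segmentation schemes turn a DNA sequence into "sentences" of
nucleotide words:

* **continuous** — a window of width 3 slides with stride 1, giving the
  L-2 overlapping trinucleotides.
* **skip** — a window of width 3 slides with stride 3 starting at
  offsets 0, 1 and 2, giving three non-overlapping derived sequences
  per input; depending on (L - offset) mod 3 the final word is a tri-,
  mono- or dinucleotide.

Vocabularies are the full canonical enumerations (64 trinucleotides, or
4 + 16 + 64 = 84 words for skip mode) with a reserved PAD index 0, so
embedding-matrix shapes are fixed regardless of corpus coverage.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_ACGT = "ACGT"
PAD_INDEX = 0
PAD_TOKEN = "<PAD>"


@dataclass
class TokenizedSequence:
    """An ordered word list derived from one parent sequence."""

    parent_id: str
    offset: int
    tokens: list[str]
    label: int | None = None

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Vocabulary:
    """Fixed word↔index map with PAD reserved at index 0."""

    mode: str
    index_to_token: list[str]
    token_to_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.token_to_index:
            self.token_to_index = {t: i for i, t in enumerate(self.index_to_token)}

    def __len__(self) -> int:
        return len(self.index_to_token)

    @property
    def n_words(self) -> int:
        """Number of biological words (PAD excluded)."""
        return len(self.index_to_token) - 1

    def __getitem__(self, token: str) -> int:
        return self.token_to_index[token]


def continuous_tsss(
    sequence: str, parent_id: str = "", label: int | None = None
) -> TokenizedSequence:
    """Overlapping trinucleotide tokenization (window 3, stride 1).

    Returns the L-2 trinucleotides left to right.  Errors for L < 3,
    where no window fits.
    """
    sequence = sequence.upper()
    if len(sequence) < 3:
        raise ValueError(
            f"sequence of length {len(sequence)} is too short for "
            f"continuous segmentation (need >= 3)"
        )
    tokens = [sequence[i : i + 3] for i in range(len(sequence) - 2)]
    return TokenizedSequence(parent_id=parent_id, offset=0, tokens=tokens, label=label)


def skip_tsss(
    sequence: str, parent_id: str = "", label: int | None = None
) -> list[TokenizedSequence]:
    """Non-overlapping window-3 tokenization at offsets 0, 1, 2.

    Each offset i chops ``sequence[i:]`` into consecutive triplets; a
    leftover of 1 or 2 characters becomes a final mono- or dinucleotide,
    so no nucleotide is discarded.  Only the first three offsets are
    produced — further shifts would be nearly identical to these.
    Requires L >= 5 so every offset yields at least one word.
    """
    sequence = sequence.upper()
    if len(sequence) < 5:
        raise ValueError(
            f"sequence of length {len(sequence)} is too short for "
            f"skip segmentation (need >= 5)"
        )
    out = []
    for off in range(3):
        sub = sequence[off:]
        tokens = [sub[i : i + 3] for i in range(0, len(sub), 3)]
        out.append(
            TokenizedSequence(parent_id=parent_id, offset=off, tokens=tokens, label=label)
        )
    return out


def build_vocabulary(mode: str) -> Vocabulary:
    """Canonical vocabulary for a segmentation mode.

    ``continuous``: PAD + the 64 trinucleotides.  ``skip``: PAD + 4
    mononucleotides + 16 dinucleotides + 64 trinucleotides, shorter
    words first, lexicographic within each word length.  Indices are
    corpus-independent and stable across calls.
    """
    if mode == "continuous":
        lengths = (3,)
    elif mode == "skip":
        lengths = (1, 2, 3)
    else:
        raise ValueError(f"unknown segmentation mode {mode!r}")
    words = [PAD_TOKEN]
    for n in lengths:
        words.extend("".join(p) for p in itertools.product(_ACGT, repeat=n))
    return Vocabulary(mode=mode, index_to_token=words)


def encode(
    tokens: TokenizedSequence, vocab: Vocabulary, max_len: int
) -> tuple[np.ndarray, int]:
    """Map words to indices, right-padded with PAD to ``max_len``.

    Words containing non-ACGT characters are skipped (logged).  Returns
    the padded index array and the true (unpadded) length for masking.
    Errors if the words do not fit, pointing at L_max recomputation.
    """
    idx = []
    for t in tokens.tokens:
        i = vocab.token_to_index.get(t)
        if i is None:
            if all(c in _ACGT for c in t):
                raise KeyError(
                    f"token {t!r} is not in the {vocab.mode!r} vocabulary — "
                    f"segmentation mode and vocabulary probably disagree"
                )
            logger.debug("encode: skipping ambiguous token %r in %s",
                         t, tokens.parent_id)
            continue
        idx.append(i)
    if len(idx) > max_len:
        raise ValueError(
            f"sequence {tokens.parent_id!r} has {len(idx)} tokens > "
            f"max_len={max_len}; recompute L_max over the whole dataset"
        )
    if len(idx) == 0:
        raise ValueError(f"sequence {tokens.parent_id!r} yields no encodable tokens")
    out = np.zeros(max_len, dtype=np.int32)
    out[: len(idx)] = idx
    return out, len(idx)


def write_sentences(sentences: Iterable[TokenizedSequence], path: str | Path) -> None:
    """One tokenized sequence per line, space-separated words."""
    with open(path, "w") as fh:
        for s in sentences:
            fh.write(" ".join(s.tokens) + "\n")


def read_sentences(path: str | Path) -> list[list[str]]:
    with open(path) as fh:
        return [line.split() for line in fh if line.strip()]


def tokenize_records(
    records: Sequence, mode: str
) -> list[TokenizedSequence]:
    """Tokenize labeled records; skip mode yields three sentences each."""
    out: list[TokenizedSequence] = []
    for r in records:
        if mode == "continuous":
            out.append(continuous_tsss(r.sequence, parent_id=r.id, label=r.label))
        elif mode == "skip":
            out.extend(skip_tsss(r.sequence, parent_id=r.id, label=r.label))
        else:
            raise ValueError(f"unknown segmentation mode {mode!r}")
    return out
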