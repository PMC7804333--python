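"""End-to-end pipeline: segmentation → embeddings → CNN → record scores.

One :class:`OriPipeline` object owns everything needed to go from raw
labeled records to per-record ORI probabilities: the segmentation mode,
the skip-gram pre-training configuration, the CNN configuration and the
sibling-aggregation rule for skip segmentation (three derived sequences
per record, combined by mean positive-class probability by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from orivec.cnn import (
    CNNConfig,
    OriCNN,
    aggregate_sibling_probs,
    build_embedding_layer,
)
from orivec.segmentation import build_vocabulary, encode, tokenize_records
from orivec.sequence_io import SequenceRecord
from orivec.skipgram import SkipGramConfig, EmbeddingMatrix, train_skipgram


@dataclass
class PipelineConfig:
    """Everything that defines one training/prediction run."""

    segmentation: str = "skip"
    mode: str = "default"  # embedding-layer training mode
    aggregation: str = "mean_prob"
    pretrain_on: str = "positives"  # or "all"
    embedding: SkipGramConfig = field(default_factory=SkipGramConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.segmentation not in ("continuous", "skip"):
            raise ValueError(f"unknown segmentation {self.segmentation!r}")
        if self.pretrain_on not in ("positives", "all"):
            raise ValueError(f"pretrain_on must be 'positives' or 'all'")


def compute_l_max(records: Sequence[SequenceRecord], segmentation: str) -> int:
    """Longest tokenized length over the dataset (per derived sequence)."""
    return max(len(t) for t in tokenize_records(records, segmentation))


class OriPipeline:
    """Fit embeddings + CNN on labeled records; score new records.

    ``l_max`` should be computed over the full dataset (training and
    evaluation records) so held-out sequences always fit the padded
    input; :func:`compute_l_max` does this.
    """

    def __init__(self, config: PipelineConfig | None = None, l_max: int | None = None):
        self.cfg = config or PipelineConfig()
        self.vocab = build_vocabulary(self.cfg.segmentation)
        self.l_max = l_max
        self.embeddings: EmbeddingMatrix | None = None
        self.model: OriCNN | None = None

    def _encode_records(self, records: Sequence[SequenceRecord]):
        """Tokenize + encode; returns ragged index arrays, labels, parent groups."""
        sents = tokenize_records(records, self.cfg.segmentation)
        encoded, labels, groups = [], [], []
        group_of = {r.id: i for i, r in enumerate(records)}
        for s in sents:
            arr, true_len = encode(s, self.vocab, self.l_max)
            encoded.append(arr[:true_len])
            labels.append(s.label)
            groups.append(group_of[s.parent_id])
        return encoded, np.array(labels), np.array(groups)

    def fit(self, records: Sequence[SequenceRecord]) -> "OriPipeline":
        if self.l_max is None:
            self.l_max = compute_l_max(records, self.cfg.segmentation)
        pre_records = (
            [r for r in records if r.label == 1]
            if self.cfg.pretrain_on == "positives"
            else list(records)
        )
        if not pre_records:
            raise ValueError("no records available for embedding pre-training")
        corpus = tokenize_records(pre_records, self.cfg.segmentation)
        emb_cfg = SkipGramConfig(**{**self.cfg.embedding.__dict__,
                                    "seed": self.cfg.embedding.seed + self.cfg.seed})
        self.embeddings = train_skipgram(corpus, self.vocab, emb_cfg)
        layer = build_embedding_layer(self.embeddings, self.cfg.mode)
        cnn_cfg = CNNConfig(**{**self.cfg.cnn.__dict__,
                               "seed": self.cfg.cnn.seed + self.cfg.seed})
        self.model = OriCNN(layer, l_max=self.l_max, config=cnn_cfg)
        encoded, labels, _ = self._encode_records(records)
        self.model.fit(encoded, labels)
        return self

    def predict_scores(
        self, records: Sequence[SequenceRecord]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-record positive-class score and predicted label."""
        if self.model is None:
            raise RuntimeError("pipeline is not fitted")
        encoded, _, groups = self._encode_records(records)
        probs = self.model.predict_proba(encoded)
        return aggregate_sibling_probs(probs, groups, self.cfg.aggregation)

    def predict(self, records: Sequence[SequenceRecord]) -> np.ndarray:
        return self.predict_scores(records)[1]
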