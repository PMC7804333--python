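"""Reading, filtering and assembling labeled DNA sequence datasets.

Datasets are two-class collections of variable-length DNA fragments:
positives contain a replication origin (ORI), negatives do not.  The
construction mirrors the usual benchmark recipe: drop fragments shorter
than 50 nt, then remove redundant sequences whose pairwise identity to a
retained sequence exceeds 80% (a greedy, longest-first stand-in for
CD-HIT clustering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")

#: sequences with a larger fraction of ambiguity characters are rejected
MAX_AMBIGUOUS_FRACTION = 0.10


class FastaParseError(ValueError):
    """Raised for malformed FASTA entries (empty sequence, bad header)."""


@dataclass
class SequenceRecord:
    """One DNA sequence with an identifier and an optional binary label.

    ``label`` is 1 for ORI-containing sequences, 0 for non-ORI, ``None``
    when unlabeled.  Sequences are uppercased on construction; a record
    whose non-ACGT fraction exceeds :data:`MAX_AMBIGUOUS_FRACTION` is
    rejected.  Remaining ambiguity characters (N etc.) are kept — the
    tokenizer skips any token containing them.
    """

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise FastaParseError(f"record {self.id!r} has an empty sequence")
        n_bad = sum(1 for c in self.sequence if c not in _ACGT)
        if n_bad / len(self.sequence) > MAX_AMBIGUOUS_FRACTION:
            raise ValueError(
                f"record {self.id!r}: {n_bad}/{len(self.sequence)} "
                f"non-ACGT characters exceeds the "
                f"{MAX_AMBIGUOUS_FRACTION:.0%} ambiguity limit"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def with_label(self, label: int) -> "SequenceRecord":
        return SequenceRecord(self.id, self.sequence, label)


@dataclass
class LabeledDataset:
    """A named two-class collection of labeled records."""

    records: list[SequenceRecord]
    name: str = "dataset"
    n_pos: int = field(default=0)
    n_neg: int = field(default=0)

    def __post_init__(self) -> None:
        pos = sum(1 for r in self.records if r.label == 1)
        neg = sum(1 for r in self.records if r.label == 0)
        if any(r.label is None for r in self.records):
            raise ValueError("every record in a LabeledDataset must carry a label")
        if self.n_pos == 0 and self.n_neg == 0:
            self.n_pos, self.n_neg = pos, neg
        elif (self.n_pos, self.n_neg) != (pos, neg):
            raise ValueError(
                f"declared class counts ({self.n_pos}, {self.n_neg}) do not "
                f"match records ({pos}, {neg})"
            )

    def __len__(self) -> int:
        return len(self.records)

    def positives(self) -> list[SequenceRecord]:
        return [r for r in self.records if r.label == 1]

    def negatives(self) -> list[SequenceRecord]:
        return [r for r in self.records if r.label == 0]

    def write_manifest(self, path: str | Path, source: str = "") -> None:
        """Write a TSV manifest: id, label, length, source file."""
        with open(path, "w") as fh:
            fh.write("id\tlabel\tlength\tsource\n")
            for r in self.records:
                fh.write(f"{r.id}\t{r.label}\t{len(r)}\t{source}\n")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into unlabeled records, order preserved.

    Multi-line sequence entries are concatenated and uppercased.  An
    entry with a header but no sequence raises :class:`FastaParseError`
    naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FastaParseError(f"record {rec.id!r} in {path} has no sequence")
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def filter_min_length(
    records: Sequence[SequenceRecord], min_len: int = 50
) -> list[SequenceRecord]:
    """Drop records strictly shorter than ``min_len`` (default 50 nt)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [r for r in records if len(r) >= min_len]
    removed = len(records) - len(kept)
    if removed:
        logger.info("filter_min_length(%d): removed %d of %d records",
                    min_len, removed, len(records))
    return kept


def _ungapped_identity(a: str, b: str, k: int = 8) -> float:
    """Approximate pairwise identity for redundancy removal.

    Shared k-mers anchor candidate ungapped alignments (diagonals); the
    best diagonal's match count is divided by the shorter length.  This
    is a deliberately simple stand-in for CD-HIT's clustering identity:
    it over- rather than under-merges only for near-identical pairs,
    which is the regime the 80% threshold targets.
    """
    if len(a) < len(b):
        a, b = b, a  # a is the longer sequence
    short = len(b)
    if short < k:
        matches = sum(x == y for x, y in zip(a, b))
        return matches / short
    anchors: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        anchors.setdefault(a[i : i + k], []).append(i)
    diag_hits: dict[int, int] = {}
    for j in range(short - k + 1):
        for i in anchors.get(b[j : j + k], ()):
            d = i - j
            diag_hits[d] = diag_hits.get(d, 0) + 1
    if not diag_hits:
        return 0.0
    # score only the best-supported diagonals (ties broken by offset)
    best = 0
    top = sorted(diag_hits, key=lambda d: (-diag_hits[d], d))[:5]
    for d in top:
        lo = max(0, -d)
        hi = min(short, len(a) - d)
        matches = sum(1 for j in range(lo, hi) if a[j + d] == b[j])
        best = max(best, matches)
    return best / short


def reduce_redundancy(
    records: Sequence[SequenceRecord], identity_threshold: float = 0.8
) -> list[SequenceRecord]:
    """Greedy longest-first redundancy removal at the given identity.

    A record is dropped when its approximate identity to any already
    retained record exceeds the threshold.  Deterministic given the
    input order (lengths tie-broken by original position); idempotent.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    order = sorted(range(len(records)), key=lambda i: (-len(records[i]), i))
    retained: list[int] = []
    for i in order:
        cand = records[i]
        if all(
            _ungapped_identity(cand.sequence, records[j].sequence)
            <= identity_threshold
            for j in retained
        ):
            retained.append(i)
    dropped = len(records) - len(retained)
    if dropped:
        logger.info("reduce_redundancy(%.0f%%): dropped %d of %d records",
                    identity_threshold * 100, dropped, len(records))
    keep = set(retained)
    return [r for i, r in enumerate(records) if i in keep]


def assemble_dataset(
    positives: Sequence[SequenceRecord],
    negatives: Sequence[SequenceRecord],
    name: str = "dataset",
    max_imbalance: float = 2.0,
) -> LabeledDataset:
    """Label the two classes (1 = ORI, 0 = non-ORI) and bundle them.

    Warns when the class-size ratio exceeds ``max_imbalance``; errors on
    an empty class, since a binary classifier cannot be trained or
    evaluated without both.
    """
    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError(
            f"both classes must be non-empty "
            f"(got {len(positives)} positives, {len(negatives)} negatives)"
        )
    ratio = max(len(positives), len(negatives)) / min(len(positives), len(negatives))
    if ratio > max_imbalance:
        logger.warning(
            "dataset %r: class imbalance %.2f exceeds %.2f",
            name, ratio, max_imbalance,
        )
    records = [r.with_label(1) for r in positives] + [
        r.with_label(0) for r in negatives
    ]
    return LabeledDataset(records=records, name=name)
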