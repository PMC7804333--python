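"""Classifier evaluation: Acc/Sn/Sp/MCC, ROC/AUC, CV and k-mer summaries.

The Matthews correlation coefficient is computed in its error-rate
form,

    MCC = [1 − (FN/(TP+FN) + FP/(TN+FP))]
          / sqrt[(1 + (FP−FN)/P) · (1 + (FN−FP)/N)],

which is algebraically identical to the textbook covariance form (the
test suite checks the equivalence exhaustively).  ROC curves are swept
over thresholds at midpoints between consecutive unique scores, with
sentinel endpoints, so the trapezoid AUC equals the normalized
Mann–Whitney U statistic (ties count 1/2) bit-for-bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from orivec.pipeline import OriPipeline, PipelineConfig, compute_l_max
from orivec.sequence_io import LabeledDataset, SequenceRecord


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix cells must be nonnegative")

    @property
    def p(self) -> int:
        """Total positives (ORIs) in the truth."""
        return self.tp + self.fn

    @property
    def n(self) -> int:
        """Total negatives (non-ORIs) in the truth."""
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass
class EvalReport:
    """Metrics plus the ROC curve and protocol metadata."""

    acc: float
    sn: float
    sp: float
    mcc: float
    auc: float | None = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    fold_matrices: list[ConfusionMatrix] = field(default_factory=list)
    protocol: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        d = asdict(self)
        text = json.dumps(d, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        auc = f"{self.auc:.3f}" if self.auc is not None else "n/a"
        return (
            f"Acc={self.acc:.3f}  Sn={self.sn:.3f}  Sp={self.sp:.3f}  "
            f"MCC={self.mcc:.3f}  AUC={auc}"
        )


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionMatrix:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape or labels.size == 0:
        raise ValueError("labels and predictions must be equal-length and nonempty")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    return ConfusionMatrix(tp, tn, fp, fn)


def basic_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(Acc, Sn, Sp); errors loudly on degenerate denominators."""
    if cm.p == 0:
        raise ZeroDivisionError("Sn is undefined: no positive samples (P = 0)")
    if cm.n == 0:
        raise ZeroDivisionError("Sp is undefined: no negative samples (N = 0)")
    acc = (cm.tp + cm.tn) / cm.total
    sn = cm.tp / cm.p
    sp = cm.tn / cm.n
    return acc, sn, sp


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient in the error-rate form."""
    if cm.p == 0 or cm.n == 0:
        raise ZeroDivisionError("MCC requires at least one sample of each class")
    # the radicand factors are (TP+FP)/P and (TN+FN)/N
    t1 = 1.0 + (cm.fp - cm.fn) / cm.p
    t2 = 1.0 + (cm.fn - cm.fp) / cm.n
    if t1 <= 0 or t2 <= 0:
        raise ZeroDivisionError(
            f"MCC is undefined: all predictions fall in one class "
            f"(TP+FP={cm.tp + cm.fp}, TN+FN={cm.tn + cm.fn})"
        )
    num = 1.0 - (cm.fn / cm.p + cm.fp / cm.n)
    return num / math.sqrt(t1 * t2)


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, list[tuple[float, float]]]:
    """Trapezoid AUC and the (1−Sp, Sn) curve from a threshold sweep.

    Thresholds are the midpoints between consecutive unique scores plus
    endpoints beyond the extremes; a sample scores positive when its
    score exceeds the threshold.  With this sweep the trapezoid area
    equals the Mann–Whitney statistic: ties contribute 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC requires both classes")
    uniq = np.unique(scores)
    cuts = np.concatenate(
        ([uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0])
    )
    points = []
    for t in cuts[::-1]:  # high threshold first: curve runs (0,0) → (1,1)
        tpr = float(np.mean(pos > t))
        fpr = float(np.mean(neg > t))
        points.append((fpr, tpr))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return auc, points


def kmer_frequencies(records: Sequence[SequenceRecord], k: int) -> dict[str, float]:
    """Mean per-record overlapping k-mer frequencies (k = 1, 2 or 3).

    Each record's counts are normalized to 1 first, then averaged over
    records, so short and long sequences weigh equally.  k-mers with
    ambiguity characters are excluded from the normalization.
    """
    import itertools

    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    kmers = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    kindex = {m: i for i, m in enumerate(kmers)}
    acc = np.zeros(len(kmers))
    for r in records:
        if len(r) < k:
            raise ValueError(f"record {r.id!r} is shorter than k={k}")
        counts = np.zeros(len(kmers))
        s = r.sequence
        for i in range(len(s) - k + 1):
            j = kindex.get(s[i : i + k])
            if j is not None:
                counts[j] += 1
        tot = counts.sum()
        if tot == 0:
            raise ValueError(f"record {r.id!r} has no unambiguous {k}-mers")
        acc += counts / tot
    acc /= len(records)
    return dict(zip(kmers, acc))


# ---------------------------------------------------------------------- #
# protocols
# ---------------------------------------------------------------------- #
def _stratified_folds(
    labels: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """k stratified folds over record indices (sizes differ by ≤1 per class)."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (1, 0):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls} has {len(idx)} records, fewer than k={k}")
        idx = rng.permutation(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(int(j))
    return [np.sort(np.array(f)) for f in folds]


def _safe_mcc(cm: ConfusionMatrix) -> float:
    """MCC, or NaN when the prediction is degenerate (one-class output);
    the strict :func:`mcc` still raises for callers who need the error."""
    try:
        return mcc(cm)
    except ZeroDivisionError:
        return float("nan")


def _report_from_pooled(
    cm: ConfusionMatrix,
    scores: np.ndarray,
    labels: np.ndarray,
    folds: list[ConfusionMatrix],
    protocol: dict,
) -> EvalReport:
    acc, sn, sp = basic_metrics(cm)
    auc, points = roc_auc(scores, labels)
    return EvalReport(
        acc=acc, sn=sn, sp=sp, mcc=_safe_mcc(cm), auc=auc, roc_points=points,
        fold_matrices=folds, protocol=protocol,
    )


def kfold_cv(
    dataset: LabeledDataset,
    config: PipelineConfig,
    k: int = 10,
    seed: int = 0,
    pooled: bool = True,
) -> EvalReport:
    """Stratified k-fold cross-validation of the full pipeline.

    Per fold, the pipeline is refit from scratch on the training
    portion — embedding pre-training included, on that portion's
    positives — and scored on the held-out records.  Records are the
    split unit, so the three skip-segmentation siblings of one sequence
    never straddle folds.  Confusion counts are pooled over folds by
    default (``pooled=False`` reports per-fold means instead; the
    per-fold matrices are always attached).
    """
    records = dataset.records
    labels = np.array([r.label for r in records])
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(labels, k, rng)
    l_max = compute_l_max(records, config.segmentation)

    fold_cms: list[ConfusionMatrix] = []
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    for f, test_idx in enumerate(folds):
        test_set = set(test_idx.tolist())
        train = [r for i, r in enumerate(records) if i not in test_set]
        test = [records[i] for i in test_idx]
        fold_cfg = PipelineConfig(**{**config.__dict__, "seed": config.seed + f})
        pipe = OriPipeline(fold_cfg, l_max=l_max).fit(train)
        scores, preds = pipe.predict_scores(test)
        ytrue = labels[test_idx]
        if config.aggregation == "per_derived":
            # every derived sequence is its own evaluation unit
            reps = 3 if config.segmentation == "skip" else 1
            ytrue = np.repeat(ytrue, reps)
        fold_cms.append(confusion(ytrue, preds))
        all_scores.append(scores)
        all_labels.append(ytrue)

    pooled_cm = sum(fold_cms[1:], fold_cms[0])
    protocol = {
        "protocol": "kfold_cv", "k": k, "seed": seed,
        "segmentation": config.segmentation, "mode": config.mode,
        "aggregation": config.aggregation, "pooled": pooled,
    }
    if pooled:
        return _report_from_pooled(
            pooled_cm, np.concatenate(all_scores), np.concatenate(all_labels),
            fold_cms, protocol,
        )
    per = np.array([[*basic_metrics(c), _safe_mcc(c)] for c in fold_cms])
    auc, points = roc_auc(np.concatenate(all_scores), np.concatenate(all_labels))
    m = per.mean(axis=0)
    protocol["per_fold_sd"] = per.std(axis=0, ddof=1).tolist()
    return EvalReport(
        acc=m[0], sn=m[1], sp=m[2], mcc=m[3], auc=auc, roc_points=points,
        fold_matrices=fold_cms, protocol=protocol,
    )


def independent_test(
    dataset: LabeledDataset,
    config: PipelineConfig,
    train_frac: float = 0.9,
    repetitions: int = 20,
    seed: int = 0,
) -> tuple[EvalReport, list[EvalReport]]:
    """Repeated stratified train/test splits, metrics averaged.

    Each repetition holds out (1 − train_frac) of every class with a
    distinct derived seed, fits the pipeline on the rest, and scores the
    held-out records.  The four rate metrics and the AUC are averaged
    arithmetically across repetitions.
    """
    records = dataset.records
    labels = np.array([r.label for r in records])
    for cls in (0, 1):
        n_cls = int((labels == cls).sum())
        if n_cls < 10:
            raise ValueError(f"class {cls} has only {n_cls} records; need >= 10")
    l_max = compute_l_max(records, config.segmentation)
    reports = []
    for rep in range(repetitions):
        rng = np.random.default_rng(seed * 100_003 + rep)
        test_idx: list[int] = []
        for cls in (1, 0):
            idx = rng.permutation(np.flatnonzero(labels == cls))
            n_test = max(1, round(len(idx) * (1 - train_frac)))
            test_idx.extend(idx[:n_test].tolist())
        test_set = set(test_idx)
        train = [r for i, r in enumerate(records) if i not in test_set]
        test = [records[i] for i in sorted(test_set)]
        rep_cfg = PipelineConfig(**{**config.__dict__, "seed": config.seed + rep})
        pipe = OriPipeline(rep_cfg, l_max=l_max).fit(train)
        scores, preds = pipe.predict_scores(test)
        ytrue = labels[sorted(test_set)]
        if config.aggregation == "per_derived":
            reps_n = 3 if config.segmentation == "skip" else 1
            ytrue = np.repeat(ytrue, reps_n)
        cm = confusion(ytrue, preds)
        acc, sn, sp = basic_metrics(cm)
        auc, points = roc_auc(scores, ytrue)
        reports.append(
            EvalReport(acc=acc, sn=sn, sp=sp, mcc=_safe_mcc(cm), auc=auc,
                       roc_points=points, fold_matrices=[cm],
                       protocol={"repetition": rep, "seed": seed})
        )
    mean = lambda a: float(np.mean(a))
    avg = EvalReport(
        acc=mean([r.acc for r in reports]),
        sn=mean([r.sn for r in reports]),
        sp=mean([r.sp for r in reports]),
        # a repetition with a one-class prediction has no MCC; average
        # over the repetitions where it is defined
        mcc=float(np.nanmean([r.mcc for r in reports])),
        auc=mean([r.auc for r in reports]),
        protocol={
            "protocol": "independent_test", "train_frac": train_frac,
            "repetitions": repetitions, "seed": seed,
            "segmentation": config.segmentation, "mode": config.mode,
        },
    )
    return avg, reports
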