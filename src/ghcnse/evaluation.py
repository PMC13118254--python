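"""Reaction-prediction metrics, recovery rates, and cross-validation.

The five prediction metrics are AUPRC (computed as average precision,
i.e. the step-wise integral of the precision-recall curve with tied
scores grouped), recall TP/(TP+FN), F1 = 2TP/(2TP+FP+FN), accuracy and
precision TP/(TP+FP), all at a fixed classification threshold (default
0.5).  Recovery rate at k is the fraction of the k highest-scoring
candidates that are true held-out reactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .gem_io import MetabolicNetwork, ValidationError
from .model import Hyperparams, ModelState, ScoredReaction, forward
from .sampling import (
    LabeledSample,
    assemble_recovery_testset,
    generate_negative_set,
    stratified_folds,
)
from .topology import build_graph, build_hypergraph
from .training import TrainConfig, train_model

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RecoveryReport",
    "binary_metrics",
    "average_precision",
    "recovery_rate",
    "feature_density",
    "run_cross_validation",
    "CrossValidationResult",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    auprc: float = float("nan")
    recall: float = float("nan")
    f1: float = float("nan")
    accuracy: float = float("nan")
    precision: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "auprc": self.auprc,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "precision": self.precision,
        }


@dataclass
class RecoveryReport:
    rate_at: dict[int, float]
    n_positives: int


def binary_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> tuple[ConfusionCounts, MetricsReport]:
    """Threshold scores and compute the confusion-based metrics.

    Empty denominators (no predicted positives, no true positives) yield
    0 rather than an error, with a log note.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must lie in (0, 1)")
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if s.size == 0 or s.shape != y.shape:
        raise ValidationError("scores and labels must be equal-length and non-empty")
    pred = (s >= threshold).astype(np.int64)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            logger.debug("empty denominator for %s; returning 0", name)
            return 0.0
        return num / den

    report = MetricsReport(
        recall=safe(tp, tp + fn, "recall"),
        f1=safe(2 * tp, 2 * tp + fp + fn, "f1"),
        accuracy=(tp + tn) / s.size,
        precision=safe(tp, tp + fp, "precision"),
    )
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn), report


def average_precision(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUPRC as average precision over descending-score thresholds."""
    y = np.asarray(labels, dtype=np.int64)
    if y.sum() == 0:
        raise ValidationError("average precision is undefined without positive labels")
    return float(average_precision_score(y, np.asarray(scores, dtype=np.float64)))


def recovery_rate(
    scored: Sequence[ScoredReaction], positive_ids: set[str], k: int
) -> float:
    """Fraction of the top-k scored candidates that are true positives.

    Ties at rank k are broken by stable reaction-id order.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(scored):
        raise ValidationError(f"k={k} exceeds the {len(scored)} scored candidates")
    ranked = sorted(scored, key=lambda sr: (-sr.score, sr.reaction_id))
    boundary = [sr.score for sr in ranked[k - 1 : k + 1]]
    if len(boundary) == 2 and boundary[0] == boundary[1]:
        logger.debug("score tie at rank %d broken by reaction id", k)
    hits = sum(1 for sr in ranked[:k] if sr.reaction_id in positive_ids)
    return hits / k


def feature_density(vectors: np.ndarray) -> np.ndarray:
    """Per-vector L2 norm divided by sqrt(dimension)."""
    v = np.asarray(vectors, dtype=np.float64)
    if v.size == 0:
        raise ValidationError("feature_density needs at least one vector")
    if v.ndim == 1:
        v = v[None, :]
    return np.linalg.norm(v, axis=1) / np.sqrt(v.shape[1])


# ---------------------------------------------------------------------------
# cross-validation protocol


@dataclass
class FoldResult:
    fold_index: int
    metrics: MetricsReport
    recovery: Optional[RecoveryReport] = None
    epochs_run: int = 0


@dataclass
class CrossValidationResult:
    folds: list[FoldResult]

    def mean_metrics(self) -> MetricsReport:
        return MetricsReport(
            **{
                key: float(np.mean([f.metrics.as_dict()[key] for f in self.folds]))
                for key in self.folds[0].metrics.as_dict()
            }
        )

    def std_metrics(self) -> MetricsReport:
        return MetricsReport(
            **{
                key: float(np.std([f.metrics.as_dict()[key] for f in self.folds]))
                for key in self.folds[0].metrics.as_dict()
            }
        )

    def mean_recovery(self) -> Optional[dict[int | str, float]]:
        if any(f.recovery is None for f in self.folds):
            return None
        keys = self.folds[0].recovery.rate_at.keys()
        return {k: float(np.mean([f.recovery.rate_at[k] for f in self.folds])) for k in keys}

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-fold table: fold, metric, value."""
        rows = []
        for f in self.folds:
            for key, val in f.metrics.as_dict().items():
                rows.append({"fold": f.fold_index, "metric": key, "value": val})
            if f.recovery is not None:
                for k, val in f.recovery.rate_at.items():
                    rows.append({"fold": f.fold_index, "metric": f"recovery@{k}", "value": val})
        return pd.DataFrame(rows)


def run_cross_validation(
    network: MetabolicNetwork,
    pool: Optional[MetabolicNetwork] = None,
    hp: Optional[Hyperparams] = None,
    cfg: Optional[TrainConfig] = None,
    k: int = 5,
    seed: int = 0,
    recovery_ks: Sequence[int] = (25, 50, 100),
) -> CrossValidationResult:
    """Stratified k-fold reaction prediction (and recovery when a pool is given).

    The dataset is the GEM's reactions (positives) plus one substitution
    negative per positive, generated once from ``seed``.  For each fold the
    topology is rebuilt from the fold's training positives, the model
    retrained from scratch, and the held-out samples scored in evaluation
    mode.  With a candidate pool, the fold's negative test samples are
    additionally replaced by all pool reactions absent from the GEM and
    top-k recovery rates are computed.
    """
    hp = hp or Hyperparams()
    cfg = cfg or TrainConfig(seed=seed)
    if network.m < k:
        raise ValidationError(f"network has {network.m} reactions; need at least k={k}")
    neg_universe = network if pool is None else _merged(network, pool)
    negatives = generate_negative_set(network.reactions, neg_universe, seed)
    samples = [LabeledSample(reaction=r, label=1) for r in network.reactions] + negatives
    folds = stratified_folds(samples, k=k, seed=seed)
    results = []
    for fold in folds:
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + fold.fold_index})
        state, history = train_model(network, fold.train, pool=pool, hp=hp, cfg=fold_cfg)
        train_pos = [s.reaction for s in fold.train if s.label == 1]
        eval_universe = neg_universe
        graph = build_graph(train_pos, eval_universe)
        hyper = build_hypergraph(train_pos, eval_universe)
        scored = forward(state, graph, hyper, [s.reaction for s in fold.test])
        scores = [sr.score for sr in scored]
        labels = [s.label for s in fold.test]
        _, metrics = binary_metrics(scores, labels, hp.classification_threshold)
        metrics.auprc = average_precision(scores, labels)
        recovery = None
        if pool is not None:
            test_pos = [s.reaction for s in fold.test if s.label == 1]
            rec_samples = assemble_recovery_testset(test_pos, pool, network)
            rec_scored = forward(state, graph, hyper, [s.reaction for s in rec_samples])
            pos_ids = {r.id for r in test_pos}
            n_pos = len(test_pos)
            rate_at = {}
            for kk in list(recovery_ks) + [n_pos]:
                if 1 <= kk <= len(rec_scored):
                    rate_at[kk] = recovery_rate(rec_scored, pos_ids, kk)
            recovery = RecoveryReport(rate_at=rate_at, n_positives=n_pos)
        results.append(
            FoldResult(
                fold_index=fold.fold_index,
                metrics=metrics,
                recovery=recovery,
                epochs_run=history.epochs_run,
            )
        )
    return CrossValidationResult(folds=results)


def _merged(network: MetabolicNetwork, pool: MetabolicNetwork) -> MetabolicNetwork:
    from .gem_io import merge_universe

    return merge_universe(network, pool)
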