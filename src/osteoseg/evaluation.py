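"""Confusion matrices, performance metrics, aggregation, and the
train/test model-selection experiment.

Osteoporosis is the positive class throughout: sensitivity is the true
positive rate among actual osteoporosis cases, specificity the true negative
rate among nonosteoporosis cases.  Metric values are reported in percent to
two decimals; both round-half-up (default) and truncation reporting
conventions are supported, because published clinical tables are not always
consistent about which they use (20/22 printed as 90.90 implies truncation
while other entries imply rounding).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from osteoseg.classifiers import (
    CLASS_ORDER,
    MlpConfig,
    TreeConfig,
    TrainedModel,
    predict_table,
    train_decision_tree,
    train_mlp,
    train_naive_bayes,
)
from osteoseg.features import FeatureTable, pixel_distribution
from osteoseg.roi_io import RoiImage
from osteoseg.segmentation import DEFAULT_K_LIST, ClusterConfig, segment

POSITIVE = "osteoporosis"
NEGATIVE = "nonosteoporosis"

METRICS = ("accuracy", "specificity", "sensitivity")


class UndefinedMetricError(ValueError):
    """A metric's denominator stratum is empty."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with osteoporosis as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(pred: Sequence[str], actual: Sequence[str]) -> ConfusionMatrix:
    """Cross-tabulate predicted vs actual diagnosis labels."""
    if len(pred) != len(actual):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(actual)} labels")
    if len(pred) == 0:
        raise ValueError("cannot build a confusion matrix from empty sequences")
    tp = fn = fp = tn = 0
    for p, a in zip(pred, actual):
        if a == POSITIVE:
            tp += p == POSITIVE
            fn += p != POSITIVE
        else:
            tn += p != POSITIVE
            fp += p == POSITIVE
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with halves away from zero (0.005 -> 0.01), unlike banker's rounding."""
    factor = 10.0**ndigits
    return math.floor(x * factor + 0.5) / factor


def truncate(x: float, ndigits: int = 2) -> float:
    """Drop digits beyond ``ndigits`` without rounding (90.909 -> 90.90)."""
    factor = 10.0**ndigits
    return math.floor(x * factor) / factor


def _report(x: float, rounding: str) -> float:
    if rounding == "half-up":
        return round_half_up(x)
    if rounding == "truncate":
        return truncate(x)
    raise ValueError(f"unknown rounding convention {rounding!r}")


def metrics(cm: ConfusionMatrix, rounding: str = "half-up") -> dict[str, float]:
    """Accuracy, specificity, and sensitivity in percent, to two decimals.

    Raises :class:`UndefinedMetricError` if a required stratum is empty
    (no actual positives for sensitivity, no actual negatives for
    specificity, no samples at all for accuracy).
    """
    if cm.total == 0:
        raise UndefinedMetricError("accuracy undefined: empty confusion matrix")
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no actual positive samples")
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: no actual negative samples")
    return {
        "accuracy": _report(100.0 * (cm.tp + cm.tn) / cm.total, rounding),
        "specificity": _report(100.0 * cm.tn / (cm.tn + cm.fp), rounding),
        "sensitivity": _report(100.0 * cm.tp / (cm.tp + cm.fn), rounding),
    }


# --------------------------------------------------------------------------
# Performance table and aggregation
# --------------------------------------------------------------------------


@dataclass
class PerformanceTable:
    """Metric values (percent) indexed by (segmentation, classifier, K, metric)."""

    k_list: tuple[int, ...] = DEFAULT_K_LIST
    cells: dict[tuple[str, str, int, str], float] = field(default_factory=dict)

    def set_cell(self, segmentation: str, classifier: str, K: int, metric: str, value: float) -> None:
        if not 0.0 <= value <= 100.0:
            raise ValueError(f"metric value {value} outside [0, 100]")
        self.cells[(segmentation, classifier, K, metric)] = value

    def cell(self, segmentation: str, classifier: str, K: int, metric: str) -> float:
        return self.cells[(segmentation, classifier, K, metric)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"segmentation": s, "classifier": c, "K": k, "metric": m, "value": v}
            for (s, c, k, m), v in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)


def _block(cells, segmentation: str, classifier: str, k_list: Iterable[int]) -> list[float]:
    if isinstance(cells, PerformanceTable):
        k_list = cells.k_list
        cells = cells.cells
    values = []
    for k in k_list:
        for m in METRICS:
            key = (segmentation, classifier, int(k), m)
            if key not in cells:
                raise ValueError(f"incomplete table: missing cell {key}")
            values.append(cells[key])
    return values


def average_performance(
    cells: PerformanceTable | dict,
    segmentation: str,
    classifier: str,
    k_list: Iterable[int] = DEFAULT_K_LIST,
) -> float:
    """Mean of one classifier's accuracy/specificity/sensitivity over all K,
    in percent to two decimals."""
    values = _block(cells, segmentation, classifier, k_list)
    return round_half_up(float(np.mean(values)))


def global_performance(
    cells: PerformanceTable | dict,
    segmentation: str,
    classifiers: Sequence[str] = ("tree", "nb", "mlp"),
    k_list: Iterable[int] = DEFAULT_K_LIST,
) -> float:
    """Mean over all classifiers, metrics, and K of one segmentation method,
    in percent to two decimals."""
    values: list[float] = []
    for clf in classifiers:
        values.extend(_block(cells, segmentation, clf, k_list))
    return round_half_up(float(np.mean(values)))


# --------------------------------------------------------------------------
# Train/test experiment
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Configuration of the model-selection experiment."""

    segmentation_methods: tuple[str, ...] = ("kmeans", "fcm")
    k_list: tuple[int, ...] = DEFAULT_K_LIST
    classifiers: tuple[str, ...] = ("tree", "nb", "mlp")
    tree_config: TreeConfig = field(default_factory=TreeConfig)
    mlp_config: MlpConfig = field(default_factory=MlpConfig)
    seed: int = 0
    rounding: str = "half-up"

    def __post_init__(self) -> None:
        for k in self.k_list:
            if k < 2:
                raise ValueError("K values must be >= 2")
        unknown = set(self.classifiers) - {"tree", "nb", "mlp"}
        if unknown:
            raise ValueError(f"unknown classifiers {sorted(unknown)}")


@dataclass
class ExperimentResult:
    """Everything the model-selection protocol produces."""

    table: PerformanceTable
    best: dict
    model: TrainedModel
    test_confusion: ConfusionMatrix
    test_metrics: dict[str, float]


def _feature_table(
    images: Sequence[tuple[RoiImage, str]], method: str, K: int, seed: int
) -> FeatureTable:
    cfg = ClusterConfig(K=K, method=method, seed=seed)
    rows = [
        pixel_distribution(segment(img, cfg), label=label, source_id=img.source_id)
        for img, label in images
    ]
    return FeatureTable(rows=rows, K=K)


def _train(kind: str, table: FeatureTable, cfg: RunConfig, seed: int) -> TrainedModel:
    if kind == "tree":
        return train_decision_tree(table, cfg.tree_config)
    if kind == "nb":
        return train_naive_bayes(table)
    return train_mlp(table, dataclasses.replace(cfg.mlp_config, seed=seed))


def run_experiment(
    cfg: RunConfig,
    train: Sequence[tuple[RoiImage, str]],
    test: Sequence[tuple[RoiImage, str]],
    features_cache: dict[tuple[str, int], tuple[FeatureTable, FeatureTable]] | None = None,
) -> ExperimentResult:
    """Run the full model-selection protocol.

    For every (segmentation method, K, classifier) combination: segment the
    images, extract pixel-distribution features, train on the training
    split, and record training accuracy/specificity/sensitivity.  The
    combination with the highest training accuracy (ties: higher
    sensitivity, then lower K) is then evaluated once on the test split.
    ``features_cache`` lets a caller that already segmented the images pass
    (train, test) feature tables keyed by (method, K).
    """
    table = PerformanceTable(k_list=tuple(cfg.k_list))
    candidates = []  # (accuracy, sensitivity, -K) ranking
    train_labels = [label for _, label in train]
    cache: dict[tuple[str, int], tuple[FeatureTable, FeatureTable]] = {}

    for method in cfg.segmentation_methods:
        for K in cfg.k_list:
            if features_cache is not None and (method, K) in features_cache:
                train_feats, test_feats = features_cache[(method, K)]
            else:
                train_feats = _feature_table(train, method, K, cfg.seed)
                test_feats = _feature_table(test, method, K, cfg.seed)
            cache[(method, K)] = (train_feats, test_feats)
            for clf in cfg.classifiers:
                model_seed = int(
                    np.random.SeedSequence(
                        [cfg.seed, cfg.k_list.index(K), cfg.segmentation_methods.index(method)]
                    ).generate_state(1)[0]
                    & 0x7FFFFFFF
                )
                model = _train(clf, train_feats, cfg, model_seed)
                cm = confusion(predict_table(model, train_feats), train_labels)
                m = metrics(cm, rounding=cfg.rounding)
                for name in METRICS:
                    table.set_cell(method, clf, K, name, m[name])
                candidates.append(
                    {
                        "method": method,
                        "classifier": clf,
                        "K": K,
                        "model": model,
                        "train_metrics": m,
                    }
                )

    best = max(
        candidates,
        key=lambda c: (
            c["train_metrics"]["accuracy"],
            c["train_metrics"]["sensitivity"],
            -c["K"],
        ),
    )
    _, test_feats = cache[(best["method"], best["K"])]
    test_labels = [label for _, label in test]
    test_cm = confusion(predict_table(best["model"], test_feats), test_labels)
    test_m = metrics(test_cm, rounding=cfg.rounding)
    report = {
        "method": best["method"],
        "classifier": best["classifier"],
        "K": best["K"],
        "train_metrics": best["train_metrics"],
    }
    return ExperimentResult(
        table=table,
        best=report,
        model=best["model"],
        test_confusion=test_cm,
        test_metrics=test_m,
    )
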