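"""Confusion matrix and the four headline metrics (Se, Sp, Acc, F1).

The positive class defaults to *acceptable*; the convention is explicit
and configurable because sensitivity/specificity swap meaning under the
opposite choice. Zero-denominator metrics are flagged undefined (None),
never silently reported as 0. Percentages are formatted to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .datasets import Corpus, class_ratio
from .errors import DataError
from .model import TrainedModel, corpus_to_arrays, predict
from .signal_io import QualityLabel

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion",
    "metrics",
    "evaluate_model",
    "write_report_table",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DataError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    """One results row: confusion counts plus Se/Sp/Acc/F1 as percentages.

    A metric is ``None`` when its denominator is zero (e.g. sensitivity
    with no positive-class segments in the test set).
    """

    confusion: ConfusionMatrix
    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    f1: Optional[float]
    train_ratio: str = ""
    test_ratio: str = ""
    positive_class: QualityLabel = QualityLabel.ACCEPTABLE
    undefined: tuple[str, ...] = field(default_factory=tuple)

    def row(self) -> dict[str, str]:
        def fmt(v: Optional[float]) -> str:
            return "undefined" if v is None else f"{v:.2f}"

        return {
            "train_ratio": self.train_ratio,
            "test_ratio": self.test_ratio,
            "sensitivity_pct": fmt(self.sensitivity),
            "specificity_pct": fmt(self.specificity),
            "accuracy_pct": fmt(self.accuracy),
            "f1_pct": fmt(self.f1),
        }


def confusion(
    truth: list[QualityLabel],
    predicted: list[QualityLabel],
    positive: QualityLabel = QualityLabel.ACCEPTABLE,
) -> ConfusionMatrix:
    """Count tp/fp/tn/fn with ``positive`` as the positive class."""
    if len(truth) == 0:
        raise DataError("cannot build a confusion matrix from no labels")
    if len(truth) != len(predicted):
        raise DataError(
            f"truth and prediction lengths differ: {len(truth)} vs {len(predicted)}"
        )
    tp = fp = tn = fn = 0
    for t, p in zip(truth, predicted):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(
    cm: ConfusionMatrix,
    positive: QualityLabel = QualityLabel.ACCEPTABLE,
) -> EvalReport:
    """Se = tp/(tp+fn), Sp = tn/(tn+fp), Acc = (tp+tn)/total,
    F1 = 2tp/(2tp+fp+fn), all as percentages."""
    if cm.total == 0:
        raise DataError("confusion matrix is empty")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> Optional[float]:
        if den == 0:
            undefined.append(name)
            return None
        return 100.0 * num / den

    se = ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    sp = ratio(cm.tn, cm.tn + cm.fp, "specificity")
    acc = ratio(cm.tp + cm.tn, cm.total, "accuracy")
    f1 = ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1")
    return EvalReport(
        confusion=cm,
        sensitivity=se,
        specificity=sp,
        accuracy=acc,
        f1=f1,
        positive_class=positive,
        undefined=tuple(undefined),
    )


def evaluate_model(
    model: TrainedModel,
    test: Corpus,
    threshold: float = 0.5,
    positive: QualityLabel = QualityLabel.ACCEPTABLE,
) -> EvalReport:
    """predict -> confusion -> metrics on a test corpus; the report carries
    the observed test class ratio."""
    if len(test) == 0:
        raise DataError("test corpus is empty")
    xs, _ = corpus_to_arrays(test, model.config)
    preds = predict(model, list(xs), threshold=threshold)
    truth = [QualityLabel(int(v)) for v in test.labels()]
    cm = confusion(truth, [lab for lab, _ in preds], positive=positive)
    report = metrics(cm, positive=positive)
    acc_frac, unacc_frac = class_ratio(test)
    report.test_ratio = f"{100 * acc_frac:.0f}:{100 * unacc_frac:.0f}"
    return report


def write_report_table(reports: list[EvalReport], path) -> None:
    """Write reports as a delimited-text table (one row per configuration)."""
    cols = [
        "train_ratio", "test_ratio",
        "sensitivity_pct", "specificity_pct", "accuracy_pct", "f1_pct",
        "tp", "fp", "tn", "fn",
    ]
    lines = ["\t".join(cols)]
    for rep in reports:
        row = rep.row()
        cm = rep.confusion
        lines.append(
            "\t".join(
                [row["train_ratio"], row["test_ratio"],
                 row["sensitivity_pct"], row["specificity_pct"],
                 row["accuracy_pct"], row["f1_pct"],
                 str(cm.tp), str(cm.fp), str(cm.tn), str(cm.fn)]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
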