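"""Evaluation: confusion matrix, classification metrics, weight errors.

The confusion matrix is laid out predicted x actual (rows are predicted
grades).  Overall accuracy is the multiclass diagonal sum over the grand
total; per-class precision, recall and specificity come from the binary
one-vs-rest reductions, and F1 = 2PR/(P+R) on the fractional precision
and recall.  The weight error of an estimate ``mc`` against a static
reference ``ms`` is ``|mc - ms| / ms x 100 %``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix3", "ClassificationReport", "WeightErrorRecord",
           "confusion_matrix", "classification_report", "weight_error",
           "error_summary", "GRADE_NAMES"]

GRADE_NAMES = ("low", "medium", "high")


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 counts, ``counts[predicted, actual]``."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (3, 3) or np.any(c < 0):
            raise ValueError("counts must be a 3x3 nonnegative integer matrix")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def binary_reduction(self, cls: int) -> tuple[int, int, int, int]:
        """(TP, FN, FP, TN) of the one-vs-rest reduction for ``cls``."""
        c = self.counts
        tp = int(c[cls, cls])
        fp = int(c[cls].sum() - tp)        # predicted cls, actually other
        fn = int(c[:, cls].sum() - tp)     # actually cls, predicted other
        tn = self.total - tp - fp - fn
        return tp, fn, fp, tn


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix3:
    """Tabulate predictions: ``counts[p, a]`` = #(predicted p, actual a)."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D sequences")
    if not (np.isin(t, (0, 1, 2)).all() and np.isin(p, (0, 1, 2)).all()):
        raise ValueError("labels must lie in {0, 1, 2}")
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (p, t), 1)
    return ConfusionMatrix3(counts)


@dataclass(frozen=True)
class ClassificationReport:
    """Overall accuracy (%) and per-class metrics (%, F1 as a fraction)."""

    overall_accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    specificity: np.ndarray
    f1_score: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"precision_pct": self.precision, "recall_pct": self.recall,
             "specificity_pct": self.specificity, "f1_score": self.f1_score},
            index=list(GRADE_NAMES))


def _ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reporting NaN",
                      stacklevel=3)
        return float("nan")
    return num / den


def classification_report(cm: ConfusionMatrix3) -> ClassificationReport:
    """Metrics of a 3-class confusion matrix.

    Overall accuracy is trace/total; per-class precision TP/(TP+FP),
    recall TP/(TP+FN), specificity TN/(TN+FP) and F1 = 2PR/(P+R).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    prec, rec, spec, f1 = (np.empty(3) for _ in range(4))
    for cls in range(3):
        tp, fn, fp, tn = cm.binary_reduction(cls)
        p = _ratio(tp, tp + fp, f"class-{cls} precision")
        r = _ratio(tp, tp + fn, f"class-{cls} recall")
        s = _ratio(tn, tn + fp, f"class-{cls} specificity")
        prec[cls], rec[cls], spec[cls] = 100.0 * p, 100.0 * r, 100.0 * s
        f1[cls] = 2.0 * p * r / (p + r) if (p + r) > 0 else float("nan")
    overall = 100.0 * np.trace(cm.counts) / cm.total
    return ClassificationReport(overall_accuracy=float(overall), precision=prec,
                                recall=rec, specificity=spec, f1_score=f1)


@dataclass(frozen=True)
class WeightErrorRecord:
    mc_kg: float
    ms_kg: float
    error_pct: float
    grade: int | None = None
    animal_id: str | None = None


def weight_error(mc_kg: float, ms_kg: float, grade: int | None = None,
                 animal_id: str | None = None) -> WeightErrorRecord:
    """Relative weight error ``|mc - ms| / ms x 100`` (%)."""
    if ms_kg <= 0:
        raise ValueError("reference weight ms must be positive")
    err = abs(mc_kg - ms_kg) / ms_kg * 100.0
    return WeightErrorRecord(mc_kg=float(mc_kg), ms_kg=float(ms_kg),
                             error_pct=float(err), grade=grade, animal_id=animal_id)


def error_summary(records) -> pd.DataFrame:
    """Per-grade mean and maximum error rate (%) of a batch of records."""
    records = list(records)
    if not records:
        raise ValueError("no error records to summarise")
    df = pd.DataFrame({"grade": [r.grade for r in records],
                       "error_pct": [r.error_pct for r in records]})
    out = df.groupby("grade", dropna=False)["error_pct"].agg(["mean", "max"])
    return out.rename(columns={"mean": "mean_error_pct", "max": "max_error_pct"})
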