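"""Leave-one-patient-out cross-validation and confusion-matrix metrics.

Each fold holds out every sample from one patient, so no subject appears
in both the training and test sets. Within a fold the attributes are
ranked by Pearson correlation on the training data only (leakage-safe;
a ``global_ranking`` flag reproduces ranking on the full table), the
top-k subset is standardized and fitted by the DFP ridge logistic
optimizer, and the held-out samples are scored. Two aggregates are
reported because they differ when fold sizes are unequal: the mean of
the per-fold discrimination rates, and the accuracy of the pooled
confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np
import pandas as pd

from .classifier import DEFAULT_LAMBDA, ConvergenceWarning, fit_dfp
from .selection import pcc_rank, top_k
from .texture import FEATURE_NAMES


@dataclass
class ConfusionMatrix:
    """2x2 counts with sputum as the positive class."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    @classmethod
    def from_predictions(cls, y_true: np.ndarray,
                         y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(tp=int(np.sum((y_true == 1) & (y_pred == 1))),
                   fp=int(np.sum((y_true == 0) & (y_pred == 1))),
                   tn=int(np.sum((y_true == 0) & (y_pred == 0))),
                   fn=int(np.sum((y_true == 1) & (y_pred == 0))))


def _rate(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return None
    return float(Fraction(num, den))


def confusion_metrics(cm: ConfusionMatrix
                      ) -> tuple[float | None, float | None, float | None]:
    """(sensitivity, specificity, accuracy) as exact fractions cast to float.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/total. A metric with a zero denominator is returned
    as None with a warning.
    """
    sens = _rate(cm.tp, cm.tp + cm.fn, "sensitivity")
    spec = _rate(cm.tn, cm.tn + cm.fp, "specificity")
    acc = _rate(cm.tp + cm.tn, cm.total, "accuracy")
    return sens, spec, acc


def format_percent(x: float | None, decimals: int = 1) -> str:
    """Half-up percentage rounding for display, e.g. 0.8346 -> '83.5'."""
    if x is None:
        return "n/a"
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(str(100.0 * x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FoldResult:
    patient_id: str
    cm: ConfusionMatrix
    rate: float  # fold discrimination rate (accuracy on the held-out patient)
    k_features: int
    selected: list[str]


@dataclass
class CVReport:
    folds: list[FoldResult]
    pooled: ConfusionMatrix
    mean_fold_rate: float
    pooled_accuracy: float
    skipped_patients: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        sens, spec, acc = confusion_metrics(self.pooled)
        return {
            "folds": [{
                "patient_id": f.patient_id,
                "confusion": {"tp": f.cm.tp, "fp": f.cm.fp,
                              "tn": f.cm.tn, "fn": f.cm.fn},
                "rate": f.rate,
                "selected_features": f.selected,
            } for f in self.folds],
            "pooled_confusion": {"tp": self.pooled.tp, "fp": self.pooled.fp,
                                 "tn": self.pooled.tn, "fn": self.pooled.fn},
            "mean_fold_rate": self.mean_fold_rate,
            "pooled_accuracy": self.pooled_accuracy,
            "pooled_sensitivity": sens,
            "pooled_specificity": spec,
            "skipped_patients": self.skipped_patients,
        }


def lopo_split(patient_ids: np.ndarray | pd.Series
               ) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """Leave-one-patient-out folds: (train_idx, test_idx, held-out patient).

    Folds partition the sample index set; patients are held out in sorted
    order for determinism.
    """
    pids = np.asarray(patient_ids).astype(str)
    unique = sorted(set(pids.tolist()))
    if len(unique) < 2:
        raise ValueError("leave-one-patient-out needs at least 2 patients")
    idx = np.arange(len(pids))
    return [(idx[pids != p], idx[pids == p], p) for p in unique]


def run_cv(dataset: pd.DataFrame, k_features: int = 16,
           lam: float = DEFAULT_LAMBDA,
           feature_names: list[str] | None = None,
           global_ranking: bool = False) -> CVReport:
    """Leave-one-patient-out evaluation of the texture + ridge-logistic pipeline.

    ``dataset`` must carry a ``patient_id`` column, a binary ``label``
    column and the feature columns (default: the 16 texture attributes).
    A fold whose training set lacks one class is skipped with a warning
    and recorded in the report.
    """
    if feature_names is None:
        feature_names = [n for n in FEATURE_NAMES if n in dataset.columns]
    missing = [c for c in [*feature_names, "label", "patient_id"]
               if c not in dataset.columns]
    if missing:
        raise ValueError(f"dataset missing columns {missing}")
    X = dataset[feature_names].to_numpy(dtype=np.float64)
    y = dataset["label"].to_numpy(dtype=int)

    global_rank = pcc_rank(X, y, feature_names) if global_ranking else None

    folds: list[FoldResult] = []
    skipped: list[str] = []
    for train_idx, test_idx, patient in lopo_split(dataset["patient_id"]):
        y_tr = y[train_idx]
        if len(np.unique(y_tr)) < 2:
            warnings.warn(
                f"fold {patient}: training labels single-class; skipped",
                stacklevel=2)
            skipped.append(patient)
            continue
        ranking = global_rank if global_rank is not None \
            else pcc_rank(X[train_idx], y_tr, feature_names)
        selected = top_k(ranking, k_features)
        cols = [feature_names.index(n) for n in selected]
        with warnings.catch_warnings():
            # near-separable folds legitimately hit max_iter at tiny lambda;
            # prediction is unaffected, so keep the CV output quiet
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = fit_dfp(X[np.ix_(train_idx, cols)], y_tr, lam=lam,
                            feature_names=selected)
        y_hat = model.predict(X[np.ix_(test_idx, cols)])
        cm = ConfusionMatrix.from_predictions(y[test_idx], y_hat)
        folds.append(FoldResult(patient, cm, (cm.tp + cm.tn) / cm.total,
                                k_features, selected))
    if not folds:
        raise ValueError("no usable folds")
    pooled = ConfusionMatrix()
    for f in folds:
        pooled = pooled + f.cm
    return CVReport(folds=folds, pooled=pooled,
                    mean_fold_rate=float(np.mean([f.rate for f in folds])),
                    pooled_accuracy=(pooled.tp + pooled.tn) / pooled.total,
                    skipped_patients=skipped)


def feature_count_curve(dataset: pd.DataFrame, ks: range | list[int] = range(1, 17),
                        lam: float = DEFAULT_LAMBDA,
                        feature_names: list[str] | None = None) -> pd.DataFrame:
    """Sweep the number of selected attributes and record both aggregates."""
    rows = []
    for k in ks:
        rep = run_cv(dataset, k_features=k, lam=lam,
                     feature_names=feature_names)
        rows.append({"k": k, "mean_fold_rate": rep.mean_fold_rate,
                     "pooled_accuracy": rep.pooled_accuracy})
    return pd.DataFrame(rows)
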