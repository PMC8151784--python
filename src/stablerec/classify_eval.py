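"""Linear-SVM classification of recurrence and all reported metrics.

The classifier is a linear-kernel SVM (C = 1 by default) on the selected
CNN features, optionally augmented with four clinical covariates (age,
ER, PgR, HER2+). The positive class is non-RFSi (recurrence within three
years), so sensitivity is the proportion of recurrences caught and
specificity the proportion of recurrence-free patients correctly cleared.

Evaluation modes:

* leave-one-patient-out on the fine-tuning cohort, either with the
  per-fold dynamically selected features or with the fixed optimal subset
  (OSF); held-out decision values are pooled into one ROC/AUC and one
  confusion matrix at decision threshold 0;
* a single fit on the full training cohort scored on an independent test
  whose patients provably did not contribute to feature selection (the
  OSF's provenance is checked and a :class:`LeakageError` raised on
  overlap).

Standardization (z-scoring of CNN columns and age by training statistics)
is refit inside every training fold, never on held-out or test patients.
AUC is the rank-based (Mann-Whitney) estimator with midrank tie handling,
which equals the trapezoidal area under the pooled ROC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .errors import LeakageError
from .stability_selection import FeatureIndexSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SvmConfig:
    C: float = 1.0


@dataclass(frozen=True)
class ClinicalBlock:
    age: float
    er: int
    pgr: int
    her2: int

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError("age must be positive")
        for name in ("er", "pgr", "her2"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.age, self.er, self.pgr, self.her2], dtype=np.float64)


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc: list[tuple[float, float]]
    patient_ids: list[str]
    scores: list[float]
    predictions: list[int]
    labels: list[int]
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_scores(
        cls,
        scores: np.ndarray,
        labels: np.ndarray,
        patient_ids: Sequence[str],
        provenance: dict | None = None,
    ) -> "EvaluationReport":
        scores = np.asarray(scores, dtype=np.float64)
        labels = np.asarray(labels, dtype=np.int64)
        preds = (scores > 0).astype(np.int64)
        tp = int(((preds == 1) & (labels == 1)).sum())
        fp = int(((preds == 1) & (labels == 0)).sum())
        tn = int(((preds == 0) & (labels == 0)).sum())
        fn = int(((preds == 0) & (labels == 1)).sum())
        total = max(tp + fp + tn + fn, 1)
        fpr, tpr, _ = roc_curve(labels, scores)
        return cls(
            tp=tp,
            fp=fp,
            tn=tn,
            fn=fn,
            accuracy=(tp + tn) / total,
            sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
            specificity=tn / (tn + fp) if tn + fp else float("nan"),
            auc=auc(scores, labels),
            roc=[(float(x), float(y)) for x, y in zip(fpr, tpr)],
            patient_ids=list(patient_ids),
            scores=[float(s) for s in scores],
            predictions=[int(p) for p in preds],
            labels=[int(l) for l in labels],
            provenance=provenance or {},
        )

    def summary_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling.

    0.50 for scores carrying no class information (e.g. all tied), 1.0
    when every positive scores strictly above every negative.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class DesignStats:
    """Training-side standardization statistics for assemble_design."""

    mean: np.ndarray
    sd: np.ndarray
    keep: np.ndarray  # boolean mask over CNN columns (zero-variance dropped)
    age_mean: float = 0.0
    age_sd: float = 1.0


def fit_design_stats(
    features: np.ndarray,
    index_set: FeatureIndexSet,
    clinical: Sequence[ClinicalBlock] | None = None,
) -> DesignStats:
    """Compute z-scoring statistics from training patients only."""
    cols = np.asarray(features, dtype=np.float64)[:, index_set.as_array()]
    mean = cols.mean(axis=0) if cols.size else np.zeros(0)
    sd = cols.std(axis=0, ddof=0) if cols.size else np.zeros(0)
    keep = sd > 0
    if cols.size and not keep.all():
        dropped = index_set.as_array()[~keep]
        msg = f"dropping {len(dropped)} zero-variance training column(s): {dropped[:8]}"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    age_mean, age_sd = 0.0, 1.0
    if clinical is not None:
        ages = np.array([c.age for c in clinical], dtype=np.float64)
        age_mean = float(ages.mean())
        age_sd = float(ages.std(ddof=0)) or 1.0
    return DesignStats(mean=mean, sd=sd, keep=keep, age_mean=age_mean, age_sd=age_sd)


def assemble_design(
    features: np.ndarray,
    index_set: FeatureIndexSet,
    clinical: Sequence[ClinicalBlock] | None = None,
    stats_: DesignStats | None = None,
) -> np.ndarray:
    """Design matrix: z-scored CNN columns then the clinical block.

    ``stats_`` must come from :func:`fit_design_stats` on the training
    patients; passing None computes it from ``features`` itself (only
    correct when ``features`` *is* the training matrix). CNN columns and
    age are z-scored by training mean/sd; binary indicators pass as 0/1.
    """
    if stats_ is None:
        stats_ = fit_design_stats(features, index_set, clinical)
    X = np.asarray(features, dtype=np.float64)[:, index_set.as_array()]
    if X.shape[1]:
        X = (X[:, stats_.keep] - stats_.mean[stats_.keep]) / stats_.sd[stats_.keep]
    if clinical is not None:
        blk = np.stack([c.as_array() for c in clinical])
        blk[:, 0] = (blk[:, 0] - stats_.age_mean) / stats_.age_sd
        X = np.hstack([X, blk])
    return X


def _fold_scores(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    svm_config: SvmConfig,
) -> np.ndarray:
    if train_X.shape[1] == 0:
        # no usable features: an uninformative constant score
        return np.zeros(test_X.shape[0])
    clf = SVC(kernel="linear", C=svm_config.C)
    clf.fit(train_X, train_y)
    return clf.decision_function(test_X)


def loo_evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    patient_ids: Sequence[str],
    feature_source: FeatureIndexSet | Mapping[str, FeatureIndexSet],
    clinical: Sequence[ClinicalBlock] | None = None,
    svm_config: SvmConfig = SvmConfig(),
) -> EvaluationReport:
    """Leave-one-patient-out evaluation on the fine-tuning cohort.

    ``feature_source`` is either one fixed :class:`FeatureIndexSet` (OSF
    mode) or a mapping held-out patient id -> set (dynamic mode).
    Standardization is refit on each fold's training patients. Held-out
    decision values are pooled into a single ROC/AUC and confusion matrix.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    n = X.shape[0]
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 patients per class")
    scores = np.empty(n)
    for f in range(n):
        train = np.delete(np.arange(n), f)
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"training fold for {patient_ids[f]} has a single class")
        fset = (
            feature_source[patient_ids[f]]
            if isinstance(feature_source, Mapping)
            else feature_source
        )
        clin_train = [clinical[i] for i in train] if clinical is not None else None
        st = fit_design_stats(X[train], fset, clin_train)
        train_X = assemble_design(X[train], fset, clin_train, st)
        test_X = assemble_design(
            X[f : f + 1],
            fset,
            [clinical[f]] if clinical is not None else None,
            st,
        )
        scores[f] = _fold_scores(train_X, y[train], test_X, svm_config)[0]
    return EvaluationReport.from_scores(
        scores,
        y,
        patient_ids,
        provenance={
            "mode": "loo",
            "feature_source": (
                "dynamic_per_fold"
                if isinstance(feature_source, Mapping)
                else "fixed_osf"
            ),
            "with_clinical": clinical is not None,
        },
    )


def independent_evaluate(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    train_ids: Sequence[str],
    test_features: np.ndarray,
    test_labels: np.ndarray,
    test_ids: Sequence[str],
    osf: FeatureIndexSet,
    train_clinical: Sequence[ClinicalBlock] | None = None,
    test_clinical: Sequence[ClinicalBlock] | None = None,
    svm_config: SvmConfig = SvmConfig(),
) -> EvaluationReport:
    """Train once on the full training cohort, score the independent test.

    Raises :class:`LeakageError` if the OSF's provenance contains any test
    patient, i.e. if a test patient contributed to feature selection.
    """
    if len(test_ids) == 0:
        raise ValueError("test set is empty")
    overlap = osf.provenance & set(test_ids)
    if overlap:
        raise LeakageError(
            f"OSF was selected using test patient(s): {sorted(overlap)[:5]}"
        )
    Xtr = np.asarray(train_features, dtype=np.float64)
    Xte = np.asarray(test_features, dtype=np.float64)
    st = fit_design_stats(Xtr, osf, train_clinical)
    train_X = assemble_design(Xtr, osf, train_clinical, st)
    test_X = assemble_design(Xte, osf, test_clinical, st)
    scores = _fold_scores(train_X, np.asarray(train_labels), test_X, svm_config)
    return EvaluationReport.from_scores(
        scores,
        np.asarray(test_labels),
        test_ids,
        provenance={
            "mode": "independent",
            "osf_provenance_size": len(osf.provenance),
            "with_clinical": train_clinical is not None,
        },
    )
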