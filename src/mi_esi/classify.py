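"""SVM classification and the five evaluation metrics.

Right-hand imagery is the positive class: a correctly recognized hand trial
increments TP, a hand trial called foot increments FN, a correctly recognized
foot trial increments TN, and a foot trial called hand increments FP. The
five scores are accuracy, sensitivity, specificity, precision and F1, all
reported as percentages rounded half-up to two decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core_io import RIGHT_FOOT, RIGHT_HAND, UNKNOWN, round2

logger = logging.getLogger(__name__)

KERNELS = ("linear", "rbf")


def train_svm(features: np.ndarray, labels, kernel: str = "linear",
              C: float = 1.0, gamma="scale") -> Pipeline:
    """Fit a margin-maximizing classifier on standardized features.

    Features are standardized with training-set statistics only (the scaler
    is part of the returned pipeline, so test trials are transformed with the
    training mean/scale — no leakage). Deterministic for fixed input.
    """
    if kernel not in KERNELS:
        raise ValueError(f"kernel must be one of {KERNELS}")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("empty or malformed feature set")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    clf = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel=kernel, C=C, gamma=gamma)),
    ])
    clf.fit(X, y)
    return clf


@dataclass
class Confusion:
    """Counts with right hand as the positive class."""

    TP: int = 0
    FN: int = 0
    TN: int = 0
    FP: int = 0
    n_skipped: int = 0  # unlabeled trials excluded from the counts

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


def evaluate(classifier, features: np.ndarray, labels) -> Confusion:
    """Confusion counts of a fitted classifier on a labeled test set.

    Trials labeled "unknown" are skipped and reported via ``n_skipped``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] == 0:
        raise ValueError("empty test set")
    pred = classifier.predict(X)
    conf = Confusion()
    for truth, p in zip(y, pred):
        if truth == UNKNOWN:
            conf.n_skipped += 1
        elif truth == RIGHT_HAND:
            conf.TP += p == RIGHT_HAND
            conf.FN += p != RIGHT_HAND
        elif truth == RIGHT_FOOT:
            conf.TN += p != RIGHT_HAND
            conf.FP += p == RIGHT_HAND
        else:
            raise ValueError(f"unexpected label {truth!r}")
    if conf.n_skipped:
        logger.info("skipped %d unlabeled trials during evaluation", conf.n_skipped)
    return conf


@dataclass
class MetricsReport:
    """The five scores as percentages; zero-denominator metrics are reported
    as 0.00 and flagged in ``undefined`` instead of raising mid-experiment."""

    Acc: float
    Sen: float
    Spec: float
    Pre: float
    F1: float
    undefined: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict[str, float]:
        return {"Acc": self.Acc, "Sen": self.Sen, "Spec": self.Spec,
                "Pre": self.Pre, "F1": self.F1}


def metrics(conf: Confusion) -> MetricsReport:
    """Acc, Sen, Spec, Pre and F1 from confusion counts, in percent."""
    if conf.total == 0:
        raise ValueError("no labeled trials to score")
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = (conf.TP + conf.TN) / conf.total
    sen = ratio(conf.TP, conf.TP + conf.FN, "Sen")
    spec = ratio(conf.TN, conf.TN + conf.FP, "Spec")
    pre = ratio(conf.TP, conf.TP + conf.FP, "Pre")
    f1 = ratio(2.0 * pre * sen, pre + sen, "F1")
    return MetricsReport(Acc=round2(100 * acc), Sen=round2(100 * sen),
                         Spec=round2(100 * spec), Pre=round2(100 * pre),
                         F1=round2(100 * f1), undefined=tuple(undefined))


def f1_from_percentages(sen_pct: float, pre_pct: float) -> float:
    """F1 (percent, 2 decimals) recomputed from printed Sen/Pre percentages."""
    if sen_pct + pre_pct == 0:
        return 0.0
    return round2(2.0 * pre_pct * sen_pct / (pre_pct + sen_pct))
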