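"""Classifier roster, confusion-matrix metric suite and the repeated-CV
significance protocol.

Five model families are supported (logistic regression, RBF support vector
machine, random forest, gradient-boosted trees via XGBoost, and a
feed-forward neural network). Evaluation follows the confusion-matrix
metric suite — accuracy, precision, recall, specificity, F1 and the
Matthews correlation coefficient — with support-weighted one-vs-rest
averaging and a generalised (R_k) MCC for more than two classes.

Model comparison uses a 10-fold x 3-repeat stratified cross-validation
(30 paired folds) scored with F1; the split is *group-aware*: all windows of
a participant stay in the same fold so identity never leaks between train
and test. Standardisation and ADASYN run inside each training fold. Paired
two-tailed t tests against the designated baseline model are corrected with
the Holm step-down procedure at family-wise alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .balance import AdasynConfig, AdasynOversampler
from .features import FeatureScaler

__all__ = [
    "MODEL_NAMES",
    "ConfusionMatrix",
    "MetricReport",
    "CVResult",
    "SignificanceReport",
    "train_classifier",
    "make_classifier",
    "confusion",
    "metric_suite",
    "repeated_stratified_cv",
    "paired_t_test",
    "holm_adjust",
    "significance_protocol",
    "binary_f1",
]

MODEL_NAMES = ("logistic", "svm", "random_forest", "gradient_boosting",
               "neural_net")

#: conservative defaults standing in for the study's unpublished settings
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "logistic": {"C": 1.0, "max_iter": 2000, "multi_class": "multinomial"},
    "svm": {"C": 1.0, "kernel": "rbf", "gamma": "scale",
            "decision_shape": "ovr"},
    "random_forest": {"n_estimators": 300, "max_depth": None},
    "gradient_boosting": {"n_estimators": 300, "max_depth": 6,
                          "learning_rate": 0.1},
    "neural_net": {"hidden_layer_sizes": (64, 32), "max_iter": 500,
                   "early_stopping": True, "alpha": 1e-3},
}


def make_classifier(name: str, hyperparams: Optional[dict] = None,
                    seed: int = 0):
    """Instantiate an unfitted classifier by roster name.

    All estimators expose ``predict`` and ``predict_proba`` and are
    deterministic given the seed. For logistic regression the multiclass
    strategy is selectable (``multi_class``: multinomial or ovr); the SVM
    uses one-vs-rest or one-vs-one via ``decision_shape``.
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    hp = dict(DEFAULT_HYPERPARAMS[name])
    hp.update(hyperparams or {})
    if name == "logistic":
        multi = hp.pop("multi_class", "multinomial")
        if multi == "ovr":
            from sklearn.multiclass import OneVsRestClassifier
            return OneVsRestClassifier(
                LogisticRegression(random_state=seed, **hp)
            )
        return LogisticRegression(random_state=seed, **hp)
    if name == "svm":
        shape = hp.pop("decision_shape", "ovr")
        return SVC(probability=True, random_state=seed,
                   decision_function_shape=shape, **hp)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if name == "gradient_boosting":
        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss",
            verbosity=0, **hp,
        )
    return MLPClassifier(random_state=seed, **hp)


def train_classifier(name: str, X, y, hyperparams: Optional[dict] = None,
                     seed: int = 0):
    """Fit a roster model; rejects single-class targets."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    model = make_classifier(name, hyperparams, seed)
    model.fit(np.asarray(X, dtype=float), y)
    return model


# ---------------------------------------------------------------------------
# Confusion matrix and metric suite


@dataclass
class ConfusionMatrix:
    """k x k count matrix; cell [i, j] = true class i predicted as class j."""

    matrix: np.ndarray
    classes: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.matrix < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def is_binary(self) -> bool:
        return self.matrix.shape[0] == 2

    def binary_cells(self) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) with class index 1 as positive."""
        if not self.is_binary:
            raise ValueError("binary cells undefined for a multiclass matrix")
        m = self.matrix
        return int(m[1, 1]), int(m[0, 1]), int(m[1, 0]), int(m[0, 0])

    @classmethod
    def from_binary_cells(cls, tp: int, fp: int, fn: int, tn: int
                          ) -> "ConfusionMatrix":
        return cls(np.array([[tn, fp], [fn, tp]]), classes=[0, 1])


def confusion(y_true, y_pred, classes: Optional[Sequence] = None
              ) -> ConfusionMatrix:
    """Tally the confusion matrix in the given class order."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside class set: {t!r} / {p!r}")
        mat[index[t], index[p]] += 1
    return ConfusionMatrix(matrix=mat, classes=classes)


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    mcc: float
    averaging: str = "binary"

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "specificity": self.specificity,
            "f1": self.f1, "mcc": self.mcc, "averaging": self.averaging,
        }


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def _binary_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    total = tp + fp + fn + tn
    accuracy = _safe_div(tp + tn, total, "accuracy")
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    specificity = _safe_div(tn, tn + fp, "specificity")
    f1 = _safe_div(2 * precision * recall, precision + recall, "F1")
    denom = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(float(tp) * tn - float(fp) * fn, denom, "MCC")
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "specificity": specificity, "f1": f1, "mcc": mcc}


def _multiclass_mcc(matrix: np.ndarray) -> float:
    """Generalised (R_k) correlation on the full k x k matrix."""
    c = matrix.astype(float)
    n = c.sum()
    t = c.sum(axis=1)  # true-class totals
    p = c.sum(axis=0)  # predicted totals
    cov_tp = np.trace(c) * n - float(t @ p)
    cov_tt = n**2 - float(t @ t)
    cov_pp = n**2 - float(p @ p)
    return _safe_div(cov_tp, np.sqrt(cov_tt * cov_pp), "multiclass MCC")


def metric_suite(cm: ConfusionMatrix, averaging: str = "binary"
                 ) -> MetricReport:
    """Compute the metric suite from a confusion matrix.

    Binary matrices use the direct TP/FP/FN/TN formulas (class 1 positive).
    Multiclass matrices compute per-class one-vs-rest metrics combined by
    the requested average (``weighted`` by true-class support, or
    ``macro``); MCC is the generalised k-class correlation, not an average.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if cm.is_binary and averaging == "binary":
        vals = _binary_metrics(*cm.binary_cells())
        return MetricReport(**vals, averaging="binary")
    if averaging == "binary":
        raise ValueError("binary averaging requires a 2x2 matrix")
    if averaging not in ("weighted", "macro"):
        raise ValueError(f"unknown averaging {averaging!r}")
    k = cm.matrix.shape[0]
    per_class = []
    for i in range(k):
        tp = int(cm.matrix[i, i])
        fn = int(cm.matrix[i].sum() - tp)
        fp = int(cm.matrix[:, i].sum() - tp)
        tn = cm.total - tp - fn - fp
        per_class.append(_binary_metrics(tp, fp, fn, tn))
    support = cm.matrix.sum(axis=1).astype(float)
    w = support / support.sum() if averaging == "weighted" else np.full(k, 1 / k)

    def avg(key: str) -> float:
        return float(sum(wi * m[key] for wi, m in zip(w, per_class)))

    accuracy = float(np.trace(cm.matrix)) / cm.total
    return MetricReport(
        accuracy=accuracy,
        precision=avg("precision"),
        recall=avg("recall"),
        specificity=avg("specificity"),
        f1=avg("f1"),
        mcc=_multiclass_mcc(cm.matrix),
        averaging=averaging,
    )


def binary_f1(y_true, y_pred) -> float:
    """F1 of the positive class (binary) or support-weighted F1 (multiclass)."""
    classes = sorted(set(np.asarray(y_true).tolist()))
    if len(classes) <= 2:
        cm = confusion(y_true, y_pred, classes=[0, 1])
        return metric_suite(cm, averaging="binary").f1
    cm = confusion(y_true, y_pred, classes=classes)
    return metric_suite(cm, averaging="weighted").f1


# ---------------------------------------------------------------------------
# Repeated, stratified, group-aware cross-validation


@dataclass
class CVResult:
    model: str
    fold_scores: np.ndarray
    pooled_confusion: ConfusionMatrix

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_scores))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_scores, ddof=1))


def participant_folds(
    participant_ids: np.ndarray, y: np.ndarray, repeats: int, k: int,
    seed: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Fold index pairs (train, test) over windows, stratified at the
    participant level so no participant straddles a fold boundary."""
    participant_ids = np.asarray(participant_ids)
    y = np.asarray(y)
    pids, first = np.unique(participant_ids, return_index=True)
    p_labels = y[first]
    counts = pd.Series(p_labels).value_counts()
    if counts.min() < k:
        raise ValueError(
            f"class {counts.idxmin()!r} has {counts.min()} participants, "
            f"fewer than k={k} folds"
        )
    folds = []
    for r in range(repeats):
        splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                   random_state=seed + r)
        for train_p, test_p in splitter.split(pids, p_labels):
            train_mask = np.isin(participant_ids, pids[train_p])
            folds.append(
                (np.flatnonzero(train_mask), np.flatnonzero(~train_mask))
            )
    return folds


def repeated_stratified_cv(
    models: dict[str, Callable[[int], object]] | Sequence[str],
    frame: pd.DataFrame,
    y: np.ndarray,
    participant_ids: np.ndarray,
    repeats: int = 3,
    k: int = 10,
    seed: int = 0,
    adasyn: Optional[AdasynConfig] = None,
    hyperparams: Optional[dict[str, dict]] = None,
) -> dict[str, CVResult]:
    """Score every model on the identical repeats x k fold sequence.

    Within each training fold: fit the z-score scaler, transform both
    partitions, optionally ADASYN-oversample the training rows, then fit
    each model on the same augmented data. The per-fold statistic is F1
    (positive class for binary, support-weighted for multiclass); pooled
    confusions accumulate the held-out predictions across folds.
    """
    if repeats * k < 2:
        raise ValueError("repeats * k must be >= 2")
    if isinstance(models, dict):
        factories = models
    else:
        hp = hyperparams or {}
        factories = {
            name: (lambda s, n=name: make_classifier(n, hp.get(n), seed=s))
            for name in models
        }
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    folds = participant_folds(participant_ids, y, repeats, k, seed)
    scores = {name: [] for name in factories}
    pooled = {name: np.zeros((len(classes), len(classes)), dtype=np.int64)
              for name in factories}
    for fold_i, (train_idx, test_idx) in enumerate(folds):
        scaler = FeatureScaler().fit(frame.iloc[train_idx])
        X_train = scaler.transform(frame.iloc[train_idx]).to_numpy()
        X_test = scaler.transform(frame.iloc[test_idx]).to_numpy()
        y_train, y_test = y[train_idx], y[test_idx]
        if adasyn is not None:
            sampler = AdasynOversampler(
                k=adasyn.k, beta=adasyn.beta, metric=adasyn.metric,
                seed=adasyn.seed + fold_i,
            )
            X_train, y_train = sampler.fit_resample(X_train, y_train)
        for name, factory in factories.items():
            model = factory(seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X_train, y_train)
            y_pred = model.predict(X_test)
            scores[name].append(binary_f1(y_test, y_pred))
            pooled[name] += confusion(y_test, y_pred, classes=classes).matrix
    return {
        name: CVResult(
            model=name,
            fold_scores=np.asarray(scores[name]),
            pooled_confusion=ConfusionMatrix(pooled[name], classes=classes),
        )
        for name in factories
    }


# ---------------------------------------------------------------------------
# Paired t test and Holm step-down correction


def paired_t_test(a: Sequence[float], b: Sequence[float]
                  ) -> tuple[float, float]:
    """Two-tailed paired t test on per-fold score differences.

    Degenerate cases: identical score vectors give (0, p=1); a constant
    nonzero difference has zero variance, for which the t statistic diverges
    and the two-tailed p is reported as 0 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need two equal-length score vectors of length >= 2")
    d = a - b
    sd = d.std(ddof=1)
    n = len(d)
    if sd == 0.0:
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        warnings.warn(
            "constant nonzero fold differences: t diverges, p -> 0",
            stacklevel=2,
        )
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sp_stats.t.sf(abs(t), df=n - 1))
    return t, p


@dataclass
class SignificanceReport:
    """Ordered pairwise comparisons with Holm-adjusted p values."""

    comparisons: list[dict] = field(default_factory=list)
    alpha: float = 0.05

    def to_records(self) -> list[dict]:
        return list(self.comparisons)


def holm_adjust(pvalues: Sequence[float], alpha: float = 0.05
                ) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjusted p values and reject flags.

    With p values sorted ascending, adjusted p_(j) = max_{i <= j}
    min(1, (m - i + 1) * p_(i)); reject where adjusted p <= alpha. The
    procedure controls the family-wise error rate and is uniformly more
    powerful than Bonferroni.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adjusted_sorted = np.maximum.accumulate(adjusted_sorted)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= alpha


def significance_protocol(
    cv_results: dict[str, CVResult],
    baseline: str = "gradient_boosting",
    alpha: float = 0.05,
) -> SignificanceReport:
    """Paired t tests of the baseline model against every rival, Holm-corrected."""
    if baseline not in cv_results:
        raise ValueError(f"baseline {baseline!r} not among CV results")
    rivals = [name for name in cv_results if name != baseline]
    if not rivals:
        raise ValueError("need at least one rival model")
    raw = []
    stats = []
    for name in rivals:
        t, p = paired_t_test(cv_results[baseline].fold_scores,
                             cv_results[name].fold_scores)
        stats.append(t)
        raw.append(p)
    adjusted, reject = holm_adjust(raw, alpha)
    comparisons = [
        {
            "baseline": baseline,
            "rival": name,
            "t": float(t),
            "p_raw": float(p),
            "p_holm": float(ph),
            "reject": bool(rej),
            "mean_diff": cv_results[baseline].mean - cv_results[name].mean,
        }
        for name, t, p, ph, rej in zip(rivals, stats, raw, adjusted, reject)
    ]
    comparisons.sort(key=lambda c: c["p_raw"])
    return SignificanceReport(comparisons=comparisons, alpha=alpha)
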