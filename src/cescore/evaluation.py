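"""Benchmarking variant-impact scores against labeled variants.

Implements the evaluation protocol used for deep-mutational-scanning and
disease-variant benchmarks: activity-based labeling (intolerant = below
50% of wild-type activity), confusion-matrix metrics (sensitivity,
precision, accuracy, balanced accuracy, MCC, F1), ROC AUC,
accuracy-maximizing threshold selection on a training split, the union rule
for integrating a coevolution score with a conservation score (predict
intolerant when either score reaches its threshold), and repeated
Monte-Carlo 90/10 cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "label_by_activity",
    "confusion_at_threshold",
    "metric_set",
    "roc_auc",
    "best_threshold",
    "integrated_classify",
    "monte_carlo_cv",
    "variants_per_residue",
    "identification_coverage",
    "ConfusionCounts",
    "MetricSet",
    "CvReport",
]


class EvaluationError(ValueError):
    pass


POSITIVE, NEGATIVE = 1, 0

_METRIC_NAMES = (
    "sensitivity", "precision", "accuracy",
    "balanced_accuracy", "mcc", "f1",
)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    precision: float
    accuracy: float
    balanced_accuracy: float
    mcc: float
    f1: float
    auc: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in _METRIC_NAMES}
        if self.auc is not None:
            d["auc"] = self.auc
        return d


@dataclass(frozen=True)
class CvReport:
    """Aggregated Monte-Carlo cross-validation results.

    ``per_repeat`` holds one metric row per repeat; ``mean`` and ``stderr``
    (sample SD / sqrt(n_repeats)) aggregate them.
    """

    per_repeat: pd.DataFrame
    mean: pd.Series
    stderr: pd.Series
    seed: int
    n_repeats: int
    train_fraction: float
    scheme: tuple


# ---------------------------------------------------------------------------
# labeling and confusion metrics
# ---------------------------------------------------------------------------

def label_by_activity(activity: float, cutoff: float = 0.5) -> int:
    """Intolerant (positive) iff activity is strictly below the cutoff
    fraction of wild-type activity."""
    if activity < 0:
        raise EvaluationError(f"negative activity {activity}")
    return POSITIVE if activity < cutoff else NEGATIVE


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise EvaluationError("scores and labels differ in length")
    if s.size == 0:
        raise EvaluationError("empty input")
    return s, y


def confusion_at_threshold(scores, labels, threshold: float, strict: bool = False) -> ConfusionCounts:
    """Confusion counts predicting positive when score >= threshold
    (or > with ``strict``)."""
    s, y = _as_arrays(scores, labels)
    pred = s > threshold if strict else s >= threshold
    pos, neg = y == POSITIVE, y == NEGATIVE
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & neg)),
        TN=int(np.sum(~pred & neg)),
        FN=int(np.sum(~pred & pos)),
    )


def metric_set(c: ConfusionCounts, auc: float | None = None) -> MetricSet:
    """All confusion-derived metrics; 0/0 denominators yield 0 (MCC
    convention included)."""
    if c.n < 1:
        raise EvaluationError("empty confusion table")
    tp, fp, tn, fn = c.TP, c.FP, c.TN, c.FN

    def safe(num: float, den: float) -> float:
        return num / den if den else 0.0

    sens = safe(tp, tp + fn)
    spec = safe(tn, tn + fp)
    prec = safe(tp, tp + fp)
    acc = (tp + tn) / c.n
    bacc = (sens + spec) / 2.0
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den else 0.0
    f1 = safe(2 * prec * sens, prec + sens)
    return MetricSet(
        sensitivity=sens, precision=prec, accuracy=acc,
        balanced_accuracy=bacc, mcc=mcc, f1=f1, auc=auc,
    )


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; ties contribute 1/2 (Mann-Whitney
    concordance probability)."""
    s, y = _as_arrays(scores, labels)
    if len(np.unique(y)) < 2:
        raise EvaluationError("ROC AUC needs both classes present")
    return float(roc_auc_score(y, s))


def best_threshold(scores, labels, strict: bool = False) -> float:
    """Accuracy-maximizing threshold over observed score values.

    Candidates are every observed score plus one point above the maximum
    (the all-negative rule); ties resolve to the smallest threshold.
    """
    s, y = _as_arrays(scores, labels)
    candidates = np.concatenate([np.unique(s), [s.max() + 1.0]])
    best_t, best_acc = None, -1.0
    for t in candidates:
        c = confusion_at_threshold(s, y, t, strict=strict)
        acc = (c.TP + c.TN) / c.n
        if acc > best_acc:
            best_acc, best_t = acc, float(t)
    return best_t


def integrated_classify(score_a, thr_a: float, score_b, thr_b: float) -> np.ndarray:
    """Union rule: predict intolerant when either score reaches its
    threshold."""
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    if a.shape != b.shape:
        raise EvaluationError("score vectors differ in length")
    return ((a >= thr_a) | (b >= thr_b)).astype(int)


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation
# ---------------------------------------------------------------------------

def _fit_predict(
    train: pd.DataFrame, test: pd.DataFrame, scheme: tuple
) -> tuple[np.ndarray, float | None]:
    """Fit thresholds on the training split; predict the test split.

    Returns (predictions, auc). For a single-score scheme the AUC uses the
    continuous test scores; the union rule has no continuous score, so its
    AUC is that of the binary prediction (equal to its balanced accuracy).
    """
    kind = scheme[0]
    ytr = train["label"].to_numpy()
    yte = test["label"].to_numpy()
    if kind == "single":
        col = scheme[1]
        thr = best_threshold(train[col], ytr)
        s = test[col].to_numpy(dtype=float)
        pred = (s >= thr).astype(int)
        auc = roc_auc(s, yte) if len(np.unique(yte)) == 2 else None
    elif kind == "integrated":
        col_a, col_b = scheme[1], scheme[2]
        thr_a = best_threshold(train[col_a], ytr)
        thr_b = best_threshold(train[col_b], ytr)
        pred = integrated_classify(test[col_a], thr_a, test[col_b], thr_b)
        auc = (
            roc_auc(pred.astype(float), yte)
            if len(np.unique(yte)) == 2 and len(np.unique(pred)) == 2
            else None
        )
    else:
        raise EvaluationError(f"unknown scheme kind {kind!r}")
    return pred, auc


def monte_carlo_cv(
    data: pd.DataFrame,
    scheme: tuple,
    n_repeats: int = 100,
    train_fraction: float = 0.9,
    seed: int = 0,
    max_redraws: int = 1000,
) -> CvReport:
    """Repeated random 90/10 split evaluation.

    ``data`` needs a binary ``label`` column plus the score columns named
    by ``scheme`` — ``("single", "CE")`` or ``("integrated", "CE", "CS")``.
    Thresholds are fitted on each training split by accuracy maximization
    and metrics measured on the held-out split. A test split missing one of
    the classes is redrawn from the same seeded stream. Fully reproducible
    for a fixed seed.
    """
    if "label" not in data.columns:
        raise EvaluationError("data must have a 'label' column")
    n = len(data)
    if n < 10:
        raise EvaluationError("need at least 10 labeled variants")
    if len(np.unique(data["label"])) < 2:
        raise EvaluationError("dataset must contain both classes")
    if not 0 < train_fraction < 1:
        # train_fraction == 1 is the degenerate fit==test sanity limit
        if train_fraction != 1.0:
            raise EvaluationError(f"bad train_fraction {train_fraction}")

    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n))
    rows = []
    redraws = 0
    for _ in range(n_repeats):
        while True:
            perm = rng.permutation(n)
            if train_fraction == 1.0:
                tr_idx = te_idx = perm
            else:
                tr_idx, te_idx = perm[:n_train], perm[n_train:]
            train = data.iloc[tr_idx]
            test = data.iloc[te_idx]
            if (
                len(np.unique(train["label"])) == 2
                and len(np.unique(test["label"])) == 2
            ):
                break
            redraws += 1
            if redraws > max_redraws:
                raise EvaluationError(
                    "could not draw a two-class test split; dataset too skewed"
                )
        pred, auc = _fit_predict(train, test, scheme)
        c = confusion_at_threshold(pred, test["label"].to_numpy(), 0.5)
        rows.append(metric_set(c, auc=auc).as_dict())
    per_repeat = pd.DataFrame(rows)
    mean = per_repeat.mean()
    stderr = (
        per_repeat.std(ddof=1) / math.sqrt(n_repeats)
        if n_repeats > 1
        else mean * 0.0
    )
    return CvReport(
        per_repeat=per_repeat, mean=mean, stderr=stderr,
        seed=seed, n_repeats=n_repeats,
        train_fraction=train_fraction, scheme=scheme,
    )


# ---------------------------------------------------------------------------
# small benchmark-table helpers
# ---------------------------------------------------------------------------

def variants_per_residue(n_variants: int, length: int) -> float:
    """Mutational-scan density: variants per residue, to 2 decimals."""
    if length < 1:
        raise EvaluationError("length must be >= 1")
    if n_variants < 0:
        raise EvaluationError("negative variant count")
    return round(n_variants / length, 2)


def identification_coverage(n_identified: int, n_total: int) -> float:
    """Percentage of variants identified, to 2 decimals."""
    if n_total < 1:
        raise EvaluationError("total must be >= 1")
    if not 0 <= n_identified <= n_total:
        raise EvaluationError("identified count outside [0, total]")
    return round(100.0 * n_identified / n_total, 2)
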