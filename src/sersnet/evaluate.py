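"""Model evaluation: confusion matrices, one-vs-rest metrics, ROC/AUC,
cross-validation, group difference spectra, per-peak t-tests and the
PCA-LDA / PCA-SVM chemometric baselines.

Per-class accuracy, precision, recall and F1 are computed from the
one-vs-rest collapse of the 4x4 confusion matrix:

    accuracy_C  = (TP + TN) / (TP + TN + FP + FN)
    precision_C = TP / (TP + FP)
    recall_C    = TP / (TP + FN)
    F1_C        = 2 * precision_C * recall_C / (precision_C + recall_C)

Averaged precision/recall/F1 are support-weighted by default (macro also
reported); overall accuracy is the pooled fraction correct (trace / total).
Four binary ROC groupings are evaluated: healthy controls versus cancer, and
each cancer class versus its complement, scoring with the positive group's
class score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from .errors import ConfigError
from .io import CLASS_ORDER, LabelError, PeakLexicon, Spectrum, SpectrumSet
from .split import AugmentConfig, FoldPlan, build_datasets

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "ROC_GROUPINGS",
    "confusion",
    "metrics",
    "roc_auc",
    "cross_validate",
    "difference_spectrum",
    "peak_ttests",
    "baseline_classifiers",
]

# Binary collapses evaluated by ROC/AUC: name -> positive class label.
# healthy_vs_cancer pools the three cancer groups as the negative class.
ROC_GROUPINGS: dict[str, str] = {
    "healthy_vs_cancer": "healthy",
    "BC_vs_rest": "BC",
    "AC_vs_rest": "AC",
    "AML_vs_rest": "AML",
}


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    class_names: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, class_idx: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) for one class against the rest."""
        c = self.counts
        tp = int(c[class_idx, class_idx])
        fp = int(c[:, class_idx].sum() - tp)
        fn = int(c[class_idx, :].sum() - tp)
        tn = int(c.sum() - tp - fp - fn)
        return tp, fp, tn, fn


@dataclass
class MetricsReport:
    overall_accuracy: float
    per_class: dict[str, dict[str, float]]
    weighted: dict[str, float]
    macro: dict[str, float]
    auc: dict[str, float] = field(default_factory=dict)
    zero_division_flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "per_class": self.per_class,
            "weighted": self.weighted,
            "macro": self.macro,
            "auc": self.auc,
            "zero_division_flags": self.zero_division_flags,
        }


def confusion(
    true_labels: Sequence,
    predicted_labels: Sequence,
    class_names: Sequence[str] = CLASS_ORDER,
) -> ConfusionMatrix:
    """Tally counts[i, j] = #(true class i, predicted class j)."""
    class_names = tuple(class_names)
    lut = {c: i for i, c in enumerate(class_names)}
    lut.update({i: i for i in range(len(class_names))})
    k = len(class_names)
    counts = np.zeros((k, k), dtype=int)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    for t, p in zip(true_labels, predicted_labels):
        if t not in lut or p not in lut:
            raise LabelError(f"unknown label in ({t!r}, {p!r})")
        counts[lut[t], lut[p]] += 1
    return ConfusionMatrix(counts, class_names)


def _safe_div(num: float, den: float, flags: list[str], what: str) -> float:
    if den == 0:
        flags.append(what)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest accuracy/precision/recall/F1 per class, plus averages."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    supports = cm.counts.sum(axis=1)
    for i, name in enumerate(cm.class_names):
        tp, fp, tn, fn = cm.one_vs_rest(i)
        precision = _safe_div(tp, tp + fp, flags, f"precision[{name}]")
        recall = _safe_div(tp, tp + fn, flags, f"recall[{name}]")
        f1 = _safe_div(2 * precision * recall, precision + recall, flags, f"f1[{name}]")
        per_class[name] = {
            "accuracy": (tp + tn) / (tp + tn + fp + fn),
            "precision": precision,
            "recall": recall,
            "f1": f1,
        }
    def _avg(metric: str, weights: np.ndarray) -> float:
        vals = np.array([per_class[c][metric] for c in cm.class_names])
        w = weights / weights.sum() if weights.sum() else np.full(len(vals), 1 / len(vals))
        return float(vals @ w)

    weighted = {m: _avg(m, supports.astype(float)) for m in ("precision", "recall", "f1")}
    macro = {m: _avg(m, np.ones(len(cm.class_names))) for m in ("precision", "recall", "f1")}
    return MetricsReport(
        overall_accuracy=float(np.trace(cm.counts) / cm.total),
        per_class=per_class,
        weighted=weighted,
        macro=macro,
        zero_division_flags=flags,
    )


def roc_auc(
    scores: np.ndarray,
    true_labels: Sequence,
    grouping: str,
    class_names: Sequence[str] = CLASS_ORDER,
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and AUC for one binary collapse of the 4-class problem.

    ``scores`` is the (n, n_classes) per-class score matrix; the positive
    group's class score is used as the decision score. Returns
    ``(fpr, tpr, auc)``; AUC is the trapezoidal area, equivalent to the
    rank-averaged Mann-Whitney statistic under ties.
    """
    if grouping not in ROC_GROUPINGS:
        raise ConfigError(f"unknown grouping {grouping!r}")
    class_names = tuple(class_names)
    pos_class = ROC_GROUPINGS[grouping]
    pos_idx = class_names.index(pos_class)
    lut = {c: i for i, c in enumerate(class_names)}
    y = np.array([t if isinstance(t, (int, np.integer)) else lut[t] for t in true_labels])
    y_bin = (y == pos_idx).astype(int)
    if len(np.unique(y_bin)) < 2:
        raise ValueError(f"AUC undefined: only one class present for {grouping}")
    score = np.asarray(scores)[:, pos_idx]
    fpr, tpr, _ = _sk_roc_curve(y_bin, score)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


def cross_validate(
    s: SpectrumSet,
    plan: FoldPlan,
    clf_factory,
    aug_cfg: AugmentConfig | None = None,
) -> dict:
    """Full rotation over the fold plan: build datasets, train, pool tests.

    ``clf_factory(rotation) -> estimator`` supplies a fresh classifier per
    rotation (any sklearn-style estimator with fit(X, y, X_val, y_val) or
    plain fit(X, y), predict and predict_scores/predict_proba).

    Test predictions are pooled across rotations into one confusion matrix;
    per-rotation accuracies are reported alongside.
    """
    aug_cfg = aug_cfg or AugmentConfig()
    pooled_true: list[int] = []
    pooled_pred: list[int] = []
    pooled_scores: list[np.ndarray] = []
    fold_acc: list[float] = []
    test_sizes: list[int] = []
    for rotation in range(plan.n_folds):
        train_set, val_set, test_set = build_datasets(s, plan, rotation, aug_cfg)
        clf = clf_factory(rotation)
        Xtr, ytr = train_set.intensity_matrix(), train_set.labels()
        Xte, yte = test_set.intensity_matrix(), test_set.labels()
        try:
            clf.fit(
                Xtr, ytr,
                X_val=val_set.intensity_matrix(), y_val=val_set.labels(),
            )
        except TypeError:
            clf.fit(Xtr, ytr)
        if hasattr(clf, "predict_scores"):
            scores = clf.predict_scores(Xte)
        else:
            scores = clf.predict_proba(Xte)
        pred = np.asarray(scores).argmax(axis=1)
        pooled_true.extend(yte.tolist())
        pooled_pred.extend(pred.tolist())
        pooled_scores.append(np.asarray(scores))
        fold_acc.append(float(np.mean(pred == yte)))
        test_sizes.append(len(yte))
    cm = confusion(pooled_true, pooled_pred, s.class_names)
    report = metrics(cm)
    scores_all = np.vstack(pooled_scores)
    for grouping in ROC_GROUPINGS:
        try:
            _, _, a = roc_auc(scores_all, pooled_true, grouping, s.class_names)
            report.auc[grouping] = a
        except ValueError:
            report.auc[grouping] = float("nan")
    return {
        "confusion": cm,
        "metrics": report,
        "fold_accuracies": fold_acc,
        "test_sizes": test_sizes,
        "pooled_true": np.asarray(pooled_true),
        "pooled_pred": np.asarray(pooled_pred),
        "pooled_scores": scores_all,
    }


def difference_spectrum(s: SpectrumSet, group_a: str, group_b: str) -> Spectrum:
    """Pointwise mean(group_a) - mean(group_b) on the shared axis."""
    sub_a = s.select_group(group_a)
    sub_b = s.select_group(group_b)
    if not len(sub_a) or not len(sub_b):
        missing = group_a if not len(sub_a) else group_b
        raise LabelError(f"group {missing!r} has no spectra")
    diff = sub_a.intensity_matrix().mean(axis=0) - sub_b.intensity_matrix().mean(axis=0)
    return Spectrum(s.axis, diff, f"{group_a}-{group_b}")


def peak_ttests(
    s: SpectrumSet,
    group_a: str,
    group_b: str,
    lexicon: PeakLexicon | None = None,
    k: int = 5,
) -> list[dict]:
    """Welch two-sample t-tests at the grid point nearest each lexicon peak.

    Returns the top-``k`` peaks ranked by ascending p value; peaks where both
    groups have zero variance are flagged ``degenerate`` and ranked last.
    """
    lexicon = lexicon or PeakLexicon.default()
    A = s.select_group(group_a)
    B = s.select_group(group_b)
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    Xa, Xb = A.intensity_matrix(), B.intensity_matrix()
    rows = []
    for pos, assignment in lexicon.entries:
        j = int(np.argmin(np.abs(s.axis - pos)))
        a, b = Xa[:, j], Xb[:, j]
        if a.var() == 0 and b.var() == 0:
            rows.append(
                dict(position=pos, assignment=assignment, t=0.0, p=1.0,
                     degenerate=True)
            )
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            dict(position=pos, assignment=assignment, t=float(t), p=float(p),
                 degenerate=False)
        )
    rows.sort(key=lambda r: (r["degenerate"], r["p"]))
    return rows[:k]


def baseline_classifiers(
    train_set: SpectrumSet,
    test_set: SpectrumSet,
    method: str = "pca_lda",
    n_components: int = 20,
) -> MetricsReport:
    """PCA-compressed chemometric baselines (PCA-LDA and PCA-SVM).

    PCA is fitted on the training spectra only; the downstream classifier
    (LDA, or an RBF SVM) is fitted on the training scores and evaluated on
    the projected test spectra.
    """
    Xtr, ytr = train_set.intensity_matrix(), train_set.labels()
    Xte, yte = test_set.intensity_matrix(), test_set.labels()
    max_rank = min(Xtr.shape)
    if n_components > max_rank:
        raise ConfigError(
            f"n_components {n_components} exceeds feasible rank {max_rank}"
        )
    if method == "pca_lda":
        tail = LinearDiscriminantAnalysis()
    elif method == "pca_svm":
        tail = SVC(kernel="rbf")
    else:
        raise ConfigError(f"unknown method {method!r}")
    pipe = Pipeline([("pca", PCA(n_components=n_components)), ("clf", tail)])
    pipe.fit(Xtr, ytr)
    pred = pipe.predict(Xte)
    cm = confusion(yte.tolist(), pred.tolist(), train_set.class_names)
    return metrics(cm)
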