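"""Feature selection, KNN classification, repeated cross-validation,
metrics, and frequency-band fusion."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FeatureTable",
    "CvConfig",
    "MetricsReport",
    "confusion_metrics",
    "knn_predict",
    "repeated_cv",
    "order_features",
    "fisher_scores",
    "sequential_select",
    "fuse_bands",
]


@dataclass
class FeatureTable:
    """Trials x features matrix with labels and per-feature provenance.

    ``feature_provenance[f]`` is ``(band_tag, model_column_index)`` telling
    which band/model column produced feature ``f`` (kept through fusion
    and reordering).
    """

    matrix: np.ndarray
    labels: list
    feature_provenance: list
    ordering_scores: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        self.labels = list(self.labels)
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.matrix.shape[0]} rows but {len(self.labels)} labels"
            )
        self.feature_provenance = list(self.feature_provenance)
        if len(self.feature_provenance) != self.matrix.shape[1]:
            raise ValueError(
                f"provenance length {len(self.feature_provenance)} != "
                f"feature count {self.matrix.shape[1]}"
            )

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def select_columns(self, cols) -> "FeatureTable":
        cols = list(cols)
        return FeatureTable(
            matrix=self.matrix[:, cols],
            labels=list(self.labels),
            feature_provenance=[self.feature_provenance[c] for c in cols],
        )

    def select_rows(self, rows) -> "FeatureTable":
        rows = list(rows)
        return FeatureTable(
            matrix=self.matrix[rows],
            labels=[self.labels[r] for r in rows],
            feature_provenance=list(self.feature_provenance),
        )


@dataclass(frozen=True)
class CvConfig:
    """Cross-validation protocol parameters."""

    k_neighbors: int = 3
    n_folds: int = 5
    n_repeats: int = 10
    seed: int = 0
    positive_class: object = None

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class MetricsReport:
    """Percent-scale classification metrics from repeated CV."""

    acc_mean: float
    acc_sd: float
    sensitivity: float | None
    specificity: float | None
    repeat_accuracies: list
    confusion: dict              # pooled counts: tp/fn/tn/fp (binary only)
    n_features: int
    positive_class: object = None
    accuracy_curve: list | None = None
    selected_count: int | None = None

    def as_dict(self) -> dict:
        return {
            "acc_mean": self.acc_mean,
            "acc_sd": self.acc_sd,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "repeat_accuracies": list(self.repeat_accuracies),
            "confusion": dict(self.confusion),
            "n_features": self.n_features,
            "positive_class": self.positive_class,
            "accuracy_curve": self.accuracy_curve,
            "selected_count": self.selected_count,
        }


def confusion_metrics(conf: dict) -> dict:
    """Percent accuracy/sensitivity/specificity from pooled confusion counts.

    ``conf`` holds ``tp``/``fn``/``tn``/``fp``. Sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP); undefined ratios come back as ``None``.
    """
    tp, fn = conf["tp"], conf["fn"]
    tn, fp = conf["tn"], conf["fp"]
    total = tp + fn + tn + fp
    return {
        "accuracy": 100.0 * (tp + tn) / total if total else None,
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else None,
        "specificity": 100.0 * tn / (tn + fp) if tn + fp else None,
    }


def knn_predict(train: FeatureTable, test: FeatureTable, k: int = 3) -> list:
    """Euclidean k-nearest-neighbor majority vote.

    A vote tie between classes is broken in favor of the tied class whose
    nearest member is closest to the query.
    """
    if k > train.n_trials:
        raise ValueError(f"k={k} exceeds training size {train.n_trials}")
    dists = cdist(test.matrix, train.matrix)    # n_test x n_train
    labels = np.asarray(train.labels, dtype=object)
    out = []
    for row in dists:
        order = np.argsort(row, kind="stable")[:k]
        neigh = labels[order]
        counts: dict = {}
        for lab in neigh:
            counts[lab] = counts.get(lab, 0) + 1
        top = max(counts.values())
        tied = [lab for lab, c in counts.items() if c == top]
        if len(tied) == 1:
            out.append(tied[0])
        else:
            # nearest neighbor among the tied classes decides
            for lab in neigh:       # neigh is distance-ordered
                if lab in tied:
                    out.append(lab)
                    break
    return out


def _confusion_update(conf, y_true, y_pred, positive):
    for t, p in zip(y_true, y_pred):
        if t == positive:
            conf["tp" if p == positive else "fn"] += 1
        else:
            conf["tn" if p != positive else "fp"] += 1


def repeated_cv(features: FeatureTable, cfg: CvConfig) -> MetricsReport:
    """Repeated stratified k-fold CV with a KNN classifier.

    Folds are re-randomized per repeat with seeds ``cfg.seed .. seed +
    n_repeats - 1``. The reported accuracy is the mean of the per-repeat
    accuracies (each repeat classifies every trial exactly once); the SD
    is across those repeat-level accuracies. Sensitivity/specificity are
    computed from the confusion counts pooled over all folds and repeats,
    for binary problems only.
    """
    y = np.asarray(features.labels, dtype=object)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < cfg.n_folds:
        small = classes[np.argmin(counts)]
        raise ValueError(
            f"class {small!r} has {counts.min()} trials, fewer than "
            f"n_folds={cfg.n_folds}"
        )
    binary = len(classes) == 2
    positive = cfg.positive_class
    if binary and positive is None:
        positive = features.labels[0]  # first-named condition

    conf = {"tp": 0, "fn": 0, "tn": 0, "fp": 0}
    repeat_accs = []
    for rep in range(cfg.n_repeats):
        skf = StratifiedKFold(
            n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed + rep,
        )
        correct = 0
        for train_idx, test_idx in skf.split(features.matrix, y):
            train = features.select_rows(train_idx)
            test = features.select_rows(test_idx)
            pred = knn_predict(train, test, cfg.k_neighbors)
            truth = [features.labels[i] for i in test_idx]
            correct += sum(p == t for p, t in zip(pred, truth))
            if binary:
                _confusion_update(conf, truth, pred, positive)
        repeat_accs.append(100.0 * correct / features.n_trials)

    sens = spec = None
    if binary:
        m = confusion_metrics(conf)
        sens, spec = m["sensitivity"], m["specificity"]

    return MetricsReport(
        acc_mean=float(np.mean(repeat_accs)),
        acc_sd=float(np.std(repeat_accs, ddof=1)) if len(repeat_accs) > 1 else 0.0,
        sensitivity=sens,
        specificity=spec,
        repeat_accuracies=repeat_accs,
        confusion=conf,
        n_features=features.n_features,
        positive_class=positive if binary else None,
    )


def fisher_scores(matrix: np.ndarray, labels) -> np.ndarray:
    """Univariate discriminability of each feature.

    Score = between-class variance / within-class variance:
    ``sum_j n_j (m_jf - m_f)^2 / sum_j sum_i (x_if - m_jf)^2``. A feature
    with zero within-class variance but nonzero between-class variance
    scores ``inf``.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
    y = np.asarray(labels, dtype=object)
    grand = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for c in np.unique(y):
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        between += Xc.shape[0] * (mc - grand) ** 2
        within += ((Xc - mc) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(
            within > 0, between / np.where(within > 0, within, 1.0),
            np.where(between > 0, np.inf, 0.0),
        )
    return scores


def order_features(features: FeatureTable, labels=None) -> np.ndarray:
    """Permutation ranking features by descending Fisher score.

    Ties (and the all-equal case) preserve original feature order.
    """
    y = features.labels if labels is None else labels
    scores = fisher_scores(features.matrix, y)
    # stable sort on negated score keeps original index order within ties
    order = np.argsort(-scores, kind="stable")
    return order


def sequential_select(features: FeatureTable, cfg: CvConfig,
                      order: np.ndarray | None = None):
    """Forward feature addition along a discriminability ordering.

    Evaluates :func:`repeated_cv` on feature prefixes of length 1..F and
    returns ``(selected_column_indices, MetricsReport)`` where the
    selection is the shortest prefix attaining the maximum mean accuracy.
    The report carries the full accuracy-vs-prefix curve.

    When used for honest held-out reporting, call this on the training
    portion only (see the pipeline's nested mode).
    """
    if features.n_features < 1:
        raise ValueError("need at least one feature")
    if order is None:
        order = order_features(features)
    order = list(order)
    curve = []
    reports = []
    for plen in range(1, len(order) + 1):
        sub = features.select_columns(order[:plen])
        rep = repeated_cv(sub, cfg)
        curve.append(rep.acc_mean)
        reports.append(rep)
    best = int(np.argmax(curve))  # argmax returns first = shortest prefix
    selected = order[: best + 1]
    report = reports[best]
    report.accuracy_curve = list(curve)
    report.selected_count = len(selected)
    return selected, report


def fuse_bands(tables: list) -> FeatureTable:
    """Column-wise concatenation of per-band feature tables.

    All tables must carry the same trials in the same order (labels are
    checked element-wise). Provenance is preserved per feature.
    """
    if not tables:
        raise ValueError("no tables to fuse")
    first = tables[0]
    for i, t in enumerate(tables[1:], start=2):
        if t.n_trials != first.n_trials:
            raise ValueError(
                f"table {i} has {t.n_trials} trials, expected {first.n_trials}"
            )
        if list(t.labels) != list(first.labels):
            raise ValueError(f"table {i} label sequence differs from table 1")
    return FeatureTable(
        matrix=np.hstack([t.matrix for t in tables]),
        labels=list(first.labels),
        feature_provenance=[p for t in tables for p in t.feature_provenance],
    )
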