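"""knn classification of MEM feature vectors with leave-one-session-out CV.

The classification task: given an element's entropy feature vector,
predict which time window (class = finest-level segment index) of the
eye-movement series it came from.  Windows whose dynamics differ from
the rest — above all the one containing the saccade — are the ones a
classifier can localise, so per-segment accuracy acts as an event
detector without any velocity threshold.

Cross-validation leaves one participant-session out: all maps of one
session form the test fold, everything else trains the classifier, one
fold per session.  knn uses Euclidean distance (features are same-scale
entropies, so no normalisation); ties are resolved deterministically —
neighbour ties by training-row order, vote ties by the smaller summed
neighbour distance, then by the lower class index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .errors import DataError
from .features import FeatureDataset
from .mem import MultilevelEntropyMap

__all__ = [
    "loso_split",
    "knn_classify",
    "evaluate",
    "run_loso",
    "run_grid",
    "n_classifier_runs",
    "overall_table",
    "best_segment_table",
    "per_segment_table",
    "compare_segments",
    "EvalReport",
    "SegmentComparison",
    "DEFAULT_K_GRID",
]

DEFAULT_K_GRID = (3, 7, 15, 31, 63, 127, 255)


def loso_split(
    dataset: FeatureDataset,
) -> Iterator[tuple[str, FeatureDataset, FeatureDataset]]:
    """Leave-one-participant-session-out folds.

    Yields ``(session_key, train, test)`` once per distinct
    participant-session, in sorted key order.
    """
    keys = sorted(set(dataset.groups.tolist()))
    if len(keys) < 2:
        raise DataError(
            "leave-one-session-out needs at least 2 participant-sessions"
        )
    for key in keys:
        mask = dataset.groups == key
        yield key, dataset.subset(np.flatnonzero(~mask)), dataset.subset(
            np.flatnonzero(mask)
        )


def n_classifier_runs(n_sessions: int, k_grid: Sequence[int] = DEFAULT_K_GRID) -> int:
    """Total classifier runs: one per fold per k value."""
    return len(k_grid) * n_sessions


def _knn_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, k: int
) -> np.ndarray:
    dist = cdist(X_test, X_train)
    # stable sort: equidistant neighbours resolved by training-row order
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    pred = np.empty(len(X_test), dtype=int)
    for i in range(len(X_test)):
        nbr = order[i]
        classes = y_train[nbr]
        d = dist[i, nbr]
        uniq, votes = np.unique(classes, return_counts=True)
        top = uniq[votes == votes.max()]
        if len(top) == 1:
            pred[i] = top[0]
        else:
            sums = np.array([d[classes == c].sum() for c in top])
            # vote tie: smaller summed distance, then lower class index
            pred[i] = int(top[np.lexsort((top, sums))[0]])
    return pred


def knn_classify(
    train: FeatureDataset, test: FeatureDataset, k: int
) -> np.ndarray:
    """Predict test labels by majority vote of the k Euclidean-nearest
    training rows."""
    if k < 1 or k > len(train):
        raise DataError(f"k={k} must be in 1..{len(train)} (training rows)")
    if train.X.shape[1] != test.X.shape[1]:
        raise DataError("train/test feature dimensions differ")
    return _knn_predict(train.X, train.y, test.X, k)


@dataclass
class EvalReport:
    """Classification metrics for one feature set and one k.

    ``per_segment_accuracy`` is indexed by class label and averaged over
    folds; ``confusion`` pools counts over folds (rows = truth, columns
    = prediction, labeled by each class's sample range).  Sensitivity
    and specificity are one-vs-rest for ``designated_class`` (by default
    the best segment).
    """

    k: int
    overall_accuracy: float
    per_segment_accuracy: pd.Series
    confusion: pd.DataFrame
    best_segment: int
    designated_class: int
    sensitivity: float
    specificity: float
    n_folds: int
    class_ranges: dict[int, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "overall_accuracy": self.overall_accuracy,
            "per_segment_accuracy": {
                str(c): float(a) for c, a in self.per_segment_accuracy.items()
            },
            "best_segment": self.best_segment,
            "designated_class": self.designated_class,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_folds": self.n_folds,
            "class_ranges": {str(c): r for c, r in self.class_ranges.items()},
            "confusion": self.confusion.to_dict(),
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def evaluate(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    fold_ids: np.ndarray,
    labels: Sequence[int],
    class_ranges: Optional[dict[int, str]] = None,
    designated_class: Optional[int] = None,
    k: int = 0,
) -> EvalReport:
    """Compute overall/per-segment accuracy, confusion and one-vs-rest
    sensitivity/specificity from pooled fold predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    fold_ids = np.asarray(fold_ids)
    if not (len(y_true) == len(y_pred) == len(fold_ids)):
        raise DataError("prediction/truth/fold vectors must share length")
    labels = list(labels)
    ranges = class_ranges or {c: str(c) for c in labels}

    overall = float(np.mean(y_true == y_pred))

    folds = sorted(set(fold_ids.tolist()))
    per_class = np.full((len(folds), len(labels)), np.nan)
    for fi, f in enumerate(folds):
        in_fold = fold_ids == f
        for ci, c in enumerate(labels):
            m = in_fold & (y_true == c)
            if m.any():
                per_class[fi, ci] = np.mean(y_pred[m] == c)
    with np.errstate(invalid="ignore"):
        seg_acc = pd.Series(np.nanmean(per_class, axis=0), index=labels)

    names = [ranges[c] for c in labels]
    conf = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for c_true, c_pred in zip(y_true, y_pred):
        conf.loc[ranges[int(c_true)], ranges[int(c_pred)]] += 1

    best = int(seg_acc.idxmax())
    target = best if designated_class is None else int(designated_class)
    tp = int(np.sum((y_true == target) & (y_pred == target)))
    fn = int(np.sum((y_true == target) & (y_pred != target)))
    tn = int(np.sum((y_true != target) & (y_pred != target)))
    fp = int(np.sum((y_true != target) & (y_pred == target)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")

    return EvalReport(
        k=k,
        overall_accuracy=overall,
        per_segment_accuracy=seg_acc,
        confusion=conf,
        best_segment=best,
        designated_class=target,
        sensitivity=sens,
        specificity=spec,
        n_folds=len(folds),
        class_ranges=dict(ranges),
    )


def run_loso(
    dataset: FeatureDataset,
    k: int,
    designated_class: Optional[int] = None,
) -> EvalReport:
    """Full leave-one-session-out evaluation for one k."""
    y_true, y_pred, fold_ids = [], [], []
    for key, train, test in loso_split(dataset):
        pred = knn_classify(train, test, k)
        y_true.append(test.y)
        y_pred.append(pred)
        fold_ids.append(np.full(len(test), key, dtype=object))
    return evaluate(
        np.concatenate(y_true),
        np.concatenate(y_pred),
        np.concatenate(fold_ids),
        labels=range(1, dataset.n_classes + 1),
        class_ranges=dataset.class_ranges,
        designated_class=designated_class,
        k=k,
    )


def run_grid(
    dataset: FeatureDataset,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    designated_class: Optional[int] = None,
) -> dict[int, EvalReport]:
    """LOSO evaluation over a grid of k values."""
    return {
        k: run_loso(dataset, k, designated_class=designated_class)
        for k in k_grid
    }


def overall_table(reports_by_set: dict[str, dict[int, EvalReport]]) -> pd.DataFrame:
    """Overall accuracy per set (rows) and k (columns)."""
    rows = {
        name: {f"k{k}": rep.overall_accuracy for k, rep in reps.items()}
        for name, reps in reports_by_set.items()
    }
    return pd.DataFrame(rows).T


def best_segment_table(
    reports_by_set: dict[str, dict[int, EvalReport]]
) -> pd.DataFrame:
    """Best per-segment accuracy per set and k, with the winning window."""
    rows = {}
    for name, reps in reports_by_set.items():
        row: dict[str, object] = {}
        segs = []
        for k, rep in reps.items():
            row[f"k{k}"] = float(rep.per_segment_accuracy.max())
            segs.append(rep.class_ranges[rep.best_segment])
        row["segment"] = max(set(segs), key=segs.count)
        rows[name] = row
    df = pd.DataFrame(rows).T
    cols = ["segment"] + [c for c in df.columns if c != "segment"]
    return df[cols]


def per_segment_table(reports: dict[int, EvalReport]) -> pd.DataFrame:
    """Per-segment accuracy (rows = sample ranges) per k for one set."""
    out = {}
    for k, rep in reports.items():
        out[f"k{k}"] = pd.Series(
            rep.per_segment_accuracy.values,
            index=[rep.class_ranges[c] for c in rep.per_segment_accuracy.index],
        )
    return pd.DataFrame(out)


@dataclass
class SegmentComparison:
    """One-way ANOVA across segment positions plus Tukey HSD pairs."""

    level: int
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # columns: segment_a, segment_b, diff, p_adj, low, high, reject


def compare_segments(
    maps: Sequence[MultilevelEntropyMap],
    level: int,
    alpha: float = 0.05,
) -> SegmentComparison:
    """Do segment positions at one level differ in mean entropy?

    Observations are the per-map cell values; the one-way ANOVA tests
    equality of segment means and Tukey's HSD locates the differing
    pairs at family-wise level ``alpha``.
    """
    if len(maps) < 2:
        raise DataError("need at least 2 maps to compare segments")
    spec = maps[0].spec
    if any(m.spec != spec for m in maps):
        raise DataError("all maps must share one MemSpec")
    nseg = spec.n_segments(level)
    if nseg < 2:
        raise DataError(f"level {level} has a single segment; nothing to compare")
    samples = [
        np.array([m.values[level - 1][s] for m in maps]) for s in range(nseg)
    ]
    f_stat, p_val = stats.f_oneway(*samples)
    res = stats.tukey_hsd(*samples)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    rows = []
    for a in range(nseg):
        for b in range(a + 1, nseg):
            rows.append(
                {
                    "segment_a": a + 1,
                    "segment_b": b + 1,
                    "diff": float(res.statistic[a, b]),
                    "p_adj": float(res.pvalue[a, b]),
                    "ci_low": float(ci.low[a, b]),
                    "ci_high": float(ci.high[a, b]),
                    "reject": bool(res.pvalue[a, b] < alpha),
                }
            )
    return SegmentComparison(
        level=level,
        anova_f=float(f_stat),
        anova_p=float(p_val),
        tukey=pd.DataFrame(rows),
    )
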