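"""10-fold cross-validation, confusion matrices and percentage metrics.

The evaluation protocol splits the image set randomly into k folds, trains a
fresh model on k-1 of them and tests on the held-out fold, rotating until
every item has been tested once.  The default split is image-level, matching
the protocol the reported results use: segments of one subject can appear in
both train and test, which leaks subject identity (amplitude scale, beat
morphology) and inflates accuracy.  A subject-level grouping that never
splits a subject across folds is available and recommended for honest
generalization estimates; the difference between the two is measurable on
synthetic cohorts with subject-specific amplitude scales.

The hypertensive class (HPT) is the positive class in per-class reporting;
macro averages over both classes are the headline numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .convmixer import ConvMixerClassifier

__all__ = [
    "FoldPlan",
    "ConfusionCounts",
    "MetricsReport",
    "kfold_split",
    "confusion_matrix",
    "metrics",
    "cross_validate",
    "CVResult",
]

_POSITIVE = "HPT"
_NEGATIVE = "NRT"


@dataclass
class FoldPlan:
    """Assignment of every item to exactly one of k folds."""

    k: int
    assignment: np.ndarray  # fold id per item, values in [0, k)
    grouping: str  # "image_level" | "subject_level"
    seed: int

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if set(np.unique(self.assignment)) - set(range(self.k)):
            raise ValueError("fold ids must lie in [0, k)")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"item": np.arange(self.assignment.size), "fold": self.assignment})


def kfold_split(
    n_items: int,
    k: int = 10,
    seed: int = 0,
    groups: Optional[Sequence] = None,
) -> FoldPlan:
    """Random k-fold partition; deterministic per seed.

    Without ``groups``: shuffled image-level folds with sizes differing by at
    most one.  With ``groups`` (subject ids per item): subjects are shuffled
    and distributed across folds so no subject is ever split between folds.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n_items:
        raise ValueError(f"cannot make {k} folds out of {n_items} items")
    if groups is None:
        assignment = np.empty(n_items, dtype=int)
        for fold, (_, test) in enumerate(
            KFold(n_splits=k, shuffle=True, random_state=seed).split(np.arange(n_items))
        ):
            assignment[test] = fold
        return FoldPlan(k=k, assignment=assignment, grouping="image_level", seed=seed)
    groups = np.asarray(groups)
    if groups.size != n_items:
        raise ValueError("groups must give one subject id per item")
    uniq = pd.unique(groups)
    if k > uniq.size:
        raise ValueError(f"cannot make {k} folds out of {uniq.size} subjects")
    order = np.random.default_rng(seed).permutation(uniq.size)
    fold_of_subject = {}
    for pos, subject_pos in enumerate(order):
        fold_of_subject[uniq[subject_pos]] = pos % k
    assignment = np.array([fold_of_subject[g] for g in groups], dtype=int)
    return FoldPlan(k=k, assignment=assignment, grouping="subject_level", seed=seed)


@dataclass
class ConfusionCounts:
    """Binary confusion counts with HPT as the positive class."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            tn=self.tn + other.tn,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.tp, self.fn], [self.fp, self.tn]],
            index=pd.Index([_POSITIVE, _NEGATIVE], name="true"),
            columns=pd.Index([_POSITIVE, _NEGATIVE], name="predicted"),
        )


def _as_label_str(values) -> np.ndarray:
    out = np.array([getattr(v, "value", v) for v in values], dtype=object)
    bad = set(out) - {_POSITIVE, _NEGATIVE}
    if bad:
        raise ValueError(f"unknown label values {sorted(map(str, bad))}; expected HPT/NRT")
    return out


def confusion_matrix(y_true, y_pred) -> ConfusionCounts:
    """Binary confusion counts over HPT/NRT label sequences."""
    yt, yp = _as_label_str(y_true), _as_label_str(y_pred)
    if yt.size != yp.size or yt.size < 1:
        raise ValueError("y_true and y_pred must have equal, non-zero length")
    pos_t, pos_p = yt == _POSITIVE, yp == _POSITIVE
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


@dataclass
class MetricsReport:
    """Accuracy / precision / recall / F1 in percent, per class and macro."""

    accuracy: float
    precision_hpt: float
    recall_hpt: float
    f1_hpt: float
    precision_nrt: float
    recall_nrt: float
    f1_nrt: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    degenerate: bool = False  # a zero-denominator ratio was reported as 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def __str__(self) -> str:
        return (
            f"accuracy {self.accuracy:.2f}%  "
            f"precision {self.precision_macro:.2f}%  "
            f"recall {self.recall_macro:.2f}%  "
            f"F1 {self.f1_macro:.2f}%"
        )


def _safe_ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def metrics(conf: ConfusionCounts) -> MetricsReport:
    """Percentage metrics from confusion counts.

    Per-class precision/recall/F1 for both classes plus macro averages;
    undefined ratios (zero denominators) are reported as 0 with the
    ``degenerate`` flag set and a warning.
    """
    n = conf.total
    if n <= 0:
        raise ValueError("metrics need at least one evaluated item")
    degenerate = False
    p_h, d1 = _safe_ratio(conf.tp, conf.tp + conf.fp)
    r_h, d2 = _safe_ratio(conf.tp, conf.tp + conf.fn)
    f_h, d3 = _safe_ratio(2 * p_h * r_h, p_h + r_h)
    p_n, d4 = _safe_ratio(conf.tn, conf.tn + conf.fn)
    r_n, d5 = _safe_ratio(conf.tn, conf.tn + conf.fp)
    f_n, d6 = _safe_ratio(2 * p_n * r_n, p_n + r_n)
    degenerate = any((d1, d2, d3, d4, d5, d6))
    if degenerate:
        warnings.warn("zero-denominator metric reported as 0", RuntimeWarning, stacklevel=2)
    acc = (conf.tp + conf.tn) / n
    return MetricsReport(
        accuracy=100.0 * acc,
        precision_hpt=100.0 * p_h,
        recall_hpt=100.0 * r_h,
        f1_hpt=100.0 * f_h,
        precision_nrt=100.0 * p_n,
        recall_nrt=100.0 * r_n,
        f1_nrt=100.0 * f_n,
        precision_macro=100.0 * (p_h + p_n) / 2,
        recall_macro=100.0 * (r_h + r_n) / 2,
        f1_macro=100.0 * (f_h + f_n) / 2,
        degenerate=degenerate,
    )


def mean_report(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of per-fold metrics (the 'average k-fold CV' table)."""
    if not reports:
        raise ValueError("no reports to average")
    fields = [f for f in MetricsReport.__dataclass_fields__ if f != "degenerate"]
    vals = {f: float(np.mean([getattr(r, f) for r in reports])) for f in fields}
    return MetricsReport(**vals, degenerate=any(r.degenerate for r in reports))


@dataclass
class CVResult:
    per_fold: list[MetricsReport]
    fold_confusions: list[ConfusionCounts]
    cumulative: ConfusionCounts
    mean: MetricsReport
    histories: list[pd.DataFrame] = field(default_factory=list)

    def per_fold_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.to_dict() for r in self.per_fold])
        df.insert(0, "fold", np.arange(len(self.per_fold)))
        return df


def cross_validate(
    images: np.ndarray,
    labels: Sequence,
    fold_plan: FoldPlan,
    model_params: Optional[dict] = None,
    keep_histories: bool = False,
) -> CVResult:
    """Train and test a fresh ConvMixer per fold.

    ``labels`` are HPT/NRT values aligned with ``images`` (N, H, W, C).
    Returns per-fold metrics, per-fold and cumulative (element-wise summed)
    confusion counts, and the arithmetic mean of the per-fold metrics.
    """
    y = _as_label_str(labels)
    if images.shape[0] != y.size or y.size == 0:
        raise ValueError("images and labels must align and be non-empty")
    model_params = dict(model_params or {})
    per_fold, confusions, histories = [], [], []
    for fold in range(fold_plan.k):
        tr, te = fold_plan.train_indices(fold), fold_plan.test_indices(fold)
        if np.unique(y[tr]).size < 2:
            raise ValueError(f"fold {fold}: training split contains a single class")
        clf = ConvMixerClassifier(**model_params)
        clf.fit(images[tr], y[tr])
        pred = clf.predict(images[te])
        conf = confusion_matrix(y[te], pred)
        confusions.append(conf)
        per_fold.append(metrics(conf))
        if keep_histories:
            histories.append(clf.history_)
    cumulative = sum(confusions[1:], confusions[0])
    return CVResult(
        per_fold=per_fold,
        fold_confusions=confusions,
        cumulative=cumulative,
        mean=mean_report(per_fold),
        histories=histories,
    )
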