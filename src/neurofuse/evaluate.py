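"""Split protocol and classification metrics.

The evaluation protocol holds out 10% of patients as an external test set,
then partitions the remaining 90% into ten folds for internal
cross-validation: each fold plays validation (9% of the total) once while
the other nine folds train (81% of the total). Splits are stratified by
class by default and reproducible from (labels, seed) alone.

Metrics: accuracy, macro-averaged precision and recall, and meanF1 — the
unweighted mean of per-class F1 scores. Fold-level metrics aggregate as
mean ± standard deviation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

METRIC_KEYS = ("accuracy", "precision", "recall", "mean_f1")


@dataclass
class SplitPlan:
    external_ids: list
    folds: list          # list of id lists; disjoint, covering the non-external ids
    seed: int
    stratified: bool

    def __post_init__(self):
        ext = set(self.external_ids)
        seen = set()
        for fold in self.folds:
            fold_set = set(fold)
            if fold_set & ext:
                raise ValueError("folds overlap the external test set")
            if fold_set & seen:
                raise ValueError("folds are not disjoint")
            seen |= fold_set

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def internal_ids(self) -> list:
        return [i for fold in self.folds for i in fold]

    def fold_split(self, f: int) -> tuple[list, list]:
        """(train_ids, validation_ids) for fold ``f``: train = other folds."""
        val = list(self.folds[f])
        train = [i for g, fold in enumerate(self.folds) if g != f for i in fold]
        return train, val


def make_splits(labels, seed: int, n_folds: int = 10,
                external_fraction: float = 0.10, stratify: bool = True) -> SplitPlan:
    """Build the external-holdout + k-fold internal plan.

    ``labels`` may be a pandas Series (ids from the index) or an array
    (positional ids). Classes with fewer than ``n_folds`` members degrade
    stratification to plain shuffling with a warning.
    """
    if isinstance(labels, pd.Series):
        ids = list(labels.index)
        y = labels.to_numpy()
    else:
        y = np.asarray(labels)
        ids = list(range(len(y)))
    n = len(ids)
    if n < 20:
        raise ValueError("need at least 20 patients to build the split plan")

    counts = pd.Series(y).value_counts()
    can_stratify = bool(stratify and counts.min() >= n_folds)
    if stratify and not can_stratify:
        warnings.warn(
            f"class with only {int(counts.min())} members: stratification degraded "
            "to plain shuffling"
        )

    idx = np.arange(n)
    internal, external = train_test_split(
        idx, test_size=external_fraction, random_state=seed,
        stratify=y if can_stratify else None, shuffle=True,
    )
    splitter = (
        StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        if can_stratify
        else KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    )
    folds = [
        [ids[internal[j]] for j in val]
        for _, val in splitter.split(internal, y[internal])
    ]
    return SplitPlan(
        external_ids=[ids[j] for j in external], folds=folds,
        seed=seed, stratified=can_stratify,
    )


def metrics(y_true, y_pred, n_classes: int | None = None, class_labels=None) -> dict:
    """Accuracy, macro precision/recall and meanF1 for one prediction set.

    Classes absent from ``y_true`` still enter the macro averages with
    F1 = 0 (a warning is emitted), so models are not rewarded for never
    predicting a rare class.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if class_labels is None:
        if n_classes is not None and np.issubdtype(y_true.dtype, np.integer):
            class_labels = np.arange(n_classes)
        else:
            class_labels = np.unique(np.concatenate([y_true, y_pred]))
    class_labels = np.asarray(class_labels)
    absent = [c for c in class_labels if c not in y_true]
    if absent:
        warnings.warn(f"classes {absent} absent from y_true contribute F1 = 0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn's own zero-division chatter
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=class_labels, zero_division=0
        )
    return {
        "accuracy": float(np.mean(y_true == y_pred)),
        "precision": float(prec.mean()),
        "recall": float(rec.mean()),
        "mean_f1": float(f1.mean()),
    }


@dataclass
class EvalReport:
    """Per-fold and aggregate metrics plus the external-test row."""

    per_fold: list = field(default_factory=list)
    external: dict | None = None

    def add_fold(self, row: dict):
        self.per_fold.append({k: float(row[k]) for k in METRIC_KEYS})

    def aggregate(self) -> dict:
        if not self.per_fold:
            raise ValueError("no folds recorded")
        tab = pd.DataFrame(self.per_fold)
        return {
            k: {"mean": float(tab[k].mean()), "std": float(tab[k].std(ddof=0))}
            for k in METRIC_KEYS
        }

    def formatted(self) -> dict:
        """Human-readable 'mean ± std' strings, e.g. '0.78 ± 0.03'."""
        return {
            k: f"{v['mean']:.2f} ± {v['std']:.2f}"
            for k, v in self.aggregate().items()
        }

    def to_dict(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "aggregate": self.aggregate(),
            "formatted": self.formatted(),
            "external": self.external,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
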