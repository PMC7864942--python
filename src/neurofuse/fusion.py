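"""Multimodal fusion strategies and the shallow decision layer.

Three ways to combine clinical, genetic and imaging information:

* feature-level — concatenate raw/handcrafted features and train one
  shallow classifier;
* intermediate-feature-level — concatenate the learned per-modality
  representations (the deep route) before the decision layer;
* decision-level — majority vote over independent per-modality classifiers.

A patient missing a modality has that block zero-masked rather than being
dropped, so partially observed patients remain classifiable. The block
order is fixed at [EHR | SNP | imaging].

Classification tasks depend on the modality combination: any combination
containing EHR is staged three ways (CN / MCI / AD); SNP without EHR
separates CN from MCI-or-AD; imaging alone separates CN from AD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .simulate import CLASSES

BLOCK_ORDER = ("ehr", "snp", "imaging")

#: decision-layer defaults: 31 trees for deep intermediate fusion,
#: 20 for the SNP+imaging shallow combination
DEEP_FUSION_TREES = 31
SNP_IMAGING_TREES = 20


@dataclass
class ClassifierSpec:
    """Decision-layer choice: kind plus kind-appropriate hyperparameters."""

    kind: str = "random_forest"
    params: dict = field(default_factory=dict)

    _ALLOWED = {
        "knn": {"k"},
        "svm_ovo": {"kernel", "C"},
        "random_forest": {"n_trees", "depth"},
        "decision_tree": {"depth"},
    }

    def __post_init__(self):
        if self.kind not in self._ALLOWED:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        extra = set(self.params) - self._ALLOWED[self.kind]
        if extra:
            raise ValueError(f"params {sorted(extra)} not valid for kind {self.kind!r}")


def make_decision_layer(spec: ClassifierSpec, seed: int = 0):
    """Instantiate the shallow classifier for a spec (unfitted)."""
    p = spec.params
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=p.get("k", 5))
    if spec.kind == "svm_ovo":
        # SVC uses one-vs-one coding for multiclass problems natively
        return SVC(kernel=p.get("kernel", "rbf"), C=p.get("C", 1.0),
                   decision_function_shape="ovo", probability=True,
                   random_state=seed)
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=p.get("n_trees", DEEP_FUSION_TREES),
            max_depth=p.get("depth"), random_state=seed)
    if spec.kind == "decision_tree":
        return DecisionTreeClassifier(max_depth=p.get("depth"), random_state=seed)
    raise ValueError(spec.kind)


def fit_decision_layer(fused, labels, spec: ClassifierSpec, seed: int = 0):
    """Fit the decision layer; deterministic given the seed."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes to fit the decision layer")
    clf = make_decision_layer(spec, seed)
    return clf.fit(np.asarray(fused), labels)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def _fuse_blocks(blocks: dict, names: dict, mask) -> tuple[np.ndarray, list[str]]:
    mask = pd.DataFrame(mask)
    n = len(mask)
    parts, provenance = [], []
    for mod in BLOCK_ORDER:
        if mod not in blocks:
            continue
        arr = np.asarray(blocks[mod], dtype=float)
        if arr.shape[0] != n:
            raise ValueError(
                f"{mod} block has {arr.shape[0]} rows, mask has {n} patients"
            )
        avail = mask[mod].to_numpy(dtype=bool)
        arr = np.where(avail[:, None], arr, 0.0)  # zero-mask missing modality
        parts.append(arr)
        provenance += [f"{mod}:{c}" for c in names[mod]]
    if not parts:
        raise ValueError("no modality blocks supplied")
    present = np.column_stack(
        [mask[m].to_numpy(dtype=bool) for m in BLOCK_ORDER if m in blocks]
    )
    orphans = ~present.any(axis=1)
    if orphans.any():
        raise ValueError(
            f"{int(orphans.sum())} patient(s) have no available modality; "
            "cannot classify an all-masked row"
        )
    return np.concatenate(parts, axis=1), provenance


def concat_intermediate(codes: dict, mask) -> tuple[np.ndarray, list[str]]:
    """Concatenate learned per-modality codes with zero-masking.

    ``codes`` maps modality -> (n_patients x width) array aligned with the
    mask's patient order (rows of unavailable patients are ignored and
    zeroed). Returns the fused matrix and column-provenance labels.
    """
    names = {m: [str(j) for j in range(np.asarray(a).shape[1])] for m, a in codes.items()}
    return _fuse_blocks(codes, names, mask)


def feature_level_fuse(blocks: dict, mask) -> tuple[np.ndarray, list[str]]:
    """Directly concatenate raw/handcrafted feature tables (shallow route).

    ``blocks`` maps modality -> DataFrame (named columns) or array; column
    provenance labels round-trip to the origin feature names.
    """
    arrays, names = {}, {}
    for mod, table in blocks.items():
        if isinstance(table, pd.DataFrame):
            arrays[mod] = table.to_numpy(dtype=float)
            names[mod] = [str(c) for c in table.columns]
        else:
            arr = np.asarray(table, dtype=float)
            arrays[mod] = arr
            names[mod] = [str(j) for j in range(arr.shape[1])]
    return _fuse_blocks(arrays, names, mask)


def decision_level_vote(predictions: dict, probabilities: dict | None = None,
                        class_order=CLASSES) -> np.ndarray:
    """Majority vote over per-modality predicted labels.

    Ties are broken by the highest mean predicted class-probability among
    the tied classes (when ``probabilities`` maps modality ->
    {class: (n,) array} or (n, n_classes) DataFrame), then by the fixed
    class order CN < MCI < AD.
    """
    mods = list(predictions)
    if len(mods) < 2:
        raise ValueError("decision-level voting needs >= 2 modality predictions")
    preds = np.column_stack([np.asarray(predictions[m], dtype=object) for m in mods])
    n = preds.shape[0]
    out = np.empty(n, dtype=object)
    order_idx = {c: i for i, c in enumerate(class_order)}
    for i in range(n):
        votes = pd.Series(preds[i]).value_counts()
        top = votes[votes == votes.max()].index.tolist()
        if len(top) == 1:
            out[i] = top[0]
            continue
        if probabilities:
            mean_p = {}
            for c in top:
                vals = []
                for m in mods:
                    tab = probabilities.get(m)
                    if tab is not None and c in tab:
                        vals.append(float(np.asarray(tab[c])[i]))
                mean_p[c] = np.mean(vals) if vals else -1.0
            best = max(mean_p.values())
            top = [c for c in top if mean_p[c] == best]
        out[i] = min(top, key=lambda c: order_idx.get(c, len(order_idx)))
    return out


# ---------------------------------------------------------------------------
# Task table
# ---------------------------------------------------------------------------

#: classification scheme per modality combination (config-overridable)
TASK_TABLE = {
    frozenset({"ehr"}): "three_class",
    frozenset({"ehr", "snp"}): "three_class",
    frozenset({"ehr", "imaging"}): "three_class",
    frozenset({"ehr", "snp", "imaging"}): "three_class",
    frozenset({"snp"}): "cn_vs_mciad",
    frozenset({"snp", "imaging"}): "cn_vs_mciad",
    frozenset({"imaging"}): "cn_vs_ad",
}


def task_for(modalities) -> str:
    key = frozenset(modalities)
    if key not in TASK_TABLE:
        raise ValueError(f"no task defined for modalities {sorted(key)}")
    return TASK_TABLE[key]


def collapse_labels(labels, scheme: str):
    """Map CN/MCI/AD labels onto the task's class scheme.

    Returns (collapsed labels, keep mask); ``cn_vs_ad`` drops MCI patients.
    """
    labels = np.asarray(labels, dtype=object)
    if scheme == "three_class":
        return labels.copy(), np.ones(len(labels), dtype=bool)
    if scheme == "cn_vs_mciad":
        out = np.where(labels == "CN", "CN", "MCI/AD").astype(object)
        return out, np.ones(len(labels), dtype=bool)
    if scheme == "cn_vs_ad":
        keep = labels != "MCI"
        return labels.copy(), keep
    raise ValueError(f"unknown scheme {scheme!r}")
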