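"""Model interpretation: perturbation ranking and cluster comparison.

Feature importance is measured by masking one feature at a time — setting
that column to the mask value (0 in model input space, consistent with the
missing-modality zero-masking) for *every* patient in the evaluation set —
and recording the drop in accuracy relative to the unmasked baseline. The
feature with the largest drop ranks first; drops can be negative. Masking
is evaluated on held-out data, not the training set, so importance is not
understated for overfit models.

The cluster comparison runs k-means (fixed seed, 10 restarts) on a raw
representation and on the learned intermediate representation of the same
patients and reports the mean silhouette coefficient of each as the
separation score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


@dataclass
class FeatureRanking:
    """Ordered feature -> accuracy-drop table."""

    table: pd.DataFrame       # columns: feature, baseline, masked, drop
    evaluation_set: str = ""

    def top(self, k: int) -> list[str]:
        return self.table["feature"].head(k).tolist()

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "rank", np.arange(1, len(out) + 1))
        out.to_csv(path, sep="\t", index=False)


def perturb_rank(predictor, X, y, feature_names=None, mask_value: float = 0.0,
                 evaluation_set: str = "") -> FeatureRanking:
    """Mask-one-feature-at-a-time importance ranking.

    ``predictor`` must expose ``predict``; ``X``/``y`` should be an
    evaluation set disjoint from the data the predictor was trained on.
    Ties in the drop are broken by the original feature index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be 2D with at least one feature column")
    if feature_names is None:
        feature_names = [str(j) for j in range(X.shape[1])]
    if len(feature_names) != X.shape[1]:
        raise ValueError("feature_names length does not match X")

    baseline = float(np.mean(predictor.predict(X) == y))
    drops = np.empty(X.shape[1])
    masked_acc = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        Xm = X.copy()
        Xm[:, j] = mask_value
        masked_acc[j] = float(np.mean(predictor.predict(Xm) == y))
        drops[j] = baseline - masked_acc[j]

    order = np.lexsort((np.arange(X.shape[1]), -drops))  # drop desc, index asc
    table = pd.DataFrame({
        "feature": [feature_names[j] for j in order],
        "baseline": baseline,
        "masked": masked_acc[order],
        "drop": drops[order],
    })
    return FeatureRanking(table=table, evaluation_set=evaluation_set)


@dataclass
class ClusterComparison:
    k: int
    raw_assignments: np.ndarray
    intermediate_assignments: np.ndarray
    raw_silhouette: float
    intermediate_silhouette: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "raw_silhouette": self.raw_silhouette,
            "intermediate_silhouette": self.intermediate_silhouette,
        }


def cluster_compare(raw, intermediate, k: int, seed: int = 0,
                    n_restarts: int = 10) -> ClusterComparison:
    """k-means on raw vs intermediate representations of the same patients."""
    raw = np.asarray(raw, dtype=float)
    inter = np.asarray(intermediate, dtype=float)
    if raw.shape[0] != inter.shape[0]:
        raise ValueError("raw and intermediate must describe the same patients")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > raw.shape[0]:
        raise ValueError("k exceeds the number of patients")

    def run(X):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        score = silhouette_score(X, labels) if len(np.unique(labels)) > 1 else -1.0
        return labels, float(score)

    raw_lab, raw_sil = run(raw)
    int_lab, int_sil = run(inter)
    return ClusterComparison(
        k=k, raw_assignments=raw_lab, intermediate_assignments=int_lab,
        raw_silhouette=raw_sil, intermediate_silhouette=int_sil, seed=seed,
    )
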