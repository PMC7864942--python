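"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as literal loops over definitions — no shared
code with the package — so agreement is meaningful.
"""

from collections import Counter
from math import log2

import numpy as np


def mi_oracle(x, y) -> float:
    """Plug-in mutual information (bits) by literal probability tables."""
    n = len(x)
    cx, cy, cxy = Counter(), Counter(), Counter()
    for a, b in zip(x, y):
        cx[a] += 1
        cy[b] += 1
        cxy[(a, b)] += 1
    mi = 0.0
    for (a, b), c in cxy.items():
        pxy = c / n
        mi += pxy * log2(pxy / ((cx[a] / n) * (cy[b] / n)))
    return mi


def entropy_oracle(x) -> float:
    n = len(x)
    return -sum((c / n) * log2(c / n) for c in Counter(x).values())


def mrmr_oracle(X, y, k):
    """Exhaustive greedy: score every remaining candidate at every step."""
    X = np.asarray(X)
    p = X.shape[1]
    selected = []
    remaining = list(range(p))
    for _ in range(k):
        scores = []
        for j in remaining:
            rel = mi_oracle(X[:, j].tolist(), list(y))
            if selected:
                red = sum(mi_oracle(X[:, j].tolist(), X[:, s].tolist()) for s in selected)
                scores.append(rel - red / len(selected))
            else:
                scores.append(rel)
        # ties within float tolerance go to the smallest index
        best = max(scores)
        best_j = next(j for j, s in zip(remaining, scores) if s >= best - 1e-9)
        selected.append(best_j)
        remaining.remove(best_j)
    return selected


def confusion_metrics_oracle(y_true, y_pred, classes):
    """Accuracy and macro precision/recall/F1 from a literal confusion matrix."""
    classes = list(classes)
    conf = {(a, b): 0 for a in classes for b in classes}
    correct = 0
    for t, p in zip(y_true, y_pred):
        conf[(t, p)] += 1
        if t == p:
            correct += 1
    precs, recs, f1s = [], [], []
    for c in classes:
        tp = conf[(c, c)]
        fp = sum(conf[(o, c)] for o in classes if o != c)
        fn = sum(conf[(c, o)] for o in classes if o != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    n = len(y_true)
    return {
        "accuracy": correct / n,
        "precision": sum(precs) / len(classes),
        "recall": sum(recs) / len(classes),
        "mean_f1": sum(f1s) / len(classes),
    }


def hwe_oracle(n_homref, n_het, n_homalt) -> float:
    """Chi-square HWE p-value with expected counts written out explicitly."""
    from scipy.stats import chi2

    n = n_homref + n_het + n_homalt
    p = (2 * n_homref + n_het) / (2.0 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    e_rr, e_rq, e_qq = n * p * p, 2 * n * p * q, n * q * q
    stat = ((n_homref - e_rr) ** 2 / e_rr
            + (n_het - e_rq) ** 2 / e_rq
            + (n_homalt - e_qq) ** 2 / e_qq)
    return float(chi2.sf(stat, 1))


def glcm_oracle(levels, offset, n_levels):
    """Co-occurrence by enumerating every voxel pair, then symmetrize."""
    levels = np.asarray(levels)
    mat = np.zeros((n_levels, n_levels))
    d0, d1, d2 = offset
    s0, s1, s2 = levels.shape
    for i in range(s0):
        for j in range(s1):
            for k in range(s2):
                i2, j2, k2 = i + d0, j + d1, k + d2
                if 0 <= i2 < s0 and 0 <= j2 < s1 and 0 <= k2 < s2:
                    a, b = levels[i, j, k], levels[i2, j2, k2]
                    mat[a, b] += 1
                    mat[b, a] += 1
    total = mat.sum()
    return mat / total if total else mat


def glcm_contrast_oracle(p):
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            total += p[i, j] * (i - j) ** 2
    return total


def perturb_rank_oracle(predictor, X, y, mask_value=0.0):
    """Literal one-feature-at-a-time masking loop; returns per-feature drops."""
    X = np.asarray(X, dtype=float)
    baseline = sum(int(a == b) for a, b in zip(predictor.predict(X), y)) / len(y)
    drops = []
    for j in range(X.shape[1]):
        Xm = np.array([[mask_value if c == j else X[r, c] for c in range(X.shape[1])]
                       for r in range(X.shape[0])])
        acc = sum(int(a == b) for a, b in zip(predictor.predict(Xm), y)) / len(y)
        drops.append(baseline - acc)
    return baseline, drops
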