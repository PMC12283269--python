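"""Independent reference implementations used to cross-check the package."""

import math

import numpy as np

from pascl.models import cosine_similarity


def brute_force_scl(Z, y, t, variant="printed"):
    """Triple-loop evaluation of the supervised contrastive loss."""
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y)
    M = len(y)
    total = 0.0
    for i in range(M):
        m_yi = sum(1 for j in range(M) if y[j] == y[i])
        if m_yi < 2:
            continue
        for j in range(M):
            if j == i or y[j] != y[i]:
                continue
            s_ij = cosine_similarity(Z[i], Z[j])
            if variant == "printed":
                denom = math.exp(s_ij / t) + sum(
                    math.exp(cosine_similarity(Z[i], Z[k]) / t)
                    for k in range(M)
                    if y[k] != y[i]
                )
            else:
                denom = sum(
                    math.exp(cosine_similarity(Z[i], Z[k]) / t)
                    for k in range(M)
                    if k != i
                )
            total -= (1.0 / (m_yi - 1)) * math.log(math.exp(s_ij / t) / denom)
    return total


def trapezoid_auc(scores, labels):
    """AUC by trapezoidal integration of the empirical ROC curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    thresholds = np.unique(scores)[::-1]
    pos = (labels == 1).sum()
    neg = (labels == 0).sum()
    tpr = [0.0]
    fpr = [0.0]
    for th in thresholds:
        pred = scores >= th
        tpr.append(((pred) & (labels == 1)).sum() / pos)
        fpr.append(((pred) & (labels == 0)).sum() / neg)
    return float(np.trapezoid(tpr, fpr))


def brute_force_silhouette(points, labels):
    """Pointwise silhouette via explicit pairwise distances."""
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels)
    n = len(y)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if y[j] == y[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(x[i] - x[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(x[i] - x[j]) for j in range(n) if y[j] == c])
            for c in np.unique(y)
            if c != y[i]
        )
        m = max(a, b)
        vals.append(0.0 if m == 0 else (b - a) / m)
    return float(np.mean(vals))
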