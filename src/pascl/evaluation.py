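"""Classification metrics, subsampled evaluation, model comparison, silhouette.

The aggregate "score" is the arithmetic mean of five indicators computed on
the binary confusion counts and rank statistics:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)            (positive predictive value)
    recall      = TP / (TP + FN)            (sensitivity)
    specificity = TN / (TN + FP)
    AUC         = #{(p_i, n_j) : p_i > n_j} / (P * N)   (ties credited 0.5)

Zero-denominator metrics are reported as 0 with a ``degenerate`` flag, which
matches how an all-negative classifier is conventionally tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion_counts",
    "classification_metrics",
    "auc_rank",
    "score",
    "metric_set_from",
    "subsample_evaluate",
    "compare_models",
    "silhouette",
    "export_embedding_plot",
    "umap_embed",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The five indicators and their mean."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    auc: float
    degenerate: tuple[str, ...] = ()

    @property
    def score(self) -> float:
        return (
            self.accuracy + self.precision + self.recall + self.specificity + self.auc
        ) / 5.0

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "auc": self.auc,
            "score": self.score,
        }


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _ratio(num: int, den: int, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def classification_metrics(counts: ConfusionCounts) -> dict[str, float | tuple]:
    """Accuracy, precision, recall and specificity from confusion counts."""
    flags: list[str] = []
    out = {
        "accuracy": _ratio(counts.tp + counts.tn, counts.total, "accuracy", flags),
        "precision": _ratio(counts.tp, counts.tp + counts.fp, "precision", flags),
        "recall": _ratio(counts.tp, counts.tp + counts.fn, "recall", flags),
        "specificity": _ratio(counts.tn, counts.tn + counts.fp, "specificity", flags),
    }
    out["degenerate"] = tuple(flags)
    return out


def auc_rank(scores: np.ndarray, labels: np.ndarray, ties: str = "half") -> float:
    """Pairwise-rank AUC: fraction of positive-negative pairs ranked correctly.

    ``ties="half"`` credits tied pairs 0.5 (so an uninformative scorer gets
    0.5); ``ties="strict"`` counts only strict inequalities.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC requires at least one positive and one negative")
    diff = pos[:, None] - neg[None, :]
    wins = (diff > 0).sum()
    if ties == "half":
        wins = wins + 0.5 * (diff == 0).sum()
    elif ties != "strict":
        raise ValueError("ties must be 'half' or 'strict'")
    return float(wins / (pos.size * neg.size))


def score(metrics: dict[str, float] | MetricSet) -> float:
    """Arithmetic mean of the five indicators."""
    if isinstance(metrics, MetricSet):
        return metrics.score
    keys = ("accuracy", "precision", "recall", "specificity", "auc")
    missing = [k for k in keys if k not in metrics]
    if missing:
        raise ValueError(f"missing metric(s): {missing}")
    return float(sum(metrics[k] for k in keys) / 5.0)


def metric_set_from(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None
) -> MetricSet:
    """Assemble a MetricSet from labels, hard predictions and rank scores."""
    base = classification_metrics(confusion_counts(y_true, y_pred))
    flags = list(base.pop("degenerate"))
    if scores is not None and np.unique(np.asarray(y_true).astype(int)).size == 2:
        auc = auc_rank(scores, y_true)
    else:
        auc = 0.0
        flags.append("auc")
    return MetricSet(auc=auc, degenerate=tuple(flags), **base)


def subsample_evaluate(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray,
    fractions: np.ndarray | None = None,
    reps: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate on random test subsets of 10%..100%, averaged over reps.

    Returns ``(per_rep, per_fraction_mean)`` tables. Subsets are stratified
    where possible; a rep whose subset lacks one class is flagged and its
    AUC omitted from the averages.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    scores = np.asarray(scores, dtype=float)
    n = y_true.size
    if n == 0:
        raise ValueError("test set is empty")
    if fractions is None:
        fractions = np.round(np.arange(0.1, 1.001, 0.1), 2)
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        m = max(1, int(round(frac * n)))
        for rep in range(reps):
            if stratified and np.unique(y_true).size == 2 and m >= 2:
                idx = _stratified_subset(y_true, m, rng)
            else:
                idx = rng.choice(n, size=m, replace=False)
            ms = metric_set_from(y_true[idx], y_pred[idx], scores[idx])
            row = {"fraction": float(frac), "rep": rep, "n": m, **ms.as_dict()}
            if "auc" in ms.degenerate:
                row["auc"] = np.nan
                row["score"] = np.nan
            rows.append(row)
    per_rep = pd.DataFrame(rows)
    mean = per_rep.groupby("fraction", as_index=False)[
        ["accuracy", "precision", "recall", "specificity", "auc", "score"]
    ].mean()
    return per_rep, mean


def _stratified_subset(y: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    m1 = int(round(m * idx1.size / y.size))
    m1 = min(max(m1, 1), min(idx1.size, m - 1))
    m0 = min(m - m1, idx0.size)
    pick = np.concatenate(
        [
            rng.choice(idx0, size=m0, replace=False),
            rng.choice(idx1, size=m1, replace=False),
        ]
    )
    return np.sort(pick)


def compare_models(
    values_a: np.ndarray, values_b: np.ndarray, paired: bool = False
) -> tuple[float, float]:
    """Student's t comparison of per-rep metric vectors.

    Unpaired mode uses the unequal-variance (Welch) two-sided test; paired
    mode is available when the reps share subsample draws. Two identical
    constant vectors give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per side")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float("inf") * np.sign(np.mean(a) - np.mean(b)), 0.0
    if paired:
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient with Euclidean distances.

    s_i = (b_i - a_i) / max(a_i, b_i); points in singleton clusters and
    coincident-cluster points (a = b = 0) contribute 0.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("silhouette requires at least two clusters")
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=-1))
    n = x.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = y == y[i]
        n_own = own.sum()
        if n_own == 1:
            continue  # singleton cluster contributes 0
        a = d[i, own].sum() / (n_own - 1)
        b = min(d[i, y == c].mean() for c in classes if c != y[i])
        m = max(a, b)
        s[i] = 0.0 if m == 0.0 else (b - a) / m
    return float(s.mean())


def export_embedding_plot(
    points: np.ndarray,
    labels: np.ndarray,
    path,
    decision_boundary: bool = True,
) -> None:
    """Scatter plot of 2-d final-layer outputs with the y = x decision line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(points, dtype=float)
    if x.size == 0:
        raise ValueError("no points to plot")
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("embedding points must be 2-dimensional")
    y = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 5))
    for cls, color, name in ((0, "tab:blue", "normal"), (1, "tab:orange", "tumor")):
        m = y == cls
        ax.scatter(x[m, 0], x[m, 1], c=color, label=name, s=18, alpha=0.8)
    if decision_boundary:
        lo = float(min(x.min(), 0.0))
        hi = float(x.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=1, label="y = x")
    ax.set_xlabel("output unit 0 (normal)")
    ax.set_ylabel("output unit 1 (tumor)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def umap_embed(x: np.ndarray, seed: int = 42, **kwargs) -> np.ndarray:
    """Thin wrapper over umap-learn for 2-d visualisation of spectra."""
    import umap

    x = np.asarray(x, dtype=float).reshape(len(x), -1)
    reducer = umap.UMAP(n_components=2, random_state=seed, **kwargs)
    return reducer.fit_transform(x)
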