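"""Noise-injection robustness benchmark and cross-system transfer analysis.

Noise is added to the preprocessed spectrum matrices the models consume,
only at evaluation time. Uniform noise draws each element from
U(-r*A, +r*A) where A is the per-sample peak magnitude (max |element|) and
r the ratio parameter; Gaussian noise is N(0, sigma^2) with sigma in the
spectra's own (dB) units. The benchmark first evaluates the model clean,
keeps only the correctly classified test samples, replicates each of them
``replicates`` times with independent noise, and reports the fraction still
classified correctly together with the noisy final-layer embeddings and two
silhouettes: one over the clean-correct subset (matching the accuracy
analysis) and one over every test sample (pure embedding geometry, free of
the selection the accuracy filter introduces).

"Transfer" follows the study's protocol: the same modelling procedure is
run independently per acquisition system and the relative score drop
100 * (score_1 - score_2) / score_1 is the transfer decline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import evaluation

__all__ = [
    "NoiseSpec",
    "RobustnessResult",
    "TransferReport",
    "add_noise",
    "robustness_eval",
    "noise_sweep",
    "transfer_decline",
]

#: default evaluation grids, spanning gentle to destructive perturbations
DEFAULT_UNIFORM_GRID = (0.02, 0.05, 0.1, 0.2)
DEFAULT_GAUSSIAN_GRID = (0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class NoiseSpec:
    """One noise condition of the robustness benchmark."""

    kind: str  # "uniform" | "gaussian"
    param: float  # ratio r (uniform) or sigma in dB (gaussian)
    replicates: int = 10
    seed: int = 0
    amplitude_mode: str = "per_sample_max"  # | "per_element" | "global_max"

    def validate(self) -> None:
        if self.kind not in ("uniform", "gaussian"):
            raise ValueError("noise kind must be 'uniform' or 'gaussian'")
        if self.param < 0:
            raise ValueError("noise parameter must be nonnegative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.amplitude_mode not in ("per_sample_max", "per_element", "global_max"):
            raise ValueError("unknown amplitude mode")


def add_noise(
    matrices: np.ndarray, spec: NoiseSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Perturbed copies of spectrum matrices; deterministic per spec.seed."""
    spec.validate()
    x = np.asarray(matrices, dtype=float)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.param == 0.0:
        return x.copy()
    if spec.kind == "gaussian":
        return x + rng.normal(0.0, spec.param, size=x.shape)
    sample_axes = tuple(range(1, x.ndim)) if x.ndim > 2 else None
    if spec.amplitude_mode == "per_element":
        amp = np.abs(x)
    elif spec.amplitude_mode == "global_max":
        amp = np.abs(x).max()
    elif sample_axes is not None:
        amp = np.abs(x).max(axis=sample_axes, keepdims=True)
    else:
        amp = np.abs(x).max()
    return x + rng.uniform(-1.0, 1.0, size=x.shape) * spec.param * amp


@dataclass
class RobustnessResult:
    accuracy_under_noise: float  # on the clean-correct subset
    silhouette: float  # of the clean-correct noisy embeddings
    silhouette_all: float  # of all noisy test embeddings (no selection)
    embeddings: np.ndarray  # (n * replicates, 2), all test samples
    labels: np.ndarray
    n_clean_correct: int


def robustness_eval(
    result, spectra: np.ndarray, labels: np.ndarray, spec: NoiseSpec
) -> RobustnessResult:
    """Accuracy under noise on the clean-correct subset of a test set.

    ``result`` is a trained model wrapper exposing ``predict(spectra)``
    (e.g. ``training.TrainResult``). Only samples the model classifies
    correctly without noise are retained, so accuracy at zero noise is 1
    by construction.
    """
    spec.validate()
    labels = np.asarray(labels).astype(int)
    x = np.asarray(spectra, dtype=float)
    pred_clean, _, _ = result.predict(x)
    keep = pred_clean == labels
    if keep.sum() == 0:
        raise ValueError("no clean-correct samples; nothing to perturb")
    rng = np.random.default_rng(spec.seed)
    # one stacked batch of all replicates (noise independent across copies)
    noisy = np.concatenate(
        [add_noise(x, spec, rng=rng) for _ in range(spec.replicates)]
    )
    all_labels = np.tile(labels, spec.replicates)
    keep_rep = np.tile(keep, spec.replicates)
    pred, _, embeddings = result.predict(noisy)
    correct = int((pred[keep_rep] == all_labels[keep_rep]).sum())

    def _sil(points, labs):
        return (
            evaluation.silhouette(points, labs)
            if np.unique(labs).size >= 2
            else float("nan")
        )

    return RobustnessResult(
        accuracy_under_noise=correct / (spec.replicates * keep.sum()),
        silhouette=_sil(embeddings[keep_rep], all_labels[keep_rep]),
        silhouette_all=_sil(embeddings, all_labels),
        embeddings=embeddings,
        labels=all_labels,
        n_clean_correct=int(keep.sum()),
    )


def noise_sweep(
    results: dict[str, object],
    spectra: np.ndarray,
    labels: np.ndarray,
    params: tuple[float, ...],
    kind: str,
    replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Full factorial model x noise-parameter table of accuracy and silhouette."""
    if not results:
        raise ValueError("model set is empty")
    if len(params) == 0:
        raise ValueError("noise parameter grid is empty")
    rows = []
    for name, result in results.items():
        for param in params:
            spec = NoiseSpec(
                kind=kind, param=float(param), replicates=replicates, seed=seed
            )
            r = robustness_eval(result, spectra, labels, spec)
            rows.append(
                {
                    "model": name,
                    "noise_kind": kind,
                    "param": float(param),
                    "accuracy": r.accuracy_under_noise,
                    "silhouette": r.silhouette,
                    "silhouette_all": r.silhouette_all,
                    "n_clean_correct": r.n_clean_correct,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TransferReport:
    score_system1: float
    score_system2: float

    @property
    def transfer_decline(self) -> float:
        return transfer_decline(self.score_system1, self.score_system2)


def transfer_decline(score1: float, score2: float, ndigits: int | None = None) -> float:
    """Relative score drop, in percent: 100 * (s1 - s2) / s1."""
    if score1 <= 0:
        raise ValueError("reference score must be positive")
    pct = 100.0 * (score1 - score2) / score1
    return round(pct, ndigits) if ndigits is not None else pct
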