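"""Patient-grouped splitting, batching, seeded SGD training and random search.

Splits are made at the volunteer level so no patient contributes samples to
more than one of train/validation/test: 75% of patients (floored) form the
train+validation pool, ~20% of those (rounded, e.g. 2 of 9) become the
validation patients, and all remaining patients are the test set. Batches
for contrastive losses are built so that every batch holds at least two
samples of each class it contains, whenever the class counts permit —
otherwise the 1/(M_yi - 1) anchor weight would skip anchors.

Training is plain SGD with momentum for 20 epochs (defaults from the
study's searched hyperparameters: CNN lr 0.001 / momentum 0.7; SC and
SCL-adjust lr 0.01 / momentum 0.95, ratio 0.7), deterministic for a fixed
seed. The two-stage SC protocol first trains encoder+projector under the
supervised contrastive loss, then removes the projector, freezes the
encoder (linear probe) and trains the 2-unit head with cross-entropy;
``freeze_encoder=False`` enables full fine-tuning instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import evaluation
from .models import (
    ArchitectureSpec,
    EmbeddingBatch,
    SCLConfig,
    SCModel,
    SpectrumClassifier,
    build_model,
    combined_loss,
    cross_entropy_loss,
    scl_loss,
)
from .nn import SGD
from .synth import Cohort

__all__ = [
    "SplitPlan",
    "TrainConfig",
    "SearchSpace",
    "TrainResult",
    "TrainingDivergedError",
    "DEFAULT_CONFIGS",
    "grouped_split",
    "make_batches",
    "train_model",
    "random_search",
]


class TrainingDivergedError(RuntimeError):
    """Raised when a training loss becomes non-finite."""


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint patient-level train/validation/test assignment."""

    train_patients: tuple[int, ...]
    val_patients: tuple[int, ...]
    test_patients: tuple[int, ...]
    counts: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        sets = [set(self.train_patients), set(self.val_patients), set(self.test_patients)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("patient appears in two splits")

    def membership(self, patient_id: np.ndarray) -> np.ndarray:
        """Per-sample split name ('train' | 'val' | 'test')."""
        out = np.empty(len(patient_id), dtype=object)
        for name, pats in (
            ("train", self.train_patients),
            ("val", self.val_patients),
            ("test", self.test_patients),
        ):
            out[np.isin(patient_id, pats)] = name
        if any(v is None for v in out):
            raise ValueError("sample with patient outside the split plan")
        return out


def grouped_split(
    patient_id: np.ndarray,
    seed: int,
    labels: np.ndarray | None = None,
    with_validation: bool = True,
    require_both_classes: bool = True,
    max_tries: int = 200,
) -> SplitPlan:
    """Draw a patient-grouped split plan, deterministic per seed.

    floor(0.75 * n_patients) patients form the train(+validation) pool;
    with validation, round(0.2 * pool) of them (at least 1) are validation
    patients; every remaining patient is test. When ``labels`` are given
    and ``require_both_classes`` is set, assignments are redrawn (with a
    deterministic sub-seed sequence) until train and test each contain both
    classes.
    """
    patient_id = np.asarray(patient_id)
    patients = np.unique(patient_id)
    n = patients.size
    if n < 4:
        raise ValueError("need at least 4 patients to populate the splits")
    n_pool = math.floor(0.75 * n)
    n_val = max(1, round(0.2 * n_pool)) if with_validation else 0
    if n_pool - n_val < 1 or n - n_pool < 1:
        raise ValueError("too few patients to populate all splits")

    for attempt in range(max_tries):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        perm = rng.permutation(patients)
        pool, test = perm[:n_pool], perm[n_pool:]
        val = pool[:n_val]
        train = pool[n_val:]
        plan = SplitPlan(
            train_patients=tuple(int(p) for p in np.sort(train)),
            val_patients=tuple(int(p) for p in np.sort(val)),
            test_patients=tuple(int(p) for p in np.sort(test)),
        )
        if labels is None or not require_both_classes:
            break
        labels = np.asarray(labels)
        ok = True
        for pats in (train, test) if not with_validation else (train, val, test):
            lab = labels[np.isin(patient_id, pats)]
            if np.unique(lab).size < 2:
                ok = False
                break
        if ok:
            break
    else:
        raise ValueError(
            "could not draw a split with both classes in every part; the "
            "cohort's label mixture may make it impossible"
        )
    counts = {
        name: int(np.isin(patient_id, pats).sum())
        for name, pats in (
            ("train", plan.train_patients),
            ("val", plan.val_patients),
            ("test", plan.test_patients),
        )
    }
    plan = replace(plan, counts=counts)
    plan.validate()
    return plan


def make_batches(
    labels: np.ndarray,
    batch_size: int,
    rng: np.random.Generator,
    contrastive: bool = False,
    strict: bool = False,
) -> list[np.ndarray]:
    """Shuffled batch index lists; the final short batch is kept.

    In contrastive mode samples are allocated so that no batch holds a
    single sample of a class unless the class count itself forces it;
    batches of size < 4 with a contrastive loss are refused in strict mode.
    """
    labels = np.asarray(labels)
    n = labels.size
    if batch_size < 1:
        raise ValueError("batch_size must be positive")
    if contrastive and batch_size < 4:
        msg = "batch_size < 4 is too small to form positive pairs reliably"
        if strict:
            raise ValueError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
    n_batches = math.ceil(n / batch_size)
    sizes = [batch_size] * (n_batches - 1) + [n - batch_size * (n_batches - 1)]
    if contrastive and n_batches > 1 and sizes[-1] == 1:
        # a singleton batch cannot form a positive pair; fold it into the
        # previous batch
        sizes = sizes[:-2] + [sizes[-2] + 1]
        n_batches -= 1
    if not contrastive:
        order = rng.permutation(n)
        return [
            order[i * batch_size : i * batch_size + sz] for i, sz in enumerate(sizes)
        ]

    capacity = np.asarray(sizes, dtype=int).copy()
    batches: list[list[int]] = [[] for _ in range(n_batches)]
    has_class: list[set] = [set() for _ in range(n_batches)]
    classes, counts = np.unique(labels, return_counts=True)
    for cls in classes[np.argsort(-counts, kind="stable")]:
        idx = rng.permutation(np.flatnonzero(labels == cls)).tolist()
        while idx:
            if len(idx) == 1:
                # leftover single: prefer a batch already holding this class
                candidates = [
                    b for b in range(n_batches) if capacity[b] > 0 and cls in has_class[b]
                ]
                if not candidates:
                    candidates = [b for b in range(n_batches) if capacity[b] > 0]
                b = max(candidates, key=lambda b: capacity[b])
                batches[b].append(idx.pop())
                capacity[b] -= 1
            else:
                viable = [b for b in range(n_batches) if capacity[b] >= 2]
                if viable:
                    b = max(viable, key=lambda b: capacity[b])
                    batches[b].extend([idx.pop(), idx.pop()])
                    capacity[b] -= 2
                else:
                    b = int(np.argmax(capacity))
                    if capacity[b] < 1:
                        raise RuntimeError("batch capacity bookkeeping failed")
                    batches[b].append(idx.pop())
                    capacity[b] -= 1
            has_class[b].add(cls)
    out = []
    for b in rng.permutation(n_batches):
        arr = np.asarray(batches[b], dtype=int)
        out.append(arr[rng.permutation(arr.size)])
    return out


DEFAULT_LRS = {"cnn": 0.001, "sc": 0.01, "scl_adjust": 0.01}
DEFAULT_MOMENTA = {"cnn": 0.7, "sc": 0.95, "scl_adjust": 0.95}


@dataclass(frozen=True)
class TrainConfig:
    """SGD training settings (defaults follow the searched hyperparameters)."""

    lr: float = 0.001
    momentum: float = 0.7
    batch_size: int = 16
    epochs: int = 20
    seed: int = 42
    ratio: float = 0.7  # scl_adjust only
    t: float = 0.5
    scl_target: str = "penultimate"
    scl_variant: str = "printed"
    scl_reduction: str = "anchor_mean"
    freeze_encoder: bool = True  # sc downstream phase
    projector_dim: int = 4
    standardize: str = "per_feature"  # or "global"
    clip_norm: float | None = 5.0  # global gradient-norm bound

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.standardize not in ("per_feature", "global"):
            raise ValueError("standardize must be 'per_feature' or 'global'")
        SCLConfig(
            t=self.t, ratio=self.ratio, scl_target=self.scl_target,
            variant=self.scl_variant, reduction=self.scl_reduction,
        ).validate()


# learning rate, momentum and ratio follow the searched values; batch size
# was searched but never printed, so each variant keeps its own default
DEFAULT_CONFIGS: dict[str, TrainConfig] = {
    "cnn": TrainConfig(lr=0.001, momentum=0.7, batch_size=4),
    "sc": TrainConfig(lr=0.01, momentum=0.95, batch_size=8),
    "scl_adjust": TrainConfig(lr=0.01, momentum=0.95, ratio=0.7, batch_size=8),
}


@dataclass
class TrainResult:
    """A trained model plus its per-epoch history and input standardiser.

    ``mean``/``std`` are the training-split statistics, per (wavelength,
    frequency-bin) element by default; the same transform is applied to any
    spectra scored later.
    """

    model: SpectrumClassifier
    history: pd.DataFrame
    mean: np.ndarray | float
    std: np.ndarray | float

    def standardize(self, spectra: np.ndarray) -> np.ndarray:
        return (np.asarray(spectra, dtype=float) - self.mean) / self.std

    def predict(self, spectra: np.ndarray):
        return self.model.predict(self.standardize(spectra))


def _check_finite(loss: float, context: str) -> None:
    if not np.isfinite(loss):
        raise TrainingDivergedError(f"non-finite loss during {context}: {loss}")


def _val_score(result_model, mean, std, cohort, mask) -> float:
    if mask.sum() == 0:
        return float("nan")
    x = (cohort.spectra[mask] - mean) / std
    pred, scores, _ = result_model.predict(x)
    return evaluation.metric_set_from(cohort.labels[mask], pred, scores).score


def train_model(
    kind: str,
    cohort: Cohort,
    split: SplitPlan,
    cfg: TrainConfig | None = None,
    arch: ArchitectureSpec | None = None,
) -> TrainResult:
    """Train one model variant on the cohort's train split.

    cnn / scl_adjust run a single 20-epoch phase with their loss; sc runs
    the two-phase protocol (representation learning, then head training on
    the frozen encoder). The per-epoch loss and validation score are
    recorded in ``history``.
    """
    cfg = cfg or DEFAULT_CONFIGS.get(kind, TrainConfig())
    cfg.validate()
    split.validate()
    if arch is None:
        arch = ArchitectureSpec(projector_dim=cfg.projector_dim)
    member = split.membership(cohort.patient_id)
    train_mask = member == "train"
    val_mask = member == "val"
    if train_mask.sum() < 2:
        raise ValueError("training split is empty or trivial")

    if cfg.standardize == "per_feature":
        mean = cohort.spectra[train_mask].mean(axis=0)
        std = cohort.spectra[train_mask].std(axis=0) + 1e-6
    else:
        mean = float(cohort.spectra[train_mask].mean())
        std = float(cohort.spectra[train_mask].std()) or 1.0
    x_train = (cohort.spectra[train_mask] - mean) / std
    y_train = cohort.labels[train_mask]

    rng = np.random.default_rng(cfg.seed)
    model = build_model(kind, arch, rng)
    # the class-balanced sampler is needed only when a contrastive term is
    # actually active (ratio 0 degrades scl_adjust to the plain cnn exactly)
    contrastive = kind == "sc" or (kind == "scl_adjust" and cfg.ratio > 0)
    if contrastive and np.min(np.bincount(y_train, minlength=2)) < 2:
        raise ValueError("contrastive training requires >= 2 samples per class")

    scl_cfg = SCLConfig(
        t=cfg.t, ratio=cfg.ratio, scl_target=cfg.scl_target,
        variant=cfg.scl_variant, reduction=cfg.scl_reduction,
    )
    rows = []

    def run_phase(phase: str, params, epochs: int) -> None:
        opt = SGD(params, lr=cfg.lr, momentum=cfg.momentum, clip_norm=cfg.clip_norm)
        for epoch in range(epochs):
            batches = make_batches(
                y_train, cfg.batch_size, rng, contrastive=contrastive
            )
            epoch_loss = 0.0
            n_correct = 0
            for idx in batches:
                xb, yb = x_train[idx], y_train[idx]
                opt.zero_grad()
                if kind == "cnn" or phase == "head":
                    h, logits = model.forward(xb)
                    loss, dlogits = cross_entropy_loss(logits, yb, return_grad=True)
                    if phase == "head" and cfg.freeze_encoder:
                        model.head.backward(dlogits)
                    else:
                        model.backward(dlogits)
                elif kind == "scl_adjust":
                    h, logits = model.forward(xb)
                    emb = EmbeddingBatch(
                        logits if cfg.scl_target == "logits" else h, yb
                    )
                    loss, dlogits, dz = combined_loss(
                        logits, emb, scl_cfg, return_grad=True
                    )
                    if cfg.scl_target == "logits":
                        model.backward(dlogits + dz)
                    else:
                        model.backward(dlogits, dh_extra=dz)
                else:  # sc representation phase
                    h, z = model.forward_projector(xb)
                    loss, dz = scl_loss(
                        EmbeddingBatch(z, yb), t=cfg.t, variant=cfg.scl_variant,
                        reduction=cfg.scl_reduction, return_grad=True,
                    )
                    model.backward_projector(dz)
                _check_finite(loss, f"{kind} {phase} epoch {epoch}")
                opt.step()
                epoch_loss += loss * len(idx)
                if phase != "representation":
                    n_correct += int((logits.argmax(axis=1) == yb).sum())
            epoch_loss /= len(y_train)
            rows.append(
                {
                    "phase": phase,
                    "epoch": epoch,
                    "loss": epoch_loss,
                    # accuracy of the pre-update batch outputs (free to record;
                    # meaningless during the SCL-only representation phase)
                    "train_accuracy": (
                        n_correct / len(y_train) if phase != "representation" else np.nan
                    ),
                    "val_score": (
                        _val_score(model, mean, std, cohort, val_mask)
                        if (epoch == epochs - 1 and phase != "representation")
                        else np.nan
                    ),
                }
            )

    if kind == "sc":
        assert isinstance(model, SCModel)
        run_phase("representation", model.representation_params(), cfg.epochs)
        params = (
            model.head_params()
            if cfg.freeze_encoder
            else model.encoder.params() + model.head_params()
        )
        run_phase("head", params, cfg.epochs)
    else:
        run_phase("single", model.params(), cfg.epochs)

    return TrainResult(
        model=model, history=pd.DataFrame(rows), mean=mean, std=std
    )


@dataclass(frozen=True)
class SearchSpace:
    """Random-search distributions for the tunable hyperparameters."""

    lr_log10_range: tuple[float, float] = (-4.0, -1.0)
    momentum_choices: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.0, 0.01), 2))
    batch_size_choices: tuple[int, ...] = (8, 16, 32)
    ratio_range: tuple[float, float] = (0.1, 0.9)
    projector_dim_choices: tuple[int, ...] = (2, 4, 8, 16)
    n_rounds: int = 500

    def sample(self, rng: np.random.Generator, kind: str, base: TrainConfig) -> TrainConfig:
        lr = 10.0 ** rng.uniform(*self.lr_log10_range)
        momentum = float(rng.choice(self.momentum_choices))
        batch_size = int(rng.choice(self.batch_size_choices))
        ratio = float(rng.uniform(*self.ratio_range))
        projector_dim = int(rng.choice(self.projector_dim_choices))
        return replace(
            base,
            lr=lr,
            momentum=momentum,
            batch_size=batch_size,
            ratio=ratio if kind == "scl_adjust" else base.ratio,
            projector_dim=projector_dim if kind == "sc" else base.projector_dim,
        )


def random_search(
    space: SearchSpace,
    cohort: Cohort,
    split: SplitPlan,
    kind: str,
    seed: int = 42,
    base_cfg: TrainConfig | None = None,
    include_default: bool = False,
) -> tuple[TrainConfig, pd.DataFrame]:
    """Sample ``space.n_rounds`` configurations, rank by validation score.

    Ties are broken by the earlier round; the full leaderboard is returned.
    """
    if space.n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if not split.val_patients:
        raise ValueError("random search needs a validation split")
    base = base_cfg or DEFAULT_CONFIGS.get(kind, TrainConfig())
    rng = np.random.default_rng(seed)
    rows, configs = [], []
    for rnd in range(space.n_rounds):
        cfg = (
            base if include_default and rnd == 0 else space.sample(rng, kind, base)
        )
        cfg = replace(cfg, seed=base.seed)
        try:
            result = train_model(kind, cohort, split, cfg)
            val = float(result.history["val_score"].iloc[-1])
        except TrainingDivergedError:
            val = float("nan")
        configs.append(cfg)
        rows.append(
            {
                "round": rnd,
                "lr": cfg.lr,
                "momentum": cfg.momentum,
                "batch_size": cfg.batch_size,
                "ratio": cfg.ratio,
                "projector_dim": cfg.projector_dim,
                "val_score": val,
            }
        )
    board = pd.DataFrame(rows)
    if board["val_score"].isna().all():
        raise RuntimeError("every search round failed")
    board = board.sort_values(
        ["val_score", "round"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    best = configs[int(board.iloc[0]["round"])]
    return best, board
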