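"""Classifier variants and losses for 77x90 photoacoustic spectrum matrices.

Three variants share one small convolutional encoder:

* ``cnn`` — encoder + 2-unit prediction head, trained with cross-entropy;
* ``sc`` — two-stage supervised-contrastive model: encoder f_theta plus a
  projection head g_theta (256 -> 4) trained with the supervised
  contrastive loss (SCL); the projector is then removed and a 2-unit head
  is trained with cross-entropy on the frozen 256-d representation h_i;
* ``scl_adjust`` — architecture identical to ``cnn``, trained with the
  weighted sum ``SCL * ratio + CE * (1 - ratio)``, the SCL term applied by
  default to the penultimate 256-d features.

The encoder layer plan (kernel counts and feature-map sizes)::

    77x90 -> conv(64) -> 64x77x90 -> maxpool 2x2 -> 64x38x45
          -> conv(4)  -> 4x38x45  -> maxpool 3x3 -> 4x12x15
          -> fc       -> 256      [-> projector 4] -> head 2

Pooling uses floor division, which reproduces the printed shape chain
exactly; convolution kernel sizes are configurable (default 3x3 with same
padding, which preserves the 77x90 plane).

The supervised contrastive loss over a batch of embeddings z_i with labels
y_i uses temperature-scaled cosine similarities s_ij = z_i.z_j/(|z_i||z_j|)::

    SCL = - sum_i 1/(M_yi - 1) sum_{j != i, y_j = y_i}
            ln[ exp(s_ij/t) / (exp(s_ij/t) + sum_{k: y_k != y_i} exp(s_ik/t)) ]

where M_yi is the number of batch samples sharing label y_i. As printed,
the denominator contains only the anchor-positive term itself plus the
different-label terms (it excludes the other positives); the canonical
supervised-contrastive denominator (all non-anchor terms) is available via
``variant="canonical"``. Anchors with no same-label partner (M_yi = 1) are
skipped, avoiding the 1/(M_yi - 1) singularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Conv2d, Flatten, Linear, MaxPool2d, Param, ReLU, Sequential

__all__ = [
    "ArchitectureSpec",
    "SCLConfig",
    "EmbeddingBatch",
    "ArchitectureError",
    "SpectrumClassifier",
    "SCModel",
    "build_model",
    "shape_chain",
    "CANONICAL_SHAPE_CHAIN",
    "check_architecture",
    "parameter_count",
    "cosine_similarity",
    "scl_loss",
    "cross_entropy_loss",
    "combined_loss",
]


class ArchitectureError(ValueError):
    """Raised when a layer plan does not produce the expected shapes."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer plan of the shared encoder and heads."""

    input_shape: tuple[int, int] = (77, 90)
    conv1_kernels: int = 64
    pool1: int = 2
    conv2_kernels: int = 4
    pool2: int = 3
    encoder_out_dim: int = 256
    projector_dim: int = 4
    head_dim: int = 2
    conv_kernel_size: int = 3


#: printed layer-by-layer output shapes for the default architecture
CANONICAL_SHAPE_CHAIN: tuple[tuple[str, tuple[int, ...]], ...] = (
    ("input", (77, 90)),
    ("conv1", (64, 77, 90)),
    ("pool1", (64, 38, 45)),
    ("conv2", (4, 38, 45)),
    ("pool2", (4, 12, 15)),
    ("fc", (256,)),
    ("head", (2,)),
)


def shape_chain(arch: ArchitectureSpec) -> list[tuple[str, tuple[int, ...]]]:
    """Per-layer output shapes implied by an architecture spec."""
    h, w = arch.input_shape
    chain = [("input", (h, w))]
    chain.append(("conv1", (arch.conv1_kernels, h, w)))
    h, w = h // arch.pool1, w // arch.pool1
    chain.append(("pool1", (arch.conv1_kernels, h, w)))
    chain.append(("conv2", (arch.conv2_kernels, h, w)))
    h, w = h // arch.pool2, w // arch.pool2
    chain.append(("pool2", (arch.conv2_kernels, h, w)))
    chain.append(("fc", (arch.encoder_out_dim,)))
    chain.append(("head", (arch.head_dim,)))
    return chain


def check_architecture(
    arch: ArchitectureSpec,
    expected: tuple[tuple[str, tuple[int, ...]], ...] = CANONICAL_SHAPE_CHAIN,
) -> None:
    """Verify the implied shape chain, naming the first mismatched layer."""
    got = shape_chain(arch)
    for (name_e, shape_e), (name_g, shape_g) in zip(expected, got):
        if shape_e != shape_g:
            raise ArchitectureError(
                f"layer {name_g!r}: expected output {shape_e}, got {shape_g}"
            )
    if any(min(s[1]) < 1 for s in got[:-2]):
        raise ArchitectureError("pooling collapsed a spatial dimension")


def _flatten_dim(arch: ArchitectureSpec) -> int:
    h, w = arch.input_shape
    h, w = h // arch.pool1, w // arch.pool1
    h, w = h // arch.pool2, w // arch.pool2
    return arch.conv2_kernels * h * w


def parameter_count(arch: ArchitectureSpec = ArchitectureSpec()) -> dict[str, int]:
    """Trainable parameter count per layer of the cnn/scl_adjust network."""
    k2 = arch.conv_kernel_size**2
    conv1 = arch.conv1_kernels * (k2 + 1)
    conv2 = arch.conv2_kernels * (arch.conv1_kernels * k2 + 1)
    fc = arch.encoder_out_dim * (_flatten_dim(arch) + 1)
    head = arch.head_dim * (arch.encoder_out_dim + 1)
    return {
        "conv1": conv1,
        "conv2": conv2,
        "fc": fc,
        "head": head,
        "total": conv1 + conv2 + fc + head,
    }


def _make_encoder(arch: ArchitectureSpec, rng: np.random.Generator) -> Sequential:
    return Sequential(
        [
            Conv2d(1, arch.conv1_kernels, arch.conv_kernel_size, rng),
            ReLU(),
            MaxPool2d(arch.pool1),
            Conv2d(arch.conv1_kernels, arch.conv2_kernels, arch.conv_kernel_size, rng),
            ReLU(),
            MaxPool2d(arch.pool2),
            Flatten(),
            Linear(_flatten_dim(arch), arch.encoder_out_dim, rng),
            ReLU(),
        ]
    )


class SpectrumClassifier:
    """Encoder + 2-unit prediction head (the ``cnn``/``scl_adjust`` network)."""

    kind = "cnn"

    def __init__(self, arch: ArchitectureSpec, rng: np.random.Generator):
        check_architecture(arch, shape_chain(arch))  # sanity only; no-op match
        self.arch = arch
        self.encoder = _make_encoder(arch, rng)
        self.head = Linear(arch.encoder_out_dim, arch.head_dim, rng)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (penultimate features h, logits). ``x`` is (B, 77, 90)."""
        h = self.encoder.forward(np.asarray(x)[:, None, :, :])
        return h, self.head.forward(h)

    def backward(self, dlogits: np.ndarray, dh_extra: np.ndarray | None = None) -> None:
        dh = self.head.backward(dlogits)
        if dh_extra is not None:
            dh = dh + dh_extra
        self.encoder.backward(dh)

    def params(self) -> list[Param]:
        return self.encoder.params() + self.head.params()

    def predict(self, x: np.ndarray, batch_size: int = 64):
        """(predicted labels, positive-class softmax scores, 2-d logits)."""
        logits = []
        x = np.asarray(x)
        for i in range(0, x.shape[0], batch_size):
            _, lg = self.forward(x[i : i + batch_size])
            logits.append(lg)
        logits = np.concatenate(logits) if logits else np.empty((0, self.arch.head_dim))
        shifted = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(shifted)
        probs /= probs.sum(axis=1, keepdims=True)
        return logits.argmax(axis=1), probs[:, 1], logits

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.value[...] = w


class SCModel(SpectrumClassifier):
    """Two-stage supervised-contrastive model: encoder, projector, head."""

    kind = "sc"

    def __init__(self, arch: ArchitectureSpec, rng: np.random.Generator):
        super().__init__(arch, rng)
        self.projector = Linear(arch.encoder_out_dim, arch.projector_dim, rng)

    def forward_projector(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (h, z): representation and its projection for the SCL phase."""
        h = self.encoder.forward(np.asarray(x)[:, None, :, :])
        return h, self.projector.forward(h)

    def backward_projector(self, dz: np.ndarray) -> None:
        self.encoder.backward(self.projector.backward(dz))

    def params(self) -> list[Param]:
        return super().params() + self.projector.params()

    def representation_params(self) -> list[Param]:
        return self.encoder.params() + self.projector.params()

    def head_params(self) -> list[Param]:
        return self.head.params()


def build_model(
    kind: str,
    arch: ArchitectureSpec = ArchitectureSpec(),
    rng: np.random.Generator | int = 42,
    expected_shapes: tuple | None = None,
) -> SpectrumClassifier:
    """Instantiate one of the three classifier variants.

    ``cnn`` and ``scl_adjust`` share identical parameter shapes (the
    variants differ only in training loss); ``sc`` adds the projection head.
    ``expected_shapes`` (e.g. ``CANONICAL_SHAPE_CHAIN``) triggers a strict
    shape-conformity check.
    """
    if expected_shapes is not None:
        check_architecture(arch, expected_shapes)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if kind in ("cnn", "scl_adjust"):
        model = SpectrumClassifier(arch, rng)
        model.kind = kind
        return model
    if kind == "sc":
        return SCModel(arch, rng)
    raise ValueError(f"unknown model kind {kind!r} (cnn | sc | scl_adjust)")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SCLConfig:
    """Supervised-contrastive loss settings."""

    t: float = 0.5  # temperature
    ratio: float = 0.7  # combined-loss weight on the SCL term
    scl_target: str = "penultimate"  # or "logits"
    variant: str = "printed"  # or "canonical"
    reduction: str = "sum"  # or "anchor_mean"; see scl_loss

    def validate(self) -> None:
        if self.t <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError("ratio must be in [0, 1]")
        if self.scl_target not in ("penultimate", "logits"):
            raise ValueError("scl_target must be 'penultimate' or 'logits'")
        if self.variant not in ("printed", "canonical"):
            raise ValueError("variant must be 'printed' or 'canonical'")
        if self.reduction not in ("sum", "anchor_mean"):
            raise ValueError("reduction must be 'sum' or 'anchor_mean'")


@dataclass
class EmbeddingBatch:
    """A batch of embedding vectors z_i with labels y_i."""

    Z: np.ndarray  # (M, d)
    y: np.ndarray  # (M,)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.y = np.asarray(self.y)
        if self.Z.ndim != 2 or self.y.shape != (self.Z.shape[0],):
            raise ValueError("Z must be (M, d) with one label per row")

    @property
    def M(self) -> int:
        return self.Z.shape[0]

    def m_yi(self) -> np.ndarray:
        """Per-anchor count of batch samples sharing the anchor's label."""
        return (self.y[:, None] == self.y[None, :]).sum(axis=1)


def cosine_similarity(z_i: np.ndarray, z_j: np.ndarray) -> float:
    """s_ij = z_i.z_j / (|z_i| |z_j|), undefined for zero vectors."""
    z_i = np.asarray(z_i, dtype=float)
    z_j = np.asarray(z_j, dtype=float)
    ni, nj = np.linalg.norm(z_i), np.linalg.norm(z_j)
    if ni == 0.0 or nj == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(z_i @ z_j / (ni * nj))


def scl_loss(
    batch: EmbeddingBatch,
    t: float = 0.5,
    variant: str = "printed",
    reduction: str = "sum",
    return_grad: bool = False,
):
    """Supervised contrastive loss of an embedding batch (and dL/dZ).

    ``variant="printed"`` uses the per-pair denominator
    exp(s_ij/t) + sum_{k: y_k != y_i} exp(s_ik/t); ``"canonical"`` uses the
    standard all-non-anchor denominator sum_{k != i} exp(s_ik/t).
    ``reduction="sum"`` sums over anchors (the loss as written);
    ``"anchor_mean"`` divides by the batch size, the convention of the
    reference supervised-contrastive implementation, which keeps the loss
    scale independent of batch size when mixing with a mean cross-entropy.
    """
    if t <= 0:
        raise ValueError("temperature must be positive")
    if variant not in ("printed", "canonical"):
        raise ValueError("variant must be 'printed' or 'canonical'")
    if reduction not in ("sum", "anchor_mean"):
        raise ValueError("reduction must be 'sum' or 'anchor_mean'")
    Z, y = batch.Z, batch.y
    M = batch.M
    if M < 2:
        raise ValueError("SCL requires a batch of at least 2 samples")
    norms = np.linalg.norm(Z, axis=1)
    # a ReLU'd representation can contain all-zero rows; treat them as
    # zero-similarity embeddings (cosine 0 to everything, subgradient 0)
    zero_rows = norms == 0.0
    safe_norms = np.where(zero_rows, 1.0, norms)
    Zn = Z / safe_norms[:, None]
    S = Zn @ Zn.T
    E = np.exp(S / t)
    same = y[:, None] == y[None, :]
    eye = np.eye(M, dtype=bool)
    pos = same & ~eye
    neg = ~same
    m_yi = same.sum(axis=1)
    w = np.where(m_yi > 1, 1.0 / np.maximum(m_yi - 1, 1), 0.0)  # skip singletons

    neg_sum = (E * neg).sum(axis=1)  # (M,)
    if variant == "printed":
        D = E + neg_sum[:, None]
    else:
        D = np.broadcast_to(((E * ~eye).sum(axis=1))[:, None], E.shape)
    with np.errstate(divide="ignore"):
        log_term = S / t - np.log(D)
    scale = 1.0 / M if reduction == "anchor_mean" else 1.0
    loss = float(-(w[:, None] * pos * log_term).sum()) * scale
    if not return_grad:
        return loss

    WP = w[:, None] * pos
    if variant == "printed":
        c = (WP / D).sum(axis=1)  # (M,)
        G = -(WP / t) * (1.0 - E / D) + neg * (E / t) * c[:, None]
    else:
        row = WP.sum(axis=1) / D[:, 0]  # sum_j w_i P_ij / D_i
        G = -(WP / t) + (~eye) * (E / t) * row[:, None]
    dZn = (G + G.T) @ Zn
    # back through row normalisation z / |z|
    proj = (dZn * Zn).sum(axis=1, keepdims=True)
    dZ = (dZn - proj * Zn) / safe_norms[:, None]
    dZ[zero_rows] = 0.0
    return loss, dZ * scale


def cross_entropy_loss(
    logits: np.ndarray, y: np.ndarray, return_grad: bool = False
):
    """Mean negative log-likelihood under a softmax over the logits."""
    logits = np.asarray(logits, dtype=float)
    y = np.asarray(y)
    if logits.ndim != 2:
        raise ValueError("logits must be (M, n_classes)")
    n_classes = logits.shape[1]
    if np.any(y < 0) or np.any(y >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    M = logits.shape[0]
    shifted = logits - logits.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(axis=1))
    log_probs = shifted - log_z[:, None]
    loss = float(-log_probs[np.arange(M), y].mean())
    if not return_grad:
        return loss
    probs = np.exp(log_probs)
    grad = probs
    grad[np.arange(M), y] -= 1.0
    return loss, grad / M


def combined_loss(
    logits: np.ndarray,
    embeddings: EmbeddingBatch,
    cfg: SCLConfig = SCLConfig(),
    return_grad: bool = False,
):
    """ratio * SCL(embeddings) + (1 - ratio) * CE(logits)."""
    cfg.validate()
    if return_grad:
        ce, dlogits = cross_entropy_loss(logits, embeddings.y, return_grad=True)
        scl, dz = scl_loss(
            embeddings, t=cfg.t, variant=cfg.variant,
            reduction=cfg.reduction, return_grad=True,
        )
        total = cfg.ratio * scl + (1.0 - cfg.ratio) * ce
        return total, (1.0 - cfg.ratio) * dlogits, cfg.ratio * dz
    ce = cross_entropy_loss(logits, embeddings.y)
    scl = scl_loss(embeddings, t=cfg.t, variant=cfg.variant, reduction=cfg.reduction)
    return cfg.ratio * scl + (1.0 - cfg.ratio) * ce
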