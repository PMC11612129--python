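"""The attention-based multi-head BI-RADS descriptor network.

Architecture: a grayscale ROI passes through a convolutional stem (conv +
max-pool + GELU) and a VGG16-style convolutional stack, yielding a g x g x d
feature map reshaped into a feature-space matrix F of g^2 rows, which is
batch-normalized.  A single tanh perceptron scores each row, a softmax turns
the scores into attention weights a_i (non-negative, summing to 1), and the
context vector c = sum_i a_i f_i is the weighted average of the feature
space.  Six dense heads read the context, one per BI-RADS descriptor; the
suggestivity (tumor-type) head additionally receives the six descriptor
outputs, because the type of a tumor depends on them, and the Boolean
malignancy head receives the descriptors, the suggestivity and the context.

The default configuration reproduces a 196 x 512 feature space from 450 x 450
inputs (g = 14, d = 512).  A structurally identical "tiny" configuration
(96 x 96 inputs, d = 64, downsampling 16, hence a 36 x 64 feature space) is
first-class and used throughout the CPU test-suite.

Orientation uses two per-neuron sigmoid outputs (parallel / anti-parallel)
because round nodules are neither: the decision reports "none" when both
values fall below a threshold tau (default 0.3).
"""

from __future__ import annotations


import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.transform import resize, rotate as sk_rotate

from .descriptors import DescriptorSet
from .errors import ConfigurationError, InputError, ModelStateError
from .nn import Adam, BatchNormRows, Conv2d, Dense, GELU, MaxPool2d
from .nn.attention import soft_attention_forward, soft_attention_backward
from .nn.layers import Layer
from .phantom import load_manifest, load_image, split_folds  # noqa: F401  (split helper re-exported)
from .roi import StandardROI, standardize_roi
from .roi_types import BoundingBox
from .vocab import DEFAULT_VOCABULARIES, Vocabularies

logger = logging.getLogger(__name__)

#: Heads driven directly by the context, in canonical order.  Orientation has
#: one sigmoid neuron per direction; all other heads are softmax.
SOFTMAX_HEADS = ("shape", "margin", "echogenicity", "posterior", "halo")
HEAD_ORDER = ("shape", "margin", "orientation", "echogenicity", "posterior", "halo")


@dataclass(frozen=True)
class NetConfig:
    """Topology and training hyperparameters.

    ``stages`` lists (channels, n_convs) blocks after the stem; every block
    ends in a 2x2 max-pool, so the total downsampling factor is
    2^(1 + len(stages)) and d equals the last block's channel count.
    """

    name: str = "default"
    input_size: int = 450
    stem_channels: int = 64
    stages: tuple[tuple[int, int], ...] = ((128, 2), (256, 3), (512, 3), (512, 3))
    tau: float = 0.3
    lr: float = 1e-4
    epochs: int = 30
    batch_size: int = 20
    seed: int = 0
    augment: bool = False
    hflip: bool = True  # label-preserving horizontal flips during training
    jitter: bool = True  # random content placement within the zero padding
    tta: bool = True  # average predictions over the horizontal flip
    lr_decay_frac: float = 1.0  # decay the learning rate at this epoch fraction
    lr_decay: float = 0.3
    swa_frac: float = 0.2  # average weights over this final fraction of epochs
    orientation_none: str = "zero"  # "zero" targets or "mask"
    loss_weights: dict = field(default_factory=dict)
    dtype: str = "float32"

    @property
    def d(self) -> int:
        return self.stages[-1][0]

    @property
    def downsample(self) -> int:
        return 2 ** (1 + len(self.stages))

    @property
    def grid(self) -> int:
        return self.input_size // self.downsample


def tiny_config(**overrides) -> NetConfig:
    """CPU-friendly topology: 96 x 96 input, d = 64, 36 x 64 feature space.

    The training defaults document the schedule the synthetic recovery study
    uses: 100 epochs of Adam at 2e-3 with stochastic weight averaging over
    the final fifth, and a doubled loss weight on the shape head, the
    hardest of the multi-task objectives at this resolution.
    """
    base = dict(name="tiny", input_size=96, stem_channels=8,
                stages=((16, 1), (32, 2), (64, 2)), lr=2e-3,
                epochs=100, batch_size=32,
                loss_weights={"shape": 2.0})
    base.update(overrides)
    return NetConfig(**base)


@dataclass(frozen=True)
class AttentionState:
    """Attention weights and context for one feature space."""

    V: np.ndarray
    a: np.ndarray  # (g^2,) non-negative, sums to 1
    c: np.ndarray  # (d,) context = a . F


@dataclass(frozen=True)
class HeadOutputs:
    """Per-value probabilities from every head."""

    descriptors: dict[str, dict[str, float]]  # six heads; orientation is sigmoid
    suggestivity: dict[str, float]
    malignancy: dict[str, float]  # {"benign": p, "malignant": p}


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _softmax_jacobian_product(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    return p * (dp - (dp * p).sum(axis=-1, keepdims=True))


class _AttentionLayer(Layer):
    """Holds the learned scoring vector V (the 1 x d weight matrix)."""

    def __init__(self, d: int, rng: np.random.Generator, dtype) -> None:
        super().__init__()
        self.params["V"] = (rng.standard_normal(d) / math.sqrt(d)).astype(dtype)


class DescriptorNet:
    """Encoder + attention + heads with explicit forward/backward passes."""

    def __init__(self, config: NetConfig,
                 vocab: Vocabularies = DEFAULT_VOCABULARIES) -> None:
        self.config = config
        self.vocab = vocab
        dtype = np.dtype(config.dtype).type
        rng = np.random.default_rng(config.seed)

        self.encoder: list[Layer] = [
            Conv2d(1, config.stem_channels, rng=rng, dtype=dtype), GELU(), MaxPool2d()]
        in_ch = config.stem_channels
        for channels, n_convs in config.stages:
            for _ in range(n_convs):
                self.encoder += [Conv2d(in_ch, channels, rng=rng, dtype=dtype), GELU()]
                in_ch = channels
            self.encoder.append(MaxPool2d())
        self.bn = BatchNormRows(config.d, dtype=dtype)
        self.att = _AttentionLayer(config.d, rng, dtype)

        self.head_values = {
            "shape": vocab.shape,
            "margin": vocab.margin,
            "orientation": ("parallel", "anti_parallel"),  # sigmoid neurons
            "echogenicity": vocab.echogenicity,
            "posterior": vocab.posterior,
            "halo": vocab.halo,
        }
        d = config.d
        self.heads = {name: Dense(d, len(vals), rng=rng, dtype=dtype)
                      for name, vals in self.head_values.items()}
        self._head_width = sum(len(v) for v in self.head_values.values())
        self.sugg_head = Dense(d + self._head_width, len(vocab.suggestivity),
                               rng=rng, dtype=dtype)
        self.mal_head = Dense(d + self._head_width + len(vocab.suggestivity), 2,
                              rng=rng, dtype=dtype)
        self.trained = False

    # -- plumbing -----------------------------------------------------------

    def layers(self) -> list[Layer]:
        return (self.encoder + [self.bn, self.att]
                + [self.heads[n] for n in HEAD_ORDER]
                + [self.sugg_head, self.mal_head])

    def _check_input(self, x: np.ndarray) -> None:
        s = self.config.input_size
        if x.shape[-2:] != (s, s):
            raise ConfigurationError(
                f"expected {s}x{s} input for config {self.config.name!r}, "
                f"got {x.shape[-2:]}")

    # -- forward ------------------------------------------------------------

    def encode_batch(self, x: np.ndarray, train: bool) -> np.ndarray:
        """(N, 1, S, S) -> batch-normalized feature space (N, g^2, d)."""
        self._check_input(x)
        h = x
        for layer in self.encoder:
            h = layer.forward(h, train=train)
        n, d, g, _ = h.shape
        self._enc_shape = (n, d, g)
        F = h.transpose(0, 2, 3, 1).reshape(n, g * g, d)
        return self.bn.forward(F, train=train)

    def forward(self, x: np.ndarray, train: bool = False) -> dict:
        F = self.encode_batch(x, train=train)
        a, c, att_cache = soft_attention_forward(F, self.att.params["V"])
        probs: dict[str, np.ndarray] = {}
        logits: dict[str, np.ndarray] = {}
        for name in HEAD_ORDER:
            z = self.heads[name].forward(c, train=train)
            logits[name] = z
            probs[name] = _sigmoid(z) if name == "orientation" else _softmax(z)
        sugg_in = np.concatenate([probs[n] for n in HEAD_ORDER] + [c], axis=1)
        z_s = self.sugg_head.forward(sugg_in, train=train)
        p_s = _softmax(z_s)
        mal_in = np.concatenate([probs[n] for n in HEAD_ORDER] + [p_s, c], axis=1)
        z_m = self.mal_head.forward(mal_in, train=train)
        p_m = _softmax(z_m)
        out = {"F": F, "a": a, "c": c, "probs": probs, "sugg": p_s, "mal": p_m}
        if train:
            out["_cache"] = (att_cache, logits)
        return out

    # -- loss and backward --------------------------------------------------

    def loss_and_backward(self, x: np.ndarray, labels: dict) -> dict[str, float]:
        """One training step's losses; leaves gradients in every layer."""
        out = self.forward(x, train=True)
        att_cache, _ = out["_cache"]
        probs, p_s, p_m = out["probs"], out["sugg"], out["mal"]
        n = x.shape[0]
        w = {**{name: 1.0 for name in HEAD_ORDER},
             "suggestivity": 1.0, "malignancy": 1.0,
             **self.config.loss_weights}
        losses: dict[str, float] = {}
        eps = 1e-9

        # malignancy head
        y_m = labels["malignancy"]
        losses["malignancy"] = float(-np.log(p_m[np.arange(n), y_m] + eps).mean())
        dz_m = (p_m - np.eye(2, dtype=p_m.dtype)[y_m]) / n * w["malignancy"]
        dmal_in = self.mal_head.backward(dz_m)
        hw, ns = self._head_width, len(self.vocab.suggestivity)
        dp_heads_mal, dp_s_mal, dc = (dmal_in[:, :hw], dmal_in[:, hw:hw + ns],
                                      dmal_in[:, hw + ns:].copy())

        # suggestivity head
        y_s = labels["suggestivity"]
        losses["suggestivity"] = float(-np.log(p_s[np.arange(n), y_s] + eps).mean())
        dz_s = ((p_s - np.eye(ns, dtype=p_s.dtype)[y_s]) / n * w["suggestivity"]
                + _softmax_jacobian_product(p_s, dp_s_mal))
        dsugg_in = self.sugg_head.backward(dz_s)
        dp_heads = dsugg_in[:, :hw] + dp_heads_mal
        dc += dsugg_in[:, hw:]

        # six descriptor heads
        offset = 0
        for name in HEAD_ORDER:
            k = len(self.head_values[name])
            p = probs[name]
            dp = dp_heads[:, offset:offset + k]
            offset += k
            if name == "orientation":
                y = labels["orientation_targets"]  # (N, 2) in {0,1}
                mask = labels["orientation_mask"]  # (N,)
                m = max(float(mask.sum()), 1.0)
                bce = -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
                losses[name] = float((bce.sum(axis=1) * mask).sum() / m)
                dz = ((p - y) * mask[:, None] / m * w[name]) + dp * p * (1 - p)
            else:
                y = labels[name]
                losses[name] = float(-np.log(p[np.arange(n), y] + eps).mean())
                k_eye = np.eye(k, dtype=p.dtype)
                dz = ((p - k_eye[y]) / n * w[name]
                      + _softmax_jacobian_product(p, dp))
            dc += self.heads[name].backward(dz)

        dF, dV = soft_attention_backward(dc, None, att_cache)
        self.att.grads["V"] = dV
        dF = self.bn.backward(dF)
        n_, d_, g_ = self._enc_shape
        dh = dF.reshape(n_, g_, g_, d_).transpose(0, 3, 1, 2)
        for layer in reversed(self.encoder):
            dh = layer.backward(dh)
        losses["total"] = float(sum(losses[k_] * w.get(k_, 1.0)
                                    for k_ in losses if k_ != "total"))
        return losses


# ---------------------------------------------------------------------------
# Spec-level single-instance operations
# ---------------------------------------------------------------------------

def encode(roi: StandardROI | np.ndarray, model: DescriptorNet) -> np.ndarray:
    """Feature-space matrix (g^2, d) for one standardized ROI."""
    x = _roi_to_input(roi, model.config)
    return model.encode_batch(x, train=False)[0]


def attend(F: np.ndarray, V: np.ndarray) -> AttentionState:
    """Soft-attention pooling of one feature space (pure function)."""
    F = np.asarray(F, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64).reshape(-1)
    if F.ndim != 2 or F.shape[1] != V.shape[0]:
        raise ConfigurationError(
            f"feature space {F.shape} incompatible with V of length {V.shape[0]}")
    a, c, _ = soft_attention_forward(F[None], V)
    return AttentionState(V=V, a=a[0], c=c[0])


def heads_forward(state: AttentionState, model: DescriptorNet) -> HeadOutputs:
    """Run the descriptor, suggestivity and malignancy heads on a context."""
    c = np.asarray(state.c, dtype=model.att.params["V"].dtype)[None, :]
    probs = {}
    for name in HEAD_ORDER:
        z = model.heads[name].forward(c, train=False)
        probs[name] = _sigmoid(z) if name == "orientation" else _softmax(z)
    sugg_in = np.concatenate([probs[n] for n in HEAD_ORDER] + [c], axis=1)
    p_s = _softmax(model.sugg_head.forward(sugg_in, train=False))
    mal_in = np.concatenate([probs[n] for n in HEAD_ORDER] + [p_s, c], axis=1)
    p_m = _softmax(model.mal_head.forward(mal_in, train=False))
    return HeadOutputs(
        descriptors={
            name: dict(zip(model.head_values[name], probs[name][0].tolist()))
            for name in HEAD_ORDER},
        suggestivity=dict(zip(model.vocab.suggestivity, p_s[0].tolist())),
        malignancy={"benign": float(p_m[0, 0]), "malignant": float(p_m[0, 1])},
    )


def decide_orientation(sigmoid_values, tau: float = 0.3) -> str:
    """Three-way orientation decision from the two sigmoid neurons.

    "none" when both values fall below tau; otherwise the argmax among the
    values reaching tau, ties resolved toward "parallel" (the prevalent
    class).
    """
    p_par, p_anti = float(sigmoid_values[0]), float(sigmoid_values[1])
    if p_par < tau and p_anti < tau:
        return "none"
    if p_par >= tau and (p_par >= p_anti or p_anti < tau):
        return "parallel"
    return "anti_parallel"


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentRanges:
    """Sampling intervals for ROI augmentation (training defaults)."""

    vertical: tuple[float, float] = (-0.1, 0.25)
    horizontal: tuple[float, float] = (-0.1, 0.15)
    zoom: tuple[float, float] = (-0.3, 0.3)
    contrast: tuple[float, float] = (0.8, 1.2)
    brightness: tuple[float, float] = (-25.0, 25.0)
    flip_p: float = 0.5
    rotation_max: float = 0.05 * 2.0 * math.pi  # radians

    @classmethod
    def identity(cls) -> "AugmentRanges":
        return cls(vertical=(0, 0), horizontal=(0, 0), zoom=(0, 0),
                   contrast=(1, 1), brightness=(0, 0), flip_p=0.0,
                   rotation_max=0.0)


@dataclass(frozen=True)
class AugmentParams:
    dv: float
    dh: float
    zoom: float
    contrast: float
    brightness: float
    flip: bool
    rotation: float  # radians


def sample_augment_params(rng: np.random.Generator,
                          ranges: AugmentRanges = AugmentRanges()) -> AugmentParams:
    return AugmentParams(
        dv=float(rng.uniform(*ranges.vertical)),
        dh=float(rng.uniform(*ranges.horizontal)),
        zoom=float(rng.uniform(*ranges.zoom)),
        contrast=float(rng.uniform(*ranges.contrast)),
        brightness=float(rng.uniform(*ranges.brightness)),
        flip=bool(rng.random() < ranges.flip_p),
        rotation=float(rng.uniform(-ranges.rotation_max, ranges.rotation_max)),
    )


def augment(image: np.ndarray, box: BoundingBox, rng: np.random.Generator,
            ranges: AugmentRanges = AugmentRanges(),
            target: int = 450) -> StandardROI:
    """Randomly jittered, rotated, photometrically altered standardized ROI.

    With every interval collapsed (identity ranges) the output equals
    ``standardize_roi(image, box, target)``.
    """
    params = sample_augment_params(rng, ranges)
    return apply_augment(image, box, params, target)


def apply_augment(image: np.ndarray, box: BoundingBox, params: AugmentParams,
                  target: int = 450) -> StandardROI:
    image = np.asarray(image)
    h, w = image.shape
    cx, cy = (box.x0 + box.x1) / 2.0, (box.y0 + box.y1) / 2.0
    bw = box.width * (1.0 + params.dh) * (1.0 + params.zoom)
    bh = box.height * (1.0 + params.dv) * (1.0 + params.zoom)
    x0, x1 = int(round(cx - bw / 2)), int(round(cx + bw / 2))
    y0, y1 = int(round(cy - bh / 2)), int(round(cy + bh / 2))
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        logger.debug("augmented box %s clipped to image bounds", (x0, y0, x1, y1))
    x0, y0 = max(0, x0), max(0, y0)
    x1, y1 = min(w, max(x1, x0 + 2)), min(h, max(y1, y0 + 2))
    jittered = BoundingBox(x0, y0, x1, y1, confidence=box.confidence)

    work = image.astype(np.float32)
    if params.rotation != 0.0:
        work = sk_rotate(work, math.degrees(params.rotation), center=(cx, cy),
                         preserve_range=True, order=1).astype(np.float32)
    crop = work[y0:y1, x0:x1]
    crop = np.clip(crop * params.contrast + params.brightness, 0, 255)
    if params.flip:
        crop = crop[:, ::-1]
    roi = standardize_roi(crop, BoundingBox(0, 0, crop.shape[1], crop.shape[0]),
                          target=target)
    return StandardROI(pixels=roi.pixels, scale_factor=roi.scale_factor,
                       pad_offsets=roi.pad_offsets,
                       content_shape=roi.content_shape, source_box=jittered)


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------

def _roi_to_input(roi: StandardROI | np.ndarray, config: NetConfig) -> np.ndarray:
    px = roi.pixels if isinstance(roi, StandardROI) else np.asarray(roi)
    x = (px.astype(config.dtype) / 255.0) - 0.5
    return x[None, None, :, :]


def _labels_from_record(rec: dict, vocab: Vocabularies, mode: str) -> dict:
    spec = rec["spec"]
    lab = {}
    for name in SOFTMAX_HEADS:
        lab[name] = vocab.descriptor_values(name).index(spec[name])
    lab["suggestivity"] = vocab.suggestivity.index(spec["suggestivity"])
    lab["malignancy"] = int(bool(rec["malignant"]))
    ori = spec["orientation"]
    if ori == "none":
        lab["orientation_targets"] = (0.0, 0.0)
        lab["orientation_mask"] = 0.0 if mode == "mask" else 1.0
    else:
        lab["orientation_targets"] = (1.0, 0.0) if ori == "parallel" else (0.0, 1.0)
        lab["orientation_mask"] = 1.0
    return lab


def _stack_labels(labels: list[dict], dtype) -> dict:
    out: dict[str, np.ndarray] = {}
    for name in SOFTMAX_HEADS + ("suggestivity", "malignancy"):
        out[name] = np.array([l[name] for l in labels], dtype=np.int64)
    out["orientation_targets"] = np.array(
        [l["orientation_targets"] for l in labels], dtype=dtype)
    out["orientation_mask"] = np.array(
        [l["orientation_mask"] for l in labels], dtype=dtype)
    return out


def prepare_rois(manifest: dict, config: NetConfig,
                 ids: list[str] | None = None
                 ) -> tuple[np.ndarray, list[dict], list[tuple[int, int]]]:
    """Standardized ROI tensor, records and content shapes for a manifest."""
    wanted = set(ids) if ids is not None else None
    records = [r for r in manifest["records"]
               if wanted is None or r["image_id"] in wanted]
    if not records:
        raise InputError("no records selected from manifest")
    rois, content_shapes = [], []
    for rec in records:
        img = load_image(manifest, rec)
        box = BoundingBox(*rec["box"], confidence=1.0)
        roi = standardize_roi(img, box, target=config.input_size)
        rois.append(roi.pixels)
        content_shapes.append(roi.content_shape)
    x = (np.stack(rois).astype(config.dtype) / 255.0) - 0.5
    return x[:, None, :, :], records, content_shapes


def train(manifest: dict, config: NetConfig,
          vocab: Vocabularies = DEFAULT_VOCABULARIES,
          train_ids: list[str] | None = None,
          log_every: int = 0) -> tuple[DescriptorNet, list[dict]]:
    """Train on (a subset of) a manifest; returns (model, per-epoch history).

    Deterministic for a fixed config seed.  Minimizes the uniform sum of
    per-head cross-entropies (orientation: per-neuron binary cross-entropy;
    see config.orientation_none for the handling of unoriented nodules).
    """
    if not manifest.get("records"):
        raise InputError("empty manifest")
    x, records, content_shapes = prepare_rois(manifest, config, train_ids)
    for rec in records:
        for name in SOFTMAX_HEADS:
            if rec["spec"][name] not in vocab.descriptor_values(name):
                raise InputError(
                    f"label {rec['spec'][name]!r} not in {name} vocabulary")
    labels = _stack_labels(
        [_labels_from_record(r, vocab, config.orientation_none) for r in records],
        dtype=np.dtype(config.dtype).type)

    model = DescriptorNet(config, vocab)
    opt = Adam(model.layers(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    n = x.shape[0]
    history: list[dict] = []
    aug_source = None
    if config.augment:
        aug_source = [(load_image(manifest, r), BoundingBox(*r["box"])) for r in records]
    swa_state = None
    swa_count = 0
    decay_at = int(config.lr_decay_frac * config.epochs)
    for epoch in range(config.epochs):
        if epoch == decay_at and 0 < decay_at < config.epochs:
            opt.lr *= config.lr_decay
        order = rng.permutation(n)
        if aug_source is not None:
            x_ep = np.empty_like(x)
            for i in range(n):
                img, box = aug_source[i]
                roi = augment(img, box, rng, target=config.input_size)
                x_ep[i, 0] = (roi.pixels.astype(config.dtype) / 255.0) - 0.5
        else:
            x_ep = x
        if (config.hflip or config.jitter) and aug_source is None:
            # Cheap label-preserving augmentation: horizontal flips of the
            # content area and random placement of the content within the
            # zero padding (the standardization contract pins content to the
            # top-left only at inference).
            x_ep = x.copy()
            size = x.shape[-1]
            flips = rng.random(n) < 0.5
            for i in range(n):
                ch, cw = content_shapes[i]
                if config.hflip and flips[i]:
                    x_ep[i, 0, :, :cw] = x[i, 0, :, cw - 1::-1]
                if config.jitter and (size > ch or size > cw):
                    dy = int(rng.integers(0, size - ch + 1))
                    dx = int(rng.integers(0, size - cw + 1))
                    if dy or dx:
                        shifted = np.full_like(x_ep[i, 0], -0.5)
                        shifted[dy:dy + ch, dx:dx + cw] = x_ep[i, 0, :ch, :cw]
                        x_ep[i, 0] = shifted
        sums: dict[str, float] = {}
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch_labels = {k: v[idx] for k, v in labels.items()}
            losses = model.loss_and_backward(x_ep[idx], batch_labels)
            opt.step()
            for k, v in losses.items():
                sums[k] = sums.get(k, 0.0) + v
            n_batches += 1
        epoch_losses = {k: v / n_batches for k, v in sums.items()}
        history.append({"epoch": epoch, **epoch_losses})
        if log_every and epoch % log_every == 0:
            logger.info("epoch %d: total loss %.4f", epoch, epoch_losses["total"])
        if config.swa_frac > 0 and epoch >= math.ceil(
                (1.0 - config.swa_frac) * config.epochs) - 1:
            # running average of weights over the final epochs (stochastic
            # weight averaging): flatter optimum, less seed-to-seed noise
            if swa_state is None:
                swa_state = [{k: v.copy() for k, v in l.params.items()}
                             for l in model.layers()]
                swa_count = 1
            else:
                swa_count += 1
                for avg, layer in zip(swa_state, model.layers()):
                    for k, v in layer.params.items():
                        avg[k] += (v - avg[k]) / swa_count
    if swa_state is not None and swa_count > 1:
        for avg, layer in zip(swa_state, model.layers()):
            for k in layer.params:
                layer.params[k] = avg[k]
        # refresh batch-norm running statistics under the averaged weights
        for start in range(0, n, config.batch_size):
            idx = np.arange(start, min(start + config.batch_size, n))
            model.forward(x[idx], train=True)
    model.trained = True
    return model, history


def predict(model: DescriptorNet, roi: StandardROI
            ) -> tuple[DescriptorSet, float, np.ndarray]:
    """Descriptors, malignancy probability and upsampled attention map.

    The attention weights are reshaped to the g x g grid and bilinearly
    upsampled to the ROI size; values are preserved up to interpolation.
    """
    if not model.trained:
        raise ModelStateError("model has not been trained")
    x = _roi_to_input(roi, model.config)
    out = model.forward(x, train=False)
    probs = out["probs"]
    if model.config.tta and isinstance(roi, StandardROI):
        # average with the horizontally flipped content (label-preserving)
        xf = x.copy()
        cw = roi.content_shape[1]
        xf[0, 0, :, :cw] = x[0, 0, :, cw - 1::-1]
        out_f = model.forward(xf, train=False)
        probs = {k: (probs[k] + out_f["probs"][k]) / 2.0 for k in probs}
        out = {**out, "sugg": (out["sugg"] + out_f["sugg"]) / 2.0,
               "mal": (out["mal"] + out_f["mal"]) / 2.0}
    values: dict[str, str] = {}
    prob_tables: dict[str, dict[str, float]] = {}
    for name in HEAD_ORDER:
        table = dict(zip(model.head_values[name], probs[name][0].tolist()))
        prob_tables[name] = table
        if name == "orientation":
            values[name] = decide_orientation(probs[name][0], tau=model.config.tau)
        else:
            values[name] = max(table, key=table.get)
    sugg_table = dict(zip(model.vocab.suggestivity, out["sugg"][0].tolist()))
    prob_tables["suggestivity"] = sugg_table
    values["suggestivity"] = max(sugg_table, key=sugg_table.get)
    dset = DescriptorSet(**values, probabilities=prob_tables)
    g = model.config.grid
    size = roi.pixels.shape[0] if isinstance(roi, StandardROI) else model.config.input_size
    amap = resize(out["a"][0].reshape(g, g), (size, size), order=1,
                  anti_aliasing=False, preserve_range=True)
    return dset, float(out["mal"][0, 1]), amap


def export_attention_overlay(roi: StandardROI, attention_map: np.ndarray,
                             path) -> None:
    """Write the ROI with the attention map blended on top as a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(roi.pixels, cmap="gray", vmin=0, vmax=255)
    ax.imshow(attention_map, cmap="inferno", alpha=0.45)
    ax.set_axis_off()
    fig.tight_layout(pad=0)
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_model(model: DescriptorNet, path) -> None:
    """Single-file archive: parameters, BN statistics, embedded config."""
    arrays = {}
    for i, layer in enumerate(model.layers()):
        for k, v in layer.params.items():
            arrays[f"p{i}:{k}"] = v
    arrays["bn_mean"] = model.bn.running_mean
    arrays["bn_var"] = model.bn.running_var
    arrays["config"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    arrays["trained"] = np.array([int(model.trained)])
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path) -> DescriptorNet:
    with np.load(path) as data:
        cfg_raw = json.loads(bytes(data["config"]).decode())
        cfg_raw["stages"] = tuple(tuple(s) for s in cfg_raw["stages"])
        config = NetConfig(**cfg_raw)
        model = DescriptorNet(config)
        for i, layer in enumerate(model.layers()):
            for k in layer.params:
                layer.params[k] = data[f"p{i}:{k}"]
        model.bn.running_mean = data["bn_mean"]
        model.bn.running_var = data["bn_var"]
        model.trained = bool(data["trained"][0])
    return model
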