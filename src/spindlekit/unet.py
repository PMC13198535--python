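"""1-D U-Net spindle segmenter, loss, augmentation and training.

The segmenter treats spindle detection as per-sample segmentation of a single
preprocessed EEG channel: the network maps an input sequence of arbitrary
length to two equal-length score masks (spindle / non-spindle); the class of
each sample is the per-sample maximum, and maximal runs of spindle samples
become candidate events.

Architecture: a U-Net with two encoder and two decoder blocks (each block is
two same-padded convolutions with ReLU), max-pooling between encoder levels
and nearest-neighbour upsampling with skip concatenation on the way up.
Filter counts, kernel size and pooling factor are recorded in
:class:`UNetConfig`.

Training uses Adam with a generalized Dice loss (inverse-squared class
frequency weights, robust to the heavy spindle/background imbalance) and an
amplitude-rescaling augmentation: each training sample is randomly upscaled
(factor uniform in [1, 2]) or downscaled (factor uniform in [0.5, 1]) with a
fair coin choosing the branch, making the detector robust to amplitude-scale
differences between recordings.  Early stopping monitors the validation
IoU-F1 score.  Implemented in NumPy (CPU, float32); single-threaded runs are
bitwise reproducible per seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import Adam, Conv1d, MaxPool1d, ReLU, Upsample1d, softmax_channels
from .errors import ContractError, ParameterError
from .evaluation import iou_f1, match_events
from .io import Event, EventList
from .preprocessing import N2Block


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters (depth is fixed at 2 encoder/2 decoder)."""

    encoder_blocks: int = 2
    decoder_blocks: int = 2
    base_filters: int = 16
    kernel_size: int = 5
    pooling: int = 2

    def __post_init__(self):
        if self.encoder_blocks != 2 or self.decoder_blocks != 2:
            raise ParameterError("this U-Net has exactly 2 encoder/2 decoder blocks")
        if self.kernel_size % 2 != 1:
            raise ParameterError("kernel_size must be odd")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 12
    learning_rate: float = 0.005
    optimizer: str = "adam"
    patience: int = 300
    max_epochs: int = 800
    upscale_range: tuple[float, float] = (1.0, 2.0)
    downscale_range: tuple[float, float] = (0.5, 1.0)
    val_fraction: float = 0.1
    min_iou: float = 0.2
    seed: int = 0


class SpindleUNet:
    """1-D U-Net mapping (B, 1, L) inputs to (B, 2, L) segmentation scores."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        f, k, p = config.base_filters, config.kernel_size, config.pooling
        c = lambda ci, co, kk=k: Conv1d(ci, co, kk, rng)
        self.enc1 = [c(1, f), ReLU(), c(f, f), ReLU()]
        self.pool1 = MaxPool1d(p)
        self.enc2 = [c(f, 2 * f), ReLU(), c(2 * f, 2 * f), ReLU()]
        self.pool2 = MaxPool1d(p)
        self.bott = [c(2 * f, 4 * f), ReLU(), c(4 * f, 4 * f), ReLU()]
        self.up2 = Upsample1d(p)
        self.dec2 = [c(6 * f, 2 * f), ReLU(), c(2 * f, 2 * f), ReLU()]
        self.up1 = Upsample1d(p)
        self.dec1 = [c(3 * f, f), ReLU(), c(f, f), ReLU()]
        self.head = c(f, 2, 1)
        self._blocks = (self.enc1 + self.enc2 + self.bott + self.dec2
                        + self.dec1 + [self.head])

    # -- parameter plumbing -------------------------------------------------
    def parameters(self):
        out = []
        for layer in self._blocks:
            out.extend(layer.parameters())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ContractError("weight list does not match architecture")
        for (p, _), w in zip(params, weights):
            p[...] = w

    @property
    def min_input_length(self) -> int:
        return self.config.pooling ** 2

    # -- forward / backward -------------------------------------------------
    def _run(self, layers, x, train):
        for layer in layers:
            x = layer.forward(x, train=train)
        return x

    def _run_back(self, layers, dy):
        for layer in reversed(layers):
            dy = layer.backward(dy)
        return dy

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits of shape (B, 2, L) for inputs of shape (B, 1, L)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[1] != 1:
            raise ContractError(f"expected (batch, 1, length) input, got {x.shape}")
        n = x.shape[2]
        unit = self.config.pooling ** 2
        if n < self.min_input_length:
            raise ParameterError(
                f"input length {n} below the minimum of {self.min_input_length}"
            )
        pad = (-n) % unit
        if pad:
            x = np.pad(x, ((0, 0), (0, 0), (0, pad)))
        self._pad = pad
        s1 = self._run(self.enc1, x, train)
        s2 = self._run(self.enc2, self.pool1.forward(s1, train), train)
        b = self._run(self.bott, self.pool2.forward(s2, train), train)
        u2 = np.concatenate([self.up2.forward(b, train), s2], axis=1)
        d2 = self._run(self.dec2, u2, train)
        u1 = np.concatenate([self.up1.forward(d2, train), s1], axis=1)
        d1 = self._run(self.dec1, u1, train)
        z = self.head.forward(d1, train)
        self._f = self.config.base_filters
        return z[:, :, : n] if pad else z

    def backward(self, dz: np.ndarray) -> None:
        if self._pad:
            dz = np.pad(dz, ((0, 0), (0, 0), (0, self._pad)))
        f = self._f
        d1 = self.head.backward(dz.astype(np.float32))
        du1 = self._run_back(self.dec1, d1)
        dd2 = self.up1.backward(du1[:, : 2 * f])
        ds1 = du1[:, 2 * f:]
        du2 = self._run_back(self.dec2, dd2)
        db = self.up2.backward(du2[:, : 4 * f])
        ds2 = du2[:, 4 * f:]
        dp2 = self._run_back(self.bott, db)
        ds2 = ds2 + self.pool2.backward(dp2)
        dp1 = self._run_back(self.enc2, ds2)
        ds1 = ds1 + self.pool1.backward(dp1)
        self._run_back(self.enc1, ds1)

    def predict_masks(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (B, 2, L) without caching activations."""
        return softmax_channels(self.forward(x, train=False))


def build_unet(config: UNetConfig | None = None, seed: int = 0) -> SpindleUNet:
    """Construct a seeded U-Net; identical seeds give identical weights."""
    return SpindleUNet(config or UNetConfig(), seed=seed)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

GDL_EPS = 1e-6


def _gdl(probs, target, sample_mask=None):
    """Generalized Dice loss and its gradient w.r.t. the probabilities."""
    if probs.shape != target.shape:
        raise ContractError(f"shape mismatch {probs.shape} vs {target.shape}")
    p = probs.astype(np.float64)
    t = target.astype(np.float64)
    if sample_mask is not None:
        m = sample_mask.astype(np.float64)[:, None, :]
        p = p * m
        t = t * m
    w = 1.0 / (t.sum(axis=(0, 2)) + GDL_EPS) ** 2  # (C,)
    inter = (p * t).sum(axis=(0, 2))
    total = (p + t).sum(axis=(0, 2))
    num = (w * inter).sum()
    den = (w * total).sum()
    if den == 0:  # no mass in either prediction or target (empty batch)
        return 0.0, np.zeros_like(p)
    loss = 1.0 - 2.0 * num / den
    # d/dp of -2*num/den, treating the class weights as constants
    dp = -2.0 * (w[None, :, None] * t * den - num * w[None, :, None]) / den ** 2
    if sample_mask is not None:
        dp = dp * sample_mask[:, None, :]
    return float(loss), dp


def generalized_dice_loss(masks: np.ndarray, target_masks: np.ndarray,
                          sample_mask: np.ndarray | None = None) -> float:
    """Generalized Dice loss in [0, 1]; weights w_c = 1/(Σ target_c + ε)²."""
    loss, _ = _gdl(np.asarray(masks), np.asarray(target_masks), sample_mask)
    return loss


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def amplitude_augment(
    block: np.ndarray,
    rng: np.random.Generator,
    upscale_range: tuple[float, float] = (1.0, 2.0),
    downscale_range: tuple[float, float] = (0.5, 1.0),
) -> np.ndarray:
    """Randomly rescale amplitudes: fair coin, then c~U(1,2) or c~U(0.5,1)."""
    lo, hi = upscale_range if rng.random() < 0.5 else downscale_range
    c = rng.uniform(lo, hi)
    return np.asarray(block) * c


# ---------------------------------------------------------------------------
# Mask <-> event conversion
# ---------------------------------------------------------------------------

def masks_to_events(masks: np.ndarray, fs: float, channel: str = "merged",
                    scorer: str = "") -> EventList:
    """Join maximal runs of spindle-class samples into events.

    Accepts either a per-sample class array (1 = spindle) or a (2, L) score
    array where a sample is spindle-class when the first mask attains the
    per-sample maximum (ties resolve to non-spindle).
    """
    masks = np.asarray(masks)
    if masks.ndim == 2:
        if masks.shape[0] != 2:
            raise ContractError(f"expected (2, L) masks, got {masks.shape}")
        cls = masks[0] > masks[1]
    elif masks.ndim == 1:
        cls = masks.astype(bool)
    else:
        raise ContractError(f"expected 1-D classes or (2, L) masks, got {masks.shape}")
    padded = np.concatenate([[False], cls, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    events = [
        Event(s / fs, (e - s) / fs, channel, scorer) for s, e in zip(starts, ends)
    ]
    return EventList(events)


def events_to_masks(events: EventList, n_samples: int, fs: float) -> np.ndarray:
    """One-hot (2, n_samples) target masks; row 0 = spindle, row 1 = rest."""
    spindle = np.zeros(n_samples, dtype=np.float32)
    for e in events:
        i0 = max(0, int(round(e.onset_s * fs)))
        i1 = min(n_samples, int(round(e.offset_s * fs)))
        spindle[i0:i1] = 1.0
    return np.stack([spindle, 1.0 - spindle])


def detect_spindles(model: SpindleUNet, blocks: Sequence[N2Block]) -> EventList:
    """Segment each N2 block and report raw events in recording time."""
    events: list[Event] = []
    for blk in blocks:
        probs = model.predict_masks(blk.samples[None, None, :])[0]
        for e in masks_to_events(probs, blk.fs, channel=blk.source_channel):
            events.append(Event(e.onset_s + blk.start_s, e.duration_s,
                                blk.source_channel))
    return EventList(events).sorted()


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _batch_arrays(xs: list[np.ndarray], targets: list[np.ndarray], unit: int):
    max_len = max(len(x) for x in xs)
    max_len += (-max_len) % unit
    b = len(xs)
    x = np.zeros((b, 1, max_len), dtype=np.float32)
    t = np.zeros((b, 2, max_len), dtype=np.float32)
    m = np.zeros((b, max_len), dtype=np.float32)
    for i, (xi, ti) in enumerate(zip(xs, targets)):
        n = len(xi)
        x[i, 0, :n] = xi
        t[i, :, :n] = ti
        m[i, :n] = 1.0
    return x, t, m


def _validation_iou_f1(model: SpindleUNet, blocks, truths, fs: float,
                       min_iou: float) -> float:
    tp = fp = fn = 0
    for x, truth in zip(blocks, truths):
        probs = model.predict_masks(np.asarray(x, dtype=np.float32)[None, None, :])[0]
        detected = masks_to_events(probs, fs)
        counts = match_events(detected, truth, min_iou=min_iou)
        tp += counts.tp
        fp += counts.fp
        fn += counts.fn
    if tp + fp + fn == 0:  # nothing annotated, nothing detected
        return 1.0
    return iou_f1(tp=tp, fp=fp, fn=fn)


def train(
    model: SpindleUNet,
    blocks: Sequence[np.ndarray],
    labels: Sequence[EventList],
    config: TrainConfig | None = None,
    fs: float = 100.0,
) -> tuple[SpindleUNet, list[dict]]:
    """Train the segmenter with early stopping on validation IoU-F1.

    ``blocks`` are preprocessed 1-D sample arrays; ``labels`` are the
    corresponding ground-truth events in block-local seconds.  The last
    ``val_fraction`` of a seeded shuffle is held out for early stopping; the
    returned model carries the weights of the best validation epoch, and the
    history records per-epoch training loss and validation IoU-F1.
    """
    config = config or TrainConfig()
    if len(blocks) != len(labels):
        raise ContractError("blocks and labels must pair up")
    n_val = int(round(config.val_fraction * len(blocks)))
    if n_val < 1:
        raise ParameterError(
            f"validation split is empty ({len(blocks)} blocks at "
            f"val_fraction={config.val_fraction})"
        )
    if len(blocks) - n_val < 1:
        raise ParameterError("no training blocks left after the validation split")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(blocks))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    targets = [
        events_to_masks(labels[i], len(blocks[i]), fs) for i in range(len(blocks))
    ]
    val_blocks = [np.asarray(blocks[i], dtype=np.float32) for i in val_idx]
    val_truths = [labels[i] for i in val_idx]
    opt = Adam(model.parameters(), lr=config.learning_rate)
    unit = model.config.pooling ** 2

    best_score = -np.inf
    best_weights = model.get_weights()
    since_best = 0
    history: list[dict] = []
    for epoch in range(1, config.max_epochs + 1):
        order = train_idx[rng.permutation(len(train_idx))]
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start: start + config.batch_size]
            xs = [
                amplitude_augment(blocks[i], rng, config.upscale_range,
                                  config.downscale_range).astype(np.float32)
                for i in batch
            ]
            ts = [targets[i] for i in batch]
            x, t, m = _batch_arrays(xs, ts, unit)
            z = model.forward(x, train=True)
            probs = softmax_channels(z)
            loss, dp = _gdl(probs, t, m)
            # softmax Jacobian: dL/dz = p * (dL/dp - sum_c p_c dL/dp_c)
            dz = probs * (dp - (probs * dp).sum(axis=1, keepdims=True))
            opt.zero_grad()
            model.backward(dz.astype(np.float32))
            opt.step()
            losses.append(loss)
        val_score = _validation_iou_f1(model, val_blocks, val_truths, fs,
                                       config.min_iou)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "val_iou_f1": val_score})
        if val_score > best_score:
            best_score = val_score
            best_weights = model.get_weights()
            since_best = 0
        else:
            if val_score == best_score:
                # among equally good epochs keep the most-trained weights
                best_weights = model.get_weights()
            since_best += 1
        if since_best >= config.patience:
            break
    model.set_weights(best_weights)
    return model, history


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: SpindleUNet, path: str | Path) -> None:
    """Single-file checkpoint: serialized weights plus embedded UNetConfig."""
    arrays = {f"w{i}": p for i, (p, _) in enumerate(model.parameters())}
    np.savez(path, _config=json.dumps(asdict(model.config)), **arrays)


def load_checkpoint(path: str | Path) -> SpindleUNet:
    data = np.load(path, allow_pickle=False)
    config = UNetConfig(**json.loads(str(data["_config"])))
    model = SpindleUNet(config, seed=0)
    model.set_weights([data[f"w{i}"] for i in range(len(model.parameters()))])
    return model
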