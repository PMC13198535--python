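"""Inference scaffolding around per-epoch sleep-stage predictors.

A stage predictor is any callable mapping a 21-epoch multichannel window
(array of shape ``(n_channels, 21 * 1800)`` at 60 Hz) to a ``(21, 5)`` matrix
of stage probabilities (columns ordered W, N1, N2, N3, REM).  Pre-trained
networks plug in behind this contract; a simple trainable spectral baseline
(band-power features + multinomial logistic regression) is provided so the
whole pipeline can be exercised without external checkpoints.

The scaffolding mirrors common practice for sequence-context stagers: the
preprocessed recording is buffered with 20 zero epochs at each end, a 21-epoch
window slides with step 1, so every real epoch is covered by exactly 21
windows; the 21 per-window probabilities for an epoch are combined by their
geometric mean and renormalized.
"""

from __future__ import annotations

from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import signal as sps
from sklearn.linear_model import LogisticRegression

from .errors import ContractError, EmptyInputError, ParameterError
from .io import Hypnogram, Recording, STAGES
from .preprocessing import STAGING_FS, preprocess_recording_for_staging

EPOCH_SAMPLES = int(30 * STAGING_FS)  # 1800 samples per epoch at 60 Hz
WINDOW_EPOCHS = 21
BUFFER_EPOCHS = 20
PROB_FLOOR = 1e-12

#: (low, high) Hz of the spectral features used by the baseline predictor.
FEATURE_BANDS = ((0.5, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 16.0), (16.0, 30.0))


class StagePredictor(Protocol):
    def __call__(self, window: np.ndarray) -> np.ndarray: ...


def validate_epoch_probabilities(probs: np.ndarray, n_epochs: int | None = None):
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2 or probs.shape[1] != 5:
        raise ContractError(f"expected (n_epochs, 5) probabilities, got {probs.shape}")
    if n_epochs is not None and probs.shape[0] != n_epochs:
        raise ContractError(
            f"expected {n_epochs} rows of probabilities, got {probs.shape[0]}"
        )
    if np.any(probs < 0):
        raise ContractError("stage probabilities must be nonnegative")
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ContractError("stage probability rows must sum to 1")
    return probs


def make_windows(preprocessed: np.ndarray) -> np.ndarray:
    """Zero-buffer and window a preprocessed recording.

    Parameters
    ----------
    preprocessed : array (n_channels, n_epochs * 1800) at 60 Hz.

    Returns
    -------
    array view of shape ``(n_epochs + 20, n_channels, 21 * 1800)``: one
    21-epoch window per step-1 slide over the recording buffered with 20 zero
    epochs at each end.  Every real epoch appears in exactly 21 windows.
    """
    preprocessed = np.atleast_2d(np.asarray(preprocessed))
    n_channels, n = preprocessed.shape
    if n % EPOCH_SAMPLES != 0:
        raise ParameterError(
            f"signal length {n} is not a whole number of 30-s epochs at 60 Hz"
        )
    n_epochs = n // EPOCH_SAMPLES
    if n_epochs == 0:
        raise EmptyInputError("recording contains no whole epochs")
    pad = BUFFER_EPOCHS * EPOCH_SAMPLES
    buffered = np.pad(preprocessed, ((0, 0), (pad, pad)))
    view = np.lib.stride_tricks.sliding_window_view(
        buffered, WINDOW_EPOCHS * EPOCH_SAMPLES, axis=1
    )  # (C, n_positions, window)
    windows = view[:, ::EPOCH_SAMPLES, :]  # step of one epoch
    return np.swapaxes(windows, 0, 1)  # (n_windows, C, window)


def aggregate_geometric_mean(per_window_probs: np.ndarray) -> np.ndarray:
    """Combine per-window probabilities into per-epoch probabilities.

    ``per_window_probs`` has shape ``(n_epochs + 20, 21, 5)``: row ``w``
    holds the predictor output for the window starting at buffered epoch
    ``w``.  Real epoch ``r`` appears at position ``r + 20 - w`` of windows
    ``w = r .. r + 20``; its 21 probability vectors are combined by the
    per-stage geometric mean (zeros floored at 1e-12 before the log) and
    renormalized to sum 1.
    """
    per_window_probs = np.asarray(per_window_probs, dtype=np.float64)
    if per_window_probs.ndim != 3 or per_window_probs.shape[1:] != (WINDOW_EPOCHS, 5):
        raise ContractError(
            f"expected (n_windows, 21, 5) probabilities, got {per_window_probs.shape}"
        )
    n_windows = per_window_probs.shape[0]
    n_epochs = n_windows - BUFFER_EPOCHS
    if n_epochs < 1:
        raise ContractError("fewer windows than the buffering scheme implies")
    logs = np.log(np.maximum(per_window_probs, PROB_FLOOR))
    out = np.empty((n_epochs, 5))
    for r in range(n_epochs):
        w = np.arange(r, r + WINDOW_EPOCHS)
        pos = r + BUFFER_EPOCHS - w
        out[r] = np.exp(logs[w, pos].mean(axis=0))
    out /= out.sum(axis=1, keepdims=True)
    return out


def predict_probabilities(
    preprocessed: np.ndarray, predictor: Callable[[np.ndarray], np.ndarray]
) -> np.ndarray:
    """Run a stage predictor over all windows and aggregate per epoch."""
    windows = make_windows(preprocessed)
    per_window = np.empty((windows.shape[0], WINDOW_EPOCHS, 5))
    for w in range(windows.shape[0]):
        per_window[w] = validate_epoch_probabilities(
            predictor(windows[w]), WINDOW_EPOCHS
        )
    return aggregate_geometric_mean(per_window)


def probabilities_to_hypnogram(probs: np.ndarray) -> Hypnogram:
    """Argmax per epoch; ties break toward the earlier stage (W<N1<N2<N3<REM)."""
    probs = validate_epoch_probabilities(probs)
    return Hypnogram([STAGES[i] for i in np.argmax(probs, axis=1)])


def stage_recording(
    recording: Recording, predictor: Callable[[np.ndarray], np.ndarray]
) -> tuple[Hypnogram, np.ndarray]:
    """Full staging pass: preprocess, window, predict, aggregate, argmax."""
    pre = preprocess_recording_for_staging(recording)
    probs = predict_probabilities(pre, predictor)
    return probabilities_to_hypnogram(probs), probs


# ---------------------------------------------------------------------------
# Trainable spectral baseline predictor
# ---------------------------------------------------------------------------

def _epoch_features(epochs: np.ndarray) -> np.ndarray:
    """Log band-power features per epoch.

    ``epochs``: array (n_epochs, n_channels, 1800).  Band powers are computed
    with Welch's method per channel, log-transformed and averaged across
    channels, yielding one 5-vector per epoch (delta/theta/alpha/sigma/beta).
    """
    n_epochs, n_channels, n = epochs.shape
    freqs, psd = sps.welch(epochs, fs=STAGING_FS, nperseg=min(256, n), axis=-1)
    feats = np.empty((n_epochs, n_channels, len(FEATURE_BANDS)))
    for b, (lo, hi) in enumerate(FEATURE_BANDS):
        sel = (freqs >= lo) & (freqs < hi)
        feats[..., b] = np.log10(psd[..., sel].mean(axis=-1) + 1e-12)
    return feats.mean(axis=1)


def _split_epochs(preprocessed: np.ndarray) -> np.ndarray:
    c, n = np.atleast_2d(preprocessed).shape
    n_epochs = n // EPOCH_SAMPLES
    arr = np.atleast_2d(preprocessed)[:, : n_epochs * EPOCH_SAMPLES]
    return np.swapaxes(arr.reshape(c, n_epochs, EPOCH_SAMPLES), 0, 1)


class BaselineStagePredictor:
    """Band-power + multinomial logistic-regression stage predictor.

    Satisfies the stage-predictor contract: accepts any channel count and is
    deterministic for fixed fitted coefficients.  Intended as a lightweight
    stand-in for pre-trained staging networks when exercising the pipeline.
    """

    def __init__(self, classifier: LogisticRegression, classes: list[str]):
        self._clf = classifier
        self._classes = classes

    def __call__(self, window: np.ndarray) -> np.ndarray:
        epochs = _split_epochs(window)
        feats = _epoch_features(epochs)
        partial = self._clf.predict_proba(feats)
        probs = np.full((feats.shape[0], 5), PROB_FLOOR)
        for j, stage in enumerate(self._classes):
            probs[:, STAGES.index(stage)] = partial[:, j]
        return probs / probs.sum(axis=1, keepdims=True)


def baseline_predictor_train(
    recordings: Sequence[Recording],
    hypnograms: Sequence[Hypnogram],
    seed: int = 0,
) -> BaselineStagePredictor:
    """Fit the spectral baseline on (recording, hypnogram) pairs."""
    if len(recordings) < 2:
        raise ParameterError("need at least 2 recordings to train the baseline")
    if len(recordings) != len(hypnograms):
        raise ContractError("recordings and hypnograms must pair up")
    feats, labels = [], []
    for rec, hyp in zip(recordings, hypnograms):
        pre = preprocess_recording_for_staging(rec)
        epochs = _split_epochs(pre)
        n = min(epochs.shape[0], len(hyp))
        feats.append(_epoch_features(epochs[:n]))
        labels.extend(hyp.labels[:n])
    x = np.concatenate(feats)
    y = np.array(labels)
    present = sorted(set(y), key=STAGES.index)
    if len(present) < 2:
        raise ParameterError(
            f"training labels contain a single stage ({present}); "
            "the baseline needs at least two"
        )
    clf = LogisticRegression(max_iter=1000, random_state=seed)
    clf.fit(x, y)
    classes = list(clf.classes_)
    return BaselineStagePredictor(clf, classes)


def constant_predictor(probs: Sequence[float]) -> Callable[[np.ndarray], np.ndarray]:
    """Predictor that returns the same probability vector for every epoch."""
    vec = np.asarray(probs, dtype=np.float64)
    vec = vec / vec.sum()

    def predict(window: np.ndarray) -> np.ndarray:
        return np.tile(vec, (WINDOW_EPOCHS, 1))

    return predict
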