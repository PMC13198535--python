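"""Signal preprocessing chains for staging and spindle detection.

Two chains are used:

* staging chain (whole recording, per channel): 4th-order Butterworth
  band-pass 0.3–30 Hz → resample to 60 Hz → robust normalization (median/IQR)
  with clipping at ±20.
* spindle chain (per contiguous N2 block): 20th-order Butterworth high-pass
  at 0.3 Hz → 20th-order low-pass at 30 Hz → resample to 100 Hz → robust
  normalization with clipping at ±20.

All filters are applied zero-phase (forward-backward, second-order sections)
so that event timing is not phase-shifted; the stated design order refers to
the one-way design, so effective attenuation is doubled.  Normalization is
computed per N2 block for the spindle chain and per whole recording for the
staging chain, mirroring each model's input unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import DegenerateSignalError, ParameterError
from .io import Hypnogram, Recording

#: Default parameters of the two chains (overridable via config files).
DEFAULT_CONFIG = {
    "staging": {"filter": {"order": 4, "band": [0.3, 30.0]}, "fs": 60.0},
    "spindle": {
        "hp": {"order": 20, "cutoff": 0.3},
        "lp": {"order": 20, "cutoff": 30.0},
        "fs": 100.0,
    },
    "clip": 20.0,
}


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter specification (one-way design order)."""

    kind: str  # highpass | lowpass | bandpass
    order: int
    cutoffs: tuple[float, ...]

    def __post_init__(self):
        if self.kind not in {"highpass", "lowpass", "bandpass"}:
            raise ParameterError(f"unknown filter kind {self.kind!r}")
        n = 2 if self.kind == "bandpass" else 1
        if len(self.cutoffs) != n:
            raise ParameterError(
                f"{self.kind} filter needs {n} cutoff(s), got {self.cutoffs}"
            )
        if any(c <= 0 for c in self.cutoffs):
            raise ParameterError("cutoffs must be positive")


STAGING_BANDPASS = FilterSpec("bandpass", 4, (0.3, 30.0))
SPINDLE_HIGHPASS = FilterSpec("highpass", 20, (0.3,))
SPINDLE_LOWPASS = FilterSpec("lowpass", 20, (30.0,))
SIGMA_BANDPASS = FilterSpec("bandpass", 4, (10.0, 16.0))

STAGING_FS = 60.0
SPINDLE_FS = 100.0
CLIP = 20.0


def butterworth_filter(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Zero-phase Butterworth filter via second-order sections.

    SOS realization keeps high-order designs (order 20) numerically stable;
    the result is checked for NaN/Inf and never returned silently corrupted.
    """
    nyq = fs / 2.0
    if any(c >= nyq for c in spec.cutoffs):
        raise ParameterError(
            f"cutoff(s) {spec.cutoffs} must be below Nyquist ({nyq} Hz)"
        )
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ParameterError("expected a 1-D signal")
    if len(x) <= 3 * spec.order:
        raise ParameterError(
            f"signal length {len(x)} too short for order-{spec.order} filter"
        )
    wn = spec.cutoffs[0] / nyq if len(spec.cutoffs) == 1 else [
        c / nyq for c in spec.cutoffs
    ]
    sos = sps.butter(spec.order, wn, btype=spec.kind, output="sos")
    y = sps.sosfiltfilt(sos, x)
    if not np.all(np.isfinite(y)):
        raise DegenerateSignalError(
            f"order-{spec.order} {spec.kind} filter produced non-finite output"
        )
    return y


def resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase FIR downsampling; output length = round(n * fs_out / fs_in).

    Upsampling is rejected: both pipelines only ever reduce the rate, and the
    preceding explicit low-pass already band-limits the signal.
    """
    if fs_out > fs_in:
        raise ParameterError(
            f"this pipeline only downsamples (fs_in={fs_in}, fs_out={fs_out})"
        )
    x = np.asarray(x, dtype=np.float64)
    if fs_out == fs_in:
        return x.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator)
    n_target = int(round(len(x) * fs_out / fs_in))
    if len(y) > n_target:
        y = y[:n_target]
    elif len(y) < n_target:
        y = np.pad(y, (0, n_target - len(y)), mode="edge")
    return y


def robust_normalize(x: np.ndarray, clip: float = CLIP) -> np.ndarray:
    """Subtract the median, divide by the IQR, clip to ±clip.

    Quartiles use linear interpolation (NumPy's default, the type-7
    convention).  A zero IQR means the signal is (near-)constant and cannot
    be normalized.
    """
    x = np.asarray(x, dtype=np.float64)
    q1, med, q3 = np.percentile(x, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    if iqr == 0:
        raise DegenerateSignalError("IQR is zero; cannot robust-normalize")
    return np.clip((x - med) / iqr, -clip, clip)


@dataclass
class N2Block:
    """A contiguous run of N2 epochs, preprocessed for spindle detection."""

    samples: np.ndarray
    fs: float
    start_s: float
    source_channel: str

    def __post_init__(self):
        if self.start_s % 30.0 != 0:
            raise ParameterError("N2 block must start on an epoch boundary")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


def spindle_chain(x: np.ndarray, fs: float, clip: float = CLIP) -> np.ndarray:
    """Apply the full spindle preprocessing chain to one raw block."""
    y = butterworth_filter(x, SPINDLE_HIGHPASS, fs)
    y = butterworth_filter(y, SPINDLE_LOWPASS, fs)
    y = resample(y, fs, SPINDLE_FS)
    return robust_normalize(y, clip=clip)


def staging_chain(x: np.ndarray, fs: float, clip: float = CLIP) -> np.ndarray:
    """Apply the full staging preprocessing chain to one whole channel."""
    y = butterworth_filter(x, STAGING_BANDPASS, fs)
    y = resample(y, fs, STAGING_FS)
    return robust_normalize(y, clip=clip)


def extract_n2_blocks(
    signal: np.ndarray,
    fs: float,
    hypnogram: Hypnogram,
    channel: str = "",
    preprocess: bool = True,
) -> list[N2Block]:
    """Cut the maximal contiguous N2 runs out of one raw channel.

    Returns one :class:`N2Block` per run, each carrying its offset in
    recording time so detections inside a block can be reported in original
    coordinates.  With ``preprocess=True`` (default) each block is passed
    through the spindle chain (HP → LP → 100 Hz → robust normalization).
    An empty list (no N2 sleep) is a valid result, not an error.
    """
    n_whole = int(len(signal) / fs // 30.0)
    usable_epochs = min(n_whole, len(hypnogram))
    blocks: list[N2Block] = []
    for start_ep, end_ep in hypnogram.runs("N2"):
        end_ep = min(end_ep, usable_epochs)
        if end_ep <= start_ep:
            continue
        i0 = int(round(start_ep * 30.0 * fs))
        i1 = int(round(end_ep * 30.0 * fs))
        raw = np.asarray(signal[i0:i1], dtype=np.float64)
        if preprocess:
            samples = spindle_chain(raw, fs)
            out_fs = SPINDLE_FS
        else:
            samples = raw
            out_fs = fs
        blocks.append(
            N2Block(samples=samples, fs=out_fs, start_s=start_ep * 30.0,
                    source_channel=channel)
        )
    return blocks


def preprocess_recording_for_staging(recording: Recording) -> np.ndarray:
    """Staging chain on every channel; returns array (n_channels, n_samples).

    Channels are processed at their native rate, resampled to a common 60 Hz
    and truncated to whole 30-s epochs, so mixed-rate recordings align.
    """
    processed = [staging_chain(sig, f) for sig, f in
                 zip(recording.signals, recording.fs)]
    n = min(len(p) for p in processed)
    n_epochs = int(n / STAGING_FS // 30.0)
    n = int(n_epochs * 30 * STAGING_FS)
    return np.stack([p[:n] for p in processed])
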