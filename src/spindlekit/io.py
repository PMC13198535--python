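"""Domain containers and file I/O for recordings, hypnograms and spindle events.

Conventions used throughout the package:

* Event times are float seconds from recording start, as half-open intervals
  ``[onset, onset + duration)``; this makes interval overlap arithmetic
  unambiguous (touching events do not overlap).
* Epochs are 30 s, 0-based: epoch *i* covers ``[30*i, 30*(i+1))`` seconds.
  A recording whose length is not a multiple of 30 s has its trailing partial
  epoch truncated.
* Amplitudes are microvolts.

Signals travel in EDF/EDF+ files.  EDF stores each channel with its own
samples-per-record count, so mixed sampling rates (e.g. 100/200/500 Hz EEG
channels in one polysomnogram) are legal and must be preserved per channel;
the reader here keeps the native rate of every channel.  Hypnograms are plain
text (one stage label per line) or two-column CSV; events are CSV with header
``onset_s,duration_s,channel,scorer``.
"""

from __future__ import annotations

import io as _io
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    FormatError,
    ParameterError,
    ValidationError,
)

STAGES = ("W", "N1", "N2", "N3", "REM")
EPOCH_S = 30.0

#: Documented alias table for hypnogram labels (matched case-insensitively).
STAGE_ALIASES = {
    "W": "W", "WAKE": "W", "WK": "W",
    "N1": "N1", "S1": "N1", "1": "N1",
    "N2": "N2", "S2": "N2", "2": "N2",
    "N3": "N3", "S3": "N3", "S4": "N3", "3": "N3", "4": "N3", "SWS": "N3",
    "REM": "REM", "R": "REM", "5": "REM",
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    """One annotated event: half-open interval [onset_s, onset_s+duration_s)."""

    onset_s: float
    duration_s: float
    channel: str = "merged"
    scorer: str = ""

    def __post_init__(self):
        if self.onset_s < 0:
            raise ValidationError(f"event onset must be >= 0, got {self.onset_s}")
        if self.duration_s <= 0:
            raise ValidationError(
                f"event duration must be > 0, got {self.duration_s}"
            )

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s

    @property
    def midpoint_s(self) -> float:
        return self.onset_s + 0.5 * self.duration_s


@dataclass
class EventList:
    """A collection of events, sortable by onset.

    Within one (channel, scorer) pair events are expected to be
    non-overlapping after postprocessing; this is validated lazily by the
    operations that require it, not at construction.
    """

    events: list[Event] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def sorted(self) -> "EventList":
        return EventList(sorted(self.events, key=lambda e: (e.onset_s, e.offset_s)))

    def for_channel(self, channel: str) -> "EventList":
        return EventList([e for e in self.events if e.channel == channel])

    def for_scorer(self, scorer: str) -> "EventList":
        return EventList([e for e in self.events if e.scorer == scorer])

    @property
    def channels(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.events:
            seen.setdefault(e.channel)
        return list(seen)

    def intervals(self) -> np.ndarray:
        """(n, 2) array of [onset, offset) pairs in onset order."""
        if not self.events:
            return np.empty((0, 2))
        ev = self.sorted()
        return np.array([[e.onset_s, e.offset_s] for e in ev])


@dataclass
class Hypnogram:
    """Ordered sequence of 30-s sleep-stage labels (W, N1, N2, N3, REM)."""

    labels: list[str]
    epoch_s: float = EPOCH_S

    def __post_init__(self):
        if len(self.labels) < 1:
            raise ValidationError("hypnogram must contain at least one epoch")
        bad = [l for l in self.labels if l not in STAGES]
        if bad:
            raise ValidationError(f"unknown stage labels: {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Hypnogram)
            and self.labels == other.labels
            and self.epoch_s == other.epoch_s
        )

    def duration_s(self, stage: str | None = None) -> float:
        if stage is None:
            return len(self.labels) * self.epoch_s
        return self.labels.count(stage) * self.epoch_s

    def stage_at(self, t_s: float) -> str:
        idx = int(t_s // self.epoch_s)
        if not 0 <= idx < len(self.labels):
            raise ParameterError(f"time {t_s} s outside hypnogram")
        return self.labels[idx]

    def runs(self, stage: str) -> list[tuple[int, int]]:
        """Maximal runs of `stage` as half-open epoch index ranges."""
        out: list[tuple[int, int]] = []
        start = None
        for i, lab in enumerate(self.labels):
            if lab == stage and start is None:
                start = i
            elif lab != stage and start is not None:
                out.append((start, i))
                start = None
        if start is not None:
            out.append((start, len(self.labels)))
        return out


@dataclass
class Recording:
    """Multichannel sampled signal with per-channel sampling rates (µV)."""

    channels: list[str]
    signals: list[np.ndarray]
    fs: list[float]

    def __post_init__(self):
        if len(self.channels) != len(self.signals) or len(self.channels) != len(self.fs):
            raise ValidationError("channels, signals and fs must have equal length")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel labels must be unique")
        if any(f <= 0 for f in self.fs):
            raise ValidationError("sampling rates must be positive")
        durs = [len(s) / f for s, f in zip(self.signals, self.fs)]
        if durs and (max(durs) - min(durs)) > max(1.0 / min(self.fs), 1e-9):
            raise ValidationError(
                f"channel durations disagree beyond one sample: {durs}"
            )

    @property
    def duration_s(self) -> float:
        return len(self.signals[0]) / self.fs[0] if self.signals else 0.0

    @property
    def n_epochs(self) -> int:
        """Number of whole 30-s epochs (trailing partial epoch truncated)."""
        return int(self.duration_s // EPOCH_S)

    def channel(self, label: str) -> tuple[np.ndarray, float]:
        try:
            i = self.channels.index(label)
        except ValueError:
            raise ParameterError(f"channel {label!r} not in recording") from None
        return self.signals[i], self.fs[i]


# ---------------------------------------------------------------------------
# EDF reading / writing
#
# EDF: 256-byte fixed-width ASCII header, then 256 bytes per signal of
# per-signal header fields, then data records of little-endian int16 samples.
# Per-channel sampling rate = samples-per-record / record-duration, so mixed
# rates are preserved naturally.
# ---------------------------------------------------------------------------

def _ascii(b: bytes) -> str:
    return b.decode("ascii", errors="replace").strip()


def read_recording(path: str | Path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (native rates, µV).

    EDF+ annotation channels ("EDF Annotations") are skipped; only signal
    channels are returned.
    """
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if len(raw) < 256:
        raise FormatError(f"{path} is too short to be an EDF file")
    buf = _io.BytesIO(raw)
    header = buf.read(256)
    try:
        n_records = int(_ascii(header[236:244]))
        record_dur = float(_ascii(header[244:252]))
        ns = int(_ascii(header[252:256]))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed EDF header") from exc
    if ns == 0:
        raise EmptyInputError(f"{path}: EDF file contains zero signals")
    sig_header = buf.read(ns * 256)
    if len(sig_header) < ns * 256:
        raise FormatError(f"{path}: truncated signal header")

    def fields(offset: int, width: int) -> list[str]:
        base = offset * ns
        return [
            _ascii(sig_header[base + i * width: base + (i + 1) * width])
            for i in range(ns)
        ]

    labels = fields(0, 16)
    # field layout: label 16, transducer 80, dim 8, pmin 8, pmax 8, dmin 8,
    # dmax 8, prefilter 80, n_samples 8, reserved 32
    off = 16 + 80 + 8
    pmin = [float(x) for x in fields(off, 8)]
    pmax = [float(x) for x in fields(off + 8, 8)]
    dmin = [int(x) for x in fields(off + 16, 8)]
    dmax = [int(x) for x in fields(off + 24, 8)]
    nsamp = [int(x) for x in fields(off + 32 + 80, 8)]

    rec_size = 2 * sum(nsamp)
    data = buf.read()
    if n_records < 0:  # EDF+ allows -1 for "unknown"; infer from file size
        n_records = len(data) // rec_size
    if len(data) < n_records * rec_size:
        raise FormatError(
            f"{path}: truncated data section "
            f"(expected {n_records * rec_size} bytes, got {len(data)})"
        )
    arr = np.frombuffer(data[: n_records * rec_size], dtype="<i2")
    arr = arr.reshape(n_records, sum(nsamp))

    channels, signals, rates = [], [], []
    col = 0
    for i in range(ns):
        block = arr[:, col: col + nsamp[i]]
        col += nsamp[i]
        if labels[i] == "EDF Annotations":
            continue
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        phys = (block.astype(np.float64) - dmin[i]) * gain + pmin[i]
        channels.append(labels[i])
        signals.append(phys.reshape(-1))
        rates.append(nsamp[i] / record_dur)
    if not channels:
        raise EmptyInputError(f"{path}: no signal channels (annotations only)")
    return Recording(channels=channels, signals=signals, fs=rates)


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a recording to a minimal EDF file (16-bit, 1-s data records).

    Intended for exporting synthetic recordings; requires integer per-channel
    sampling rates.  The signal is truncated to whole 1-s records.
    """
    path = Path(path)
    for f in recording.fs:
        if abs(f - round(f)) > 1e-9:
            raise ParameterError(f"EDF export requires integer rates, got {f}")
    ns = len(recording.channels)
    n_records = int(min(len(s) / f for s, f in zip(recording.signals, recording.fs)))
    if n_records < 1:
        raise EmptyInputError("recording shorter than one 1-s EDF record")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + ns)), 8), pad("", 44),
        pad(str(n_records), 8), pad("1", 8), pad(str(ns), 4),
    ])
    pmins, pmaxs, scaled = [], [], []
    for sig in recording.signals:
        amp = float(np.max(np.abs(sig))) if len(sig) else 1.0
        amp = max(amp, 1e-6) * 1.0000001
        pmins.append(-amp)
        pmaxs.append(amp)
        dig = np.round(sig / amp * 32767.0).astype("<i2")
        scaled.append(dig)
    sig_header = b"".join([
        b"".join(pad(c, 16) for c in recording.channels),
        b"".join(pad("", 80) for _ in range(ns)),
        b"".join(pad("uV", 8) for _ in range(ns)),
        b"".join(pad(f"{p:.3f}"[:8], 8) for p in pmins),
        b"".join(pad(f"{p:.3f}"[:8], 8) for p in pmaxs),
        b"".join(pad("-32767", 8) for _ in range(ns)),
        b"".join(pad("32767", 8) for _ in range(ns)),
        b"".join(pad("", 80) for _ in range(ns)),
        b"".join(pad(str(int(round(f))), 8) for f in recording.fs),
        b"".join(pad("", 32) for _ in range(ns)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            for sig, f in zip(scaled, recording.fs):
                n = int(round(f))
                fh.write(struct.pack(f"<{n}h", *sig[r * n:(r + 1) * n]))


# ---------------------------------------------------------------------------
# Hypnogram reading / writing
# ---------------------------------------------------------------------------

def _normalize_stage(token: str, lineno: int) -> str:
    stage = STAGE_ALIASES.get(token.strip().upper())
    if stage is None:
        raise FormatError(
            f"line {lineno}: unknown sleep stage label {token.strip()!r}"
        )
    return stage


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a hypnogram from plain text (one label/line) or 2-column CSV.

    CSV rows are ``epoch_index,label``; a header row is detected and skipped.
    Labels are mapped case-insensitively through :data:`STAGE_ALIASES`.
    """
    labels: list[str] = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        token = line.split(",")[-1] if "," in line else line
        if lineno == 1 and token.strip().upper() in {"STAGE", "LABEL"}:
            continue
        labels.append(_normalize_stage(token, lineno))
    if not labels:
        raise EmptyInputError(f"{path}: no hypnogram labels found")
    return Hypnogram(labels=labels)


def write_hypnogram(hypnogram: Hypnogram, path: str | Path) -> None:
    Path(path).write_text("\n".join(hypnogram.labels) + "\n")


# ---------------------------------------------------------------------------
# Event reading / writing
# ---------------------------------------------------------------------------

EVENT_HEADER = "onset_s,duration_s,channel,scorer"


def read_events(path: str | Path) -> EventList:
    """Read events from CSV with columns onset_s,duration_s[,channel[,scorer]]."""
    events: list[Event] = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(",")]
        if lineno == 1 and parts[0].lower() in {"onset_s", "onset"}:
            continue
        try:
            onset = float(parts[0])
            duration = float(parts[1])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"line {lineno}: cannot parse event row {line!r}") from exc
        channel = parts[2] if len(parts) > 2 and parts[2] else "merged"
        scorer = parts[3] if len(parts) > 3 else ""
        try:
            events.append(Event(onset, duration, channel, scorer))
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from exc
    return EventList(events)


def write_events(event_list: EventList, path: str | Path) -> None:
    rows = [EVENT_HEADER]
    for e in event_list.sorted():
        rows.append(f"{e.onset_s:.6f},{e.duration_s:.6f},{e.channel},{e.scorer}")
    Path(path).write_text("\n".join(rows) + "\n")


def events_from_arrays(
    onsets: Sequence[float],
    durations: Sequence[float],
    channel: str = "merged",
    scorer: str = "",
) -> EventList:
    """Convenience constructor from parallel onset/duration sequences."""
    return EventList(
        [Event(float(o), float(d), channel, scorer) for o, d in zip(onsets, durations)]
    )
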