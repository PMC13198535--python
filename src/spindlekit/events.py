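"""Event postprocessing, cross-channel aggregation and spindle characteristics.

Postprocessing follows the standard two-pass rule for candidate spindle
events: first merge events separated by less than 0.1 s when at least one
member of the pair is shorter than 0.3 s (rescuing fragmented detections),
then remove events shorter than 0.3 s or longer than 2.5 s.

Characteristics are computed from the *unprocessed* channel signal through a
4th-order Butterworth 10–16 Hz band-pass:

* frequency — mean of the per-interval instantaneous frequencies, where each
  instantaneous frequency is half the reciprocal of a zero-crossing interval
  of the band-passed signal (crossings located by linear interpolation);
* amplitude — mean absolute value of the Hilbert analytic signal of the
  band-passed signal over the event;
* density — events per minute of N2 sleep;
* class — fast when frequency > 13 Hz, slow otherwise.

Per the study design, spindles are aggregated across channels by interval
union for model-vs-reference agreement, while characteristics and densities
are computed separately per channel from that channel's own signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .errors import ContractError, DegenerateSignalError, ParameterError
from .io import Event, EventList, Hypnogram, Recording
from .preprocessing import SIGMA_BANDPASS, butterworth_filter

MIN_DURATION_S = 0.3
MAX_DURATION_S = 2.5
MERGE_GAP_S = 0.1
FAST_SLOW_SPLIT_HZ = 13.0
HILBERT_PAD_S = 0.5


@dataclass(frozen=True)
class SpindleRecord:
    """Per-spindle characteristics."""

    onset_s: float
    duration_s: float
    frequency_hz: float
    amplitude_uv: float
    channel: str
    speed_class: str  # "fast" (> 13 Hz) or "slow" (<= 13 Hz)


def classify_speed(frequency_hz: float) -> str:
    return "fast" if frequency_hz > FAST_SLOW_SPLIT_HZ else "slow"


# ---------------------------------------------------------------------------
# Postprocessing
# ---------------------------------------------------------------------------

def postprocess_events(events: EventList) -> EventList:
    """Merge fragmented detections, then enforce the 0.3–2.5 s duration band.

    Input events must come from a single channel, be sorted by onset and
    non-overlapping.  The merge pass walks left to right and is iterated to
    a fixed point: two neighbours separated by a gap smaller than 0.1 s are
    merged when at least one of them is shorter than 0.3 s.  The second pass
    removes events shorter than 0.3 s or longer than 2.5 s.  Idempotent.
    """
    ev = events.sorted().events
    iv = events.intervals()
    if len(iv) > 1 and np.any(iv[1:, 0] < iv[:-1, 1] - 1e-12):
        raise ContractError("postprocess_events requires non-overlapping input")
    merged: list[Event] = []
    i = 0
    while i < len(ev):
        cur = ev[i]
        while i + 1 < len(ev):
            nxt = ev[i + 1]
            gap = nxt.onset_s - cur.offset_s
            if gap < MERGE_GAP_S and (
                cur.duration_s < MIN_DURATION_S or nxt.duration_s < MIN_DURATION_S
            ):
                cur = Event(cur.onset_s, nxt.offset_s - cur.onset_s,
                            cur.channel, cur.scorer)
                i += 1
            else:
                break
        merged.append(cur)
        i += 1
    kept = [
        e for e in merged
        if MIN_DURATION_S <= e.duration_s <= MAX_DURATION_S
    ]
    return EventList(kept)


def union_merge_channels(
    per_channel: Mapping[str, EventList] | Iterable[EventList],
) -> EventList:
    """Merge overlapping events across channels into single "merged" events.

    The transitive closure of temporal overlap becomes one event spanning the
    earliest onset to the latest offset; non-overlapping events are kept
    separate.  Touching half-open intervals ([0,1) and [1,1.5)) do not
    overlap and stay separate.
    """
    lists = list(per_channel.values()) if isinstance(per_channel, Mapping) \
        else list(per_channel)
    all_events = sorted(
        (e for lst in lists for e in lst),
        key=lambda e: (e.onset_s, e.offset_s),
    )
    out: list[Event] = []
    for e in all_events:
        if out and e.onset_s < out[-1].offset_s:
            last = out[-1]
            new_off = max(last.offset_s, e.offset_s)
            out[-1] = Event(last.onset_s, new_off - last.onset_s, "merged")
        else:
            out.append(Event(e.onset_s, e.duration_s, "merged"))
    return EventList(out)


# ---------------------------------------------------------------------------
# Characteristics
# ---------------------------------------------------------------------------

def sigma_bandpass(signal: np.ndarray, fs: float) -> np.ndarray:
    """10–16 Hz 4th-order zero-phase Butterworth band-pass."""
    return butterworth_filter(signal, SIGMA_BANDPASS, fs)


def _event_slice(event: Event, n: int, fs: float) -> tuple[int, int]:
    i0 = int(round(event.onset_s * fs))
    i1 = int(round(event.offset_s * fs))
    if i0 < 0 or i1 > n or i1 <= i0:
        raise ParameterError(
            f"event [{event.onset_s}, {event.offset_s}) s outside signal "
            f"of {n / fs:.1f} s"
        )
    return i0, i1


def _zero_crossing_frequency(segment: np.ndarray, fs: float) -> float:
    x = np.asarray(segment, dtype=np.float64)
    sign = np.sign(x)
    nz = np.flatnonzero(sign != 0)
    if len(nz) < 2:
        raise DegenerateSignalError(
            "fewer than two zero crossings; frequency undefined"
        )
    crossings: list[float] = []
    # sign changes between consecutive nonzero samples; runs of exact zeros
    # in between count once, located at the (first) zero sample
    for a, b in zip(nz[:-1], nz[1:]):
        if sign[a] * sign[b] < 0:
            if b == a + 1:
                crossings.append(a + x[a] / (x[a] - x[b]))
            else:
                crossings.append(float(a + 1))
    times = np.asarray(crossings) / fs
    if len(times) < 2:
        raise DegenerateSignalError(
            "fewer than two zero crossings; frequency undefined"
        )
    intervals = np.diff(times)
    return float(np.mean(0.5 / intervals))


def spindle_frequency(
    raw_signal: np.ndarray,
    event: Event,
    fs: float,
    filtered: np.ndarray | None = None,
) -> float:
    """Dominant frequency of one event by the zero-crossing method (Hz).

    ``filtered`` may carry the pre-computed 10–16 Hz band-passed signal to
    avoid re-filtering when characterizing many events of one channel.
    """
    if filtered is None:
        filtered = sigma_bandpass(np.asarray(raw_signal, dtype=np.float64), fs)
    i0, i1 = _event_slice(event, len(filtered), fs)
    return _zero_crossing_frequency(filtered[i0:i1], fs)


def spindle_amplitude(
    raw_signal: np.ndarray,
    event: Event,
    fs: float,
    filtered: np.ndarray | None = None,
) -> float:
    """Mean Hilbert-envelope amplitude of one event (µV).

    The analytic signal is computed on the event padded with 0.5 s of
    band-passed context on each side (where available) and then cropped,
    which suppresses Hilbert edge transients.
    """
    if filtered is None:
        filtered = sigma_bandpass(np.asarray(raw_signal, dtype=np.float64), fs)
    i0, i1 = _event_slice(event, len(filtered), fs)
    pad = int(round(HILBERT_PAD_S * fs))
    j0, j1 = max(0, i0 - pad), min(len(filtered), i1 + pad)
    env = np.abs(hilbert(filtered[j0:j1]))
    return float(np.mean(env[i0 - j0: i1 - j0]))


def spindle_density(events: EventList | int, hypnogram: Hypnogram) -> float:
    """Spindles per minute of N2 sleep."""
    n2_min = hypnogram.duration_s("N2") / 60.0
    if n2_min == 0:
        raise DegenerateSignalError("no N2 sleep; density undefined")
    count = events if isinstance(events, int) else len(events)
    return count / n2_min


def characterize(
    events: EventList,
    recording: Recording,
    hypnogram: Hypnogram | None = None,
) -> pd.DataFrame:
    """Per-spindle characteristics, separately per channel.

    For each channel appearing in ``events``, frequency and amplitude are
    computed from that channel's raw signal (10–16 Hz band-passed once per
    channel); duration comes from the event itself, and the fast/slow class
    splits at 13 Hz.  Returns one row per spindle with columns ``channel,
    onset_s, duration_s, frequency_hz, amplitude_uv, speed_class``.
    """
    rows = []
    for channel in events.channels:
        signal, fs = recording.channel(channel)  # raises on unknown channel
        filtered = sigma_bandpass(np.asarray(signal, dtype=np.float64), fs)
        for e in events.for_channel(channel).sorted():
            freq = spindle_frequency(signal, e, fs, filtered=filtered)
            amp = spindle_amplitude(signal, e, fs, filtered=filtered)
            rows.append({
                "channel": channel, "onset_s": e.onset_s,
                "duration_s": e.duration_s, "frequency_hz": freq,
                "amplitude_uv": amp, "speed_class": classify_speed(freq),
            })
    return pd.DataFrame(
        rows, columns=["channel", "onset_s", "duration_s", "frequency_hz",
                       "amplitude_uv", "speed_class"]
    )


def summarize_characteristics(
    records: pd.DataFrame, hypnogram: Hypnogram, subject: str = ""
) -> pd.DataFrame:
    """Subject-level summary: per channel × speed class, the mean duration,
    frequency and amplitude plus the spindle density (SPM of N2).

    Output is a long table with columns ``subject, channel, speed_class,
    metric, value`` suitable for :func:`spindlekit.evaluation.compare_cohorts`
    after concatenation across subjects.
    """
    rows = []
    for (channel, speed), grp in records.groupby(["channel", "speed_class"]):
        rows.append({"subject": subject, "channel": channel,
                     "speed_class": speed, "metric": "density",
                     "value": spindle_density(len(grp), hypnogram)})
        for metric, col in (("duration", "duration_s"),
                            ("frequency", "frequency_hz"),
                            ("amplitude", "amplitude_uv")):
            rows.append({"subject": subject, "channel": channel,
                         "speed_class": speed, "metric": metric,
                         "value": float(grp[col].mean())})
    return pd.DataFrame(
        rows, columns=["subject", "channel", "speed_class", "metric", "value"]
    )
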