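"""Synthetic stage-structured EEG with planted spindles and simulated raters.

The generator emulates what the analysis pipeline needs from an overnight
EEG: a hypnogram with realistic stage bouts, a colored-noise background with
stage-dependent rhythms, sigma-band spindle bursts planted only in N2 sleep,
and imperfect raters.  It makes every pipeline stage testable with known
ground truth.

Model choices (see the methods note for rationale):

* Hypnogram: first-order Markov chain over W/N1/N2/N3/REM whose default
  transition matrix has stationary distribution (0.15, 0.07, 0.50, 0.18,
  0.10) — about half the night in N2 — with mean bout lengths of several
  minutes.
* Background: colored noise with amplitude spectrum ∝ 1/f (power ∝ 1/f²)
  over 0.3–45 Hz, total RMS 10 µV, emulating artifact-free sleep EEG whose
  power falls steeply with frequency (sigma-band background ≈ 1 µV RMS).
  Stage rhythms are added as band-limited noise: delta in N3, alpha in Wake,
  theta in N1/REM.
* Spindles: Gaussian-enveloped sinusoids whose nominal duration is the
  envelope's full width at half maximum; ground-truth events are exactly the
  half-maximum bounds.  Arrivals are Poisson at the requested density within
  N2, thinned by a refractory gap; the achieved density is reported with a
  warning if the target is unreachable.

All randomness flows from one root seed through named substreams
(hypnogram / signal / spindles / rater), so runs are reproducible and
components can be varied independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError
from .io import Event, EventList, Hypnogram, Recording, STAGES

#: Default stationary stage distribution of the hypnogram chain.
STAGE_STATIONARY = np.array([0.15, 0.07, 0.50, 0.18, 0.10])
#: Per-step probability of re-drawing the stage (controls bout lengths).
STAGE_SWITCH = 0.15

#: (low Hz, high Hz, RMS µV) of the stage-dependent background rhythms.
STAGE_RHYTHMS = {
    "W": (8.0, 12.0, 6.0),
    "N1": (4.0, 7.0, 3.0),
    "N3": (0.75, 2.0, 20.0),
    "REM": (4.0, 7.0, 5.0),
}

BACKGROUND_RMS_UV = 10.0
BACKGROUND_BAND = (0.3, 45.0)
#: FWHM duration d maps to Gaussian sigma d / (2 sqrt(2 ln 2)).
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SpindleGenParams:
    """Spindle population parameters.

    ``density_spm`` / ``density_sd_spm`` and ``subject_frequency_sd_hz`` are
    between-subject distributions used by :func:`gen_cohort_study`;
    :func:`gen_recording` itself plants at exactly ``density_spm`` with
    event-level scatter given by the ``*_sd`` duration/frequency/amplitude
    fields.  Defaults follow healthy-control frontal fast-spindle statistics
    (density 3.43 ± 1.70 SPM, duration 0.87 ± 0.09 s, subject-mean frequency
    13.91 ± 0.14 Hz); the envelope peak of 8.6 µV corresponds to a ~7 µV
    mean Hilbert envelope over the half-maximum event.
    """

    density_spm: float = 3.43
    density_sd_spm: float = 1.70
    duration_mean_s: float = 0.87
    duration_sd_s: float = 0.09
    frequency_mean_hz: float = 13.91
    frequency_sd_hz: float = 0.25
    subject_frequency_sd_hz: float = 0.14
    amplitude_peak_uv: float = 8.6
    amplitude_sd_uv: float = 0.8
    refractory_s: float = 1.0

    def __post_init__(self):
        if self.density_spm < 0 or self.refractory_s < 0:
            raise ParameterError("density and refractory must be nonnegative")
        if not 10.0 < self.frequency_mean_hz < 16.0:
            raise ParameterError("spindle frequency mean must lie in (10, 16) Hz")


@dataclass(frozen=True)
class RaterParams:
    """Imperfect-rater model: thinning, boundary jitter, false positives."""

    hit_prob: float = 0.8
    onset_jitter_sd_s: float = 0.0
    duration_jitter_sd_s: float = 0.0
    fp_rate_per_min: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.hit_prob <= 1.0:
            raise ParameterError("hit_prob must be in [0, 1]")
        if min(self.onset_jitter_sd_s, self.duration_jitter_sd_s,
               self.fp_rate_per_min) < 0:
            raise ParameterError("jitter SDs and fp_rate must be nonnegative")


def _substreams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# Hypnogram generation
# ---------------------------------------------------------------------------

def default_transition_matrix() -> np.ndarray:
    """Markov matrix 0.85·I + 0.15·1πᵀ, whose stationary distribution is π."""
    return (1 - STAGE_SWITCH) * np.eye(5) + STAGE_SWITCH * np.outer(
        np.ones(5), STAGE_STATIONARY
    )


def gen_hypnogram(
    n_epochs: int,
    seed: int | np.random.Generator = 0,
    transition_matrix: np.ndarray | None = None,
    start_stage: str | None = None,
) -> Hypnogram:
    """Sample a hypnogram from a first-order Markov chain over the 5 stages."""
    if n_epochs < 1:
        raise ParameterError("n_epochs must be >= 1")
    p = default_transition_matrix() if transition_matrix is None \
        else np.asarray(transition_matrix, dtype=np.float64)
    if p.shape != (5, 5) or np.any(p < 0) or np.any(np.abs(p.sum(1) - 1) > 1e-9):
        raise ParameterError("transition matrix must be 5x5 row-stochastic")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(np.random.SeedSequence(seed))
    if start_stage is None:
        state = int(rng.choice(5, p=STAGE_STATIONARY))
    else:
        state = STAGES.index(start_stage)
    labels = []
    for _ in range(n_epochs):
        labels.append(STAGES[state])
        state = int(rng.choice(5, p=p[state]))
    return Hypnogram(labels)


# ---------------------------------------------------------------------------
# Signal generation
# ---------------------------------------------------------------------------

def _spectrum_noise(n: int, fs: float, rng: np.random.Generator,
                    shape, rms: float) -> np.ndarray:
    """Gaussian noise with the given one-sided amplitude-spectrum shape."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = shape(freqs)
    spec = amp * (rng.standard_normal(len(freqs))
                  + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    cur = np.sqrt(np.mean(x ** 2))
    return x * (rms / cur) if cur > 0 else x


def colored_background(n: int, fs: float, rng: np.random.Generator,
                       rms: float = BACKGROUND_RMS_UV) -> np.ndarray:
    lo, hi = BACKGROUND_BAND

    def shape(f):
        a = np.zeros_like(f)
        sel = (f >= lo) & (f <= hi)
        a[sel] = 1.0 / f[sel]
        return a

    return _spectrum_noise(n, fs, rng, shape, rms)


def band_noise(n: int, fs: float, rng: np.random.Generator,
               lo: float, hi: float, rms: float) -> np.ndarray:
    def shape(f):
        return ((f >= lo) & (f <= hi)).astype(float)

    return _spectrum_noise(n, fs, rng, shape, rms)


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    tries = 0
    while np.any(bad) and tries < 100:
        out = np.where(bad, rng.normal(mean, sd, size=size), out)
        bad = (out < lo) | (out > hi)
        tries += 1
    return np.clip(out, lo, hi)


def _place_spindles(
    runs_s: list[tuple[float, float]],
    params: SpindleGenParams,
    rng: np.random.Generator,
    channel: str,
) -> list[tuple[Event, float, float, float]]:
    """Draw spindle events inside N2 runs.

    Returns (event, frequency, peak amplitude, phase) tuples; the event
    bounds are the envelope half-maximum interval.  Placement rejects
    candidates that would come closer than the refractory gap to an already
    placed event or whose waveform support would leave the run.
    """
    n2_minutes = sum(b - a for a, b in runs_s) / 60.0
    target = rng.poisson(params.density_spm * n2_minutes)
    if target == 0 or not runs_s:
        return []
    durations = np.array([b - a for a, b in runs_s])
    placed: list[tuple[float, float]] = []
    out = []
    attempts = 0
    max_attempts = 200 * target
    while len(out) < target and attempts < max_attempts:
        attempts += 1
        dur = float(_truncated_normal(rng, params.duration_mean_s,
                                      params.duration_sd_s, 0.3, 2.5))
        margin = 1.2 * dur  # keep the sub-half-maximum tails inside the run
        r = rng.choice(len(runs_s), p=durations / durations.sum())
        a, b = runs_s[r]
        if b - a < 2 * margin:
            continue
        center = rng.uniform(a + margin, b - margin)
        onset = center - dur / 2.0
        offset = center + dur / 2.0
        gap = params.refractory_s
        if any(onset < p1 + gap and p0 - gap < offset for p0, p1 in placed):
            continue
        freq = float(_truncated_normal(rng, params.frequency_mean_hz,
                                       params.frequency_sd_hz, 10.05, 15.95))
        amp = float(max(0.5, rng.normal(params.amplitude_peak_uv,
                                        params.amplitude_sd_uv)))
        phase = float(rng.uniform(0, 2 * np.pi))
        placed.append((onset, offset))
        out.append((Event(onset, dur, channel, "truth"), freq, amp, phase))
    if len(out) < target:
        achieved = len(out) / n2_minutes if n2_minutes else 0.0
        warnings.warn(
            f"requested spindle density {params.density_spm:.2f} SPM "
            f"unreachable under refractory {params.refractory_s}s; "
            f"achieved {achieved:.2f} SPM"
        )
    return out


def gen_recording(
    hypnogram: Hypnogram,
    channels: Sequence[str] = ("F3-A2",),
    fs: float = 100.0,
    spindle_params: SpindleGenParams | Mapping[str, SpindleGenParams] | None = None,
    seed: int = 0,
    background_rms_uv: float = BACKGROUND_RMS_UV,
) -> tuple[Recording, EventList]:
    """Synthesize a recording for a hypnogram, with ground-truth spindles.

    ``spindle_params`` may be a single population applied to every channel or
    a mapping channel → population.  Spindles are planted only inside N2
    epochs; the returned events carry the channel label and exact
    half-maximum bounds in recording time.
    """
    if fs < 100.0:
        raise ParameterError("generator requires fs >= 100 Hz")
    if spindle_params is None:
        spindle_params = SpindleGenParams()
    streams = _substreams(seed, ["signal", "spindles"])
    sig_rng, spin_rng = streams["signal"], streams["spindles"]
    n = int(round(len(hypnogram) * hypnogram.epoch_s * fs))
    runs_s = [(a * hypnogram.epoch_s, b * hypnogram.epoch_s)
              for a, b in hypnogram.runs("N2")]
    t = np.arange(n) / fs

    per_sample_stage = np.repeat(np.array(hypnogram.labels),
                                 int(hypnogram.epoch_s * fs))[:n]
    signals, truth = [], []
    for ch in channels:
        x = colored_background(n, fs, sig_rng, rms=background_rms_uv)
        for stage, (lo, hi, rms) in STAGE_RHYTHMS.items():
            mask = per_sample_stage == stage
            if mask.any():
                x = x + band_noise(n, fs, sig_rng, lo, hi, rms) * mask
        params = spindle_params[ch] if isinstance(spindle_params, Mapping) \
            else spindle_params
        for event, freq, amp, phase in _place_spindles(runs_s, params,
                                                       spin_rng, ch):
            center = event.midpoint_s
            sigma = event.duration_s * _FWHM_TO_SIGMA
            i0 = max(0, int((center - 4 * sigma) * fs))
            i1 = min(n, int((center + 4 * sigma) * fs))
            tt = t[i0:i1] - center
            x[i0:i1] += amp * np.exp(-tt ** 2 / (2 * sigma ** 2)) * np.sin(
                2 * np.pi * freq * tt + phase
            )
            truth.append(event)
        signals.append(x)
    recording = Recording(channels=list(channels), signals=signals,
                          fs=[fs] * len(channels))
    return recording, EventList(truth).sorted()


# ---------------------------------------------------------------------------
# Simulated raters
# ---------------------------------------------------------------------------

def simulate_rater(
    truth: EventList,
    params: RaterParams,
    seed: int = 0,
    hypnogram: Hypnogram | None = None,
    scorer: str = "rater",
) -> EventList:
    """An imperfect rater: thin hits, jitter boundaries, add false positives.

    False positives arrive as a Poisson process over N2 sleep (or over the
    truth's time span when no hypnogram is given).  The output is sorted and
    overlap-free (later conflicting events are dropped), hence valid input
    for postprocessing and matching.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    events: list[Event] = []
    for e in truth.sorted():
        if rng.random() >= params.hit_prob:
            continue
        onset = max(0.0, e.onset_s + rng.normal(0, params.onset_jitter_sd_s)
                    if params.onset_jitter_sd_s else e.onset_s)
        dur = e.duration_s + (rng.normal(0, params.duration_jitter_sd_s)
                              if params.duration_jitter_sd_s else 0.0)
        dur = float(np.clip(dur, 0.3, 2.5))
        events.append(Event(onset, dur, e.channel, scorer))
    if params.fp_rate_per_min > 0:
        if hypnogram is not None:
            spans = [(a * 30.0, b * 30.0) for a, b in hypnogram.runs("N2")]
        else:
            end = max((e.offset_s for e in truth), default=0.0)
            spans = [(0.0, end)] if end > 0 else []
        total_min = sum(b - a for a, b in spans) / 60.0
        n_fp = rng.poisson(params.fp_rate_per_min * total_min)
        lens = np.array([b - a for a, b in spans], dtype=float)
        for _ in range(n_fp):
            if not spans:
                break
            r = rng.choice(len(spans), p=lens / lens.sum())
            a, b = spans[r]
            dur = float(_truncated_normal(rng, 0.7, 0.2, 0.3, 2.5))
            if b - a <= dur:
                continue
            onset = rng.uniform(a, b - dur)
            events.append(Event(onset, dur, truth.events[0].channel
                                if truth.events else "merged", scorer))
    events.sort(key=lambda e: (e.onset_s, e.offset_s))
    keep: list[Event] = []
    for e in events:
        if keep and e.onset_s < keep[-1].offset_s:
            continue
        keep.append(e)
    return EventList(keep)


# ---------------------------------------------------------------------------
# Cohort studies
# ---------------------------------------------------------------------------

def gen_cohort_study(
    n_a: int,
    n_b: int,
    params_a: SpindleGenParams | Mapping[str, SpindleGenParams],
    params_b: SpindleGenParams | Mapping[str, SpindleGenParams],
    seed: int = 0,
    n_epochs: int = 280,
    channels: Sequence[str] = ("F3-A2", "F4-A1"),
    fs: float = 100.0,
) -> tuple[list, list]:
    """Two synthetic cohorts of (Recording, Hypnogram, truth EventList).

    Per subject, the planted density is drawn from the population's
    ``density_spm ± density_sd_spm`` (truncated at 0) and the subject-mean
    frequency from ``frequency_mean_hz ± subject_frequency_sd_hz``; the
    recording is then generated at those subject-level parameters.
    """
    if n_a < 2 or n_b < 2:
        raise ParameterError("each cohort needs at least 2 subjects")
    root = np.random.SeedSequence(seed)
    seeds = root.generate_state(2 * (n_a + n_b)) % (2 ** 31)
    out_a, out_b = [], []
    idx = 0
    for group, n_subjects, params in (("a", n_a, params_a), ("b", n_b, params_b)):
        for s in range(n_subjects):
            hyp_seed, rec_seed = int(seeds[idx]), int(seeds[idx + 1])
            idx += 2
            draw_rng = np.random.default_rng(hyp_seed + 1)

            def subject_params(p: SpindleGenParams) -> SpindleGenParams:
                density = float(_truncated_normal(
                    draw_rng, p.density_spm, p.density_sd_spm, 0.0, np.inf))
                freq = float(_truncated_normal(
                    draw_rng, p.frequency_mean_hz, p.subject_frequency_sd_hz,
                    10.05, 15.95))
                return replace(p, density_spm=density, frequency_mean_hz=freq,
                               density_sd_spm=0.0, subject_frequency_sd_hz=0.0)

            if isinstance(params, Mapping):
                sp = {ch: subject_params(p) for ch, p in params.items()}
            else:
                sp = subject_params(params)
            hyp = gen_hypnogram(n_epochs, seed=hyp_seed)
            rec, truth = gen_recording(hyp, channels=channels, fs=fs,
                                       spindle_params=sp, seed=rec_seed)
            (out_a if group == "a" else out_b).append((rec, hyp, truth))
    return out_a, out_b
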