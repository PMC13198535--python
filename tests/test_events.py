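import numpy as np
import pytest

from spindlekit.errors import ContractError, DegenerateSignalError, ParameterError
from spindlekit.events import (
    characterize,
    classify_speed,
    postprocess_events,
    spindle_amplitude,
    spindle_density,
    spindle_frequency,
    union_merge_channels,
)
from spindlekit.io import Event, EventList, Hypnogram, Recording


def _events(pairs, channel="C3"):
    return EventList([Event(o, d, channel) for o, d in pairs])


class TestPostprocess:
    def test_merge_then_keep(self):
        out = postprocess_events(_events([(0.0, 0.2), (0.25, 0.2)]))
        assert [(e.onset_s, e.duration_s) for e in out] == [(0.0, 0.45)]

    def test_isolated_short_event_removed(self):
        assert len(postprocess_events(_events([(0.0, 0.25)]))) == 0

    def test_overlong_event_removed(self):
        assert len(postprocess_events(_events([(0.0, 3.0)]))) == 0

    def test_long_events_with_small_gap_not_merged(self):
        # both members >= 0.3 s: gap rule does not apply
        out = postprocess_events(_events([(0.0, 0.5), (0.55, 0.5)]))
        assert len(out) == 2

    def test_chain_merge_to_fixed_point(self):
        out = postprocess_events(_events([(0.0, 0.2), (0.25, 0.2), (0.5, 0.2)]))
        assert [(e.onset_s, round(e.duration_s, 6)) for e in out] == [(0.0, 0.7)]

    def test_overlapping_input_rejected(self):
        with pytest.raises(ContractError):
            postprocess_events(_events([(0.0, 1.0), (0.5, 1.0)]))

    def test_random_sets_bounds_and_idempotence(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            t = 0.0
            pairs = []
            for _ in range(rng.integers(1, 15)):
                t += rng.uniform(0.01, 1.0)
                d = rng.uniform(0.05, 3.0)
                pairs.append((t, d))
                t += d
            out = postprocess_events(_events(pairs))
            for e in out:
                assert 0.3 <= e.duration_s <= 2.5
            again = postprocess_events(out)
            assert [(e.onset_s, e.duration_s) for e in again] == \
                   [(e.onset_s, e.duration_s) for e in out]


class TestUnionMerge:
    def test_cross_channel_overlap_merged(self):
        out = union_merge_channels({
            "C3": _events([(0.0, 1.0)], "C3"),
            "C4": _events([(0.5, 1.0)], "C4"),
        })
        assert [(e.onset_s, e.duration_s, e.channel) for e in out] == \
               [(0.0, 1.5, "merged")]

    def test_disjoint_events_kept(self):
        out = union_merge_channels({
            "C3": _events([(0.0, 0.5)], "C3"),
            "C4": _events([(2.0, 0.5)], "C4"),
        })
        assert len(out) == 2

    def test_touching_half_open_intervals_stay_separate(self):
        out = union_merge_channels({
            "C3": _events([(0.0, 1.0)], "C3"),
            "C4": _events([(1.0, 0.5)], "C4"),
        })
        assert len(out) == 2

    def test_matches_bruteforce_union_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            per_channel = {}
            for ch in ("a", "b", "c"):
                t = 0.0
                pairs = []
                for _ in range(rng.integers(0, 8)):
                    t += rng.uniform(0.0, 2.0)
                    d = rng.uniform(0.1, 1.5)
                    pairs.append((t, d))
                    t += d
                per_channel[ch] = _events(pairs, ch)
            out = union_merge_channels(per_channel)
            # oracle: quadratic overlap graph + connected components
            evs = [e for lst in per_channel.values() for e in lst]
            n = len(evs)
            comp = list(range(n))

            def find(i):
                while comp[i] != i:
                    comp[i] = comp[comp[i]]
                    i = comp[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    a, b = evs[i], evs[j]
                    if a.onset_s < b.offset_s and b.onset_s < a.offset_s:
                        comp[find(i)] = find(j)
            spans = {}
            for i, e in enumerate(evs):
                r = find(i)
                lo, hi = spans.get(r, (np.inf, -np.inf))
                spans[r] = (min(lo, e.onset_s), max(hi, e.offset_s))
            expected = sorted(spans.values())
            assert len(out) == len(expected)
            for e, (lo, hi) in zip(out, expected):
                assert e.onset_s == pytest.approx(lo)
                assert e.offset_s == pytest.approx(hi)


def _sine_recording(freq, amp=10.0, fs=100.0, secs=10.0, channels=("C3",)):
    t = np.arange(int(secs * fs)) / fs
    sig = amp * np.sin(2 * np.pi * freq * t)
    return Recording(list(channels), [sig.copy() for _ in channels],
                     [fs] * len(channels))


class TestFrequencyEstimator:
    @pytest.mark.parametrize("freq", [10.5, 11.0, 11.5, 12.0, 12.5, 13.0,
                                      13.5, 14.0, 14.5, 15.0, 15.5])
    def test_sinusoid_grid_within_tenth_hz(self, freq):
        rec = _sine_recording(freq)
        est = spindle_frequency(rec.signals[0], Event(4.0, 1.0), 100.0)
        assert abs(est - freq) < 0.1

    def test_twelve_hz_classified_slow(self):
        rec = _sine_recording(12.0)
        est = spindle_frequency(rec.signals[0], Event(4.0, 1.0), 100.0)
        assert abs(est - 12.0) < 0.1
        assert classify_speed(est) == "slow"

    def test_boundary_thirteen_is_slow(self):
        assert classify_speed(13.0) == "slow"
        assert classify_speed(13.0001) == "fast"

    def test_zero_signal_undefined(self):
        with pytest.raises(DegenerateSignalError):
            spindle_frequency(np.zeros(2000), Event(4.0, 1.0), 100.0)


class TestAmplitudeEstimator:
    @pytest.mark.parametrize("amp", [1.0, 5.0, 10.0, 50.0])
    def test_sinusoid_envelope_within_three_percent(self, amp):
        rec = _sine_recording(13.0, amp=amp)
        est = spindle_amplitude(rec.signals[0], Event(4.0, 1.0), 100.0)
        assert abs(est - amp) / amp < 0.03

    def test_linearity(self):
        rec = _sine_recording(13.0, amp=7.0)
        e = Event(4.0, 1.0)
        a1 = spindle_amplitude(rec.signals[0], e, 100.0)
        a2 = spindle_amplitude(2.0 * rec.signals[0], e, 100.0)
        assert a2 == pytest.approx(2.0 * a1, rel=1e-9)

    def test_zero_signal_zero_amplitude(self):
        assert spindle_amplitude(np.zeros(2000), Event(4.0, 1.0), 100.0) == 0.0

    def test_event_outside_signal_rejected(self):
        with pytest.raises(ParameterError):
            spindle_amplitude(np.zeros(100), Event(4.0, 1.0), 100.0)


class TestDensity:
    def test_arithmetic(self):
        hyp = Hypnogram(["N2"] * 30)  # 15 min
        assert spindle_density(30, hyp) == pytest.approx(2.0)

    def test_zero_events(self):
        assert spindle_density(EventList([]), Hypnogram(["N2"] * 10)) == 0.0

    def test_no_n2_undefined(self):
        with pytest.raises(DegenerateSignalError):
            spindle_density(5, Hypnogram(["W", "REM"]))


class TestCharacterize:
    def test_planted_14hz_events_fast(self):
        rec = _sine_recording(14.0, secs=30.0)
        events = _events([(5.0, 1.0), (12.0, 1.0)])
        out = characterize(events, rec)
        assert list(out["speed_class"]) == ["fast", "fast"]
        assert np.allclose(out["frequency_hz"], 14.0, atol=0.1)

    def test_identical_channels_identical_characteristics(self):
        rec = _sine_recording(13.5, secs=30.0, channels=("C3", "C4"))
        events = EventList([Event(5.0, 1.0, "C3"), Event(5.0, 1.0, "C4")])
        out = characterize(events, rec)
        a = out[out.channel == "C3"].drop(columns="channel").reset_index(drop=True)
        b = out[out.channel == "C4"].drop(columns="channel").reset_index(drop=True)
        assert a.equals(b)

    def test_unknown_channel_rejected(self):
        rec = _sine_recording(13.5)
        with pytest.raises(ParameterError):
            characterize(EventList([Event(1.0, 1.0, "Oz")]), rec)
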