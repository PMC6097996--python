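"""Beat consensus, beep scheduling and audio rendering."""

import numpy as np
import pytest

from cabat.stimulus import (
    BeatAnnotation,
    TapTake,
    Waveform,
    assemble_trial,
    beep_schedule,
    consensus_beats,
    phase_difference,
    render_beep_track,
)


def _take(drummer, take, onsets, latency=0.0):
    return TapTake(drummer, take, tuple(onsets), latency)


BEATS = np.arange(0.5, 5.5, 0.5)  # 10 beats, 500 ms period


class TestConsensusBeats:
    def test_identical_takes_recovered_exactly(self):
        takes = [_take("d1", "a", BEATS), _take("d1", "b", BEATS)]
        ann, report = consensus_beats(takes)
        np.testing.assert_allclose(ann.beat_times, BEATS, atol=1e-12)
        assert ann.mean_period == pytest.approx(0.5, abs=1e-12)
        assert report["within_drummer_phase"]["d1"] == pytest.approx(0.0, abs=1e-12)
        assert not report["rejected"]

    def test_constant_30ms_offset_phase(self):
        takes = [_take("d1", "a", BEATS), _take("d1", "b", BEATS + 0.030)]
        _, report = consensus_beats(takes)
        assert report["within_drummer_phase"]["d1"] == pytest.approx(
            2 * np.pi * 0.06, abs=1e-6
        )
        assert not report["within_flagged"]["d1"]  # 0.377 rad < 0.6

    def test_threshold_radian_percent_conversions(self):
        assert 0.6 / (2 * np.pi) * 100 == pytest.approx(9.5, abs=0.05)
        assert 0.7 / (2 * np.pi) * 100 == pytest.approx(11.1, abs=0.05)

    def test_latency_correction_applied(self):
        takes = [
            _take("d1", "a", BEATS + 0.02, latency=0.02),
            _take("d1", "b", BEATS + 0.02, latency=0.02),
        ]
        ann, _ = consensus_beats(takes)
        np.testing.assert_allclose(ann.beat_times, BEATS, atol=1e-12)

    def test_selects_most_consistent_take_pair(self):
        # the tempo-warped third take must be ignored
        warped = BEATS * 1.08
        takes = [
            _take("d1", "a", BEATS),
            _take("d1", "b", BEATS + 0.005),
            _take("d1", "c", warped),
        ]
        ann, _ = consensus_beats(takes)
        np.testing.assert_allclose(ann.beat_times, BEATS + 0.0025, atol=1e-9)

    def test_between_drummer_flagging(self):
        takes = [
            _take("d1", "a", BEATS), _take("d1", "b", BEATS),
            _take("d2", "a", BEATS + 0.06), _take("d2", "b", BEATS + 0.06),
        ]
        _, report = consensus_beats(takes)
        # 60 ms at 500 ms period = 0.12 beats = 0.754 rad > 0.7
        assert report["between_drummer_phase"][("d1", "d2")] == pytest.approx(
            2 * np.pi * 0.12, abs=1e-6
        )
        assert report["rejected"]

    def test_permutation_invariance(self):
        takes = [
            _take("d1", "a", BEATS + 0.004), _take("d1", "b", BEATS),
            _take("d2", "a", BEATS + 0.01), _take("d2", "b", BEATS + 0.012),
        ]
        ann1, _ = consensus_beats(takes)
        ann2, _ = consensus_beats(list(reversed(takes)))
        np.testing.assert_allclose(ann1.beat_times, ann2.beat_times, atol=1e-12)

    def test_global_time_shift_equivariance(self):
        takes = [_take("d1", "a", BEATS), _take("d1", "b", BEATS + 0.01)]
        shifted = [_take("d1", "a", BEATS + 1.0), _take("d1", "b", BEATS + 1.01)]
        a1, _ = consensus_beats(takes)
        a2, _ = consensus_beats(shifted)
        np.testing.assert_allclose(
            np.asarray(a2.beat_times) - 1.0, a1.beat_times, atol=1e-12
        )

    def test_single_take_drummer_rejected(self):
        with pytest.raises(ValueError):
            consensus_beats([_take("d1", "a", BEATS)])


class TestPhaseDifference:
    def test_arithmetic(self):
        a = np.asarray([1.0, 1.5, 2.0])
        assert phase_difference(a, a + 0.03, 0.5) == pytest.approx(
            2 * np.pi * 0.06, abs=1e-9
        )


class TestBeepSchedule:
    def _ann(self):
        return BeatAnnotation(tuple(BEATS), 0.5)

    def test_target_on_beats(self):
        sched = beep_schedule(self._ann(), "target")
        np.testing.assert_allclose(sched.onsets, BEATS, atol=1e-12)

    def test_tiny_offset_approaches_target(self):
        sched = beep_schedule(self._ann(), "lure", P=1e-9, direction="behind")
        np.testing.assert_allclose(sched.onsets, BEATS, atol=1e-8)

    def test_behind_shifts_later_by_p_times_period(self):
        sched = beep_schedule(self._ann(), "lure", P=0.1, direction="behind")
        np.testing.assert_allclose(sched.onsets, BEATS + 0.05, atol=1e-12)

    def test_half_beat_symmetry_on_isochronous_beats(self):
        ahead = beep_schedule(self._ann(), "lure", P=0.5, direction="ahead")
        behind = beep_schedule(self._ann(), "lure", P=0.5, direction="behind")
        shared_a = [t for t in ahead.onsets if min(abs(t - u) for u in behind.onsets) < 1e-9]
        assert len(shared_a) >= len(BEATS) - 1  # equal up to boundary beeps

    def test_offset_round_trip(self):
        target = beep_schedule(self._ann(), "target")
        for p in (0.05, 0.2, 0.5):
            lure = beep_schedule(self._ann(), "lure", P=p, direction="behind")
            implied = (np.asarray(lure.onsets) - np.asarray(target.onsets)) / 0.5
            np.testing.assert_allclose(implied, p, atol=1e-9)

    def test_out_of_range_p(self):
        for p in (0.0, 0.6, -0.1):
            with pytest.raises(ValueError):
                beep_schedule(self._ann(), "lure", P=p, direction="ahead")

    def test_duration_clips_onsets(self):
        sched = beep_schedule(self._ann(), "target", duration=2.0)
        assert max(sched.onsets) <= 2.0


class TestRender:
    def test_empty_schedule_is_silent(self):
        from cabat.stimulus import BeepSchedule

        wave = render_beep_track(BeepSchedule("target", ()), duration=1.0)
        assert np.all(wave.samples == 0.0)

    def test_single_beep_sample_counts(self):
        from cabat.stimulus import BeepSchedule

        wave = render_beep_track(
            BeepSchedule("target", (0.1,)), duration=0.5, sample_rate=44_100
        )
        start = int(round(0.1 * 44_100))
        region = wave.samples[start:start + 882]
        assert np.abs(region).max() > 0
        assert np.all(wave.samples[:start] == 0.0)
        assert np.all(wave.samples[start + 882:] == 0.0)
        # fade: RMS of the last 441 samples is below the first 441
        assert np.sqrt((region[441:] ** 2).mean()) < np.sqrt((region[:441] ** 2).mean())

    def test_onsets_recoverable_by_threshold_detection(self):
        sched = beep_schedule(BeatAnnotation(tuple(BEATS), 0.5), "target")
        sr = 44_100
        wave = render_beep_track(sched, duration=6.0, sample_rate=sr)
        active = np.abs(wave.samples) > 1e-6
        edges = np.nonzero(active[1:] & ~active[:-1])[0] + 1
        # the sine crosses exactly zero mid-beep; merge edges closer than 15 ms
        onsets = [edges[0]]
        for e in edges[1:]:
            if e - onsets[-1] > 0.015 * sr:
                onsets.append(e)
        detected = np.asarray(onsets) / sr
        assert len(detected) == len(sched.onsets)
        # the 1 kHz sine's first sample is 0, so allow one sample of slack
        np.testing.assert_allclose(detected, sched.onsets, atol=1.5 / sr)

    def test_peak_normalisation_and_overlap(self):
        from cabat.stimulus import BeepSchedule

        wave = render_beep_track(
            BeepSchedule("target", (0.1, 0.105)), duration=0.3, amplitude=0.8
        )
        assert np.abs(wave.samples).max() == pytest.approx(0.8, abs=1e-9)

    def test_out_of_range_onset_errors(self):
        from cabat.stimulus import BeepSchedule

        with pytest.raises(ValueError):
            render_beep_track(BeepSchedule("target", (2.0,)), duration=1.0)


class TestAssembleTrial:
    def test_twelve_second_trial(self):
        sr = 44_100
        five = Waveform(sr, np.zeros(5 * sr))
        trial = assemble_trial(five, five, gap=2.0)
        assert trial.duration == pytest.approx(12.0, abs=1.0 / sr)

    def test_zero_gap_concatenates(self):
        sr = 8000
        a = Waveform(sr, np.ones(100) * 0.5)
        b = Waveform(sr, np.ones(50) * 0.25)
        trial = assemble_trial(a, b, gap=0.0)
        assert len(trial.samples) == 150

    def test_length_is_sum_of_parts(self):
        sr = 8000
        a = Waveform(sr, np.zeros(123))
        b = Waveform(sr, np.zeros(456))
        trial = assemble_trial(a, b, gap=1.0)
        assert len(trial.samples) == 123 + 456 + 8000
        assert np.all(trial.samples[123:123 + 8000] == 0.0)

    def test_sample_rate_mismatch(self):
        with pytest.raises(ValueError):
            assemble_trial(Waveform(8000, np.zeros(10)), Waveform(44100, np.zeros(10)))


def test_waveform_peak_invariant():
    with pytest.raises(ValueError):
        Waveform(8000, np.asarray([1.5]))


def test_tap_take_invariants():
    with pytest.raises(ValueError):
        TapTake("d", "t", (0.5, 0.4, 0.9))
    with pytest.raises(ValueError):
        TapTake("d", "t", (0.5, 0.9))
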