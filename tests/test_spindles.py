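"""Spindle detector: moving statistics, decision logic, events, densities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import recall_precision
from sleeposc.errors import AlignmentError, CalibrationError
from sleeposc.io_preprocess import Hypnogram
from sleeposc.spindles import (
    BANDS,
    SpindleEvent,
    SpindleParams,
    calibrate_relpower_threshold,
    decide_candidates,
    deduplicate_across_channels,
    detect_spindles,
    finalize_events,
    hold_previous,
    moving_correlation,
    moving_rms,
    relative_power_series,
    spindle_density,
)

FS = 128.0


class TestMovingRMS:
    def test_constant_signal(self):
        t, v = moving_rms(np.full(int(10 * FS), 4.0), FS)
        assert np.allclose(v, 4.0)

    def test_unit_sine_integer_periods(self):
        # 10 Hz sine, 0.3 s window = 3 full periods -> RMS 1/sqrt(2)
        x = np.sin(2 * np.pi * 10 * np.arange(int(10 * FS)) / FS)
        _, v = moving_rms(x, FS, window=0.3, step=0.1)
        assert np.allclose(v, 1 / np.sqrt(2), atol=0.02)

    def test_series_shorter_than_window_empty(self):
        t, v = moving_rms(np.zeros(10), FS, window=0.3)
        assert t.size == 0 and v.size == 0

    def test_mostly_masked_bins_dropped(self):
        x = np.ones(int(2 * FS))
        mask = np.zeros(x.size, dtype=bool)
        mask[:int(1 * FS)] = True
        _, v = moving_rms(x, FS, mask=mask)
        assert np.isnan(v[0])
        assert np.isfinite(v[-1])


class TestMovingCorrelation:
    def test_identical_series(self):
        x = np.random.default_rng(0).standard_normal(int(5 * FS))
        _, v = moving_correlation(x, x, FS)
        assert np.allclose(v, 1.0)

    def test_negated_series(self):
        x = np.random.default_rng(0).standard_normal(int(5 * FS))
        _, v = moving_correlation(x, -x, FS)
        assert np.allclose(v, -1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(int(12 * FS))
        b = rng.standard_normal(int(12 * FS))
        _, v = moving_correlation(a, b, FS)
        assert abs(np.nanmean(v[:100])) < 0.2

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            moving_correlation(np.zeros(100), np.zeros(99), FS)

    def test_zero_variance_window_undefined(self):
        a = np.zeros(int(2 * FS))
        b = np.random.default_rng(2).standard_normal(int(2 * FS))
        _, v = moving_correlation(a, b, FS)
        assert np.all(np.isnan(v))


class TestRelativePower:
    def test_pure_inband_sine(self):
        x = np.sin(2 * np.pi * 13.5 * np.arange(int(30 * FS)) / FS)
        _, v = relative_power_series(x, FS, (12.0, 15.0))
        assert np.all(v >= 0.95)

    def test_out_of_band_sine(self):
        x = np.sin(2 * np.pi * 5.0 * np.arange(int(30 * FS)) / FS)
        _, v = relative_power_series(x, FS, (12.0, 15.0))
        assert np.all(v <= 0.05)

    def test_white_noise_flat_spectrum_fraction(self):
        x = np.random.default_rng(3).standard_normal(int(600 * FS))
        _, v = relative_power_series(x, FS, (12.0, 15.0))
        expected = 3.0 / 39.5
        assert np.mean(v) == pytest.approx(expected, rel=0.5)

    def test_all_zero_frames_excluded(self):
        _, v = relative_power_series(np.zeros(int(10 * FS)), FS, (12.0, 15.0))
        assert np.all(np.isnan(v))

    def test_frame_grid_step(self):
        t, _ = relative_power_series(np.ones(int(10 * FS)), FS, (12.0, 15.0))
        assert t[0] == 0.0
        assert np.allclose(np.diff(t), 0.2)


class TestCalibration:
    def test_threshold_is_cross_channel_mean(self, processed_night,
                                             calibrated_thresholds):
        rec, hyp, _ = processed_night
        thr = calibrated_thresholds["fast"]
        means = []
        for lab in rec.channel_labels:
            t, v = relative_power_series(rec.channels[lab], rec.sampling_rate,
                                         BANDS["fast"])
            stages = np.array([hyp.stage_at(tt) for tt in t])
            means.append(np.nanmean(v[stages == "N2"]))
        assert thr["N2"] == pytest.approx(float(np.mean(means)), rel=1e-6)

    def test_threshold_between_background_and_spindles(self, processed_night,
                                                       calibrated_thresholds):
        rec, hyp, truth = processed_night
        lab = "C3-A2"
        t, v = relative_power_series(rec.channels[lab], rec.sampling_rate,
                                     BANDS["fast"])
        fast = [tr for tr in truth if tr.kind == "fast_spindle"]
        in_spindle = np.zeros(t.size, dtype=bool)
        for tr in fast:
            in_spindle |= (t < tr.end) & (t + 2.0 > tr.start)
        stages = np.array([hyp.stage_at(tt) for tt in t])
        n2 = stages == "N2"
        thr = calibrated_thresholds["fast"]["N2"]
        assert np.nanmean(v[n2 & ~in_spindle]) < thr < np.nanmean(v[n2 & in_spindle])

    def test_non_calibration_night_rejected(self, processed_night):
        rec, hyp, _ = processed_night
        import dataclasses
        other = dataclasses.replace(rec.meta, is_calibration_night=False)
        rec2 = type(rec)(channels=rec.channels, sampling_rate=rec.sampling_rate,
                         meta=other)
        with pytest.raises(CalibrationError):
            calibrate_relpower_threshold(rec2, hyp, BANDS["fast"])

    def test_insufficient_stage_data_rejected(self, processed_night):
        rec, _, _ = processed_night
        short_hyp = Hypnogram(stages=("N2",) * 4 + ("W",) * 236)
        with pytest.raises(CalibrationError):
            calibrate_relpower_threshold(rec, short_hyp, BANDS["fast"])


def _brute_force_candidates(c1, c2, c3, step):
    """Independent enumeration of the 2-of-3 rule and run extraction."""
    positive = [(int(a) + int(b) + int(c)) >= 2 for a, b, c in zip(c1, c2, c3)]
    out = []
    i = 0
    while i < len(positive):
        if positive[i]:
            j = i
            while j + 1 < len(positive) and positive[j + 1]:
                j += 1
            out.append((round(i * step, 10), round(j * step + step, 10)))
            i = j + 1
        else:
            i += 1
    return out


class TestDecision:
    def test_all_criteria_make_one_candidate(self):
        n = 30
        params = SpindleParams()
        times = np.arange(n) * 0.1
        rms = np.zeros(n)
        rms[10:20] = 2.0
        corr = np.zeros(n)
        corr[10:20] = 0.9
        rel = np.zeros(n)
        rel[10:20] = 0.5
        cands = decide_candidates(times, rms, corr, rel, 1.0, 0.2, params)
        assert len(cands) == 1
        s, e = cands[0]
        assert (s, e) == (pytest.approx(1.0), pytest.approx(2.0))

    def test_single_criterion_never_detects(self):
        n = 50
        params = SpindleParams()
        times = np.arange(n) * 0.1
        rms = np.full(n, 5.0)          # criterion 1 true everywhere
        corr = np.zeros(n)
        rel = np.zeros(n)
        assert decide_candidates(times, rms, corr, rel, 1.0, 0.2, params) == []

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = 500
        params = SpindleParams()
        times = np.arange(n) * 0.1
        c1 = rng.random(n) < 0.3
        c2 = rng.random(n) < 0.3
        c3 = rng.random(n) < 0.3
        rms = np.where(c1, 2.0, 0.0)
        corr = np.where(c2, 0.9, 0.0)
        rel = np.where(c3, 0.5, 0.0)
        got = decide_candidates(times, rms, corr, rel, 1.0, 0.2, params)
        expected = _brute_force_candidates(c1, c2, c3, 0.1)
        assert [(round(s, 10), round(e, 10)) for s, e in got] == expected


class TestFinalize:
    def _run(self, candidates, hyp=None):
        params = SpindleParams()
        n = int(600 * FS)
        xb = np.sin(2 * np.pi * 13.0 * np.arange(n) / FS)
        if hyp is None:
            hyp = Hypnogram(stages=("N2",) * 20)
        rel_t = np.arange(0, 595, 1.8)
        rel_v = np.full(rel_t.size, 0.3)
        held = hold_previous(np.arange(0, 599.7, 0.1), rel_t, rel_v)
        return finalize_events(candidates, xb, FS,
                               np.arange(0, 599.7, 0.1), held, params, hyp,
                               "C3-A2", "fast")

    def test_short_candidate_discarded(self):
        assert self._run([(10.0, 10.4)]) == []

    def test_long_merged_candidate_discarded(self):
        assert self._run([(10.0, 11.2), (11.3, 12.5)]) == []

    def test_nearby_candidates_merged(self):
        events = self._run([(10.0, 10.4), (10.5, 10.9)])
        assert len(events) == 1
        assert events[0].duration == pytest.approx(0.9)

    def test_event_characteristics(self):
        events = self._run([(10.0, 11.0)])
        assert len(events) == 1
        ev = events[0]
        assert ev.frequency == pytest.approx(13.0, abs=0.5)
        assert ev.p2p_amplitude == pytest.approx(2.0, abs=0.05)
        assert ev.stage == "N2"

    def test_wake_onset_discarded(self):
        hyp = Hypnogram(stages=("W",) * 20)
        assert self._run([(10.0, 11.0)], hyp) == []


def _ev(channel, start, relpower):
    return SpindleEvent(channel=channel, start=start, end=start + 1.0,
                        duration=1.0, p2p_amplitude=30.0, frequency=13.0,
                        mean_relative_power=relpower, stage="N2", band="fast")


class TestDeduplication:
    def test_max_relpower_survives(self):
        events = [_ev("C3-A2", 100.0, 0.30), _ev("C4-A1", 100.2, 0.25)]
        out = deduplicate_across_channels(events)
        assert len(out) == 1
        assert out[0].channel == "C3-A2"

    def test_single_channel_untouched(self):
        events = [_ev("C3-A2", 100.0, 0.3), _ev("C3-A2", 100.3, 0.2)]
        assert len(deduplicate_across_channels(events)) == 2

    def test_transitive_chain_one_survivor(self):
        events = [_ev("C3-A2", 0.0, 0.2), _ev("C4-A1", 0.4, 0.5),
                  _ev("O1-A2", 0.8, 0.3)]
        out = deduplicate_across_channels(events)
        assert len(out) == 1
        assert out[0].mean_relative_power == 0.5

    def test_tie_broken_by_earliest_onset(self):
        events = [_ev("C4-A1", 100.1, 0.3), _ev("C3-A2", 100.0, 0.3)]
        out = deduplicate_across_channels(events)
        assert out[0].start == 100.0

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_grouping(self, seed):
        rng = np.random.default_rng(seed)
        chans = ["C3-A2", "C4-A1", "O1-A2", "O2-A1"]
        events = [_ev(chans[rng.integers(4)], float(rng.uniform(0, 30)),
                      float(rng.uniform(0.05, 0.9))) for _ in range(12)]
        out = deduplicate_across_channels(events)
        # brute force: transitive closure via repeated pairwise linking
        groups = [{i} for i in range(len(events))]
        changed = True
        while changed:
            changed = False
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    if any(abs(events[i].start - events[j].start) < 0.5
                           and events[i].channel != events[j].channel
                           for i in groups[gi] for j in groups[gj]):
                        groups[gi] |= groups[gj]
                        del groups[gj]
                        changed = True
                        break
                if changed:
                    break
        expected = set()
        for g in groups:
            best = min(g, key=lambda i: (-events[i].mean_relative_power,
                                         events[i].start))
            expected.add((events[best].channel, events[best].start))
        assert {(ev.channel, ev.start) for ev in out} == expected
        # no two survivors on different channels closer than 0.5 s
        s = sorted(out, key=lambda e: e.start)
        for a, b in zip(s, s[1:]):
            if a.channel != b.channel:
                assert b.start - a.start >= 0.5


class TestDensity:
    def test_arithmetic(self):
        events = [_ev("C3-A2", 30.0 * i, 0.3) for i in range(30)]
        hyp = Hypnogram(stages=("N2",) * 30)
        df = spindle_density(events, hyp, {"N2": 900.0, "N3": 0.0})
        pooled = df[(df["stage"] == "N2") & (df["channel"] == "pooled")]
        assert pooled["density"].iloc[0] == pytest.approx(2.0)

    def test_zero_denominator_missing_not_zero(self):
        events = [_ev("C3-A2", 10.0, 0.3)]
        hyp = Hypnogram(stages=("N2",))
        df = spindle_density(events, hyp, {"N2": 30.0, "N3": 0.0})
        n3 = df[(df["stage"] == "N3") & (df["channel"] == "pooled")]
        assert np.isnan(n3["density"].iloc[0])

    def test_mask_reduces_denominator(self):
        events = [_ev("C3-A2", 30.0 * i, 0.3) for i in range(30)]
        hyp = Hypnogram(stages=("N2",) * 40)
        df = spindle_density(events, hyp, {"N2": 900.0, "N3": 0.0})
        pooled = df[(df["stage"] == "N2") & (df["channel"] == "pooled")]
        # 20 min of N2 minus 5 min mask -> 15 artifact-free minutes
        assert pooled["density"].iloc[0] == pytest.approx(2.0)


class TestDetector:
    def test_recall_and_precision_on_truths(self, processed_night,
                                            calibrated_thresholds):
        rec, hyp, truth = processed_night
        events, _ = detect_spindles(rec, hyp, BANDS["fast"],
                                    calibrated_thresholds["fast"],
                                    band_name="fast")
        fast = [t for t in truth if t.kind == "fast_spindle"]
        recall, precision = recall_precision(events, fast)
        assert recall >= 0.8
        assert precision >= 0.7

    def test_band_selectivity(self, processed_night, calibrated_thresholds):
        rec, hyp, truth = processed_night
        slow_events, _ = detect_spindles(rec, hyp, BANDS["slow"],
                                         calibrated_thresholds["slow"],
                                         band_name="slow")
        slow_truth = [t for t in truth if t.kind == "slow_spindle"]
        recall, _ = recall_precision(slow_events, slow_truth)
        assert recall >= 0.8
        # detected frequencies respect the band
        for ev in slow_events:
            assert 8.5 <= ev.frequency <= 12.5

    def test_duration_gate_invariant(self, processed_night,
                                     calibrated_thresholds):
        rec, hyp, _ = processed_night
        for band in ("slow", "fast", "overall"):
            events, _ = detect_spindles(rec, hyp, BANDS[band],
                                        calibrated_thresholds[band],
                                        band_name=band)
            for ev in events:
                assert 0.5 <= ev.duration <= 2.0
                assert ev.stage in ("N2", "N3")

    def test_raising_corr_threshold_monotone(self, processed_night,
                                             calibrated_thresholds):
        rec, hyp, _ = processed_night
        counts = []
        for thr in (0.55, 0.65, 0.85):
            params = SpindleParams(band=BANDS["fast"], corr_threshold=thr)
            events, _ = detect_spindles(rec, hyp, BANDS["fast"],
                                        calibrated_thresholds["fast"],
                                        params=params, band_name="fast")
            counts.append(len(events))
        assert counts[0] >= counts[1] >= counts[2]
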