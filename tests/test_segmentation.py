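import numpy as np
import pytest

from hiberkit.baseline import (ArousalOnset, compute_thermal_distance,
                               delta_t_series, detect_arousal_onset,
                               predict_arousal_time)
from hiberkit.segmentation import (BoutSegment, bout_statistics,
                                   ibat_lead_time, max_cooling_rate,
                                   max_rewarming_rate, segment_record)
from hiberkit.synthetic import TelemetryGenSpec, generate_telemetry
from hiberkit.telemetry import TelemetryTrace

H = 3600.0


def trace(times, values, channel="core", animal="A01"):
    return TelemetryTrace(animal, channel, np.asarray(times, float),
                          np.asarray(values, float))


def detect_onsets(channels, segs):
    """Run the ΔT/VF pipeline over segmented torpor bouts."""
    onsets, priors = [], []
    for s in (x for x in segs if x.kind == "torpor"):
        pred = predict_arousal_time(s.start, priors)
        bl = compute_thermal_distance(channels["iBAT"], channels["ambient"],
                                      pred, torpor_start=s.start)
        dts = delta_t_series(channels["iBAT"], channels["ambient"], bl)
        keep = (dts.times >= s.start) & (dts.times <= s.end + 6 * H)
        dts.times, dts.delta_t = dts.times[keep], dts.delta_t[keep]
        onset = detect_arousal_onset(dts, channels["ventilation"], torpor_start=s.start)
        if onset is not None:
            onsets.append(onset)
            priors.append((onset.onset_time - s.start) / H)
    return onsets


class TestSegmentRecord:
    def test_three_bout_cohort_matches_truth(self, small_cohort):
        spec, traces, truth = small_cohort
        for aid, chans in traces.items():
            segs = segment_record(chans["core"], chans["ambient"])
            onsets = detect_onsets(chans, segs)
            segs = segment_record(chans["core"], chans["ambient"], onsets=onsets)
            torpor = [s for s in segs if s.kind == "torpor"]
            arousal = [s for s in segs if s.kind == "arousal"]
            ibe = [s for s in segs if s.kind == "ibe"]
            assert len(torpor) == 3
            assert len(arousal) == 3
            assert len(ibe) >= 2
            for b in truth.animals[aid].bouts:
                tor = next(s for s in torpor if s.bout_index == b.bout_index)
                # 25 °C crossing and onset-derived arousal boundary
                assert abs(tor.start - b.entry_t25) < 10 * 60
                assert abs(tor.end - b.thermogenesis_onset) < 10 * 60
                aro = next(s for s in arousal if abs(s.start - tor.end) < 1)
                assert abs(aro.end - b.euthermia_t30) < 10 * 60

    def test_square_test_drop(self):
        # T_b dips to 20 °C for 5 h then returns: one test_drop, no bouts
        t = np.arange(0, 48 * H, 300.0)
        v = np.full(t.size, 34.0)
        dip = (t > 20 * H) & (t < 25 * H)
        v[dip] = 20.0
        segs = segment_record(trace(t, v), trace(t, np.full(t.size, 7.4), "ambient"))
        kinds = [s.kind for s in segs]
        assert kinds.count("test_drop") == 1
        assert "torpor" not in kinds

    def test_constant_trace_single_euthermia(self):
        t = np.arange(0, 24 * H, 300.0)
        segs = segment_record(trace(t, np.full(t.size, 34.0)),
                              trace(t, np.full(t.size, 7.4), "ambient"))
        assert len(segs) == 1
        assert segs[0].kind == "euthermia"

    def test_segments_ordered_and_nonoverlapping(self, small_cohort):
        _, traces, _ = small_cohort
        chans = next(iter(traces.values()))
        segs = segment_record(chans["core"], chans["ambient"])
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end <= b.start + 1e-6
        # every torpor preceded by an entry
        for i, s in enumerate(segs):
            if s.kind == "torpor":
                assert segs[i - 1].kind == "entry"

    def test_deterministic_and_translation_invariant(self, small_cohort):
        _, traces, _ = small_cohort
        chans = next(iter(traces.values()))
        segs1 = segment_record(chans["core"], chans["ambient"])
        segs2 = segment_record(chans["core"], chans["ambient"])
        assert segs1 == segs2
        shift = 12345.0
        core_s = trace(chans["core"].times + shift, chans["core"].values)
        amb_s = trace(chans["ambient"].times + shift, chans["ambient"].values,
                      "ambient")
        segs3 = segment_record(core_s, amb_s)
        for a, b in zip(segs1, segs3):
            assert b.start - a.start == pytest.approx(shift, abs=1.0)
            assert b.kind == a.kind


class TestBoutStatistics:
    def test_first_bout_mean_across_animals(self):
        segs = [
            BoutSegment("A01", "torpor", 0.0, 50 * H, bout_index=1),
            BoutSegment("A02", "torpor", 0.0, 63 * H, bout_index=1),
        ]
        st = bout_statistics(segs)
        row = st.per_index[st.per_index.bout_index == 1].iloc[0]
        assert row["mean"] == pytest.approx(56.5)

    def test_torpid_offset(self):
        t = np.arange(0, 60 * H, 300.0)
        amb = np.full(t.size, 7.4)
        segs = [BoutSegment("A01", "torpor", 0.0, 60 * H, bout_index=1)]
        st = bout_statistics(segs, trace(t, amb + 0.75), trace(t, amb, "ambient"))
        assert st.torpid_offset == pytest.approx(0.75, abs=1e-6)

    def test_zero_ibe_not_an_error(self):
        segs = [BoutSegment("A01", "torpor", 0.0, 50 * H, bout_index=1)]
        st = bout_statistics(segs)
        assert len(st.ibe_durations) == 0

    def test_requires_a_torpor_segment(self):
        with pytest.raises(ValueError):
            bout_statistics([BoutSegment("A01", "euthermia", 0.0, 10 * H)])


class TestRates:
    def test_constructed_cooling_slope_recovered_exactly(self):
        # piecewise-linear: flat, then -3.24 °C/h for 2 h, then flat
        t = np.arange(0, 6 * H, 60.0)
        v = np.full(t.size, 33.0)
        seg = (t >= 2 * H) & (t <= 4 * H)
        v[seg] = 33.0 - 3.24 * (t[seg] - 2 * H) / H
        v[t > 4 * H] = v[seg][-1]
        entry = BoutSegment("A01", "entry", 0.0, 6 * H)
        rate = max_cooling_rate(trace(t, v), entry)
        assert rate == pytest.approx(-3.24, abs=1e-9)

    def test_constant_trace_zero_slope(self):
        t = np.arange(0, 3 * H, 60.0)
        entry = BoutSegment("A01", "entry", 0.0, 3 * H)
        assert max_cooling_rate(trace(t, np.full(t.size, 30.0)), entry) == pytest.approx(0.0, abs=1e-9)

    def test_sigmoid_max_rate_within_5pct_of_analytic(self):
        # logistic descent, analytic max |dT/dt| = k (hi-lo) / 4
        hi, lo, k = 33.4, 8.15, 0.513  # per-hour
        t = np.arange(0, 40 * H, 300.0)
        v = lo + (hi - lo) / (1 + np.exp(k * (t / H - 20.0)))
        entry = BoutSegment("A01", "entry", 0.0, 40 * H)
        rate = max_cooling_rate(trace(t, v), entry)
        analytic = -k * (hi - lo) / 4
        assert rate == pytest.approx(analytic, rel=0.05)

    def test_constructed_rewarming_slope(self):
        t = np.arange(0, 3 * H, 60.0)
        v = np.clip(8.0 + 18.3 * t / H, None, 34.0)
        aro = BoutSegment("A01", "arousal", 0.0, 3 * H)
        rate = max_rewarming_rate(trace(t, v), aro)
        assert rate == pytest.approx(18.3, abs=1e-9)

    def test_logistic_rewarm_within_5pct(self):
        lo, hi, k = 8.0, 34.0, 2.815
        t = np.arange(0, 6 * H, 60.0)
        v = lo + (hi - lo) / (1 + np.exp(-k * (t / H - 3.0)))
        aro = BoutSegment("A01", "arousal", 0.0, 6 * H)
        analytic = k * (hi - lo) / 4
        assert max_rewarming_rate(trace(t, v), aro) == pytest.approx(analytic, rel=0.05)

    def test_window_shorter_than_segment_fatal(self):
        t = np.arange(0, 20 * 60.0, 60.0)
        entry = BoutSegment("A01", "entry", 0.0, 20 * 60.0)
        with pytest.raises(ValueError):
            max_cooling_rate(trace(t, np.full(t.size, 30.0)), entry, window_min=60)


class TestLeadTime:
    @pytest.mark.parametrize("lead_min", [40.0, 20.0])
    def test_generator_lead_recovered(self, lead_min):
        spec = TelemetryGenSpec(n_animals=1, n_cycles=1, seed=21,
                                ibat_lead_min=lead_min)
        traces, truth = generate_telemetry(spec)
        aid = next(iter(traces))
        chans = traces[aid]
        b = truth.animals[aid].bouts[0]
        segs = segment_record(chans["core"], chans["ambient"])
        onsets = detect_onsets(chans, segs)
        assert onsets, "onset must be detected"
        lead = ibat_lead_time(chans["iBAT"], chans["core"], onsets[0])
        assert lead == pytest.approx(lead_min, abs=5.0)

    def test_simultaneous_rise_zero_lead(self):
        t = np.arange(0, 50 * H, 300.0)
        base = np.full(t.size, 8.0)
        rise = np.clip((t - 45 * H) / H * 10.0, 0, 25)
        core = trace(t, base + rise, "core")
        ibat = trace(t, base + 0.7 + rise, "iBAT")
        onset = ArousalOnset("b", 45 * H, 0.6, 12.0, 3)
        lead = ibat_lead_time(ibat, core, onset)
        assert lead == pytest.approx(0.0, abs=5.0)

    def test_core_never_rises_returns_none(self):
        t = np.arange(0, 50 * H, 300.0)
        core = trace(t, np.full(t.size, 8.0), "core")
        ibat = trace(t, np.full(t.size, 8.7), "iBAT")
        onset = ArousalOnset("b", 45 * H, 0.6, 12.0, 3)
        assert ibat_lead_time(ibat, core, onset) is None
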