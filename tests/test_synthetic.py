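import numpy as np
import pytest

from hiberkit.baseline import compute_thermal_distance, predict_arousal_time
from hiberkit.segmentation import segment_record
from hiberkit.synthetic import (ImageGenSpec, TelemetryGenSpec, generate_cohort,
                                generate_section_image, generate_telemetry,
                                generate_torpid_segment)

H = 3600.0


class TestDeterminism:
    def test_same_seed_identical_telemetry(self):
        spec = TelemetryGenSpec(n_animals=1, n_cycles=1, seed=42)
        t1, _ = generate_telemetry(spec)
        t2, _ = generate_telemetry(spec)
        for aid in t1:
            for ch in t1[aid]:
                np.testing.assert_array_equal(t1[aid][ch].values,
                                              t2[aid][ch].values)
                np.testing.assert_array_equal(t1[aid][ch].times,
                                              t2[aid][ch].times)

    def test_different_seed_differs(self):
        a, _ = generate_telemetry(TelemetryGenSpec(n_animals=1, n_cycles=1, seed=1))
        b, _ = generate_telemetry(TelemetryGenSpec(n_animals=1, n_cycles=1, seed=2))
        aid = next(iter(a))
        assert not np.array_equal(a[aid]["core"].values, b[aid]["core"].values)

    def test_same_seed_identical_image(self):
        i1, t1 = generate_section_image(30.0, n_cells=50, seed=9)
        i2, t2 = generate_section_image(30.0, n_cells=50, seed=9)
        np.testing.assert_array_equal(i1.signal_channel, i2.signal_channel)
        np.testing.assert_array_equal(t1["positive"], t2["positive"])


class TestTelemetryGen:
    def test_truth_consistent_with_traces(self, single_bout):
        spec, chans, truth = single_bout
        b = truth.bouts[0]
        core = chans["core"]
        # core is euthermic before entry and torpid at the baseline window
        pre = core.values[core.times < b.entry_start - H]
        assert pre.mean() > 30
        mid = (b.entry_t25 + b.core_rise) / 2
        torpid = core.values[(core.times > mid - H) & (core.times < mid + H)]
        assert abs(torpid.mean() - (spec.ambient_mean + spec.torpid_offset)) < 1.5
        # ordering of truth events
        assert (b.entry_start < b.entry_t25 < b.thermogenesis_onset
                < b.core_rise < b.euthermia_t30 <= b.arousal_complete)
        # iBAT leads core by the configured lead
        assert b.core_rise - b.thermogenesis_onset == pytest.approx(
            spec.ibat_lead_min * 60.0)

    def test_arousal_completes_in_2p5_to_3_h(self, single_bout):
        _, _, truth = single_bout
        b = truth.bouts[0]
        assert 2.0 <= (b.arousal_complete - b.core_rise) / H <= 3.2

    def test_td_noise_level_as_specified(self, single_bout):
        spec, chans, truth = single_bout
        b = truth.bouts[0]
        pred = predict_arousal_time(b.entry_t25, [])
        bl = compute_thermal_distance(chans["iBAT"], chans["ambient"], pred,
                                      torpor_start=b.entry_t25)
        assert bl.td_mean == pytest.approx(spec.td_offset, abs=0.05)
        assert bl.td_sd == pytest.approx(spec.td_sd, abs=0.05)

    def test_ventilation_regimes(self, single_bout):
        spec, chans, truth = single_bout
        b = truth.bouts[0]
        vf = chans["ventilation"]
        torpid = vf.values[(vf.times > b.entry_t25 + 12 * H)
                           & (vf.times < b.thermogenesis_onset - H)]
        assert np.median(torpid) < 2.0
        surge = vf.values[(vf.times > b.thermogenesis_onset + 10 * 60)
                          & (vf.times < b.thermogenesis_onset + 30 * 60)]
        assert (surge > 10).all()

    def test_entry_times_gated_to_dark_phase(self):
        spec = TelemetryGenSpec(n_animals=4, n_cycles=3, seed=17)
        _, truth = generate_telemetry(spec)
        zts = []
        for at in truth.animals.values():
            for b in at.bouts:
                zts.append((b.entry_t25 / H) % 24.0)
        zts = np.array(zts)
        # dark phase is ZT 8-24 under 8L:16D; entries target ZT ~17-22
        assert (zts > 8.0).mean() > 0.85

    def test_near_noise_free_limit_recovers_td_exactly(self):
        spec = TelemetryGenSpec(
            n_animals=1, n_cycles=1, seed=0, td_sd=1e-9, ambient_sd=1e-9,
            ambient_meas_sd=0.0, core_noise_sd=0.0)
        traces, truth = generate_telemetry(spec)
        aid = next(iter(traces))
        b = truth.animals[aid].bouts[0]
        bl = compute_thermal_distance(
            traces[aid]["iBAT"], traces[aid]["ambient"],
            predict_arousal_time(b.entry_t25, []), torpor_start=b.entry_t25)
        assert bl.td_mean == pytest.approx(spec.td_offset, abs=1e-6)

    def test_impossible_spec_rejected(self):
        with pytest.raises(ValueError):
            TelemetryGenSpec(max_rewarming=0.5)   # cannot complete rewarming

    def test_shiver_dropout_creates_ibat_gaps(self):
        base = TelemetryGenSpec(n_animals=1, n_cycles=1, seed=30)
        drop = TelemetryGenSpec(n_animals=1, n_cycles=1, seed=30,
                                shiver_dropout=True)
        t_full, _ = generate_telemetry(base)
        t_drop, truth = generate_telemetry(drop)
        aid = next(iter(t_full))
        assert len(t_drop[aid]["iBAT"]) < len(t_full[aid]["iBAT"])
        # a gap occurs during the arousal rise, and never in the torpid plateau
        b = truth.animals[aid].bouts[0]
        dt = np.diff(t_drop[aid]["iBAT"].times)
        gap_times = t_drop[aid]["iBAT"].times[:-1][dt > 60]
        assert ((gap_times > b.thermogenesis_onset)
                & (gap_times < b.arousal_complete)).any()
        in_plateau = ((gap_times > b.entry_t25 + 5 * H)
                      & (gap_times < b.thermogenesis_onset - H))
        assert not in_plateau.any()


class TestTorpidSegment:
    def test_levels_and_quiescence(self):
        ib, amb, vf = generate_torpid_segment(20.0, seed=3)
        assert np.median(ib.values - np.interp(ib.times, amb.times, amb.values)) \
            == pytest.approx(0.71, abs=0.05)
        assert (vf.values < 5).all()


class TestImages:
    def test_fraction_zero_no_bright_cells(self):
        img, truth = generate_section_image(0.0, n_cells=60, seed=11)
        # no nucleus neighbourhood should carry mean signal above 1.5x background
        bg = np.median(img.signal_channel)
        for r, c in truth["centres"]:
            patch = img.signal_channel[int(r) - 3:int(r) + 4, int(c) - 3:int(c) + 4]
            assert patch.mean() < 1.5 * bg

    def test_requested_fraction_realised(self):
        _, truth = generate_section_image(22.6, n_cells=300, seed=12)
        assert truth["fraction_positive"] == pytest.approx(22.6, abs=0.5)

    def test_zero_cells_with_positive_fraction_fatal(self):
        with pytest.raises(ValueError):
            generate_section_image(10.0, n_cells=0)


class TestCohort:
    def test_manifest_links_groups_animals_sections(self):
        cohort = generate_cohort(
            telemetry_spec=TelemetryGenSpec(n_animals=1, n_cycles=1, seed=1),
            group_fractions={"a": 5.0, "b": 50.0},
            animals_per_group=2, sections_per_animal=2,
            cells_per_section=60, seed=5)
        m = cohort["manifest"]
        assert len(m) == 2 * 2 * 2
        assert set(m.group) == {"a", "b"}
        assert len(cohort["images"]) == len(m)
        # per-animal truth close to group truth
        g = m.groupby("group")["true_animal_fraction"].mean()
        assert g["b"] == pytest.approx(50.0, abs=5.0)
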