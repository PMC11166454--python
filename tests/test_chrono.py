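import numpy as np
import pytest

from hiberkit.chrono import (CircularSample, aggregate_sections,
                             circular_summary, group_compare, rayleigh_test,
                             to_circular)
from hiberkit.telemetry import ExperimentClock

from conftest import perm_maxt_pvalues


@pytest.fixture()
def clock():
    from datetime import datetime
    return ExperimentClock(lights_on=8, light_hours=8, dark_hours=16,
                           t0=datetime(2024, 1, 1, 8, 0))


class TestToCircular:
    def test_lights_on_maps_to_zero(self, clock):
        s = to_circular([0.0], clock)
        assert s.angles[0] == pytest.approx(0.0)

    def test_six_hours_maps_to_quarter_turn(self, clock):
        s = to_circular([6 * 3600.0], clock)
        assert s.angles[0] == pytest.approx(np.pi / 2)

    def test_dark_phase_angles(self, clock):
        # events 17-22 h after lights-on fall in the dark under 8L:16D
        times = np.arange(17, 22.1, 0.5) * 3600.0
        s = to_circular(times, clock)
        zt = s.angles * 24 / (2 * np.pi)
        assert (zt >= clock.light_hours).all()


class TestRayleigh:
    def test_identical_angles_maximal_concentration(self):
        r = rayleigh_test(CircularSample(np.full(8, 1.2)))
        assert r.R == pytest.approx(1.0)
        assert r.p < 1e-4
        assert r.mean_direction == pytest.approx(1.2)

    def test_perfectly_uniform_angles(self):
        r = rayleigh_test(CircularSample(np.array([0, np.pi / 2, np.pi,
                                                   3 * np.pi / 2])))
        assert r.R == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_von_mises_detected_and_mean_recovered(self):
        rng = np.random.default_rng(12)
        a = rng.vonmises(np.pi, 2.0, 100) % (2 * np.pi)
        r = rayleigh_test(CircularSample(a))
        assert r.p < 0.01
        assert abs((r.mean_direction - np.pi + np.pi) % (2 * np.pi) - np.pi) \
            < np.deg2rad(10)

    def test_agrees_with_independent_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        a = rng.vonmises(1.0, 1.0, 40) % (2 * np.pi)
        r = rayleigh_test(CircularSample(a))
        z_pg, p_pg = pg.circ_rayleigh(a)
        assert r.Z == pytest.approx(z_pg, rel=1e-9)
        # the two P-value corrections agree closely at moderate Z
        assert np.log10(r.p) == pytest.approx(np.log10(p_pg), abs=0.5)

    def test_rotation_invariance_and_equivariance(self):
        rng = np.random.default_rng(8)
        a = rng.vonmises(0.7, 1.5, 50) % (2 * np.pi)
        shift = 1.234
        r1 = rayleigh_test(CircularSample(a))
        r2 = rayleigh_test(CircularSample((a + shift) % (2 * np.pi)))
        assert r2.p == pytest.approx(r1.p, rel=1e-9)
        assert (r2.mean_direction - r1.mean_direction) % (2 * np.pi) == \
            pytest.approx(shift, abs=1e-9)

    def test_small_n_uses_simulated_null(self):
        # n = 5 concentrated angles: series formula would be inaccurate;
        # the simulated null still gives a small but non-degenerate p
        r = rayleigh_test(CircularSample(np.full(5, 0.3)))
        assert 0 < r.p < 0.05

    def test_n_below_3_fatal(self):
        with pytest.raises(ValueError):
            rayleigh_test(CircularSample(np.array([0.1, 0.2])))


class TestCircularSummary:
    def test_degenerate_sample(self):
        s = circular_summary(CircularSample(np.full(6, 2.0)))
        assert s.mean_direction == pytest.approx(2.0)
        assert s.circular_sd == pytest.approx(0.0, abs=1e-7)

    def test_antipodal_pair_undefined_mean(self):
        s = circular_summary(CircularSample(np.array([0.0, np.pi])))
        assert s.mean_direction is None
        assert np.isinf(s.circular_sd)

    def test_sd_decreases_with_concentration(self):
        rng = np.random.default_rng(4)
        sds = []
        for kappa in (0.5, 2.0, 8.0):
            a = rng.vonmises(0.0, kappa, 400) % (2 * np.pi)
            sds.append(circular_summary(CircularSample(a)).circular_sd)
        assert sds[0] > sds[1] > sds[2]


class TestGroupCompare:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(2)
        base = rng.normal(10, 1, 4)
        res = group_compare({"ctrl": base, "other": base.copy()}, "ctrl")
        assert res.f_statistic == pytest.approx(0.0, abs=1e-9)
        assert (res.comparisons.p_adjusted > 0.99).all()

    def test_huge_effect_detected(self):
        rng = np.random.default_rng(3)
        vals = {"IBE_12h": rng.normal(0.3, 0.2, 4),
                "A_d0p5": rng.normal(93, 3, 4)}
        res = group_compare(vals, "IBE_12h")
        assert res.comparisons.p_adjusted.iloc[0] < 1e-4

    def test_adjusted_p_not_below_raw_t_p(self):
        from scipy import stats as sps
        rng = np.random.default_rng(9)
        vals = {"ctrl": rng.normal(5, 1, 4),
                "g1": rng.normal(6, 1, 4),
                "g2": rng.normal(5.5, 1, 4),
                "g3": rng.normal(4.5, 1, 4)}
        res = group_compare(vals, "ctrl")
        for _, row in res.comparisons.iterrows():
            raw = sps.ttest_ind(vals[row["group"]], vals["ctrl"]).pvalue
            assert row["p_adjusted"] >= raw - 1e-9

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(42)
        means = [0.3, 0.8, 1.5, 0.5, 2.5, 0.4]
        samples = [rng.normal(m, 1.0, 4) for m in means]
        names = ["ctrl", "g1", "g2", "g3", "g4", "g5"]
        res = group_compare(dict(zip(names, samples)), "ctrl")
        _, p_perm = perm_maxt_pvalues(samples, n_perm=40_000, seed=1)
        np.testing.assert_allclose(res.comparisons.p_adjusted.to_numpy(),
                                   p_perm, atol=0.02)

    def test_single_animal_group_excluded(self):
        rng = np.random.default_rng(1)
        vals = {"ctrl": rng.normal(1, 0.1, 4), "ok": rng.normal(2, 0.1, 4),
                "single": [5.0]}
        with pytest.warns(UserWarning, match="excluded"):
            res = group_compare(vals, "ctrl")
        assert "single" not in set(res.comparisons.group)

    def test_missing_control_fatal(self):
        with pytest.raises(ValueError, match="control"):
            group_compare({"a": [1, 2], "b": [3, 4]}, "ctrl")

    def test_section_aggregation_unweighted_mean(self):
        import pandas as pd
        df = pd.DataFrame({
            "group": ["g"] * 3 + ["g"] * 3,
            "animal_id": ["a1"] * 3 + ["a2"] * 3,
            "percent_positive": [10, 20, 30, 40, 50, 60],
        })
        per_animal = aggregate_sections(df)
        assert sorted(per_animal.percent_positive) == [20.0, 50.0]


class TestCalibration:
    def test_type_i_error_at_5pct(self):
        # 2000 uniform samples of n = 28 (cohort size of the entry/arousal
        # clock analysis); heavier 5000-sim version runs in the acceptance suite
        rng = np.random.default_rng(100)
        n_sim, n = 2000, 28
        a = rng.uniform(0, 2 * np.pi, size=(n_sim, n))
        rej = sum(rayleigh_test(CircularSample(row)).p < 0.05 for row in a)
        assert rej / n_sim == pytest.approx(0.05, abs=0.015)
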