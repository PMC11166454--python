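"""Synthetic hibernation telemetry and section images with known ground truth.

The telemetry generator emulates the torpor–arousal (T–A) cycling of a small
hibernator held at a short photoperiod and ~7 °C ambient: euthermic core
temperature around 33.4 °C with a circadian ripple; sigmoidal entry into
torpor reaching a maximal cooling rate of −3.24 °C h⁻¹; a multi-day torpid
plateau riding 0.75 °C above ambient (brown-fat temperature 0.71 °C above
ambient with 0.19 °C thermoregulatory noise); brown-fat-led rewarming in
which T_iBAT precedes core temperature by a configurable lead (default
40 min), reaches +18.3 °C h⁻¹ and completes within ~2.5–3 h; short
"test-drops" before the first full bout; and ventilation frequency below
2 breaths min⁻¹ in torpor, surging past 10 breaths min⁻¹ at arousal onset.
Torpor entries are circadian-gated to the dark phase (ZT ~17–22); arousal
times inherit the broad bout-duration variance and show no circadian
preference.

Thermogenesis onset is modelled as a well-defined instant: rewarming starts
with a brief linear "ignition" ramp (the first 1 °C) and continues as a
logistic whose maximum slope equals the configured maximal rewarming rate.
All ground-truth event times (25 °C entry crossings, thermogenesis onsets,
core-rise starts, 30 °C euthermia crossings, test-drop spans) are computed
from the noise-free curves.

The image generator renders two-channel sections (nuclear stain + signal)
with a controllable fraction of signal-positive nuclei and per-cell truth.

All randomness flows from the single seed in the generation spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime

import numpy as np

from .telemetry import ExperimentClock, TelemetryTrace

__all__ = [
    "TelemetryGenSpec",
    "ImageGenSpec",
    "GroundTruth",
    "AnimalTruth",
    "BoutTruth",
    "generate_telemetry",
    "generate_torpid_segment",
    "generate_section_image",
    "generate_cohort",
    "DEFAULT_CLOCK",
]

#: Generator time base: t = 0 is lights-on (08:00) on day 0 under 8 L : 16 D.
DEFAULT_CLOCK = ExperimentClock(
    lights_on=8.0, light_hours=8.0, dark_hours=16.0,
    t0=datetime(2024, 1, 1, 8, 0, 0),
)

H = 3600.0  # seconds per hour


@dataclass
class TelemetryGenSpec:
    """Study conditions for the telemetry generator (defaults mirror the
    short-photoperiod, cold-adapted hamster paradigm)."""

    n_animals: int = 6
    n_cycles: int = 4
    seed: int = 0
    # euthermic state
    euthermic_tb: float = 33.4          # °C, cold-adapted euthermic set point
    euthermic_tb_sd: float = 0.5        # between-animal sd
    circadian_amplitude: float = 0.5    # °C peak ripple of euthermic T_b
    ibat_euthermic_offset: float = 0.3  # T_iBAT − T_b when euthermic
    # ambient
    ambient_mean: float = 7.4
    ambient_sd: float = 0.53            # slow drift sd (AR(1), tau ~6 h)
    ambient_tau_h: float = 6.0
    ambient_meas_sd: float = 0.05
    # entry
    max_cooling: float = -3.24          # °C h⁻¹, maximal entry cooling rate
    entry_zt: float = 19.5              # target ZT of the 25 °C entry crossing
    entry_zt_kappa: float = 2.0         # von Mises concentration (0 = no gating)
    # torpor
    torpid_offset: float = 0.75         # T_b − T_a in torpor
    td_offset: float = 0.71             # T_iBAT − T_a in torpor (the TD)
    td_sd: float = 0.19                 # AR(1) sd of torpid iBAT noise
    td_noise_tau_s: float = 30.0
    bout_mean_h: tuple = (56.5, 60.3, 64.1, 67.9, 71.7, 75.5)
    bout_sd_h: tuple = (9.9, 9.7, 9.5, 9.3, 9.1, 8.9)
    bout_min_h: float = 42.0            # sampled animals were torpid > 40 h
    ibe_mean_h: tuple = (61.2, 53.5, 45.9, 38.2, 30.6, 22.9)
    ibe_sd_h: tuple = (38.3, 32.2, 26.1, 20.0, 13.9, 7.86)
    ibe_min_h: float = 13.0             # entry criterion requires ≥ 12 h IBE
    # arousal
    max_rewarming: float = 18.3         # °C h⁻¹ (both T_iBAT and T_b)
    ibat_lead_min: float = 40.0         # core rise lags iBAT onset, minutes
    ignition_rate_ibat: float = 8.0     # °C h⁻¹ over the first 1 °C
    ignition_rate_core: float = 6.0
    # test-drops
    testdrop_prob: float = 0.86
    testdrop_depth: float = 21.4        # °C minimum T_b during a test-drop
    testdrop_duration_h: float = 5.3
    # ventilation
    vf_torpid: float = 1.0
    vf_euthermic: float = 60.0
    vf_peak: float = 120.0
    vf_rise_h: float = 0.5              # time from onset to peak VF
    vf_noise_frac: float = 0.05
    vf_noise_floor: float = 0.25
    # measurement noise and cadences
    core_noise_sd: float = 0.1
    core_dt_s: float = 300.0
    ibat_dt_s: float = 4.0
    ambient_dt_s: float = 60.0
    vf_dt_s: float = 60.0
    lead_in_h: float = 30.0             # euthermia before the first event
    shiver_dropout: bool = False        # drop iBAT reads at ΔT ∈ [14, 18] °C

    def __post_init__(self) -> None:
        if self.max_cooling >= 0:
            raise ValueError("max_cooling must be negative")
        if self.max_rewarming <= 0 or self.ignition_rate_ibat <= 0:
            raise ValueError("rewarming rates must be positive")
        if min(self.bout_mean_h) <= 0 or min(self.ibe_mean_h) <= 0:
            raise ValueError("durations must be positive")
        amp = self.euthermic_tb - (self.ambient_mean + self.torpid_offset)
        t_complete = (math.log(amp) + math.log(199.0)) * amp / (4 * self.max_rewarming)
        if t_complete > 6.0:
            raise ValueError("impossible spec: rewarming cannot complete in <6 h")


@dataclass
class BoutTruth:
    """Ground-truth event times (seconds) for one torpor bout."""

    bout_index: int
    entry_start: float          # departure of the entry sigmoid from euthermia
    entry_t25: float            # downward 25 °C crossing of clean core T_b
    thermogenesis_onset: float  # iBAT ignition instant
    core_rise: float            # core T_b ignition instant
    euthermia_t30: float        # upward 30 °C crossing of clean core T_b
    arousal_complete: float
    td_offset: float            # true T_iBAT − T_a during this bout


@dataclass
class AnimalTruth:
    animal_id: str
    euthermic_tb: float
    test_drops: list            # list of (start, end) seconds
    bouts: list                 # list of BoutTruth


@dataclass
class GroundTruth:
    spec: TelemetryGenSpec
    animals: dict               # animal_id -> AnimalTruth


def _ar1_fast(rng: np.random.Generator, n: int, sd: float, tau_s: float, dt_s: float) -> np.ndarray:
    """Vectorised AR(1) via scipy.signal.lfilter."""
    if n == 0:
        return np.empty(0)
    from scipy.signal import lfilter

    phi = math.exp(-dt_s / tau_s)
    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -phi], eps)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _cross(tgrid: np.ndarray, vals: np.ndarray, level: float, direction: str) -> float | None:
    s = vals - level
    if direction == "down":
        idx = np.nonzero((s[:-1] > 0) & (s[1:] <= 0))[0]
    else:
        idx = np.nonzero((s[:-1] < 0) & (s[1:] >= 0))[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    f = s[i] / (s[i] - s[i + 1])
    return float(tgrid[i] + f * (tgrid[i + 1] - tgrid[i]))


def _rise_curve(dt_h: np.ndarray, amp: float, ignition: float, max_rate: float) -> np.ndarray:
    """Rewarming above baseline: linear ignition ramp over the first 1 °C,
    then a logistic with maximum slope ``max_rate``, continuous at the join.
    ``dt_h`` is time since thermogenesis onset in hours; negative values give 0."""
    amp = max(amp, 1.5)
    k = 4.0 * max_rate / amp
    t1 = 1.0 / ignition                       # time at which ramp reaches 1 °C
    s0 = math.log(amp - 1.0) / k              # logistic offset so f(t1) = 1
    ramp = ignition * np.maximum(dt_h, 0.0)
    logi = amp * _logistic(k * (dt_h - t1 - s0))
    out = np.where(dt_h <= t1, np.minimum(ramp, 1.0), logi)
    return np.where(dt_h <= 0.0, 0.0, np.minimum(out, amp))


class _AnimalCurves:
    """Noise-free channel curves for one animal, assembled from a cycle
    schedule.  Everything is vectorised over time arrays."""

    def __init__(self, spec: TelemetryGenSpec, t_eu: float, ta_path_t: np.ndarray,
                 ta_path: np.ndarray, schedule: dict):
        self.spec = spec
        self.t_eu = t_eu
        self.ta_t = ta_path_t
        self.ta = ta_path
        self.sched = schedule

    def ambient(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.ta_t, self.ta)

    def _ripple(self, t: np.ndarray) -> np.ndarray:
        return self.spec.circadian_amplitude * np.sin(2 * np.pi * t / (24 * H))

    def core(self, t: np.ndarray) -> np.ndarray:
        return self._channel(t, core=True)

    def ibat(self, t: np.ndarray) -> np.ndarray:
        return self._channel(t, core=False)

    def _channel(self, t: np.ndarray, core: bool) -> np.ndarray:
        sp = self.spec
        eu = self.t_eu + (0.0 if core else sp.ibat_euthermic_offset)
        hi = eu + self._ripple(t)
        off = sp.torpid_offset if core else sp.td_offset
        out = hi.copy()                      # euthermia by default
        for td0, td1, depth in self.sched["test_drops"]:
            m = (t >= td0) & (t <= td1)
            if m.any():
                dip = (eu - depth) * 0.5 * (1 - np.cos(2 * np.pi * (t[m] - td0) / (td1 - td0)))
                out[m] = hi[m] - dip
        for cyc in self.sched["cycles"]:
            t_rise = cyc["core_rise"] if core else cyc["t_on"]
            # entry sigmoid blended into the torpid plateau (g: 1 -> 0)
            m = (t >= cyc["entry_start"]) & (t < t_rise)
            if m.any():
                tm = t[m]
                g = _logistic(-cyc["k_entry"] * (tm - cyc["tc_entry"]) / H)
                plateau = self.ambient(tm) + off
                out[m] = plateau + (hi[m] - plateau) * g
            # arousal: ignition ramp + logistic rise above a frozen baseline
            m2 = (t >= t_rise) & (t < cyc["next_start"])
            if m2.any():
                tm = t[m2]
                base = cyc["ta_arousal"] + off
                amp = eu - base
                v = _rise_curve((tm - t_rise) / H, amp,
                                sp.ignition_rate_core if core else sp.ignition_rate_ibat,
                                sp.max_rewarming)
                h = np.clip(v / amp, 0.0, 1.0)
                out[m2] = base + v + (hi[m2] - eu) * h
        return out

    def vf(self, t: np.ndarray) -> np.ndarray:
        sp = self.spec
        eu = self.t_eu
        out = np.full(t.shape, sp.vf_euthermic)
        for cyc in self.sched["cycles"]:
            # entry: scale with the core cooling fraction
            m = (t >= cyc["entry_start"]) & (t < cyc["t_on"])
            if m.any():
                g = _logistic(-cyc["k_entry"] * (t[m] - cyc["tc_entry"]) / H)
                out[m] = sp.vf_torpid + (sp.vf_euthermic - sp.vf_torpid) * g
            # arousal surge from thermogenesis onset
            m2 = (t >= cyc["t_on"]) & (t < cyc["next_start"])
            if m2.any():
                frac = np.clip((t[m2] - cyc["t_on"]) / (sp.vf_rise_h * H), 0.0, 1.0)
                surge = sp.vf_torpid + (sp.vf_peak - sp.vf_torpid) * frac
                # decay from peak back to euthermic after completion
                done = t[m2] >= cyc["arousal_complete"]
                decay = np.clip((t[m2] - cyc["arousal_complete"]) / (2.0 * H), 0.0, 1.0)
                out[m2] = np.where(done, sp.vf_peak + (sp.vf_euthermic - sp.vf_peak) * decay, surge)
        return out


def _build_schedule(spec: TelemetryGenSpec, rng: np.random.Generator,
                    t_eu: float) -> tuple[dict, float]:
    """Draw the cycle timetable for one animal.  Returns (schedule, t_total)."""
    sched: dict = {"test_drops": [], "cycles": []}
    t = spec.lead_in_h * H

    if rng.random() < spec.testdrop_prob:
        d_sub = max(2.0, rng.normal(spec.testdrop_duration_h, 1.0)) * H
        depth = float(np.clip(rng.normal(spec.testdrop_depth, 1.5), 16.0, 24.5))
        # testdrop_duration_h is the time spent below euthermia (30 °C); the
        # cosine dip must be wider by the sub-euthermic fraction of its period
        c = np.clip((t_eu - 30.0) / max(t_eu - depth, 1e-6), 0.01, 0.99)
        frac = 1.0 - math.acos(1.0 - 2.0 * c) / math.pi
        d = d_sub / frac
        sched["test_drops"].append((t, t + d, depth))
        t = t + d + max(spec.ibe_min_h, rng.normal(20.0, 4.0)) * H

    for i in range(spec.n_cycles):
        j = min(i, len(spec.bout_mean_h) - 1)
        bout_h = max(spec.bout_min_h, rng.normal(spec.bout_mean_h[j], spec.bout_sd_h[j]))
        ibe_h = max(spec.ibe_min_h, rng.normal(spec.ibe_mean_h[j], spec.ibe_sd_h[j]))
        cyc = {"bout_h": bout_h, "ibe_h": ibe_h, "entry_nominal": t}
        sched["cycles"].append(cyc)
        # placeholder; timing resolved in generate (needs ambient + gating)
        t = t + (20.6 + bout_h + 3.0 + ibe_h) * H
    return sched, t


def generate_telemetry(
    spec: TelemetryGenSpec,
    clock: ExperimentClock = DEFAULT_CLOCK,
) -> tuple[dict, GroundTruth]:
    """Generate a telemetry cohort with ground truth.

    Returns ``(traces, truth)`` where ``traces[animal_id][channel]`` is a
    :class:`TelemetryTrace` (channels: core, iBAT, ambient, ventilation) and
    ``truth`` records every event time computed from the noise-free curves.
    """
    rng = np.random.default_rng(spec.seed)
    traces: dict = {}
    animals: dict = {}

    for a in range(spec.n_animals):
        animal_id = f"A{a + 1:02d}"
        t_eu = float(rng.normal(spec.euthermic_tb, spec.euthermic_tb_sd))
        sched, _ = _build_schedule(spec, rng, t_eu)

        # resolve exact cycle timing with circadian gating of the entry crossing
        amp_nom = t_eu - (spec.ambient_mean + spec.torpid_offset)
        k_entry = 4.0 * abs(spec.max_cooling) / amp_nom        # h⁻¹
        half_w = math.log(199.0) / k_entry                     # h, 0.5 % tails
        # offset of the 25 °C crossing from the sigmoid centre (hours, negative)
        lo_nom = spec.ambient_mean + spec.torpid_offset
        ofs25 = -math.log((25.0 - lo_nom) / (t_eu - 25.0)) / k_entry

        t_cursor = sched["test_drops"][-1][1] + 20.0 * H if sched["test_drops"] else spec.lead_in_h * H
        cycles = []
        for i, cyc in enumerate(sched["cycles"]):
            entry_start = max(t_cursor, spec.lead_in_h * H)
            tc = entry_start + half_w * H
            t25_nom = tc + ofs25 * H
            if spec.entry_zt_kappa > 0:
                target_zt = (spec.entry_zt +
                             rng.vonmises(0.0, spec.entry_zt_kappa) * 24.0 / (2 * math.pi)) % 24.0
                zt_nom = float(clock.zeitgeber_hours(t25_nom))
                shift = (target_zt - zt_nom) % 24.0
                entry_start += shift * H
                tc += shift * H
                t25_nom += shift * H
            entry_end = tc + half_w * H
            t25 = t25_nom
            core_rise = t25 + cyc["bout_h"] * H
            t_on = core_rise - spec.ibat_lead_min * 60.0
            # completion: rise reaches 99.5 % of amplitude
            t1 = 1.0 / spec.ignition_rate_core
            k_r = 4.0 * spec.max_rewarming / amp_nom
            t_complete = core_rise + (t1 + (math.log(amp_nom - 1.0) + math.log(199.0)) / k_r) * H
            ibe_start = t_complete
            next_start = t_complete + cyc["ibe_h"] * H
            cycles.append({
                "entry_start": entry_start, "tc_entry": tc, "k_entry": k_entry,
                "entry_end": entry_end, "t25_nom": t25, "t_on": t_on,
                "core_rise": core_rise, "arousal_complete": t_complete,
                "next_start": next_start, "bout_h": cyc["bout_h"],
                "ta_entry": spec.ambient_mean, "ta_arousal": spec.ambient_mean,
            })
            t_cursor = next_start
        t_total = t_cursor + 2.0 * H

        # ambient AR(1) path on a 60 s master grid
        n_ta = int(t_total / 60.0) + 2
        ta_t = 60.0 * np.arange(n_ta)
        ta = spec.ambient_mean + _ar1_fast(rng, n_ta, spec.ambient_sd,
                                           spec.ambient_tau_h * H, 60.0)
        sched_resolved = {"test_drops": sched["test_drops"], "cycles": cycles}
        for cyc in cycles:
            cyc["ta_entry"] = float(np.interp(cyc["entry_end"], ta_t, ta))
            cyc["ta_arousal"] = float(np.interp(cyc["t_on"], ta_t, ta))
        curves = _AnimalCurves(spec, t_eu, ta_t, ta, sched_resolved)

        # --- truth events from clean curves (10 s grids around transitions) ---
        bouts = []
        for i, cyc in enumerate(cycles):
            g_entry = np.arange(cyc["entry_start"], cyc["t_on"], 10.0)
            t25 = _cross(g_entry, curves.core(g_entry), 25.0, "down")
            g_arousal = np.arange(cyc["core_rise"] - 600.0, cyc["arousal_complete"] + 600.0, 10.0)
            t30 = _cross(g_arousal, curves.core(g_arousal), 30.0, "up")
            bouts.append(BoutTruth(
                bout_index=i + 1,
                entry_start=cyc["entry_start"],
                entry_t25=t25 if t25 is not None else cyc["t25_nom"],
                thermogenesis_onset=cyc["t_on"],
                core_rise=cyc["core_rise"],
                euthermia_t30=t30 if t30 is not None else cyc["arousal_complete"],
                arousal_complete=cyc["arousal_complete"],
                td_offset=spec.td_offset,
            ))
        animals[animal_id] = AnimalTruth(
            animal_id=animal_id, euthermic_tb=t_eu,
            test_drops=[(s, e) for s, e, _ in sched["test_drops"]],
            bouts=bouts,
        )

        # --- emit noisy samples ---
        t_core = np.arange(0.0, t_total, spec.core_dt_s)
        t_ibat = np.arange(0.0, t_total, spec.ibat_dt_s)
        t_amb = np.arange(0.0, t_total, spec.ambient_dt_s)
        t_vf = np.arange(0.0, t_total, spec.vf_dt_s)

        core_v = curves.core(t_core) + rng.normal(0.0, spec.core_noise_sd, t_core.size)
        ibat_clean = curves.ibat(t_ibat)
        ibat_v = ibat_clean + _ar1_fast(rng, t_ibat.size, spec.td_sd,
                                        spec.td_noise_tau_s, spec.ibat_dt_s)
        amb_v = np.interp(t_amb, ta_t, ta) + rng.normal(0.0, spec.ambient_meas_sd, t_amb.size)
        vf_clean = curves.vf(t_vf)
        vf_v = vf_clean + rng.normal(0.0, 1.0, t_vf.size) * (
            spec.vf_noise_frac * vf_clean + spec.vf_noise_floor)
        vf_v = np.clip(vf_v, 0.0, None)

        if spec.shiver_dropout:
            # transponder loses contact during shivering: ΔT ~14–18 °C of the
            # rewarming rise (not the entry descent through the same band)
            dt_clean = ibat_clean - np.interp(t_ibat, ta_t, ta) - spec.td_offset
            rising = np.gradient(ibat_clean, t_ibat) > 0
            keep = ~((dt_clean >= 14.0) & (dt_clean <= 18.0) & rising)
            t_ibat, ibat_v = t_ibat[keep], ibat_v[keep]

        traces[animal_id] = {
            "core": TelemetryTrace(animal_id, "core", t_core, np.clip(core_v, *(-9.9, 44.9))),
            "iBAT": TelemetryTrace(animal_id, "iBAT", t_ibat, np.clip(ibat_v, *(-9.9, 44.9))),
            "ambient": TelemetryTrace(animal_id, "ambient", t_amb, np.clip(amb_v, *(-9.9, 44.9))),
            "ventilation": TelemetryTrace(animal_id, "ventilation", t_vf, vf_v),
        }

    return traces, GroundTruth(spec=spec, animals=animals)


def generate_torpid_segment(
    duration_h: float,
    spec: TelemetryGenSpec | None = None,
    seed: int = 0,
) -> tuple[TelemetryTrace, TelemetryTrace, TelemetryTrace]:
    """An arousal-free torpid record (iBAT, ambient, ventilation) for
    false-alarm calibration: iBAT rides td_offset above a drifting ambient
    with AR(1) noise of sd ``td_sd``; VF stays at the torpid level."""
    sp = spec or TelemetryGenSpec()
    rng = np.random.default_rng(seed)
    t_end = duration_h * H
    t_ib = np.arange(0.0, t_end, sp.ibat_dt_s)
    t_amb = np.arange(0.0, t_end, sp.ambient_dt_s)
    t_vf = np.arange(0.0, t_end, sp.vf_dt_s)
    n_ta = t_amb.size + 1
    ta = sp.ambient_mean + _ar1_fast(rng, n_ta, sp.ambient_sd, sp.ambient_tau_h * H, sp.ambient_dt_s)
    ta_t = sp.ambient_dt_s * np.arange(n_ta)
    ib = np.interp(t_ib, ta_t, ta) + sp.td_offset + _ar1_fast(
        rng, t_ib.size, sp.td_sd, sp.td_noise_tau_s, sp.ibat_dt_s)
    amb = np.interp(t_amb, ta_t, ta) + rng.normal(0.0, sp.ambient_meas_sd, t_amb.size)
    vf = np.clip(sp.vf_torpid + rng.normal(0.0, 0.3, t_vf.size), 0.0, None)
    return (
        TelemetryTrace("torpid", "iBAT", t_ib, ib),
        TelemetryTrace("torpid", "ambient", t_amb, amb),
        TelemetryTrace("torpid", "ventilation", t_vf, vf),
    )


# ---------------------------------------------------------------------------
# Section images
# ---------------------------------------------------------------------------

@dataclass
class ImageGenSpec:
    """Rendering parameters for synthetic two-channel section images."""

    shape: tuple = (700, 700)
    pixel_size_um: float = 0.5
    margin_px: int = 60                  # nucleus-free border; must admit a
                                         # 500 µm² background patch (~45 px)
    nucleus_radius_um: float = 3.0
    nucleus_amp: float = 120.0
    nucleus_amp_cv: float = 0.2
    background: float = 10.0             # signal-channel background level
    signal_amp: float = 60.0             # added signal over a positive nucleus
    read_noise_sd: float = 2.0
    min_sep_factor: float = 2.3          # min centre distance / radius


def _place_centres(rng: np.random.Generator, n: int, shape, margin: int,
                   min_dist: float, max_tries: int = 200000) -> np.ndarray:
    lo_r, hi_r = margin, shape[0] - margin
    lo_c, hi_c = margin, shape[1] - margin
    centres: list = []
    grid = {}
    cell = min_dist
    tries = 0
    while len(centres) < n and tries < max_tries:
        tries += 1
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        key = (int(r // cell), int(c // cell))
        ok = True
        for dk in range(-1, 2):
            for dj in range(-1, 2):
                for (rr, cc) in grid.get((key[0] + dk, key[1] + dj), ()):
                    if (rr - r) ** 2 + (cc - c) ** 2 < min_dist ** 2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            centres.append((r, c))
            grid.setdefault(key, []).append((r, c))
    if len(centres) < n:
        raise ValueError(f"could not place {n} nuclei without overlap")
    return np.asarray(centres)


def generate_section_image(
    fraction_positive: float,
    n_cells: int = 300,
    spec: ImageGenSpec | None = None,
    seed: int = 0,
    section_id: str = "S1",
    animal_id: str = "A01",
    group: str = "none",
):
    """Render a section with ``fraction_positive`` % signal-positive nuclei.

    Returns ``(image, truth)`` where ``image`` is a
    :class:`hiberkit.quant.SectionImage` and ``truth`` a dict with nucleus
    centres (row, col), the per-cell positivity flags and the ROI polygons
    (tissue ROI and a background patch in the nucleus-free margin).
    """
    from .quant import SectionImage  # local import to avoid cycle

    if not 0.0 <= fraction_positive <= 100.0:
        raise ValueError("fraction_positive must be in [0, 100]")
    if n_cells == 0 and fraction_positive > 0:
        raise ValueError("cannot have positive cells with n_cells = 0")
    sp = spec or ImageGenSpec()
    rng = np.random.default_rng(seed)
    rad_px = sp.nucleus_radius_um / sp.pixel_size_um
    centres = _place_centres(rng, n_cells, sp.shape, sp.margin_px,
                             sp.min_sep_factor * rad_px)
    n_pos = int(round(fraction_positive / 100.0 * n_cells))
    flags = np.zeros(n_cells, dtype=bool)
    flags[rng.choice(n_cells, size=n_pos, replace=False)] = True

    nuc = np.zeros(sp.shape, dtype=float)
    sig = np.full(sp.shape, sp.background, dtype=float)
    sigma = rad_px / 1.6
    half = int(math.ceil(3.5 * sigma))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    stamp = np.exp(-(yy ** 2 + xx ** 2) / (2 * sigma ** 2))
    sig_stamp = np.exp(-(yy ** 2 + xx ** 2) / (2 * (1.15 * sigma) ** 2))
    amps = sp.nucleus_amp * np.clip(
        rng.normal(1.0, sp.nucleus_amp_cv, n_cells), 0.4, 2.0)
    for (r, c), amp, pos in zip(centres, amps, flags):
        ri, ci = int(round(r)), int(round(c))
        r0, r1 = ri - half, ri + half + 1
        c0, c1 = ci - half, ci + half + 1
        nuc[r0:r1, c0:c1] += amp * stamp
        if pos:
            sig[r0:r1, c0:c1] += sp.signal_amp * sig_stamp
    nuc = rng.poisson(np.clip(nuc, 0, None)).astype(float) + rng.normal(
        0.0, sp.read_noise_sd, sp.shape)
    sig = rng.poisson(np.clip(sig, 0, None)).astype(float) + rng.normal(
        0.0, sp.read_noise_sd, sp.shape)

    img = SectionImage(
        nuclear_channel=np.clip(nuc, 0, None),
        signal_channel=np.clip(sig, 0, None),
        pixel_size_um=sp.pixel_size_um,
        section_id=section_id,
        animal_id=animal_id,
        group=group,
    )
    m = sp.margin_px
    hgt, wid = sp.shape
    tissue_roi = [(m - 5, m - 5), (wid - m + 5, m - 5),
                  (wid - m + 5, hgt - m + 5), (m - 5, hgt - m + 5)]   # (x, y)
    bg_roi = [(5, 5), (wid - 5, 5), (wid - 5, m - 8), (5, m - 8)]
    truth = {
        "centres": centres,
        "positive": flags,
        "fraction_positive": 100.0 * flags.mean() if n_cells else float("nan"),
        "tissue_roi": tissue_roi,
        "background_roi": bg_roi,
    }
    return img, truth


def generate_cohort(
    telemetry_spec: TelemetryGenSpec | None = None,
    group_fractions: dict | None = None,
    animals_per_group: int = 4,
    sections_per_animal: int = 3,
    cells_per_section: int = 300,
    between_animal_sd: float = 1.5,
    image_spec: ImageGenSpec | None = None,
    seed: int = 0,
) -> dict:
    """Full synthetic study: a telemetry cohort plus a quantification cohort.

    ``group_fractions`` maps group name -> true mean % positive cells
    (default: a six-phase pattern with strong elevation at early arousal, as
    in the choroid plexus).  Per-animal true fractions are the group mean
    plus Gaussian between-animal scatter; each section is rendered
    independently.  Returns a dict with keys ``telemetry``, ``truth``,
    ``images`` (list of (image, truth) tuples) and ``manifest`` (DataFrame).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    tel_spec = telemetry_spec or TelemetryGenSpec(seed=int(rng.integers(2 ** 31)))
    traces, truth = generate_telemetry(tel_spec)
    if group_fractions is None:
        group_fractions = {
            "ENT_lt25": 1.0, "T_40h": 65.0, "A_d0p5": 93.0,
            "A_d3": 60.0, "IBE_1h": 2.0, "IBE_12h": 0.3,
        }
    images = []
    rows = []
    for group, frac in group_fractions.items():
        for a in range(animals_per_group):
            animal_frac = float(np.clip(rng.normal(frac, between_animal_sd), 0.0, 100.0))
            animal_id = f"{group}-a{a + 1}"
            for s in range(sections_per_animal):
                img_seed = int(rng.integers(2 ** 31))
                img, itruth = generate_section_image(
                    animal_frac, n_cells=cells_per_section, spec=image_spec,
                    seed=img_seed, section_id=f"s{s + 1}",
                    animal_id=animal_id, group=group)
                images.append((img, itruth))
                rows.append({
                    "group": group, "animal_id": animal_id,
                    "section_id": f"s{s + 1}",
                    "true_group_fraction": frac,
                    "true_animal_fraction": animal_frac,
                    "true_section_fraction": itruth["fraction_positive"],
                })
    return {
        "telemetry": traces,
        "truth": truth,
        "images": images,
        "manifest": pd.DataFrame(rows),
    }
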