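"""The six sampling-point criteria of the torpor–arousal cycle.

Brain sampling across the T–A cycle uses six physiologically anchored phase
labels, each with strict criteria evaluated from live telemetry:

* ``ENT_lt25``  — torpor entry: at least 12 h of inter-bout euthermia, then a
  steady decline of core T_b below 25 °C with T_iBAT also below 25 °C and the
  animal in a curled-up torpid posture;
* ``T_40h``    — deep torpor: 40 h after the entry crossing, with both T_b and
  T_iBAT within 2 °C of ambient and ventilation below 2 breaths min⁻¹;
* ``A_d0p5``   — earliest arousal: torpid > 40 h, then ΔT >= 0.5 °C with
  VF > 10 breaths min⁻¹;
* ``A_d3``     — early arousal: same criteria at ΔT >= 3 °C;
* ``IBE_1h`` / ``IBE_12h`` — 1 h / 12 h after euthermia (T_b = 30 °C) is
  regained following an arousal.

``classify_phase`` is a pure function of an :class:`AnimalState`; ``replay``
applies the criteria chronologically over an aligned cohort table, an offline
stand-in for live monitoring dashboards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline import (ArousalOnset, TorporBaseline, compute_thermal_distance,
                       delta_t_series, detect_arousal_onset, predict_arousal_time)
from .segmentation import BoutSegment, segment_record
from .telemetry import TelemetryTrace

__all__ = [
    "PHASE_LABELS",
    "PhaseCriteria",
    "AnimalState",
    "PhaseLabel",
    "classify_phase",
    "eligibility",
    "replay",
]

PHASE_LABELS = ("ENT_lt25", "T_40h", "A_d0p5", "A_d3", "IBE_1h", "IBE_12h", "none")


@dataclass(frozen=True)
class PhaseCriteria:
    """All thresholds of the sampling criteria (defaults as published)."""

    entry_tb: float = 25.0          # °C, T_b and T_iBAT must both be below
    min_ibe_h: float = 12.0         # h of euthermia required before an entry
    torpid_at_h: float = 40.0       # h after entry for the torpid sample
    torpid_band: float = 2.0        # °C of ambient for T_b and T_iBAT
    torpid_vf: float = 2.0          # breaths/min upper bound in torpor
    min_torpor_h: float = 40.0      # h torpid before arousal labels
    arousal_dt_1: float = 0.5       # °C ΔT, earliest arousal
    arousal_dt_2: float = 3.0       # °C ΔT, early arousal
    arousal_vf: float = 10.0        # breaths/min lower bound at arousal
    euthermia_tb: float = 30.0      # °C, IBE is declared at this T_b
    ibe_1_h: float = 1.0
    ibe_12_h: float = 12.0


@dataclass
class AnimalState:
    """Snapshot of one animal at time ``t`` (seconds), with history."""

    t: float
    T_b: float | None = None
    T_iBAT: float | None = None
    T_a: float | None = None
    VF: float | None = None
    delta_t: float | None = None
    posture_torpid: bool | None = None
    segments: list = field(default_factory=list)   # BoutSegments up to t

    def _current(self) -> BoutSegment | None:
        for s in reversed(self.segments):
            if s.start <= self.t:
                return s
        return None


@dataclass(frozen=True)
class PhaseLabel:
    label: str
    evidence: dict

    def __post_init__(self) -> None:
        if self.label not in PHASE_LABELS:
            raise ValueError(f"unknown phase label {self.label!r}")


def _finite(*vals) -> bool:
    return all(v is not None and np.isfinite(v) for v in vals)


def classify_phase(state: AnimalState, criteria: PhaseCriteria | None = None) -> PhaseLabel:
    """Assign at most one sampling label to a state.

    Precedence: arousal > torpid > entry > IBE — an animal satisfying a later
    arousal criterion is never down-labelled to an earlier phase.  When the
    only candidate label cannot be evaluated because a required channel is
    absent, the result is ``none`` with the reason in the evidence.
    """
    c = criteria or PhaseCriteria()
    cur = state._current()
    ev: dict = {"t": state.t}

    # history-derived quantities
    torpor_start = None
    prior_euthermic_h = None
    ibe_elapsed_h = None
    if cur is not None:
        if cur.kind == "torpor":
            torpor_start = cur.start
        elif cur.kind == "arousal":
            pass
        elif cur.kind in ("ibe", "euthermia"):
            ibe_elapsed_h = (state.t - cur.start) / 3600.0
        if cur.kind in ("entry", "torpor"):
            prev = [s for s in state.segments if s.end <= cur.start
                    and s.kind in ("ibe", "euthermia")]
            if prev:
                prior_euthermic_h = prev[-1].duration_h
    torpid_h = (state.t - torpor_start) / 3600.0 if torpor_start is not None else None

    # --- arousal labels ---
    if torpid_h is not None and torpid_h > c.min_torpor_h:
        if not _finite(state.delta_t) or not _finite(state.VF):
            ev["reason"] = "insufficient channels for arousal criteria"
        else:
            ev.update(delta_t=state.delta_t, VF=state.VF, torpid_h=torpid_h)
            if state.delta_t >= c.arousal_dt_2 and state.VF > c.arousal_vf:
                return PhaseLabel("A_d3", ev)
            if state.delta_t >= c.arousal_dt_1 and state.VF > c.arousal_vf:
                return PhaseLabel("A_d0p5", ev)

    # --- torpid sample ---
    if torpid_h is not None and torpid_h >= c.torpid_at_h:
        if _finite(state.T_b, state.T_iBAT, state.T_a, state.VF):
            ev.update(T_b=state.T_b, T_iBAT=state.T_iBAT, T_a=state.T_a,
                      VF=state.VF, torpid_h=torpid_h)
            in_band = (abs(state.T_b - state.T_a) <= c.torpid_band
                       and abs(state.T_iBAT - state.T_a) <= c.torpid_band)
            quiescent = state.VF < c.torpid_vf
            arousing = (_finite(state.delta_t)
                        and state.delta_t >= c.arousal_dt_1)
            if in_band and quiescent and not arousing:
                return PhaseLabel("T_40h", ev)
        else:
            ev.setdefault("reason", "insufficient channels for torpid criteria")

    # --- entry ---
    if cur is not None and cur.kind in ("entry", "torpor"):
        if _finite(state.T_b, state.T_iBAT):
            ev.update(T_b=state.T_b, T_iBAT=state.T_iBAT,
                      prior_euthermic_h=prior_euthermic_h)
            posture_ok = state.posture_torpid
            if posture_ok is None:
                posture_ok = True
                ev["posture"] = "unavailable; criterion degraded to temperature-only"
            ibe_ok = prior_euthermic_h is not None and prior_euthermic_h >= c.min_ibe_h
            entering = cur.kind == "entry" or (
                torpid_h is not None and torpid_h * 60.0 <= 30.0)
            if (entering and ibe_ok and posture_ok
                    and state.T_b < c.entry_tb and state.T_iBAT < c.entry_tb):
                return PhaseLabel("ENT_lt25", ev)
        else:
            ev.setdefault("reason", "insufficient channels for entry criteria")

    # --- IBE ---
    if cur is not None and cur.kind == "ibe" and ibe_elapsed_h is not None:
        ev.update(ibe_elapsed_h=ibe_elapsed_h)
        if ibe_elapsed_h >= c.ibe_12_h:
            return PhaseLabel("IBE_12h", ev)
        if ibe_elapsed_h >= c.ibe_1_h:
            return PhaseLabel("IBE_1h", ev)

    return PhaseLabel("none", ev)


def eligibility(segments: list[BoutSegment], min_cycles: int = 3) -> bool:
    """True when at least ``min_cycles`` completed torpor→arousal→IBE cycles
    precede the current (possibly open) bout."""
    completed = 0
    stage = 0   # 0: want torpor, 1: want arousal, 2: want ibe
    for s in segments:
        if s.kind == "torpor":
            stage = 1
        elif s.kind == "arousal" and stage == 1:
            stage = 2
        elif s.kind == "ibe" and stage == 2:
            completed += 1
            stage = 0
    return completed >= min_cycles


def replay(
    cohort: dict,
    criteria: PhaseCriteria | None = None,
    grid_s: float = 60.0,
) -> pd.DataFrame:
    """Chronological log of label firings for a cohort.

    ``cohort`` maps animal id -> dict of channel -> :class:`TelemetryTrace`
    (channels ``core``, ``ambient`` required; ``iBAT`` and ``ventilation``
    enable the arousal labels).  For each animal the record is segmented,
    per-bout baselines and ΔT/VF onsets are computed, and the first time each
    label's criteria hold in each cycle is logged.  Deterministic for a fixed
    input.
    """
    c = criteria or PhaseCriteria()
    rows = []
    for animal_id in sorted(cohort):
        channels = cohort[animal_id]
        core = channels.get("core")
        ambient = channels.get("ambient")
        ibat = channels.get("iBAT")
        vf = channels.get("ventilation")
        if core is None:
            raise ValueError(f"{animal_id}: core channel is required")
        have_arousal = ibat is not None and vf is not None and ambient is not None
        if not have_arousal:
            warnings.warn(
                f"{animal_id}: iBAT/ventilation/ambient missing - "
                "arousal labels disabled", stacklevel=2)

        segs = segment_record(core, ambient)
        onsets: list[ArousalOnset] = []
        baselines: dict[int, TorporBaseline] = {}
        if have_arousal:
            priors: list[float] = []
            for s in [x for x in segs if x.kind == "torpor"]:
                pred = predict_arousal_time(s.start, priors)
                try:
                    bl = compute_thermal_distance(
                        ibat, ambient, pred, torpor_start=s.start, torpor_end=s.end,
                        bout_id=f"{animal_id}-b{s.bout_index}")
                except ValueError:
                    continue
                dts = delta_t_series(ibat, ambient, bl, grid_s=grid_s)
                keep = (dts.times >= s.start) & (dts.times <= s.end + 6 * 3600.0)
                dts.times, dts.delta_t = dts.times[keep], dts.delta_t[keep]
                onset = detect_arousal_onset(
                    dts, vf, torpor_start=s.start,
                    min_torpor_h=c.min_torpor_h, dt_thresh=c.arousal_dt_1,
                    vf_thresh=c.arousal_vf)
                baselines[s.bout_index] = bl
                if onset is not None:
                    onsets.append(onset)
                    priors.append((onset.onset_time - s.start) / 3600.0)
            segs = segment_record(core, ambient, onsets=onsets)

        prev_euthermic_h = None
        for s in segs:
            if s.kind in ("ibe", "euthermia"):
                prev_euthermic_h = s.duration_h
            if s.kind == "entry":
                continue
            if s.kind == "torpor":
                # ENT fires at the entry->torpor crossing if the entry criteria held
                if prev_euthermic_h is not None and prev_euthermic_h >= c.min_ibe_h:
                    rows.append((animal_id, s.start, "ENT_lt25", s.bout_index))
                # T-40h
                t40 = s.start + c.torpid_at_h * 3600.0
                if t40 < s.end:
                    rows.append((animal_id, t40, "T_40h", s.bout_index))
                if have_arousal:
                    onset = next((o for o in onsets
                                  if s.start < o.onset_time <= s.end + 60.0), None)
                    bl = baselines.get(s.bout_index)
                    if onset is not None:
                        rows.append((animal_id, onset.onset_time, "A_d0p5", s.bout_index))
                        if bl is not None:
                            # ΔT = 3 °C crossing after the onset
                            dts = delta_t_series(ibat, ambient, bl, grid_s=grid_s)
                            m = dts.times >= onset.onset_time
                            above = np.nonzero(m & (dts.delta_t >= c.arousal_dt_2))[0]
                            if above.size:
                                rows.append((animal_id, float(dts.times[above[0]]),
                                             "A_d3", s.bout_index))
            if s.kind == "ibe":
                bout = max((x.bout_index or 0) for x in segs
                           if x.kind == "torpor" and x.start < s.start)
                if s.start + c.ibe_1_h * 3600.0 <= s.end:
                    rows.append((animal_id, s.start + c.ibe_1_h * 3600.0, "IBE_1h", bout))
                if s.start + c.ibe_12_h * 3600.0 <= s.end:
                    rows.append((animal_id, s.start + c.ibe_12_h * 3600.0, "IBE_12h", bout))

    log = pd.DataFrame(rows, columns=["animal_id", "t_seconds", "label", "bout_index"])
    return log.sort_values(["animal_id", "t_seconds"], kind="stable").reset_index(drop=True)
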