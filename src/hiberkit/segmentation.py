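"""Torpor–arousal cycle segmentation and bout statistics.

The core-temperature record of a hibernating animal is partitioned into
labelled, non-overlapping segments:

* ``euthermia`` — regulated high body temperature before the first bout or
  after a test-drop;
* ``test_drop`` — a completed sub-euthermic excursion shorter than a cutoff
  (default 24 h), the brief practice drops seen before full multi-day bouts;
* ``entry`` — from the last euthermic local maximum to the downward 25 °C
  crossing of T_b;
* ``torpor`` — from that crossing to the start of rewarming;
* ``arousal`` — from rewarming start to the upward 30 °C crossing;
* ``ibe`` — inter-bout euthermia after an arousal.

The torpor→arousal boundary on a core-only record is found by confirming a
2 °C rise above the torpid plateau trend and then refining backwards to the
last time the (median-smoothed) trace sat within 0.5 °C of the plateau —
i.e. the start of the core ignition ramp.  When brown-fat and ventilation
channels are available, the ΔT/VF detector's onset overrides this boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline import ArousalOnset
from .telemetry import TelemetryTrace, align_channels

__all__ = [
    "BoutSegment",
    "CycleStats",
    "segment_record",
    "bout_statistics",
    "max_cooling_rate",
    "max_rewarming_rate",
    "ibat_lead_time",
]

SEGMENT_KINDS = ("euthermia", "test_drop", "entry", "torpor", "arousal", "ibe")


@dataclass(frozen=True)
class BoutSegment:
    """A labelled, half-open time interval [start, end) of one animal's record."""

    animal_id: str
    kind: str
    start: float
    end: float
    bout_index: int | None = None   # ordinal, torpor segments only

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.end > self.start:
            raise ValueError("segment end must exceed start")

    @property
    def duration_h(self) -> float:
        return (self.end - self.start) / 3600.0


@dataclass
class CycleStats:
    """Cohort-level bout statistics."""

    bout_durations: pd.DataFrame     # one row per torpor segment
    ibe_durations: pd.DataFrame      # one row per ibe segment
    per_index: pd.DataFrame          # mean/sd duration by bout_index
    torpid_offset: float | None      # mean (T_b − T_a) during torpor, °C
    test_drop_durations_h: list = field(default_factory=list)

    @property
    def n_bouts(self) -> int:
        return len(self.bout_durations)


def _smooth(trace: TelemetryTrace, window_s: float) -> np.ndarray:
    s = pd.Series(trace.values, index=pd.to_timedelta(trace.times, unit="s"))
    return s.rolling(pd.Timedelta(seconds=window_s), min_periods=1,
                     center=True).median().to_numpy()


def _interp_cross(t0, v0, t1, v1, level) -> float:
    if v1 == v0:
        return float(t0)
    return float(t0 + (level - v0) / (v1 - v0) * (t1 - t0))


def _hinge_start(times, vals, i_confirm, pre_h: float = 3.0, post_min: float = 10.0):
    """Rewarming start as the breakpoint of a flat-then-rising hinge fit.

    Least-squares fit of ``y = mu`` (t < tau) joined to ``y = mu + s (t-tau)``
    (t >= tau, s >= 0) over a window reaching ``pre_h`` hours before and
    ``post_min`` minutes past the confirmation index; the breakpoint grid is
    the sample grid.  Robust to slow plateau drift and noise, unbiased at the
    corner of the ignition ramp.
    """
    lo = int(np.searchsorted(times, times[i_confirm] - pre_h * 3600.0))
    hi = min(int(np.searchsorted(times, times[i_confirm] + post_min * 60.0)), len(times))
    tt = times[lo:hi]
    yy = vals[lo:hi]
    if len(tt) < 6:
        return float(times[i_confirm])
    best_sse, best_tau = np.inf, float(times[i_confirm])
    for m in range(3, len(tt) - 2):
        tau = tt[m]
        mu = yy[:m].mean()
        x = tt[m:] - tau
        y1 = yy[m:]
        s = max(0.0, float((x * (y1 - mu)).sum() / (x * x).sum()))
        sse = float(((yy[:m] - mu) ** 2).sum() + ((y1 - mu - s * x) ** 2).sum())
        if sse < best_sse:
            best_sse, best_tau = sse, float(tau)
    return best_tau


def segment_record(
    core: TelemetryTrace,
    ambient: TelemetryTrace | None = None,
    entry_thresh: float = 25.0,
    euthermia_thresh: float = 30.0,
    testdrop_max_h: float = 24.0,
    smooth_window_s: float = 1800.0,
    rise_confirm: float = 2.0,
    rise_thresh: float = 0.5,
    onsets: list[ArousalOnset] | None = None,
) -> list[BoutSegment]:
    """Label a core-temperature record into T–A cycle segments.

    Sub-euthermic excursions are delimited by the downward crossing of
    ``euthermia_thresh`` and the next upward crossing back; excursions that
    never reach ``entry_thresh`` are ignored (euthermic dips), completed
    excursions shorter than ``testdrop_max_h`` are labelled ``test_drop``,
    and all others become entry/torpor/arousal(/ibe) sequences.  ``onsets``
    (from the ΔT/VF detector) override the core-derived torpor→arousal
    boundary of the bout containing them.
    """
    if len(core) < 3:
        raise ValueError("core trace too short to segment")
    t = core.times
    v = _smooth(core, smooth_window_s)
    # ambient-compensated series for the torpor->arousal boundary: the torpid
    # plateau tracks ambient, so rises are judged on (T_b - T_a) when possible
    if ambient is not None and len(ambient) >= 2:
        v_comp = v - np.interp(t, ambient.times, ambient.values)
    else:
        v_comp = v
    segs: list[BoutSegment] = []
    aid = core.animal_id

    # sub-euthermic excursions on the smoothed trace
    below = v < euthermia_thresh
    edges = np.diff(below.astype(int))
    starts = np.nonzero(edges == 1)[0] + 1      # first index below
    ends = np.nonzero(edges == -1)[0] + 1       # first index back above
    if below[0]:
        starts = np.r_[0, starts]
    excursions = []
    for i0 in starts:
        i1_candidates = ends[ends > i0]
        i1 = int(i1_candidates[0]) if i1_candidates.size else len(t)  # open-ended
        excursions.append((int(i0), i1))
    # merge excursions separated by < 1 h above threshold (noise at the edge)
    merged = []
    for i0, i1 in excursions:
        if merged and i1 <= merged[-1][1]:
            continue
        if merged and t[i0] - t[min(merged[-1][1], len(t) - 1)] < 3600.0:
            merged[-1] = (merged[-1][0], i1)
        else:
            merged.append((i0, i1))

    bout_index = 0
    cursor = float(t[0])
    for i0, i1 in merged:
        seg_v = v[i0:i1]
        if seg_v.size == 0 or np.nanmin(seg_v) > entry_thresh:
            continue                       # shallow dip, stays euthermia
        completed = i1 < len(t)
        # crossing times at the excursion edges
        t_down = (_interp_cross(t[i0 - 1], v[i0 - 1], t[i0], v[i0], euthermia_thresh)
                  if i0 > 0 else float(t[i0]))
        t_up = (_interp_cross(t[i1 - 1], v[i1 - 1], t[i1], v[i1], euthermia_thresh)
                if completed else float(t[-1]))

        if completed and (t_up - t_down) / 3600.0 < testdrop_max_h:
            if t_down > cursor:
                segs.append(BoutSegment(aid, _pre_kind(segs), cursor, t_down))
            segs.append(BoutSegment(aid, "test_drop", t_down, t_up))
            cursor = t_up
            continue

        # full bout: 25 °C downward crossing inside the excursion
        rel = np.nonzero(v[i0:i1] < entry_thresh)[0]
        j = i0 + int(rel[0])
        t25 = _interp_cross(t[j - 1], v[j - 1], t[j], v[j], entry_thresh) if j > 0 else float(t[j])

        # entry start: last euthermic local maximum before the drop
        t_entry = _entry_start(t, v, i0, euthermia_thresh)
        t_entry = max(t_entry, cursor)

        # torpor -> arousal boundary
        t_arousal = None
        if onsets:
            for on in onsets:
                if t25 < on.onset_time < t_up:
                    t_arousal = float(on.onset_time)
                    break
        if t_arousal is None:
            t_arousal = _core_arousal_start(t, v_comp, j, i1, rise_confirm, rise_thresh)

        if t_entry > cursor:
            segs.append(BoutSegment(aid, _pre_kind(segs), cursor, t_entry))
        bout_index += 1
        segs.append(BoutSegment(aid, "entry", t_entry, t25))
        if t_arousal is not None and t_arousal > t25:
            segs.append(BoutSegment(aid, "torpor", t25, t_arousal, bout_index=bout_index))
            if completed:
                segs.append(BoutSegment(aid, "arousal", t_arousal, t_up))
                cursor = t_up
            else:
                segs.append(BoutSegment(aid, "arousal", t_arousal, float(t[-1])))
                cursor = float(t[-1])
        else:
            segs.append(BoutSegment(aid, "torpor", t25, t_up if completed else float(t[-1]),
                                    bout_index=bout_index))
            cursor = t_up if completed else float(t[-1])

    if cursor < float(t[-1]) - 1.0:
        segs.append(BoutSegment(aid, _pre_kind(segs), cursor, float(t[-1])))
    if not segs:
        segs.append(BoutSegment(aid, "euthermia", float(t[0]), float(t[-1])))

    if ambient is None:
        warnings.warn("ambient trace missing: torpid offset unavailable", stacklevel=2)
    return segs


def _pre_kind(segs: list[BoutSegment]) -> str:
    """Euthermic spans are 'ibe' after a torpor bout, else 'euthermia'."""
    for s in reversed(segs):
        if s.kind in ("torpor", "arousal"):
            return "ibe"
        if s.kind == "test_drop":
            return "euthermia"
    return "euthermia"


def _entry_start(t, v, i0, euthermia_thresh) -> float:
    """Last local maximum above the euthermia threshold before index i0."""
    lo = np.searchsorted(t, t[i0] - 12 * 3600.0)
    win = v[lo:i0]
    if win.size == 0:
        return float(t[i0])
    above = win >= euthermia_thresh
    if not above.any():
        return float(t[i0])
    # local maxima in the window
    best = lo + int(np.nonzero(above)[0][-1])
    for k in range(i0 - 2, lo, -1):
        if v[k] >= euthermia_thresh and v[k] >= v[k - 1] and v[k] >= v[k + 1]:
            best = k
            break
    return float(t[best])


def _core_arousal_start(t, v, j25, i1, rise_confirm, rise_thresh) -> float | None:
    """Rewarming start within a torpid excursion from the core trace alone.

    A rise of ``rise_confirm`` °C over the trailing plateau median confirms
    that rewarming is underway; the start itself is then located by the hinge
    (flat-then-rising changepoint) fit around the confirmation point.
    """
    i_end = min(i1, len(t) - 1)
    if i_end - j25 < 5:
        return None
    lo = j25 + max(3, (i_end - j25) // 10)   # stay clear of the entry tail
    seg = slice(lo, i_end + 1)
    times = t[seg]
    vals = v[seg]
    n = vals.size
    if n < 5:
        return None
    # trailing median via pandas (time-based 4 h window, 1 h lag)
    s = pd.Series(vals, index=pd.to_timedelta(times, unit="s"))
    trail = s.rolling(pd.Timedelta(hours=5), min_periods=3).median().shift(1).to_numpy()
    dev = vals - trail
    conf = np.nonzero(dev >= rise_confirm)[0]
    if conf.size == 0:
        return None
    ic = int(conf[0])
    return _hinge_start(t, v, lo + ic)


def bout_statistics(
    segments: list[BoutSegment],
    core: TelemetryTrace | None = None,
    ambient: TelemetryTrace | None = None,
) -> CycleStats:
    """Durations per bout/IBE, per-index summaries and the torpid offset.

    The torpid offset is the mean of (T_b − T_a) over all torpor segments,
    computed on the aligned grid; it is ``None`` when either trace is absent.
    """
    torpor = [s for s in segments if s.kind == "torpor"]
    if not torpor:
        raise ValueError("bout_statistics requires at least one torpor segment")
    ibe = [s for s in segments if s.kind == "ibe"]
    drops = [s.duration_h for s in segments if s.kind == "test_drop"]

    bouts = pd.DataFrame({
        "animal_id": [s.animal_id for s in torpor],
        "bout_index": [s.bout_index for s in torpor],
        "duration_h": [s.duration_h for s in torpor],
    })
    ibes = pd.DataFrame({
        "animal_id": [s.animal_id for s in ibe],
        "duration_h": [s.duration_h for s in ibe],
    })
    per_index = (bouts.groupby("bout_index")["duration_h"]
                 .agg(["mean", "std", "count"]).reset_index())

    offset = None
    if core is not None and ambient is not None:
        diffs = []
        table = align_channels([core, ambient], grid=300.0)
        tt = table.index.to_numpy(float)
        d = (table["core"] - table["ambient"]).to_numpy(float)
        for s in torpor:
            # the settled torpid plateau: skip the post-25 °C cooling tail
            # (up to 12 h, never more than 40 % of the bout)
            settle = s.start + min(12 * 3600.0, 0.4 * (s.end - s.start))
            m = (tt >= settle) & (tt <= s.end)
            if m.any():
                diffs.append(d[m])
        if diffs:
            alld = np.concatenate(diffs)
            offset = float(np.nanmean(alld))
    return CycleStats(
        bout_durations=bouts,
        ibe_durations=ibes,
        per_index=per_index,
        torpid_offset=offset,
        test_drop_durations_h=drops,
    )


def _max_window_slope(times: np.ndarray, values: np.ndarray, window_s: float,
                      mode: str) -> float:
    """Extreme least-squares slope (°C h⁻¹) over sliding windows of
    ``window_s`` seconds.  Gap-aware: windows whose span deviates from the
    target by > 25 % are skipped."""
    n = len(times)
    if n < 2:
        raise ValueError("need at least 2 samples for a slope")
    j = np.searchsorted(times, times + window_s, side="left")
    j = np.clip(j, 0, n - 1)
    # prefix sums for O(n) windowed regression
    t = times / 3600.0
    ct = np.concatenate([[0.0], np.cumsum(t)])
    cv = np.concatenate([[0.0], np.cumsum(values)])
    ctt = np.concatenate([[0.0], np.cumsum(t * t)])
    ctv = np.concatenate([[0.0], np.cumsum(t * values)])
    best = None
    for i in range(n):
        k = int(j[i])
        if k <= i + 1:
            continue
        span = times[k] - times[i]
        if span < 0.75 * window_s or span > 1.5 * window_s:
            continue
        m = k - i + 1
        st = ct[k + 1] - ct[i]
        sv = cv[k + 1] - cv[i]
        stt = ctt[k + 1] - ctt[i]
        stv = ctv[k + 1] - ctv[i]
        denom = m * stt - st * st
        if denom <= 0:
            continue
        slope = (m * stv - st * sv) / denom
        if best is None:
            best = slope
        elif (mode == "min" and slope < best) or (mode == "max" and slope > best):
            best = slope
    if best is None:
        raise ValueError("no complete sliding window in segment")
    return float(best)


def max_cooling_rate(core: TelemetryTrace, entry: BoutSegment,
                     window_min: float = 60.0) -> float:
    """Steepest cooling slope during entry (°C h⁻¹, negative), the regression
    over the steepest sliding window."""
    sub = core.crop(entry.start, entry.end)
    if len(sub) < 2 or sub.times[-1] - sub.times[0] < window_min * 60.0:
        raise ValueError("entry segment shorter than the slope window")
    return _max_window_slope(sub.times, sub.values, window_min * 60.0, "min")


def max_rewarming_rate(trace: TelemetryTrace, arousal: BoutSegment,
                       window_min: float = 30.0) -> float:
    """Steepest rewarming slope during arousal (°C h⁻¹, positive)."""
    sub = trace.crop(arousal.start, arousal.end)
    if len(sub) < 2 or sub.times[-1] - sub.times[0] < window_min * 60.0:
        raise ValueError("arousal segment shorter than the slope window")
    return _max_window_slope(sub.times, sub.values, window_min * 60.0, "max")


def ibat_lead_time(
    ibat: TelemetryTrace,
    core: TelemetryTrace,
    onset: ArousalOnset,
    core_rise_thresh: float = 0.5,
    baseline_window_h: float = 2.0,
    confirm_samples: int = 2,
) -> float | None:
    """Minutes by which the brown-fat onset precedes the core rise.

    The core torpid baseline is the median of core samples over the
    ``baseline_window_h`` hours preceding the onset; the core rise is the
    first of ``confirm_samples`` consecutive samples at least
    ``core_rise_thresh`` above it.  ``None`` when the core never rises.
    """
    t0 = onset.onset_time
    pre = core.crop(t0 - baseline_window_h * 3600.0 - 600.0, t0)
    if len(pre) < 3:
        raise ValueError("no core data before onset to establish a baseline")
    base = float(np.median(pre.values))
    post = core.crop(t0, t0 + 6 * 3600.0)
    if len(post) == 0:
        return None
    above = post.values >= base + core_rise_thresh
    if confirm_samples > 1:
        kern = np.ones(confirm_samples, dtype=int)
        runs = np.convolve(above.astype(int), kern, mode="valid") == confirm_samples
        hits = np.nonzero(runs)[0]
    else:
        hits = np.nonzero(above)[0]
    if hits.size == 0:
        return None
    return float((post.times[int(hits[0])] - t0) / 60.0)
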