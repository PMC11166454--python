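"""Torpor baseline (thermal distance) and arousal-onset detection.

During deep torpor, brown-adipose-tissue temperature sits a small, roughly
constant offset above ambient.  That per-bout offset — the *thermal distance*
TD, the mean of (T_iBAT − T_a) over a stable torpid window — defines a
tailored torpor baseline of zero for each bout, so that the rewarming signal

    ΔT = (T_iBAT − T_a) − TD

is insensitive to ambient drift.  The earliest reliable predictor of an
arousal event is the conjunction of a small ΔT elevation (0.5 °C) with a rise
in ventilation frequency above 10 breaths min⁻¹, evaluated only after the
animal has been torpid for more than 40 h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .telemetry import TelemetryTrace, align_channels

__all__ = [
    "TorporBaseline",
    "DeltaTSeries",
    "ArousalOnset",
    "predict_arousal_time",
    "compute_thermal_distance",
    "delta_t",
    "delta_t_series",
    "detect_arousal_onset",
]

#: Population-level default torpor bout duration, hours, used to predict the
#: first arousal of an animal with no bout history.
DEFAULT_BOUT_HOURS = 60.0


@dataclass(frozen=True)
class TorporBaseline:
    """Per-bout thermal distance TD: mean/sd of (T_iBAT − T_a) over a torpid
    baseline window."""

    bout_id: str
    window_start: float
    window_end: float
    td_mean: float
    td_sd: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.window_end - self.window_start < 5 * 3600.0 - 1e-6:
            raise ValueError("baseline window must span at least 5 h")
        if self.n_samples < 100:
            raise ValueError("baseline requires at least 100 aligned samples")
        if not np.isfinite(self.td_mean) or self.td_sd < 0:
            raise ValueError("invalid TD statistics")


@dataclass
class DeltaTSeries:
    """ΔT per the baseline transform, defined only where both iBAT and
    ambient samples exist (gaps are NaN)."""

    bout_id: str
    times: np.ndarray
    delta_t: np.ndarray
    baseline: TorporBaseline


@dataclass(frozen=True)
class ArousalOnset:
    """Earliest time the two arousal criteria held persistently."""

    bout_id: str
    onset_time: float
    delta_t_at_onset: float
    vf_at_onset: float
    persistence_samples: int
    dt_thresh: float = 0.5
    vf_thresh: float = 10.0

    def __post_init__(self) -> None:
        if self.delta_t_at_onset < self.dt_thresh - 1e-9:
            raise ValueError(f"onset requires delta_t >= {self.dt_thresh} °C")
        if self.vf_at_onset <= self.vf_thresh:
            raise ValueError(f"onset requires VF > {self.vf_thresh} breaths/min")


def predict_arousal_time(
    bout_start: float,
    prior_bout_durations_h,
    default_h: float = DEFAULT_BOUT_HOURS,
) -> float:
    """Predicted arousal time (seconds) from the mean of prior bout durations;
    falls back to a population default when no history exists."""
    priors = np.asarray(list(prior_bout_durations_h), dtype=float)
    if priors.size and np.any(priors < 0):
        raise ValueError("bout durations must be nonnegative")
    hours = float(priors.mean()) if priors.size else float(default_h)
    return bout_start + hours * 3600.0


def compute_thermal_distance(
    ibat: TelemetryTrace,
    ambient: TelemetryTrace,
    predicted_arousal: float,
    min_window_h: float = 5.0,
    lead_h: float = 20.0,
    torpor_start: float | None = None,
    torpor_end: float | None = None,
    bout_id: str = "bout",
    grid_s: float = 60.0,
) -> TorporBaseline:
    """Thermal distance TD over the latest admissible torpid window.

    The window is the span of length ``min_window_h`` ending ``lead_h`` hours
    before the predicted arousal time, so that the baseline is established
    well clear of the actual rewarming.  When the torpid span is already
    known (offline analysis), ``torpor_end`` additionally caps the window:
    a bout much shorter than predicted would otherwise place the window on
    the arousal itself.  TD is the mean of (T_iBAT − T_a) over aligned
    sample pairs in the window; the sd is reported alongside.
    """
    end = predicted_arousal - lead_h * 3600.0
    if torpor_end is not None:
        end = min(end, torpor_end - 3600.0)
    start = end - min_window_h * 3600.0
    if torpor_start is not None and start < torpor_start:
        raise ValueError(
            "insufficient baseline window: torpor too short to place a "
            f"{min_window_h} h window ending {lead_h} h before predicted arousal"
        )
    table = align_channels([ibat, ambient], grid=grid_s)
    sel = table.loc[(table.index >= start) & (table.index <= end)]
    diffs = (sel["iBAT"] - sel["ambient"]).dropna()
    if len(diffs) == 0:
        raise ValueError("all-gap alignment in baseline window")
    if len(diffs) < 100:
        raise ValueError(
            f"insufficient baseline window: only {len(diffs)} aligned samples"
        )
    return TorporBaseline(
        bout_id=bout_id,
        window_start=start,
        window_end=end,
        td_mean=float(diffs.mean()),
        td_sd=float(diffs.std(ddof=1)),
        n_samples=int(len(diffs)),
    )


def delta_t(ibat_value, ambient_value, baseline: TorporBaseline):
    """ΔT = (T_iBAT − T_a) − TD.  Pure arithmetic; accepts scalars or arrays."""
    return (np.asarray(ibat_value, float) - np.asarray(ambient_value, float)) - baseline.td_mean


def delta_t_series(
    ibat: TelemetryTrace,
    ambient: TelemetryTrace,
    baseline: TorporBaseline,
    grid_s: float = 60.0,
) -> DeltaTSeries:
    """ΔT on a regular grid; NaN wherever either channel has a gap."""
    table = align_channels([ibat, ambient], grid=grid_s)
    dt = (table["iBAT"] - table["ambient"]).to_numpy(float) - baseline.td_mean
    return DeltaTSeries(
        bout_id=baseline.bout_id,
        times=table.index.to_numpy(float),
        delta_t=dt,
        baseline=baseline,
    )


def _rolling_median_by_time(times: np.ndarray, values: np.ndarray, window_s: float) -> np.ndarray:
    s = pd.Series(values, index=pd.to_timedelta(times, unit="s"))
    return s.rolling(pd.Timedelta(seconds=window_s), min_periods=1).median().to_numpy()


def detect_arousal_onset(
    dts: DeltaTSeries,
    vf: TelemetryTrace,
    torpor_start: float,
    min_torpor_h: float = 40.0,
    dt_thresh: float = 0.5,
    vf_thresh: float = 10.0,
    persistence: int = 3,
    vf_smooth_s: float = 60.0,
) -> ArousalOnset | None:
    """Earliest persistent satisfaction of the arousal criteria.

    Returns the first of ``persistence`` consecutive grid samples at which
    ΔT >= ``dt_thresh`` and (median-smoothed) VF > ``vf_thresh``, restricted
    to times more than ``min_torpor_h`` after torpor entry; ``None`` if the
    criteria are never met.  VF is smoothed with a trailing 1-min rolling
    median before thresholding to reject single-frame glitches.
    """
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    if len(vf) == 0:
        raise ValueError("criteria require ventilation: VF trace is empty")
    t = dts.times
    if vf.times[0] > t[-1] or vf.times[-1] < t[0]:
        raise ValueError("criteria require ventilation: VF does not cover the span")
    vf_sm = _rolling_median_by_time(vf.times, vf.values, vf_smooth_s)
    # step-hold smoothed VF onto the ΔT grid (staleness: 2 native gaps or 5 min)
    native = np.median(np.diff(vf.times)) if len(vf) > 1 else 60.0
    horizon = max(2.5 * native, 300.0)
    pos = np.searchsorted(vf.times, t, side="right") - 1
    vf_on_grid = np.full(t.shape, np.nan)
    has = pos >= 0
    age = np.where(has, t - vf.times[np.clip(pos, 0, None)], np.inf)
    fresh = has & (age <= horizon)
    vf_on_grid[fresh] = vf_sm[pos[fresh]]

    eligible = (t - torpor_start) > min_torpor_h * 3600.0
    with np.errstate(invalid="ignore"):
        cond = (
            eligible
            & np.isfinite(dts.delta_t)
            & (dts.delta_t >= dt_thresh)
            & np.isfinite(vf_on_grid)
            & (vf_on_grid > vf_thresh)
        )
    # first run of `persistence` consecutive True
    if persistence == 1:
        hits = np.nonzero(cond)[0]
    else:
        kern = np.ones(persistence, dtype=int)
        runs = np.convolve(cond.astype(int), kern, mode="valid") == persistence
        hits = np.nonzero(runs)[0]
    if hits.size == 0:
        return None
    i0 = int(hits[0])
    return ArousalOnset(
        bout_id=dts.bout_id,
        onset_time=float(t[i0]),
        delta_t_at_onset=float(dts.delta_t[i0]),
        vf_at_onset=float(vf_on_grid[i0]),
        persistence_samples=persistence,
        dt_thresh=dt_thresh,
        vf_thresh=vf_thresh,
    )
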