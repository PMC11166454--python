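"""Telemetry data model, readers/writers, binning and channel alignment.

A hibernation telemetry record consists of several asynchronously sampled
channels: core body temperature (T_b, implanted logger, minutes cadence),
interscapular brown-adipose-tissue temperature (T_iBAT, transponder tag read
every few seconds), ambient temperature (T_a) and ventilation frequency (VF,
breaths per minute, derived from video).  Each channel is held as a
:class:`TelemetryTrace`: an irregular series of (time, value) samples on a
single time axis of seconds since experiment start.  Gaps are represented by
*absent samples*, never by filled-in values — transponder reads drop out when
the animal shivers, and downstream estimators must see those spans as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "TEMP_BOUNDS",
    "DEFAULT_STALENESS_S",
    "TelemetryTrace",
    "ExperimentClock",
    "read_trace",
    "write_trace",
    "bin_average",
    "align_channels",
]

#: Recognised channel names.
CHANNELS = ("core", "iBAT", "ambient", "ventilation")

#: Plausibility bounds for temperature channels, beyond device physics.
TEMP_BOUNDS = (-10.0, 45.0)

#: Default staleness horizon per channel for grid alignment, seconds.  The
#: horizon reflects the native cadence of each device: transponder tag and
#: ambient sensors report every few seconds to a minute, the core logger on a
#: minutes scale.
DEFAULT_STALENESS_S: Mapping[str, float] = {
    "core": 900.0,
    "iBAT": 120.0,
    "ambient": 120.0,
    "ventilation": 180.0,
}


@dataclass(frozen=True)
class ExperimentClock:
    """Maps experiment seconds to wall-clock and zeitgeber time.

    Parameters
    ----------
    lights_on : float
        Clock time of lights-on in hours (e.g. ``8.0`` for 08:00).
    light_hours, dark_hours : float
        Photoperiod; must sum to 24 h.  The short-photoperiod hibernation
        regime is 8 h light : 16 h dark.
    t0 : datetime, optional
        Calendar datetime of experiment start (time 0 of every trace).
    """

    lights_on: float = 8.0
    light_hours: float = 8.0
    dark_hours: float = 16.0
    t0: datetime | None = None

    def __post_init__(self) -> None:
        if abs(self.light_hours + self.dark_hours - 24.0) > 1e-9:
            raise ValueError(
                f"photoperiod must sum to 24 h, got "
                f"{self.light_hours}+{self.dark_hours}"
            )
        if not 0.0 <= self.lights_on < 24.0:
            raise ValueError("lights_on must be a clock hour in [0, 24)")

    def zeitgeber_hours(self, t_seconds) -> np.ndarray:
        """Hours after lights-on (ZT) for experiment times in seconds."""
        t = np.asarray(t_seconds, dtype=float)
        if self.t0 is not None:
            start = (
                self.t0.hour * 3600.0
                + self.t0.minute * 60.0
                + self.t0.second
                + self.t0.microsecond * 1e-6
            )
        else:
            start = 0.0
        zt = (start + t - self.lights_on * 3600.0) % 86400.0
        return zt / 3600.0

    def is_dark(self, t_seconds) -> np.ndarray:
        return self.zeitgeber_hours(t_seconds) >= self.light_hours


@dataclass
class TelemetryTrace:
    """One channel of timestamped samples for one animal.

    ``times`` are seconds since experiment start, strictly increasing, with
    gaps allowed.  ``values`` are °C for temperature channels and
    breaths min⁻¹ for ventilation.
    """

    animal_id: str
    channel: str
    times: np.ndarray
    values: np.ndarray
    device_accuracy: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0)) + 1
                raise ValueError(
                    f"times must be strictly increasing; violation at sample {i}"
                )
        if np.any(~np.isfinite(self.values)):
            raise ValueError("values must be finite; represent gaps by absent samples")
        if self.channel == "ventilation":
            if np.any(self.values < 0):
                raise ValueError("ventilation frequency must be >= 0")
        else:
            lo, hi = TEMP_BOUNDS
            if np.any((self.values < lo) | (self.values > hi)):
                raise ValueError(f"temperature outside plausibility bounds {TEMP_BOUNDS}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def crop(self, start: float, end: float) -> "TelemetryTrace":
        """Sub-trace with start <= t <= end (may be empty-length invalid; use
        only when at least one sample falls inside)."""
        m = (self.times >= start) & (self.times <= end)
        return replace(self, times=self.times[m], values=self.values[m])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_seconds": self.times,
                "value": self.values,
                "channel": self.channel,
                "animal_id": self.animal_id,
            }
        )


def _valid_mask(channel: str, values: np.ndarray) -> np.ndarray:
    finite = np.isfinite(values)
    if channel == "ventilation":
        return finite & (values >= 0)
    lo, hi = TEMP_BOUNDS
    return finite & (values >= lo) & (values <= hi)


def read_trace(
    path: str | Path,
    channel: str,
    clock: ExperimentClock | None = None,
    animal_id: str | None = None,
) -> TelemetryTrace:
    """Read one telemetry channel from delimited text.

    The file must have a header and either a ``t_seconds`` column or a
    ``timestamp_iso8601`` column (converted to seconds using ``clock.t0``),
    plus a ``value`` column; ``channel`` and ``animal_id`` columns are
    optional.  Comma and tab delimiters are auto-detected.  Rows whose value
    violates the channel's plausibility bounds are dropped with a warning;
    non-monotone timestamps among the remaining rows are a fatal error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - message path
        raise ValueError(f"unreadable telemetry file {path}: {exc}") from exc
    cols = {c.strip(): c for c in df.columns}
    if "t_seconds" in cols:
        times = pd.to_numeric(df[cols["t_seconds"]], errors="coerce").to_numpy(float)
    elif "timestamp_iso8601" in cols:
        if clock is None or clock.t0 is None:
            raise ValueError(
                "timestamp_iso8601 input requires an ExperimentClock with t0"
            )
        ts = pd.to_datetime(df[cols["timestamp_iso8601"]], errors="coerce")
        times = (ts - pd.Timestamp(clock.t0)).dt.total_seconds().to_numpy(float)
    else:
        raise ValueError(f"{path}: need a t_seconds or timestamp_iso8601 column")
    if "value" not in cols:
        raise ValueError(f"{path}: need a value column")
    values = pd.to_numeric(df[cols["value"]], errors="coerce").to_numpy(float)
    if animal_id is None:
        if "animal_id" in cols and len(df) and not df[cols["animal_id"]].isna().all():
            animal_id = str(df[cols["animal_id"]].dropna().iloc[0])
        else:
            animal_id = path.stem

    ok = np.isfinite(times) & _valid_mask(channel, values)
    n_dropped = int(len(values) - ok.sum())
    if n_dropped:
        warnings.warn(
            f"{path.name}: dropped {n_dropped} row(s) violating {channel} invariants",
            stacklevel=2,
        )
    times, values = times[ok], values[ok]
    if len(times) < 2:
        raise ValueError(f"{path}: fewer than 2 valid rows")
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        # report in original (post-filter) row numbering, 0-based data rows
        raise ValueError(
            f"{path}: non-monotone timestamps at data row {int(bad[0]) + 1}"
        )
    return TelemetryTrace(animal_id=animal_id, channel=channel, times=times, values=values)


def write_trace(trace: TelemetryTrace, path: str | Path, sep: str = ",") -> None:
    """Write a trace as delimited text (UTF-8, header, empty string for NA)."""
    df = trace.to_frame()
    df["t_seconds"] = df["t_seconds"].map(lambda v: format(v, ".3f"))
    df["value"] = df["value"].map(lambda v: format(v, ".6g"))
    df.to_csv(path, sep=sep, index=False, na_rep="")


def bin_average(trace: TelemetryTrace, width: float) -> TelemetryTrace:
    """Average samples into fixed-width time bins.

    Bins are ``[k*width, (k+1)*width)`` on the absolute time axis; the output
    carries one sample per non-empty bin at the bin midpoint whose value is
    the arithmetic mean of in-bin samples.  Empty bins are emitted as gaps
    (absent samples), never interpolated.  This is the "binned into 10 min
    averages" display convention for long records.
    """
    if width <= 0:
        raise ValueError("bin width must be > 0")
    if len(trace) == 0:
        raise ValueError("cannot bin an empty trace")
    idx = np.floor(trace.times / width).astype(np.int64)
    # groupby preserves bin order since times are sorted
    uniq, inverse = np.unique(idx, return_inverse=True)
    sums = np.bincount(inverse, weights=trace.values)
    counts = np.bincount(inverse)
    mids = (uniq + 0.5) * width
    return replace(trace, times=mids.astype(float), values=sums / counts)


def align_channels(
    traces: Sequence[TelemetryTrace],
    grid: float,
    staleness: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Resample asynchronous channels onto a common time grid.

    For each grid point the channel value is the most recent sample within
    that channel's staleness horizon (step-hold), otherwise NaN (gap).  No
    value is ever invented further than one horizon from a real sample.

    Returns a DataFrame indexed by grid time (seconds) with one column per
    channel.
    """
    if not traces:
        raise ValueError("align_channels requires at least one trace")
    ids = {t.animal_id for t in traces}
    if len(ids) > 1:
        raise ValueError(f"traces from multiple animals: {sorted(ids)}")
    if grid <= 0:
        raise ValueError("grid spacing must be > 0")
    horizons = dict(DEFAULT_STALENESS_S)
    if staleness:
        horizons.update(staleness)

    t_lo = min(t.times[0] for t in traces)
    t_hi = max(t.times[-1] for t in traces)
    n = int(np.floor((t_hi - t_lo) / grid)) + 1
    grid_t = t_lo + grid * np.arange(n)

    out = pd.DataFrame(index=pd.Index(grid_t, name="t_seconds"))
    for tr in traces:
        h = horizons.get(tr.channel, grid)
        # most recent sample index at/before each grid point
        pos = np.searchsorted(tr.times, grid_t, side="right") - 1
        vals = np.full(n, np.nan)
        has = pos >= 0
        age = np.where(has, grid_t - tr.times[np.clip(pos, 0, None)], np.inf)
        fresh = has & (age <= h)
        vals[fresh] = tr.values[pos[fresh]]
        out[tr.channel] = vals
    return out
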