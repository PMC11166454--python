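"""Circular statistics of bout timing and group comparisons of cell counts.

Entry into torpor is circadian-gated while arousal is not; testing this uses
the Rayleigh test of circular uniformity on event times mapped to zeitgeber
angles (0 = lights-on, 2π = 24 h).  Differences in percent c-fos-positive
cells between sampling-phase groups are tested by one-way ANOVA with
Dunnett's multiple-comparisons test against a control group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .telemetry import ExperimentClock

__all__ = [
    "CircularSample",
    "RayleighResult",
    "CircularSummary",
    "GroupComparison",
    "to_circular",
    "rayleigh_test",
    "circular_summary",
    "group_compare",
]


@dataclass
class CircularSample:
    """Angles in radians on [0, 2π); zeitgeber convention (0 = lights-on)."""

    angles: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 1:
            raise ValueError("angles must be 1-D")
        if np.any((self.angles < 0) | (self.angles >= 2 * np.pi)):
            raise ValueError("angles must lie in [0, 2π)")

    def __len__(self) -> int:
        return len(self.angles)


@dataclass(frozen=True)
class RayleighResult:
    n: int
    mean_direction: float    # radians; NaN when R == 0
    R: float                 # mean resultant length in [0, 1]
    Z: float                 # n R²
    p: float                 # in (0, 1]


@dataclass(frozen=True)
class CircularSummary:
    n: int
    mean_direction: float | None   # None when undefined (R = 0)
    circular_sd: float             # sqrt(-2 ln R), radians
    R: float


def to_circular(event_times_s, clock: ExperimentClock) -> CircularSample:
    """Map event times (seconds since experiment start) to zeitgeber angles."""
    zt = clock.zeitgeber_hours(np.asarray(event_times_s, dtype=float))
    angles = (2 * np.pi * zt / 24.0) % (2 * np.pi)
    return CircularSample(angles=angles)


def _resultant(angles: np.ndarray) -> tuple[float, float]:
    C = float(np.cos(angles).sum())
    S = float(np.sin(angles).sum())
    n = len(angles)
    R = min(math.hypot(C, S) / n, 1.0)
    mean_dir = math.atan2(S, C) % (2 * math.pi)
    return R, mean_dir


def _rayleigh_p_series(Z: float, n: int) -> float:
    """Series approximation for the Rayleigh P-value (accurate for n >= 10)."""
    p = math.exp(-Z) * (
        1.0
        + (2.0 * Z - Z * Z) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z ** 2 + 76.0 * Z ** 3 - 9.0 * Z ** 4) / (288.0 * n * n)
    )
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def _rayleigh_p_exact_mc(R_obs: float, n: int, n_sim: int = 100_000) -> float:
    """Small-sample null distribution of R by simulation (fixed internal seed
    so results are reproducible)."""
    rng = np.random.default_rng(180_360)
    a = rng.uniform(0.0, 2 * np.pi, size=(n_sim, n))
    Rs = np.hypot(np.cos(a).sum(axis=1), np.sin(a).sum(axis=1)) / n
    p = (np.count_nonzero(Rs >= R_obs) + 1) / (n_sim + 1)
    return min(p, 1.0)


def rayleigh_test(sample: CircularSample) -> RayleighResult:
    """Rayleigh test of circular uniformity.

    Z = n R²; the P-value uses the standard series approximation for n >= 10
    and a simulated exact null for smaller samples.
    """
    n = len(sample)
    if n < 3:
        raise ValueError("Rayleigh test requires n >= 3")
    R, mean_dir = _resultant(sample.angles)
    Z = n * R * R
    if n >= 10:
        p = _rayleigh_p_series(Z, n)
    else:
        p = _rayleigh_p_exact_mc(R, n)
    return RayleighResult(n=n, mean_direction=mean_dir if R > 0 else float("nan"),
                          R=R, Z=Z, p=p)


def circular_summary(sample: CircularSample, r_eps: float = 1e-12) -> CircularSummary:
    """Mean direction and circular standard deviation sqrt(−2 ln R).

    When R = 0 (perfectly balanced angles) the mean direction is undefined
    and reported as ``None`` with an infinite circular sd.
    """
    n = len(sample)
    if n < 2:
        raise ValueError("circular summary requires n >= 2")
    R, mean_dir = _resultant(sample.angles)
    if R <= r_eps:
        return CircularSummary(n=n, mean_direction=None, circular_sd=float("inf"), R=R)
    return CircularSummary(n=n, mean_direction=mean_dir,
                           circular_sd=math.sqrt(-2.0 * math.log(R)), R=R)


@dataclass
class GroupComparison:
    """One-way ANOVA with Dunnett's test against a named control group."""

    control: str
    group_stats: pd.DataFrame        # group, n, mean, sd
    f_statistic: float
    df_between: int
    df_within: int
    p_omnibus: float
    comparisons: pd.DataFrame        # group, statistic, p_adjusted

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA: F({self.df_between}, {self.df_within}) = "
            f"{self.f_statistic:.3f}, p = {self.p_omnibus:.4g}",
            f"Dunnett vs control '{self.control}':",
        ]
        for _, row in self.comparisons.iterrows():
            lines.append(f"  {row['group']:>10s}: t = {row['statistic']:+.3f}, "
                         f"p_adj = {row['p_adjusted']:.4g}")
        return "\n".join(lines)


def aggregate_sections(section_values: pd.DataFrame,
                       value_col: str = "percent_positive") -> pd.DataFrame:
    """Per-animal values as the unweighted mean over that animal's sections.

    Expects columns ``group``, ``animal_id`` and ``value_col``.
    """
    return (section_values.groupby(["group", "animal_id"], sort=False)[value_col]
            .mean().reset_index())


def group_compare(per_animal_values: dict, control: str) -> GroupComparison:
    """One-way fixed-effects ANOVA plus Dunnett's multiple-comparisons test.

    ``per_animal_values`` maps group name -> per-animal values (one number
    per animal, typically the mean percent positive over its sections).
    Groups with fewer than 2 animals are excluded with a warning; the control
    group must be present and is excluded from the comparisons table.
    """
    if control not in per_animal_values:
        raise ValueError(f"control group {control!r} missing")
    groups = {}
    for name, vals in per_animal_values.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 2:
            warnings.warn(f"group {name!r} has <2 animals; excluded", stacklevel=2)
            continue
        groups[name] = arr
    if control not in groups:
        raise ValueError(f"control group {control!r} has <2 animals")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 animals")

    names = [control] + [g for g in groups if g != control]
    samples = [groups[g] for g in names]
    F, p_omni = sps.f_oneway(*samples)
    k = len(samples)
    n_tot = sum(len(s) for s in samples)

    res = sps.dunnett(*samples[1:], control=samples[0], alternative="two-sided")
    comparisons = pd.DataFrame({
        "group": names[1:],
        "statistic": np.asarray(res.statistic, dtype=float),
        "p_adjusted": np.asarray(res.pvalue, dtype=float),
    })
    stats_df = pd.DataFrame({
        "group": names,
        "n": [len(s) for s in samples],
        "mean": [float(s.mean()) for s in samples],
        "sd": [float(s.std(ddof=1)) for s in samples],
    })
    return GroupComparison(
        control=control,
        group_stats=stats_df,
        f_statistic=float(F),
        df_between=k - 1,
        df_within=n_tot - k,
        p_omnibus=float(p_omni),
        comparisons=comparisons,
    )


def plot_circular(sample: CircularSample, ax=None, **kwargs):
    """Polar scatter of a circular sample with its mean-resultant arrow.

    Convenience display in the style of chronobiology "Rayleigh plots";
    requires matplotlib.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.plot(sample.angles, np.ones(len(sample)), "ko", ms=4, **kwargs)
    R, mu = _resultant(sample.angles)
    ax.annotate("", xy=(mu, R), xytext=(0, 0),
                arrowprops={"arrowstyle": "-|>", "lw": 2})
    ax.set_yticks([])
    return ax
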