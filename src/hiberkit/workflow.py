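"""End-to-end per-animal analysis: segmentation + baselines + onset detection.

Convenience composition of the module pipeline for one animal's channel set:
core-temperature segmentation, per-bout thermal-distance baselines using
arousal times predicted from the animal's own bout history, ΔT/VF onset
detection, and a final segmentation pass with the detected onsets overriding
the core-derived torpor→arousal boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .baseline import (ArousalOnset, TorporBaseline, compute_thermal_distance,
                       delta_t_series, detect_arousal_onset,
                       predict_arousal_time)
from .segmentation import BoutSegment, segment_record

__all__ = ["AnimalAnalysis", "analyze_animal"]

H = 3600.0


@dataclass
class AnimalAnalysis:
    segments: list                      # final segments (onset-overridden)
    core_only_segments: list            # first-pass, core-derived boundaries
    baselines: dict = field(default_factory=dict)   # bout_index -> TorporBaseline
    onsets: dict = field(default_factory=dict)      # bout_index -> ArousalOnset


def analyze_animal(
    channels: dict,
    grid_s: float = 60.0,
    default_bout_h: float = 60.0,
) -> AnimalAnalysis:
    """Run the full pipeline on one animal's ``{channel: TelemetryTrace}``."""
    core = channels["core"]
    ambient = channels.get("ambient")
    ibat = channels.get("iBAT")
    vf = channels.get("ventilation")

    first = segment_record(core, ambient)
    baselines: dict = {}
    onsets: dict = {}
    if ibat is not None and vf is not None and ambient is not None:
        priors: list[float] = []
        for s in (x for x in first if x.kind == "torpor"):
            pred = predict_arousal_time(s.start, priors, default_h=default_bout_h)
            try:
                bl = compute_thermal_distance(
                    ibat, ambient, pred, torpor_start=s.start, torpor_end=s.end,
                    bout_id=f"{core.animal_id}-b{s.bout_index}", grid_s=grid_s)
            except ValueError:
                continue
            dts = delta_t_series(ibat, ambient, bl, grid_s=grid_s)
            keep = (dts.times >= s.start) & (dts.times <= s.end + 6 * H)
            dts.times, dts.delta_t = dts.times[keep], dts.delta_t[keep]
            onset = detect_arousal_onset(dts, vf, torpor_start=s.start)
            baselines[s.bout_index] = bl
            if onset is not None:
                onsets[s.bout_index] = onset
                priors.append((onset.onset_time - s.start) / H)
        final = segment_record(core, ambient, onsets=list(onsets.values()))
    else:
        final = first
    return AnimalAnalysis(segments=final, core_only_segments=first,
                          baselines=baselines, onsets=onsets)
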