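# hiberkit

Analysis toolkit for torpor–arousal (T–A) cycling in hibernating small
mammals monitored by multi-channel temperature telemetry, with a companion
module for quantifying immediate-early-gene (c-fos) expression in brain
sections sampled at defined cycle phases.

## Who this is for

Physiologists running hibernation studies in which animals carry a core
body-temperature logger (T_b, minutes cadence), an interscapular
brown-adipose-tissue transponder (T_iBAT, read every few seconds) and an
ambient sensor (T_a), with ventilation frequency (VF, breaths min⁻¹) scored
from video.  The central problem is catching arousal from torpor *early*:
core temperature is a late indicator, but brown-fat thermogenesis and
breathing accelerate minutes after arousal begins.

## The method

**Thermal-distance baseline and ΔT.**  For each torpor bout a baseline is
established from a ≥ 5 h torpid window placed 20 h before the predicted
arousal time (predicted from that animal's mean prior bout duration).  The
thermal distance TD is the mean of (T_iBAT − T_a) over the window, so that

```
ΔT = (T_iBAT − T_a) − TD
```

is a per-bout rewarming signal with a tailored zero that is insensitive to
ambient drift.

**Earliest reliable arousal onset.**  After an animal has been torpid for
more than 40 h, the onset is the first time ΔT ≥ 0.5 °C *and* VF > 10
breaths min⁻¹ hold simultaneously for three consecutive aligned samples.

**Cycle segmentation.**  Records are labelled into euthermia, test-drops
(completed sub-euthermic excursions shorter than 24 h), entry (to the
downward 25 °C crossing of T_b), torpor, arousal (to the upward 30 °C
crossing) and inter-bout euthermia (IBE), with bout statistics, maximal
cooling/rewarming slopes (sliding-window least squares) and the iBAT-to-core
rewarming lead time.

**Phase criteria.**  Six sampling labels (ENT<25 °C, T-40 h, AΔ0.5 °C,
AΔ3 °C, IBE-1 h, IBE-12 h) implement the published criteria exactly, both as
a pure state classifier and as an offline replay over a cohort.

**Statistics.**  Rayleigh tests of circular uniformity on zeitgeber-mapped
event times (Z = nR², Zar's series P-value, simulated exact null for small
n), and one-way ANOVA with Dunnett's multiple-comparisons test against a
control group for quantification outputs.

**c-fos quantification.**  Nuclei are segmented from the nuclear-stain
channel (smooth → Otsu → watershed split → size filter); the positivity
threshold is a signal-to-background ratio (default 2.0 — set it knowingly)
times the mean intensity of the most homogeneous 500 µm² background patch; a
cell is positive when ≥ 10 % of its pixels exceed the threshold; results are
percent positive cells per ROI.

**Synthetic generators.**  `hiberkit.synthetic` renders whole telemetry
cohorts (sigmoidal entries reaching −3.24 °C h⁻¹, multi-day plateaus 0.75 °C
above ambient, brown-fat-led logistic rewarming at +18.3 °C h⁻¹ with a
40 min core lag, test-drops, circadian-gated entries) and two-channel
section images with a controllable positive fraction — with exact ground
truth, so every stage of the pipeline is testable with no external data.

## Worked example

```python
from hiberkit import TelemetryGenSpec, generate_telemetry, analyze_animal

spec = TelemetryGenSpec(n_animals=1, n_cycles=2, seed=5)
traces, truth = generate_telemetry(spec)
res = analyze_animal(traces["A01"])

for s in res.segments:
    print(f"{s.kind:>9s}  {s.start/3600:7.1f} -> {s.end/3600:7.1f} h")
bl = res.baselines[1]
on = res.onsets[1]
print(f"TD = {bl.td_mean:.2f} +/- {bl.td_sd:.2f} C")
print(f"onset at {on.onset_time/3600:.2f} h "
      f"(dT={on.delta_t_at_onset:.2f} C, VF={on.vf_at_onset:.0f})")
```

prints

```
euthermia      0.0 ->    31.5 h
test_drop     31.5 ->    36.4 h
euthermia     36.4 ->    63.2 h
    entry     63.2 ->    68.5 h
   torpor     68.5 ->   125.5 h
  arousal    125.5 ->   127.9 h
      ibe    127.9 ->   184.1 h
    entry    184.1 ->   189.2 h
   torpor    189.2 ->   241.5 h
  arousal    241.5 ->   243.9 h
      ibe    243.9 ->   324.7 h
TD = 0.71 +/- 0.21 C
onset at 125.55 h (dT=0.88 C, VF=22)
```

This animal shows a ~5 h test-drop before cycling begins, then enters its
first bout (T_b crossing 25 °C at 68.5 h), stays torpid 57 h on a plateau
~0.7 °C above ambient, and the ΔT/VF detector fires at 125.55 h — within
minutes of the true thermogenesis onset, some 40 min before core
temperature responds.  A command-line interface (`hiberkit simulate |
segment | detect-arousal | replay | stats | quantify`) wraps the same
functions.

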