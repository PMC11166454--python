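# Methods

This note records the models, estimators, defaults and design choices behind
`hiberkit`, and what the synthetic-data tests do and do not demonstrate
about real recordings.

## Data model

All channels are irregular time series of (seconds-since-start, value)
samples.  Gaps are represented by *absent samples*, never interpolated:
transponder reads drop out when animals shiver, and a forward-filled value
during a rewarming event would be exactly the kind of artifact the analysis
must not create.  Channel alignment onto a common grid is step-hold with a
per-channel staleness horizon (120 s for the fast iBAT/ambient sensors,
900 s for the minutes-cadence core logger, 180 s for video-derived
ventilation); beyond the horizon a grid point is a gap.  Temperature
plausibility bounds are [−10, 45] °C — outside device physics; rows beyond
them are dropped on ingest with a count.

## Torpor baseline and ΔT

During deep torpor, brown-fat temperature rides a small stable offset above
ambient.  The thermal distance TD is the mean of (T_iBAT − T_a) over a
torpid baseline window; the rewarming signal is ΔT = (T_iBAT − T_a) − TD.
Subtracting ambient first makes the signal immune to ambient drift;
subtracting the per-bout mean tailors the zero to each bout.

Window placement: the latest admissible span of at least 5 h ending 20 h
before the predicted arousal time, where the prediction is the bout start
plus the animal's mean prior bout duration (population default 60 h with no
history).  In offline analysis the window is additionally capped to end at
least 1 h before the segmented end of the torpor bout: bout durations have
an sd of ~10 h, so a bout much shorter than predicted would otherwise put
the "baseline" on the arousal itself.  TD uses aligned sample pairs (both
channels fresh on a 60 s grid), requiring ≥ 100 pairs.

## Arousal-onset detection

Criteria: after more than 40 h of torpor, ΔT ≥ 0.5 °C together with
ventilation > 10 breaths min⁻¹.  Two debouncing choices are ours:
ventilation is smoothed with a trailing 1-min rolling median before
thresholding, and the conjunction must hold for 3 consecutive aligned
samples (~3 min at the default 60 s grid) — enough to reject single-read
glitches while costing at most a few minutes of latency.  Both are
configurable.  Lowering either threshold can only advance the reported
onset (monotonicity, property-tested).

## Cycle segmentation

Crossing-based, on a 30-min centred rolling median of core temperature:
sub-euthermic excursions are delimited by the 30 °C crossings; excursions
that never reach 25 °C are ignored; completed excursions shorter than 24 h
are test-drops (observed test-drops last hours, full bouts days — 24 h
cleanly separates the modes); the rest become entry / torpor / arousal /
IBE.  Entry runs from the last euthermic local maximum to the downward
25 °C crossing; this left edge is intrinsically fuzzy under the circadian
ripple and is not used for timing statistics.

The torpor→arousal boundary from core temperature alone is found in two
steps on the ambient-compensated series (T_b − T_a, since the torpid
plateau tracks ambient): a 2 °C elevation over the trailing 5 h median
confirms rewarming, then the boundary is the breakpoint of a least-squares
flat-then-rising hinge fit over a window from 3 h before to 10 min after
the confirmation.  On synthetic cohorts this lands within ±10 min of the
true core-rise instant in ~96 % of bouts (the 5-min logger cadence bounds
what is resolvable); when iBAT and ventilation exist, the ΔT/VF onset
overrides this boundary and is accurate to a few minutes.

Slope estimators use sliding-window least squares (60 min windows for
cooling, 30 min for rewarming — spanning the near-linear phase of each
transition), reporting the extreme window slope; windows with > 25 % span
deficit from gaps are skipped.  A windowed slope of a smooth sigmoid is
mathematically below the instantaneous maximum; the deficit is quadratic in
window length and under 1 % at these defaults, tested against analytic
derivatives at 5 %.

The iBAT lead time is the interval from the detected ΔT/VF onset to the
first confirmed core sample 0.5 °C above the pre-onset core median.

## Phase criteria

The six sampling labels follow the published criteria exactly (ENT<25 °C
with ≥ 12 h prior IBE and both T_b and T_iBAT below 25 °C; T-40 h with both
temperatures within 2 °C of ambient and VF < 2; AΔ0.5 °C and AΔ3 °C as the
onset criteria at the two ΔT levels, the 3 °C label requiring the same
eligibility; IBE at the upward 30 °C crossing plus 1 h / 12 h).  Precedence
is arousal > torpid > entry > IBE, so at most one label fires per state.
The torpid posture check is an optional manual-annotation flag; without it
the entry criterion degrades to temperature-only with a logged caveat,
because posture cannot be derived from telemetry.  Animals are eligible for
sampling after three completed torpor→arousal→IBE cycles.

## Circular statistics

Event times are mapped to zeitgeber angles (2π = 24 h, 0 = lights-on).  The
Rayleigh statistic is Z = nR²; P-values use Zar's series approximation
p = e^(−Z)[1 + (2Z − Z²)/4n − (24Z − 132Z² + 76Z³ − 9Z⁴)/288n²], clipped to
(0, 1], which is accurate for n ≥ 10; below that an exact-by-simulation
null (10⁵ uniform replicates, fixed internal seed) is used instead.
Calibration at the study's cohort size (n = 28) is verified by simulation:
type-I error 5 % ± 1 %, power > 95 % against von Mises κ = 2.  The circular
sd is √(−2 ln R); R = 0 leaves the mean direction explicitly undefined
rather than silently zero.

## Group comparison

Per-animal values are unweighted means over that animal's sections (three
sections per animal in the sampling design; the aggregation rule is ours).
The omnibus test is one-way fixed-effects ANOVA; the per-group comparisons
against the named control use Dunnett's test in its multivariate-t
formulation (scipy implementation).  Tests cross-check the adjusted
p-values against an independent max-|t| permutation oracle (10⁵ shuffles);
at 6 groups × 4 animals they agree to well under 0.02.  Groups with one
animal are excluded with a warning.  Section-within-animal nesting is not
modelled (no mixed effects).

## c-fos quantification

Cell detection re-implements a standard nuclei pipeline with every knob in
config: Gaussian smoothing (1 µm), Otsu threshold inside the ROI (with a
contrast guard of 4 background-sd separation so noise-only ROIs yield zero
cells), distance-transform watershed to split touching nuclei (4 µm minimum
peak separation), and an area filter (12–400 µm²).

The positivity threshold is ratio × mean signal of a 500 µm² background
patch; within the background ROI the square patch with minimal signal
variance is chosen, for reproducibility.  The signal-to-background ratio is
**not** recoverable from the sampling design it mirrors; the default is 2.0
and it is surfaced in every result record.  A cell is positive when ≥ 10 %
of its pixels exceed the threshold ("above-threshold signal within the cell
boundary", made quantitative).  Quantification is invariant to affine
rescaling of the signal channel (the threshold scales with background) and
percent positive is monotone non-increasing in the ratio; both are
property-tested.  Zero detected cells yields an explicitly undefined
percentage, never 0 %.

## Synthetic generators

The telemetry generator is phenomenological, not a heat-balance model.  Its
defaults are the study conditions: euthermic T_b 33.4 °C (cold-adapted set
point, between-animal sd 0.5) with a 0.5 °C circadian ripple (amplitude not
quantified in the source physiology; chosen as a realistic default);
ambient 7.4 ± 0.53 °C as a slow AR(1) (τ = 6 h); entry as a logistic whose
maximum cooling rate is −3.24 °C h⁻¹; a torpid plateau with T_b = T_a +
0.75 °C and T_iBAT = T_a + 0.71 °C carrying AR(1) thermoregulatory noise of
sd 0.19 °C (the observed TD sd); rewarming as a 1 °C linear ignition ramp
(iBAT 8 °C h⁻¹, core 6 °C h⁻¹ — within the observed early-rewarming speeds)
joined continuously to a logistic with maximum slope +18.3 °C h⁻¹, core
lagging iBAT by 40 min, completing in ~2.8 h; bout durations 56.5 → 75.5 h
(sd ~9–10 h, floored at 42 h since sampled animals were torpid > 40 h) and
IBE 61.2 → 22.9 h by bout index; one pre-cycling test-drop with probability
0.86, 5.3 h below euthermia, nadir ~21.4 °C; ventilation 1 breath min⁻¹
torpid, 60 euthermic, surging to 120 over 30 min from thermogenesis onset.
Entry crossings are circadian-gated to ZT ~19.5 (von Mises κ = 2) while
arousal times inherit bout-duration variance and are effectively uniform —
reproducing the observed asymmetry (entries clustered, arousals not).
Cadences: iBAT 4 s, core 5 min, ambient and ventilation 1 min.  Optional
shiver dropout deletes iBAT reads on the rising limb at ΔT 14–18 °C.

The ignition ramp exists so that "thermogenesis onset" is a well-defined
instant; ground-truth events (25 °C entry crossings, thermogenesis onsets,
core-rise starts, 30 °C crossings, test-drop spans) are computed from the
noise-free curves on a 10 s grid.  All randomness flows from the single
spec seed.

Images: nuclei are Gaussian blobs placed with a minimum-distance constraint
inside a 700² px canvas at 0.5 µm px⁻¹, leaving a nucleus-free margin that
serves as the background ROI; the signal channel adds a per-positive-cell
signal over a background of 10 counts with Poisson + Gaussian read noise.

**What passing tests do not show.**  The generator's curves are smooth and
its noise well-behaved; real records have logger artifacts (e.g. sensor
migration), non-stationary ambient excursions, behavioural temperature
spikes and video dropouts that the tests do not exercise.  Detector and
segmentation accuracies quoted here are therefore upper bounds specific to
the simulated conditions; thresholds and horizons are all configurable for
that reason.

## Numerical choices and degenerate inputs

Bin averaging emits empty bins as gaps; alignment never invents a value
beyond one staleness horizon.  The hinge fit uses the sample grid as its
breakpoint lattice.  R is clamped to ≤ 1 before √(−2 ln R).  A record with
no sub-euthermic crossing segments to a single euthermia interval (not an
error); a torpor record ending mid-bout leaves the bout open.  Dunnett and
permutation p-values are reported as computed, including exact zeros from
the scipy quadrature at extreme effect sizes.

## Problem sizes

The test suite and the acceptance script use cohorts of 6 animals × 4
cycles, 50 single-bout records for onset recovery, 500 seventy-hour
arousal-free records for false alarms, 5000 simulations for Rayleigh
calibration, 10⁵ permutation shuffles, and 300-cell sections (three per
animal, four animals per group) for quantification — sizes at which every
Monte-Carlo margin in the tests is stable across seeds.
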