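# Methods

This note documents the models, conventions and numerical choices behind
`cbdrive`: what the analysis computes, what the synthetic generator does
and does not emulate, and where genuinely open design decisions were
resolved.

## Conventions

* World frame: right-handed, metres; gaze is a unit direction from the
  head position, so AOI hit-testing is purely angular.
* Time: seconds from session start; **every window is half-open [a, b)**.
  A press exactly at `trigger + cutoff` is outside the window; a fixation
  boundary exactly on a bin edge belongs to the later bin. This single
  rule removes all boundary ambiguity.
* The session directory format (gaze.csv, driving.csv, presses.csv,
  events.json, aois.json, meta.json) is an invention of this package —
  raw logger schemas from commercial trackers vary and none is public for
  this design. Floats round-trip exactly via shortest-repr CSV.

## Experimental schedule

A session holds 72 changes in 36 pairs — 12 pairs per complexity level,
each pair one behaviour change (relevant or irrelevant) followed after a
gap of 0, 1, 2, 4, 6 or 8 s by a property change. Blocks follow the
counterbalanced group orders A (medium–high–low), B (high–low–medium),
C (low–medium–high). Choices made where the design description is silent:

* **Relevant/irrelevant split**: 6 + 6 pairs per level (18/18 overall).
  Only the total number of behaviour changes is documented; the balanced
  split is the only symmetric choice.
* **Gap balance**: each gap level is used in exactly 6 pairs overall *and*
  twice per complexity level; placement within a level is randomised by
  the seed. Balancing within levels keeps the proximity factor orthogonal
  to complexity.
* **Inter-pair spacing**: uniform on [10, 60] s. The study reports 10 s to
  2 min depending on driving; the generator's timeline is a fixed-route
  abstraction (driving does not feed back into event times), and [10, 60]
  keeps sessions near 20 minutes.

## Fixation detection (I-DT)

Dispersion is the **maximum pairwise angular separation** of the window's
unit directions — the spherical analogue of the classic I-DT extent. The
device guideline band is 0.7°–1.3°; the default threshold is its midpoint,
1.0°, and is configurable since the guideline's exact dispersion metric
(per-axis vs angular) is not public.

* Greedy leftmost-maximal windows: grow while dispersion ≤ θ; emit when
  duration ≥ 100 ms; otherwise slide the start by one sample.
* Windows longer than 500 ms are **split into equal-span consecutive
  fixations** (k = ⌈duration/0.5 s⌉ chunks) rather than discarded:
  dwell time is preserved while every emitted fixation honours the
  100–500 ms band. Splitting is configurable off.
* Invalid samples and inter-sample gaps > 50 ms (blinks, dropouts) break
  the window, so a fixation never bridges a blink.
* Implementation detail: the pairwise test is accelerated by a per-axis
  bounding box on the directions (box diagonal upper-bounds, largest
  per-axis extent lower-bounds the maximal chord), with an exact pairwise
  fallback only when the threshold falls between the bounds. The result is
  bit-identical to the naive algorithm; the test suite proves equivalence
  against an exhaustive-window oracle over hundreds of random traces.

AOI membership uses the **fixation centroid**, not per-sample voting,
matching the "fixations landed on the AOI" reading; saccade samples never
contribute dwell. The AOI centre is linearly interpolated at the fixation
midpoint and the angular radius is arctan(radius/distance).

## Response coding

* C1: right button ↔ behaviour changes, left ↔ property changes.
* C2 is interpreted **per button side**: a press must precede the next
  change *requiring the same side*. Under a literal any-next-change
  reading, 0 s-gap pairs would make behaviour detections impossible, which
  contradicts the design's premise that the two buttons keep simultaneous
  changes separable.
* Cutoff derivation is two-pass: a generous 10 s C1 window harvests
  reaction times across the whole cohort, the cutoff is mean + 3 sample
  SD, and matching is re-run. The canonical fixed window 4.1 s is
  available as `paper_default` mode; the inside/outside press audit is
  exactly complementary by construction.
* Tie-breaks are deterministic: presses are scanned in time order, a press
  qualifies for at most one change (the latest same-side change preceding
  it), and the earliest qualifying press wins; later qualifying presses
  become false alarms. Every press ends as exactly one of attributed /
  false alarm.

## LBFTS and derived analyses

A miss is LBFTS when AOI dwell ≥ 100 ms in both the 4 s pre- and 4 s
post-windows. Both denominators are reported — both-window gazers (the
per-gaze normalisation) and all changes — because published practice is
ambiguous between them. The 2 s pre-window robustness variant is a config
switch; narrowing the window can only shrink the both-gazer set (window
nesting), which the suite asserts.

Rate-of-change (ROC) across complexity is the **percentage-point
difference** between adjacent levels (a ratio variant exists but is
non-default). A brake "hit" is a rising edge of the pedal boolean. The
"learning" comparison takes the session's three complexity blocks as its
sessions and contrasts the first against the third per change type;
anticipatory gaze is summarised as dwell in the [−1, 0) s bin, lingering
as dwell in [+3, +4) for property changes.

## Statistics

The unit of analysis is the **participant** (per-participant cell means).
The factorial ANOVA uses the balanced-design SS decomposition (= Type
I/II/III on balanced data; unbalanced input is rejected). Effect sizes:
η²ₚ = SS_effect/(SS_effect + SS_error), Cohen's d = mean(Δ)/SD(Δ). Tukey
HSD comes from the studentised-range distribution; Bonferroni multiplies
raw p by the number of comparisons, capped at 1. Type-I calibration of all
three test families is checked by 1000-replicate null simulation
(acceptance band 3.5–6.5% at nominal 5%).

## Synthetic generator: what it emulates, what it does not

Each participant is a parameter set (`DriverParams`): per-cell detection
probabilities, a lognormal RT law, gaze-allocation probabilities per
change type, per-complexity fixation rate, speed and brake rate, and a
learning slope on property-change detection. Defaults encode the study
conditions:

* detection probabilities decrease with complexity at per-type slopes
  (behaviour-relevant flattest, behaviour-irrelevant steepest between
  medium and high); property detection is further multiplied by 0.55 at
  the 0 s gap (simultaneity penalty) and gains +0.002 per encounter
  (practice, property only — the design's behaviour changes showed none);
* RT ~ truncated lognormal(μ=0.12, σ=0.62), giving realised mean + 3 SD
  near 4.1 s — the documented window is only a cutoff, so the lognormal
  is an explicit stand-in and stays configurable;
* gaze is an alternating fixation/saccade renewal process at 120 Hz:
  road-directed fixations (target jitter σ=2°, truncated at ±5°) with
  30 ms saccades, plus scheduled AOI dwells of 180–350 ms placed with
  probability `p_gaze_pre/post` in the 4 s windows. Behaviour-relevant
  pre-dwells start `anticipatory_lead_s` = 1 s before the trigger;
  detected property changes get an extra 0.3 s dwell in the [+3, +4) bin.
  AOIs sit ≥ 8° off the road axis, so accidental dwell is impossible and
  the generator-level identity E[LBFTS fraction] =
  p_pre · p_post · (1 − p_detect) holds per cell;
* driving: per-complexity speed (26/25/18 km/h) with clipped noise under
  the 30 km/h limit, brake presses as a Poisson process at the
  per-level per-minute rates with a 160 ms refractory gap so every press
  yields a resolvable rising edge at 25 Hz; fixation rates per minute
  follow the per-level profile (≈ 214/176/191).

Deliberate idealisations, and hence what passing tests do **not** show
about real data:

* gaze and detection are drawn **independently**, so the both-gazer LBFTS
  rate equals the miss rate by construction; in humans gaze predicts
  detection, so real LBFTS rates and gaze-coverage percentages will
  differ from the synthetic ones;
* the head is static and the route timeline is fixed: completion time
  does not vary with complexity, and speed never feeds back into event
  timing;
* no smooth pursuit, no saccade dynamics beyond linear interpolation, no
  scene content. Percentages that depend on the undeposited human cohort
  (overall detection 55.9%, misses 44.1%, LBFTS 31.2%, 60.2% gazed,
  per-level brake counts and durations) are calibration guidance for the
  defaults, not reproduction targets.

## Problem sizes

The acceptance script summarises a 30-participant synthetic cohort with
full gaze streams (~22 min at 120 Hz each); parameter-recovery studies use
50 replicate cohorts of n = 80 in detection-only mode (no gaze stream),
where the recovery configuration switches off wrong-button presses and
false alarms and fixes a 10 s cutoff so the estimator is uncensored.
These sizes were chosen to keep Monte-Carlo error well below the decision
bands they feed.

## Known limitations

* The C2 same-side interpretation and the iterative cutoff derivation are
  documented choices, not documented facts of the original protocol; both
  are configurable.
* The balanced factorial ANOVA rejects unbalanced designs rather than
  falling back to regression-based SS; real (incomplete) cohorts need the
  participant-level aggregation to stay balanced.
* The generator's brake rates are taken from the reported per-level counts
  divided by reported durations; with the refractory gap the realised
  counts run ~5–25% below the nominal rate at the highest setting.
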