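# Methods

This note documents the models, conventions and numerical choices behind
hexawalk, and what the synthetic data can and cannot establish.

## The synthetic walker

Each leg is a two-phase oscillator. A cycle opens at touch-down (AEP): the
protraction angle ramps linearly from `aep_deg` down to `pep_deg` over the
stance (`stance_fraction` of the cycle period, default 0.65), then returns
along a cosine half-wave during swing. Cycle periods are drawn per cycle as
`period_s + N(0, period_jitter_sd_s)`, floored at 20% of the intrinsic
period; white Gaussian noise (`angle_noise_sd_deg`) is added to the angle
at each frame. The simulation itself is event-driven in continuous time
(exact event timestamps, no frame quantisation); markers are sampled at the
frame rate afterwards.

Two coordination rules couple the oscillators along directed edges:

* **Rule 2** (excitatory): `rule2_latency_s` (default 40 ms) after a sender
  touch-down, the receiver's remaining stance is shortened by
  `rule2_strength` of itself. With equal intrinsic periods this is a
  contraction map on the lift-off-to-touch-down lag: the receiver's
  lift-off settles `latency/strength` after the sender's touch-down.
* **Rule 1** (inhibitory): while a sender is in swing, a rule-1-coupled
  receiver may not lift off; its lift-off is deferred to the sender's
  touch-down. Because rule 2 can only *advance* a receiver, a receiver
  drifting early would otherwise escape entrainment; the hold reflects that
  boundary.

The default topology has posterior→anterior ipsilateral edges (L2→L1,
L3→L2, R2→R1, R3→R2) and left→right contralateral edges between homologous
legs. Contralateral directionality is a plotting-convention choice (phases
of the operated right side are referenced to the intact left side), not a
claim about the biology. A lesion forces the strengths of the edges whose
neural path crosses the cut to zero: `T2_right` severs R2→R1 and L2→R2
(both couplings adjacent to the right pro-to-mesothorax connective),
`T3_right` severs R3→R2. Severed-edge sets can be overridden.

Default parameters emulate the sham cohorts of the motivating experiments:
AEP/PEP of 62/10° (front), 26/−10° (middle), 0/−26° (hind legs), i.e. step
lengths of ~52/36/26°; cycle period 0.7 s for all legs; period jitter
0.05 s; angle noise 1°; forward speed 30 mm/s; 50 Hz frame rate. All legs
share one intrinsic period deliberately: in steady walking the legs of one
animal step at a common frequency, and the stance-shortening mechanism can
only entrain receivers whose intrinsic period is not shorter than the
sender's. Default coupling strengths (0.3 ipsilateral, 0.15 contralateral)
put the locked lift-off lag at `latency/strength ≈ 0.13 s`, i.e. a mean
phase near 60–70° with per-animal R around 0.6–0.75 — the sham-like regime.
Body translation/rotation is commanded (vx, vy, yaw), integrated by
explicit Euler at the frame rate, and is *not* emergent from leg forces; no
mechanics, ground-reaction forces or load transfer are simulated.

What the generator does **not** emulate: residual mechanical coupling after
a lesion (a lesioned edge is exactly zero), active/passive femoral
movement, 3-D kinematics, curve-walking dynamics, short-step classes, and
any adaptation over time. Passing tests therefore show that the *analysis
chain* is correct and sensitive under realistic noise — not that the
oscillator model is a faithful animal model.

## Camera, tracking, calibration

Rendering projects arena positions into a 480×640, 8-bit top-view camera at
0.25 mm/px whose centre follows the root marker (optionally with Gaussian
follow noise); the camera's own arena position per frame is the gantry
stream. Markers are Gaussian blobs (σ = 2 px, peak 255). Detection
thresholds the image (strictly greater than `intensity_threshold`,
default 100), labels 8-connected components, discards those under
`min_pixels` (default 4) and returns intensity-weighted centroids.
Tracking assigns labels greedily in ascending distance order within
`max_jump_px` (default 15), one detection per label; unmatched labels get a
gap flag and keep their last position. Greedy assignment is deliberately
simple and can swap crossing markers — the dorsal nine-marker layout keeps
markers far apart, and the limitation is accepted. Image coordinates have
the origin top-left with y down; the arena frame is y-north, hence the
calibration's default y flip. Gaps are filled by linear interpolation up to
3 frames (60 ms, the time scale of the velocity filter); longer gaps are an
error, not a guess.

## Kinematics conventions

Heading is the direction of the metathorax-root→prothorax marker chord
(a total-least-squares three-marker fit is available as `axis_fit="fit"`;
the chord is the default because it is deterministic and the choice is not
fixed by the source analysis). Headings are unwrapped before
differentiation. Velocities project the frame-to-frame displacement of the
root marker onto the heading of the *earlier* frame; Rot is the heading
increment per frame interval. All three series are smoothed with a sliding
median of `round(window_ms × rate/1000)` samples forced odd (60 ms → 3
samples at 50 Hz), truncating the window at the series edges. All
interfaces use degrees, millimetres and seconds.

The swing/stance estimates inherit a known bias: angle reversals at the
thorax–coxa joint stand in for true ground contact, neglecting the small
phase shift between the two. This is reproduced as-is.

## Step-cycle segmentation

Events are local extrema of the protraction angle subject to a prominence
threshold (default 5°, well below the smallest default step length of 26°)
and a same-kind separation (default 0.1 s, well below the 0.7 s period).
Two numerical choices matter at realistic noise levels:

* the series is pre-filtered with a 5-sample sliding median before peak
  finding, so single-frame noise does not seed spurious reversals;
* the event angle is refined by a quadratic fit to the raw series within
  ±2 samples of the detected index. Reading the filtered series flattens
  the extremum (AEPs biased low, PEPs high, up to ~2°); reading the raw
  sample alone leaves the frame-clock quantisation on the steep stance
  side of the PEP corner (~1°). The vertex readout keeps the median bias
  below ~0.4° at 2° angle noise. Event *times* stay on the frame clock
  (1-frame accuracy).

Alternation is enforced by keeping the more extreme of two consecutive
same-kind events. Cycles are AEP→PEP→AEP triples; the period is defined
AEP-to-AEP to match the phase-reference convention; partial cycles at the
ends are discarded. Both the cycle period and the stance duration are
reported, since summary tables in this literature are ambiguous about
which "duration" they list. No short-step classification is applied.

## Circular statistics

Phases live in [0, 360)°; a lift-off exactly on a reference touch-down is
phase 0 (closed-left/open-right intervals — a tie-break the convention
leaves open). Per-animal mean vectors are unweighted; the cohort mean phase
is the circular mean of per-animal Φ values, while pooled samples feed the
15°-bin rose-plot histograms and the Kuiper test only. The Watson–Williams
F test uses the standard `1 + 3/(8κ̂)` correction with κ̂ from Fisher's
piecewise ML approximation; it refuses exactly-tied degenerate data and
warns when the within-group concentration r_w < 0.45 (assumption
violation). The two-sample Kuiper statistic V = D⁺ + D⁻ is computed from
the merged-sample EDF difference — this form is invariant to the circular
origin — with the asymptotic tail probability
`2Σ(4k²λ² − 1)e^(−2k²λ²)`, λ = (√N_e + 0.155 + 0.24/√N_e)·V,
N_e = nm/(n+m), clamped to 1 below λ = 0.4. Both tests are cross-checked
in the suite against independent brute-force/reference-formula oracles.

## Balanced bootstrap

"Balanced" is interpreted as equal expected per-animal contribution with
the pooled total preserved: with N values over k animals, draw ⌈N/k⌉ with
replacement from each animal, then truncate uniformly at random to N.
Intervals are percentile (2.5/97.5 and 0.5/99.5) of the replicate medians;
the point estimate is the median of replicate medians. BCa refinements are
deliberately not used — the procedure specifies plain bootstrap CIs.
Significance is disjointness of closed intervals (touching endpoints count
as overlap, the conservative reading), with the 99%-CI tier mapped to the
double-arrow (p < 0.01) level. The effect-size denominator is the mean of
the two cohorts' full 95% CI widths; a half-width variant is available
(`denominator="half_width"`) because the verbal definition ("divided by
their mean 95% CI") is ambiguous — effect sizes are therefore comparable
within a run, not across conventions.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is exactly
reproducible; the pipeline writes a manifest with all derived seeds. The
test suite and acceptance script run at desk scale: single trials of
60–250 s (≈90–350 cycles/leg) for recovery and coupling checks, 10-seed
replicates for the lesion-sensitivity check, 500 replicate cohorts
(5 animals × 100 values, B = 1000) for CI coverage, and ~150-frame stacks
for the pixel round trip. The full-scale defaults (B = 10,000; arbitrary
trial counts) are available through the same interfaces.

## Known limitations

Greedy tracking can mislabel crossing markers; the lesion model removes
edges rather than attenuating them; no load transfer means post-lesion
"residual coordination" in the model arises only through remaining neural
edges; the Watson–Williams test is reported even where its concentration
assumption fails (flagged by a warning), mirroring common practice; and
effect sizes depend on the CI-width convention noted above.
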