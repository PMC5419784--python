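# Methods

## Signals, units and conventions

All detection operates on per-leg sagittal-plane kinematics sampled at
100 Hz: shank (tibia) angle w.r.t. vertical (deg, positive when the shank
top is forward), shank angular velocity (deg/s, positive during forward
swing rotation, so mid-swing is the per-cycle maximum), ankle angle (deg),
foot angular acceleration (deg/s²), shank vertical position (m), and
calcaneus/toe vertical velocities (mm/s, positive up). The optional
vertical ground-reaction force (N) lives on its own 1000 Hz clock; all
cross-rate comparisons are made in seconds. Sample *i* occurs at *i*/rate
(0-based, no half-sample offset). The CSV reader requires a `# units:`
header and rejects mismatched units rather than guessing conversions.

## Detection model

Each leg runs an independent five-state machine whose states are the last
fired event (MS→IC→FF→HO→TO→MS). A rule for event *E* is armed only while
the machine sits in *E*'s predecessor state and any guard flag is raised;
"post ipsilateral IC" search anchors are therefore state guards, not time
windows. Flags are pre-events (e.g. the B6 shank-velocity trough that
must precede the midpoint toe-off); a flag is lowered exactly when its
guarded event fires. Detectors start in the TO state, so the first event
found at gait onset is the MS anchor; generic (config) thresholds make
detection work from the first step.

**Extremum rules** (maxima/minima) arm when the raw signal crosses the
current threshold in the event direction, then track the running extremum
and fire after `reversal_samples` (k, default 1) consecutive ticks without
a new extremum, stamping the event at the extremum sample. k=1 minimises
latency; raising k trades delay for noise immunity. **Crossing rules**
(the fixed ±50 mm/s rules of `rtgsd_g6`, the B6 M1·A toe-off) fire at the
crossing tick itself.

**Adaptive thresholds.** Once per completed cycle (on MS, deferred 150 ms
so the causal filter has caught up; a rate divisor can slow this further)
the update layer revisits each adaptive event: it finds the event's
extremum in a low-pass-filtered copy of the channel within ±150 ms of the
real-time firing, backtracks to the true raw extremum within ±50 ms of the
filtered one, pushes that amplitude into a 5-deep ring buffer, and sets

    threshold = mean(history) − (3·SD + offset)   for maxima
    threshold = mean(history) + (3·SD + offset)   for minima

with SD the sample standard deviation (0 for a single element). The search
window is anchored on the real-time firing rather than spanning the whole
cycle because several channels carry two minima per cycle (e.g. the shank
angular velocity's IC trough vs. the deeper TO trough); a whole-cycle
argmin would latch the wrong one. The update layer is strictly decoupled:
it never retroactively edits fired events, and freezing it (divisor → ∞)
degrades timing but cannot break state-machine soundness.

**Offsets.** The per-event offsets (config data in
`variants.DEFAULT_OFFSETS`) are the safety margin that keeps a threshold
clear of the expected extremum while the history is short — with one
history element the SD term vanishes, and a threshold parked within the
signal's noise of the next peak stalls the machine for whole cycles at
gait onset. Defaults are ~3–5× each signal's amplitude variability (e.g.
40 deg/s on the ±300–400 deg/s shank-velocity extrema, 3 deg on the 25 deg
shank-angle peak); events without an entry fall back to 5 % of the generic
threshold magnitude. Larger offsets arm earlier (more conservative, the
precision-over-timing trade).

**Low-pass filter.** The update layer filters with a causal 2nd-order
Butterworth at 6 Hz (comfortably above the ~1 Hz cycle rate and the
≤ ~5 Hz kinematic content; passband gain ≥ 0.95 at 0.8 Hz), initialised at
the first sample's steady state. Its group delay (~40 ms at low frequency)
is why the raw backtrack window is ±50 ms and the update is deferred.

**Secondary toe-off.** While the machine waits in HO, a
negative-to-positive zero crossing of the shank angular velocity fires TO
(marked `secondary`) if the primary definition has not — but only after
the velocity has been negative for ≥ 30 ms, i.e. the late-stance trough
region was actually entered. Without that dwell requirement, noise
wiggling around the small positive mid-stance baseline fires premature
toe-offs; with it, the fallback still rescues a primary threshold that is
never reached at all. It is enabled for `rtgsd_min` and `rtgsd_b6`, whose
primary TO depends on adaptive/derived thresholds that can drift
unreachable; the G6 toe-off is a fixed 50 mm/s crossing with no such
failure mode.

**B6 toe-off coefficient.** TO is the upward crossing of M1·A(speed),
where M1 is the raw amplitude of that cycle's shank-velocity trough
(captured by the TO flag) and A ∈ (0,1) maps walking speed to the fraction
of the trough at which the midpoint falls. The literature values behind
A(speed) are not recoverable, so the shipped table is a flat placeholder
(A = 0.5 at 3/4/5 km/h, linear interpolation, nearest-endpoint outside the
range with a warning); users should supply their own. A = 0.5 puts the
firing roughly halfway up the trough recovery, which is why `rtgsd_b6`
carries a systematic ≈ +30 ms TO delay in every report here.

**G6 initial contact.** Two definitions are available: the default stamps
IC at the calcaneus vertical-velocity minimum, enabled by a flag at the
post-MS zero crossing to negative (robust; the amended definition), while
`ic_mode="crossing"` uses the bare upward crossing of −50 mm/s, which
necessarily fires later (after the minimum).

## Reference detectors

IC/TO: upward/downward crossings of a 20 N threshold on the vertical GRF,
with strict IC,TO alternation; a recording that begins mid-stance
contributes no event for that stance, and a trailing stance without an
observed TO is searched open-ended for FF/HO. FF/HO: inside each
GRF-defined stance window, FF is the first time the toe vertical speed
falls below 100 mm/s and HO the first post-FF time the heel vertical
velocity rises above +100 mm/s. All reference events are stamped at the
crossing; the debounce (default 30 ms, set 0 for the bare rule) only
requires the condition to persist, so it filters chatter without shifting
stamps. A stance with no qualifying crossing yields no event and a logged
sequence error, never a silent drop.

## Synthetic gait generator

Real validation data for these detectors (treadmill walking with force
plates and optical markers) cannot be shipped, so the test bed is a
generator whose waveforms are sums of periodic bumps
`exp(κ(cos 2π(φ−μ) − 1))` placed relative to configurable event phases
(defaults IC 0 %, FF 8 %, HO 40 %, TO 62 %, MS 80 % of the cycle, textbook
stance proportions). Extremum-defined events sit exactly at bump centres;
crossing-defined events (the ±50 mm/s rules, the GRF 20 N edges) have the
bump sharpness solved in closed form so the crossing lands exactly on the
event phase. The GRF is a double-hump curve equal to 20 N exactly at the
stance edges and decaying within ~5 ms outside. The right leg is the left
waveform shifted by half a cycle. Cycle periods follow speed (1.2/1.1/1.0 s
at 3/4/5 km/h) with per-cycle Gaussian jitter (SD 20 ms, truncated at
±3 SD) that rescales whole cycles, so intra-cycle phase relations — and
the analytic ground-truth event times — stay exact. Trials end 0.05 cycle
before the final cycle boundary so no half-risen, unlabelled peak remains
at the data edge.

Per-channel additive white Gaussian noise defaults to ~1–2 % of each
waveform's peak-to-peak range (e.g. 8 deg/s on the shank velocity, 3 N on
the GRF) — deliberately small, because the intended inputs are
model-derived, already-smoothed kinematics rather than raw sensor streams.
Bump extremum widths are chosen so that converged adaptive thresholds
retain a multi-sample, multi-σ margin below the peaks, as real
(band-limited) gait extrema do.

What the generator does **not** emulate: musculoskeletal coupling between
channels (each waveform is constructed independently), pathological or
asymmetric gait, soft-tissue artefact, sensor drift/bias, double support
dynamics in the GRF, or band-limited noise. Passing tests therefore
demonstrate the correctness and timing of the detection *machinery* under
controlled, realistic-scale conditions — not clinical performance on real
subjects, whose published delays depend on datasets that are not
reproducible here.

## Evaluation

Detected events are matched to reference events one-to-one per leg and
event type by greedy nearest-in-time assignment inside a 350 ms window
(wide enough that even a badly biased heel-off still registers as a match
rather than an FP+FN pair; the window is config). Precision is
TP/(TP+FP), reported as absent when TP+FP = 0. Delays are
t_detected − t_reference in ms (positive = late), legs pooled; Bland–Altman
limits are mean ± 1.96·SD of the paired differences. The first gait cycle
per leg (delimited by reference ICs) is excluded *after* matching, so
threshold convergence at gait onset neither pollutes delay statistics nor
creates boundary FP/FN artefacts; set `exclude_warmup_cycles=0` to include
onset.

## Problem sizes used in the shipped checks

The acceptance script and the end-to-end tests run 3 speeds × 30 cycles per
leg (≈ 100 s of walking per variant) at the default noise level — enough
for ~1 550 matched event pairs per run, which stabilises the per-cell mean
delay estimates to ~1 ms while keeping a full run in a few seconds.
Property suites use 200 short (3-cycle) randomized trials for state-machine
soundness and causality-under-truncation.

## Known limitations

* Heel-off remains the weak event for threshold-based detection; the B6
  shank-height minimum is shallow and easily washed out (the shipped
  robustness fixture shows exactly this as counted false negatives).
* The B6 A(speed) table is a placeholder; absolute B6 TO delays are only
  meaningful once literature values are supplied.
* The update layer assumes the real-time layer fired the event it is
  re-estimating; a cycle with a missed event simply skips that update.
* Streaming detection is single-threaded pure Python (~40 µs/tick), ample
  for 100 Hz real-time margins but not tuned for batch throughput.
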