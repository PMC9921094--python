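# Methods

## Scope and model

`mothnav` is a desk-scale, closed-loop reconstruction of a robotic
odor-source-localization study: three navigation policies (RMI, SZL, SC)
driving a unicycle agent through a synthetic intermittent plume under three
wind scenarios, evaluated by success rate, localization time and crosswind
RMSE. The controller mathematics and the trial protocol are implemented
exactly; the physical plumes, sensors and robot dynamics of the original
experiments are replaced by generative models, so batch-level outcome
numbers are properties of this simulator, not re-measurements of the
physical study.

## Environment

**Wind.** Spatially uniform per tick. Direction and speed follow
independent Ornstein–Uhlenbeck processes around the scenario mean, using
the exact discretisation `x' = μ + (x−μ)e^(−dt/τ) + σ√(1−e^(−2dt/τ))·ξ`,
so the configured `direction_sd`/`speed_sd` are the stationary SDs and the
zero-SD limit is exactly constant wind. The mean direction points from the
fan position through the odor source (the fan blows across the arena).
Defaults: correlation time τ = 2 s; indoor scenarios (A, B)
`direction_sd = 0.1 rad`, `speed_sd = 0.05 m/s`; the outdoor scenario (C)
`0.5 rad` and `0.3 m/s` — an indoor fan wanders a few degrees, a rooftop
wind tens of degrees.

**Plume.** Gaussian puffs ("filaments") released from the source at
10 s⁻¹ on a deterministic schedule (after t seconds exactly ⌊10t⌋ puffs
have been released). Each puff advects with the instantaneous wind plus a
per-axis diffusive jitter `N(0, 0.02·√dt m)`, grows as
`σ(age) = 0.02 + 0.005·age` m, and is pruned once it is more than 3σ
outside the arena. Concentration is the kernel sum
`Σ q·exp(−|p−c|²/2σ²)/σ²`. This produces the feature the RMI law feeds on:
detections at a fixed point are intermittent, and their frequency decreases
with distance and crosswind offset.

**Scenarios.** Odor source at the origin in a rectangle
x ∈ [−0.5, 2.0], y ∈ [−1.0, 1.0] m (the original arenas' extents are not
recorded; this is the declared default). Fan at (−0.5, 0) for A/C, at
(0, −0.3) — blowing along +y, displacing the plume off the +x axis — for
B. Start poses (1.5, 0) for A and (1.5, 0.3) for B/C, heading toward −x
(the start heading is not recorded in the protocol; facing the arena
interior is the declared default). The plume is spun up for 5 s before the
agent is released.

## Sensing

Two point antennae 0.05 m ahead and ±0.03 m lateral of the body centre; a
hit is concentration ≥ 150 (arbitrary units; a fresh puff peaks at 2500).
Wind is reported as the quadrant of the body-frame *arrival* bearing
(±45° bands; boundary ties go to front/back; below 0.05 m/s the previous
class is held). Odor-detection frequency is edge-triggered: an onset is a
false→true transition on either antenna, subject to a 0.1 s per-sensor
refractory so one filament crossing is one event; a sustained contact
counts once; simultaneous bilateral onsets are a single frontal event.
`f` = onsets in the last 5 s / 5 s (0.2 Hz resolution). Sensor lag and
deconvolution of real gas sensors are deliberately not modeled — detection
is instantaneous.

## Controllers

Shared surge/zigzag/loop machine, with every timing constant configurable
(`FsmParams`): surge 0.5 s; three zigzag turns then loop; any onset resets
to surge. Geometry not fixed by the behavioural program is declared here:
surge steers 30° toward the firing antenna (frontal detections go straight);
zigzag legs are a 60° turn at the commanded angular speed followed by a 1 s
straight, first turn toward the last hit side (frontal → left by
convention); the loop keeps the third turn's sign. The agent starts in
zigzag (searching) and in the inactive mode — deliberate exploration before
any plume contact.

RMI evaluates `K_v, K_ω` every tick from the current `f` and mode and
clamps to `v ∈ [50, 250] mm/s`, `ω ∈ [0.5, 3.0] rad/s` (the study states
that speed limits existed but not their values; these brackets contain
every tabulated operating point). The printed source of the active-mode
`f > 0.7` coefficient row would command negative speeds and a 246 rad/s
turn gain under the stated column order; the default here swaps the two
middle entries (`a_v = −114, b_v = 246, a_ω = −1.59, b_ω = 2.81`), which
restores positive speeds and near-continuity of `K_v` at the breakpoint
(166.52 vs 166.2 mm/s). The raw printed row remains available
(`GainTable.paper_printed()`). The inactive-mode `K_ω` discontinuity at
0.7 Hz (2.64 vs 1.43 rad/s) is implemented as printed. SZL is RMI driven
by a degenerate constant gain table (150 mm/s, 1.5 rad/s, wide clamps), so
the stated equivalence between the two is structural.

SC: on an onset, pivot to put the wind class on "front", then drive
straight at 150 mm/s; after 1 s without odor, cast perpendicular to the
wind, alternating sides, legs 1.5 s doubling per reversal **up to a 6 s
cap**, then constant. The cap, and pivoting in place during re-orientation
(rather than driving through U-turns), keep the cast sweep bounded: an
uncapped doubling cast, or one that drives through its reversals, drifts
out of any finite arena even with no odor present, whereas the protocol
expects a no-odor trial to end by timeout. A tracked crawler can pivot in
place, so neither choice is unphysical.

## Trial protocol and metrics

dt = 10 ms everywhere (the robot's sensor sampling period). Success:
centre within 0.1 m of the source; failure: leaving the arena or 180 s.
Outcomes are exclusive and checked every tick, including at t = 0.
Identical seeds give bit-identical trials; a batch of n trials uses seeds
`base … base+n−1`.

Crosswind RMSE `√(Σᵢ(yᵢ − y_odor)²/n)` is computed over every logged step.
Localization-time statistics use successful trials only. Success counts are
compared with a two-sided Fisher's exact test (scipy); an independent
hypergeometric enumeration serves as its oracle in the tests. The
multiple-comparison procedure named for times/RMSE in the original study is
not specified there and is out of scope; a Mann–Whitney rank-sum hook is
provided instead.

The analysis stage bins per-tick (f, v, |ω|) samples by odor frequency
(0.1 Hz bins, medians — the generating statistic of the source figures is
not stated, medians are robust to the clamp) and refits each branch of the
affine gain law by least squares on per-bin median frequency vs median
speed. On noiseless logs generated from the law the coefficients are
recovered to numerical precision; this closes the loop between the analysis
stage and the controller core.

## What the generator does and does not show

The synthetic plume reproduces intermittency, frequency grading and
wind-advected geometry, but not the broad low-concentration background, the
sensor response dynamics, or the real turbulent spectra of the physical
arenas. Consequently the *protocol and controller mathematics* transfer,
and so does the study's central qualitative mechanism — in the
displaced-plume scenario the mode-modulated RMI agent meanders least
(lowest crosswind RMSE) and the wind-led SC agent is not more successful —
but absolute success rates do not: at desk scale the thin simulated plume
makes the odor-only state machine lose contact more often than the physical
robot did, and upwind surging (SC) profits from the simulator's clean wind
signal in the aligned scenario. Passing tests therefore certify the
algorithms and the protocol, not field performance.

## Problem sizes

The qualitative scenario-B comparison uses 100 trials per algorithm
(≈ 5× the original repetition count, affordable because failed trials run
their full 3 simulated minutes in well under a second); oracle-equivalence
checks use 10⁵ random sensor ticks and all 2×2 tables with group sizes
≤ 20; noisy parameter recovery uses 200 samples per 0.1 Hz bin
(SD 10 mm/s).
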