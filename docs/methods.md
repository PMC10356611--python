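# Methods

## The decision model and its simulator

The simulator realises a rise-to-threshold account of egg-laying site
selection.  Each egg-laying cycle is: an inter-egg refractory period, an
ovulation standstill, a search period, an abdomen bend, and deposition.
During the search a latent decision variable `A(t)` starts from
`reset_level` and follows a drift–diffusion process

    dA = r(v(substrate(t))) dt + noise_sd · dW,

integrated at the video frame rate (Euler–Maruyama, dt = 0.5 s at 2 Hz).
The drift is substrate dependent: on the favoured (lower-sucrose) option
it equals `drift_rate_high`; on the disfavoured option it starts at
`drift_rate_low` and relaxes exponentially toward `drift_rate_high` with
timescale `value_adapt_tau`, clocked from the fly's last visit to the
favoured option.  This is the simplest process consistent with three
observations the model must reproduce: a strong pooled bias toward the
lower-sucrose option, suppression of egg laying on the worse option for
roughly two minutes after leaving the better one, and a gradual recovery
thereafter.  When `A` crosses `threshold_level` the abdomen bend is
emitted; deposition follows `bend_to_deposit_delay` later and is deferred
until the fly is off the plastic barrier strip, on which eggs are never
laid.  `A` then resets.  The latent process is also reset after every
crossing, including any crossing that would yield no egg; whether real
egg-less events reset the biological process is unknown, and the
simulator adopts the reset convention throughout.

Parameter defaults (all in `DriftParams`, all overridable):

| parameter | default | units | rationale |
|---|---|---|---|
| `threshold_level` | 1.0 | latent | sets the latent scale |
| `drift_rate_high` | 0.02 | s⁻¹ | 50 s deterministic crossing, matching tens-of-seconds searches |
| `drift_rate_low` | −0.03 | s⁻¹ | the signal falls on the disfavoured option, keeping early crossings there rare |
| `noise_sd` | 0.03 | s^−½ | search-duration variability without noise-dominated choice |
| `value_adapt_tau` | 120 | s | the ~2 min recovery of the disfavoured option |
| `ovulation_duration_mean` | 60 | s | flies stand still about a minute while ovulating |
| `bend_to_deposit_delay` | 3 | s | bend-to-deposition latency |
| `inter_egg_refractory` | 60 | s | ovulation tends to follow the previous egg quickly |

`drift_rate_low` and `noise_sd` were calibrated once, jointly, so that a
default cohort lays ≥90% of eggs on the favoured half while still
exhibiting the late recovery of egg laying on the disfavoured half; they
were then frozen.  Ovulation durations are Gamma distributed (shape 4)
around the mean: strictly positive and unimodal.

A gentle hyperpolarization of the command neurons is modelled by
`DriftParams.scaled(factor)`, which attenuates the drift rates *and* the
diffusion coefficient by the same factor — a leak conductance shrinks the
effect of all synaptic input alike.  Scaling only the deterministic drift
would leave crossings noise-dominated and would weaken, rather than
sharpen, the choice bias; the uniform attenuation reproduces both the
two-to-several-fold lengthening of the search and the increased fraction
of eggs on the preferred option.

### Locomotion

Only the substrate-occupancy statistics matter downstream, so locomotion
is a two-state bout process: walking bouts (exponential, mean 15 s; bout
speed uniform on 2–6 mm/s; heading diffusing at 1.1 rad·s^−½) alternate
with pauses drawn from a mixture of short rests (mean 6 s, 88%) and long
rests (mean 60 s, 12%), inside a 20 × 40 mm chamber with reflective walls
and a 2.5 mm barrier strip at the midline.  The mixture was chosen so
that half-to-half transitions occur every ~30–120 s while occasional
minutes-long same-substrate residencies occur, as they do in real flies —
without them the long-elapsed-time bins of the rate curve would be
empty.  The walking fraction outside egg-laying periods comes out well
below one, in line with real non-egg-laying behaviour.

### What the generator does and does not emulate

It produces trajectories, annotated egg events, raw two-channel
fluorescence (gain on the latent variable, background, optional baseline
random walk and photon noise, volumes stamped at half completion), spike
trains implicitly via the forward model, and synapse tables with planted
recurrent motifs.  It does not emulate: body-posture kinematics, the
dip of the calcium signal during ovulation, egg-less threshold crossings,
feeding or other competing drives, spatial memory, or heterogeneity
across flies (all simulated flies share one parameter set).  Tests passing
on simulated data therefore validate the estimators' arithmetic and the
internal consistency of the model — not the biological fidelity of any
particular parameter value.

## Search-onset detection

The locomotor speed trace up to egg deposition is smoothed with an 18.5 s
centered boxcar, truncated at the trace ends, and scanned backward from
deposition for the most recent frame below 0.1 mm/s — the end of the
ovulation standstill.  The centered window is the reading under which the
documented 9 s minimum duration arises naturally (half the window rounded
down to the 0.5 s frame grid); the floor is additionally enforced as an
explicit clamp and clamped or fallback detections are flagged.  The
backward scan direction implements "start of the search" as the *end* of
the standstill; a forward scan would find the standstill's beginning.

## Rate curves

All flies in a condition are pooled.  Per elapsed-time bin: `n_eggs`
(depositions), `n_frames` (search-period frames), `n_visits` (changes of
bin assignment into the bin — rolling forward into the next bin and a
transition resetting the clock both count; staying put does not).  The
mean rate is `120 · n_eggs/n_frames`; the 90% CI is Clopper–Pearson on
`n_eggs/n_visits` rescaled by `120 · n_visits/n_frames`, making the CI
independent of the frame rate.  Searches shorter than 30 s are padded to
30 s by extending the start earlier; padded frames inherit the elapsed
values they would have had, and they do accrue visit counts.  Elapsed
time is measured from the most recent transition whether or not it
occurred within the current search; frames before any transition are
clocked from session start and flagged.  Curves are keyed by the
substrate currently occupied, which is equivalent to the direction of the
most recent transition.  Default bin edges are geometric
(0, 15, 30, 60, 120, 240, 480, 960, 1920, 3840, 7200 s) and configurable;
the two-bin early/late contrast is insensitive to the edge choice.

## ΔF/F

`F_actual = F_cell − F_background` removes autofluorescence and detector
offset and makes the ratio robust to ROI size.  `F0(t)` is the centered
running mean of `F_actual` over 20 min, truncated (not discarded) at the
recording edges so early events remain usable; a trailing window is the
alternative reading, and the fixed-`F0` variant (`fixed_f0=True`) bounds
the impact of that choice.  With a stimulation schedule, 105 s after each
onset is excluded from the `F0` estimate and flagged.  Samples with
`F0 ≤ 0` become NaN; an all-NaN result raises.  Everything downstream
lives on a 10 Hz grid filled by previous-neighbour assignment (each grid
point takes the latest sample at or before it).

Event-triggered ensembles drop, per trace, all samples at or after the
next exclusion event (e.g. the return transition), so a fly that returns
20 s after a transition contributes only 20 s to the post-transition
average.  The rise-slope statistic smooths ΔF/F with a 5 s boxcar, finds
the signal minimum after ovulation start, takes the first subsequent zero
crossing as the rise start, and divides the smoothed value 3.3 s before
bend completion (approximately when the bend begins) by the elapsed
time.  Traces that never re-reach zero are flagged NaN and excluded from
group statistics.  Stimulation responses are binned by the maximum ΔF/F
1–3 s after onset into seven bins; only the outer catch-alls (0.02 and
0.52) are canonical, and the five 0.10-wide interior edges are this
package's choice (configurable).  The behavioural response is reported as
post (2–4 s) minus pre (−2–0 s); the sign convention is documented
because prose descriptions of subtraction order are ambiguous.

## Ephys utilities

Spikes are peaks of the zero-phase high-pass-filtered (2nd-order
Butterworth, default 100 Hz) membrane potential above threshold,
separated by more than 1 ms (the larger of a violating pair survives).
The default threshold is 5× a MAD-based robust SD of the filtered trace;
real recordings vary, so both the cutoff and the threshold are exposed.
Sliding spike rate is the count in a 5 s (or 100 ms) window divided by
the window, assigned to the window centre, stepped at 0.1 ms.  De-spiked
`V_m` blanks 150 ms centred on each peak; overlapping windows merge.  The
junction-potential correction subtracts 13 mV exactly once (a flag
refuses re-application).  The fluorescence forward model convolves the
rate with a causal unit-mass exponential (τ = 300 ms, indicator off
kinetics, truncated at 8τ) then a centered 2.8 s boxcar (slowest
volumetric frame period); unit-mass normalisation is this package's
choice so a constant rate maps to itself — only the relative decay shape
matters.  Half-decay times interpolate linearly between samples and are
flagged NaN when the tail never crosses the midpoint.

## Motif search

Duplicate (pre, post) rows are summed before the synapse threshold
(default ten) is applied.  A single-intermediary loop around a seed class
is a non-seed cell that receives a thresholded connection from a seed
cell on each hemisphere *and* sends one to a seed cell on each
hemisphere; the intermediary may receive from and project to different
individual seed cells (the stricter same-cell reading is obtainable from
the returned evidence).  The one-directional relaxation
(`require_both_directions=False`) is also exposed.  Results are invariant
to row order and to splitting counts across duplicate rows, and raising
the threshold can only remove results.  Gap junctions are out of scope.

## Statistical choices

Clopper–Pearson intervals use the standard beta-quantile bounds (0 and 1
at the boundaries).  The binary-group rank-sum test exploits that with
0/1 data the rank-sum statistic is a monotone function of the group-1
event count, whose exact permutation null is hypergeometric: for
`n1 + n2 ≤ 40` the exact two-sided permutation p-value is returned, and
for larger samples the tie-corrected normal approximation (without
continuity correction, so identical groups give exactly p = 1).  The
normal approximation alone is badly off in deep tails at small n, which
is why the hybrid exists.

## Problem sizes

The test suite exercises cohorts of 12–40 simulated flies at 1–2 h per
session, which gives hundreds of eggs per contrast — enough for every
qualitative direction checked to be stable across seeds.  The acceptance
script simulates 200 flies × 2 h per chamber condition.  Numerical
tolerances: oracle equalities are asserted at 1e-9–1e-12; stochastic
directions are asserted as inequalities with comfortable margins rather
than as point values.
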