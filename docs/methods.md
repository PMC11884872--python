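# Methods

This note documents the models, parameter choices and numerical decisions
behind `sonoreach`, and what the synthetic tests do and do not establish
about real data.

## Coordinate and displacement conventions

Pose streams use image coordinates (y grows downward). Displacement is
`(rest_y − y) · mm_per_pixel`, so upward paw motion is positive. The paw
position is the **mean** y of the digits whose tracking likelihood passes
the confidence floor (default 0.6); the mean was preferred over the median
for smoothness, at the cost of slightly less robustness to a single
mistracked digit. If no digit passes the floor, the sample is flagged
invalid and **holds the last valid displacement** — dropping frames would
stall both the trial machine and the tone, whereas a brief hold only
delays threshold crossings by the dropout length. Eight digits are tracked
in total, four per forepaw; the keypoint list is configurable via the
bodypart name prefixes.

The pose CSV dialect is the three-header-row single-animal layout
(scorer / bodyparts / coords, with x/y/likelihood cycling per bodypart).
The multi-animal variant (an `individuals` row) is detected and rejected
with a clear message. The dialect carries no time column, so timestamps
are synthesized as `frame_index / fps` (default 70 fps, the rate at which
the task is normally run).

## Trial state machine

Three states: `AT_REST → REACHING → REFRACTORY`.

| parameter | default | meaning |
|---|---|---|
| `target_offset` | 15 mm | target-zone height above rest |
| `start_tolerance` | 2 mm | start band; rising above it begins a reach |
| `refractory` | 0.5 s | minimum interval after a success before re-arming |
| `likelihood_floor` | 0.6 | digit confidence gate |
| `smooth_window` | 3 frames | causal moving average before the FSM |

The target height and the return-to-start requirement define the task;
the 2 mm start band and the 0.5 s refractory are this package's choices
(some hysteresis is necessary to avoid chatter at the rest position, and
some minimum inter-trial interval to keep reward delivery well defined;
neither value is critical and both are configurable). A reach that enters
the target zone emits `target_entry`, `success` and a `reward` (5 µl)
event in the same frame and then requires *both* return to the start band
*and* refractory expiry before `trial_reset`. A frame that jumps straight
from the start band into the target zone counts in that same frame. The
streaming machine is verified against an independent brute-force excursion
scan on random traces.

The 3-frame causal smoother attenuates a minimum-jerk peak by well under
0.1 mm at 70 fps, so threshold behavior is preserved for apexes more than
~0.05 mm from the target; equivalence tests between the machine and the
simulator's ground truth run with `smooth_window = 1` because a planted
apex lying *within* that hair's-breadth band of 15 mm may legitimately be
counted differently after smoothing.

## Sonification

Frequency map: linear from 2 kHz (rest) to 20 kHz at `d_max` (default
equal to the target height, so the target sounds the top of the band),
clipped outside [0, d_max] — the band is the speaker-rated range, so
extrapolation is not meaningful. The mapping input is
displacement-from-rest, not absolute pixel position. "Movement intensity"
in the audio validation is taken to be instantaneous vertical
displacement (not velocity); the correlation and slope are computed on
range-normalized variables so a perfect recode gives slope exactly 1.

Synthesis is offline (the real-time loop only *logs* tone commands): a
phase accumulator carries phase across the piecewise-constant frequency
steps, and activity transitions are shaped by a raised-cosine envelope of
5 ms, so the rendered audio is click-free. Sample rate 44.1 kHz with a
Nyquist guard against `f_max`.

Validation closes the loop: a Hann-window magnitude spectrogram
(`nperseg = 512`, 50% hop, parabolic peak interpolation) tracks the
dominant frequency. Because commands update once per camera frame
(~14 ms) while windows span ~12 ms, a window may contain two commanded
tones; a window is scored as matching when its spectral peak lies within
one frequency bin (≈ 86 Hz) of *a frequency commanded during that
window*, and only windows fully inside active spans are scored (on/off
ramps carry no commanded frequency).

## Behavior simulator

Each reach is a **minimum-jerk** position pulse (`s(u) = 10u³ − 15u⁴ +
6u⁵` up and mirrored back), rescaled so the sampled maximum equals the
drawn apex exactly, plus additive Gaussian jitter. Minimum jerk is the
standard smooth-reach model and is fully specified, which real reach
trajectories for this task are not.

No kinematic distribution parameters are published for this task, so all
of the following are documented stand-ins, chosen once for plausibility:

| parameter | default | role |
|---|---|---|
| `base_reach_rate` | 3 /min | Day-1 left-paw reach rate |
| `rate_gain_feedback` / `control` | 1.35 / 1.08 per day | planted rate learning |
| `peak_mean_base` | 13 mm | Day-1 mean apex (most early reaches miss) |
| `peak_mean_gain_feedback` / `control` | +1.5 / +0.5 mm per day | planted accuracy learning |
| `peak_sd_base` | 4 mm | Day-1 apex spread |
| `peak_sd_gain_feedback` / `control` | ×0.6 / ×1.0 per day | feedback reaches become consistent |
| `noise_sd` | 0.3 mm | frame-level kinematic jitter |
| `right_paw_rate` | 3 /min, apex 8 ± 2 mm | constant non-task movements (ratio denominator) |
| `reach_duration` | 0.8 ± 0.1 s | pulse length |
| `min_gap` | 2 s | enforced rest between reaches |

Learning is planted in *both* the reach rate (driving the reach-ratio
curve) and the apex distribution (driving the Day-1 vs Day-2+ trajectory
cluster structure). The right paw is constant-rate because the analysis
only needs it as a normalization denominator. Displacements are converted
to pixel pose frames via a fixed internal calibration (0.1 mm/px, rest at
y = 400 px) so the calibration code paths are always exercised.

What the simulator does **not** model: pixel-level video, tracking error
structure (likelihoods are constant 0.99 with optional uniform dropouts),
inter-digit kinematic differences, and — deliberately — any behavioral
*response* to the tone. The learning effects are planted, not emergent, so
passing tests demonstrate that the pipeline detects such effects when
present and stays calibrated when absent; they say nothing about whether
auditory feedback drives learning in real animals.

## Analysis

Reach segmentation offline uses the same excursion rule as the real-time
machine (maximal runs above `start_tolerance`), applied per paw.
Segments are linearly time-warped to T = 100 samples. PCA keeps the
smallest component count explaining ≥ 90% of variance (capped at 10).
Clustering is a full-covariance Gaussian mixture with 10 seeded restarts
per candidate K (1–6), selected by minimum BIC; labels come from maximum
responsibility. t-SNE (seeded, PCA-initialized) is strictly a
visualization and never feeds the clustering. Note BIC's finite-sample
behavior: on a few hundred rows of mildly non-Gaussian clusters it can
occasionally split one component in two; recovery statistics are
therefore reported over seeds rather than asserted per seed.

The reach ratio is `left_count / right_count`, normalized per animal to
Day 1 (hence Day 1 ≡ 1). Mice with a zero right-paw count on any day, or
a zero Day-1 ratio, cannot be normalized and are excluded with a report.
Per-day comparisons use Welch's t-test by default (pooled-variance
available via a flag); days on which both groups are constant and equal
(the Day-1 anchor) report p = 1, d = 0 rather than NaN. The two-way
repeated-measures ANOVA (group between, day within,
Greenhouse–Geisser-corrected within-subject terms) is delegated to
`pingouin.mixed_anova`. Cohen's d uses the pooled-SD definition.

Statistical calibration (type-I error, power) runs on table-level
synthetic cohorts: normalized ratios `1 + σz` (σ = 0.3) from Day 2 on,
with an optional additive group offset expressed in pooled-SD units, plus
a count-level Poisson variant drawn from the simulator's own rate model.
The planted quantities are defined at the table level, so full
pose-stream simulation would add cost without information.

## Determinism and seeds

A master seed fans out via `SeedSequence(master, spawn_key=(group, mouse,
day))`, so any single session is reproducible in isolation. The replay
clock is simulated (virtual time), making the entire closed loop — event
log, tone log, per-frame timings — bit-reproducible; the pipeline's tidy
outputs are byte-identical across runs with the same seed. Latency
instrumentation is bookkeeping over injected per-stage delays under the
simulated clock; it verifies the measurement chain, and makes no claim
about real hardware throughput or latency.

## Problem sizes used in tests

The design defaults are the full study (7 mice per group × 2 groups ×
4 days × 30 min at 70 fps). Tests and the acceptance script scale the
*session length* down (60–300 s) and occasionally the cohort (3 × 3) —
these sizes were chosen so the planted effects remain comfortably
detectable at desk scale; all rates and effect sizes stay at their
defaults. Monte-Carlo sizes: 1,000 random FSM traces, 100 clustering
seeds, 200 statistical simulations.

## Known limitations

* The simulator's kinematic parameters are stand-ins; absolute reach
  counts and success rates should not be compared against real animals.
* The audio path renders offline from the tone log; real-time audio
  device callbacks (and their buffering latency) are out of scope.
* GMM cluster count selection by BIC is only asymptotically consistent
  (see above).
* The multi-animal pose dialect, video decoding and network inference are
  out of scope; the pose source is a CSV replay or the simulator.
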