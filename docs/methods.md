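# Methods

This note documents the models, calibration, and numerical choices behind
`voc_ethogram`, and what its tests do and do not establish.

## Observation model

Tracks are fixed-rate 2-D centroid series in a vertical arena, origin at the
bottom-left corner, y increasing upward (a slip is a decrease in y). The
frame interval is 0.25 s; all parameter formulas assume it, so a track with a
different `dt` is rejected rather than resampled, and missing frames are
errors rather than interpolation targets. The default arena is 50 mm wide ×
150 mm high with the uppermost 20% labeled "top", the lowest 20% "bottom",
and a 20 mm × 10 mm food patch centered on the bottom edge. The zone
geometry is a configuration convention of this package — the named areas are
standard for this assay but their exact extents are not a measured quantity —
and every zone parameter is settable in the arena configuration.

## Segment kinematics

Tracks are cut into non-overlapping 5-s segments of exactly 20 sub-segments;
a trailing partial window is discarded. Per segment:

| parameter | definition | units |
|---|---|---|
| speed | Σ‖Δ‖ / 5 s | mm/s |
| acceleration | mean over the 19 pairs of \|v(k+1) − v(k)\| / 0.25 s, v(k) = ‖Δₖ‖/0.25 s | mm/s² |
| locomotory rate | Σ‖Δ‖ / (5 s − stop time); undefined if fully stopped | mm/s |
| meander | Σ\|Δheading\| between consecutive *moving* sub-segments / moving path length; undefined with < 2 moving sub-segments | rad/mm |
| stop duration | 0.25 s × #(‖Δ‖ < 0.1 mm, strict) | s |
| slipping number | maximal runs of sub-segments with Δy < −2 mm | count |

Choices worth stating explicitly:

* **Acceleration uses absolute speed differences.** Group-level acceleration
  is reported as a positive magnitude; a signed mean would be ≈ 0 for any
  stationary gait.
* **Meander is per unit distance (rad/mm), not per unit time.** The two
  conventions disagree dimensionally; per-distance is the one that makes
  meander a shape property independent of pace. Stopped sub-segments are
  skipped because the heading of a sub-resolution displacement is tracker
  noise. On a circular arc of radius r sampled in 20 steps the estimator
  returns (19/20)/r — the first moving step contributes path but no heading
  change — converging to 1/r with window length.
* **The slip detector** (threshold 2 mm per 0.25 s, i.e. 8 mm/s downward,
  roughly twice the fastest group-mean walking speed; maximal runs merged
  into one event) is an operational definition of this package. Its
  sensitivity is measured against the generator's labeled ground truth
  (≥ 0.95 at the default threshold in the test suite).
* **Undefined values stay NaN.** Fully stopped segments have no meander or
  locomotory rate; group summaries exclude them and report exclusion counts.
  Only the SOM input imputes them (see below).

## Box-counting fractal dimension

N(r) is the number of cells of a grid of side r, anchored at the arena
origin, containing at least one position; D is the least-squares slope of
log N(r) against log(1/r). Defaults: dyadic box sizes from height/2 (75 mm)
down to 0.5 mm (8 scales), windows of 30 min tiled without overlap. The
0.5-mm floor sits 5× above the 0.1-mm movement-resolution threshold so
tracker noise does not masquerade as fine structure. The grid is anchored
(no offset averaging) to keep the estimator deterministic; a robustness test
verifies the line fixture stays within 1.0 ± 0.1 when the scale range is
halved or doubled. The fit uses all supplied scales — no automatic
scaling-region selection — so finite-size effects at the largest boxes bias
the lattice fixture slightly below 2 (≈ 1.91 with the defaults); estimates
are reported with their fit R². A window length of 30 s is also supported
via the `window` argument for users who want the short-window reading;
30 min is the default because D is a coverage statistic and needs path.

## SOM ethogram

Inputs are the six parameters per segment, min–max scaled to [0, 1] with the
training bounds stored in the model; later data are clipped to the stored
bounds (with a clip count reported). Undefined meander/locomotory-rate
entries are imputed as 0 *after* scaling: a fully stopped segment is
legitimately minimal-activity input to the map, and the imputation count is
retained on the normalized table.

The map is 14 × 10 (140 nodes ≈ 2/3 occupancy under the 5√n sizing heuristic
for cohort-scale inputs, taller than wide so the dominant activity gradient
lies along the vertical axis). Weights are initialized uniformly at random
from the seed. Training is sequential over randomly sampled rows, two
phases with linearly decaying learning rate and Gaussian neighborhood
radius: rough ordering (10 passes, α 0.5→0.05, radius 5→1) then fine tuning
(40 passes, α 0.05→0.01, radius 1→0.5). Per-phase iteration caps (150 000
and 600 000) bound training time on large cohorts; at the caps a full
18-group cohort (≈ 97 000 segments) trains in ≈ 9 s and, empirically, fewer
fine-tuning iterations leave cluster boundaries unstable between seeds.
Identical seed + data give bit-identical models; models serialize to a
single JSON file (grid shape, weights, bounds, schedule, seed).

The codebook is clustered by Ward linkage on the Euclidean distance matrix
of the 140 weight vectors, heights rescaled to 0–100%, cut at nine clusters
whose ids follow dendrogram leaf order. The nine clusters map onto four
patterns by a fixed 3/1/3/2 rule evaluated on codebook profiles: the two
lowest-speed clusters are *stop*; of the rest, the three highest-meander are
*zigzag*; of the remaining four, the highest meander-to-speed ratio is
*circling*; the other three are *active*. The rule is the package's
operationalization of pattern semantics that would otherwise require visual
inspection; the partition sizes are fixed, so the rule degrades loudly (a
labeling error) when the codebook has no activity gradient.

## Synthetic cohorts: what is emulated, and how it is calibrated

Each individual is simulated at 0.25-s steps as:

1. **Move/stop bouts** — a two-state Markov chain; stop-bout mean length is
   5 steps (exit probability 0.2), entry probability set per preset from the
   target stationary stop time.
2. **Correlated walk** — while moving, heading gains N(0, turn_sd) per step,
   then relaxes toward "up" with weight `geotaxis_drift` (toward the food
   patch with weight `food_attraction`); near the ceiling the drift target
   rotates to the nearest horizontal so climbers patrol the top edge instead
   of pounding the wall (uncompensated wall reflections would otherwise bias
   recovered speed low by ≈ 2%). Step length is \|N(μ, (jitter·μ)²)\| capped
   at 1.9 mm — just below the slip threshold, so gait can never masquerade
   as a slip — with μ solved from the capped-folded-normal mean so the
   downstream speed estimator is unbiased. Stopped steps displace
   uniformly below 0.08 mm. Walls reflect.
3. **Slips** — per 5-s block, Poisson(slip_rate) single-step drops of
   ≈ 2.2 mm (clipped ≥ 2.05 mm, i.e. always detectable), placed uniformly at
   non-adjacent positions (never at a block boundary) so detected maximal
   runs correspond one-to-one to injected events; a per-step Bernoulli
   arrival would merge ≈ 4% of events and bias recovery. A slip fires only
   when the fly has that much wall height beneath it, and the fly rights
   itself (heading up) after falling. Events are recorded as ground truth
   `(start, length)` labels on the track.
4. **Individual heterogeneity** — each fly draws its nominal speed and slip
   rate from N(group mean, group SD), so cohort dispersion matches the
   group-level SDs the presets encode (n = 15 statistics).

The while-moving step speed is back-solved from the preset's nominal segment
speed by an explicit path budget (stop time, stop dribble, slip falls), with
the slip term capped at 45% of the path — the sustainability bound beyond
which falls cannot be climbed back.

**Preset calibration.** The nine strain × treatment presets pin nominal
speeds and slip counts (and their SDs) to the screening study's published
group statistics; pre-exposure sessions use the strain's control preset.
Quantities with no published value — stop durations, turning spread,
geotaxis drift, gait jitter, food attraction, p53 treated speeds — were
chosen once, at design time, to realize every published qualitative
contrast: exposure lowers speed, acceleration, and locomotory rate, raises
stop duration, meander, and slipping, reduces track complexity (fractal D),
and shifts time from the active pattern to the stop pattern. Two of these
choices deserve comment:

* *Gait jitter encodes the acceleration contrast.* Any detectable slip is a
  ≥ 8 mm/s speed spike, so with slip counts rising several-fold after
  exposure the slip contribution to acceleration necessarily rises; the
  published *decrease* in acceleration is realized by high within-gait speed
  variability in control presets (jitter fraction 0.8) versus low
  variability in treated presets (0.2) — behaviorally: a brisk stop-start
  gait versus a uniformly sluggish one.
* *Stop durations respect the locomotory-rate contrast.* Stop time and
  locomotory rate jointly constrain each other (locomotory rate =
  speed/(1 − stop/5)); treated stop durations are set high enough to rise
  but low enough that locomotory rate still falls.

**A sustainability limit, surfaced rather than hidden.** For one group
(p38b × formaldehyde) the pinned pair (4.03 slips per 5 s, 2.18 mm/s) is
jointly unrealizable in a bounded arena: the implied downward flux exceeds
what the total path could climb back even moving straight up (the bound is
≈ 2.4 slips per 5 s at that speed). Under the wall-height gating this group
settles into a climb/slip equilibrium whose realized slip count (≈ 1–1.5 per
5 s) and speed sit below nominal. The direction of every contrast is
preserved; recovery targets are asserted only for control presets, which are
all sustainable.

**What the generator does not emulate.** Odor plumes, dose–response
kinetics, circadian or fatigue drift within a session, wall-following other
than the ceiling-patrol rule, tracker artifacts (identity swaps, jitter
beyond the stop threshold), grooming or flight. Passing recovery and
direction tests therefore shows the estimators are correct and the analysis
is sensitive to effects of the published size under this model's
assumptions — not that real recordings would be this clean.

## Reporting

Group summaries are mean ± SD with n per strain × treatment × session
(SD = 0 by convention for n = 1; undefined entries excluded and counted).
Pearson correlations are computed on per-individual mean parameters pooled
across groups — group sizes of 15 imply individual-level statistics —
with segment-level correlation available via `level="segment"`. Hypothesis
tests (ANOVA, multiple comparisons) are deliberately out of scope; the
summary tables expose what external statistics packages need. The pipeline
runner writes every stage product (tracks, features, fractal estimates,
occupancy, SOM model, ethogram, summaries, correlations, figures) plus a
run log with seed, configuration, and stage timings; identical config + seed
reproduce identical tables.

## Problem sizes used in validation

Recovery checks simulate 15 individuals × 30 min per control preset
(5 400 segments per group); direction checks simulate the full nine-group
pre/post design at 15 individuals × 15 min (97 200 segments) — long enough
that group-mean Monte-Carlo error is small against the calibrated effect
sizes, and the full battery (simulation, features, fractal, SOM, ethogram)
completes in well under a minute on one core. Fractal windows in these runs
equal the track length (15–30 min).

## Known limitations

* The acceleration and meander estimators are frame-rate-bound: behaviors
  faster than 0.25 s (tremor, saccadic turns) alias into the gait statistics.
* The box-count estimator has finite-size bias at scales near the arena
  dimensions (visible as ≈ −0.09 on the filled-lattice fixture); comparisons
  should hold the box-size range fixed.
* Pattern labeling assumes the 3/1/3/2 partition; a cohort genuinely lacking
  one of the four behaviors will still be forced into it.
* The slip detector cannot see slips slower than 8 mm/s; the generator
  respects the same floor, so sensitivity estimates do not cover slow slides.
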