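# Methods

## The measurement model

A trial is a dual-hand recording: for each of the two hands, a sequence of
frames carrying time since start (s), Cartesian position (mm) and
roll/pitch/yaw (degrees), sampled nominally at 25 fps.  The two tracks are
index-aligned — every inter-hand computation assumes frame *i* of the left
hand and frame *i* of the right hand are simultaneous — so frames with any
non-finite channel are dropped *pairwise* on ingest.  If a file carries no
time column, timestamps are synthesised as `frame_index / fps`.  Positions
are mm and time is seconds throughout; all scoring constants are metric.
Orientation channels are carried and validated (normalised into
[−360, 360]°) but enter none of the indicators.

## Kinematic indicators

**Task time** is last minus first timestamp.

**Manipulator collisions** counts *occasions* on which the 3D Euclidean
distance between the hands falls below the collision threshold (default
100 mm).  An occasion is a maximal contiguous run of sub-threshold frames,
not a frame count: per-frame counting would scale linearly with the frame
rate, which is an acquisition artefact, while the number of distinct
approaches is rate-stable.  The same run-length convention is used for
high-acceleration events.

**High-acceleration movements** thresholds each hand's acceleration
magnitude at 10 m/s² and sums the two hands' run counts.  Acceleration is
estimated by differentiating position twice with second-order central
differences (`numpy.gradient`, exact for quadratic-in-time motion) after
converting mm to m.  Raw double-differencing at 25 fps amplifies sensor
noise by (fps)² ≈ 625, so positions are pre-smoothed with a centered
moving average (default 5 frames, configurable, odd).  The smoothing runs
in *valid* mode: the (window − 1) edge frames without a full window are
trimmed rather than padded, because any padding scheme bends a linear
track at the boundary and the resulting kink registers as a spurious
event.  A 5-frame window at 25 fps suppresses sub-0.1 s transients; an
event must be sustained for roughly 0.2 s to survive, which at 10 m/s²
corresponds to a hand displacement of order 100 mm — a genuine ballistic
flick, not sensor jitter.

**Economy-of-motion** is each hand's polyline path length (sum of
consecutive-frame Euclidean displacements).  Both per-hand values and
their mean are reported; the composite score consumes the mean, which
reconciles the per-hand definition with the published score's anchor on
the "average distance" of the two hands.

**Used workspace** is the volume covered by movement, computed by default
as the convex hull (Qhull) of both hands' pooled positions; an axis-aligned
bounding box is available as a cheaper, rotation-variant alternative.
Degenerate (coplanar/collinear) point sets yield volume 0 with a warning
rather than an error, since a perfectly planar motion has no 3D coverage.
Whether the original analysis pooled hands or used one is not documented;
pooling is this package's choice and is configurable only through the
recording itself (feed a single hand twice).

Four ratio derivatives — workspace/time, time/workspace, eom/time,
time/eom — are stored as exact ratios of the base fields.

## The composite MC score

```
MC = time_coeff/t + eom_coeff/EOM + (W/t)/ws_divisor − penalty_coeff·(t/W)
```

Defaults: `time_coeff` 5000 points·s, `eom_coeff` 6000 points·mm,
`ws_divisor` 60 mm³ s⁻¹ per point, `penalty_coeff` 4000 points·mm³·s⁻¹.
At the anchor profile (t < 83 s, EOM < 300 mm, W/t > 1200 mm³/s) the three
positive terms contribute at least 60 + 20 + 20 points, and a trial slow
relative to its covered workspace (t/W at 0.0025 s/mm³) loses 10.  The
score is strictly decreasing in time and economy-of-motion and strictly
increasing in workspace (the time-term, workspace-term and penalty-term
derivatives all have the same sign in t).  The nominal 100-point maximum
is *not* enforced: the formula is unbounded above and below, no clamping
or internal rounding is applied, and values are rounded (1 decimal) only
at report time.  Non-positive time, economy-of-motion or workspace make
the score undefined and raise, rather than clamp — a zero-path or
zero-volume trial is a data problem, not a score of −∞.

## Overall proficiency classes

A trial's overall score is BABA + dVSS + MC.  The published bands are
printed as integer ranges (0–130, 131–170, 171–240); real-valued sums need
a convention at the edges, and this package uses half-open intervals —
low iff overall ≤ 130, moderate iff 130 < overall ≤ 170, high iff
overall > 170 — which is the unique integer-compatible extension that
keeps `classify` monotone and reproduces the published 6/8/6 split of the
shipped 20-trial table.  The 240 ceiling is nominal and not enforced.

## Statistics

Pearson correlations use the product-moment formula with two-sided
p-values from the exact t transform `t = r·√((n−2)/(1−r²))` on n−2
degrees of freedom (scipy's implementation; an independently coded
textbook formula serves as the test oracle).  Inputs with zero variance
or fewer than 3 pairs raise.

Indicator screening correlates each of the 5 base indicators and 4
derivatives against each external score (18 tests) and flags p < α
(default 0.05).  No multiplicity correction is applied by default — the
screening is an exploratory variable-selection heuristic, and published
analyses of this design report raw thresholds — but Holm step-down
adjustment is available (`holm=True`).  Indicators that are constant
across the cohort (e.g. zero collisions everywhere) have undefined
correlation; they are reported with `result=None` and never selected.

Min-max normalisation to [0, 1] is provided for presentation (plotting
scores of different ranges on one axis).  Pearson's r is invariant under
positive affine maps, so normalising before correlating changes nothing;
the inference path therefore uses raw scores, and the equivalence is
asserted by a test.

Group comparisons (e.g. low- vs high-proficiency economy-of-motion) use a
two-tailed two-sample t-test, Welch's unequal-variance variant by default
— the safer choice when group variances are unknown — with Student's
pooled test selectable.  Descriptive summaries use the sample (n−1) SD,
which reproduces the published ± values exactly.

## Synthetic data generator

The generator exists because raw recordings of this kind of study are not
public: it provides inputs with the statistical structure the analysis
assumes, with known ground truth.

Each hand moves through minimum-jerk segments (position profile
10τ³ − 15τ⁴ + 6τ⁵) between via-points drawn uniformly in a per-hand cubic
workspace (default 40 mm edge).  Minimum-jerk motion is the standard
smooth model of point-to-point reaching and gives the acceleration
detector a clean null: cruise accelerations are ~10⁻³ m/s², four orders
below threshold.  A latent proficiency p ∈ [0, 1] drives affine links:

| parameter | at p = 0 | at p = 1 | effect |
|---|---|---|---|
| cruise speed (mm/s) | 2.5 | 5.2 | time ↓ with skill |
| detour factor | 2.6 | 1.1 | path length ↓ with skill |
| tremor SD (mm) | 0.30 | 0.05 | path length ↓ with skill |
| inter-hand gap (mm) | 40 | 160 | collisions ↓, workspace rate ↑ |

Detours route each segment through a perpendicular midpoint bump of
height (L/2)·√(d²−1), clipped into the workspace box, so unskilled paths
are longer without covering more volume.  Tremor is band-limited
(moving-averaged white noise, 1 s window): raw white noise at 25 fps
would dominate the path length.  Ballistic "twitches" — out-and-back
140 mm minimum-jerk flicks over ~0.4 s, the minimum displacement scale a
genuine supra-10 m/s² event can have at this frame rate — occur at a small
*proficiency-independent* Poisson rate, deliberately making the
high-acceleration count a weak indicator, as it is in published
console-training cohorts.  External BABA and dVSS scores are affine in the
same latent proficiency plus Gaussian noise (SD 5 points), clipped to
their scales.

Default magnitudes target the published orders for this task: trial times
of ~60–240 s, hand path lengths of ~250–800 mm, workspace-usage rates of
~10³ mm³/s, MC scores of a few tens to ~140 points.  The realised
cohort-level correlations mirror the published effect-size hierarchy:
completion time correlates strongly with the simulator score (mean
r ≈ −0.8), economy-of-motion moderately (≈ −0.5), the workspace rate
weakly positively (≈ +0.3), and high-acceleration/collision counts
unreliably.

All randomness flows from `numpy.random.default_rng` (PCG64); identical
specs and seeds give bit-identical recordings across runs.

**What passing the synthetic tests shows — and does not.**  Recovery of
the built-in links shows that the indicator computations, the composite
score and the screening statistics jointly detect skill structure of the
assumed form at the study's sample size (n = 20 trials).  It does not
validate the generator's realism: real console motion has postural
constraints, task-phase structure, serially correlated noise and
left/right asymmetries the generator omits, and the published raw-motion
group contrasts (e.g. right-hand economy-of-motion in low vs high trials)
remain unverifiable without the original recordings.

## Pipeline and determinism

The pipeline matches recordings to score rows by trial key
(`p<participant>c<cycle>`), reporting all unmatched identifiers at once.
CSV outputs are written with fixed `%.10g` formatting; the run log records
a SHA-256 configuration hash and library versions but no timestamps, so a
rerun with identical inputs is byte-identical.  Scores-only mode skips
recordings entirely and takes MC values from the score table, enabling
re-analysis of published tables.

## Numerical choices and degenerate inputs

- Hull volume and Delaunay-based test oracles agree to ~1e−8 relative;
  ties at exactly the collision/acceleration threshold are excluded
  (strict `<` / `>`) so a hand resting exactly at 100 mm is not a
  collision.
- Trajectory files are written with 10 significant digits; round-trips
  are exact to ~1e−6 mm.
- Breakdown totals satisfy the additive identity to 1e−9.
- Empty cohorts, single-trial cycles (SD undefined), constant sequences
  and sub-3-frame recordings raise typed errors rather than returning
  NaN.

## Known limitations

- Hands only: the trajectory dialect has no foot channels, although the
  indicator definitions would extend to them.
- The workspace hull treats the union of both hands' positions as one
  point cloud; separate per-hand volumes are not reported.
- The inter-hand distance is 3D Euclidean; no planar projection option.
- The generator's proficiency links are affine by construction —
  convenient for recovery tests, but real learning curves are not.
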