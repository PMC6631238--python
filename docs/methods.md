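# Methods

## Problem and signal model

The task is simultaneous recognition of eating and drinking from one
wrist-worn IMU sampled at 100 Hz, in free-living conditions, with near
real-time (causal) processing. The two activities differ structurally:
eating is a many-minute activity composed of sparse hand-to-mouth
gestures separated by pauses; drinking is a single gesture of a few
seconds whose gyroscope magnitude carries two prominent rotation peaks
(grabbing/raising the container, putting it back). This asymmetry
motivates the semi-hierarchical design: two binary recognizers with
segmentation tailored per activity, fused afterwards, then filtered by
daily-evidence rules.

## Preprocessing

Streams are downsampled by an integer factor (default 2, 100 → 50 Hz),
low-pass filtered per channel with a causal Butterworth filter, and
smoothed with the past-side half of a Gaussian kernel (normalized to unit
sum, renormalized over the available history at the stream head so
constants are preserved exactly). Every stage is a single forward pass:
output *i* depends only on inputs 0..*i*, so the same code path works on
a live stream. Defaults: cutoff 5 Hz, order 4 — retains hand-gesture
bandwidth (< ≈5 Hz) while suppressing sensor noise; smoothing σ = 0.5 s,
kernel truncated at 3σ — smooths within a gesture without bridging
adjacent gestures. Downsampling precedes filtering. All three defaults
are configurable in `RunConfig`.

## Segmentation

* **FW** — length `round(length_s·fs)` samples, stride
  `round(length·(1−overlap))`, trailing partial window discarded.
* **DW** — a left-to-right scan of a 1-D signal (here the gyroscope
  magnitude) maintaining the current maximal descending run. A run
  restarts when the signal rises above its running minimum by more than
  `floor` (keeps noise from fragmenting runs). When a run ends, a window
  boundary is placed just past the run minimum iff the run's drop
  (max − min) exceeds `θ = max(floor, scale·σ_N)` where σ_N is the
  standard deviation of the N input samples preceding the *run start*.
  Freezing θ at the run start matters: evaluated at the run end, the
  window of "previous N samples" contains the peak itself, and a peak
  would mask its own descending flank. With a symmetric gesture peak the
  pre-peak window still contains the rising flank (σ ≈ 0.35 × amplitude),
  which bounds usable `scale` below ≈ 2.8; the default is **scale = 2**
  with `floor = 0.1 deg/s` and `N = 100` (2 s at 50 Hz). The dispersion
  measure itself is a design choice — the method this reconstructs is
  not fully specified in the literature we follow — and is fully
  configurable.
* **DFW** — DW applied independently to consecutive blocks of
  `t_s` seconds (default 10 s, matching the eating-branch window):
  threshold history resets at each block start (θ = floor until N
  samples accrue) and a split is forced at every block edge, so no
  window exceeds `t_s`. DW/DFW windows partition the signal exactly.

## Features

Each window maps to a fixed 33-value descriptor (ordering documented in
`FEATURE_NAMES`): per-axis mean, population variance and a Haar-like
step response (first-half mean − second-half mean; odd windows split at
`n // 2`) for all six axes; pairwise axis correlations within each
sensor (defined 0 when either axis has zero variance); accelerometer
axis covariances; gyroscope zero-crossing rates of the mean-removed
signal per second; *manipulation* — the window mean of
(|gx|+|gy|+|gz|) / max(|a|, ε) with ε = 1e-6 m/s²; *linear
acceleration* — the window mean of | |a| − g | with g = 9.80665 m/s²;
and the RMS of the accelerometer magnitude. All moments are population
moments. Only time-domain features are used: the intended deployment is
a phone/wearable, where FFTs per window are a needless cost.

The two-stage selection procedure is provided to reproduce how this set
was derived: (1) among feature pairs with |r| > 0.8, drop the
computationally costlier member (cost ranking: correlations/covariances
> Haar > variance > zero-crossings > RMS > mean; ties by name), pairs
processed in descending |r|; (2) drop features whose normalized impurity
importance falls below 1 % in either of two forests trained on
eat-vs-rest and drink-vs-rest labels. The runtime pipeline uses the
fixed 33-name list. An optional min-max scaler exists but is off by
default: forests are scale-invariant.

## Class balancing and branch models

Both branches balance training data with SMOTE followed by ENN. SMOTE
synthesizes minority samples by interpolating toward one of the k = 5
nearest minority neighbours until parity; ENN (k = 3, majority vote,
ties kept) removes samples of either class contradicted by their
neighbourhood, cleaning the boundary SMOTE blurs. Both steps are
implemented here on top of scikit-learn's `NearestNeighbors` and are
deterministic under the run seed. A minority class smaller than k+1
raises with advice to lower k.

The classifier is a 100-tree Random Forest (impurity splits, seeded);
any sklearn-style estimator with `fit`/`predict_proba` can be plugged in
its place. The drinking branch's training set is thinned to ≈ 3.5
negative windows per positive before balancing, half of them drawn from
eating windows when available — the boundary that matters is against
near-miss manipulative gestures, not quiet background.

## Restriction layer

* **E1.** The meal probability by hour of day is
  `p_time(t) = min(1, Σ_k exp(−(t−μ_k)²/2σ²))` with unit-peak components
  at μ = 8.0, 12.5, 20.0 h and σ = 1.5 h; no midnight wrap-around. The
  smoothed evidence is `p_meal(i) = Σ_{n=0..N} p_class(i−n)·p_time(i−n)/N`
  with N = 3 — the formula is applied literally, N+1 terms over N; the
  first N windows sum whatever history exists. A window stays positive
  iff it is raw-positive (`p_class > 0.5`) **and** `p_meal > 0.5`
  (boundary 0.5 → negative). The conjunction makes E1 a true filter:
  because of the N+1/N normalization, the evidence threshold alone is
  *looser* than the raw threshold wherever `p_time ≈ 1` and would add
  positives near meal-probability peaks, violating the layer's
  monotonicity (it must never increase positive time).
* **Minute smoothing.** Window flags are rasterized onto the
  non-overlapping 10-s unit grid (each unit takes the flag of the window
  whose centre is nearest its own; earlier window on ties) and minutes
  are blocks of six units anchored at the stream start; a minute is
  eating iff strictly more than 3 of its 6 units are. With 25 % overlap
  the FW stride is 7.5 s, so "six consecutive windows" is not exactly a
  minute; the unit-grid rasterization keeps the minute rule exact for
  any overlap.
* **E2.** Runs of eating minutes shorter than 5 min are removed;
  survivors become meal intervals. Idempotent by construction.
* **E3** (disabled by default). Energy is the causal trailing mean of
  (|a|−g)² over 5 s; a meal is kept iff the maximum energy within 120 s
  before its start exceeds 3 × the stream's median energy. It is off in
  the default pipeline because meals are frequently not preceded by an
  energy burst (e.g. waiting seated at the table before the food
  arrives), which costs true meals; the default combination is
  E1 + E2 for eating and D1 for drinking.
* **D1.** A positive drinking window becomes a drink event iff it
  contains at least one local maximum of the gyroscope magnitude above
  60 deg/s (minimum peak separation 0.25 s). Defaults chosen so that
  genuine drink peaks (≳ 150 deg/s) pass with wide margin while typing,
  walking (≈ 35–40 deg/s) and nail-biting oscillations (≈ 45 deg/s)
  do not.
* **Fusion.** Per 10-s unit: drink if any surviving drink event overlaps
  it, else eat if inside a meal interval, else other (a sip during a
  meal scores as drink; its neighbours stay eat).

## Evaluation

Eating is scored on the 1-min grid (a true/predicted minute is eating
iff > 3 of its six 10-s units are), drinking and the 3-class overall
matrix on the 10-s grid, with minute labels broadcast to their six
units. Precision/recall/F1 are per class with supports from the truth
rows; weighted averages use supports; every 0/0 is defined as 0.
Drinking is additionally scored at event level: predictions are matched
one-to-one to ground-truth events greedily in time order, a match
requiring a gap of at most 10 s (0 for overlapping intervals); FP/h for
drinking counts unmatched predictions per hour, for eating
false-positive minutes per hour.

## Synthetic data: what it emulates, and what it does not

`generate_day` renders a 16-h day (6:00–22:00) at 100 Hz as
gravity baseline (slowly wandering tilt) + per-activity template +
white noise, with an exactly matching label track. Defaults are the
study conditions used throughout the tests:

* three meals — 8:00 (10 min), 12:30 (16.5 min), 20:00 (10 min) —
  totalling 36.5 min = 3.8 % of the day; bites are single broad
  flexion bumps (85 deg/s nominal, ×0.8–1.2) every ≈ 8 s;
* 34 drinks of 7 s (≈ 0.4 % of the day, roughly a third of them sips
  inside meals), each a two-peak pronation template (150 deg/s) with a
  tilted low-rotation hold between the peaks;
* an optional 10-s high-energy accelerometer burst 30–120 s before each
  meal (meal preparation), used by the E3 tests;
* a fixed background routine of desk work, walking and idle time with a
  90-min table-game block and 30 min of nail biting in the post-lunch
  afternoon — the two confusers reported as the dominant sources of
  false positives in free-living validation. Table-game gestures share
  the bite template at 0.55–0.85× amplitude with irregular timing;
  nail biting is a small fast wrist oscillation.

Training days are generated *without* the distractor activities. This
reproduces the deployment reality that validation surfaces activities
the training data never covered, and it is what yields the
characteristic raw eating branch: near-perfect sensitivity with a
false-positive plateau over the confuser block (≈ 5.5 FP min/h on the
default day), which the restriction layer then removes (to ≈ 0–0.1/h)
because leisure-time confusers fall outside the meal-probability gates.
The reduction is therefore a structural property of the day's routine,
the same mechanism reported for the real recordings.

What the generator does **not** emulate: biomechanical realism
(templates are parametric bumps, not recorded gestures), left-handed
wear, orientation drift beyond a slow sinusoidal tilt, sensor artifacts
(saturation, dropouts), or confusers that overlap meal times. Passing
the synthetic-recovery tests therefore shows the pipeline's machinery is
correct and its restriction logic effective under these conditions; it
does not certify performance on real wrist data.

## Numerical and design choices

* Intervals are half-open `[start, end)` seconds since midnight; sample
  *i* covers `[t0 + i/fs, t0 + (i+1)/fs)`; grid units are labeled by
  midpoint coverage with precedence drink > eat > other.
* Branch training labels are per-class interval membership of the
  window midpoint (not the precedence-rasterized grid): a sip during a
  meal is a drinking-branch positive *and* an eating-branch positive.
* DFW block phase is anchored at the stream start, aligning blocks with
  the eating branch's windows deterministically.
* DFW windows shorter than 2 samples are discarded before feature
  extraction (features need ≥ 2 samples); no other minimum is imposed.
* Correlation over a constant axis is 0; 0/0 metrics are 0; the
  `manipulation` denominator is guarded at 1e-6 m/s².
* Default problem sizes: the demo trains on one 16-h synthetic day and
  evaluates on another (≈ 7 700 eating windows and ≈ 7 000 drinking
  windows per day) — one day per side is sufficient for stable recovery
  under the default conditions.
* All randomness (generator, subsampling, SMOTE, forests) flows from
  the single `RunConfig.seed`.

## Known limitations

* The dynamic-threshold dispersion measure (std) and its scale are a
  reconstruction; other choices (range-based, MAD) may segment
  differently.
* E1's gate is wide wherever the classifier is confidently wrong inside
  meal hours; a confuser performed at lunchtime would pass E1 and, if
  longer than 5 min, E2 as well. Adapting Gaussian centres per user is
  out of scope.
* The 5-min meal rule delays any downstream reminder by construction.
* Drinking precision is the weakest figure (strong non-drink rotations
  that pass D1); enriching training with more confuser gestures is the
  natural next step.
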