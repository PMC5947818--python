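# Methods

This note documents the modelling assumptions, parameter choices and
numerical conventions behind `geomood`, and what the synthetic validation
cohort does and does not establish.

## Coordinate frame

All computation happens in a local planar frame in km east/north of a
reference point, using an equirectangular projection
(y = Δlat·111.195 km/°, x = Δlon·111.195·cos(ref_lat) km/°). The projection
is invertible and agrees with great-circle distance to well under 0.5 % for
offsets below 50 km away from the poles — the scale of personal mobility —
and keeps every distance threshold in the pipeline (100 km/h, 500 m, 400 m,
0.01 km) metrically meaningful. The reference defaults to the first fix of
each trace: traces are anonymized relative coordinates, so absolute
position is immaterial. Fixes sharing a timestamp are averaged; the format
does not define an order for them.

## Preprocessing

*Speed filter* (`v_max` = 100 km/h). A fix is flagged when the speed from
its previous or to its next fix exceeds `v_max`. Low-accuracy fixes arrive
as bursts repeating one exact coordinate far off the true path, so removal
is coordinate-wise: any exact coordinate carrying ≥ `burst_min_count` (3)
fixes of which at least one is flagged loses all its fixes. The
total-occurrence count matters because consecutive burst fixes have zero
inter-fix speed — only a burst's temporal edges are flagged. A second pass
removes remaining fixes whose every adjacent speed still exceeds `v_max`
(lone spikes); fixes fast on one side only are kept, because a true fix
next to a removed burst is exactly such a point. The filter is
deliberately not iterated to a fixed point: cascading removals could eat
genuine travel between distant fixes.

*Downsampling* (12 samples/hour). Hour epochs align to clock hours in the
configured timezone (default UTC), with grid points at :00, :05, …, :55 —
the phase is a convention, the source procedure does not pin one. An epoch
whose fixes have per-axis SD < 0.01 km on both axes is stationary and all
12 grid samples take the epoch mean; otherwise each grid point takes the
coordinate-wise median of raw fixes within ±2.5 min, and empty windows stay
missing.

*Imputation*. A missing run is filled with the mean of its flanking samples
iff the flanks lie within 0.5 km of each other and the run lasts ≤ 2 h (any
start time) or ≤ 12 h with its first missing slot at or after 21:00 local
clock time. The 9-pm clause is anchored to the run's *start*: a gap opening
late in the evening is overwhelmingly a phone charging overnight at home,
which is also why runs crossing midnight qualify by start time while a gap
opening at midday does not, however long it lasts.

## Places

Instantaneous speed is attributed to the interval between grid-adjacent
recorded samples; a window mean averages the interval speeds whose
midpoints fall in the window (centred ±5 min, backward 10 min, forward
10 min). The underlying definition integrates |dD/dτ| over the windows
without fixing a discretization; interval attribution is the natural one on
a regular grid. A sample transitions when any window mean exceeds
d = 1.5 km/h; samples with empty windows count as stationary.

Clustering grows K-means++ from K = 1 and accepts the largest K whose
fitted centres remain pairwise ≥ l = 0.4 km apart (stop at the first
violation; a single seeded K-means++ restart per K, configurable).
Clustering is fit per analysis window — the calendar week — so the weekly
cluster count NC is week-local. Home inference, in contrast, uses the full
trace: the modal overnight (02:00–07:00) coordinate per day, then the mode
over days, with coordinates binned at 0.01 km (the stationarity SD scale)
to make the mode of continuous data well defined. Ties break to the
earliest occurrence; both tie-breaks are deterministic.

## Features

Natural logarithms are used throughout (the entropy ratio NENT is
base-invariant, and every downstream model is scale-free in the feature).
Occupancy proportions p_i are computed over stationary samples only;
transit time is carried by the separate TT feature, so
HS + non-home-stationary share + TT = 100 % of recorded time. NENT is
clipped to [0, 1] to absorb last-bit rounding in ENT/ln N. Variance and
spectral-power arguments of logs are floored at 1e-10 to keep LV and the
diurnal features finite on degenerate (constant) inputs. The home cluster
for HS is the cluster centre nearest the origin, required within l; a week
spent wholly away from home scores HS = 0.

The diurnal features evaluate the unnormalized Lomb–Scargle periodogram at
25 frequencies evenly spaced in frequency across wavelengths 23.5–24.5 h,
on mean-centred signals (the estimator should not respond to DC offset) and
average the band power. DM uses the raw km coordinates and therefore grows
with the spatial scale of movement (ln-scale shift of ln 100 for a ×10
scaling); DMN standardizes each axis, making the feature scale-free but
direction-sensitive — the same commute due north and due north-east yield
band powers differing by a factor 2 after per-axis standardization; DMD
uses the standardized Euclidean distance from home and is exactly rotation
invariant. One identity worth recording: because the periodogram at fixed
sample times is a signal-independent quadratic form, the *raw* axis-power
sum in DM is itself invariant under rotation of the coordinate frame;
direction sensitivity of the axis-based features enters only through the
per-axis normalization of DMN.

Subsets: base (whole week), weekday (Mon–Fri), weekend, the element-wise
median over ten constituents (base, weekday, weekend, and the week with
each day removed in turn), and the daily-exclusion subset, which removes
days whose maximum distance from home d_i exceeds median(D) + α·SD(D)
(sample SD; no exclusion below two recorded days). The exclusion
multiplier α defaults to 1.0, the centre of the search grid
{0, 0.25, …, 3.0}; `optimize_alpha` selects α per feature by the stratified
CV accuracy of a single-feature logistic-regression classifier computed on
*training folds only* — optimizing on all data would leak test labels into
the feature definition — and `extract_feature_table(alpha_grid=...)`
precomputes the exclusion-subset features over the whole grid so that
fold-confined selection costs one column lookup per fold.

A week enters the feature table when at least 4 days have ≥ 50 % of their
5-min slots recorded (the sufficiency rule; the source procedure requires
"sufficient data" without quantifying it). Weeks missing any feature used
by a model are dropped from that model's data. Weeks run Monday 00:00 to
Sunday 24:00 local time (ISO convention).

## Labels

A week's QIDS score is the single response within ±3.5 d of the week if
exactly one exists; otherwise, with ≥ 2 responses within ±7 d, the linear
interpolant between responses is evaluated at the seven local-noon day
midpoints and averaged, holding the nearest response's value constant
beyond the first/last response (the source rule does not specify
extrapolation). Note that for weekly responders the ±3.5 d window usually
contains two responses, so interpolation is the common path and
single-response labeling the fallback. `depressed = score ≥ 11`, strictly.

## Models

The quadratic-logistic score model Q̂ = a/(1 + e^−(β₀+β₁·f+β₂·f²)) uses
a = 27, the QIDS ceiling, and is fitted by nonlinear least squares from
five deterministic starting points (zero vector, ±1 intercept, ±1 linear
coefficients), taking the lowest-cost solution — the bounded continuous
response makes least squares on the mean function the natural estimator,
and the multi-start makes the fit reproducible without a random seed. With
several features the model uses β₁·f + β₂·f² element-wise (a diagonal
quadratic form).

QDA fits one Gaussian per class with its own covariance; a small shrinkage
toward scaled identity (reg_param = 1e-3) keeps the fit defined when a
discrete feature (NC) is nearly constant within a class. Priors are equal,
matching the class-equalized training sets. F1 is the harmonic mean of
sensitivity and specificity (named `f1_sesp` to avoid confusion with
precision-recall F1); ROC curves come from a threshold sweep over the QDA
class-1 posterior and AUC from the trapezoid rule. Regression models are
compared to the constant-mean baseline by the standard F-test on residual
sums of squares.

## Validation protocol

Leave-one-participant-out and participant-wise k-fold (k ∈ {5, 10})
cross-validation never let a participant appear in training and test
simultaneously; k-fold partitions are regenerated ⌈N/k⌉ times and
stratified so each fold contains a participant with depressed weeks when
possible (unstratified partitions can produce folds with no positives).
The within-participant 3-fold scheme interleaves each participant's weeks
(1,4,7…/2,5,8…/3,6,9…) so all three folds cover the whole observation
span. Training sets are class-equalized by keeping all minority weeks and
subsampling the majority without replacement, redrawn M = 100 times; test
predictions of one redraw are pooled across folds before computing metrics,
and results are reported as median ± IQR (Q3 − Q1) over redraws. Folds with
single-class training data are skipped and counted. The greedy wrapper
evaluates every remaining feature joined to the selected set under full CV
(fresh seeded equalization per evaluation, for unbiasedness), with ties
breaking to canonical column order; selection runs are typically configured
with a smaller M than the final evaluation, since the argmax is far less
seed-sensitive than the metric estimate.

## Synthetic cohort

The generator emulates the structure the analysis assumes: per participant
a home at the origin and ~6 recurrent places 1.5–10 km away (mutually
≥ 1 km); weekly mood as a two-state Markov chain (depressed stationary
fraction 0.3, persistence 0.6) with integer QIDS scores drawn per state
(well ≈ N(5, 2) clipped to [0, 10]; depressed ≈ N(16, 2) clipped to
[11, 27]), so the flag ⇔ score ≥ 11 invariant holds exactly; days with
guaranteed home residence 00:00–07:00 and up to three block-scheduled
excursions with straight-line travel at 30 km/h; fixes every ~120 s
(SD 30 s, 2 m coordinate noise); artifact bursts of 5 identical fixes
displaced 10–15 km off-path at 10 s spacing, ~2/day, kept temporally
disjoint; gaps of 1–8 h deleting fixes at ~1/week; one QIDS response inside
every week. Behavioural effects are strong and clearly directional —
daytime home-stay probability 0.55 (well) vs 0.9 (depressed), places
visited per week 3–5 vs 1, departure jitter 0.5 h vs 1.5 h — with modest
participant-level random effects (SD 0.06 on home-stay, ±1 on place
habits). The base sampling interval is a desk-scale choice rather than the
~250 fixes/hour of real devices: the device rate is an artifact of
collection, not a parameter of the method. No quantitative effect sizes
exist to copy from real cohorts (published evidence is directional), so
these are the package's own choices, documented here precisely because the
headline classification numbers depend on them.

What passing tests show: the pipeline removes the injected artifact class
without touching true fixes, recovers homes, places, and behavioural
contrasts from noisy traces, and detects the simulated depressed weeks far
above chance under participant-wise validation, with permuted labels
falling to AUC ≈ 0.5. What they do not show: performance on real cohorts,
where effect sizes are smaller, mood–behaviour coupling is heterogeneous
and sometimes inverted, homes move, and data quality varies by device.
The synthetic F1 (~0.96) is an upper bound produced by construction, not a
clinical claim.

## Problem sizes and determinism

The validation cohort is 20 participants × 10 weeks (≈ 1 M raw fixes,
200 labeled weeks), processed end-to-end in about a minute; all stages are
deterministic given the configuration seed (per-week clustering seeds are
derived by hashing participant and week identifiers, equalization redraws
from one seeded generator in fixed loop order). Degenerate inputs are
handled explicitly: empty traces and weeks produce missing features rather
than errors; constant signals hit documented floors; ties break
deterministically everywhere.

## Known limitations

- One home per participant; moves and second homes are not modelled.
- Weekday/weekend subsets proxy working patterns; shift workers violate
  the proxy (the synthetic generator does not model them either).
- The stationarity and clustering thresholds (1.5 km/h, 0.4 km) are taken
  as given, not re-optimized.
- The quadratic-logistic fit is non-convex; the deterministic multi-start
  makes it reproducible but not provably global.
- Employment-status subgroup analysis is exposed only insofar as the
  evaluation accepts arbitrary week subsets; no subgroup machinery is
  built in.
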