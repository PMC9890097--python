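# Methods

## Signal model and feature set

A trace is a uniformly sampled tri-axial acceleration series in g (default
50 Hz, device range ±8 g). The classification unit is the non-overlapping
1-s epoch aligned to the trace start; a trailing partial window is dropped.
Per epoch the extractor emits exactly 25 predictors: per-axis mean, standard
error (sd/√n), sample standard deviation (ddof = 1), bias-adjusted skewness,
minimum and maximum (18), SMA, mean OBA, mean VBA, VBAmax, and the three
pairwise Pearson correlations. VBA is the Euclidean norm of the *raw*
sample, so the static 1 g of gravity is retained and a motionless device
reads 1 g regardless of orientation; VBAmax (the 1-s maximum) is the energy
proxy used in the diel aggregation. Two conventions keep static postures
well-defined: the skewness of a constant axis is 0, and a correlation
involving a zero-variance axis is 0. Note that SMA and mean OBA coincide
under these definitions (both are the epoch mean of |x|+|y|+|z|); both
columns are kept so that each named feature family is present explicitly.

The itemization above is one concrete realization of the seven feature
families (means, standard errors, SMA, OBA, VBA, skews, axis correlations)
summing to 25 columns; epoch-level VBA mean/max are classifier inputs, while
*bout-averaged* VBA is reserved for the energetics/speed analyses and never
enters the classifier.

`compute_features` evaluates everything vectorized across epochs;
`extract_features` is the simple per-epoch formulation. The two paths are
independent implementations and the test suite checks them against each
other and against a naive per-definition loop at 1e-10.

## Supervised SOM

The classifier is a 7×10 rectangular Kohonen map trained online: features
are z-scored with training-set statistics (zero-variance features dropped
with a warning), the codebook starts from seeded N(0, 0.5²) noise in
z-scored space, and at each of T steps a random training vector x moves
every node w by lr(t)·h(w, b, t)·(x − w), where b is the best-matching unit
(minimal Euclidean distance, ties to the lowest node index) and h is a
Gaussian neighbourhood over grid coordinates. Learning rate (0.5 → 0.01)
and radius (max(grid)/2 → 0.5) decay linearly; T defaults to 10·n clipped
to [2000, 30000]. Supervision is post hoc: nodes take the majority label of
the training epochs they win (ties break to the globally more frequent
class, then lexicographically) and empty nodes inherit the label of the
nearest labelled node in codebook space. This unsupervised-map +
majority-vote construction, with a rectangular grid and Gaussian
neighbourhood, is a deliberate simplification of joint two-layer supervised
SOM variants and of hexagonal topologies: it reproduces predict-by-BMU
behaviour with far fewer free choices, and all hyperparameters are exposed.
The quantization error (mean distance of training vectors to their BMU) is
recorded before and after training; training must not increase it.

Splits are stratified 80/20 by behaviour with a seed; a class with fewer
than 2 epochs cannot straddle the split and is rejected by name.

## Evaluation conventions

Per-behaviour metrics are one-vs-rest: sensitivity TP/(TP+FN), precision
TP/(TP+FP), specificity TN/(TN+FP), accuracy (TP+TN)/total, alongside a
global multiclass accuracy (trace/total). A 0/0 ratio is reported as an
explicit undefined marker (`None`/NaN in tables) rather than silently 0 —
small held-out sets routinely lack a class, and hiding that would overstate
performance.

## Energy classes

Low = Lying/Resting, Sitting, Vigilance, Standing Vigilance; high =
Bounding, Jumping, Turning, Galloping (bounding the most costly); medium is
the residual set (Walking, Vigilant Walking, Scurrying, Climbing). Only low
and high membership is anchored in the observed VBAmax ordering; the medium
set is an inference and the map is a plain configurable dict.

## Speed and distance

Calibration bouts relate bout-mean VBA to mean speed per gait on the
log₁₀–log₁₀ scale. The fit is ordinary least squares with gait-specific
intercept and slope (equivalent to the full gait × log VBA interaction,
fitted per gait); R² is reported over the pooled data and the residual
variance over the pooled residuals. Prediction is 10^(aₖ + bₖ·log₁₀ VBA);
galloping is aliased to the walking coefficients (walks share the
multi-beat pattern of gallops; bounds are 2-beat, so bound coefficients
would be the wrong template). Locomotor bouts are maximal runs of one gait
label at 1-s resolution — any label change breaks a bout, including between
two gaits. Vigilant Walking is excluded from the default locomotor set
(configurable). Distance is speed × duration per bout, summed per
individual and calendar day; a bout crossing midnight counts toward the day
it starts.

## Rest bouts and the density test

Lying/Resting ∪ Sitting form one stationary state; stationary bouts are
maximal runs of that state, with durations in minutes. The ≥10-min filter
separates pauses from sleep-relevant rest; a bout of exactly 10 min is kept
(the boundary convention is documented here because only "less than 10 min
removed" is specified by the filtering rule).

The two-sample density test statistic is T = ∫(f̂_A − f̂_B)² over a fixed
101-point grid spanning the pooled range ± 3 bandwidths, where both
Gaussian KDEs share one pooled-sample bandwidth from the normal reference
rule h = σ̂·(4/(3n))^{1/5}. Because bandwidth and grid depend only on the
pooled sample, they are permutation-invariant, and the null is built by
permuting group labels (the kernel matrix is computed once and each
permutation is a signed re-weighting). p = (1 + #{T* ≥ T})/(n_perm + 1),
so p is valid at finite n_perm and never 0. Degenerate pools (all values
identical) are rejected. Calibration: across six independent batches of
1,000 null replicates the rejection rate at α = 0.05 was 4.4–5.6%
(mean 5.2%).

## Synthetic-data generator

The generator defines the study conditions for all tests.

*Signal regimes.* Each behaviour has a unit gravity axis, a dynamic
amplitude (g), a stride frequency (Hz) and a white-noise sd. The rendered
signal is gravity + amplitude·sin(2πft+φ) along a deterministic
gravity-orthogonal axis + 0.3·amplitude·sin(4πft+2φ) along the gravity axis
+ noise, with an independent random phase per bout. Amplitudes rank the
behaviours so that per-epoch peak VBA orders postures < walking gaits <
turning/galloping < jumping < bounding, matching the observed energetic
ordering; the absolute amplitudes, frequencies and orientations are free
generator parameters chosen to keep the 12 classes well separated in
feature space — they are not field measurements, so classifier scores on
this data certify the pipeline, not field performance. Real signals differ
in ways the generator deliberately omits: no gait biomechanics or
inter-stride variability, no transitional/ambiguous epochs, no posture
drift within a behaviour, no sensor saturation or mounting shifts. Field
confusion between similar behaviours (e.g. the vigilance postures) will be
higher than the synthetic scores.

*Schedule.* A semi-Markov chain at 1-s resolution: sojourns are exponential
with per-behaviour means (resampled until ≥1 s, rounded to whole epochs).
The probability of entering Lying/Resting at a transition is solved from
the target resting *time* fraction via q·d_rest/(q·d_rest+(1−q)·d̄) = f;
hour-of-day weights then scale the entry odds of active (non-Lying/Sitting)
behaviours, redistributing activity across the day (nocturnal default: peak
at 19:00 declining to 01:00, quiet 07:00–18:00) without changing the
long-run rest fraction over whole diel cycles. Sex presets differ only in
resting parameters: rest fractions 7.67% (male) vs 23.65% (female) — the
reported Lying/Resting budget contrast — and mean rest dwells of 4.75 vs
7.64 min, chosen so that exponential bouts surviving the 10-min filter
average 14.75 vs 17.64 min, the reported long-bout means.

*Calibration.* Bout-mean VBAs are log-uniform per gait (walks 1.2–3.2 g,
bounds 4.5–8 g) and log₁₀ speed = aₖ + bₖ·log₁₀ VBA + N(0, σ) with σ = 0.05
by default. Default coefficients anchor typical walking bouts (~2 g) at
0.56 m/s and bounding bouts (~6.8 g) at 1.39 m/s — the measured mean gait
speeds — with slopes 1.1 (walk) and 0.9 (bound) as free parameters.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which each check is statistically decisive:
classifier validation on ~2,000 epochs (167 per class, 80/20 split);
speed-model recovery at 200 bouts/gait (3-SE check) and 30 replicates of
500 bouts/gait (bias < 2%); type-I calibration over 500 null replicates of
n = 100 + 100 with 99 permutations each; budget contrasts through the full
pipeline on 12-h per-sex deployments; long-rest-bout duration contrasts on
21-day schedules (at shorter durations the ≥10-min bout counts are too few
for the direction to be stable). Full-scale field data (weeks × 50 Hz)
streams through the same code unchanged.

## Known limitations

- Classified label streams fragment long rest bouts: a single misclassified
  epoch splits a bout, so bout statistics on predicted labels are biased
  short relative to truth — exactly as for any epoch-wise classifier
  without temporal smoothing (an HMM smoother is out of scope). The
  long-bout duration analyses therefore run on schedule labels, with the
  classifier validated separately.
- The SOM has no rejection option: every epoch gets one of the 12 labels.
- Per-gait OLS assumes log-normal residuals and independence across bouts;
  no mixed effects (individual as a random effect is out of scope).
- Hour-of-day handling assumes a fixed clock offset; no daylight-saving or
  timezone database logic.
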