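# Methods

`gazevalence` classifies the affective valence of an image — unpleasant,
neutral, or pleasant — from the eye movements of people who viewed it.
This note records the models, conventions and numerical choices the
package commits to, and what its synthetic-data validation does and does
not establish.

## Data model and conventions

A *fixation* is a quadruple (x, y, t_start, t_end): a gaze dwell of at
least 100 ms at a pixel location. Coordinates are 0-based pixels with the
origin at the top-left corner and y increasing downward; times are in
milliseconds. A *saccade* is derived from two consecutive fixations of
one observer: it runs from the first fixation's location to the second's
and, by the package's timing convention, occupies the inter-fixation gap
(t_end of the first to t_start of the second). Zero-duration gaps are
legal; the events they would make undefined (velocity) are excluded from
the affected histogram only, never from the scanpath.

Images are labelled from their mean 1–9 SAM valence rating: the closed
band [3.8, 5.8] is neutral, below is unpleasant, above is pleasant. Both
band edges are assigned to neutral; the inclusive choice is a package
convention (`NEUTRAL_VALENCE_LOW/HIGH` in `gaze_data`).

## Feature representations

All features are computed per image with events pooled across that
image's observers (pooling is order-invariant). Ten blocks concatenate,
in fixed order, to an 872-dimensional vector:

| block | dims | content |
|---|---|---|
| saliency_map | 300 | 15×20 down-sampled fixation-density map |
| top10_salient | 20 | ten strongest density peaks, normalized (x, y) |
| fixation_histogram | 256 | fixation counts on a 16×16 spatial grid |
| saliency_histogram | 10 | density values sampled at the fixations |
| fixation_duration_hist | 60 | fixation durations |
| saccade_duration_hist | 60 | inter-fixation gap durations |
| saccade_slope_hist | 30 | undirected line angles, 6° bins |
| saccade_length_hist | 50 | Euclidean amplitudes |
| saccade_velocity_hist | 50 | amplitude / gap duration |
| saccade_orientation_hist | 36 | angle between successive saccades, 5° bins |

**Histograms.** Equal-width bins with centers at the midpoints of the
bin intervals; values are assigned to the nearest center, with
out-of-range values clipped into the end bins, then normalized to
probability mass (raw counts via `counts=True`; an empty input maps to
the all-zero vector). Bin ranges are *dataset-global constants* rather
than per-image extrema: per-image ranges would erase the absolute-scale
differences (e.g. longer fixations on unpleasant images) that the
mean-value analysis shows are class-informative. Shipped defaults:
fixation duration 100–2000 ms, saccade duration 0–1000 ms (gap durations
routinely sit below the 100 ms fixation floor, hence the lower range),
length 0–1280 px (the image diagonal's order), velocity 0–10 px/ms,
slope 0–180°, orientation 0–180°. All are overridable via
`BinningScheme`.

**Saccade orientation range.** The inter-saccade angle is computed as
the arccosine of the cosine similarity of the two displacement vectors,
which lies in [0°, 180°]; the 36 bins therefore quantize at 5°. A 360°
convention (10° bins) is selectable by passing a scheme with
`range_high=360`, but is not the default because the arccos formula
cannot produce angles beyond 180°.

**Density (saliency) map.** Fixation counts accumulated at integer pixel
locations, smoothed with an isotropic Gaussian of σ = 10 px (≈2° visual
angle at the source data's viewing geometry), truncated at 4σ with
zero-padded borders, and rescaled so the maximum is 1. The 15×20 coarse
map is an exact area-weighted block average (fractional pixel rows and
columns are split proportionally) followed by a min–max rescale to
[0, 1]; a constant map maps to all zeros by convention. Fixations are
unweighted by duration.

**Top-ten salient locations.** Inhibition of return: repeatedly take the
global maximum of a working copy of the map (ties broken toward the
smallest row-major index, so a constant map yields the origin first),
record (x/width, y/height), and zero a disk of radius 2σ around the
peak. Coordinates are resolution-normalized so the block is comparable
across image sizes.

**Mean-value features.** The six traditional statistics — mean fixation
duration, saccade duration, saccade length, slope, velocity, orientation
per image — min–max normalized to [0, 1] across the dataset's images. A
property constant across images maps to 0; a single-image dataset is an
error. `MeanValueFeaturizer` freezes the min/max on a fit set and clips
held-out images into [0, 1].

## Classification protocol

10 repetitions of a 10-fold scheme with train/validation/test
proportions 0.9/0.05/0.05. Validation and test sets are drawn with an
equal number of images per class — `max(1, round(ratio × min class
count))` each, i.e. one image per class per split at the default
24/47/24 scale — and the remaining images train. Features are
standardized on each fold's training rows. One-vs-rest SVMs (linear,
polynomial, RBF) are fitted over a small hyperparameter grid (C ∈
{0.1, 1, 10}; degree ∈ {2, 3} for polynomial; γ = "scale"); the grid
point with the best validation Bookmaker score is evaluated on the test
set. The grid is a package choice; the protocol fixes only that the
validation split selects hyperparameters.

**Bookmaker informedness.** For class c in the one-vs-rest
decomposition, informedness is recall + inverse recall − 1 (Youden's J);
the multiclass score is the prevalence-weighted average over classes
(weights = row sums / total; an unweighted macro-average is available
via `weighted=False`). It is +1 for an error-free confusion matrix,
exactly 0 whenever the rows are mutually proportional (predictions
independent of the truth), −1 for a fully perverse binary matrix, and is
invariant to scaling all counts. A class with no test items contributes
zero with zero weight. Standard errors reported by `aggregate` are
sample SD over √k across all repeat×fold results.

## Feature reduction and selection

*Decomposition*: PCA (centered) or SVD (uncentered) fitted on training
rows only, keeping the minimal number of leading components whose
cumulative explained variance reaches the threshold (default 0.9); a
matrix without variance is an error. *Wrapper search* over binary masks
— at dimension granularity (872 bits, the full-study setting) or block
granularity (10 bits, the fast setting) — maximizes the validation
Bookmaker score of a downstream SVM:

- **SFS/SBS** — greedy add from empty / remove from full, stopping when
  no single change strictly improves the objective; ties break toward
  the lowest index; backward never empties the mask.
- **GA** — binary genetic algorithm: population 30, 100 generations,
  tournament selection (size 3), one-point crossover at rate 0.8,
  per-bit mutation 0.02, elitism of 1 (so the best-fitness trajectory is
  non-decreasing). All-zero offspring are repaired by activating one
  random bit.
- **PSO** — mutated binary particle swarm: swarm 30, 100 iterations,
  inertia 0.72, cognitive = social = 1.49, velocities clamped to ±6,
  bit-flip transfer probability |tanh(v)| (a V-shaped transfer, chosen
  so that zero velocity is a fixed point of the update — a sigmoid
  transfer randomizes bits at v = 0), plus a 0.05 bit-mutation rate.

These evolutionary settings are package defaults, config-overridable;
they are conventional values, not tuned to any dataset. By default the
wrapper objective scores each candidate on one fixed train/validation
split to bound cost; `n_objective_folds` averages over several folds for
a finer (slower) objective. The *contribution analysis* averages, over
the masks of many runs, the fraction of each block's dimensions
selected, and ranks blocks by that fraction.

## Synthetic data generator

Viewing is simulated as a correlated random walk attracted to 2–4
per-image attractor points scattered around the image center. Per
observer: fixation locations are Gaussian around the current attractor
with class-scaled spread; durations are log-normal (median ≈ 280 ms at
neutral) floored at 100 ms; steps either jump to a new attractor (p =
0.3) or continue the walk with a wrapped-normal turning angle and
log-normal step length; gap durations are distance over a log-normal
velocity (median 0.7 px/ms); the scanpath truncates at the 5-s window.
Class effects at full magnitude: spread ×0.6 / ×1.4 for unpleasant /
pleasant (attentional narrowing under negative affect), duration
log-shift ±0.25 (longer for unpleasant), step length ×1.3 / ×0.75, and
turning-angle dispersion ×1.55 / ×0.65 (larger angular changes for
unpleasant). `effect_magnitude` interpolates every knob to the neutral
value; 0 is the null mode, in which all classes share one generative
process by construction. Each image's mean valence rating is drawn
uniformly inside its class's band so the labelling pathway stays
consistent. Defaults mirror the study scale: 24/47/24 images, 25
observers, 1024×768 px, 5-s window.

Two couplings are physically unavoidable in this mechanism and matter
for interpreting planted-signal experiments: spatial spread propagates
into saccade lengths (within-attractor distances scale with spread) and
into gap durations (gap = distance / velocity). A spread-only planting
therefore carries signal in the four fixation-location blocks *and* in
the saccade-length/duration histograms, while slope, orientation,
velocity and fixation-duration blocks remain null — which is what the
planted-signal recovery test asserts.

What passing these tests shows: the pipeline detects and ranks
class-conditional structure of the kinds the generator plants, at the
study's sample sizes, and reports chance on label-permuted data. What it
does not show: performance on real affective-image gaze, which has
image-content-driven fixation patterns, observer idiosyncrasies, arousal
as a second affective dimension, and measurement noise that the
generator does not model.

## Numerical and degenerate-input conventions

- Fixation-duration validation allows 1 µs slack (durations are often
  reconstructed through float time sums).
- Empty event lists yield all-zero histogram vectors; an image with no
  fixations at all is an error.
- Chance-level calibration averages the CV score over several label
  permutations of the same features: a single 95-image dataset carries
  accidental class–feature correlations of order ±0.1 Bookmaker, so a
  single permutation is an unreliable chance estimate.
- Scale choices in the test suite (e.g. 3 CV repeats inside the
  monotonicity sweep, block-granularity wrapper runs, 8 selection runs
  in the contribution check) are the package's demo profile; the full
  protocol (10×10 CV, dimension-granularity masks) is configuration.

## Known limitations

- The "conservative sampling" balance rule is interpreted as an equal
  per-class draw for validation/test; its original literature source is
  not fully specified in the text this design follows.
- SBS at dimension granularity over 872 features costs O(d²) SVM fits
  per run and is practical only with the memoized single-fold objective.
- The generator's attractors stand in for image content; there is no
  actual image, so bottom-up (visual) salience is out of scope.
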