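# gazevalence

Recognize the affective **valence** of an image — *unpleasant*, *neutral*
or *pleasant* — from the eye movements of the people who viewed it.

When observers free-view affective pictures, their gaze changes in
measurable ways: negative content compacts the spatial spread of
fixations (attentional narrowing), lengthens fixation durations, and
alters saccade amplitudes and angular behavior. `gazevalence` turns a
table of fixations (image id, observer id, x, y, t_start, t_end) into
per-image feature vectors, classifies the three valence categories with
one-vs-rest SVMs under a repeated class-balanced cross-validation
protocol, and quantifies which gaze features carry the signal. It is
aimed at researchers in affective computing, multimedia analysis, and
eye-movement behavioral studies.

## The method in brief

**Features.** Ten per-image representations pooled over observers,
concatenating to an 872-dimensional vector
(300 + 20 + 256 + 10 + 60 + 60 + 30 + 50 + 50 + 36): a 15×20
down-sampled fixation-density ("saliency") map, obtained by smoothing
the pooled fixation map with a Gaussian of σ = 10 px and normalizing to
[0, 1]; the ten strongest density peaks extracted with inhibition of
return; a 16×16-grid fixation histogram (64×48 px cells on a 1024×768
image); a 10-bin histogram of density values at the fixations; and
equal-width histograms of fixation duration FD = t_end − t_start (60
bins), saccade duration (60), saccade slope — the undirected angle of
the line joining consecutive fixations, 6° bins over [0°, 180°) —
saccade length ‖S‖ (50), saccade velocity ‖S‖/(t_end − t_start) (50),
and inter-saccade orientation cos⁻¹(Sᵢ·Sᵢ₋₁ / ‖Sᵢ‖‖Sᵢ₋₁‖) (36). Six
traditional mean-value features (per-image means, min–max normalized
across images) serve as the behavioral-science baseline.

**Evaluation.** 10 × 10-fold cross-validation with 0.9/0.05/0.05
train/validation/test splits, equal images per class in validation and
test. Performance is scored by multiclass **Bookmaker informedness** —
the prevalence-weighted average over classes of recall + inverse
recall − 1 — which is +1 for perfect prediction, 0 at chance regardless
of class imbalance, and −1 for perverse prediction. Accuracy (%) is
reported alongside.

**Feature fusion.** PCA/SVD keeping the minimal components explaining
90% of variance, sequential forward/backward selection, a binary
genetic algorithm and a mutated binary particle swarm, all maximizing
validation Bookmaker score; a contribution analysis ranks the ten
blocks by the fraction of their dimensions the wrappers keep.

**Synthetic data.** Real affective-gaze corpora (IAPS imagery with
NUSEF fixations) are not redistributable, so the package ships a
generator that emulates the class-conditional structure — spread,
duration, saccade-length and turning-angle effects with a continuous
effect-magnitude dial and a zero-effect null mode — at the study scale
(24/47/24 images, ~25 observers, 5-s viewing). See `docs/methods.md`.

## Worked example

```sh
gazevalence generate --seed 7 --out demo/fixations.csv --n-observers 10
gazevalence baseline --fixations demo/fixations.csv \
    --labels demo/fixations_labels.csv \
    --kernels linear --n-repeats 2 --out demo/results --seed 7
```

The first command simulates 95 labelled images (950 scanpaths). The
second extracts all features and prints one row per feature × kernel:

```
                 feature kernel  mean_bookmaker  se_bookmaker  mean_accuracy_pct  se_accuracy_pct  n_folds
            saliency_map linear           0.425         0.083             61.667            5.554       20
           top10_salient linear           0.000         0.063             33.333            4.189       20
      fixation_histogram linear           0.525         0.099             68.333            6.612       20
      saliency_histogram linear           0.275         0.092             51.667            6.153       20
  fixation_duration_hist linear           0.925         0.041             95.000            2.731       20
   saccade_duration_hist linear           0.700         0.076             80.000            5.073       20
      saccade_slope_hist linear           0.050         0.080             36.667            5.353       20
     saccade_length_hist linear           0.775         0.057             85.000            3.804       20
   saccade_velocity_hist linear           0.050         0.050             36.667            3.333       20
saccade_orientation_hist linear           0.325         0.091             55.000            6.058       20
                full_set linear           0.925         0.041             95.000            2.731       20
  mean_fixation_duration linear           0.900         0.046             93.333            3.059       20
   ...
```

Reading the output: `mean_bookmaker` is the chance-corrected score
(0 = chance, 1 = perfect) averaged over the 20 repeat × fold test sets,
with its standard error; accuracy is in percent (chance ≈ 33% for three
balanced test items). On this synthetic draw the duration histogram and
the full 872-dim set classify almost perfectly, while saccade slope and
velocity carry little signal — the generator's duration effect is
strong and its angular effect subtle at 10 observers. The fusion
experiment (`gazevalence fusion ...`) adds the reduction/selection
comparison and the per-block contribution ranking.

The same machinery is available as a library:

```python
from gazevalence import SyntheticConfig, generate, feature_matrix
from gazevalence import make_cv_plan, train_eval, aggregate
import numpy as np

rs = generate(SyntheticConfig(seed=7, n_observers=10))
X, y = feature_matrix(rs).to_numpy(), np.array(rs.labels())
plan = make_cv_plan(y, seed=7)
print(aggregate(train_eval(X, y, plan, kernel="linear"))["mean_bookmaker"])
```

## Layout

- `src/gazevalence/gaze_data.py` — fixation/saccade/scanpath model, CSV I/O, valence labelling
- `src/gazevalence/features.py` — the ten feature blocks and mean-value features
- `src/gazevalence/evaluation.py` — CV protocol, SVMs, Bookmaker informedness
- `src/gazevalence/selection.py` — PCA/SVD, SFS/SBS, GA, PSO, contribution analysis
- `src/gazevalence/synthetic.py` — class-conditional gaze generator
- `src/gazevalence/pipeline.py`, `cli.py` — experiment drivers and the `gazevalence` command
- `src/gazevalence/curated.py` — the curated 95-image IAPS id set (47/24/24)
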