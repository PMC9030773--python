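# gazebiom

Implicit, stimulus-independent eye-movement biometrics for wearable
eye-tracking recordings of pedestrians navigating real-world routes.

Most eye-movement biometrics work in the lab: a seated subject, a fixed
screen, a controlled stimulus. This package targets the harder setting —
a walking person wearing eye-tracking glasses, where the visual stimulus
is the street itself and is never the same twice — and asks whether the
oculomotor *style* of a person (how long they fixate, how far and fast
they saccade, where on the scene they look, what they look at) is enough
to identify or verify them. It is aimed at researchers in behavioral
biometrics and gaze analysis who want a complete, reproducible reference
pipeline plus a synthetic test bed.

## What it implements

* **Data model and I/O** — recordings as fixation/saccade/blink event
  streams (CSV) with optional raw 60 Hz samples on a 1280 × 960 scene
  frame; tracking-ratio quality filter (recordings below 70% excluded).
* **Event detection** — a dispersion-threshold (I-DT) classifier for users
  with raw samples only (50 px bounding-box dispersion, 80 ms minimum
  fixation, 70 ms blink gap).
* **Segmentation** — non-overlapping windows of length `T_win`
  (5–100 s grid); the segment is the classification sample.
* **Five feature sets per segment** — basic statistics (93 = 11 metrics
  × 8 statistics + 5 scalars), pupillary response (8), a Gaussian
  fixation-density map downsampled to 20 × 20 = 400 values, fixation
  semantics over 20 scene classes (40 = FC/FD per class, pixel-crowding
  adjusted), and Bulling-style saccade n-gram encoding (40 wordbook
  features, fold-fitted). Combined: 581 columns.
* **Recognition** — a 500-tree random forest (sqrt features per split)
  for multiclass identification under stratified 10-fold and
  leave-one-route-out (LORO) cross-validation, and per-subject binary
  verification with balanced impostor sampling and a 7:3 split.
* **Evaluation** — accuracy, Rank-k identification rate, CMC curve, ROC
  and interpolated EER (FPR = FNR), chance level 1/n.
* **Synthetic cohort generator** — per-subject oculomotor/attentional
  trait profiles (lognormal fixation durations, gamma amplitudes,
  von Mises direction bias, main-sequence velocity law, spatial and
  semantic preferences) with a single `heterogeneity` knob; at 0 the
  cohort is exchangeable and recognition must sit at chance.

## Worked example

```bash
gazebiom identify --cv loro --subjects 10 --routes 4 --twin 50 --seed 7
```

or, through the library (as in `analysis/03_identification.py`):

```python
from gazebiom.synthetic import simulate_cohort
from gazebiom.feature_table import cohort_features
from gazebiom.recognition import ClassifierConfig, identify_loro
from gazebiom.evaluation import summarize

cohort = simulate_cohort(10, 4, heterogeneity=1.0, seed=7)
feats = cohort_features(cohort, t_win=50.0)
run = identify_loro(feats, config=ClassifierConfig(n_estimators=500, seed=7),
                    feature_set="combined")
print(summarize(run))
```

On this 10-subject cohort (319 segments at T_win = 50 s, chance level
10%), the per-feature-set accuracies printed by the analysis drivers are:

```
    basic / kfold: accuracy  99.1%, EER   0.3%
    basic / loro : accuracy  97.8%, EER   0.8%
  density / kfold: accuracy  54.2%, EER  18.1%
  saccade / kfold: accuracy  73.0%, EER   8.8%
 combined / kfold: accuracy 100.0%, EER   0.0%
 combined / loro : accuracy 100.0%, EER   0.0%
```

Reading: each row is one classification run; "accuracy" is the fraction
of held-out segments whose top-ranked candidate is the true subject, and
EER is the equal-error operating point of the micro-averaged ROC. LORO
rows train on three routes and test on the held-out fourth, so they
measure stimulus-independent recognition. Synthetic subjects are far more
separable than real ones — the generator encodes identity directly into
the trait parameters — so these numbers characterize the pipeline, not
real-world difficulty.

The numbered scripts under `analysis/` run the full narrative (cohort
simulation and summary, feature extraction, identification, verification,
window-size sweep) and write their tables under `results/`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole chain from scratch on a freshly simulated cohort —
simulation, quality filter, segmentation, all five feature sets, 10-fold
and LORO identification and per-subject verification with the 500-tree
forest — and prints the resulting accuracies and EERs. The specification
this package follows defines no numeric acceptance targets (the reference
figures were measured on private recordings), so the JSON it writes is an
empty object.

## Layout

```
src/gazebiom/        library: data_model, synthetic, events, segmentation,
                     features/ (statistical, density, semantic,
                     saccade_encoding), feature_table, recognition,
                     evaluation, pipeline, cli
analysis/            numbered narrative drivers (01_simulate_cohort ...)
tests/               pytest suite incl. acceptance criteria
docs/methods.md      model, parameters, numerical choices, limitations
```
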