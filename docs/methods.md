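# Methods

## Model

trimorf treats MoRF prediction as per-residue binary classification
over intrinsically disordered protein sequences. The design rests on
one structural observation: residues within `flank` (= 20) positions
of a terminus lack full neighbouring context, so their scoring windows
are truncated and their feature distribution differs from interior
residues. The sequence is therefore trisected — left terminal zone
(positions 1..20), middle zone (21..n−20), right terminal zone
(n−19..n) — and two classifiers are trained: a *terminal* model on
segments whose MoRF run touches a terminal zone and a *middle* model
on runs inside the middle zone. Sequences of length ≤ 40 have no
middle zone and are scored entirely by the terminal model.

### Training segments

For each maximal MoRF run, the positive segment is the run plus 20
residues upstream and downstream, clipped at the sequence bounds. A
run whose residues fall in both zones contributes its segment to both
models' training pools: the per-residue zone conditions do not resolve
straddling runs, and duplicating keeps the boundary signal instead of
discarding it. Each positive segment is paired with one negative
segment of identical length and zone, placed uniformly at random (with
an explicit seed) among start positions that (a) contain no MoRF
residue and (b) share no residue with any run's *flanked* extent — the
stricter disjointness prevents negative windows from overlapping
positive windows and leaking labels. When no placement satisfies both,
the positive is kept alone and a warning is logged; on realistic
sequence lengths this affects a few percent of segments. Class balance
is thus achieved at extraction time (1:1), not through class weights.

### Features

A segment or query window of length *l* over the selected channels
forms an *l* × *u* structural matrix *M*; its feature vector stacks the
lagged second moments AC(k, j) = (1/l) Σ_{i≤l−k} M(i,j) M(i+k,j) for
lags k = 1..DF (DF = 10), flattened channel-major. Three deliberate
choices:

* **No mean-centering.** The statistic is a raw second moment, not the
  mean-centered quantity usually called auto-covariance; the formula
  is implemented exactly as stated and the classifier consumes its
  scale information (a mean shift in the channel raises every lag).
* **Empty-sum convention.** For k ≥ l the sum is empty and the lag is
  0, keeping the vector length fixed at DF·u for arbitrarily short
  segments.
* **Default channel `HSEa_up`** (upper α half-sphere exposure, u = 1).
  A forward channel search on the original benchmarks leaves HSE as
  the best group and its α-up attribute as the single best channel;
  "HSEu" is mapped to HSEa_up here, an assumption the configuration
  makes explicit and overridable (any channel subset can be selected).
  Both models currently share this featurization; the feature
  configuration is pluggable should a different middle-zone extractor
  be wanted.

### Classifier and score normalisation

Each zone model is an RBF-kernel SVM with C = 1000 and γ = 0.0038,
values carried over from earlier MoRF work on closely related features
and deliberately not re-tuned. Features are z-scored per dimension
(scaler fitted on each model's own training features and stored in the
bundle); a fixed γ only makes sense on a controlled feature scale.
Decision values — not Platt probabilities; only ranking metrics are
reported — are mapped to [0, 1] by min–max normalisation against the
bounds observed on that model's training samples, clipping outside.
Normalisation makes the two models' tracks commensurable and the
ensemble average meaningful.

### Query scoring and post-processing

Each residue j gets the window max(1, j−20)..min(n, j+20) (≤ 41
residues, truncated at termini), featurized through the identical code
path as training segments, scored by its zone's model. Raw tracks are
then smoothed: each residue's final score is
(max(window) + median(window)) / 2 over the score window j−w..j+w
(truncated; even-length medians average the two central order
statistics). The phrase "maximum plus median divided by two" is
resolved as **(max + median)/2**, not max + median/2: the former is
positively homogeneous and keeps scores on the input scale, which both
the [0, 1] normalisation and track averaging rely on; the latter can
exceed 1. This is the single most consequential interpretation in the
package. Default window flanks: 12 for the model's own track, 4 and 15
for MoRFpred-plus- and MoRFchibi-style external tracks, 8 for the
re-smoothing of the combined track; external tracks with no known
sweep value (e.g. PROMIS-style) are averaged unprocessed.

### Ensembling

`combine_tracks` is the plain arithmetic mean of aligned tracks;
`run_combined_pipeline` composes: own raw track → smooth (flank 12);
each external track → smooth with its flank (or pass through); average;
re-smooth the average (flank 8, switchable off).

### Evaluation

Scores and labels are pooled across all residues of all sequences into
one global ROC curve; AUC is the trapezoidal area, identical to the
Mann–Whitney statistic with half credit for ties (the standard
estimator; verified against an independent rank-based computation in
the tests). `fpr_at_tpr` returns the smallest FPR among actual curve
points with TPR ≥ target — conservative and interpolation-free, so the
reported operating point exists. With heavily tied scores the curve
may contain no point near the target TPR and the answer jumps to the
next achievable corner; that is a property of the convention, not a
bug.

## Synthetic benchmark generator

The generator emulates the MoRF benchmark regime rather than protein
physics: per sequence, a random length in 60–600, a uniform-random
amino-acid string, and exactly one MoRF of length 5–25. With
probability `terminal_placement_prob` (default 0.3, roughly the
terminal share seen in the real benchmark composition) the MoRF is
placed to touch a terminal zone, otherwise fully inside the middle
zone. All 13 structural channels carry label-independent plausible
noise (normalised positive triples for the SS probabilities, bounded
noise for ASA/angles/HSE/contact numbers); only the signal channel
(default `HSEa_up`) differs by label: Gaussian background
(mean 13, sd 3 — realistic half-sphere count scale) smoothed by a
moving average of half-width 2 to mimic the residue-level
autocorrelation of real structural predictors, plus a mean shift of
`effect_size × background_sd` (default 2.0) on MoRF residues. The
shift is added **after** smoothing so the realised between-class mean
difference equals the nominal effect exactly in expectation; smoothing
the shift itself would dilute run edges and make the nominal effect
unattainable.

What passing tests on this generator do and do not show: they validate
the machinery — segment routing, featurization, dispatch, smoothing,
evaluation — and that the pipeline recovers a localized mean-shift
signal in a single channel. They do not show performance on real
disordered proteins, whose signal is weaker, spread across correlated
channels, and entangled with composition biases the generator omits.

Two calibration facts the test suite and acceptance script compute:
with the default effect size, held-out pooled AUC (200 training / 100
held-out sequences) is well above 0.85; with the effect switched off
it is chance level. Note that smoothing and windowing correlate scores
within a sequence, so the effective sample size of a pooled AUC is
closer to the number of MoRFs than the number of residues — chance-
level AUC therefore fluctuates by several hundredths from seed to
seed, which is why calibration checks fix their seeds.

## Numerical and design choices

* Coordinates are 1-based inclusive in every file and error message;
  0-based only inside array code.
* Feature flattening is channel-major (all lags of channel 1 first);
  fixed and documented so stored bundles remain valid.
* Bundle serialisation uses a versioned joblib archive containing the
  two estimators, scalers, normalisation bounds and a manifest (seed,
  per-model sample counts, SHA-256 fingerprint of the training data) —
  two runs with the same data and seed produce identical manifests and
  scores.
* Degenerate decision-value bounds (all training decision values
  equal) are widened by 1e-9 to keep normalisation defined.
* The single-model ablation (`train_bundle(..., pooled=True)`) fits
  one SVM on all segments and installs it for both zones, so the
  two-model comparison differs only in model routing.
* Problem sizes in the tests and acceptance script (tens to hundreds
  of simulated sequences) are chosen as the smallest sets on which the
  pooled-AUC properties are stable across seeds.

## Known limitations

* The SPIDER2 dialect is best-effort: the exact set and order of
  output files concatenated upstream is not standardised, so the
  column map must be checked against the files at hand.
* The middle model reuses the terminal model's featurization; an
  alternative middle-zone feature extractor can be plugged in but none
  is shipped.
* No hyperparameter search (C, γ, DF, flanks are fixed defaults) and
  no learned fusion weights — averaging only.
* External predictors are never re-implemented or executed; their
  tracks are opaque inputs.
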