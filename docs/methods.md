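# Methods

## The decoding procedure

Let x ∈ ℝ^S be a population response vector over S sites and c ∈ {1…C}
the condition of the trial it came from.  The pipeline estimates how well
c can be predicted from x, as a function of time, via resampled k-fold
cross-validation:

1. **Splits.**  For each usable site and each class, k·m trials are drawn
   without replacement (m = examples per class per split, default 1) and
   dealt into k splits.  The i-th pseudo-population vector of class c in a
   split concatenates, across sites, each site's i-th sampled class-c
   trial; sites are matched only by class and within-split sample index,
   never by trial order or time-in-session, since separately recorded
   sites carry no common trial identity.  With `simultaneous=True` one
   draw of trial indices is shared by all sites (validated to have
   identical trial counts and label sequences), preserving trial identity.
2. **Preprocessing.**  Each preprocessor fits on the fold's training
   matrix only and transforms both matrices; preprocessors chain in list
   order.  Z-scoring uses the sample (n−1) standard deviation; a constant
   training feature maps to all zeros (not NaN, not dropped) so that the
   feature↔site alignment is identical in every fold.
3. **Classification.**  The template classifier stores the per-class mean
   of the training rows.  `max_correlation` scores a test row by Pearson
   correlation with each template — the centred variant; the name admits
   an uncentred reading, and the centred form was chosen because it makes
   the decision invariant to additive offsets in overall excitability.  A
   zero-variance row or template scores 0 (a constant vector carries no
   pattern, and the convention avoids NaN propagation).  `min_euclidean`
   scores by negative Euclidean distance.  Argmax decides; exact ties go
   to the lowest class index for reproducibility (ties have measure zero
   for continuous data).
4. **Temporal cross-training.**  The classifier trained at bin t_i is
   tested at every bin t_j (all pairs when the TCT matrix is requested,
   t_i = t_j only otherwise).  A diagonal-dominant TCT matrix means the
   code is dynamic: the patterns carrying the information change with
   latency.
5. **Resampling.**  The whole procedure repeats over n_resamples runs
   (default 50; the tests and the acceptance script use 5–10, which is
   enough for the high-contrast synthetic conditions), each with a fresh
   seeded trial draw.  Accuracy is averaged over folds within a run; runs
   are kept separate so the spread across resamples stays available.

**Generalization analysis.**  A class mapping assigns each class a train
label set and a test label set (e.g. train on `car_upper`, test on
`car_lower`).  When a class's two sets are equal the sampler reduces
exactly — draw for draw — to the basic datasource; when they differ, test
trials are drawn first and training trials from the train pool minus those
test trials, so cross-validation discipline survives partial overlap.

**Seeding contract.**  Resample run r draws from
`numpy.random.default_rng([master_seed, r])`; the optional label shuffle
uses a fixed distinct stream tag.  The pipeline is a pure function of
(data, configuration, master seed), verified down to byte-identical result
files.

## Measures

* **Zero-one accuracy**: fraction of correct predictions; chance 1/C.
* **Normalized rank**: the true class's decision value is ranked among the
  C values (1 = largest, ties averaged) and mapped to 1 − (r−1)/(C−1), so
  chance is 0.5 and perfect 1.  The measure is defined here this way
  because only its name is conventional; the scaling was chosen for those
  two anchor points.
* **Mutual information**: plug-in estimator on the (true, predicted)
  confusion table in bits, with 0·log 0 ≡ 0 and no bias correction.
  Confusion counts are pooled over folds within a run before the MI is
  taken (pooling was chosen over per-fold averaging because per-fold
  tables are too sparse at m = 1).  MI is computed on the matched
  train/test diagonal only by default; the full T² matrix is storage-heavy
  and rarely informative.

### Null calibration

Three conventions matter when checking chance-level behaviour:

* **Per-run counts.**  Resample runs redraw from the same finite trial
  pool, so they are not independent replicates; binomial null intervals
  for accuracy (and the uniform-rank interval for normalized rank,
  variance (C+1)/(12(C−1))) are therefore evaluated at the per-run
  prediction count N = k·C·m, not at the total over runs.
* **MI null bound.**  Under independence the plug-in MI is biased upward
  with expectation ≈ (C−1)²/(2N ln 2) bits (the χ² connection:
  2N ln 2 · MI ≈ χ² with (C−1)² degrees of freedom), so that quantity is a
  *typical value*, not a ceiling; cross-validation folds are also
  positively correlated, inflating it further by a small design effect.
  The documented null bound is therefore twice the independence
  expectation, (C−1)²/(N ln 2) bits at the per-run count — wide enough to
  be a genuine bound, and still ~12× below the ~2.8 bits of a decodable
  7-class signal.
* **Degenerate transfer maps.**  With many sites and strong tuning, a
  classifier tested across a transformation it cannot bridge (independent
  position tuning) produces a near-deterministic class-to-class mapping;
  the realized accuracy is then ≈ (fixed points of a random map)/C, whose
  randomness lives in the tuning draw, not in trials.  Chance-level checks
  for this regime average over several generator seeds and use the
  fixed-point null (mean 1/C, per-draw sd √((C−1)/C)/C).

## Data formats and binning

Raster-format stores one site per file pair: a dense trials × time-points
`.npy` matrix plus a JSON sidecar with per-trial label lists and site
metadata; labels are case-sensitive exact strings (silent case folding
could merge conditions).  Continuous (LFP/EEG-like) data pass through
every operation unchanged — nothing assumes binary spikes.  Binned-format
is a single HDF5 container of per-site trials × bins matrices sharing one
bin specification; datasets are written with `track_times=False` so equal
content gives equal bytes.

Binning indices are 1-based inclusive at the interface: bin b covers raw
columns [start + (b−1)·step, start + (b−1)·step + width − 1], emitted
while the window's last column ≤ end.  A trailing window that would
overrun is dropped, never padded: a partial mean is a different estimator,
and dropping reproduces the standard arithmetic (150-wide windows stepped
by 50 over 1000 points → 18 bins; a 400-wide window at 601 → exactly one
bin).  Whether the convention should instead keep partial windows is
genuinely open; the drop rule is this package's choice.  Bin centres are
(first + last)/2 of each window.

## The synthetic generator

Each site fires at `baseline_rate_hz` (default 5 Hz) until
`onset_ms + latency_ms` (500 + 100 ms), then steps to baseline +
w·`delta_rate_hz` (default Δ = 30 Hz), where the tuning weight w ∈ [0, 1]
gives each site one preferred class (w = 1) and uniform [0, 0.3] weights
elsewhere — separable at the default Δ yet leaving non-trivial confusions.
Position tuning blends a position-shared profile with independently drawn
position-specific ones: w = invariance·w_shared + (1−invariance)·w_specific.
With `dynamic_epochs = m > 1` the post-latency window splits into m equal
epochs with independently re-drawn tuning, producing a dynamic code.
Spikes are independent Bernoulli(rate·10⁻³) per 1 ms bin — equivalent to
Poisson at physiological rates, capped at one spike/ms, and keeping
rasters binary; rates above 1000 Hz are rejected.  Every (class, position)
condition contributes exactly `trials_per_condition` trials (default 20),
interleaved in one seeded random order shared by all sites so the bundle
is also valid for simultaneous-mode analysis.

The generator deliberately omits spike-history structure (refractoriness,
bursting), correlated noise across sites, and baseline drift.  Passing
tests therefore demonstrate that the pipeline's bookkeeping and statistics
are correct and that it recovers planted selectivity, invariance, and
dynamics; they do not certify performance on real data, where noise
correlations and nonstationarity can change absolute accuracies.

## Defaults and degenerate inputs

| parameter | default | rationale |
| --- | --- | --- |
| k_splits | user-set (examples use 20 or 18) | 20 splits ⇒ train on 19, test on 1 |
| examples_per_class_per_split | 1 | smallest balanced design |
| n_resamples | 50 | stable means on real-scale data; scale down for high-SNR simulations |
| bin width/step | user-set (150/50 typical) | rate estimate vs. temporal resolution trade-off |
| baseline / Δ | 5 / 30 Hz | typical cortical baseline; strong but not saturating modulation |

Sites lacking k·m trials of some class are excluded with a warning and an
exclusion list rather than failing the run, mirroring practical datasets
with missing conditions.  Surplus trials are re-drawn independently on
every resample run — that re-draw is what makes resampling informative.
Empty matrices, unknown label fields, overlapping class mappings,
heterogeneous time axes, and truncated result files all raise explicit
errors naming the offender.

## Problem sizes

The test suite and acceptance script run the default 50-site population
for signal recovery, TCT (5 resamples, full 18 × 18 matrix), and
invariance analyses (single 400 ms bin, 18 splits), with smaller 3–8-site
instances for exhaustive split audits; these sizes give tight recovery
of the planted structure while keeping a full run to tens of seconds.
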