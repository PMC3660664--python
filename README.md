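# popdecode

Population decoding of multivariate neural activity, for systems
neuroscientists who record many sites (spiking units, LFP/EEG channels, …)
across repeated experimental trials and want to ask how much information a
population carries, when it carries it, and how abstract the underlying
code is.

A *pattern classifier* is trained on the joint activity of the population
on a subset of trials and must predict the experimental condition of
held-out trials.  Because most electrophysiology datasets are recorded a
few sites at a time, population response vectors are assembled as
**pseudo-populations**: for each condition, same-condition trials from
separately recorded sites are concatenated as if simultaneous.  The
pipeline is organised around four exchangeable stages:

1. **Datasources** draw balanced k-fold cross-validation splits of
   pseudo-population (or genuinely simultaneous) data, including a
   *generalization* variant that trains each class on one set of condition
   labels and tests it on another (e.g. train on objects shown at the
   upper retinal position, test at the lower one) to measure invariance.
2. **Feature preprocessors** learn parameters from the training data only
   (z-score normalization, F-statistic feature selection) and apply them
   unchanged to the test data — no leakage.
3. **Classifiers** — the maximum-correlation-coefficient classifier
   assigns a test vector x to the class c maximising the Pearson
   correlation r(x, μ̂_c) with the class's mean training vector
   (template) μ̂_c; a nearest-centroid variant (argmin ‖x − μ̂_c‖₂) is
   included for classifier-dependence checks.
4. **The cross-validator** repeats the whole procedure over many
   *resample runs* with freshly drawn splits, trains at every time bin and
   tests at every time bin (the temporal cross-training, TCT, matrix), and
   reduces predictions to zero-one accuracy, normalized rank, plug-in
   mutual information, and confusion counts.

Data enter in **raster-format** (one file per site: a trials × time-points
matrix plus per-trial condition labels and site metadata) and are reduced
to **binned-format** by sliding-window averaging — e.g. 150 ms bins
stepped by 50 ms, or a single 400 ms bin covering time points 601–1000.

A synthetic-data module generates Poisson-like spike rasters with
configurable class selectivity, response latency, position invariance, and
temporal code dynamics, emulating a classic seven-object × three-position
experiment, so the entire pipeline is testable without any external
recordings.  See `docs/methods.md` for the generative model and the
statistical conventions.

## Worked example

Simulate a 20-site population (7 objects × 3 positions × 20 repeats,
500 ms fixation + 500 ms stimulus at 1 ms resolution), bin it, decode
object identity with 20 cross-validation splits, and plot:

```sh
popdecode simulate --out rasters --n-sites 20 --seed 42
popdecode bin --raster-dir rasters --bin-width 150 --step 50 --out binned_150_50.h5
popdecode decode --binned binned_150_50.h5 --label stimulus_ID \
    --k-splits 20 --n-resamples 10 --seed 42 --tct --out results.json
popdecode plot --results results.json --out-dir plots \
    --measure zero_one --event-time 500 --tct
```

which prints

```
wrote 20 sites x 420 trials x 1000 time points to rasters
binned 20 sites into 18 bins -> binned_150_50.h5
decoded 7 classes over 18 time bins; peak accuracy 0.964 (chance 0.143) -> results.json
wrote plots/timecourse_zero_one.png
wrote plots/tct_zero_one.png
```

Before stimulus onset the decoder sits at chance (1/7 ≈ 0.143, the
horizontal line in the time-course plot); shortly after the 500 ms onset
(vertical marker) accuracy rises steeply, peaking at 0.964 here — with the
default 50 sites it saturates near 1.0.  The TCT heatmap (train time on
the y-axis, test time on the x-axis) is uniform off-diagonal for this
static code; simulating with `--dynamic-epochs 2` produces the
diagonal-dominant pattern of a dynamic population code.  The same pipeline
with `popdecode decode-gen` and a train-upper/test-lower class mapping
measures position invariance.

The library mirrors the CLI one-to-one:

```python
import popdecode as pd

sites = pd.generate_dataset(pd.SyntheticConfig(seed=42))
binned = pd.bin_sites(sites, pd.BinSpec(150, 50))
results = pd.run_resample_decoding(
    binned, pd.SplitSpec("stimulus_ID", k_splits=20),
    preprocessors=[pd.ZScoreNormalizer()], n_resamples=10, master_seed=42,
)
print(results.diagonal("zero_one"))   # accuracy per time bin
```

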