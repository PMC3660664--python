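"""Resampled cross-validation decoding loop, accuracy measures, results I/O.

One *resample run* draws fresh pseudo-population splits from the seeded
generator and runs a full k-fold cross-validation: per fold, preprocessors
are fitted on the training data only, a template classifier is trained at
each training time bin, and predictions are made at each test time bin —
all (train, test) pairs when the temporal cross-training (TCT) matrix is
requested, the diagonal only otherwise.  Strong diagonal dominance of the
TCT matrix indicates a dynamic population code: different activity
patterns carry the information at different latencies.

Measures computed from the single prediction stream:

* zero-one accuracy (fraction of correct predictions; chance = 1/C);
* normalized rank of the true class's decision value (chance = 0.5,
  perfect = 1);
* plug-in mutual information of the (true, predicted) confusion table, in
  bits (0 under independence, log2 C for a perfect uniform channel);
* pooled confusion counts per time bin.

Fold results are averaged within each run; runs are kept separate so the
spread across resamples remains available.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from scipy import stats

from .classifiers import (
    DecisionValues,
    test_template_classifier,
    train_template_classifier,
)
from .datasources import ClassMapping, DataSplits, SplitSpec, _get_data, identity_mapping
from .io_formats import BinnedCollection

logger = logging.getLogger("popdecode")

RESULTS_FORMAT_VERSION = 1

#: seed-stream tags: run r uses default_rng([master_seed, r]); the label
#: shuffle (when requested) uses default_rng([master_seed, _SHUFFLE_TAG]).
_SHUFFLE_TAG = 0x5F5E100


# ---------------------------------------------------------------------------
# Measures
# ---------------------------------------------------------------------------


def zero_one_loss(decisions: DecisionValues, true_y) -> float:
    """Fraction of test points whose predicted class equals the true class."""
    true_y = np.asarray(true_y)
    if len(true_y) != len(decisions.predicted):
        raise ValueError(
            f"{len(decisions.predicted)} predictions vs {len(true_y)} labels"
        )
    return float(np.mean(decisions.predicted == true_y))


def normalized_rank(decisions: DecisionValues, true_y) -> float:
    """Mean normalized rank of the true class's decision value.

    Per test point the true class's value is ranked among all C values
    (1 = largest, ties averaged) and mapped to ``1 - (r-1)/(C-1)``, so a
    clairvoyant classifier scores 1, an inverted one 0, and chance is 0.5.
    """
    values = decisions.values
    C = values.shape[1]
    if C < 2:
        raise ValueError("normalized rank needs at least 2 classes")
    true_y = np.asarray(true_y, dtype=int)
    if len(true_y) != values.shape[0]:
        raise ValueError(f"{values.shape[0]} rows vs {len(true_y)} labels")
    ranks = stats.rankdata(-values, axis=1, method="average")
    r_true = ranks[np.arange(len(true_y)), true_y]
    return float(np.mean(1.0 - (r_true - 1.0) / (C - 1.0)))


def mutual_information(confusion: np.ndarray) -> float:
    """Plug-in mutual information of a (true x predicted) count table, bits.

    The joint distribution is the normalized table; ``0 * log 0 = 0``.  The
    plug-in estimator is biased upward by roughly ``(C-1)^2 / (2 N ln 2)``
    bits for an N-count table under independence; no bias correction is
    applied.
    """
    confusion = np.asarray(confusion, dtype=float)
    if np.any(confusion < 0):
        raise ValueError("confusion counts must be non-negative")
    total = confusion.sum()
    if total <= 0:
        raise ValueError("confusion table has no counts")
    p = confusion / total
    pr = p.sum(axis=1, keepdims=True)
    pc = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pr * pc))
    return float(np.nansum(terms))


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------


@dataclass
class DecodingResults:
    """Per-resample decoding measures over train-time x test-time pairs.

    ``zero_one[r, ti, tj]`` is run r's fold-averaged accuracy when training
    at bin ``ti`` and testing at bin ``tj``; entries are NaN off the
    diagonal when the TCT matrix was not computed.  ``confusion[c, c', t]``
    pools true-class-c / predicted-class-c' counts at matched train/test
    time ``t`` over all runs and folds; ``mutual_information_bits[r, t]``
    is the plug-in MI of run r's pooled confusion at time ``t``.
    """

    zero_one: np.ndarray  # (R, T, T)
    normalized_rank: np.ndarray  # (R, T, T)
    mutual_information_bits: np.ndarray  # (R, T)
    confusion: np.ndarray  # (C, C, T)
    bin_centers: np.ndarray  # (T,)
    class_names: tuple
    config: dict[str, Any] = field(default_factory=dict)

    @property
    def n_resamples(self) -> int:
        return self.zero_one.shape[0]

    @property
    def mean_zero_one(self) -> np.ndarray:
        """(T, T) accuracy averaged over resample runs."""
        return self.zero_one.mean(axis=0)

    @property
    def mean_normalized_rank(self) -> np.ndarray:
        return self.normalized_rank.mean(axis=0)

    @property
    def mean_mutual_information(self) -> np.ndarray:
        return self.mutual_information_bits.mean(axis=0)

    def diagonal(self, measure: str = "zero_one") -> np.ndarray:
        """Matched train/test time course of a measure, averaged over runs."""
        if measure == "mutual_information":
            return self.mean_mutual_information
        return np.diagonal(getattr(self, f"mean_{measure}"))

    @property
    def chance_level(self) -> float:
        return 1.0 / len(self.class_names)


def save_results(results: DecodingResults, path: str | Path) -> Path:
    """Write results as a versioned JSON container (lossless round-trip)."""
    path = Path(path)
    payload = {
        "format_version": RESULTS_FORMAT_VERSION,
        "zero_one": results.zero_one.tolist(),
        "normalized_rank": results.normalized_rank.tolist(),
        "mutual_information_bits": results.mutual_information_bits.tolist(),
        "confusion": results.confusion.tolist(),
        "bin_centers": results.bin_centers.tolist(),
        "class_names": list(results.class_names),
        "config": results.config,
    }
    path.write_text(json.dumps(payload, sort_keys=True))
    return path


def load_results(path: str | Path) -> DecodingResults:
    """Load a results container saved by :func:`save_results`."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (json.JSONDecodeError, ValueError) as exc:
        raise ValueError(f"corrupt results file {path}: {exc}") from exc
    version = payload.get("format_version")
    if version != RESULTS_FORMAT_VERSION:
        raise ValueError(
            f"results file {path} has format version {version}; "
            f"expected {RESULTS_FORMAT_VERSION}"
        )
    return DecodingResults(
        zero_one=np.asarray(payload["zero_one"], dtype=float),
        normalized_rank=np.asarray(payload["normalized_rank"], dtype=float),
        mutual_information_bits=np.asarray(
            payload["mutual_information_bits"], dtype=float
        ),
        confusion=np.asarray(payload["confusion"], dtype=float),
        bin_centers=np.asarray(payload["bin_centers"], dtype=float),
        class_names=tuple(payload["class_names"]),
        config=payload["config"],
    )


# ---------------------------------------------------------------------------
# The decoding loop
# ---------------------------------------------------------------------------


def _shuffled_labels(
    binned: BinnedCollection, label_name: str, rng: np.random.Generator
) -> BinnedCollection:
    """Permute the decoded label list independently per site (null model)."""
    site_labels = []
    for sl in binned.site_labels:
        sl = dict(sl)
        labels = list(sl[label_name])
        perm = rng.permutation(len(labels))
        sl[label_name] = [labels[p] for p in perm]
        site_labels.append(sl)
    return BinnedCollection(
        site_data=binned.site_data,
        site_labels=site_labels,
        site_info=binned.site_info,
        bin_spec=binned.bin_spec,
        bin_centers=binned.bin_centers,
    )


def run_resample_decoding(
    binned: BinnedCollection,
    spec: SplitSpec,
    preprocessors: Sequence = (),
    classifier_variant: str = "max_correlation",
    n_resamples: int = 50,
    master_seed: int = 0,
    tct: bool = False,
    mapping: ClassMapping | None = None,
    shuffle_labels: bool = False,
) -> DecodingResults:
    """Run the full resampled cross-validation decoding procedure.

    Parameters
    ----------
    binned:
        Binned collection to decode.
    spec:
        Split configuration; ``spec.resample_seed`` is ignored here in
        favour of per-run seeds derived from ``master_seed`` (run r draws
        from ``default_rng([master_seed, r])``).
    preprocessors:
        Feature-preprocessor objects (e.g. :class:`ZScoreNormalizer`),
        refitted on every fold's training data at every training time bin
        and chained in list order.  May be empty (raw rates decoded).
    mapping:
        Optional :class:`ClassMapping` switching to the generalization
        datasource (train on one label set per class, test on another).
    tct:
        Compute the full train-time x test-time matrix when True; the
        diagonal only when False (off-diagonal entries are NaN).
    shuffle_labels:
        Permute the decoded labels once (seeded) before decoding — a null
        run whose accuracy should sit at chance.

    Returns
    -------
    DecodingResults with per-run arrays and the pooled confusion counts.
    """
    if shuffle_labels:
        shuffle_rng = np.random.default_rng([master_seed, _SHUFFLE_TAG])
        binned = _shuffled_labels(binned, spec.label_name, shuffle_rng)
    if mapping is None:
        mapping = identity_mapping(binned, spec.label_name)

    C = len(mapping.class_names)
    T = binned.n_bins
    acc = np.full((n_resamples, T, T), np.nan)
    rank = np.full((n_resamples, T, T), np.nan)
    mi = np.empty((n_resamples, T))
    confusion = np.zeros((C, C, T))
    excluded: tuple[int, ...] = ()

    for r in range(n_resamples):
        rng = np.random.default_rng([master_seed, r])
        splits = _get_data(binned, spec, mapping, rng)
        excluded = splits.excluded_sites
        acc_sum = np.zeros((T, T))
        rank_sum = np.zeros((T, T))
        conf_run = np.zeros((C, C, T))
        k = splits.k_splits
        for s in range(k):
            test_y = splits.test_y[s]
            n_test = len(test_y)
            for ti in range(T):
                train_X = splits.train_X[s, ti]
                for fp in preprocessors:
                    train_X = fp.fit_transform(train_X, splits.train_y[s])
                model = train_template_classifier(
                    train_X, splits.train_y[s], classifier_variant, mapping.class_names
                )
                test_times = range(T) if tct else (ti,)
                # one pass over all requested test bins: stack, preprocess
                # with the ti-fitted parameters, classify jointly
                stacked = np.concatenate([splits.test_X[s, tj] for tj in test_times])
                for fp in preprocessors:
                    stacked = fp.transform(stacked)
                decisions = test_template_classifier(model, stacked)
                for block, tj in enumerate(test_times):
                    sl = slice(block * n_test, (block + 1) * n_test)
                    sub = DecisionValues(
                        values=decisions.values[sl],
                        predicted=decisions.predicted[sl],
                        class_names=decisions.class_names,
                    )
                    acc_sum[ti, tj] += zero_one_loss(sub, test_y)
                    rank_sum[ti, tj] += normalized_rank(sub, test_y)
                    if ti == tj:
                        np.add.at(conf_run[:, :, ti], (test_y, sub.predicted), 1)
        if tct:
            acc[r] = acc_sum / k
            rank[r] = rank_sum / k
        else:
            acc[r][np.diag_indices(T)] = np.diagonal(acc_sum) / k
            rank[r][np.diag_indices(T)] = np.diagonal(rank_sum) / k
        for t in range(T):
            mi[r, t] = mutual_information(conf_run[:, :, t])
        confusion += conf_run

    config = {
        "label_name": spec.label_name,
        "k_splits": spec.k_splits,
        "examples_per_class_per_split": spec.examples_per_class_per_split,
        "simultaneous": spec.simultaneous,
        "preprocessors": [type(fp).__name__ for fp in preprocessors],
        "classifier_variant": classifier_variant,
        "n_resamples": n_resamples,
        "master_seed": master_seed,
        "tct": tct,
        "shuffle_labels": shuffle_labels,
        "mapping": None
        if mapping is None
        else {
            "class_names": list(mapping.class_names),
            "train_label_sets": [sorted(s) for s in mapping.train_label_sets],
            "test_label_sets": [sorted(s) for s in mapping.test_label_sets],
        },
        "excluded_sites": list(excluded),
        "bin_spec": {
            "bin_width": binned.bin_spec.bin_width,
            "step": binned.bin_spec.step,
            "start_index": binned.bin_spec.start_index,
            "end_index": binned.bin_spec.end_index,
        },
    }
    return DecodingResults(
        zero_one=acc,
        normalized_rank=rank,
        mutual_information_bits=mi,
        confusion=confusion,
        bin_centers=np.asarray(binned.bin_centers, dtype=float),
        class_names=tuple(mapping.class_names),
        config=config,
    )


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------

_MEASURE_LABELS = {
    "zero_one": "Classification accuracy",
    "normalized_rank": "Normalized rank",
    "mutual_information": "Mutual information (bits)",
}


def plot_time_course(
    results: DecodingResults,
    measure: str = "zero_one",
    path: str | Path | None = None,
    event_times: Sequence[float] = (),
):
    """Line plot of a measure's matched train/test time course.

    Draws a horizontal chance line (1/C for accuracy, 0.5 for normalized
    rank, 0 for MI) and optional vertical markers at significant event
    times such as stimulus onset.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if measure not in _MEASURE_LABELS:
        raise ValueError(f"unknown measure {measure!r}; choose from {sorted(_MEASURE_LABELS)}")
    y = results.diagonal(measure)
    chance = {"zero_one": results.chance_level, "normalized_rank": 0.5, "mutual_information": 0.0}[measure]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(results.bin_centers, y, marker="o", label=_MEASURE_LABELS[measure])
    ax.axhline(chance, color="black", linestyle="--", label=f"chance = {chance:.3g}")
    for t in event_times:
        ax.axvline(t, color="black")
    ax.set_xlabel("Time (raw time-point units)")
    ax.set_ylabel(_MEASURE_LABELS[measure])
    ax.legend(loc="best", fontsize="small")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig


def plot_tct_matrix(
    results: DecodingResults,
    measure: str = "zero_one",
    path: str | Path | None = None,
    event_times: Sequence[float] = (),
):
    """Heatmap of the temporal cross-training matrix.

    Training time runs along the vertical axis and test time along the
    horizontal axis; a bright diagonal against darker off-diagonal entries
    signals a dynamic population code.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if measure not in ("zero_one", "normalized_rank"):
        raise ValueError("TCT heatmaps support zero_one or normalized_rank")
    mat = getattr(results, f"mean_{measure}")
    centers = results.bin_centers
    extent = [centers[0], centers[-1], centers[0], centers[-1]]
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    im = ax.imshow(mat, origin="lower", aspect="auto", extent=extent)
    for t in event_times:
        ax.axvline(t, color="white", linewidth=0.8)
        ax.axhline(t, color="white", linewidth=0.8)
    ax.set_xlabel("Test time (raw time-point units)")
    ax.set_ylabel("Train time (raw time-point units)")
    fig.colorbar(im, ax=ax, label=_MEASURE_LABELS[measure])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
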