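"""Cross-validation datasources: pseudo-population training/test splits.

Most electrophysiology datasets are recorded a few sites at a time, so a
population response vector must be assembled as a *pseudo-population*: for
each class, same-condition trials from separately recorded sites are
concatenated as if they had been recorded simultaneously.  The datasource
partitions each site's trials into k disjoint cross-validation splits and
emits, per split and per time bin, balanced training and test matrices in
which feature j always corresponds to the same site.

Two sampling modes exist:

* the basic mode decodes one label field directly, with classes given by
  the distinct label values;
* the generalization mode trains each class on one set of label values and
  tests it on another (e.g. train on objects at the upper position, test on
  the same objects at the lower position) to measure how invariant the
  population code is to the transformation between the two sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Sequence

import numpy as np

from .io_formats import BinnedCollection, ValidationError

logger = logging.getLogger("popdecode")


class ConfigurationError(Exception):
    """The requested split configuration cannot be satisfied by the data."""


@dataclass(frozen=True)
class SplitSpec:
    """How to draw cross-validation splits.

    ``k_splits`` splits are drawn; a classifier trains on k-1 of them and
    tests on the held-out one.  ``examples_per_class_per_split`` pseudo-
    population vectors per class go into every split.  A site is usable only
    if it has at least ``k_splits * examples_per_class_per_split`` trials of
    every class; others are excluded with a warning.

    With ``simultaneous=True`` trial identity is preserved across sites (all
    sites must share identical trial counts and label sequences), so one
    recorded trial contributes every feature of a population vector.
    """

    label_name: str
    k_splits: int
    examples_per_class_per_split: int = 1
    resample_seed: int = 0
    simultaneous: bool = False

    def __post_init__(self) -> None:
        if self.k_splits < 2:
            raise ValidationError("k_splits must be >= 2")
        if self.examples_per_class_per_split < 1:
            raise ValidationError("examples_per_class_per_split must be >= 1")


@dataclass(frozen=True)
class ClassMapping:
    """Per-class training and test label sets for generalization analyses.

    ``train_label_sets[c]`` lists the label values whose trials train class
    ``c``; ``test_label_sets[c]`` lists the values a test trial of class
    ``c`` may carry.  No label value may belong to two classes' train sets
    (likewise test sets).
    """

    class_names: tuple[str, ...]
    train_label_sets: tuple[frozenset[str], ...]
    test_label_sets: tuple[frozenset[str], ...]

    @classmethod
    def from_lists(
        cls,
        class_names: Sequence[str],
        train_label_sets: Sequence[Sequence[str]],
        test_label_sets: Sequence[Sequence[str]],
    ) -> "ClassMapping":
        return cls(
            tuple(class_names),
            tuple(frozenset(s) for s in train_label_sets),
            tuple(frozenset(s) for s in test_label_sets),
        )

    def __post_init__(self) -> None:
        C = len(self.class_names)
        if len(self.train_label_sets) != C or len(self.test_label_sets) != C:
            raise ValidationError(
                "train_label_sets and test_label_sets must match class_names in length"
            )
        for sets, kind in ((self.train_label_sets, "train"), (self.test_label_sets, "test")):
            seen: dict[str, str] = {}
            for name, labels in zip(self.class_names, sets):
                for lab in labels:
                    if lab in seen and seen[lab] != name:
                        raise ValidationError(
                            f"label {lab!r} appears in the {kind} sets of both "
                            f"classes {seen[lab]!r} and {name!r}"
                        )
                    seen[lab] = name


@dataclass
class DataSplits:
    """Pseudo-population cross-validation splits.

    ``train_X[s, t]`` is the training matrix for fold ``s`` at time bin
    ``t`` (rows: ``(k-1) * examples_per_class * C`` pseudo-population
    vectors; columns: sites); ``test_X[s, t]`` the held-out split's matrix.
    ``train_y[s]`` / ``test_y[s]`` hold class indices into ``class_names``.
    """

    train_X: np.ndarray  # (k, n_bins, n_train_rows, n_sites)
    train_y: np.ndarray  # (k, n_train_rows)
    test_X: np.ndarray  # (k, n_bins, n_test_rows, n_sites)
    test_y: np.ndarray  # (k, n_test_rows)
    class_names: tuple[str, ...]
    site_ids: tuple[int, ...]
    excluded_sites: tuple[int, ...] = ()

    @property
    def k_splits(self) -> int:
        return self.train_X.shape[0]

    @property
    def n_bins(self) -> int:
        return self.train_X.shape[1]


# ---------------------------------------------------------------------------
# Sampling core
# ---------------------------------------------------------------------------


def _class_pools(
    labels: Sequence[str], label_sets: Sequence[frozenset[str]]
) -> list[np.ndarray]:
    """Trial indices of each class, ascending, under one label-set list."""
    labels = np.asarray(labels, dtype=object)
    return [
        np.flatnonzero(np.isin(labels, sorted(s))) for s in label_sets
    ]


def _sample_site(
    train_pools: list[np.ndarray],
    test_pools: list[np.ndarray],
    k: int,
    m: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Draw per-class trial assignments for one site.

    Returns (train_sel, test_sel), each of shape (C, k, m) holding trial
    indices: bucket j of class c feeds fold j's test set (test_sel) and the
    training sets of all other folds (train_sel).  Returns None if the site
    lacks trials.

    When a class's train and test pools are the same trials, one draw of
    k*m trials serves both (the classic k-fold discipline).  When they
    differ, test trials are drawn first and training trials are then drawn
    from the train pool minus those test trials, which keeps train and test
    disjoint even if the label sets overlap partially.
    """
    C = len(train_pools)
    need = k * m
    train_sel = np.empty((C, k, m), dtype=int)
    test_sel = np.empty((C, k, m), dtype=int)
    for c in range(C):
        tr_pool, te_pool = train_pools[c], test_pools[c]
        if np.array_equal(tr_pool, te_pool):
            if len(tr_pool) < need:
                return None
            chosen = rng.choice(tr_pool, size=need, replace=False).reshape(k, m)
            train_sel[c] = chosen
            test_sel[c] = chosen
        else:
            if len(te_pool) < need:
                return None
            te_chosen = rng.choice(te_pool, size=need, replace=False)
            remaining = np.setdiff1d(tr_pool, te_chosen)
            if len(remaining) < need:
                return None
            tr_chosen = rng.choice(remaining, size=need, replace=False)
            train_sel[c] = tr_chosen.reshape(k, m)
            test_sel[c] = te_chosen.reshape(k, m)
    return train_sel, test_sel


def _get_data(
    binned: BinnedCollection,
    spec: SplitSpec,
    mapping: ClassMapping,
    rng: np.random.Generator,
) -> DataSplits:
    k, m = spec.k_splits, spec.examples_per_class_per_split
    C = len(mapping.class_names)
    T = binned.n_bins

    per_site_pools = []
    for labels in (sl.get(spec.label_name) for sl in binned.site_labels):
        if labels is None:
            available = sorted(binned.site_labels[0].keys())
            raise ConfigurationError(
                f"unknown label_name {spec.label_name!r}; available: {available}"
            )
        per_site_pools.append(
            (
                _class_pools(labels, mapping.train_label_sets),
                _class_pools(labels, mapping.test_label_sets),
            )
        )

    if spec.simultaneous:
        _validate_simultaneous(binned, spec.label_name)

    usable: list[int] = []
    selections: list[tuple[np.ndarray, np.ndarray]] = []
    shared_sel: tuple[np.ndarray, np.ndarray] | None = None
    excluded: list[int] = []
    for i, (tr_pools, te_pools) in enumerate(per_site_pools):
        if spec.simultaneous:
            # trial identity preserved: one draw, reused by every site
            if shared_sel is None:
                shared_sel = _sample_site(tr_pools, te_pools, k, m, rng)
                if shared_sel is None:
                    raise ConfigurationError(
                        "insufficient trials per class for simultaneous splits; "
                        f"class counts: {_count_report(tr_pools, te_pools, mapping)}"
                    )
            sel = shared_sel
        else:
            sel = _sample_site(tr_pools, te_pools, k, m, rng)
        if sel is None:
            excluded.append(i)
            continue
        usable.append(i)
        selections.append(sel)

    if not usable:
        counts = _count_report(*per_site_pools[0], mapping)
        raise ConfigurationError(
            f"no site has >= k_splits*examples = {k * m} trials for every class; "
            f"per-class counts of site 0: {counts}"
        )
    if excluded:
        logger.warning(
            "excluded %d of %d sites with insufficient trials per class: %s",
            len(excluded), binned.n_sites, excluded,
        )

    n_test = C * m
    n_train = C * (k - 1) * m
    train_X = np.empty((k, T, n_train, len(usable)))
    test_X = np.empty((k, T, n_test, len(usable)))
    # row order — train: (bucket ascending, class, example); test: (class, example)
    test_y = np.tile(np.repeat(np.arange(C), m), (k, 1))
    train_y = np.tile(np.repeat(np.arange(C), m), (k, k - 1))

    for j, (site, (train_sel, test_sel)) in enumerate(zip(usable, selections)):
        data = binned.site_data[site]  # (n_trials, T)
        for s in range(k):
            rows = []
            for bucket in range(k):
                if bucket == s:
                    continue
                rows.append(train_sel[:, bucket, :].reshape(-1))  # (C*m,)
            train_idx = np.concatenate(rows)
            train_X[s, :, :, j] = data[train_idx].T
            test_X[s, :, :, j] = data[test_sel[:, s, :].reshape(-1)].T

    return DataSplits(
        train_X=train_X,
        train_y=train_y,
        test_X=test_X,
        test_y=test_y,
        class_names=mapping.class_names,
        site_ids=tuple(usable),
        excluded_sites=tuple(excluded),
    )


def _count_report(
    train_pools: list[np.ndarray],
    test_pools: list[np.ndarray],
    mapping: ClassMapping,
) -> dict[str, tuple[int, int]]:
    return {
        name: (len(tr), len(te))
        for name, tr, te in zip(mapping.class_names, train_pools, test_pools)
    }


def _validate_simultaneous(binned: BinnedCollection, label_name: str) -> None:
    ref = binned.site_labels[0].get(label_name)
    for i, sl in enumerate(binned.site_labels):
        if binned.site_data[i].shape[0] != binned.site_data[0].shape[0]:
            raise ConfigurationError(
                f"simultaneous=True requires equal trial counts; site {i} has "
                f"{binned.site_data[i].shape[0]} trials vs {binned.site_data[0].shape[0]}"
            )
        if sl.get(label_name) != ref:
            raise ConfigurationError(
                f"simultaneous=True requires identical label sequences; "
                f"site {i} differs on {label_name!r}"
            )


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def identity_mapping(binned: BinnedCollection, label_name: str) -> ClassMapping:
    """One class per distinct label value (sorted), train set == test set."""
    values: set[str] = set()
    for sl in binned.site_labels:
        if label_name in sl:
            values.update(sl[label_name])
    if not values:
        available = sorted(binned.site_labels[0].keys())
        raise ConfigurationError(
            f"unknown label_name {label_name!r}; available: {available}"
        )
    names = tuple(sorted(values))
    sets = tuple(frozenset([v]) for v in names)
    return ClassMapping(names, sets, sets)


def basic_get_data(
    binned: BinnedCollection,
    spec: SplitSpec,
    rng: np.random.Generator | None = None,
) -> DataSplits:
    """Draw pseudo-population cross-validation splits decoding one label field.

    Classes are the distinct values of ``spec.label_name`` in sorted order.
    Per usable site (and independently across sites unless
    ``spec.simultaneous``), ``k_splits * examples_per_class_per_split``
    trials per class are sampled without replacement and dealt into the k
    splits; the i-th vector of class c in a split concatenates, across
    sites, each site's i-th sampled class-c trial.
    """
    if rng is None:
        rng = np.random.default_rng(spec.resample_seed)
    return _get_data(binned, spec, identity_mapping(binned, spec.label_name), rng)


def generalization_get_data(
    binned: BinnedCollection,
    spec: SplitSpec,
    mapping: ClassMapping,
    rng: np.random.Generator | None = None,
) -> DataSplits:
    """Draw splits that train each class on one label set and test on another.

    Training vectors come only from trials whose label is in
    ``mapping.train_label_sets[c]``; test vectors only from
    ``mapping.test_label_sets[c]``.  Cross-validation discipline is
    preserved: a trial never serves both training and test in one resample
    draw, even when the label sets overlap.  With train sets equal to test
    sets this reduces exactly to :func:`basic_get_data` restricted to those
    labels (same seed, same draws).
    """
    if rng is None:
        rng = np.random.default_rng(spec.resample_seed)
    return _get_data(binned, spec, mapping, rng)


def filter_sites(
    binned: BinnedCollection, predicate: Callable[[dict[str, Any]], bool]
) -> BinnedCollection:
    """Keep only sites whose ``site_info`` satisfies ``predicate`` (order kept).

    A predicate that indexes a missing site_info key raises an error naming
    the key.
    """
    keep = []
    for i, info in enumerate(binned.site_info):
        try:
            ok = predicate(info)
        except KeyError as exc:
            raise KeyError(
                f"site {i}: site_info has no key {exc.args[0]!r}; "
                f"available keys: {sorted(info)}"
            ) from exc
        if ok:
            keep.append(i)
    return BinnedCollection(
        site_data=[binned.site_data[i] for i in keep],
        site_labels=[binned.site_labels[i] for i in keep],
        site_info=[binned.site_info[i] for i in keep],
        bin_spec=binned.bin_spec,
        bin_centers=binned.bin_centers,
    )
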