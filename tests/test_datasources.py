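"""Pseudo-population splits: balance, disjointness, determinism, generalization."""

import numpy as np
import pytest

import popdecode as pd
from conftest import make_site


def tiny_collection(rng, n_sites=4, classes=("A", "B", "C"), trials_per_class=8,
                    n_bins=3):
    """Collection whose binned values encode (site, trial) so membership of
    any pseudo-population entry can be audited exactly."""
    site_data, site_labels, site_info = [], [], []
    n_trials = trials_per_class * len(classes)
    for i in range(n_sites):
        labels = [classes[t % len(classes)] for t in range(n_trials)]
        # value = 1000*site + trial, identical in every bin
        data = np.tile(1000.0 * i + np.arange(n_trials)[:, None], (1, n_bins))
        site_data.append(data)
        site_labels.append({"stimulus_ID": labels})
        site_info.append({"site_index": i})
    spec = pd.BinSpec(1, 1, 1, n_bins)
    return pd.BinnedCollection(site_data, site_labels, site_info, spec,
                               spec.bin_centers())


def trial_of(value):
    return int(round(value)) % 1000


class TestBasicSplits:
    def test_split_shapes_20_splits_7_classes(self, default_binned):
        """20 splits, 7 classes, 1 example: test 7 rows, train 19*7 = 133 rows."""
        splits = pd.basic_get_data(
            default_binned, pd.SplitSpec("stimulus_ID", 20, resample_seed=4)
        )
        assert splits.test_X.shape[2] == 7
        assert splits.train_X.shape[2] == 19 * 7
        assert splits.train_X.shape[0] == 20

    def test_smallest_legal_configuration(self, rng):
        col = tiny_collection(rng, classes=("A", "B"), trials_per_class=2)
        splits = pd.basic_get_data(col, pd.SplitSpec("stimulus_ID", 2))
        assert splits.train_X.shape[2] == 2
        assert splits.test_X.shape[2] == 2

    def test_trials_never_reused_across_splits(self, rng):
        """Per site, the multiset of trials over all splits has no duplicates."""
        for seed in range(10):
            col = tiny_collection(rng)
            splits = pd.basic_get_data(
                col, pd.SplitSpec("stimulus_ID", 4, 2, resample_seed=seed)
            )
            k = splits.k_splits
            for j in range(len(splits.site_ids)):
                test_trials = [
                    trial_of(v) for s in range(k) for v in splits.test_X[s, 0, :, j]
                ]
                assert len(set(test_trials)) == len(test_trials)
                for s in range(k):
                    train_trials = {trial_of(v) for v in splits.train_X[s, 0, :, j]}
                    fold_test = {trial_of(v) for v in splits.test_X[s, 0, :, j]}
                    assert not (train_trials & fold_test)
                    # training folds reuse exactly the other splits' trials
                    assert train_trials == set(test_trials) - fold_test

    def test_class_balance(self, rng):
        col = tiny_collection(rng)
        splits = pd.basic_get_data(col, pd.SplitSpec("stimulus_ID", 4, 2))
        C = len(splits.class_names)
        for s in range(4):
            counts = np.bincount(splits.test_y[s], minlength=C)
            assert np.all(counts == 2)
            counts = np.bincount(splits.train_y[s], minlength=C)
            assert np.all(counts == 2 * 3)

    def test_feature_columns_follow_sites(self, rng):
        """Column j of every matrix holds site j's values (audit via encoding)."""
        col = tiny_collection(rng, n_sites=5)
        splits = pd.basic_get_data(col, pd.SplitSpec("stimulus_ID", 3))
        for j, site in enumerate(splits.site_ids):
            vals = np.concatenate(
                [splits.train_X[:, :, :, j].ravel(), splits.test_X[:, :, :, j].ravel()]
            )
            assert np.all((np.round(vals) // 1000) == site)

    def test_determinism_under_seed(self, rng):
        col = tiny_collection(rng)
        a = pd.basic_get_data(col, pd.SplitSpec("stimulus_ID", 4, resample_seed=7))
        b = pd.basic_get_data(col, pd.SplitSpec("stimulus_ID", 4, resample_seed=7))
        np.testing.assert_array_equal(a.train_X, b.train_X)
        np.testing.assert_array_equal(a.test_X, b.test_X)
        c = pd.basic_get_data(col, pd.SplitSpec("stimulus_ID", 4, resample_seed=8))
        assert not np.array_equal(a.train_X, c.train_X)

    def test_unknown_label_name(self, rng):
        col = tiny_collection(rng)
        with pytest.raises(pd.ConfigurationError, match="stimulus_ID"):
            pd.basic_get_data(col, pd.SplitSpec("no_such_label", 2))

    def test_sites_with_too_few_trials_are_excluded(self, rng):
        col = tiny_collection(rng, n_sites=3, trials_per_class=8)
        # cripple site 1: drop most of class A's trials
        labels = col.site_labels[1]["stimulus_ID"]
        col.site_labels[1]["stimulus_ID"] = ["B" if l == "A" else l for l in labels[:-1]] + ["A"]
        splits = pd.basic_get_data(col, pd.SplitSpec("stimulus_ID", 4))
        assert splits.excluded_sites == (1,)
        assert splits.site_ids == (0, 2)

    def test_no_usable_site_is_configuration_error(self, rng):
        col = tiny_collection(rng, trials_per_class=3)
        with pytest.raises(pd.ConfigurationError, match="counts"):
            pd.basic_get_data(col, pd.SplitSpec("stimulus_ID", 4))


class TestSimultaneous:
    def test_trial_identity_preserved(self, rng):
        col = tiny_collection(rng, n_sites=4)
        spec = pd.SplitSpec("stimulus_ID", 4, simultaneous=True)
        splits = pd.basic_get_data(col, spec)
        # every pseudo-population row must come from one recorded trial
        for s in range(4):
            for X in (splits.train_X[s, 0], splits.test_X[s, 0]):
                trials = np.round(X).astype(int) % 1000
                assert np.all(trials == trials[:, :1])

    def test_mismatched_label_sequences_rejected(self, rng):
        col = tiny_collection(rng, n_sites=3)
        col.site_labels[2]["stimulus_ID"] = list(
            reversed(col.site_labels[2]["stimulus_ID"])
        )
        with pytest.raises(pd.ConfigurationError, match="identical label sequences"):
            pd.basic_get_data(col, pd.SplitSpec("stimulus_ID", 4, simultaneous=True))


class TestGeneralization:
    def upper_lower_collection(self, rng, n_sites=3, trials_per_cond=6):
        classes = ["A", "B", "C"]
        positions = ["upper", "lower"]
        labels = [
            f"{c}_{p}" for c in classes for p in positions
            for _ in range(trials_per_cond)
        ]
        site_data, site_labels, site_info = [], [], []
        for i in range(n_sites):
            data = np.tile(1000.0 * i + np.arange(len(labels))[:, None], (1, 2))
            site_data.append(data)
            site_labels.append({"combined": list(labels)})
            site_info.append({"site_index": i})
        spec = pd.BinSpec(1, 1, 1, 2)
        col = pd.BinnedCollection(site_data, site_labels, site_info, spec,
                                  spec.bin_centers())
        return col, classes

    def test_train_upper_test_lower(self, rng):
        col, classes = self.upper_lower_collection(rng)
        mapping = pd.ClassMapping.from_lists(
            classes,
            [[f"{c}_upper"] for c in classes],
            [[f"{c}_lower"] for c in classes],
        )
        spec = pd.SplitSpec("combined", 3)
        splits = pd.generalization_get_data(col, spec, mapping)
        labels = col.site_labels[0]["combined"]
        for s in range(3):
            for v in splits.train_X[s, 0, :, 0]:
                assert labels[trial_of(v)].endswith("_upper")
            for v in splits.test_X[s, 0, :, 0]:
                assert labels[trial_of(v)].endswith("_lower")

    def test_degenerate_mapping_equals_basic(self, rng):
        """Train sets == test sets reproduces basic_get_data draw-for-draw."""
        col, classes = self.upper_lower_collection(rng)
        sets = [[f"{c}_upper"] for c in classes]
        mapping = pd.ClassMapping.from_lists([f"{c}_upper" for c in classes], sets, sets)
        spec = pd.SplitSpec("combined", 3, resample_seed=5)
        gen = pd.generalization_get_data(col, spec, mapping)
        # restrict the collection to the upper-position trials and run basic
        keep = [
            i for i, l in enumerate(col.site_labels[0]["combined"])
            if l.endswith("_upper")
        ]
        restricted = pd.BinnedCollection(
            [d[keep] for d in col.site_data],
            [{"combined": [sl["combined"][i] for i in keep]} for sl in col.site_labels],
            col.site_info, col.bin_spec, col.bin_centers,
        )
        basic = pd.basic_get_data(restricted, spec)
        # the encoded values carry original trial ids, so equal draws mean
        # bit-identical matrices
        np.testing.assert_array_equal(gen.train_X, basic.train_X)
        np.testing.assert_array_equal(gen.test_X, basic.test_X)
        np.testing.assert_array_equal(gen.train_y, basic.train_y)

    def test_overlapping_label_sets_stay_disjoint(self, rng):
        """Partial train/test label overlap never puts a trial on both sides."""
        col, classes = self.upper_lower_collection(rng, trials_per_cond=8)
        mapping = pd.ClassMapping.from_lists(
            classes,
            [[f"{c}_upper", f"{c}_lower"] for c in classes],  # train on both
            [[f"{c}_lower"] for c in classes],  # test on lower only
        )
        for seed in range(10):
            spec = pd.SplitSpec("combined", 3, resample_seed=seed)
            splits = pd.generalization_get_data(col, spec, mapping)
            for j in range(len(splits.site_ids)):
                train_pool = {trial_of(v) for v in splits.train_X[:, 0, :, j].ravel()}
                test_pool = {trial_of(v) for v in splits.test_X[:, 0, :, j].ravel()}
                assert not (train_pool & test_pool)

    def test_overlapping_classes_rejected(self):
        with pytest.raises(pd.ValidationError, match="both"):
            pd.ClassMapping.from_lists(
                ["x", "y"], [["a"], ["a"]], [["b"], ["c"]]
            )

    def test_insufficient_trials_is_configuration_error(self, rng):
        col, classes = self.upper_lower_collection(rng, trials_per_cond=2)
        mapping = pd.ClassMapping.from_lists(
            classes,
            [[f"{c}_upper"] for c in classes],
            [[f"{c}_lower"] for c in classes],
        )
        with pytest.raises(pd.ConfigurationError):
            pd.generalization_get_data(col, pd.SplitSpec("combined", 3), mapping)


class TestFilterSites:
    def collection(self, rng):
        sites = [
            make_site(rng, brain_area="IT" if i % 2 == 0 else "V4")
            for i in range(6)
        ]
        return pd.bin_sites(sites, pd.BinSpec(5, 5))

    def test_predicate_filter_matches_brute_force(self, rng):
        col = self.collection(rng)
        kept = pd.filter_sites(col, lambda info: info["brain_area"] == "IT")
        expected = [i for i, info in enumerate(col.site_info)
                    if info["brain_area"] == "IT"]
        assert kept.n_sites == len(expected)
        assert [info["site_index"] for info in kept.site_info] == [
            col.site_info[i]["site_index"] for i in expected
        ]

    def test_always_true_predicate_is_identity(self, rng):
        col = self.collection(rng)
        kept = pd.filter_sites(col, lambda info: True)
        assert kept.n_sites == col.n_sites
        for a, b in zip(kept.site_data, col.site_data):
            np.testing.assert_array_equal(a, b)

    def test_missing_key_named_in_error(self, rng):
        col = self.collection(rng)
        with pytest.raises(KeyError, match="depth"):
            pd.filter_sites(col, lambda info: info["depth"] > 0)
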