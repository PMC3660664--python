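"""Feature preprocessors: fitted on training data only, applied to both sets.

A preprocessor learns its parameters from the training matrix of one
cross-validation fold and applies them unchanged to that fold's test
matrix, so no test-set statistic can leak into the decoding.  Preprocessors
chain in list order: the output of one feeds the next, on both the train
and the test path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ZScoreParams:
    """Per-feature mean and standard deviation learned from training data."""

    mean: np.ndarray
    sd: np.ndarray


class ZScoreNormalizer:
    """Z-score each feature using training-set statistics.

    Normalization stops sites with high firing rates from dominating the
    classifier.  The standard deviation uses the sample (n-1) convention.
    A constant training feature (sd = 0) maps to all zeros rather than NaN
    or being dropped, which keeps feature/site alignment stable across
    folds.
    """

    def __init__(self) -> None:
        self.params: ZScoreParams | None = None

    def fit_transform(self, train_X: np.ndarray, train_y=None) -> np.ndarray:
        params, out = zscore_fit_transform(train_X, train_y)
        self.params = params
        return out

    def transform(self, test_X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("fit_transform must be called before transform")
        return zscore_transform_test(self.params, test_X)

    def fitted_info(self) -> dict:
        assert self.params is not None
        return {"mean": self.params.mean.tolist(), "sd": self.params.sd.tolist()}


def zscore_fit_transform(
    train_X: np.ndarray, train_y=None
) -> tuple[ZScoreParams, np.ndarray]:
    """Learn per-feature mean/sd from ``train_X`` and z-score it.

    ``train_y`` is accepted but unused; the argument exists so label-aware
    preprocessors share one call signature.
    """
    train_X = np.asarray(train_X, dtype=float)
    if train_X.size == 0:
        raise ValueError("cannot fit z-score parameters on an empty matrix")
    mean = train_X.mean(axis=0)
    sd = train_X.std(axis=0, ddof=1) if train_X.shape[0] > 1 else np.zeros(train_X.shape[1])
    params = ZScoreParams(mean=mean, sd=sd)
    return params, zscore_transform_test(params, train_X)


def zscore_transform_test(params: ZScoreParams, test_X: np.ndarray) -> np.ndarray:
    """Apply training-derived z-score parameters; test statistics never enter."""
    test_X = np.asarray(test_X, dtype=float)
    if test_X.shape[1] != params.mean.shape[0]:
        raise ValueError(
            f"test matrix has {test_X.shape[1]} features but parameters were "
            f"fitted for {params.mean.shape[0]}"
        )
    safe_sd = np.where(params.sd == 0, 1.0, params.sd)
    out = (test_X - params.mean) / safe_sd
    out[:, params.sd == 0] = 0.0
    return out


class TopKFeatureSelector:
    """Keep the k features best separating the classes on training data.

    Features are ranked by a one-way between-class F-statistic computed on
    the training matrix only; the selected index set is applied unchanged
    to test data.  Ties are broken toward the lowest feature index.
    """

    def __init__(self, k: int) -> None:
        self.k = k
        self.indices: np.ndarray | None = None

    def fit_transform(self, train_X: np.ndarray, train_y) -> np.ndarray:
        self.indices, out = select_top_k_features_fit(train_X, train_y, self.k)
        return out

    def transform(self, test_X: np.ndarray) -> np.ndarray:
        if self.indices is None:
            raise RuntimeError("fit_transform must be called before transform")
        return np.asarray(test_X, dtype=float)[:, self.indices]

    def fitted_info(self) -> dict:
        assert self.indices is not None
        return {"selected_features": self.indices.tolist()}


def select_top_k_features_fit(
    train_X: np.ndarray, train_y, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rank features by one-way F-statistic on training data; keep top k.

    Returns the selected feature indices (in ascending index order, chosen
    by descending F with lowest-index tie-break) and the reduced training
    matrix.  Features whose F-statistic is undefined (no variance anywhere)
    rank last.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    n_features = train_X.shape[1]
    if not (1 <= k <= n_features):
        raise ValueError(f"k must be in [1, {n_features}]; got {k}")
    groups = [train_X[train_y == c] for c in np.unique(train_y)]
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, _ = stats.f_oneway(*groups, axis=0)
    f_stat = np.asarray(f_stat, dtype=float)
    f_stat = np.where(np.isnan(f_stat), -np.inf, f_stat)
    # stable sort on -F keeps the lowest index first among ties
    order = np.argsort(-f_stat, kind="stable")
    selected = np.sort(order[:k])
    return selected, train_X[:, selected]
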