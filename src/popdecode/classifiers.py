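"""Template classifiers: per-class mean templates, correlation or distance.

The maximum-correlation classifier learns one template per class — the
unweighted mean of that class's training vectors — and assigns a test
vector to the class whose template it correlates with most strongly
(Pearson correlation).  Because correlation is invariant to shifting and
positive scaling of the test vector, the classifier reads out the *pattern*
of activity across sites rather than its overall level.

A nearest-centroid variant (negative Euclidean distance to each template)
is provided so that the dependence of results on the classifier choice can
be assessed with the rest of the pipeline unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

VARIANTS = ("max_correlation", "min_euclidean")


@dataclass
class TrainedTemplateModel:
    """Fitted state: one mean-activity template per class."""

    templates: np.ndarray  # (C, n_features)
    class_names: tuple
    variant: str

    def to_dict(self) -> dict:
        return {
            "templates": self.templates.tolist(),
            "class_names": list(self.class_names),
            "variant": self.variant,
        }


@dataclass
class DecisionValues:
    """Per-class decision values and argmax predictions for a test set.

    ``values[i, c]`` scores test row i against class c; ``predicted[i]`` is
    the argmax over classes, ties broken toward the lowest class index.
    """

    values: np.ndarray  # (n_test, C)
    predicted: np.ndarray  # (n_test,) class indices
    class_names: tuple


def train_template_classifier(
    train_X: np.ndarray,
    train_y,
    variant: str = "max_correlation",
    class_names: Sequence | None = None,
) -> TrainedTemplateModel:
    """Learn per-class mean templates from training data.

    ``train_y`` holds class indices ``0..C-1``; every class must contribute
    at least one training row.  ``class_names`` defaults to the indices.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown classifier variant {variant!r}; choose from {VARIANTS}")
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=int)
    C = int(train_y.max()) + 1 if class_names is None else len(class_names)
    templates = np.empty((C, train_X.shape[1]))
    for c in range(C):
        rows = train_X[train_y == c]
        if rows.shape[0] == 0:
            name = class_names[c] if class_names is not None else c
            raise ValueError(f"class {name!r} has no training rows")
        templates[c] = rows.mean(axis=0)
    names = tuple(class_names) if class_names is not None else tuple(range(C))
    return TrainedTemplateModel(templates=templates, class_names=names, variant=variant)


def test_template_classifier(
    model: TrainedTemplateModel, test_X: np.ndarray
) -> DecisionValues:
    """Score test vectors against the class templates and predict classes.

    ``max_correlation``: decision value = Pearson correlation between the
    test row and the template; a zero-variance (constant) row or template
    yields 0 by convention, since a constant vector carries no pattern.
    ``min_euclidean``: decision value = negative Euclidean distance.
    """
    test_X = np.asarray(test_X, dtype=float)
    if test_X.shape[1] != model.templates.shape[1]:
        raise ValueError(
            f"test matrix has {test_X.shape[1]} features; model expects "
            f"{model.templates.shape[1]}"
        )
    if model.variant == "max_correlation":
        values = _pearson_matrix(test_X, model.templates)
    elif model.variant == "min_euclidean":
        diffs = test_X[:, None, :] - model.templates[None, :, :]
        values = -np.linalg.norm(diffs, axis=2)
    else:  # pragma: no cover - guarded at train time
        raise ValueError(f"unknown variant {model.variant!r}")
    predicted = np.argmax(values, axis=1)  # argmax takes the lowest index on ties
    return DecisionValues(values=values, predicted=predicted, class_names=model.class_names)


def _pearson_matrix(X: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of X with every row of T.

    Degenerate rows (zero variance on either side) get correlation 0.
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    Tc = T - T.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    tn = np.linalg.norm(Tc, axis=1)
    denom = np.outer(xn, tn)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (Xc @ Tc.T) / denom
    vals[denom == 0] = 0.0
    return vals


class TemplateClassifier:
    """Object wrapper pairing :func:`train` and :func:`test` for pipelines."""

    def __init__(self, variant: str = "max_correlation") -> None:
        if variant not in VARIANTS:
            raise ValueError(f"unknown classifier variant {variant!r}; choose from {VARIANTS}")
        self.variant = variant
        self.model: TrainedTemplateModel | None = None

    def train(self, train_X, train_y, class_names=None) -> TrainedTemplateModel:
        self.model = train_template_classifier(train_X, train_y, self.variant, class_names)
        return self.model

    def test(self, test_X) -> DecisionValues:
        if self.model is None:
            raise RuntimeError("train must be called before test")
        return test_template_classifier(self.model, test_X)
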