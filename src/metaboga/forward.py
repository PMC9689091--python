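"""Forward selection over a gene rank: the "most compact and accurate" model.

Features are added in gene-rank order; each nested model's cross-validated
average accuracy forms the size curve.  The chosen model is the smallest
size whose accuracy is within a small tolerance of the curve's maximum --
accuracy first, then compactness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec, CVScheme, FoldEvaluator, make_folds
from .datasets import ConfigurationError
from .preprocess import ComparisonDataset

__all__ = ["ForwardModel", "forward_select", "best_models_table"]


@dataclass
class ForwardModel:
    """An ordered feature list with its nested-model accuracy curve."""

    comparison: str
    method: str
    features: list[str]  # the chosen model, in rank order
    feature_indices: list[int]
    size_curve: np.ndarray = field(repr=False)  # accuracy at sizes 1..len
    chosen_size: int = 0
    average_accuracy: float = 0.0

    def to_json_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "method": self.method,
            "features": list(self.features),
            "feature_indices": [int(i) for i in self.feature_indices],
            "size_curve": [float(v) for v in self.size_curve],
            "chosen_size": int(self.chosen_size),
            "average_accuracy": float(self.average_accuracy),
        }


def forward_select(
    rank: Sequence[int],
    data: ComparisonDataset,
    classifier: ClassifierSpec | None = None,
    scheme: CVScheme | None = None,
    max_size: int = 30,
    tolerance: float = 0.01,
) -> ForwardModel:
    """Pick the most compact nested model near the accuracy maximum.

    ``rank`` lists feature indices in descending gene-frequency order.  For
    each size s = 1..max_size the top-s features are evaluated by
    cross-validated average accuracy; the chosen size is the smallest s
    within ``tolerance`` of the curve's maximum (exact ties also resolve to
    the smallest size).
    """
    classifier = classifier or ClassifierSpec()
    scheme = scheme or CVScheme()
    rank = [int(r) for r in rank]
    if not rank:
        raise ConfigurationError("empty gene rank")
    max_size = min(max_size, len(rank))
    if max_size < 1:
        raise ConfigurationError("max_size must be >= 1")

    X, y = data.X, data.y
    folds = make_folds(y, scheme)
    scorer = FoldEvaluator(X, y, classifier, folds)
    curve = np.empty(max_size)
    for s in range(1, max_size + 1):
        curve[s - 1] = scorer.accuracy(rank[:s])
    chosen = int(np.argmax(curve >= curve.max() - tolerance)) + 1

    names = data.feature_names
    return ForwardModel(
        comparison=data.name,
        method=classifier.method,
        features=[names[i] for i in rank[:chosen]],
        feature_indices=rank[:chosen],
        size_curve=curve,
        chosen_size=chosen,
        average_accuracy=float(curve[chosen - 1]),
    )


def best_models_table(models: Iterable) -> pd.DataFrame:
    """Summarize average accuracy per comparison x method and flag the best.

    ``models`` may be :class:`ForwardModel` objects or
    ``(comparison, method, average_accuracy)`` triples.  Within each
    comparison every method tied with the maximum accuracy is flagged.
    """
    rows = []
    for m in models:
        if isinstance(m, ForwardModel):
            rows.append((m.comparison, m.method, float(m.average_accuracy)))
        else:
            comparison, method, acc = m
            rows.append((str(comparison), str(method), float(acc)))
    if not rows:
        raise ConfigurationError("no models supplied")
    frame = pd.DataFrame(rows, columns=["comparison", "method", "average_accuracy"])
    best = frame.groupby("comparison")["average_accuracy"].transform("max")
    frame["best"] = frame["average_accuracy"] == best
    return frame
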