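"""Loaders for the published reference results shipped with the package.

Three small TSV tables transcribe the reference study's printed outputs:

* ``best_model_features.tsv`` -- the metabolite list of the best
  forward-selected model per comparison (with the winning method);
* ``common_metabolites.tsv`` -- the four intersection sets per comparison,
  transcribed verbatim (including one dot-for-space artifact that the name
  normalizer resolves);
* ``reported_accuracy.tsv`` -- the 15 published average accuracies
  (comparison x method).

These serve as inputs for the intersection analysis and as regression
anchors for the reporting logic; they are *results of* the reference
analysis, not data it was run on.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_best_model_features",
    "load_common_metabolites",
    "load_reported_accuracies",
]


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("metaboga") / "data" / name) as path:
        return pd.read_csv(path, sep="\t")


def load_best_model_features() -> dict[str, tuple[str, list[str]]]:
    """Per comparison: (winning method, ordered metabolite list)."""
    frame = _read("best_model_features.tsv")
    out: dict[str, tuple[str, list[str]]] = {}
    for comparison, group in frame.groupby("comparison", sort=False):
        methods = group["method"].unique()
        assert len(methods) == 1
        out[str(comparison)] = (str(methods[0]), [str(f) for f in group["feature"]])
    return out


def load_common_metabolites() -> dict[str, dict[str, set[str]]]:
    """Per comparison: the four intersection sets keyed like
    ``knn_nearcent_svm`` / ``knn_nearcent`` / ``knn_svm`` / ``nearcent_svm``.
    """
    frame = _read("common_metabolites.tsv")
    out: dict[str, dict[str, set[str]]] = {}
    for (comparison, models), group in frame.groupby(
        ["comparison", "models"], sort=False
    ):
        out.setdefault(str(comparison), {})[str(models)] = {
            str(m) for m in group["metabolite"]
        }
    return out


def load_reported_accuracies() -> pd.DataFrame:
    """The 15 published average accuracies (comparison, method, value)."""
    return _read("reported_accuracy.tsv")
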