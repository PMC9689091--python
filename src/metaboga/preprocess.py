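"""Inclusion filtering, probabilistic quotient normalization (PQN), and the
five pairwise stage-comparison datasets.

PQN corrects per-sample dilution: it assumes most signals vary with dilution
only, estimates each sample's most likely quotient against a reference
spectrum (the median spectrum by default), and divides the sample by it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datasets import COMPARISON_PAIRS, STAGES, ConfigurationError, comparison_name
from .table import FeatureTable

__all__ = [
    "PQNConfig",
    "PQNNormalizer",
    "ComparisonDataset",
    "InclusionError",
    "apply_inclusion",
    "pqn_normalize",
    "pqn_quotients",
    "make_comparisons",
    "pair_dataset",
]


class InclusionError(ValueError):
    """No samples survive the inclusion filter."""


# -- inclusion filtering ---------------------------------------------------

def apply_inclusion(
    table: FeatureTable, stages: Sequence[str] = STAGES
) -> tuple[FeatureTable, pd.DataFrame]:
    """Keep samples with a recognized stage label and a complete feature vector.

    Feature columns still missing a value across the retained samples are
    dropped afterwards.  Returns the filtered table and a log with one row
    per exclusion: columns ``kind`` ("sample" or "feature"), ``id``,
    ``rule`` and ``detail``.

    Raises
    ------
    InclusionError
        If no sample survives.
    """
    log_rows: list[dict[str, str]] = []
    keep = pd.Series(True, index=table.intensities.index)

    known = set(stages)
    for sid, stage in table.stages.items():
        if stage not in known:
            keep[sid] = False
            log_rows.append(
                {"kind": "sample", "id": str(sid), "rule": "stage_label",
                 "detail": f"stage {stage!r} is not one of {sorted(known)}"}
            )
    incomplete = table.intensities.isna().any(axis=1)
    for sid in table.intensities.index[incomplete & keep]:
        keep[sid] = False
        n_missing = int(table.intensities.loc[sid].isna().sum())
        log_rows.append(
            {"kind": "sample", "id": str(sid), "rule": "complete_data",
             "detail": f"{n_missing} missing intensity value(s)"}
        )

    if not keep.any():
        raise InclusionError("no samples survive inclusion")

    retained = table.subset_samples(keep[keep].index)
    still_missing = retained.intensities.isna().any(axis=0)
    for feat in retained.intensities.columns[still_missing]:
        log_rows.append(
            {"kind": "feature", "id": str(feat), "rule": "complete_data",
             "detail": "missing in retained samples"}
        )
    if still_missing.any():
        retained = FeatureTable(
            retained.intensities.loc[:, ~still_missing], retained.stages
        )
    log = pd.DataFrame(log_rows, columns=["kind", "id", "rule", "detail"])
    return retained, log


# -- PQN -------------------------------------------------------------------

@dataclass
class PQNConfig:
    """Settings for probabilistic quotient normalization.

    reference : "median" or "mean" -- how the reference spectrum is built
        over samples.
    quotient : "median" or "mean" -- how the per-feature quotients are
        aggregated into one normalization factor per sample.
    regions : optional list of (lower, upper) feature-index windows (upper
        exclusive) restricting which features enter the quotient.
    power : exponent applied to the per-feature quotients before
        aggregation (the aggregate is taken back to power 1).
    """

    reference: str = "median"
    quotient: str = "median"
    regions: Sequence[tuple[int, int]] | None = None
    power: float = 1.0

    def validate(self, n_features: int) -> None:
        if self.reference not in ("median", "mean"):
            raise ConfigurationError(f"unknown reference method {self.reference!r}")
        if self.quotient not in ("median", "mean"):
            raise ConfigurationError(f"unknown quotient method {self.quotient!r}")
        if self.power <= 0:
            raise ConfigurationError("power must be > 0")
        if self.regions is not None:
            spans = sorted((int(a), int(b)) for a, b in self.regions)
            prev_end = 0
            for a, b in spans:
                if not (0 <= a < b <= n_features):
                    raise ConfigurationError(f"region ({a}, {b}) out of bounds")
                if a < prev_end:
                    raise ConfigurationError("regions overlap")
                prev_end = b

    def region_mask(self, n_features: int) -> np.ndarray:
        if self.regions is None:
            return np.ones(n_features, dtype=bool)
        mask = np.zeros(n_features, dtype=bool)
        for a, b in self.regions:
            mask[int(a):int(b)] = True
        return mask


def _reference_spectrum(X: np.ndarray, method: str) -> np.ndarray:
    return np.median(X, axis=0) if method == "median" else np.mean(X, axis=0)


def pqn_quotients(
    X: np.ndarray,
    reference: np.ndarray,
    cfg: PQNConfig | None = None,
    sample_ids: Sequence | None = None,
) -> np.ndarray:
    """Per-sample most-likely quotients of ``X`` against ``reference``.

    Features outside the configured regions, with a non-positive reference
    value, or with a non-positive sample value are excluded from the
    quotient.  A sample with no usable feature raises a ``ValueError``
    naming it.
    """
    cfg = cfg or PQNConfig()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    cfg.validate(p)
    usable_cols = cfg.region_mask(p)
    ref_ok = reference > 0
    if not ref_ok[usable_cols].all():
        warnings.warn(
            f"{int((~ref_ok & usable_cols).sum())} reference value(s) are zero; "
            "those features are excluded from the quotients",
            stacklevel=2,
        )
    usable_cols &= ref_ok

    quotients = np.empty(n)
    agg = np.median if cfg.quotient == "median" else np.mean
    for i in range(n):
        row_ok = usable_cols & (X[i] > 0)
        if not row_ok.any():
            sid = sample_ids[i] if sample_ids is not None else i
            raise ValueError(f"sample {sid!r} has no usable feature for PQN quotient")
        ratios = X[i, row_ok] / reference[row_ok]
        quotients[i] = agg(ratios ** cfg.power) ** (1.0 / cfg.power)
    return quotients


def pqn_normalize(
    table: FeatureTable, cfg: PQNConfig | None = None
) -> tuple[FeatureTable, pd.Series]:
    """PQN-normalize a table against its own reference spectrum.

    Returns the normalized table and the per-sample quotients that were
    divided out (the dilution estimates, up to the overall scale of the
    reference).
    """
    cfg = cfg or PQNConfig()
    X = table.values()
    reference = _reference_spectrum(X, cfg.reference)
    q = pqn_quotients(X, reference, cfg, sample_ids=table.sample_ids)
    normalized = pd.DataFrame(
        X / q[:, None], index=table.intensities.index, columns=table.intensities.columns
    )
    quotients = pd.Series(q, index=table.intensities.index, name="pqn_quotient")
    return FeatureTable(normalized, table.stages), quotients


class PQNNormalizer(TransformerMixin, BaseEstimator):
    """Probabilistic quotient normalization as a scikit-learn transformer.

    ``fit`` learns the reference spectrum from the training samples;
    ``transform`` divides each sample by its quotient against that
    reference.  With the default median reference and median quotient this
    is the standard dilution correction for spectral and LC-MS feature data.

    Parameters
    ----------
    reference : {"median", "mean"}, default="median"
    quotient : {"median", "mean"}, default="median"
    regions : list of (int, int) or None
        Feature-index windows entering the quotient (upper bound exclusive).
    power : float, default=1.0

    Attributes
    ----------
    reference_ : ndarray of shape (n_features,)
        The learned reference spectrum.
    n_features_in_ : int
    """

    def __init__(self, reference="median", quotient="median", regions=None, power=1.0):
        self.reference = reference
        self.quotient = quotient
        self.regions = regions
        self.power = power

    def _cfg(self) -> PQNConfig:
        return PQNConfig(
            reference=self.reference,
            quotient=self.quotient,
            regions=self.regions,
            power=self.power,
        )

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        cfg = self._cfg()
        cfg.validate(X.shape[1])
        self.n_features_in_ = X.shape[1]
        self.reference_ = _reference_spectrum(X, cfg.reference)
        return self

    def quotients(self, X) -> np.ndarray:
        check_is_fitted(self, "reference_")
        X = check_array(X, dtype=float)
        return pqn_quotients(X, self.reference_, self._cfg())

    def transform(self, X):
        q = self.quotients(X)
        return np.asarray(X, dtype=float) / q[:, None]


# -- pairwise comparisons --------------------------------------------------

@dataclass
class ComparisonDataset:
    """A two-stage slice of the cohort, e.g. Control-DN.

    ``positive_label`` is the later progression stage of the pair.
    """

    name: str
    table: FeatureTable = field(repr=False)
    positive_label: str

    def __post_init__(self) -> None:
        present = set(self.table.stages.unique())
        if len(present) != 2:
            raise ConfigurationError(
                f"comparison {self.name!r} must contain exactly two stages, "
                f"found {sorted(present)}"
            )
        if self.positive_label not in present:
            raise ConfigurationError(
                f"positive label {self.positive_label!r} absent from {self.name!r}"
            )

    @property
    def X(self) -> np.ndarray:
        return self.table.values()

    @property
    def y(self) -> np.ndarray:
        return self.table.stages.to_numpy()

    @property
    def feature_names(self) -> list[str]:
        return self.table.feature_names

    def restrict(self, feature_idx: Sequence[int]) -> np.ndarray:
        """Intensity matrix restricted to the given feature indices."""
        return self.X[:, np.asarray(feature_idx, dtype=int)]


def pair_dataset(table: FeatureTable, first: str, second: str) -> ComparisonDataset:
    """Build one comparison dataset; sample order follows the input table."""
    mask = table.stages.isin([first, second])
    missing = [s for s in (first, second) if not (table.stages == s).any()]
    if missing:
        raise ConfigurationError(f"stage(s) missing from table: {missing}")
    return ComparisonDataset(
        name=comparison_name((first, second)),
        table=table.subset_samples(mask),
        positive_label=second,
    )


def make_comparisons(table: FeatureTable) -> list[ComparisonDataset]:
    """The five pairwise stage comparisons, in canonical order.

    Raises a configuration error naming any absent stage.
    """
    present = set(table.stages.unique())
    missing = [s for s in STAGES if s not in present]
    if missing:
        raise ConfigurationError(f"stage(s) missing from table: {missing}")
    return [pair_dataset(table, a, b) for a, b in COMPARISON_PAIRS]
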