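"""Labeled samples x metabolites intensity tables and their CSV dialect.

The on-disk format is a plain CSV whose first column is ``sample_id``, second
column ``stage`` and remaining columns one metabolite feature each.  Metabolite
names routinely contain commas, colons and parentheses (``"Cer(d18:1/24:1) i2"``),
so every non-numeric field -- headers included -- is quoted on write.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "FormatError", "read_table", "write_table"]

SAMPLE_COL = "sample_id"
STAGE_COL = "stage"


class FormatError(ValueError):
    """Raised when a table or file violates the documented format."""


@dataclass
class FeatureTable:
    """An intensity matrix (samples x metabolite features) with stage labels.

    Parameters
    ----------
    intensities : pandas.DataFrame
        Non-negative intensities; index = sample identifiers, columns =
        metabolite names (unique).
    stages : pandas.Series
        Per-sample stage label, aligned with ``intensities.index``.
    """

    intensities: pd.DataFrame
    stages: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.stages.index):
            self.stages = self.stages.reindex(self.intensities.index)
            if self.stages.isna().any():
                raise FormatError("stages index does not match intensities index")
        if self.intensities.columns.duplicated().any():
            dupes = self.intensities.columns[self.intensities.columns.duplicated()]
            raise FormatError(f"duplicate metabolite names: {sorted(set(dupes))}")
        if self.intensities.index.duplicated().any():
            dupes = self.intensities.index[self.intensities.index.duplicated()]
            raise FormatError(f"duplicate sample ids: {sorted(set(dupes))}")

    # -- basic protocol ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    def values(self) -> np.ndarray:
        return self.intensities.to_numpy(dtype=float)

    def subset_samples(self, mask_or_ids) -> "FeatureTable":
        sub = self.intensities.loc[mask_or_ids]
        return FeatureTable(sub, self.stages.loc[sub.index])

    def is_complete(self) -> bool:
        return not self.intensities.isna().any().any()

    def validate(self) -> None:
        """Check completeness and positivity; raise :class:`FormatError` if violated."""
        if not self.is_complete():
            bad = self.intensities.isna()
            row = bad.any(axis=1).idxmax()
            col = bad.loc[row].idxmax()
            raise FormatError(f"missing intensity for sample {row!r}, feature {col!r}")
        if (self.values() < 0).any():
            raise FormatError("negative intensities present")

    def __eq__(self, other: object) -> bool:  # frame equality, not identity
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.intensities.equals(other.intensities) and self.stages.equals(
            other.stages
        )


def write_table(table: FeatureTable, path) -> None:
    """Write a :class:`FeatureTable` to CSV with all text fields quoted."""
    frame = table.intensities.copy()
    frame.insert(0, STAGE_COL, table.stages)
    frame.index.name = SAMPLE_COL
    frame.to_csv(path, quoting=csv.QUOTE_NONNUMERIC)


def read_table(path) -> FeatureTable:
    """Read the documented CSV dialect back into a :class:`FeatureTable`.

    Raises
    ------
    FormatError
        If the label columns are missing, metabolite names repeat, or an
        intensity cell is empty or non-numeric (the offending sample and
        feature are named).
    """
    frame = pd.read_csv(path, index_col=0)
    if frame.index.name != SAMPLE_COL:
        raise FormatError(
            f"first column must be {SAMPLE_COL!r}, found {frame.index.name!r}"
        )
    if STAGE_COL not in frame.columns[:1]:
        raise FormatError(f"second column must be {STAGE_COL!r}")
    stages = frame[STAGE_COL].astype(str)
    intensities = frame.drop(columns=[STAGE_COL])
    for col in intensities.columns:
        converted = pd.to_numeric(intensities[col], errors="coerce")
        bad = converted.isna() & intensities[col].notna()
        if bad.any():
            raise FormatError(
                f"non-numeric intensity for sample {bad.idxmax()!r}, feature {col!r}"
            )
        if converted.isna().any():
            missing = converted.isna().idxmax()
            raise FormatError(
                f"missing intensity for sample {missing!r}, feature {col!r}"
            )
        intensities[col] = converted
    return FeatureTable(intensities, stages)
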