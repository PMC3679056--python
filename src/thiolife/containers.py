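"""Shared in-memory containers for the labeling-microarray pipeline.

The central object is :class:`IntensityMatrix`: per-feature hybridization
intensities with per-feature detection p-values across a set of arrays, each
array annotated with its RNA fraction (``total``, ``pre`` for pre-existing,
``new`` for newly synthesized), biological replicate, and condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The three RNA pools of a metabolic-labeling half-life design.
FRACTIONS = ("total", "pre", "new")

#: Required columns of the array-metadata table.
ARRAY_COLUMNS = ("fraction", "replicate", "condition")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class IntensityMatrix:
    """Features x arrays intensities with detection p-values and metadata.

    Parameters
    ----------
    intensity
        DataFrame of positive intensities, indexed by feature id, one column
        per array id.
    detection_p
        DataFrame of detection p-values in (0, 1], same shape/labels as
        ``intensity``.
    arrays
        DataFrame indexed by array id with columns ``fraction`` (one of
        ``total``/``pre``/``new``), ``replicate`` and ``condition``.
    """

    intensity: pd.DataFrame
    detection_p: pd.DataFrame
    arrays: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        idx = self.intensity.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise DataError(f"duplicate feature ids: {dups}")
        if self.intensity.columns.has_duplicates:
            dups = self.intensity.columns[
                self.intensity.columns.duplicated()
            ].unique().tolist()
            raise DataError(f"duplicate array ids: {dups}")
        if not self.detection_p.index.equals(idx) or not (
            self.detection_p.columns.equals(self.intensity.columns)
        ):
            raise DataError("intensity and detection_p labels do not match")
        missing = [
            a for a in self.intensity.columns if a not in self.arrays.index
        ]
        if missing:
            raise DataError(f"arrays missing from metadata: {missing}")
        for col in ARRAY_COLUMNS:
            if col not in self.arrays.columns:
                raise DataError(f"array metadata lacks column {col!r}")
        bad_frac = set(self.arrays["fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise DataError(f"unknown fraction labels: {sorted(bad_frac)}")

        inten = self.intensity.to_numpy(dtype=float)
        detp = self.detection_p.to_numpy(dtype=float)
        if not np.all(np.isfinite(inten)):
            raise DataError("non-finite or non-numeric intensity values")
        if np.any(inten[np.isfinite(detp)] <= 0):
            raise DataError("non-positive intensity where detection_p present")
        finite_p = detp[np.isfinite(detp)]
        if np.any((finite_p <= 0) | (finite_p > 1)):
            raise DataError("detection p-values must lie in (0, 1]")

    # -- convenience -----------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensity.index

    @property
    def array_ids(self) -> pd.Index:
        return self.intensity.columns

    @property
    def n_features(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.intensity.shape[1]

    def array_metadata(self) -> pd.DataFrame:
        """Metadata restricted (and ordered) to the arrays present."""
        return self.arrays.loc[self.array_ids]

    def subset_arrays(self, array_ids) -> "IntensityMatrix":
        return IntensityMatrix(
            self.intensity[list(array_ids)],
            self.detection_p[list(array_ids)],
            self.arrays.loc[list(array_ids)],
        )

    def subset_fraction(self, fraction: str) -> "IntensityMatrix":
        if fraction not in FRACTIONS:
            raise ValueError(f"unknown fraction {fraction!r}")
        meta = self.array_metadata()
        keep = meta.index[meta["fraction"] == fraction]
        return self.subset_arrays(keep)

    def subset_features(self, feature_ids) -> "IntensityMatrix":
        return IntensityMatrix(
            self.intensity.loc[list(feature_ids)],
            self.detection_p.loc[list(feature_ids)],
            self.arrays.copy(),
        )
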