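"""Reading and writing the pipeline's tab-separated file dialects.

An intensity table is a TSV with a ``feature_id`` column followed by two
columns per array, ``<array_id>_intensity`` and ``<array_id>_p``; array
metadata (fraction, replicate, condition) lives in a sidecar TSV keyed by
``array_id``. A GEO-series-matrix-like layout (feature rows, one intensity
column per sample) is also accepted when no ``_intensity`` suffixes are
present, in which case detection p-values default to the metadata-supplied
threshold pass (p = 1e-6).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import ARRAY_COLUMNS, DataError, IntensityMatrix

INTENSITY_SUFFIX = "_intensity"
DETECTION_SUFFIX = "_p"


def read_array_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "array_id" not in meta.columns:
        raise DataError(f"{path}: metadata needs an array_id column")
    missing = [c for c in ARRAY_COLUMNS if c not in meta.columns]
    if missing:
        raise DataError(f"{path}: metadata lacks columns {missing}")
    meta = meta.set_index("array_id")
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise DataError(f"{path}: duplicate array ids {dups}")
    meta["replicate"] = meta["replicate"].astype(int)
    return meta


def read_intensity_table(
    path: str | Path, metadata_path: str | Path
) -> IntensityMatrix:
    """Load an intensity TSV plus its array-metadata sidecar, validated."""
    table = pd.read_csv(path, sep="\t")
    if "feature_id" not in table.columns:
        raise DataError(f"{path}: needs a feature_id column")
    table["feature_id"] = table["feature_id"].astype(str)
    if table["feature_id"].duplicated().any():
        dups = table.loc[table["feature_id"].duplicated(), "feature_id"].tolist()
        raise DataError(f"{path}: duplicate feature ids {dups}")
    table = table.set_index("feature_id")
    meta = read_array_metadata(metadata_path)

    int_cols = [c for c in table.columns if c.endswith(INTENSITY_SUFFIX)]
    if int_cols:
        array_ids = [c[: -len(INTENSITY_SUFFIX)] for c in int_cols]
        intensity = table[int_cols].copy()
        intensity.columns = array_ids
        detection = pd.DataFrame(index=table.index)
        for a in array_ids:
            pcol = a + DETECTION_SUFFIX
            if pcol not in table.columns:
                raise DataError(f"{path}: missing detection column {pcol!r}")
            detection[a] = table[pcol]
    else:
        # series-matrix-like layout: every non-index column is an intensity
        intensity = table.copy()
        detection = pd.DataFrame(1e-6, index=table.index, columns=table.columns)

    non_numeric = [
        c for c in intensity.columns
        if not pd.api.types.is_numeric_dtype(intensity[c])
    ]
    if non_numeric:
        raise DataError(f"{path}: non-numeric intensity columns {non_numeric}")
    missing = [a for a in intensity.columns if a not in meta.index]
    if missing:
        raise DataError(f"{path}: arrays missing from metadata: {missing}")
    return IntensityMatrix(
        intensity.astype(float), detection.astype(float), meta
    )


def write_intensity_table(
    m: IntensityMatrix, path: str | Path, metadata_path: str | Path
) -> None:
    out = pd.DataFrame(index=m.feature_ids)
    for a in m.array_ids:
        out[a + INTENSITY_SUFFIX] = m.intensity[a]
        out[a + DETECTION_SUFFIX] = m.detection_p[a]
    out.to_csv(path, sep="\t", index_label="feature_id")
    m.array_metadata().to_csv(metadata_path, sep="\t", index_label="array_id")


def write_table(df: pd.DataFrame, path: str | Path, index_label="feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Two- or three-column annotation TSV: feature_id, term_id[, namespace]."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(ann.columns)
    if "feature_id" not in cols or "term_id" not in cols:
        if len(cols) in (2, 3):  # headerless fallback
            ann = pd.read_csv(path, sep="\t", header=None, dtype=str)
            ann.columns = ["feature_id", "term_id", "namespace"][: len(cols)]
        else:
            raise DataError(f"{path}: expected feature_id/term_id[/namespace]")
    return ann


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    table["gene"] = table["gene"].astype(str)
    return table
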