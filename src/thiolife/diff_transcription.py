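"""Condition-dependent de novo transcription from newly synthesized RNA.

Replicate new-RNA arrays per condition are pooled into a composite
intensity (inverse-variance-weighted mean with an error estimate from a
declared additive + multiplicative intensity error model), composites are
compared between conditions with a delta-method z-test on the log ratio,
and changes are called at a joint fold-change / p-value threshold. Fold
changes use the signed convention of published response tables: magnitude
>= 1, negative meaning decreased relative to the baseline condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DataError, IntensityMatrix

DEFAULT_FC_THRESHOLD = 1.7
DEFAULT_P_THRESHOLD = 1e-4


@dataclass(frozen=True)
class ErrorModelParams:
    """Additive + multiplicative intensity error model.

    Per-replicate model variance is ``sigma_add**2 + (epsilon * x)**2``:
    a constant background term plus a fractional term proportional to
    signal, the standard two-component model for one-color array
    intensities.
    """

    sigma_add: float = 10.0
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma_add < 0 or self.epsilon < 0:
            raise ValueError("error model parameters must be >= 0")
        if self.sigma_add == 0 and self.epsilon == 0:
            raise ValueError("sigma_add and epsilon cannot both be 0")

    def variance(self, x: np.ndarray) -> np.ndarray:
        return self.sigma_add**2 + (self.epsilon * np.asarray(x, dtype=float)) ** 2


def build_composite(
    replicates: pd.DataFrame | np.ndarray,
    params: ErrorModelParams | None = None,
) -> pd.DataFrame:
    """Pool replicate arrays into composite per-feature intensities.

    ``replicates`` is features x replicates. The composite mean is the
    inverse-variance-weighted mean under the error model; its variance is
    the larger of the model variance of that mean and the empirical
    variance of the mean (so observed replicate scatter can only widen the
    error). Returns columns ``mean``, ``se``, ``n``.
    """
    params = params or ErrorModelParams()
    x = np.asarray(replicates, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise DataError("composites need >= 2 replicate arrays")
    n = x.shape[1]
    v = params.variance(x)
    w = 1.0 / v
    mean = (w * x).sum(axis=1) / w.sum(axis=1)
    model_var = 1.0 / w.sum(axis=1)
    sample_var_of_mean = x.var(axis=1, ddof=1) / n
    var = np.maximum(model_var, sample_var_of_mean)
    index = (
        replicates.index
        if isinstance(replicates, pd.DataFrame)
        else pd.RangeIndex(x.shape[0])
    )
    return pd.DataFrame(
        {"mean": mean, "se": np.sqrt(var), "n": n}, index=index
    )


def ratio_significance(
    a: pd.DataFrame,
    b: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Delta-method z-test of composite b against composite a per feature.

    The log ratio L = ln(b/a) has variance se_a^2/mean_a^2 +
    se_b^2/mean_b^2 by the delta method; a two-sided normal p-value is
    attached and the signed fold change reported as b/a when >= 1 and
    -(a/b) otherwise. A feature is significant when |fold| >=
    ``fc_threshold`` AND p <= ``p_threshold`` (raw p; no multiplicity
    correction is applied in this analysis).
    """
    if not a.index.equals(b.index):
        raise DataError("composite tables must cover the same features")
    ma, mb = a["mean"].to_numpy(), b["mean"].to_numpy()
    if np.any(ma <= 0) or np.any(mb <= 0):
        raise DataError("composite means must be positive")
    sa, sb = a["se"].to_numpy(), b["se"].to_numpy()
    log_ratio = np.log(mb / ma)
    var_l = (sa / ma) ** 2 + (sb / mb) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(log_ratio == 0.0, 0.0, log_ratio / np.sqrt(var_l))
    p = 2.0 * stats.norm.sf(np.abs(z))
    ratio = mb / ma
    fold = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    significant = (np.abs(fold) >= fc_threshold) & (p <= p_threshold)
    return pd.DataFrame(
        {"fold_change": fold, "p_value": p, "significant": significant},
        index=a.index,
    )


def count_changes(diff: pd.DataFrame) -> tuple[int, int, int]:
    """(n_significant, n_up, n_down) over significant rows by fold sign."""
    if len(diff) == 0:
        return (0, 0, 0)
    sig = diff[diff["significant"].astype(bool)]
    n_up = int((sig["fold_change"] > 0).sum())
    n_down = int((sig["fold_change"] < 0).sum())
    return (len(sig), n_up, n_down)


def differential_transcription(
    mat_a: IntensityMatrix,
    mat_b: IntensityMatrix,
    params: ErrorModelParams | None = None,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Composite-and-ratio test between two new-RNA intensity matrices."""
    new_a = mat_a.subset_fraction("new")
    new_b = mat_b.subset_fraction("new")
    common = new_a.feature_ids.intersection(new_b.feature_ids)
    comp_a = build_composite(new_a.intensity.loc[common], params)
    comp_b = build_composite(new_b.intensity.loc[common], params)
    return ratio_significance(comp_a, comp_b, fc_threshold, p_threshold)


def load_response_table(
    timepoint: str,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Published nitrate-addition fold-change table as a DiffTable.

    ``timepoint`` is ``"1h"`` or ``"4h"``: array features with
    significantly different newly-synthesized RNA abundance during the
    first or fourth hour after nitrate addition to N-depleted K. brevis
    cultures, as printed (signed fold-change convention). The significance
    flag is recomputed from the stated thresholds.
    """
    if timepoint not in ("1h", "4h"):
        raise ValueError("timepoint must be '1h' or '4h'")
    path = resources.files("thiolife") / "data" / f"nitrate_response_{timepoint}.tsv"
    with resources.as_file(path) as fp:
        table = pd.read_csv(fp, sep="\t", dtype={"feature_id": str})
    table = table.set_index("feature_id")
    table["significant"] = (np.abs(table["fold_change"]) >= fc_threshold) & (
        table["p_value"] <= p_threshold
    )
    return table
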