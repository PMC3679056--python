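"""Closed-form half-life estimators from normalized fraction ratios.

With first-order decay at rate ``delta`` and steady state over a labeling
window ``t`` the three ratio forms give algebraically identical half-lives
``t_half = ln2 / delta``:

==========  =========================  ================================
kind        ratio r                    t_half
==========  =========================  ================================
``np``      new / pre = e^(dt) - 1     t * ln2 / ln(1 + r)
``nt``      new / total = 1 - e^(-dt)  -t * ln2 / ln(1 - r)
``pt``      pre / total = e^(-dt)      -t * ln2 / ln(r)
==========  =========================  ================================

Estimates are clamped to a [floor, ceiling] range (defaults 1 and 8640
minutes) with explicit cap flags. The ``np`` form is the primary estimator:
it combines the overall performance of ``nt`` with the short-half-life
precision of ``pt``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

KINDS = ("np", "nt", "pt")

DEFAULT_T_LABEL = 120.0
DEFAULT_FLOOR = 1.0
DEFAULT_CEILING = 8640.0

#: Default summary bin edges in minutes: 6 h, 12 h, 24 h, 48 h, 72 h, 144 h.
DEFAULT_BIN_EDGES = (0.0, 360.0, 720.0, 1440.0, 2880.0, 4320.0, 8640.0, math.inf)


@dataclass(frozen=True)
class HalfLifeEstimate:
    minutes: float
    capped_low: bool
    capped_high: bool


def _clamp(value: float, floor: float, ceiling: float) -> HalfLifeEstimate:
    if value < floor:
        return HalfLifeEstimate(floor, True, False)
    if value > ceiling:
        return HalfLifeEstimate(ceiling, False, True)
    return HalfLifeEstimate(float(value), False, False)


def halflife_from_ratio(
    ratio: float,
    kind: str,
    t_label: float = DEFAULT_T_LABEL,
    floor: float = DEFAULT_FLOOR,
    ceiling: float = DEFAULT_CEILING,
) -> HalfLifeEstimate:
    """Closed-form half-life (minutes) from one ratio, clamped to range.

    ``nt`` ratios >= 1 mean decay faster than measurable (pre-existing
    fraction indistinguishable from zero) and return the floor; ``pt``
    ratios >= 1 mean no measurable decay and return the ceiling.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}")
    if not (ratio > 0):
        raise ValueError(f"ratio must be positive, got {ratio}")
    if t_label <= 0:
        raise ValueError("t_label must be positive")
    if not 0 < floor < ceiling:
        raise ValueError("need 0 < floor < ceiling")

    if kind == "np":
        value = t_label * LN2 / math.log1p(ratio)
    elif kind == "nt":
        if ratio >= 1.0:
            return HalfLifeEstimate(floor, True, False)
        value = -t_label * LN2 / math.log1p(-ratio)
    else:  # pt
        if ratio >= 1.0:
            return HalfLifeEstimate(ceiling, False, True)
        value = -t_label * LN2 / math.log(ratio)
    return _clamp(value, floor, ceiling)


def _vector_estimates(
    ratio: np.ndarray, kind: str, t_label: float, floor: float, ceiling: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized counterpart of :func:`halflife_from_ratio`."""
    r = np.asarray(ratio, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "np":
            value = t_label * LN2 / np.log1p(r)
        elif kind == "nt":
            value = np.where(r >= 1.0, floor, -t_label * LN2 / np.log1p(-r))
        else:
            value = np.where(r >= 1.0, ceiling, -t_label * LN2 / np.log(r))
    capped_low = value < floor
    capped_high = value > ceiling
    if kind == "nt":
        capped_low |= r >= 1.0
    if kind == "pt":
        capped_high |= r >= 1.0
    return np.clip(value, floor, ceiling), capped_low, capped_high


def estimate_halflives(
    normalized: pd.DataFrame,
    t_label: float = DEFAULT_T_LABEL,
    floor: float = DEFAULT_FLOOR,
    ceiling: float = DEFAULT_CEILING,
) -> pd.DataFrame:
    """All three estimators for every kept feature of a normalized table.

    Expects columns ``n_norm``, ``p_norm``, ``np_ratio`` (and optionally a
    boolean ``kept`` which is applied first). Features whose ratios are not
    positive are dropped with a log entry. Returns a DataFrame with columns
    ``t_half_np``/``t_half_nt``/``t_half_pt`` plus capped flags per kind.
    """
    if not 0 < floor < ceiling:
        raise ValueError("need 0 < floor < ceiling")
    df = normalized
    if "kept" in df.columns:
        df = df[df["kept"].astype(bool)]
    ok = (df["np_ratio"] > 0) & (df["n_norm"] > 0) & (df["p_norm"] > 0)
    if (~ok).any():
        logger.warning(
            "dropping %d feature(s) with non-positive ratios: %s",
            int((~ok).sum()),
            list(df.index[~ok][:5]),
        )
        df = df[ok]

    out = pd.DataFrame(index=df.index)
    for kind, col in (("np", "np_ratio"), ("nt", "n_norm"), ("pt", "p_norm")):
        value, lo, hi = _vector_estimates(
            df[col].to_numpy(), kind, t_label, floor, ceiling
        )
        out[f"t_half_{kind}"] = value
        out[f"capped_low_{kind}"] = lo
        out[f"capped_high_{kind}"] = hi
    return out


@dataclass(frozen=True)
class HalfLifeSummary:
    n_features: int
    mean: float
    median: float
    min: float
    max: float
    bin_edges: tuple[float, ...]
    bin_fractions: tuple[float, ...]

    def as_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "mean_min": self.mean,
            "median_min": self.median,
            "min_min": self.min,
            "max_min": self.max,
            "mean_h": self.mean / 60.0,
            "median_h": self.median / 60.0,
        }


def summarize_halflives(
    table: pd.DataFrame,
    estimator: str = "np",
    bin_edges=DEFAULT_BIN_EDGES,
) -> HalfLifeSummary:
    """Distribution summary (minutes) of one estimator's half-lives."""
    if estimator not in KINDS:
        raise ValueError(f"estimator must be one of {KINDS}")
    if len(table) == 0:
        raise ValueError("empty half-life table")
    t = table[f"t_half_{estimator}"].to_numpy(dtype=float)
    edges = np.asarray(list(bin_edges), dtype=float)
    counts, _ = np.histogram(t, bins=edges)
    fractions = counts / len(t)
    return HalfLifeSummary(
        n_features=len(t),
        mean=float(np.mean(t)),
        median=float(np.median(t)),
        min=float(np.min(t)),
        max=float(np.max(t)),
        bin_edges=tuple(edges.tolist()),
        bin_fractions=tuple(fractions.tolist()),
    )


def estimator_concordance(
    table: pd.DataFrame, pair: tuple[str, str] = ("np", "nt")
) -> float:
    """Spearman rank correlation between two estimators' half-lives.

    Computed on the capped estimates (as a published half-life table would
    contain), ties mid-ranked. Raises on constant input, where rank
    correlation is undefined.
    """
    a, b = pair
    if a not in KINDS or b not in KINDS:
        raise ValueError(f"estimators must be among {KINDS}")
    if len(table) < 3:
        raise ValueError("need at least 3 features for a rank correlation")
    x = table[f"t_half_{a}"].to_numpy(dtype=float)
    y = table[f"t_half_{b}"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant estimator")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)
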