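"""Transcription-inhibition qPCR decay analysis.

Relative expression at each time point is the efficiency-corrected fold
change between inhibitor-treated and carrier-control samples,
``efficiency^-(Ct_treated - Ct_control)``. Under first-order decay the log
relative expression falls linearly through the origin (expression is 1 at
t = 0 by construction, since it is measured relative to time-matched
controls), so the decay rate is a through-origin least-squares slope and
``t_half = ln2 / delta``. A non-positive fitted rate is reported as "no
detectable decay" rather than a negative half-life.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)


def relative_expression(
    ct_treated: float, ct_control: float, efficiency: float = 2.0
) -> float:
    """Efficiency-corrected expression of treated relative to control."""
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must lie in (1, 2]")
    return float(efficiency ** -(ct_treated - ct_control))


@dataclass(frozen=True)
class DecayFit:
    gene: str
    t_half_min: float  # math.inf when no decay detected
    no_decay: bool
    r_squared: float
    n_used: int
    n_censored: int

    @property
    def t_half_h(self) -> float:
        return self.t_half_min / 60.0


def fit_decay_halflife(
    times_hours,
    rel_expr,
    gene: str = "gene",
    through_origin: bool = True,
) -> DecayFit:
    """Exponential decay fit of relative expression over time.

    Least squares of ``ln(rel_expr)`` on time (minutes), by default with
    the intercept fixed at 0: ``delta = -sum(t * ln y) / sum(t^2)``.
    Non-positive expression values (transcript undetected) are censored
    points, excluded with a log entry. With ``through_origin=False`` a
    free-intercept fit is used instead.
    """
    t = np.asarray(list(times_hours), dtype=float) * 60.0
    y = np.asarray(list(rel_expr), dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and rel_expr must have the same length")
    censored = ~(y > 0)
    if censored.any():
        logger.warning(
            "%s: excluding %d censored point(s) at t(h)=%s",
            gene,
            int(censored.sum()),
            (t[censored] / 60.0).tolist(),
        )
    t, y = t[~censored], y[~censored]
    if len(np.unique(t)) < 2:
        raise ValueError("need >= 2 distinct time points with detectable signal")
    ln_y = np.log(y)

    if through_origin:
        delta = -(t * ln_y).sum() / (t * t).sum()
        resid = ln_y + delta * t
        ss_tot = float((ln_y**2).sum())
    else:
        slope, intercept = np.polyfit(t, ln_y, 1)
        delta = -slope
        resid = ln_y - (intercept + slope * t)
        ss_tot = float(((ln_y - ln_y.mean()) ** 2).sum())
    ss_res = float((resid**2).sum())
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)

    if delta <= 0:
        return DecayFit(gene, math.inf, True, r2, len(t), int(censored.sum()))
    return DecayFit(gene, LN2 / delta, False, r2, len(t), int(censored.sum()))


def fit_qpcr_table(table: pd.DataFrame, through_origin: bool = True) -> pd.DataFrame:
    """Per-gene decay fits from a long qPCR table.

    Expects columns ``gene``, ``time_h``, ``ct_treated``, ``ct_control``,
    ``efficiency``. Replicate measurements at the same time point are
    averaged on the relative-expression scale before fitting.
    """
    required = {"gene", "time_h", "ct_treated", "ct_control", "efficiency"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"qPCR table lacks columns: {sorted(missing)}")
    rows = []
    for gene, grp in table.groupby("gene", sort=True):
        rel = np.array(
            [
                relative_expression(r.ct_treated, r.ct_control, r.efficiency)
                for r in grp.itertuples()
            ]
        )
        by_time = (
            pd.DataFrame({"time_h": grp["time_h"].to_numpy(), "rel": rel})
            .groupby("time_h", sort=True)["rel"]
            .mean()
        )
        fit = fit_decay_halflife(
            by_time.index, by_time.to_numpy(), gene=gene, through_origin=through_origin
        )
        rows.append(
            (
                gene,
                fit.t_half_min,
                fit.t_half_h,
                fit.no_decay,
                fit.r_squared,
                fit.n_used,
                fit.n_censored,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "t_half_min",
            "t_half_h",
            "no_decay",
            "r_squared",
            "n_used",
            "n_censored",
        ],
    ).set_index("gene")
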