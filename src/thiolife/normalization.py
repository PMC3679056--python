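"""Detection filtering, ratio formation and regression normalization.

The amount of template RNA differs between the total, pre-existing and
newly synthesized pools, so intensities are not directly comparable across
fractions. Because the two labeled pools sum to the total pool, the raw
ratios ``n = new/total`` and ``p = pre/total`` of every feature must fall on
a single straight line with negative slope; an ordinary least-squares fit of
``p`` on ``n`` recovers the unknown per-fraction scale factors:

    p = alpha + beta * n,  with  c_n = -beta/alpha,  c_p = 1/alpha

so that ``c_n * n + c_p * p = 1`` exactly on the fitted line. A probe
quality score (PQS) — the perpendicular distance of each feature from the
line in units of ``k`` times the robust spread of all distances — flags
unreliable probes; features with PQS > 1 are removed and the fit repeated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FRACTIONS, DataError, IntensityMatrix

logger = logging.getLogger(__name__)

REPLICATE_METHODS = ("mean", "median", "geometric_mean")


class NormalizationError(RuntimeError):
    """Regression normalization failed or is ill-posed."""


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of pre/total on new/total and the implied scale factors."""

    slope: float
    intercept: float
    c_n: float
    c_p: float
    dist_scale: float  # spread of perpendicular distances to the line
    n_points: int

    def perpendicular_distance(self, n_raw, p_raw) -> np.ndarray:
        resid = np.asarray(p_raw) - (self.intercept + self.slope * np.asarray(n_raw))
        return np.abs(resid) / math.sqrt(1.0 + self.slope**2)


def detection_filter(
    m: IntensityMatrix, p_threshold: float = 1e-4
) -> pd.Index:
    """Features detected (p <= threshold) on EVERY array, order preserved."""
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must lie in (0, 1]")
    ok = (m.detection_p.to_numpy() <= p_threshold).all(axis=1)
    kept = m.feature_ids[ok]
    if len(kept) == 0:
        logger.warning("detection filter at p<=%g removed every feature", p_threshold)
    return kept


def combine_replicates(
    m: IntensityMatrix, method: str = "median", condition: str | None = None
) -> pd.DataFrame:
    """Combine replicate arrays into one intensity per feature per fraction.

    Returns a DataFrame indexed like the matrix with columns ``total``,
    ``pre``, ``new``.
    """
    if method not in REPLICATE_METHODS:
        raise ValueError(f"method must be one of {REPLICATE_METHODS}")
    meta = m.array_metadata()
    if condition is not None:
        meta = meta[meta["condition"] == condition]
    out = {}
    for fraction in FRACTIONS:
        cols = meta.index[meta["fraction"] == fraction]
        if len(cols) == 0:
            raise DataError(f"no arrays for fraction {fraction!r}")
        x = m.intensity[list(cols)].to_numpy(dtype=float)
        if method == "mean":
            out[fraction] = x.mean(axis=1)
        elif method == "median":
            out[fraction] = np.median(x, axis=1)
        else:  # geometric mean
            out[fraction] = np.exp(np.log(x).mean(axis=1))
    return pd.DataFrame(out, index=m.feature_ids)


def compute_raw_ratios(combined: pd.DataFrame) -> pd.DataFrame:
    """Per-feature raw ratios n = new/total and p = pre/total.

    Features with non-positive total intensity are dropped with a logged
    reason.
    """
    for col in FRACTIONS:
        if col not in combined.columns:
            raise DataError(f"combined intensities lack column {col!r}")
    bad = combined.index[combined["total"] <= 0]
    if len(bad):
        logger.warning(
            "dropping %d feature(s) with non-positive total intensity: %s",
            len(bad),
            list(bad[:5]),
        )
    ok = combined.loc[combined["total"] > 0]
    return pd.DataFrame(
        {
            "n_raw": ok["new"] / ok["total"],
            "p_raw": ok["pre"] / ok["total"],
        },
        index=ok.index,
    )


def _york_fit(
    n: np.ndarray, p: np.ndarray, rho: float = 0.5, max_iter: int = 50
) -> tuple[float, float]:
    """Errors-in-variables straight-line fit (York's method).

    Both ratios carry multiplicative measurement error, and the shared
    total-fraction denominator correlates the two errors (correlation 1/2
    when the three pools are measured with equal log-noise). Per-point
    error SDs are therefore taken proportional to the measured values,
    sigma_x ~ n_i and sigma_y ~ p_i with correlation ``rho``; the common
    noise scale cancels from the weights. Plain OLS is inconsistent under
    this structure (regressor noise attenuates the slope), while the York
    solution is the maximum-likelihood line. Reduces to (weighted) OLS as
    regressor noise vanishes.
    """
    omega_x = 1.0 / np.maximum(n, 1e-12) ** 2
    omega_y = 1.0 / np.maximum(p, 1e-12) ** 2
    alpha_i = np.sqrt(omega_x * omega_y)
    b = stats.linregress(n, p).slope  # OLS start
    for _ in range(max_iter):
        w = omega_x * omega_y / (
            omega_x + b**2 * omega_y - 2.0 * b * rho * alpha_i
        )
        x_bar = (w * n).sum() / w.sum()
        y_bar = (w * p).sum() / w.sum()
        u = n - x_bar
        v = p - y_bar
        beta_i = w * (
            u / omega_y + b * v / omega_x - (b * u + v) * rho / alpha_i
        )
        b_new = (w * beta_i * v).sum() / (w * beta_i * u).sum()
        if abs(b_new - b) <= 1e-12 * max(1.0, abs(b)):
            b = b_new
            break
        b = b_new
    a = y_bar - b * x_bar
    return float(b), float(a)


def fit_normalization(ratios: pd.DataFrame, method: str = "eiv") -> RegressionFit:
    """Straight-line fit of p_raw on n_raw; scale factors from the line.

    ``method="eiv"`` (default) uses an errors-in-variables York fit with a
    multiplicative error structure — appropriate because both ratios are
    noisy and share the total-fraction denominator, which attenuates a
    naive OLS slope. ``method="ols"`` gives plain least squares of p on n.
    Both coincide on noiseless (exactly collinear) data. Raises
    :class:`NormalizationError` when the fit is ill-posed or the fractions
    are not complementary (slope >= 0 or intercept <= 0).
    """
    if method not in ("eiv", "ols"):
        raise ValueError("method must be 'eiv' or 'ols'")
    if len(ratios) < 3:
        raise NormalizationError("need at least 3 features to fit normalization")
    n = ratios["n_raw"].to_numpy(dtype=float)
    p = ratios["p_raw"].to_numpy(dtype=float)
    if np.ptp(n) == 0.0:
        raise NormalizationError("degenerate regression: n_raw is constant")
    if method == "ols":
        res = stats.linregress(n, p)
        beta, alpha = float(res.slope), float(res.intercept)
    else:
        beta, alpha = _york_fit(n, p)
    if not (np.isfinite(beta) and np.isfinite(alpha)):
        raise NormalizationError("regression produced non-finite coefficients")
    if beta >= 0 or alpha <= 0:
        raise NormalizationError(
            "fractions not complementary: expected negative slope and "
            f"positive intercept, got slope={beta:.4g}, intercept={alpha:.4g}"
        )
    # spread of the signed perpendicular distances (their mean is ~0, so
    # this is the SD of the distance distribution, not of |d|)
    d_signed = (p - (alpha + beta * n)) / math.sqrt(1.0 + beta**2)
    return RegressionFit(
        slope=beta,
        intercept=alpha,
        c_n=-beta / alpha,
        c_p=1.0 / alpha,
        dist_scale=float(np.std(d_signed)),
        n_points=len(n),
    )


def compute_pqs(
    ratios: pd.DataFrame, fit: RegressionFit, k: float = 3.0
) -> pd.Series:
    """Probe quality score: perpendicular distance in units of k * sigma_d.

    A PQS of 1 therefore sits ``k`` spread-units from the regression line.
    With ``dist_scale == 0`` any off-line feature scores infinity.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    d = fit.perpendicular_distance(ratios["n_raw"], ratios["p_raw"])
    # distances at the float rounding level of the fitted line count as zero,
    # so exactly collinear (noiseless) data is never filtered
    tol = 1e-12 * (abs(fit.intercept) + abs(fit.slope) + 1.0)
    d = np.where(d <= tol, 0.0, d)
    if fit.dist_scale <= tol:
        pqs = np.where(d > 0, np.inf, 0.0)
    else:
        pqs = d / (k * fit.dist_scale)
    return pd.Series(pqs, index=ratios.index, name="pqs")


def normalize_iterative(
    ratios: pd.DataFrame, k: float = 3.0, max_iter: int = 2, method: str = "eiv"
) -> tuple[pd.DataFrame, RegressionFit, pd.DataFrame]:
    """Iterated fit / score / filter cycle, then apply the final fit.

    Each iteration fits the regression on surviving features, scores every
    survivor, and removes those with PQS > 1; the loop stops when an
    iteration removes nothing or after ``max_iter`` rounds. The fit of the
    last executed iteration defines the normalized ratios, so every kept
    feature has PQS <= 1 under the reported fit.

    Returns ``(normalized, fit, removal_log)`` where ``normalized`` has
    columns ``n_norm``, ``p_norm``, ``np_ratio``, ``pqs``, ``kept`` over all
    input features and ``removal_log`` lists (feature_id, iteration, pqs).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    kept_idx = ratios.index
    removals: list[tuple[str, int, float]] = []
    fit: RegressionFit | None = None
    pqs_final: pd.Series | None = None
    for iteration in range(1, max_iter + 1):
        if len(kept_idx) < 3:
            raise NormalizationError(
                f"fewer than 3 features remain at iteration {iteration}"
            )
        sub = ratios.loc[kept_idx]
        fit = fit_normalization(sub, method=method)
        pqs_final = compute_pqs(sub, fit, k=k)
        out = pqs_final.index[pqs_final > 1.0]
        if len(out) == 0:
            break
        for fid in out:
            removals.append((fid, iteration, float(pqs_final[fid])))
        kept_idx = kept_idx.difference(out, sort=False)
    assert fit is not None and pqs_final is not None
    kept_idx = pqs_final.index[pqs_final <= 1.0]

    n_norm = fit.c_n * ratios["n_raw"]
    p_norm = fit.c_p * ratios["p_raw"]
    pqs_all = compute_pqs(ratios, fit, k=k)
    normalized = pd.DataFrame(
        {
            "n_norm": n_norm,
            "p_norm": p_norm,
            "np_ratio": n_norm / p_norm,
            "pqs": pqs_all,
            "kept": ratios.index.isin(kept_idx),
        },
        index=ratios.index,
    )
    nonpos = normalized.index[
        normalized["kept"] & ((normalized["n_norm"] <= 0) | (normalized["p_norm"] <= 0))
    ]
    if len(nonpos):
        logger.warning(
            "dropping %d feature(s) with non-positive normalized ratios: %s",
            len(nonpos),
            list(nonpos[:5]),
        )
        normalized.loc[nonpos, "kept"] = False
    removal_log = pd.DataFrame(
        removals, columns=["feature_id", "iteration", "pqs"]
    )
    return normalized, fit, removal_log
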