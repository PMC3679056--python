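"""Stability-class GO-term enrichment against the array background.

Features are binned by half-life, and each term annotated on the array is
tested for over-representation in the bin with a one-sided Fisher's exact
(hypergeometric) test against all arrayed features, followed by
Benjamini-Hochberg FDR control. Terms are tested exactly as annotated; no
GO-graph ancestor propagation is performed (slim mappings are an upstream
concern).
"""

from __future__ import annotations

import math
from collections.abc import Collection

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import DataError

NAMESPACES = ("P", "F", "C")


def bin_features(
    table: pd.DataFrame,
    lower: float,
    upper: float = math.inf,
    estimator: str = "np",
) -> pd.Index:
    """Features whose half-life lies in the half-open bin [lower, upper)."""
    if not lower < upper:
        raise ValueError("need lower < upper")
    t = table[f"t_half_{estimator}"]
    return table.index[(t >= lower) & (t < upper)]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    study: Collection[str],
    background: Collection[str],
    annotations: pd.DataFrame,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-term enrichment of the study set relative to the background.

    ``annotations`` is a long table with columns ``feature_id``,
    ``term_id`` and optionally ``namespace``. Only annotations of
    background features count. Returns one row per term with the 2x2
    counts (a = study & term, b = study w/o term, c = background & term,
    d = background w/o term), the one-sided hypergeometric p-value (or
    two-sided Fisher p with ``alternative="two-sided"``) and the BH-FDR
    q-value, sorted by (fdr, p).
    """
    study_set = set(study)
    bg_set = set(background)
    if not study_set <= bg_set:
        extra = sorted(study_set - bg_set)[:5]
        raise DataError(f"study features not in background: {extra}")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    if "feature_id" not in annotations or "term_id" not in annotations:
        raise DataError("annotations need feature_id and term_id columns")

    ann = annotations[annotations["feature_id"].isin(bg_set)]
    ann = ann.drop_duplicates(subset=["feature_id", "term_id"])
    if "namespace" not in ann.columns:
        ann = ann.assign(namespace="P")

    n_study = len(study_set)
    n_bg = len(bg_set)
    rows = []
    for (term, namespace), grp in ann.groupby(["term_id", "namespace"], sort=True):
        members = set(grp["feature_id"])
        a = len(members & study_set)
        c = len(members)
        rows.append((term, namespace, a, n_study - a, c, n_bg - c))
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "namespace", "a", "b", "c", "d", "p_one_sided", "fdr"]
        )
    out = pd.DataFrame(rows, columns=["term_id", "namespace", "a", "b", "c", "d"])

    if alternative == "greater":
        # P(X >= a) drawing n_study from n_bg with c successes
        out["p_one_sided"] = stats.hypergeom.sf(
            out["a"] - 1, n_bg, out["c"], n_study
        )
    else:
        out["p_one_sided"] = [
            stats.fisher_exact([[r.a, r.b], [r.c - r.a, r.d - r.b]]).pvalue
            for r in out.itertuples()
        ]
    out["p_one_sided"] = out["p_one_sided"].clip(0.0, 1.0)
    out["fdr"] = bh_fdr(out["p_one_sided"])
    return out.sort_values(["fdr", "p_one_sided", "term_id"]).reset_index(drop=True)
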