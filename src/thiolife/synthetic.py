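"""Ground-truthed simulation of 4-thiouracil labeling microarray experiments.

Under steady state, RNA synthesis balances first-order decay, so after a
labeling window of ``t_label`` minutes a transcript with decay rate
``delta = ln2 / t_half`` partitions into

* pre-existing fraction  ``P/T = exp(-delta * t_label)``
* newly synthesized fraction  ``N/T = 1 - P/T``

of its (constant) total abundance. The generator draws log-normal true
half-lives, forms the three RNA pools, mixes them through an imperfect
bead-separation model, scales each fraction by a hidden per-fraction factor
(the amount of template RNA differs between pools, so array intensities are
not directly comparable across fractions), applies multiplicative log-normal
array noise plus an additive background, and attaches monotone detection
p-values. Every simulator takes an explicit seed; there is no global random
state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .containers import FRACTIONS, DataError, IntensityMatrix

LN2 = math.log(2.0)

# Each simulator seeds its generator as default_rng([stream, seed]) with a
# distinct stream id, so passing the same seed to different simulators never
# replays the same underlying random stream.
_STREAM_HALFLIVES = 11
_STREAM_INTENSITY = 12
_STREAM_ANNOTATION = 13
_STREAM_RESPONSE = 14
_STREAM_QPCR = 15

#: Hidden per-fraction scale factors emulating unequal template amounts.
DEFAULT_SCALE_FACTORS = {"total": 1.0, "pre": 1.3, "new": 0.25}

#: Detection p-values are floored here so they stay inside (0, 1].
DETECTION_P_FLOOR = 1e-6


class ParameterError(ValueError):
    """Simulation parameter outside its valid range."""


# ---------------------------------------------------------------------------
# parameter bundles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelingDesign:
    """Layout of a labeling experiment.

    ``t_label`` is the 4tU exposure in minutes (default 120 = 2 h);
    ``n_replicates`` biological replicates per fraction (default 6).
    """

    t_label: float = 120.0
    n_replicates: int = 6
    conditions: tuple[str, ...] = ("steady_state",)

    def __post_init__(self) -> None:
        if self.t_label <= 0:
            raise ParameterError("t_label must be positive")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")
        if len(self.conditions) < 1:
            raise ParameterError("at least one condition label required")


@dataclass(frozen=True)
class ContaminationModel:
    """Imperfect streptavidin separation of labeled from unlabeled RNA.

    ``capture_efficiency``: fraction of labeled RNA recovered in the new
    pool. ``carryover``: fraction of unlabeled RNA contaminating the new
    pool (non-specific bead binding). ``leakage``: fraction of labeled RNA
    remaining in the pre-existing pool (incomplete capture). Carryover
    contaminates the new pool without depleting the pre pool: pool amounts
    are relative and the hidden scale factors absorb overall mass.
    """

    capture_efficiency: float = 0.95
    carryover: float = 0.01
    leakage: float = 0.02

    def __post_init__(self) -> None:
        for name in ("capture_efficiency", "carryover", "leakage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")

    @classmethod
    def off(cls) -> "ContaminationModel":
        """Perfect separation (identity mixing)."""
        return cls(capture_efficiency=1.0, carryover=0.0, leakage=0.0)


def _default_detect_p(intensity: np.ndarray, background: float) -> np.ndarray:
    """Monotone-decreasing detection p-value: p = clip(bg / x, 1e-6, 1)."""
    with np.errstate(divide="ignore"):
        p = np.where(intensity > 0, background / np.maximum(intensity, 1e-300), 1.0)
    return np.clip(p, DETECTION_P_FLOOR, 1.0)


@dataclass(frozen=True)
class NoiseModel:
    """Per-array measurement noise and detection model.

    ``lognormal_sd`` is the SD of log-intensity noise; ``background`` an
    additive positive intensity floor that also sets the detection scale.
    """

    lognormal_sd: float = 0.2
    background: float = 0.01
    seed: int = 0
    detect_p_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.lognormal_sd < 0:
            raise ParameterError("lognormal_sd must be >= 0")
        if self.background < 0:
            raise ParameterError("background must be >= 0")

    @classmethod
    def off(cls, seed: int = 0) -> "NoiseModel":
        return cls(lognormal_sd=0.0, background=0.0, seed=seed)

    def detection_p(self, intensity: np.ndarray) -> np.ndarray:
        if self.detect_p_fn is not None:
            return np.asarray(self.detect_p_fn(intensity), dtype=float)
        return _default_detect_p(intensity, self.background)


@dataclass(frozen=True)
class ResponseSpec:
    """Composition of a two-condition transcriptional-response simulation.

    ``frac_transcriptionally_up``/``down`` features change their de novo
    synthesis rate by ``effect_fold``; ``frac_stabilized`` features change
    total abundance with NO change in the newly synthesized pool (the
    post-transcriptional stabilization scenario).
    """

    frac_transcriptionally_up: float = 0.0
    frac_transcriptionally_down: float = 0.0
    effect_fold: float = 3.0
    frac_stabilized: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "frac_transcriptionally_up",
            "frac_transcriptionally_down",
            "frac_stabilized",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        total = (
            self.frac_transcriptionally_up
            + self.frac_transcriptionally_down
            + self.frac_stabilized
        )
        if total > 1.0:
            raise ParameterError("response fractions must sum to <= 1")
        if self.effect_fold <= 1.0:
            raise ParameterError("effect_fold must be > 1")


@dataclass
class SimulationTruth:
    """Hidden ground truth recorded alongside a simulated experiment."""

    kinetics: pd.DataFrame
    scale_factors: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------


def simulate_true_halflives(
    n_features: int,
    median_minutes: float = 1998.0,
    log_sd: float = 1.0,
    seed: int = 0,
    abundance_median: float = 1e5,
    abundance_log_sd: float = 0.5,
) -> pd.DataFrame:
    """Draw per-feature true half-lives and steady-state abundances.

    Half-lives are log-normal with the stated *median* (the log-normal
    median is ``exp(mu)``, so ``mu = ln(median_minutes)``); abundances are
    an independent log-normal in arbitrary intensity units. The default
    median of 1998 min (33.3 h) reflects an unusually stable dinoflagellate
    transcriptome.

    Returns a DataFrame indexed by ``feature_id`` with columns
    ``t_half_true`` (minutes) and ``abundance``.
    """
    if n_features < 1:
        raise ParameterError("n_features must be >= 1")
    if median_minutes <= 0:
        raise ParameterError("median_minutes must be positive")
    if log_sd < 0:
        raise ParameterError("log_sd must be >= 0")
    rng = np.random.default_rng([_STREAM_HALFLIVES, seed])
    t_half = median_minutes * np.exp(log_sd * rng.standard_normal(n_features))
    abundance = abundance_median * np.exp(
        abundance_log_sd * rng.standard_normal(n_features)
    )
    idx = pd.Index(
        [f"F{i:05d}" for i in range(1, n_features + 1)], name="feature_id"
    )
    return pd.DataFrame(
        {"t_half_true": t_half, "abundance": abundance}, index=idx
    )


def true_fractions(
    t_half: np.ndarray | pd.Series, t_label: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact steady-state (new, pre) fractions of total for given half-lives."""
    delta = LN2 / np.asarray(t_half, dtype=float)
    frac_pre = np.exp(-delta * t_label)
    frac_new = -np.expm1(-delta * t_label)
    return frac_new, frac_pre


def _pool_amounts(
    kin: pd.DataFrame, t_label: float, contam: ContaminationModel
) -> pd.DataFrame:
    """Relative pool amounts (before scaling/noise) per feature."""
    frac_new, frac_pre = true_fractions(kin["t_half_true"], t_label)
    abundance = kin["abundance"].to_numpy(dtype=float)
    new_pool = contam.capture_efficiency * frac_new + contam.carryover * frac_pre
    pre_pool = frac_pre + contam.leakage * frac_new
    return pd.DataFrame(
        {
            "total": abundance,
            "pre": abundance * pre_pool,
            "new": abundance * new_pool,
            "frac_new_true": frac_new,
            "frac_pre_true": frac_pre,
        },
        index=kin.index,
    )


def simulate_fraction_intensities(
    kin: pd.DataFrame,
    design: LabelingDesign | None = None,
    contam: ContaminationModel | None = None,
    noise: NoiseModel | None = None,
    scale_factors: Mapping[str, float] | None = None,
    condition: str | None = None,
) -> tuple[IntensityMatrix, SimulationTruth]:
    """Simulate the three-fraction array set for a half-life experiment.

    Emits ``n_replicates`` arrays per fraction per condition. Returns the
    intensity matrix plus a truth sidecar holding per-feature kinetics, the
    exact fractions, and the hidden per-fraction scale factors.
    """
    design = design or LabelingDesign()
    contam = contam or ContaminationModel()
    noise = noise or NoiseModel()
    scale = dict(scale_factors or DEFAULT_SCALE_FACTORS)
    if set(scale) != set(FRACTIONS):
        raise ParameterError(f"scale_factors must have keys {FRACTIONS}")
    for col in ("t_half_true", "abundance"):
        if col not in kin.columns:
            raise DataError(f"kinetics table lacks column {col!r}")
        if kin[col].isna().any():
            bad = kin.index[kin[col].isna()].tolist()
            raise DataError(f"missing kinetics for features: {bad[:5]}")

    pools = _pool_amounts(kin, design.t_label, contam)
    rng = np.random.default_rng([_STREAM_INTENSITY, noise.seed])
    conditions = (condition,) if condition is not None else design.conditions

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for cond in conditions:
        for fraction in FRACTIONS:
            base = scale[fraction] * pools[fraction].to_numpy()
            for rep in range(1, design.n_replicates + 1):
                if noise.lognormal_sd > 0:
                    jitter = np.exp(
                        noise.lognormal_sd * rng.standard_normal(len(base))
                    )
                else:
                    jitter = 1.0
                array_id = (
                    f"{fraction}_r{rep}"
                    if len(conditions) == 1
                    else f"{cond}_{fraction}_r{rep}"
                )
                columns[array_id] = base * jitter + noise.background
                meta_rows.append((array_id, fraction, rep, cond))

    intensity = pd.DataFrame(columns, index=kin.index)
    detection_p = pd.DataFrame(
        {a: noise.detection_p(intensity[a].to_numpy()) for a in intensity},
        index=kin.index,
    )
    arrays = pd.DataFrame(
        meta_rows, columns=["array_id", "fraction", "replicate", "condition"]
    ).set_index("array_id")

    truth = SimulationTruth(
        kinetics=pd.concat(
            [kin, pools[["frac_new_true", "frac_pre_true"]]], axis=1
        ),
        scale_factors=scale,
    )
    return IntensityMatrix(intensity, detection_p, arrays), truth


# default stability classes used when over-assigning annotation terms
DEFAULT_STABILITY_CLASSES = {
    "<6 h": (0.0, 360.0),
    "6 h - 3 d": (360.0, 4320.0),
    ">=3 d": (4320.0, math.inf),
}

_NAMESPACES = ("P", "F", "C")


def stability_class_of(
    t_half: np.ndarray | pd.Series,
    classes: Mapping[str, tuple[float, float]] | None = None,
) -> pd.Series:
    """Assign each half-life to its [lower, upper) stability class."""
    classes = classes or DEFAULT_STABILITY_CLASSES
    t = pd.Series(np.asarray(t_half, dtype=float), index=getattr(t_half, "index", None))
    out = pd.Series("", index=t.index, dtype=object)
    for name, (lo, hi) in classes.items():
        out[(t >= lo) & (t < hi)] = name
    return out


def simulate_annotations(
    kin: pd.DataFrame,
    n_terms: int,
    enriched_term_spec: Mapping[str, tuple[str, float]] | None = None,
    seed: int = 0,
    base_p: float = 0.05,
    classes: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Assign GO-like terms to features, optionally enriched in a class.

    Every feature independently receives each term with probability
    ``base_p``; a term listed in ``enriched_term_spec`` as
    ``term -> (stability class, odds multiplier)`` is assigned with
    probability ``min(1, base_p * multiplier)`` to features in that class.
    Returns a long DataFrame with columns ``feature_id``, ``term_id``,
    ``namespace``.
    """
    if n_terms < 0:
        raise ParameterError("n_terms must be >= 0")
    classes = classes or DEFAULT_STABILITY_CLASSES
    enriched = dict(enriched_term_spec or {})
    for term, (cls, mult) in enriched.items():
        if cls not in classes:
            raise ParameterError(f"unknown stability class {cls!r} for {term}")
        if mult <= 0:
            raise ParameterError("odds multiplier must be positive")

    rng = np.random.default_rng([_STREAM_ANNOTATION, seed])
    feature_class = stability_class_of(kin["t_half_true"], classes)
    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    namespaces = rng.choice(_NAMESPACES, size=n_terms)

    rows: list[tuple[str, str, str]] = []
    for term, ns in zip(terms, namespaces):
        p = np.full(len(kin), base_p)
        if term in enriched:
            cls, mult = enriched[term]
            p = np.where(feature_class == cls, min(1.0, base_p * mult), p)
        hit = rng.random(len(kin)) < p
        for fid in kin.index[hit]:
            rows.append((fid, term, ns))
    return pd.DataFrame(rows, columns=["feature_id", "term_id", "namespace"])


def simulate_response_experiment(
    kin: pd.DataFrame,
    design: LabelingDesign | None = None,
    spec: ResponseSpec | None = None,
    noise: NoiseModel | None = None,
    scale_factor: float = DEFAULT_SCALE_FACTORS["new"],
    seed: int | None = None,
) -> tuple[IntensityMatrix, IntensityMatrix, pd.DataFrame]:
    """Simulate newly-synthesized-RNA pools for a two-condition design.

    Condition A is the baseline (e.g. nutrient-depleted) culture, condition
    B the treated one (e.g. after nitrate addition). Transcriptionally
    changed features have their new-pool synthesis multiplied (up) or
    divided (down) by ``effect_fold``; stabilized features change total
    abundance but not the newly synthesized pool, so they look identical in
    these matrices. Returns (matrix_a, matrix_b, truth) with truth column
    ``response_class`` in {none, up, down, stabilized}.
    """
    design = design or LabelingDesign(n_replicates=3, conditions=("depleted", "added"))
    spec = spec or ResponseSpec()
    noise = noise or NoiseModel()
    if design.n_replicates < 2:
        raise ParameterError("response designs need >= 2 replicates per condition")
    rng = np.random.default_rng(
        [_STREAM_RESPONSE, noise.seed if seed is None else seed]
    )

    n = len(kin)
    n_up = int(round(spec.frac_transcriptionally_up * n))
    n_down = int(round(spec.frac_transcriptionally_down * n))
    n_stab = int(round(spec.frac_stabilized * n))
    order = rng.permutation(n)
    response_class = np.full(n, "none", dtype=object)
    response_class[order[:n_up]] = "up"
    response_class[order[n_up : n_up + n_down]] = "down"
    response_class[order[n_up + n_down : n_up + n_down + n_stab]] = "stabilized"

    frac_new, _ = true_fractions(kin["t_half_true"], design.t_label)
    base = scale_factor * kin["abundance"].to_numpy() * frac_new
    effect = np.ones(n)
    effect[response_class == "up"] = spec.effect_fold
    effect[response_class == "down"] = 1.0 / spec.effect_fold

    def build(cond: str, synth: np.ndarray) -> IntensityMatrix:
        cols: dict[str, np.ndarray] = {}
        meta = []
        for rep in range(1, design.n_replicates + 1):
            if noise.lognormal_sd > 0:
                jitter = np.exp(noise.lognormal_sd * rng.standard_normal(n))
            else:
                jitter = 1.0
            aid = f"{cond}_new_r{rep}"
            cols[aid] = synth * jitter + noise.background
            meta.append((aid, "new", rep, cond))
        intensity = pd.DataFrame(cols, index=kin.index)
        detp = pd.DataFrame(
            {a: noise.detection_p(intensity[a].to_numpy()) for a in intensity},
            index=kin.index,
        )
        arrays = pd.DataFrame(
            meta, columns=["array_id", "fraction", "replicate", "condition"]
        ).set_index("array_id")
        return IntensityMatrix(intensity, detp, arrays)

    cond_a, cond_b = design.conditions[0], design.conditions[-1]
    mat_a = build(cond_a, base)
    mat_b = build(cond_b, base * effect)
    truth = kin.copy()
    truth["response_class"] = response_class
    truth["effect_applied"] = effect
    return mat_a, mat_b, truth


def simulate_qpcr(
    t_half: float,
    times_hours,
    efficiency: float = 2.0,
    ct_sd: float = 0.0,
    seed: int = 0,
    gene: str = "gene",
    ct_control: float = 20.0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Simulate a transcription-inhibition qPCR time course.

    Control Ct is constant; the treated Ct satisfies
    ``efficiency^-(ct_treated - ct_control) = exp(-ln2 * t / t_half)`` plus
    Gaussian Ct noise, i.e. first-order decay relative to time-matched
    carrier controls. Times are in hours; ``t_half`` in minutes.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ParameterError("efficiency must lie in (1, 2]")
    if t_half <= 0:
        raise ParameterError("t_half must be positive")
    times = np.asarray(list(times_hours), dtype=float)
    if np.any(times < 0):
        raise ParameterError("times must be >= 0")
    rng = np.random.default_rng([_STREAM_QPCR, seed])
    rows = []
    for t_h in times:
        # exp(-ln2 * t/t_half) = eff^-dct  =>  dct = ln2*(t/t_half)/ln(eff)
        dct = LN2 * (t_h * 60.0 / t_half) / math.log(efficiency)
        for _ in range(n_replicates):
            noise_ct = ct_sd * rng.standard_normal() if ct_sd > 0 else 0.0
            rows.append(
                (gene, t_h, ct_control + dct + noise_ct, ct_control, efficiency)
            )
    return pd.DataFrame(
        rows, columns=["gene", "time_h", "ct_treated", "ct_control", "efficiency"]
    )
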