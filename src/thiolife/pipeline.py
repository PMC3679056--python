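"""Pipeline configuration and the end-to-end half-life run.

A :class:`PipelineConfig` holds every stage parameter with defaults equal
to the study settings (2 h labeling, detection p <= 1e-4 on all arrays,
PQS cut at k = 3 with one repeat, half-life caps 1-8640 min, primary
estimator new/pre). Configs load from a flat key-value YAML file; unknown
keys are rejected, and CLI flags override config values.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, enrichment, halflife, io, normalization

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    intensities: str = ""
    arrays: str = ""
    annotations: str = ""
    out_dir: str = "thiolife_out"
    p_threshold: float = 1e-4
    replicate_method: str = "median"
    pqs_k: float = 3.0
    max_iter: int = 2
    t_label_min: float = 120.0
    floor_min: float = 1.0
    ceiling_min: float = 8640.0
    estimator: str = "np"
    bin_lower_min: float = 4320.0
    bin_upper_min: float = math.inf
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ConfigError("p_threshold must lie in (0, 1]")
        if self.replicate_method not in normalization.REPLICATE_METHODS:
            raise ConfigError(
                f"replicate_method must be one of {normalization.REPLICATE_METHODS}"
            )
        if self.pqs_k <= 0:
            raise ConfigError("pqs_k must be positive")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if self.t_label_min <= 0:
            raise ConfigError("t_label_min must be positive")
        if not 0 < self.floor_min < self.ceiling_min:
            raise ConfigError("need 0 < floor_min < ceiling_min")
        if self.estimator not in halflife.KINDS:
            raise ConfigError(f"estimator must be one of {halflife.KINDS}")
        if not self.bin_lower_min < self.bin_upper_min:
            raise ConfigError("need bin_lower_min < bin_upper_min")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if raw.get("bin_upper_min") in ("inf", ".inf"):
            raw["bin_upper_min"] = math.inf
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Detection filter -> normalization -> half-lives -> summaries
    (-> enrichment when annotations are given), writing all artifacts.

    Returns a dict of in-memory results; files land under
    ``config.out_dir``.
    """
    if not config.intensities or not config.arrays:
        raise ConfigError("config must name intensities and arrays paths")
    for path in (config.intensities, config.arrays):
        if not Path(path).exists():
            raise ConfigError(f"input path does not exist: {path}")
    if config.annotations and not Path(config.annotations).exists():
        raise ConfigError(f"input path does not exist: {config.annotations}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
            raise RuntimeError(f"[{name}] {exc}") from exc

    matrix = stage("read", io.read_intensity_table, config.intensities, config.arrays)
    detected = stage(
        "detection_filter", normalization.detection_filter, matrix, config.p_threshold
    )
    matrix_f = matrix.subset_features(detected)
    combined = stage(
        "combine_replicates",
        normalization.combine_replicates,
        matrix_f,
        config.replicate_method,
    )
    ratios = stage("compute_raw_ratios", normalization.compute_raw_ratios, combined)
    normalized, fit, removal_log = stage(
        "normalize_iterative",
        normalization.normalize_iterative,
        ratios,
        config.pqs_k,
        config.max_iter,
    )
    halflives = stage(
        "estimate_halflives",
        halflife.estimate_halflives,
        normalized,
        config.t_label_min,
        config.floor_min,
        config.ceiling_min,
    )
    summary = stage(
        "summarize", halflife.summarize_halflives, halflives, config.estimator
    )

    io.write_table(normalized, out_dir / "normalized_ratios.tsv")
    io.write_table(
        removal_log.set_index("feature_id"), out_dir / "removal_log.tsv"
    )
    hl_out = halflives.copy()
    for kind in halflife.KINDS:
        hl_out[f"t_half_{kind}_h"] = hl_out[f"t_half_{kind}"] / 60.0
    io.write_table(hl_out, out_dir / "halflives.tsv")

    results: dict = {
        "matrix": matrix,
        "n_detected": len(detected),
        "normalized": normalized,
        "fit": fit,
        "removal_log": removal_log,
        "halflives": halflives,
        "summary": summary,
    }

    if config.annotations:
        ann = stage("read_annotations", io.read_annotations, config.annotations)
        study = stage(
            "bin_features",
            enrichment.bin_features,
            halflives,
            config.bin_lower_min,
            config.bin_upper_min,
            config.estimator,
        )
        enr = stage(
            "fisher_enrichment",
            enrichment.fisher_enrichment,
            study,
            halflives.index,
            ann,
        )
        io.write_table(enr.set_index("term_id"), out_dir / "enrichment.tsv", "term_id")
        results["enrichment"] = enr
        results["study_size"] = len(study)

    _write_summary_report(summary, fit, removal_log, out_dir, config)
    _write_run_log(config, results, out_dir)
    return results


def _write_summary_report(summary, fit, removal_log, out_dir: Path, config) -> None:
    kv = summary.as_dict()
    kv.update(
        {
            "regression_slope": fit.slope,
            "regression_intercept": fit.intercept,
            "c_n": fit.c_n,
            "c_p": fit.c_p,
            "n_removed_pqs": len(removal_log),
            "estimator": config.estimator,
        }
    )
    with open(out_dir / "summary.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for key, value in kv.items():
            fh.write(f"{key}\t{value}\n")
    lines = [
        f"features summarized      : {summary.n_features}",
        f"median half-life         : {summary.median:.1f} min "
        f"({summary.median / 60:.1f} h)",
        f"mean half-life           : {summary.mean:.1f} min "
        f"({summary.mean / 60:.1f} h)",
        f"range                    : {summary.min:.1f} - {summary.max:.1f} min",
        f"features removed by PQS  : {len(removal_log)}",
    ]
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")


def _write_run_log(config: PipelineConfig, results: dict, out_dir: Path) -> None:
    import numpy
    import scipy

    lines = [
        f"thiolife {__version__}",
        f"numpy {numpy.__version__}; scipy {scipy.__version__}; "
        f"pandas {pd.__version__}",
        "parameters:",
    ]
    for f in dataclasses.fields(config):
        lines.append(f"  {f.name} = {getattr(config, f.name)}")
    lines.append(f"n_detected = {results['n_detected']}")
    lines.append(f"n_kept = {int(results['normalized']['kept'].sum())}")
    (out_dir / "run_log.txt").write_text("\n".join(lines) + "\n")
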