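"""End-to-end orchestration: simulate -> label -> filter -> evaluate ->
fairness -> alert burden, with a reproducibility manifest.

A run is described by a :class:`PipelineConfig` (constructible from a YAML
file); every stage's randomness derives from the configured seeds, so the
same config produces bit-identical report bundles.  Any stage failure is
re-raised as :class:`~sepsisval.errors.PipelineError` naming the stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alerts import AlertConfig, alert_times, burden_curve, simulate_silencing
from .errors import ConfigurationError, PipelineError
from .evaluation import (
    EvalConfig,
    encounter_table,
    evaluate_model,
    reanchor_to_recognition,
)
from .fairness import fairness_audit
from .filters import FilterConfig, apply_filters, truncate_post_onset
from .io import read_cohort, write_cohort
from .labeling import LabelingConfig, label_cohort
from .sofa import SofaConfig
from .synthetic import SimConfig, SyntheticCohort, generate_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig | None = None
    cohort_dir: str | None = None
    output_dir: str | None = None
    seed: int | None = None
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    sofa: SofaConfig = field(default_factory=SofaConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    alert_silencing_hours: float = 8.0
    alert_bin_width_hours: float = 4.0
    alert_threshold: int | None = None  # None: reuse the calibrated threshold
    fairness_bootstrap: int = 200
    recognition_indicators: tuple[str, ...] = ("any",)
    save_cohort: bool = False
    cohort_format: str = "csv"

    def resolved(self) -> "PipelineConfig":
        """Propagate the pipeline seed into the stage seeds."""
        if self.seed is None:
            return self
        sim = replace(self.sim, seed=self.seed) if self.sim is not None else None
        evaluation = replace(self.evaluation, bootstrap_seed=self.seed + 1000)
        return replace(self, sim=sim, evaluation=evaluation)


_SECTION_TYPES = {
    "sim": SimConfig,
    "labeling": LabelingConfig,
    "sofa": SofaConfig,
    "filters": FilterConfig,
    "evaluation": EvalConfig,
}


def _build_section(cls, mapping):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - fields
    if unknown:
        raise ConfigurationError(
            f"unknown {cls.__name__} option(s): {sorted(unknown)}"
        )
    coerced = {}
    for key, value in mapping.items():
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        if key == "process" and isinstance(value, dict):
            from .synthetic import ScoreProcessParams

            value = ScoreProcessParams(**value)
        coerced[key] = value
    return cls(**coerced)


def config_from_dict(data: dict) -> PipelineConfig:
    kwargs: dict = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _build_section(_SECTION_TYPES[key], value or {})
        else:
            kwargs[key] = value
    return _build_section(PipelineConfig, kwargs)


def config_from_yaml(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


@dataclass
class ReportBundle:
    config: PipelineConfig
    cohort: SyntheticCohort
    labels: pd.DataFrame
    ledger: pd.DataFrame
    thresholds: dict[str, int]
    metrics: pd.DataFrame
    calibration: dict[str, pd.DataFrame]
    fairness: pd.DataFrame
    alert_burden: pd.DataFrame
    manifest: dict
    output_dir: Path | None = None


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (PipelineError, ConfigurationError):
                raise
            except Exception as exc:  # noqa: BLE001 - re-tagged with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig | str | Path) -> ReportBundle:
    """Execute the full validation pipeline and (optionally) write the
    report bundle to ``config.output_dir``."""
    if not isinstance(config, PipelineConfig):
        config = config_from_yaml(config)
    config = config.resolved()

    cohort = _stage("simulate")(_get_cohort)(config)
    labels = _stage("label")(label_cohort)(cohort, config.labeling, config.sofa)
    result = _stage("filter")(apply_filters)(cohort, labels, config.filters)

    thresholds: dict[str, int] = {}
    metric_frames: list[pd.DataFrame] = []
    calibration: dict[str, pd.DataFrame] = {}

    model_ids = sorted(result.predictions["model_id"].unique())
    eval_cfg = config.evaluation
    for model_id in model_ids:
        thr, metrics, curve = _stage("evaluate")(evaluate_model)(
            result.predictions, labels, model_id, eval_cfg
        )
        thresholds[model_id] = thr
        metric_frames.append(metrics)
        calibration[model_id] = curve
        for indicator in config.recognition_indicators:
            relabeled = reanchor_to_recognition(labels, indicator)
            re_preds = truncate_post_onset(
                result.predictions_untruncated, relabeled
            )
            anchor = (
                "clinician_recognition"
                if indicator == "any"
                else f"recognition_{indicator}"
            )
            _, re_metrics, _ = _stage("evaluate")(evaluate_model)(
                re_preds,
                relabeled,
                model_id,
                eval_cfg,
                threshold=thr,
                anchor=anchor,
                include_prediction_level=False,
            )
            metric_frames.append(re_metrics)

    metrics = pd.concat(metric_frames, ignore_index=True)

    # Fairness audit on the primary (first) model's encounter max scores.
    primary = model_ids[0]
    enc_tab = encounter_table(result.predictions, labels, primary)
    max_scores = enc_tab.set_index("encounter_id")["max_score"]
    fairness = _stage("fairness")(fairness_audit)(
        cohort.encounters,
        labels,
        max_scores,
        n_bootstrap=config.fairness_bootstrap,
        seed=eval_cfg.bootstrap_seed + 7,
    )

    alert_thr = (
        config.alert_threshold
        if config.alert_threshold is not None
        else thresholds[primary]
    )
    raw_alerts = _stage("alerts")(alert_times)(result.predictions, alert_thr, primary)
    silenced = _stage("alerts")(simulate_silencing)(
        raw_alerts, config.alert_silencing_hours
    )
    included_enc = cohort.encounters[
        cohort.encounters["encounter_id"].isin(result.included_ids)
    ]
    raw_curve = burden_curve(raw_alerts, included_enc, config.alert_bin_width_hours)
    sil_curve = burden_curve(silenced, included_enc, config.alert_bin_width_hours)
    alert_burden = raw_curve.merge(
        sil_curve[["bin_start_h", "n_alerts", "mean_alerts_per_encounter"]],
        on="bin_start_h",
        suffixes=("_raw", "_silenced"),
    )

    manifest = {
        "package": "sepsisval",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "n_encounters_input": int(len(cohort.encounters)),
        "n_encounters_included": int(result.ledger.n_included),
        "thresholds": thresholds,
        "alert_threshold": int(alert_thr),
        "n_alerts_raw": int(len(raw_alerts)),
        "n_alerts_silenced": int(len(silenced)),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }

    bundle = ReportBundle(
        config=config,
        cohort=cohort,
        labels=labels,
        ledger=result.ledger.to_frame(),
        thresholds=thresholds,
        metrics=metrics,
        calibration=calibration,
        fairness=fairness,
        alert_burden=alert_burden,
        manifest=manifest,
    )
    if config.output_dir:
        bundle.output_dir = _write_bundle(bundle, Path(config.output_dir), config)
    return bundle


def _get_cohort(config: PipelineConfig) -> SyntheticCohort:
    if config.cohort_dir:
        return read_cohort(config.cohort_dir)
    if config.sim is None:
        raise ConfigurationError("config needs either cohort_dir or a sim section")
    return generate_cohort(config.sim)


def _write_bundle(
    bundle: ReportBundle, out_dir: Path, config: PipelineConfig
) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.labels.to_csv(out_dir / "labels.csv", index=False, date_format="%Y-%m-%dT%H:%M:%S")
    bundle.ledger.to_csv(out_dir / "exclusions.csv", index=False)
    bundle.metrics.to_csv(out_dir / "metrics.csv", index=False)
    bundle.fairness.to_csv(out_dir / "fairness.csv", index=False)
    bundle.alert_burden.to_csv(out_dir / "alert_burden.csv", index=False)
    for model_id, curve in bundle.calibration.items():
        curve.to_csv(out_dir / f"calibration_{model_id}.csv", index=False)
    with open(out_dir / "thresholds.json", "w") as fh:
        json.dump(bundle.thresholds, fh, indent=2)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)
    if config.save_cohort:
        write_cohort(bundle.cohort, out_dir / "cohort", fmt=config.cohort_format)
    return out_dir
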