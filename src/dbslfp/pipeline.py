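"""End-to-end orchestration: config, stages, artifacts, logging.

A run is driven by a :class:`RunConfig` (usually loaded from YAML) and
produces a directory of machine-readable artifacts: the synthetic
fixture, the epoch manifest, the band-power table, the outlier report,
the marginal-prediction grid, the additivity results, the classifier
report and a ground-truth comparison, plus a ``run.log`` recording
seeds.  Deterministic stages are bit-reproducible for a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import additivity as _additivity
from . import classifier as _classifier
from . import lme as _lme
from . import outliers as _outliers
from . import preprocess as _preprocess
from . import spectral as _spectral
from . import synth as _synth
from .design import ROIS, StudyDesign, make_design
from .errors import ConfigurationError, StageError, ValidationError
from .spectral import BANDS

log = logging.getLogger("dbslfp.pipeline")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str = "run_artifacts"
    seed: int = 0
    # design
    subjects: int = 3
    datasets_per_subject: int = 2
    trials_per_condition: int = 10
    channels_per_roi: int = 2
    rois: tuple[str, ...] = ROIS
    sampling_rate: float = 2000.0
    # scenario
    scenario: str = "mixed"
    # generator: "signal" synthesizes voltages and runs the full chain;
    # "table" draws the band-power table from the hierarchical model.
    generator: str = "signal"
    artifact_fraction: float = 0.097
    artifact_amplitude: float = 8.0
    # analysis
    target_rate: float = 1000.0
    n_boot: int = 999
    alpha: float = 0.05
    outlier_threshold: float = 5.0
    train_frac: float = 0.7
    fit_pooled: bool = True
    bands: tuple = tuple((b.name, b.lo, b.hi) for b in BANDS)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not 0 < self.train_frac < 1:
            raise ConfigurationError("train_frac must lie in (0, 1)")
        if not 0 <= self.artifact_fraction <= 1:
            raise ConfigurationError("artifact_fraction must lie in [0, 1]")
        if self.outlier_threshold <= 0:
            raise ConfigurationError("outlier_threshold must be > 0")
        if self.generator not in ("signal", "table"):
            raise ConfigurationError("generator must be 'signal' or 'table'")
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise ConfigurationError(f"band '{name}': lo must be < hi")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def design(self) -> StudyDesign:
        return make_design(
            {
                "subjects": self.subjects,
                "datasets_per_subject": self.datasets_per_subject,
                "trials_per_condition": self.trials_per_condition,
                "channels_per_roi": self.channels_per_roi,
                "rois": self.rois,
                "sampling_rate": self.sampling_rate,
            },
            seed=self.seed,
        )


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(name, exc) from exc
            log.info("stage %s: done", name)
            return out
        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper
    return deco


@_stage("simulate")
def stage_simulate(config: RunConfig, out: Path):
    """Plant effects, synthesize recordings, inject artifacts, write fixture."""
    design = config.design()
    effects, truth = _synth.plant_effects(design, config.scenario, seed=config.seed)
    truth[["pair", "roi", "band", "interaction_true", "class_true"]].to_csv(
        out / "ground_truth.csv", index=False
    )
    sessions, labels = {}, {}
    for subject, dataset in design.datasets:
        ses = _synth.synthesize_session(design, effects, subject, dataset, seed=config.seed)
        if config.artifact_fraction > 0:
            ses, lab = _synth.inject_edge_artifacts(
                ses,
                config.artifact_fraction,
                config.artifact_amplitude,
                seed=config.seed + 17,
            )
            labels[f"{subject}_{dataset}"] = [int(i) for i in lab]
        sessions[(subject, dataset)] = ses
    _synth.write_fixture(sessions, {}, out / "fixture")
    (out / "fixture" / "artifact_labels.json").write_text(json.dumps(labels, indent=1))
    return design, effects, truth, sessions


@_stage("preprocess+power")
def stage_power(config: RunConfig, out: Path, sessions: dict):
    """Re-reference, decimate, segment and build the band-power table."""
    tables, scores, manifests = [], [], []
    for ses in sessions.values():
        epochs = _preprocess.preprocess_session(ses, target_rate=config.target_rate)
        manifests.append(epochs.manifest)
        t, s = _spectral.build_power_table(epochs, return_edge_scores=True)
        tables.append(t)
        scores.append(s)
    manifest = pd.concat(manifests, ignore_index=True)
    manifest.to_csv(out / "epoch_manifest.csv", index=False)
    table = pd.concat(tables, ignore_index=True)
    score_df = pd.concat(scores, ignore_index=True)
    table.to_csv(out / "power_table.csv", index=False)
    return table, score_df


@_stage("screen")
def stage_screen(config: RunConfig, out: Path, table: pd.DataFrame, scores: pd.DataFrame):
    """Remove edge-artifact epochs and serialize the report."""
    clean, report = _outliers.flag_outliers(table, scores, config.outlier_threshold)
    report.to_json(out / "outlier_report.json")
    return clean


@_stage("fit")
def stage_fit(config: RunConfig, out: Path, table: pd.DataFrame):
    """Pooled mixed model: marginal grid with bootstrap p/q + variance parts."""
    spec = _lme.ModelSpec(rois=tuple(config.rois))
    grid = _lme.marginal_grid(
        table, spec, n_boot=config.n_boot, seed=config.seed, alpha=config.alpha
    )
    grid.to_csv(out / "marginal_grid.csv", index=False)
    fit = _lme.fit_lme(table, spec)
    vd = _lme.variance_decomposition(fit)
    (out / "variance_decomposition.json").write_text(json.dumps(vd.as_dict(), indent=1))
    return grid, vd


@_stage("additivity")
def stage_additivity(config: RunConfig, out: Path, table: pd.DataFrame):
    """Three-subset interaction analysis and heatmap exports."""
    results = _additivity.analyze_additivity(
        table,
        n_boot=config.n_boot,
        seed=config.seed,
        alpha=config.alpha,
        rois=tuple(config.rois),
    )
    results[list(_additivity.RESULT_COLUMNS)].to_csv(out / "additivity_results.csv", index=False)
    report = _additivity.additivity_report(results)
    for pair, hm in report["median"].items():
        hm.to_csv(out / f"additivity_heatmap_{pair}.csv")
    report["tally"].to_csv(out / "additivity_tally.csv", index=False)
    return results


@_stage("classify")
def stage_classify(config: RunConfig, out: Path, results: pd.DataFrame, table: pd.DataFrame):
    """Decision-tree interaction-class model with report + importances."""
    features = _classifier.build_feature_table(results, table)
    train, test = _classifier.split_train_test(features, config.train_frac, seed=config.seed)
    model = _classifier.train_tree(train, seed=config.seed)
    report = _classifier.evaluate(model, test)
    report.to_json(out / "classifier_report.json")
    report.confusion.to_csv(out / "confusion_matrix.csv")
    _classifier.feature_importances(model).to_csv(out / "feature_importances.csv", index=False)
    return model, report


@_stage("compare")
def stage_compare(out: Path, results: pd.DataFrame, truth: pd.DataFrame):
    """Ground-truth comparison for synthetic runs."""
    merged = results.merge(
        truth[["pair", "roi", "band", "interaction_true", "class_true"]],
        on=["pair", "roi", "band"],
    )
    merged["class_correct"] = merged["class"] == merged["class_true"]
    merged.to_csv(out / "ground_truth_comparison.csv", index=False)
    log.info("class recovery: %.3f", merged["class_correct"].mean())
    return merged


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the artifact directory.

    Any stage failure aborts with a :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("dbslfp")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        log.info("config: %s", json.dumps(dataclasses.asdict(config), default=str))
        log.info("seed: %d", config.seed)
        if config.generator == "signal":
            design, effects, truth, sessions = stage_simulate(config, out)
            table, scores = stage_power(config, out, sessions)
            table = stage_screen(config, out, table, scores)
        else:
            design = config.design()
            effects, truth = _synth.plant_effects(design, config.scenario, seed=config.seed)
            truth[["pair", "roi", "band", "interaction_true", "class_true"]].to_csv(
                out / "ground_truth.csv", index=False
            )
            table = _synth.simulate_power_table(design, effects, seed=config.seed)
            table.to_csv(out / "power_table.csv", index=False)
            table[["epoch_id", "subject", "dataset", "trial", "condition"]].drop_duplicates(
                "epoch_id"
            ).to_csv(out / "epoch_manifest.csv", index=False)
        if config.fit_pooled:
            stage_fit(config, out, table)
        results = stage_additivity(config, out, table)
        stage_classify(config, out, results, table)
        stage_compare(out, results, truth)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
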