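"""Config-driven orchestration of the full red-edge classification experiment.

Stage order: simulate (or load) -> band-information ranking -> separability ->
red-edge indices -> texture PC1 -> index importance -> per-scheme random
forest classification -> accuracy evaluation -> McNemar comparisons. Stage
dependencies are validated before execution (a scheme needing texture layers
fails fast if the texture stage is disabled). Given the same config the run
is fully reproducible: every stochastic stage derives its seed from the
master seed and the stage name.
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

from . import classification, evaluation, feature_importance
from . import red_edge_indices, spectral_analysis, synthetic_scene, texture_features
from .classification import RFConfig, SCHEME_IDS, SCHEMES, texture_layer_name
from .raster_io import (
    MultibandRaster,
    SampleSet,
    extract_pixels,
    read_raster,
    read_samples,
    write_labels,
    write_raster,
    write_samples,
)
from .reference import ABS_ANALYSIS_ORDER
from .texture_features import GLCMConfig

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "abs", "separability", "indices", "texture",
              "importance", "classify", "evaluate", "mcnemar")

#: Spectral-scheme band subsets used by the separability stage.
SPECTRAL_SCHEMES = {
    "A-1": ("R", "G", "B", "NIR"),
    "A-2": ("R", "G", "B", "NIR", "RE1"),
    "A-3": ("R", "G", "B", "NIR", "RE2"),
    "A-4": ("R", "G", "B", "NIR", "RE1", "RE2"),
}

TEXTURE_BANDS = ("RE1", "RE2", "NIR")


@dataclass
class RunConfig:
    """Everything one experiment run needs; loadable from a YAML mapping."""

    out_dir: str = "rededge_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # synthetic scene (used by the simulate stage)
    scene_width: int = 256
    scene_height: int = 256
    field_count: int = 120
    polygons_per_class: int | None = 20
    polygon_size: int = 5
    # or an external scene
    raster_path: str | None = None
    samples_path: str | None = None
    # analysis settings
    band_order: tuple[str, ...] = ABS_ANALYSIS_ORDER
    jbh_convention: str = "sqrt"
    glcm_levels: int = 64
    glcm_window: int = 3
    n_trees: int = 100
    schemes: tuple[str, ...] = SCHEME_IDS
    top_k: int = 4
    mcnemar_pairs: tuple[tuple[str, str], ...] | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "band_order", "schemes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if raw.get("mcnemar_pairs"):
            raw["mcnemar_pairs"] = tuple(tuple(p) for p in raw["mcnemar_pairs"])
        return cls(**raw)

    def validate(self) -> None:
        unknown_stage = set(self.stages) - set(ALL_STAGES)
        if unknown_stage:
            raise ValueError(f"unknown stages: {sorted(unknown_stage)}")
        unknown_scheme = set(self.schemes) - set(SCHEME_IDS)
        if unknown_scheme:
            raise ValueError(f"unknown schemes: {sorted(unknown_scheme)}")
        if "classify" in self.stages:
            needs_texture = any(s.startswith("B") for s in self.schemes)
            needs_indices = any(s.startswith("C") for s in self.schemes)
            if needs_texture and "texture" not in self.stages:
                raise ValueError(
                    "schemes "
                    f"{[s for s in self.schemes if s.startswith('B')]} need "
                    "the texture stage, which is not enabled"
                )
            if needs_indices and "indices" not in self.stages:
                raise ValueError(
                    "schemes "
                    f"{[s for s in self.schemes if s.startswith('C')]} need "
                    "the indices stage, which is not enabled"
                )
        if "simulate" not in self.stages and (self.raster_path is None
                                              or self.samples_path is None):
            raise ValueError(
                "without the simulate stage, raster_path and samples_path "
                "must be provided"
            )


@dataclass
class RunResult:
    """In-memory handles to everything a run produced."""

    config: RunConfig
    raster: MultibandRaster
    samples: SampleSet
    abs_table: pd.DataFrame | None = None
    separability: dict[str, spectral_analysis.SeparabilityReport] = field(
        default_factory=dict)
    importance: list[feature_importance.ImportanceRecord] = field(
        default_factory=list)
    runs: dict[str, classification.SchemeRun] = field(default_factory=dict)
    accuracy: dict[str, evaluation.AccuracyReport] = field(default_factory=dict)
    mcnemar: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)


def _scaled_sample_request(config: RunConfig) -> dict[str, int]:
    """Per-class polygon request: a flat count per class, or the reference
    survey counts when ``polygons_per_class`` is None."""
    if config.polygons_per_class is None:
        return synthetic_scene.paper_sample_request()
    return {label: config.polygons_per_class
            for label in synthetic_scene.CLASS_NAMES}


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the enabled stages in order and persist per-stage artifacts
    under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- scene -------------------------------------------------------------
    if "simulate" in config.stages:
        spec = synthetic_scene.default_paper_spec(
            width=config.scene_width, height=config.scene_height,
            field_count=config.field_count, seed=config.seed,
        )
        raster, labels = synthetic_scene.generate_scene(spec)
        samples = synthetic_scene.generate_samples(
            labels, spec, _scaled_sample_request(config),
            seed=config.seed, polygon_size=config.polygon_size,
        )
        write_raster(raster, out / "scene.tif")
        write_labels(labels, list(spec.class_labels), out / "labels.tif")
        write_samples(samples, out / "samples.geojson")
    else:
        raster = read_raster(config.raster_path)
        samples = read_samples(config.samples_path)

    result = RunResult(config=config, raster=raster, samples=samples)
    train_pixels = extract_pixels(raster, samples, role="train")

    # --- band information ranking ------------------------------------------
    if "abs" in config.stages:
        stats = spectral_analysis.band_statistics(raster, config.band_order)
        ranked = spectral_analysis.abs_ranking(stats)
        result.abs_table = pd.DataFrame(
            [{"band": s.band, "sigma": s.sigma, "abs_index": s.abs_index,
              "rank": s.rank} for s in ranked]
        )
        result.abs_table.to_csv(out / "abs.csv", index=False)

    # --- separability -------------------------------------------------------
    if "separability" in config.stages:
        rows = []
        for scheme_id, bands in SPECTRAL_SCHEMES.items():
            signatures = spectral_analysis.class_signatures(
                train_pixels, list(bands))
            report = spectral_analysis.j_bh_distance(
                signatures, convention=config.jbh_convention)
            result.separability[scheme_id] = report
            rows.append({"scheme": scheme_id, "bands": "+".join(bands),
                         "j_bh": report.j_bh,
                         "upper_bound": report.upper_bound})
        pd.DataFrame(rows).to_csv(out / "separability.csv", index=False)

    # --- derived layers ------------------------------------------------------
    derived: dict[str, np.ndarray] = {}
    if "indices" in config.stages:
        index_stack = red_edge_indices.compute_all(raster)
        for name in index_stack.names:
            derived[name] = index_stack.layer(name)
    if "texture" in config.stages:
        glcm = GLCMConfig(levels=config.glcm_levels, window=config.glcm_window)
        for band in TEXTURE_BANDS:
            pc1 = texture_features.band_texture_pc1(
                raster.band(band), glcm, source_band=band)
            derived[texture_layer_name(band)] = pc1.layer

    # --- index importance ----------------------------------------------------
    if "importance" in config.stages:
        if "indices" not in config.stages:
            raise ValueError("importance stage needs the indices stage")
        index_pixels = extract_pixels(
            _stack_of(derived, red_edge_indices.INDEX_NAMES), samples,
            role="train")
        result.importance = feature_importance.evaluate_importance(
            index_pixels, list(red_edge_indices.INDEX_NAMES),
            seed=int(synthetic_scene.stage_rng(config.seed, "importance")
                     .integers(2**31)),
        )
        frame = pd.DataFrame(
            [{"feature": r.feature, "f_value": r.f_value, "mdg": r.mdg,
              "rank_sda": r.rank_sda, "rank_rf": r.rank_rf,
              "entered": r.entered} for r in result.importance]
        )
        frame.to_csv(out / "importance.csv", index=False)

    # --- classification ------------------------------------------------------
    if "classify" in config.stages:
        result.runs = classification.run_scheme_suite(
            raster, derived, samples,
            config=RFConfig(n_trees=config.n_trees, seed=config.seed),
            scheme_ids=config.schemes,
        )
        for scheme_id, run in result.runs.items():
            write_labels(run.class_map.labels, list(run.class_map.legend),
                         out / f"classmap_{scheme_id}.tif")

    # --- evaluation ----------------------------------------------------------
    if "evaluate" in config.stages:
        if not result.runs:
            raise ValueError("evaluate stage needs the classify stage")
        summary_rows = []
        for scheme_id, run in result.runs.items():
            cm = evaluation.confusion_matrix(run.class_map, samples)
            report = evaluation.accuracy_metrics(cm)
            result.accuracy[scheme_id] = report
            report.to_frame().to_csv(out / f"accuracy_{scheme_id}.csv")
            summary_rows.append({"scheme": scheme_id,
                                 "oa_percent": round(report.oa, 2),
                                 "kappa": round(report.kappa, 4)})
        pd.DataFrame(summary_rows).to_csv(out / "accuracy_summary.csv",
                                          index=False)

    # --- McNemar -------------------------------------------------------------
    if "mcnemar" in config.stages:
        if not result.runs:
            raise ValueError("mcnemar stage needs the classify stage")
        pairs = (list(config.mcnemar_pairs)
                 if config.mcnemar_pairs is not None else None)
        result.mcnemar = evaluation.mcnemar_matrix(result.runs, samples, pairs)
        result.mcnemar.to_csv(out / "mcnemar.csv", index=False)

    result.summary = _summarize(result)
    with open(out / "report.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
    return result


def _stack_of(derived: dict[str, np.ndarray], names: tuple[str, ...]):
    from .raster_io import FeatureStack

    stack = FeatureStack()
    for name in names:
        stack.add(name, derived[name])
    return stack


def _summarize(result: RunResult) -> dict:
    summary: dict = {"seed": result.config.seed}
    if result.abs_table is not None:
        summary["abs_ranking"] = result.abs_table["band"].tolist()
    if result.separability:
        summary["j_bh"] = {k: round(v.j_bh, 4)
                           for k, v in result.separability.items()}
    if result.importance:
        summary["top4_sda"] = feature_importance.select_top_k(
            result.importance, min(4, len(result.importance)), by="sda")
        summary["top4_rf"] = feature_importance.select_top_k(
            result.importance, min(4, len(result.importance)), by="rf")
    if result.accuracy:
        summary["oa_percent"] = {k: round(v.oa, 2)
                                 for k, v in result.accuracy.items()}
        summary["kappa"] = {k: round(v.kappa, 4)
                            for k, v in result.accuracy.items()}
    if result.mcnemar is not None:
        summary["mcnemar_significant_fraction"] = float(
            result.mcnemar["significant"].mean())
    return summary
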