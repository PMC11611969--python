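"""End-to-end orchestration: phantom -> change -> enhance -> locate -> evaluate -> report.

A :class:`PipelineConfig` (YAML/JSON on disk) either points at existing
volumes or enables phantom generation; :func:`run_all` validates the config
up front, runs every stage, and writes the series report (CSV + JSON with a
provenance block recording every under-specified default actually used:
threshold formula and value, connectivity, precedence, condensation-table
identity). Given fixed seeds the outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .change import classify_changes, label_components
from .enhance import EnhanceParams, detect_ce_lesions
from .evaluate import match_components, summarize_misclassification
from .io_volumes import BinaryMask, read_labelmap, read_mask, read_volume, write_volume
from .locate import (
    AtlasCondensation,
    LocationParams,
    RegionSet,
    default_condensation,
    load_condensation_table,
    locate_components,
)
from .phantom import PhantomSpec, generate_lesion_series, generate_anatomy, generate_postcontrast, random_phantom_spec
from .report import StudyReportRow, build_report, build_series_report

__all__ = ["ConfigError", "PipelineConfig", "run_all"]


class ConfigError(ValueError):
    """The pipeline configuration is invalid; raised before any output is written."""


@dataclass
class PhantomConfig:
    enabled: bool = False
    seed: int = 0
    n_timepoints: int = 4
    n_lesions: int | None = None
    noise_sd: float = 0.0
    write_volumes: bool = True


@dataclass
class InputConfig:
    lesion_masks: list[str] = field(default_factory=list)
    t1post: str | None = None
    ventricles: str | None = None
    cortical_ribbon: str | None = None
    infratentorial: str | None = None
    atlas: str | None = None


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; round-trips through YAML.

    Unknown keys (at any level) are rejected, and validation runs before any
    file is written.
    """

    study_id: str = "study"
    output_dir: str = "mslesion-out"
    connectivity: int = 26
    min_new_voxels: int = 1
    compare_to: str = "previous"  # or "baseline"
    condensation_table: str | None = None
    enhance: EnhanceParams = field(default_factory=EnhanceParams)
    location: LocationParams = field(default_factory=LocationParams)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    inputs: InputConfig = field(default_factory=InputConfig)

    @staticmethod
    def _build(cls, d: dict, ctx: str):
        import dataclasses

        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s) in {ctx}: {sorted(unknown)}")
        try:
            return cls(**{k: tuple(v) if isinstance(v, list) and k in ("median_kernel", "precedence") else v for k, v in d.items()})
        except (TypeError, ValueError) as e:
            raise ConfigError(f"invalid {ctx} config: {e}") from e

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sub = {}
        for key, sub_cls in (("enhance", EnhanceParams), ("location", LocationParams), ("phantom", PhantomConfig), ("inputs", InputConfig)):
            if key in d:
                sub[key] = cls._build(sub_cls, d.pop(key) or {}, key)
        cfg = cls._build(cls, d, "pipeline")
        for k, v in sub.items():
            setattr(cfg, k, v)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def validate(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ConfigError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        if self.compare_to not in ("previous", "baseline"):
            raise ConfigError(f"compare_to must be 'previous' or 'baseline', got {self.compare_to!r}")
        if self.condensation_table is not None and not Path(self.condensation_table).exists():
            raise ConfigError(f"condensation table not found: {self.condensation_table}")
        if not self.phantom.enabled:
            if not self.inputs.lesion_masks:
                raise ConfigError("either enable phantom generation or provide inputs.lesion_masks")
            needed = {
                "ventricles": self.inputs.ventricles,
                "cortical_ribbon": self.inputs.cortical_ribbon,
                "infratentorial": self.inputs.infratentorial,
            }
            for name, p in needed.items():
                if p is None:
                    raise ConfigError(f"inputs.{name} is required when phantom generation is off")
            for p in list(self.inputs.lesion_masks) + [v for v in [self.inputs.t1post, *needed.values(), self.inputs.atlas] if v]:
                if not Path(p).exists():
                    raise ConfigError(f"input file not found: {p}")

    def load_condensation(self) -> AtlasCondensation:
        if self.condensation_table is None:
            return default_condensation()
        return load_condensation_table(self.condensation_table)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_all(config: PipelineConfig, write: bool = True):
    """Run the full study pipeline under one config.

    Returns ``(series_table, provenance)``; when ``write`` is on, also writes
    ``report.csv`` / ``report.json`` (and, for phantoms, the generated
    volumes, masks and truth table) under ``config.output_dir``.
    """
    config.validate()
    condensation = config.load_condensation()
    out = Path(config.output_dir)

    truth = None
    if config.phantom.enabled:
        pc = config.phantom
        spec = random_phantom_spec(
            seed=pc.seed, n_lesions=pc.n_lesions, n_timepoints=pc.n_timepoints, noise_sd=pc.noise_sd
        )
        flair, t1, regions = generate_anatomy(spec)
        masks, truth = generate_lesion_series(spec, pc.n_timepoints, config.connectivity)
        post = [generate_postcontrast(spec, t) for t in range(pc.n_timepoints)]
        t1posts = [p[0] for p in post]
        enhancing_truths = [p[2] for p in post]
    else:
        masks = [read_mask(p) for p in config.inputs.lesion_masks]
        regions = RegionSet(
            ventricles=read_mask(config.inputs.ventricles),
            cortical_ribbon=read_mask(config.inputs.cortical_ribbon),
            infratentorial=read_mask(config.inputs.infratentorial),
            atlas=read_labelmap(config.inputs.atlas) if config.inputs.atlas else None,
        )
        t1posts = [None] * len(masks)
        if config.inputs.t1post is not None:
            t1posts[-1] = read_volume(config.inputs.t1post)
        enhancing_truths = [None] * len(masks)

    rows: list[StudyReportRow] = []
    provenance: dict = {
        "package_version": __version__,
        "connectivity": config.connectivity,
        "compare_to": config.compare_to,
        "threshold_rule": config.enhance.threshold_rule,
        "threshold_k": config.enhance.threshold_k,
        "vessel_threshold": config.enhance.vessel_threshold,
        "min_component_voxels": config.enhance.min_component_voxels,
        "precedence": list(config.location.precedence),
        "condensation_table": "shipped hammers_condensation_23"
        if config.condensation_table is None
        else str(config.condensation_table),
        "n_key_areas": condensation.n_key_areas,
        "stages": [],
    }
    evaluations = []
    for t, mask in enumerate(masks):
        stage: dict = {"timepoint": t}
        change = None
        if t > 0:
            ref = masks[0] if config.compare_to == "baseline" else masks[t - 1]
            change = classify_changes(ref, mask, config.connectivity, config.min_new_voxels)
            stage["n_new"] = change.n_new
            stage["n_progressing"] = change.n_progressing
        labels = label_components(mask, config.connectivity)
        locations = locate_components(labels, regions, config.location, condensation)
        enh = None
        if t1posts[t] is not None:
            enh = detect_ce_lesions(t1posts[t], config.enhance, lesion_mask=mask)
            stage["threshold_used"] = enh.threshold_used
            stage["n_enhancing"] = len(enh.components)
            stage["n_excluded_by_vessel"] = enh.n_excluded_by_vessel
            if enhancing_truths[t] is not None:
                m = match_components(enh.candidate_mask, enhancing_truths[t], config.connectivity)
                n_fp, n_fn, n_mis = summarize_misclassification(m)
                evaluations.append(
                    {"timepoint": t, "n_tp": m.n_tp, "n_fp": n_fp, "n_fn": n_fn, "n_misclassified": n_mis}
                )
        rows.append(
            build_report(change, locations, enh, study_id=config.study_id, timepoint=t)
        )
        provenance["stages"].append(stage)
    series = build_series_report(rows)
    if evaluations:
        provenance["ce_evaluation_vs_truth"] = evaluations

    if write:
        out.mkdir(parents=True, exist_ok=True)
        series.to_csv(out / "report.csv", index=False)
        payload = {
            "study_id": config.study_id,
            "rows": [r.to_dict() for r in rows],
            "cumulative_new": series["cumulative_new"].tolist(),
            "provenance": provenance,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
        if truth is not None:
            truth.to_frame().to_csv(out / "phantom_truth.csv", index=False)
            if config.phantom.write_volumes:
                write_volume(flair, out / "flair.nii.gz")
                write_volume(t1, out / "t1.nii.gz")
                for t, (m, tp) in enumerate(zip(masks, t1posts)):
                    write_volume(m, out / f"lesions_t{t}.nii.gz")
                    write_volume(tp, out / f"t1post_t{t}.nii.gz")
                write_volume(regions.ventricles, out / "ventricles.nii.gz")
                write_volume(regions.cortical_ribbon, out / "cortical_ribbon.nii.gz")
                write_volume(regions.infratentorial, out / "infratentorial.nii.gz")
                write_volume(regions.atlas, out / "atlas.nii.gz")
    return series, provenance
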