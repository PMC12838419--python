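"""Configuration schema and the end-to-end pipeline driver.

One YAML/JSON config drives the whole workflow: OCT processing ->
twist correction -> registration -> fusion -> reconstruction -> wall and
calcifications -> validation.  Unknown keys are rejected; every run
writes a provenance record (config hash, package version, stage timings).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calcification import CalcificationModel, embed_calcifications
from .errors import ConfigError
from .fusion import (FusionConfig, LabeledPointCloud, add_wall, fuse,
                     mesh_to_point_cloud, remove_overlapping_points,
                     reconstruct_surface, select_points_region,
                     BoxRegion, SphereRegion)
from .oct_processing import Calibration, process_pullback
from .registration import TwistConfig, correct_twist, register_pullback
from .validation import (ValidationConfig, lumen_area_profile,
                         stenosis_from_profile, vertex_distance_stats)

log = logging.getLogger(__name__)

_SECTIONS = {"calibration": Calibration, "twist": TwistConfig,
             "fusion": FusionConfig, "validation": ValidationConfig}


@dataclass
class PipelineConfig:
    """Validated bag of per-stage settings plus paths and seed."""

    calibration: Calibration = field(default_factory=Calibration)
    twist: TwistConfig = field(default_factory=TwistConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    bloom_offset_mm: float = 0.5
    ccta_cloud_density: float = 10.0
    regions: list = field(default_factory=list)   # declarative residual cleanup
    seed: int = 0
    keep_intermediates: bool = False

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc or {})
        kw = {}
        for name, typ in _SECTIONS.items():
            sub = doc.pop(name, {})
            if not isinstance(sub, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            valid = typ.__dataclass_fields__.keys()
            unknown = set(sub) - set(valid)
            if unknown:
                raise ConfigError(f"unknown keys in {name!r}: {sorted(unknown)}")
            try:
                kw[name] = typ(**sub)
            except Exception as e:
                raise ConfigError(f"invalid {name!r} section: {e}") from e
        for scalar in ("bloom_offset_mm", "ccta_cloud_density", "seed",
                       "keep_intermediates", "regions"):
            if scalar in doc:
                kw[scalar] = doc.pop(scalar)
        if doc:
            raise ConfigError(f"unknown config keys: {sorted(doc)}")
        cfg = cls(**kw)
        if cfg.bloom_offset_mm < 0 or cfg.ccta_cloud_density <= 0:
            raise ConfigError("bloom offset must be >= 0, cloud density > 0")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = {name: asdict(getattr(self, name)) for name in _SECTIONS}
        d.update(bloom_offset_mm=self.bloom_offset_mm,
                 ccta_cloud_density=self.ccta_cloud_density,
                 regions=self.regions, seed=self.seed,
                 keep_intermediates=self.keep_intermediates)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _build_region(doc: dict):
    kind = doc.get("kind")
    if kind == "sphere":
        return SphereRegion(np.asarray(doc["center"], float), float(doc["radius"]))
    if kind == "box":
        return BoxRegion(np.asarray(doc["min"], float), np.asarray(doc["max"], float))
    raise ConfigError(f"unknown region kind {kind!r}")


@dataclass
class PipelineResult:
    """Artifacts of one full run."""

    lumen_mesh: object
    wall_mesh: object
    stack: object
    area_profile: object
    stenosis: object
    provenance: dict


def run_pipeline(config: PipelineConfig, frames, centerline, landmarks,
                 ccta_lumen_mesh, calcification_meshes=(),
                 out_dir=None) -> PipelineResult:
    """Execute the full fusion workflow on in-memory inputs.

    ``frames`` may be a list or generator of annotated frames; CCTA inputs
    are a lumen mesh plus optional calcification meshes.  Intermediates
    are written to ``out_dir`` when ``config.keep_intermediates`` is set.
    """
    from . import io as cio
    timings = {}
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        timings[name] = time.perf_counter()

    def _done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    _stage("oct_process")
    series = process_pullback(frames, config.calibration, skip_empty=True)
    _done("oct_process")
    _stage("twist")
    series = correct_twist(series, config.twist)
    _done("twist")
    if out and config.keep_intermediates:
        cio.write_contour_archive(series, out / "contours.json")

    _stage("register")
    stack = register_pullback(series, centerline, landmarks)
    _done("register")

    _stage("fuse")
    ccta_cloud = mesh_to_point_cloud(ccta_lumen_mesh, config.ccta_cloud_density,
                                     seed=config.seed)
    filtered = remove_overlapping_points(ccta_cloud, LabeledPointCloud(
        stack.all_points(),
        np.full(len(stack.all_points()), "OCT", object)), config.fusion)
    for rdoc in config.regions:
        filtered = select_points_region(filtered, _build_region(rdoc),
                                        keep=bool(rdoc.get("keep", False)))
    fused = fuse(filtered, stack)
    _done("fuse")
    if out and config.keep_intermediates:
        cio.write_point_cloud_ply(fused, out / "fused_cloud.ply")

    _stage("reconstruct")
    lumen = reconstruct_surface(fused, stack.centerline)
    _done("reconstruct")

    _stage("wall")
    wall = add_wall(lumen, config.fusion)
    if calcification_meshes:
        calcs = [CalcificationModel(m, config.bloom_offset_mm)
                 for m in calcification_meshes]
        wall = embed_calcifications(wall, calcs)
    _done("wall")

    _stage("profile")
    profile = lumen_area_profile(lumen, stack.centerline)
    stenosis = stenosis_from_profile(profile)
    _done("profile")

    if out:
        cio.write_mesh(lumen, out / "lumen.stl")
        cio.write_mesh(wall, out / "model.stl")

    provenance = {"config_sha256": config.digest(), "version": __version__,
                  "stage_seconds": timings, "n_frames": len(series),
                  "pct_AS": stenosis.pct_AS}
    if out:
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return PipelineResult(lumen_mesh=lumen, wall_mesh=wall, stack=stack,
                          area_profile=profile, stenosis=stenosis,
                          provenance=provenance)


def validation_report_csv(report, path) -> None:
    """Write a one-row CSV mirroring the clinical report layout."""
    import pandas as pd
    df = pd.DataFrame([{
        "vd_median_mm": report.vd_median,
        "vd_q1_mm": report.vd_iqr[0], "vd_q3_mm": report.vd_iqr[1],
        "ad_median_mm2": report.ad_median,
        "ad_q1_mm2": report.ad_iqr[0], "ad_q3_mm2": report.ad_iqr[1],
        "zdiff_mean": report.zdiff_mean, "zdiff_sd": report.zdiff_sd,
        "r_squared": report.r_squared,
    }])
    df.to_csv(path, index=False)
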