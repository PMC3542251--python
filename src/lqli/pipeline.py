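"""End-to-end run: detect per rectangle, merge curves, smooth, classify.

A :class:`RunConfig` gathers the per-stage parameters (detection
thresholds, classifier thresholds, geometry overrides, seed) from a single
YAML file; every run writes its intermediates plus a manifest (inputs,
config hash, seed, package version) sufficient to reproduce the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, io
from .classification import ClassifierConfig, PatternCall, classify
from .detection import CellDetection, DetectionParams, IHCImage, detect_cells
from .geometry import FrontAnnotation, RectangleROI, build_roi
from .profiling import DensityProfile, bin_counts, merge_profiles, smooth_profile, to_density

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_outputs"]


def _dataclass_from_dict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v  # YAML lists -> window tuples
        for k, v in d.items()
    }
    return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    detection: DetectionParams = field(default_factory=DetectionParams)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    roi_width_um: float = 1000.0
    roi_length_um: float = 4000.0
    bin_um: float = 5.0
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        kwargs = dict(raw)
        if "detection" in kwargs:
            kwargs["detection"] = _dataclass_from_dict(DetectionParams, kwargs["detection"])
        if "classifier" in kwargs:
            kwargs["classifier"] = _dataclass_from_dict(ClassifierConfig, kwargs["classifier"])
        return _dataclass_from_dict(cls, kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sha256(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass(frozen=True)
class PipelineResult:
    rois: list[RectangleROI]
    detections: list[list[CellDetection]]
    profiles: list[DensityProfile]
    merged: DensityProfile
    smoothed: DensityProfile
    call: PatternCall
    config: RunConfig


def run_pipeline(
    image: IHCImage,
    front: FrontAnnotation,
    roi_specs: list[float],
    cfg: RunConfig | None = None,
) -> PipelineResult:
    """Analyze one slide at the given arc positions along the front.

    Each rectangle is detected and profiled independently; the per-ROI
    curves are averaged into a mean curve which is smoothed and
    pattern-classified.  Deterministic for fixed inputs.
    """
    cfg = cfg or RunConfig()
    if not roi_specs:
        raise ValueError("need at least one ROI arc position")
    rois, dets, profiles = [], [], []
    for arc in roi_specs:
        roi = build_roi(
            front,
            arc,
            width=cfg.roi_width_um,
            length=cfg.roi_length_um,
            bin_um=cfg.bin_um,
        )
        d = detect_cells(image, roi, cfg.detection)
        rois.append(roi)
        dets.append(d)
        profiles.append(to_density(bin_counts(d, roi), roi))
    merged = merge_profiles(profiles)
    smoothed = smooth_profile(merged, cfg.classifier.window_bins)
    call = classify(merged, cfg.classifier)
    return PipelineResult(
        rois=rois,
        detections=dets,
        profiles=profiles,
        merged=merged,
        smoothed=smoothed,
        call=call,
        config=cfg,
    )


def write_outputs(result: PipelineResult, outdir, inputs: dict | None = None) -> Path:
    """Write all intermediates plus a reproducibility manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, (roi, d, p) in enumerate(zip(result.rois, result.detections, result.profiles)):
        io.write_roi_geojson(roi, outdir / f"roi_{i}.geojson")
        io.write_detections_csv(d, outdir / f"detections_{i}.csv")
        io.write_profile_csv(p, outdir / f"profile_{i}.csv")
    io.write_profile_csv(result.merged, outdir / "profile_mean.csv")
    io.write_profile_csv(result.smoothed, outdir / "profile_smoothed.csv")
    with open(outdir / "pattern_call.json", "w") as fh:
        json.dump(result.call.to_dict(result.config.classifier), fh, indent=1)
    manifest = {
        "package": "lqli",
        "version": __version__,
        "config": result.config.to_dict(),
        "config_sha256": result.config.sha256(),
        "seed": result.config.seed,
        "inputs": inputs or {},
        "n_rectangles": len(result.rois),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return outdir
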