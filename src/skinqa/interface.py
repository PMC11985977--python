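"""Run configuration and stage orchestration.

Ties the simulator and the analysis stages into one reproducible run: a
validated :class:`RunConfig` selects a mode (simulate / preprocess / stp /
esfr / stretch / full), every output is listed in a manifest JSON carrying
the seed and a hash of the configuration, and validation warnings are
logged rather than silently dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as skio
from . import synthetic
from .config import DetectorConfig
from .esfr import EdgeRoi, compute_sfr
from .preprocessing import average_frames, detect_skin_roi, flat_field_correct
from .stp import StpPoint, fit_stp, mean_pixel_value
from .stretching import analyse_stretch_series

logger = logging.getLogger(__name__)

MODES = ("simulate", "preprocess", "stp", "esfr", "stretch", "full")
PRESETS = ("stp", "edge", "stretch")

__all__ = ["RunConfig", "ValidationFailure", "run"]


class ValidationFailure(ValueError):
    """Configuration or input validation failed before any computation."""


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    ``paths`` holds mode-specific input files (raw/flat/dark stacks or a
    manifest); ``params`` holds stage knobs (preset, oversample, n_bins,
    n_zones, roi rectangle, pitch override, ...).  Every referenced path
    must exist at run start.
    """

    mode: str
    out_dir: Path
    seed: int = 0
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    paths: dict[str, str] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationFailure(f"unknown mode {self.mode!r}; expected one of {MODES}")
        self.out_dir = Path(self.out_dir)
        preset = self.params.get("preset", "stp")
        if self.mode in ("simulate",) and preset not in PRESETS:
            raise ValidationFailure(f"unknown preset {preset!r}; expected one of {PRESETS}")
        for key, p in self.paths.items():
            if not Path(p).exists():
                raise ValidationFailure(f"input path for {key!r} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValidationFailure("config file must contain a mapping")
        detector = DetectorConfig(**raw.pop("detector", {}))
        known = {"mode", "out_dir", "seed", "paths", "params"}
        unknown = set(raw) - known
        if unknown:
            raise ValidationFailure(f"unknown config keys: {sorted(unknown)}")
        return cls(detector=detector, **raw)

    def config_hash(self) -> str:
        """Hash of everything that determines the computation (not where
        its outputs land)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run(config: RunConfig) -> dict[str, Any]:
    """Execute the requested stages and write a manifest of every output."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "mode": config.mode,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "outputs": [],
        "warnings": [],
        "timings_s": {},
    }
    stages = _STAGES[config.mode]
    for stage in stages:
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                stage(config, manifest)
            except Exception as exc:
                raise type(exc)(
                    f"stage {stage.__name__.lstrip('_')} failed: {exc}"
                ) from exc
        for w in caught:
            manifest["warnings"].append(str(w.message))
            logger.warning("%s: %s", stage.__name__.lstrip("_"), w.message)
        manifest["timings_s"][stage.__name__.lstrip("_")] = round(
            time.perf_counter() - t0, 3
        )
    path = config.out_dir / "manifest.json"
    skio.write_json(manifest, path)
    return manifest


def _record(manifest: dict, path: Path) -> Path:
    manifest["outputs"].append(str(path))
    return path


def _simulate(config: RunConfig, manifest: dict) -> None:
    preset = config.params.get("preset", "stp")
    out = config.out_dir
    cfg = config.detector
    seed = config.seed
    if preset == "stp":
        scene = synthetic.make_stp_scene(cfg)
        times = config.params.get("exposure_times_ms", list(np.linspace(20, 500, 8)))
        dose_rate = config.params.get("dose_rate_mgy_s", 2.0)
        series = synthetic.make_stp_series(scene, cfg, times, dose_rate, seed)
        entries = []
        for i, (ak, stack) in enumerate(series.points):
            p = skio.write_stack(
                stack, out / f"raw_{i:02d}.tif",
                {"air_kerma_mgy": ak, "seed": seed,
                 "exposure_ms": series.exposure_times_ms[i]},
            )
            _record(manifest, p)
            entries.append({"stack": p.name, "air_kerma_mgy": ak})
        _record(manifest, skio.write_stack(series.flat, out / "flat.tif", {"seed": seed}))
        _record(manifest, skio.write_stack(series.dark, out / "dark.tif", {"seed": seed}))
        meta = {"preset": preset, "seed": seed, "dose_rate_mgy_s": dose_rate,
                "points": entries}
    elif preset == "edge":
        angle = config.params.get("edge_angle_deg", 5.0)
        sigma = config.params.get("psf_sigma_mm", 0.2)
        scene = synthetic.make_slanted_edge_scene(angle, sigma, 0.05, cfg)
        ak = config.params.get("air_kerma_mgy", 0.8)
        stack = synthetic.make_frame_stack(scene, cfg, ak, seed)
        dark_scene = dataclasses.replace(scene, edge_angle_deg=None)
        dark = synthetic.make_frame_stack(dark_scene, cfg, 0.0, seed + 1, label="dark")
        _record(manifest, skio.write_stack(stack, out / "edge.tif",
                {"seed": seed, "edge_angle_deg": angle, "psf_sigma_mm": sigma}))
        _record(manifest, skio.write_stack(dark, out / "dark.tif", {"seed": seed}))
        meta = {"preset": preset, "seed": seed, "edge_angle_deg": angle,
                "psf_sigma_mm": sigma}
    else:  # stretch
        scene = synthetic.make_stretch_scene(cfg)
        elongs = config.params.get("elongations_pct", [0, 20, 40, 60, 80, 100])
        series = synthetic.make_stretch_series(scene, elongs, seed=seed, config=cfg)
        entries = []
        for step in series.steps:
            p = skio.write_stack(
                step.stack, out / f"stretch_{int(step.elongation_pct):03d}.tif",
                {"elongation_pct": step.elongation_pct, "seed": seed},
            )
            _record(manifest, p)
            entries.append({"stack": p.name, "elongation_pct": step.elongation_pct})
        _record(manifest, skio.write_stack(series.dark, out / "dark.tif", {"seed": seed}))
        meta = {"preset": preset, "seed": seed, "t0_mm": series.t0_mm,
                "steps": entries}
    _record(manifest, skio.write_json(meta, out / "simulation.json"))


def _preprocess(config: RunConfig, manifest: dict) -> None:
    out = config.out_dir
    raw = skio.read_stack(config.paths["raw"], config.detector)
    flat = skio.read_stack(config.paths["flat"], config.detector)
    dark = skio.read_stack(config.paths["dark"], config.detector)
    flat_mean = average_frames(flat)
    dark_mean = average_frames(dark)
    roi = detect_skin_roi(
        flat_mean, dark_mean,
        full_scale=config.detector.full_scale,
        border_erosion_px=config.params.get("border_erosion_px", 0),
    )
    corrected = flat_field_correct(
        average_frames(raw), dark_mean, flat_mean, roi,
        full_scale=config.detector.full_scale,
    )
    _record(manifest, skio.write_corrected(corrected, out / "corrected.tif"))
    skio.write_roi(roi, out / "roi_mask.png", out / "roi_contour.csv")
    _record(manifest, out / "roi_mask.png")
    _record(manifest, out / "roi_contour.csv")
    _record(manifest, skio.write_json(
        {"m": corrected.m, "roi_area_px": roi.area_px}, out / "preprocess.json"))


def _stp(config: RunConfig, manifest: dict) -> None:
    out = config.out_dir
    spec = yaml.safe_load(Path(config.paths["manifest"]).read_text())
    base = Path(config.paths["manifest"]).parent
    flat = skio.read_stack(base / spec["flat"], config.detector)
    dark = skio.read_stack(base / spec["dark"], config.detector)
    flat_mean = average_frames(flat)
    dark_mean = average_frames(dark)
    roi = detect_skin_roi(flat_mean, dark_mean, full_scale=config.detector.full_scale)
    points = []
    for entry in spec["points"]:
        stack = skio.read_stack(base / entry["stack"], config.detector)
        corrected = flat_field_correct(
            average_frames(stack), dark_mean, flat_mean, roi,
            full_scale=config.detector.full_scale,
        )
        points.append(StpPoint(air_kerma=float(entry["air_kerma_mgy"]),
                               mpv=mean_pixel_value(corrected)))
    fit = fit_stp(points)
    pd.DataFrame([dataclasses.asdict(p) for p in points]).to_csv(
        out / "stp_points.csv", index=False)
    _record(manifest, out / "stp_points.csv")
    fit_dict = dataclasses.asdict(fit)
    fit_dict["relative_deviations"] = list(fit.relative_deviations)
    _record(manifest, skio.write_json(fit_dict, out / "stp_fit.json"))


def _esfr(config: RunConfig, manifest: dict) -> None:
    out = config.out_dir
    image = skio.read_stack(config.paths["image"], config.detector)
    mean = average_frames(image)
    x, y, w, h = config.params.get("roi_xywh", _default_edge_roi(mean.shape))
    roi = EdgeRoi(
        pixels=mean[y : y + h, x : x + w],
        pitch_mm=config.params.get("pitch_mm", config.detector.pixel_pitch_mm),
        orientation=config.params.get("orientation", "vertical"),
    )
    curve = compute_sfr(roi, oversample=config.params.get("oversample", 4))
    pd.DataFrame(
        {"frequency_lp_mm": curve.frequencies, "sfr": curve.values}
    ).to_csv(out / "sfr_curve.csv", index=False)
    _record(manifest, out / "sfr_curve.csv")
    _record(manifest, skio.write_json(
        {"sfr50_lp_mm": curve.sfr50, "sfr10_lp_mm": curve.sfr10,
         "edge_angle_deg": curve.edge_angle_deg}, out / "sfr_summary.json"))


def _default_edge_roi(shape: tuple[int, int]) -> tuple[int, int, int, int]:
    h0, w0 = shape
    w, h = min(128, w0), min(120, h0)
    return (w0 - w) // 2, (h0 - h) // 2, w, h


def _stretch(config: RunConfig, manifest: dict) -> None:
    out = config.out_dir
    spec = yaml.safe_load(Path(config.paths["manifest"]).read_text())
    base = Path(config.paths["manifest"]).parent

    class _Step:
        def __init__(self, elongation_pct, stack):
            self.elongation_pct = elongation_pct
            self.stack = stack

    class _Series:
        pass

    series = _Series()
    series.dark = skio.read_stack(base / spec["dark"], config.detector)
    series.t0_mm = float(spec.get("t0_mm", 0.5))
    series.steps = [
        _Step(float(e["elongation_pct"]),
              skio.read_stack(base / e["stack"], config.detector))
        for e in spec["steps"]
    ]
    table, trends = analyse_stretch_series(
        series,
        n_bins=config.params.get("n_bins", 256),
        full_scale=config.detector.full_scale,
    )
    table.to_csv(out / "stretch_table.csv", index=False)
    _record(manifest, out / "stretch_table.csv")
    _record(manifest, skio.write_json(
        {k: dataclasses.asdict(v) for k, v in trends.items()},
        out / "stretch_trends.json"))


def _full(config: RunConfig, manifest: dict) -> None:
    """Simulate every preset, then run the matching analysis on each."""
    for preset in PRESETS:
        sim_dir = config.out_dir / f"sim_{preset}"
        sim_cfg = RunConfig(
            mode="simulate", out_dir=sim_dir, seed=config.seed,
            detector=config.detector, params={**config.params, "preset": preset},
        )
        sub = run(sim_cfg)
        manifest["outputs"].extend(sub["outputs"])
        ana_dir = config.out_dir / f"analysis_{preset}"
        if preset == "stp":
            meta = skio.read_json(sim_dir / "simulation.json")
            man = {"flat": "flat.tif", "dark": "dark.tif", "points": meta["points"]}
            man_path = sim_dir / "stp_manifest.yaml"
            man_path.write_text(yaml.safe_dump(man))
            ana = RunConfig(mode="stp", out_dir=ana_dir, seed=config.seed,
                            detector=config.detector,
                            paths={"manifest": str(man_path)})
        elif preset == "edge":
            ana = RunConfig(mode="esfr", out_dir=ana_dir, seed=config.seed,
                            detector=config.detector,
                            paths={"image": str(sim_dir / "edge.tif")},
                            params=dict(config.params))
        else:
            meta = skio.read_json(sim_dir / "simulation.json")
            man = {"dark": "dark.tif", "t0_mm": meta["t0_mm"], "steps": meta["steps"]}
            man_path = sim_dir / "stretch_manifest.yaml"
            man_path.write_text(yaml.safe_dump(man))
            ana = RunConfig(mode="stretch", out_dir=ana_dir, seed=config.seed,
                            detector=config.detector,
                            paths={"manifest": str(man_path)})
        sub = run(ana)
        manifest["outputs"].extend(sub["outputs"])
        manifest["warnings"].extend(sub["warnings"])


_STAGES = {
    "simulate": [_simulate],
    "preprocess": [_preprocess],
    "stp": [_stp],
    "esfr": [_esfr],
    "stretch": [_stretch],
    "full": [_full],
}
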