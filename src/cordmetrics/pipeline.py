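"""Configuration, logging, and the end-to-end simulate-then-analyze pipeline.

``run_pipeline`` generates a synthetic dataset (histology image, recording,
structure masks, landmark scenes) from one seed, runs every analysis stage
on it, writes per-stage JSON/CSV outputs, and records a machine-readable
manifest (config echo, package version, seeds, result hash).  Reruns under
an identical config produce an identical manifest hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError
from . import ephys, histology, morphometry, posture, simulate

log = logging.getLogger("cordmetrics")


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=level, handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class HistologyConfig:
    k: int = 16
    radius: int = 1
    delta: float = 20.0
    pixel_size: float = 0.65
    image_size: int = 192          # synthetic demo image edge, px


@dataclass
class EphysConfig:
    band_low: float = 500.0
    band_high: float = 5000.0
    bin_ms: float = 1.0
    response_window_ms: tuple[float, float] = (0.5, 10.0)
    latency_sd_tol: float = 0.3
    amplitude_cv_tol: float = 0.3
    min_high_freq: float = 100.0
    min_high_freq_eff: float = 90.0


@dataclass
class MorphometryConfig:
    min_size: int = 10
    pixel_size: float = 1.0
    rostro_caudal_axis: str = "columns"


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "cordmetrics_out"
    histology: HistologyConfig = field(default_factory=HistologyConfig)
    ephys: EphysConfig = field(default_factory=EphysConfig)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)


def validate_config(cfg: PipelineConfig) -> None:
    """Range-check every parameter before any stage runs."""
    if cfg.seed < 0:
        raise ConfigError("seed", "must be >= 0")
    h = cfg.histology
    if h.k < 2:
        raise ConfigError("histology.k", "must be >= 2")
    if h.radius < 1:
        raise ConfigError("histology.radius", "must be >= 1")
    if h.delta <= 0:
        raise ConfigError("histology.delta", "must be positive")
    if h.pixel_size <= 0:
        raise ConfigError("histology.pixel_size", "must be positive")
    if h.image_size < 32:
        raise ConfigError("histology.image_size", "must be >= 32")
    e = cfg.ephys
    if not 0 < e.band_low < e.band_high:
        raise ConfigError("ephys.band_low", "need 0 < band_low < band_high")
    if e.bin_ms <= 0:
        raise ConfigError("ephys.bin_ms", "must be positive")
    w0, w1 = e.response_window_ms
    if not 0 <= w0 < w1:
        raise ConfigError("ephys.response_window_ms", "need 0 <= start < end")
    m = cfg.morphometry
    if m.min_size < 0:
        raise ConfigError("morphometry.min_size", "must be >= 0")
    if m.pixel_size <= 0:
        raise ConfigError("morphometry.pixel_size", "must be positive")
    if m.rostro_caudal_axis not in ("rows", "columns"):
        raise ConfigError("morphometry.rostro_caudal_axis", "must be 'rows' or 'columns'")


def _build_section(cls, data: dict, prefix: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"{prefix}.{sorted(unknown)[0]}", "unknown field")
    # tuples arrive as lists from YAML
    kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(prefix, str(exc)) from exc


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    sections = {}
    for name, cls in (("histology", HistologyConfig), ("ephys", EphysConfig),
                      ("morphometry", MorphometryConfig)):
        sections[name] = _build_section(cls, data.pop(name, {}) or {}, name)
    known = {"seed", "output_dir"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(sorted(unknown)[0], "unknown field")
    cfg = PipelineConfig(seed=int(data.get("seed", 0)),
                         output_dir=str(data.get("output_dir", "cordmetrics_out")),
                         **sections)
    validate_config(cfg)
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    if not path.exists():
        raise DataError(f"config file not found: {path}")
    with open(path) as f:
        try:
            data = yaml.safe_load(f)
        except yaml.YAMLError as exc:
            raise ConfigError("<file>", f"not valid YAML: {exc}") from exc
    if data is not None and not isinstance(data, dict):
        raise ConfigError("<file>", "top level must be a mapping")
    return config_from_dict(data or {})


# --------------------------------------------------------------------------
# pipeline stages
# --------------------------------------------------------------------------

def _histology_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    h = cfg.histology
    params = simulate.SynthHistologyParams(
        width=h.image_size, height=h.image_size, pixel_size=h.pixel_size,
        collagen_layout="clustered", seed=cfg.seed + 1)
    image, truth = simulate.gen_trichrome_image(params)
    model = histology.cluster_colors(image, k=h.k, seed=cfg.seed + 1)
    classmap = histology.classify_clusters(
        model, histology.ClassRule(delta=h.delta))
    areas = histology.quantify_areas(classmap, h.pixel_size)
    intensity = histology.blue_intensity(image, classmap)
    cmap = histology.compactness(
        intensity, radius=h.radius,
        mask=classmap.classes == histology.TissueClass.COLLAGEN)
    hist = histology.bin_compactness(cmap, pixel_size=h.pixel_size)
    classmap.class_rule.to_csv(outdir / "histology_clusters.csv", index=False)
    result = {
        "area_per_class_um2": areas.area_per_class,
        "blue_purple_ratio": areas.blue_purple_ratio,
        "ratio_defined": areas.ratio_defined,
        "compactness_level_fractions": hist.level_fractions.tolist(),
        "true_fractions": params.fractions().tolist(),
    }
    return result


def _ephys_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    e = cfg.ephys
    params = simulate.SynthRecordingParams(
        stim_blocks=((5.0, 40), (200.0, 60)), unit_latency=3.0,
        latency_jitter_sd=0.05, response_prob=1.0, spont_rate=15.0,
        noise_sd=5.0, spike_amplitude=120.0, seed=cfg.seed + 2)
    rec, truth, spont = simulate.gen_recording(params)
    filtered = ephys.bandpass_filter(rec, e.band_low, e.band_high)
    spikes = ephys.detect_spikes(filtered, baseline_window=(0.0, params.baseline * 0.9))
    responses = ephys.build_response_table(
        spikes, rec.stim_times, e.response_window_ms, rec.stim_freqs)
    spont_detected = ephys.spontaneous_spikes(spikes, rec.stim_times,
                                              e.response_window_ms)
    flags = (
        ephys.check_constant_latency(responses, e.latency_sd_tol, e.amplitude_cv_tol),
        ephys.check_frequency_following(responses, e.min_high_freq, e.min_high_freq_eff),
        ephys.collision_test(responses, spont_detected, expected_latency_ms=3.0),
    )
    verdict = ephys.classify_antidromic(*flags, responses=responses)
    responses.to_csv(outdir / "ephys_responses.csv", index=False)
    hist = ephys.psth(spikes.spike_times, rec.stim_times,
                      bin_ms=e.bin_ms, window_ms=(-20.0, 20.0))
    return {
        "efficiency_pct": ephys.efficiency(responses),
        "true_responded_fraction_pct": 100.0 * float(truth["responded"].mean()),
        "classification": verdict.classification,
        "n_criteria_met": verdict.n_criteria_met,
        "caudal_respondent": ephys.caudal_responsiveness(hist),
        "n_detected_spikes": int(spikes.spike_times.size),
    }


def _morphometry_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    m = cfg.morphometry
    result = {}
    for placement in ("uniform", "border"):
        params = simulate.SynthStructureParams(
            n_structures=12, kind="neurite", placement=placement,
            pixel_size=m.pixel_size, rostro_caudal_axis=m.rostro_caudal_axis,
            seed=cfg.seed + 3)
        mask, truth = simulate.gen_structure_mask(params)
        smask = morphometry.StructureMask(mask, m.pixel_size, m.rostro_caudal_axis)
        stats = morphometry.measure_structures(smask, kind="neurite")
        dhi = histology.compute_dhi(mask)
        truth.to_csv(outdir / f"morpho_truth_{placement}.csv", index=False)
        result[placement] = {
            "n_structures": stats.n_structures,
            "true_n_structures": int(len(truth)),
            "total_length_um": stats.total_length,
            "true_total_length_um": float(truth["length_um"].sum()),
            "dhi": dhi.dhi,
        }
    return result


def _angles_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    frames = []
    requested = [(150.0, 20.0), (120.0, 35.0), (95.0, 10.0), (170.0, 5.0)]
    for i, (ctl, trunk) in enumerate(requested):
        scene = simulate.gen_landmark_scene(ctl, trunk, seed=cfg.seed + 4 + i,
                                            frame_id=i)
        c, t = posture.scene_angles(scene)
        frames.append({"frame": i, "ctl_angle": c, "trunk_angle": t,
                       "true_ctl": ctl, "true_trunk": trunk})
    df = pd.DataFrame(frames)
    df.to_csv(outdir / "angles.csv", index=False)
    ranges = posture.angle_range(df)
    return {"per_frame": df[["ctl_angle", "trunk_angle"]].round(9).to_dict("records"),
            "ctl_range": ranges["ctl_angle"]["range"],
            "trunk_range": ranges["trunk_angle"]["range"]}


def _canonical(obj):
    if isinstance(obj, dict):
        return {k: _canonical(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float):
        return round(obj, 12)
    return obj


def run_pipeline(cfg: PipelineConfig, output_dir: str | Path | None = None) -> dict:
    """Run every stage on self-generated data; returns the manifest."""
    validate_config(cfg)
    outdir = Path(output_dir if output_dir is not None else cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: seed=%d out=%s", cfg.seed, outdir)
    results = {
        "histology": _histology_stage(cfg, outdir),
        "ephys": _ephys_stage(cfg, outdir),
        "morphometry": _morphometry_stage(cfg, outdir),
        "angles": _angles_stage(cfg, outdir),
    }
    manifest = {
        "package": "cordmetrics",
        "version": __version__,
        "seed": cfg.seed,
        "config": _canonical(dataclasses.asdict(cfg)),
        "results": _canonical(results),
    }
    payload = json.dumps(manifest, sort_keys=True).encode()
    manifest["manifest_hash"] = hashlib.sha256(payload).hexdigest()
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    log.info("pipeline done: hash=%s", manifest["manifest_hash"])
    return manifest
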