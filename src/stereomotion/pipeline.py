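"""End-to-end pipeline: (simulate) -> register -> detect -> track -> kinetics.

Configuration is a validated YAML document (unknown keys rejected); every
output directory receives a provenance record with the configuration hash,
seed and package version so any result bundle can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .simcore import (DriftModel, Movie, MotilityModel, PhotophysicsModel,
                      SimulationConfig, StereociliumGeometry, simulate_movie)
from .register import correct_movie
from .spots import SpotDetection, detect_puncta, sum_intensity, detections_to_csv
from .kymotrack import (OrganellePath, Track, build_kymograph, link_tracks,
                        project_to_axis, tracks_to_csv)
from .kinetics import (classify_motility, detect_steps, summarize_velocities,
                       velocity_of_track, summary_to_json)

log = logging.getLogger("stereomotion")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EmitterSpec(_Strict):
    mode: str = "static"
    start_nm: float = 0.0
    n: int = 1
    speed: float = 100.0
    diffusion_coeff: float = 1.0e5
    step_size: float = 150.0
    step_rate: float = 0.1
    duty_on: float = 0.5
    duty_off: float = 0.5
    n_fluorophores: int = 1
    bleach_rate: float = 0.0
    dark_on_rate: float = 0.0
    dark_off_rate: float = 0.0
    start_spacing_nm: float = 0.0  # spacing between the n copies


class SimulationBlock(_Strict):
    image_shape: tuple[int, int] = (64, 256)
    n_frames: int = 100
    exposure: float = 0.1
    psf_sigma: float = 152.0
    quantal_yield: float = 200.0
    background_rate: float = 10.0
    read_noise_sd: float = 2.0
    camera_gain: float = 1.0
    camera_offset: float = 100.0
    drift_velocity: tuple[float, float] = (0.0, 0.0)
    drift_random_walk_sd: float = 0.0
    axis_base_nm: tuple[float, float] = (2000.0, 5000.0)
    axis_tip_nm: tuple[float, float] = (38000.0, 5000.0)
    axis_radius_nm: float = 0.0
    emitters: list[EmitterSpec] = Field(default_factory=list)


class RegistrationBlock(_Strict):
    enabled: bool = True
    reference: int | str = "first"
    mode: str = "chained"


class DetectionBlock(_Strict):
    threshold_sd: float = 5.0
    min_separation: int = 5
    window_radius: int = 3
    annulus: tuple[float, float] = (5.0, 7.0)


class LinkingBlock(_Strict):
    max_jump_nm: float = 500.0
    max_gap: int = 2


class KineticsBlock(_Strict):
    min_frames: int = 4
    loc_noise_nm: float = 30.0
    v_min: float = 20.0
    r2_min: float = 0.8
    dwell_min: int = 2
    min_duration_s: float = 0.0


class PathBlock(_Strict):
    control_points_px: Optional[list[tuple[float, float]]] = None
    half_width_px: float = 2.0


class PipelineConfig(_Strict):
    """Validated pipeline configuration (YAML-serializable)."""

    input_movie: Optional[str] = None
    simulation: Optional[SimulationBlock] = None
    pixel_size: float = Field(gt=0)
    frame_interval: float = Field(gt=0)
    seed: int = 0
    output_dir: str = "stereomotion_out"
    registration: RegistrationBlock = Field(default_factory=RegistrationBlock)
    detection: DetectionBlock = Field(default_factory=DetectionBlock)
    linking: LinkingBlock = Field(default_factory=LinkingBlock)
    kinetics: KineticsBlock = Field(default_factory=KineticsBlock)
    path: PathBlock = Field(default_factory=PathBlock)

    @model_validator(mode="after")
    def _check_source(self) -> "PipelineConfig":
        if self.input_movie is None and self.simulation is None:
            raise ValueError("config needs either input_movie or a simulation block")
        if self.input_movie is not None and not Path(self.input_movie).exists():
            raise ValueError(f"input_movie not found: {self.input_movie}")
        return self

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str)
            .encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig(**yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    """Bundle of everything one pipeline run produced."""

    movie: Movie
    corrected: Movie
    drift_trace: object
    detections: list[list[SpotDetection]]
    tracks: list[Track]
    kymograph: object
    per_track: list[dict]
    summary: dict
    ground_truth: object = None
    output_dir: Path = None


def _emitters_from_block(block: SimulationBlock
                         ) -> list[tuple[MotilityModel, PhotophysicsModel, float]]:
    out = []
    for spec in block.emitters:
        mot = MotilityModel(mode=spec.mode, speed=spec.speed,
                            diffusion_coeff=spec.diffusion_coeff,
                            step_size=spec.step_size, step_rate=spec.step_rate,
                            duty_on=spec.duty_on, duty_off=spec.duty_off)
        photo = PhotophysicsModel(n_fluorophores=spec.n_fluorophores,
                                  bleach_rate=spec.bleach_rate,
                                  dark_on_rate=spec.dark_on_rate,
                                  dark_off_rate=spec.dark_off_rate)
        for i in range(spec.n):
            out.append((mot, photo, spec.start_nm + i * spec.start_spacing_nm))
    return out


def simulate_from_config(config: PipelineConfig
                         ) -> tuple[Movie, object, StereociliumGeometry]:
    blk = config.simulation
    sim_cfg = SimulationConfig(
        image_shape=tuple(blk.image_shape), pixel_size=config.pixel_size,
        frame_interval=config.frame_interval, n_frames=blk.n_frames,
        exposure=blk.exposure, psf_sigma=blk.psf_sigma,
        quantal_yield=blk.quantal_yield, background_rate=blk.background_rate,
        read_noise_sd=blk.read_noise_sd, camera_gain=blk.camera_gain,
        camera_offset=blk.camera_offset,
        drift_model=DriftModel(velocity=tuple(blk.drift_velocity),
                               random_walk_sd=blk.drift_random_walk_sd),
        seed=config.seed)
    geometry = StereociliumGeometry(base_point=tuple(blk.axis_base_nm),
                                    tip_point=tuple(blk.axis_tip_nm),
                                    radius=blk.axis_radius_nm)
    movie, truth = simulate_movie(sim_cfg, geometry, _emitters_from_block(blk))
    return movie, truth, geometry


def default_path_for(config: PipelineConfig,
                     geometry: StereociliumGeometry | None) -> OrganellePath:
    if config.path.control_points_px is not None:
        pts = np.asarray(config.path.control_points_px)
    elif geometry is not None:
        pts = np.array([geometry.base_point, geometry.tip_point]) / config.pixel_size
    else:
        raise ValueError("config.path.control_points_px required for real movies")
    return OrganellePath(control_points=pts,
                         half_width=config.path.half_width_px,
                         pixel_size=config.pixel_size)


def run_pipeline(config: PipelineConfig, write_outputs: bool = True
                 ) -> PipelineResult:
    """Run all stages and (optionally) write the result bundle to disk."""
    stage = "setup"
    try:
        truth = geometry = None
        if config.simulation is not None:
            stage = "simulate"
            movie, truth, geometry = simulate_from_config(config)
        else:
            stage = "load"
            movie = Movie.from_tiff(config.input_movie, config.pixel_size,
                                    config.frame_interval)

        stage = "register"
        if config.registration.enabled and movie.n_frames >= 2:
            corrected, trace = correct_movie(movie,
                                             reference=config.registration.reference,
                                             mode=config.registration.mode)
        else:
            corrected, trace = movie, None

        stage = "detect"
        det = config.detection
        psf_sigma_px = ((config.simulation.psf_sigma if config.simulation else 152.0)
                        / config.pixel_size)
        detections = []
        for t in range(corrected.n_frames):
            ds = detect_puncta(corrected.frames[t], psf_sigma_px=psf_sigma_px,
                               min_separation=det.min_separation,
                               threshold_sd=det.threshold_sd,
                               window_radius=det.window_radius)
            for d in ds:
                d.frame = t
                sum_intensity(corrected.frames[t], d,
                              window_radius=det.window_radius,
                              annulus=det.annulus)
            detections.append(ds)

        stage = "track"
        tracks = link_tracks(detections, max_jump_nm=config.linking.max_jump_nm,
                             max_gap=config.linking.max_gap,
                             pixel_size=config.pixel_size)
        path = default_path_for(config, geometry)
        for tr in tracks:
            project_to_axis(tr, path)

        stage = "kymograph"
        kymo = build_kymograph(corrected, path)

        stage = "kinetics"
        kin = config.kinetics
        per_track = []
        estimates = []
        mode_counts: dict[str, int] = {}
        for tr in tracks:
            s = tr.s_nm
            t_s = tr.times(config.frame_interval)
            call = classify_motility(s, config.frame_interval,
                                     loc_noise_nm=kin.loc_noise_nm,
                                     min_frames=kin.min_frames,
                                     v_min=kin.v_min, r2_min=kin.r2_min,
                                     dwell_min=kin.dwell_min)
            mode_counts[call.mode] = mode_counts.get(call.mode, 0) + 1
            rec = {"track_id": tr.track_id, "mode": call.mode,
                   "v_nm_s": np.nan, "se": np.nan, "r2": np.nan,
                   "n_steps": call.n_steps, "mean_step_nm": np.nan,
                   "duration_s": (t_s[-1] - t_s[0]) if len(t_s) > 1 else 0.0,
                   "n_points": tr.n_frames}
            finite = np.isfinite(s)
            if finite.sum() >= kin.min_frames:
                est = velocity_of_track(s[finite], t_s[finite],
                                        min_frames=kin.min_frames)
                estimates.append(est)
                rec.update(v_nm_s=est.velocity, se=est.stderr, r2=est.r_squared)
                if finite.sum() >= 6:
                    sf = detect_steps(s[finite], noise_sd=kin.loc_noise_nm,
                                      min_plateau=kin.dwell_min)
                    if sf.n_steps:
                        rec["mean_step_nm"] = float(np.mean(np.abs(sf.step_sizes)))
            per_track.append(rec)

        vsum = summarize_velocities(estimates, min_duration=kin.min_duration_s,
                                    min_r_squared=kin.r2_min,
                                    direction="tipward")
        summary = {
            "n_tracks": len(tracks),
            "mode_counts": mode_counts,
            "tipward_velocity_mean_nm_s": vsum.mean,
            "tipward_velocity_sd_nm_s": vsum.sd,
            "tipward_n": vsum.n,
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "version": __version__,
        }
        result = PipelineResult(movie=movie, corrected=corrected,
                                drift_trace=trace, detections=detections,
                                tracks=tracks, kymograph=kymo,
                                per_track=per_track, summary=summary,
                                ground_truth=truth)
        if write_outputs:
            result.output_dir = _write_bundle(config, result)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc


def _write_bundle(config: PipelineConfig, result: PipelineResult) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"{config.content_hash()}_seed{config.seed}"
    result.corrected.to_tiff(out / f"corrected_{tag}.tif")
    if result.drift_trace is not None:
        result.drift_trace.to_csv(out / f"drift_{tag}.csv")
    flat = [d for ds in result.detections for d in ds]
    if flat:
        detections_to_csv(flat, out / f"detections_{tag}.csv")
    tracks_to_csv(result.tracks, out / f"tracks_{tag}.csv",
                  frame_interval=config.frame_interval)
    result.kymograph.to_tiff(out / f"kymograph_{tag}.tif")
    result.kymograph.to_png(out / f"kymograph_{tag}.png")
    import pandas as pd
    pd.DataFrame(result.per_track).to_csv(out / f"kinetics_{tag}.csv", index=False)
    summary_to_json(result.summary, out / f"summary_{tag}.json")
    provenance = {"version": __version__, "seed": config.seed,
                  "config_hash": config.content_hash(),
                  "config": config.model_dump()}
    (out / f"provenance_{tag}.json").write_text(
        json.dumps(provenance, indent=2, default=str))
    if result.ground_truth is not None:
        result.ground_truth.to_json(out / f"ground_truth_{tag}.json")
        result.ground_truth.positions_csv(out / f"true_positions_{tag}.csv")
    log.info("wrote result bundle to %s (tag %s)", out, tag)
    return out
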