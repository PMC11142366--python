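"""Synthetic single-plane time-lapse movies of stereocilium-confined emitters.

Emitters live on (or near) a 1-D axis embedded in a 2-D image, move according
to a per-emitter motility model (static, diffusive, processive, step-wise or
intermittent), photobleach and blink, and are rendered through a Gaussian
approximation of the microscope PSF onto a camera with Poisson shot noise,
Gaussian read noise, gain and offset.  Every movie comes with a complete
latent record (``GroundTruth``) so downstream estimators can be validated by
parameter recovery.

Units: positions in nm, time in s, rates in 1/s, image coordinates in pixels
with ``(x, y) = (column, row)`` and pixel centers at integer coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.special import erf

__all__ = [
    "DriftModel",
    "SimulationConfig",
    "StereociliumGeometry",
    "MotilityModel",
    "PhotophysicsModel",
    "EmitterTruth",
    "GroundTruth",
    "Movie",
    "sample_trajectory",
    "simulate_movie",
]

MotilityMode = Literal["static", "diffusive", "processive", "stepwise", "intermittent"]


@dataclass(frozen=True)
class DriftModel:
    """Lateral stage drift: a linear velocity plus a per-frame random walk.

    ``velocity`` is (x, y) in nm/s; ``random_walk_sd`` is the standard
    deviation of the isotropic per-frame random-walk increment in nm.
    """

    velocity: tuple[float, float] = (0.0, 0.0)
    random_walk_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.random_walk_sd < 0:
            raise ValueError("random_walk_sd must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Imaging and camera parameters for a simulated movie.

    Defaults emulate light-sheet single-plane time-lapse imaging of
    stereocilia: 100 ms exposure, frames every 0.1-1 s, a 40x/0.8 NA
    water-immersion objective (pixel size 162.5 nm, Gaussian PSF sigma
    ~152 nm from 0.21*lambda/NA at lambda = 580 nm).

    ``quantal_yield`` is the expected number of detected photons per
    fluorophore per frame; its absolute scale is arbitrary camera counts
    unless the user calibrates gain against a photon standard.
    """

    image_shape: tuple[int, int] = (64, 256)  # (rows, cols)
    pixel_size: float = 162.5  # nm / pixel
    frame_interval: float = 1.0  # s
    n_frames: int = 100
    exposure: float = 0.1  # s
    psf_sigma: float = 152.0  # nm
    quantal_yield: float = 200.0  # photons / fluorophore / frame
    background_rate: float = 10.0  # photons / pixel / frame
    read_noise_sd: float = 2.0  # camera counts
    camera_gain: float = 1.0  # counts / photon
    camera_offset: float = 100.0  # counts
    drift_model: DriftModel = field(default_factory=DriftModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.exposure > self.frame_interval:
            raise ValueError("exposure must be <= frame_interval")
        for name in ("quantal_yield", "background_rate", "read_noise_sd",
                     "camera_gain", "psf_sigma", "frame_interval", "exposure"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["drift_model"] = asdict(self.drift_model)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        drift = d.pop("drift_model", None)
        if drift is not None:
            drift = DriftModel(velocity=tuple(drift.get("velocity", (0.0, 0.0))),
                               random_walk_sd=drift.get("random_walk_sd", 0.0))
            d["drift_model"] = drift
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)


@dataclass(frozen=True)
class StereociliumGeometry:
    """Straight stereocilium axis from base to tip, in nm image coordinates.

    The axial coordinate s runs from 0 at the base to ``length`` at the tip.
    ``radius`` is the lateral confinement half-width; 0 confines emitters to
    the axis itself (the default regime for a thin protrusion imaged in a
    single plane).
    """

    base_point: tuple[float, float]
    tip_point: tuple[float, float]
    radius: float = 0.0

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.length <= 0:
            raise ValueError("base and tip must differ")

    @property
    def length(self) -> float:
        b = np.asarray(self.base_point, dtype=float)
        t = np.asarray(self.tip_point, dtype=float)
        return float(np.hypot(*(t - b)))

    @property
    def unit_vector(self) -> np.ndarray:
        b = np.asarray(self.base_point, dtype=float)
        t = np.asarray(self.tip_point, dtype=float)
        return (t - b) / self.length

    @property
    def normal_vector(self) -> np.ndarray:
        u = self.unit_vector
        return np.array([-u[1], u[0]])

    def axial_to_xy(self, s: np.ndarray, lateral: np.ndarray | float = 0.0) -> np.ndarray:
        """Map axial coordinates (nm) to 2-D (x, y) nm positions."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        b = np.asarray(self.base_point, dtype=float)
        xy = b[None, :] + s[:, None] * self.unit_vector[None, :]
        return xy + np.atleast_1d(lateral)[:, None] * self.normal_vector[None, :] \
            if np.any(np.asarray(lateral)) else xy


@dataclass(frozen=True)
class MotilityModel:
    """Motion law for one emitter along the stereocilium axis.

    Modes mirror the behaviors seen on kymographs of tagged molecules in
    stereocilia: ``static`` (anchored molecules), ``diffusive`` (free
    cytosolic tag), ``processive`` (dimeric motor walking tip-ward at
    constant speed), ``stepwise`` (tethered motor hopping between plateaus),
    ``intermittent`` (motor alternating pauses and tip-ward runs).
    Parameters irrelevant to the chosen mode are ignored.
    """

    mode: MotilityMode = "static"
    speed: float = 100.0  # nm/s, processive / intermittent
    diffusion_coeff: float = 1.0e5  # nm^2/s, diffusive
    step_size: float = 150.0  # nm, stepwise
    step_rate: float = 0.1  # 1/s, stepwise
    duty_on: float = 0.5  # 1/s, rate paused -> moving (intermittent)
    duty_off: float = 0.5  # 1/s, rate moving -> paused (intermittent)

    def __post_init__(self) -> None:
        relevant = {
            "static": (),
            "diffusive": ("diffusion_coeff",),
            "processive": ("speed",),
            "stepwise": ("step_size", "step_rate"),
            "intermittent": ("speed", "duty_on", "duty_off"),
        }
        if self.mode not in relevant:
            raise ValueError(f"unknown motility mode {self.mode!r}")
        for name in relevant[self.mode]:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 for mode {self.mode!r}")


@dataclass(frozen=True)
class PhotophysicsModel:
    """Fluorophore count, photobleaching and dark-state blinking.

    Each of ``n_fluorophores`` bleaches independently at ``bleach_rate``
    (absorbing) and blinks between emitting and dark states at
    ``dark_on_rate`` (emitting -> dark) and ``dark_off_rate`` (dark ->
    emitting).
    """

    n_fluorophores: int = 1
    bleach_rate: float = 0.0  # 1/s
    dark_on_rate: float = 0.0  # 1/s
    dark_off_rate: float = 0.0  # 1/s

    def __post_init__(self) -> None:
        if self.n_fluorophores < 1:
            raise ValueError("n_fluorophores must be >= 1")
        for name in ("bleach_rate", "dark_on_rate", "dark_off_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class EmitterTruth:
    """Latent record for one simulated emitter."""

    motility: MotilityModel
    photophysics: PhotophysicsModel
    start_s: float  # nm along axis
    axial_nm: np.ndarray  # (n_frames,) true axial position
    xy_nm: np.ndarray  # (n_frames, 2) true image-plane position (pre-drift)
    emitting: np.ndarray  # (n_fluorophores, n_frames) bool, per-fluorophore
    bleach_frame: np.ndarray  # (n_fluorophores,) first bleached frame or -1
    visible: np.ndarray = field(init=False)  # (n_frames,) any fluorophore emitting

    def __post_init__(self) -> None:
        self.visible = self.emitting.any(axis=0)


@dataclass
class GroundTruth:
    """Full latent state of a simulated movie."""

    emitters: list[EmitterTruth]
    drift_nm: np.ndarray  # (n_frames, 2) cumulative drift (x, y)
    config: SimulationConfig
    geometry: StereociliumGeometry

    def visible_lifetimes(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-emitter visible duration (s) and right-censoring flags.

        Duration counts frames from the start until the last frame with any
        emitting fluorophore; an emitter still visible in the final frame is
        censored.
        """
        dt = self.config.frame_interval
        durations, censored = [], []
        for em in self.emitters:
            vis = np.flatnonzero(em.visible)
            if vis.size == 0:
                continue
            durations.append((vis[-1] - vis[0] + 1) * dt)
            censored.append(bool(em.visible[-1]))
        return np.asarray(durations), np.asarray(censored, dtype=bool)

    def to_json(self, path: str | Path) -> None:
        recs = []
        for i, em in enumerate(self.emitters):
            recs.append({
                "emitter": i,
                "mode": em.motility.mode,
                "motility": asdict(em.motility),
                "photophysics": asdict(em.photophysics),
                "start_s_nm": em.start_s,
                "bleach_frame": em.bleach_frame.tolist(),
            })
        Path(path).write_text(json.dumps(recs, indent=2))

    def positions_csv(self, path: str | Path) -> None:
        rows = []
        for i, em in enumerate(self.emitters):
            for t in range(len(em.axial_nm)):
                rows.append((i, t, em.axial_nm[t], em.xy_nm[t, 0], em.xy_nm[t, 1],
                             bool(em.visible[t]),
                             self.drift_nm[t, 0], self.drift_nm[t, 1]))
        pd.DataFrame(rows, columns=["emitter", "frame", "s_nm", "x_nm", "y_nm",
                                    "visible", "drift_x_nm", "drift_y_nm"]).to_csv(
            path, index=False)


@dataclass
class Movie:
    """Time-ordered stack of 2-D frames with physical calibration."""

    frames: np.ndarray  # (n_frames, rows, cols)
    pixel_size: float  # nm / pixel
    frame_interval: float  # s

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def to_tiff(self, path: str | Path) -> None:
        data = np.clip(np.rint(self.frames), 0, 65535).astype(np.uint16)
        tifffile.imwrite(
            path, data, photometric="minisblack",
            metadata={"axes": "TYX",
                      "pixel_size_nm": self.pixel_size,
                      "frame_interval_s": self.frame_interval})

    @classmethod
    def from_tiff(cls, path: str | Path, pixel_size: float,
                  frame_interval: float) -> "Movie":
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        return cls(frames=data.astype(np.float64), pixel_size=pixel_size,
                   frame_interval=frame_interval)


def sample_trajectory(model: MotilityModel, geometry: StereociliumGeometry,
                      start: float, n_frames: int, frame_interval: float,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample axial positions (nm) at frame times for one motility model.

    Position is updated once per frame.  Diffusion is reflected at both
    ends of the axis; processive, step-wise and intermittent motion is
    tip-ward and absorbed at the tip (motors pile up at stereocilia tips).
    """
    if not 0 <= start <= geometry.length:
        raise ValueError(
            f"start position {start} nm outside axis [0, {geometry.length:.1f}] nm")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L, dt = geometry.length, frame_interval
    t = np.arange(n_frames) * dt

    if model.mode == "static":
        return np.full(n_frames, float(start))
    if model.mode == "processive":
        return np.minimum(start + model.speed * t, L)
    if model.mode == "diffusive":
        incr = rng.normal(0.0, np.sqrt(2 * model.diffusion_coeff * dt), n_frames - 1)
        s = np.empty(n_frames)
        s[0] = start
        for i, d in enumerate(incr):
            s[i + 1] = _reflect(s[i] + d, L)
        return s
    if model.mode == "stepwise":
        s = np.empty(n_frames)
        s[0] = start
        pos = float(start)
        # exponential waiting times between instantaneous tip-ward jumps
        next_step = rng.exponential(1.0 / model.step_rate)
        for i in range(1, n_frames):
            now = i * dt
            while next_step <= now and pos < L:
                pos = min(pos + model.step_size, L)
                next_step += rng.exponential(1.0 / model.step_rate)
            s[i] = pos
        return s
    if model.mode == "intermittent":
        s = np.empty(n_frames)
        s[0] = start
        pos = float(start)
        moving = True
        p_stop = 1.0 - np.exp(-model.duty_off * dt)
        p_go = 1.0 - np.exp(-model.duty_on * dt)
        for i in range(1, n_frames):
            if moving:
                pos = min(pos + model.speed * dt, L)
            if rng.random() < (p_stop if moving else p_go):
                moving = not moving
            s[i] = pos
        return s
    raise ValueError(f"unknown motility mode {model.mode!r}")


def _reflect(s: float, L: float) -> float:
    """Reflect a coordinate into [0, L]."""
    if L <= 0:
        return 0.0
    period = 2 * L
    s = s % period
    return period - s if s > L else s


def _sample_photophysics(photo: PhotophysicsModel, n_frames: int, dt: float,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-fluorophore emitting masks and bleach frames.

    Bleaching is absorbing.  Blinking is a two-state Markov chain sampled at
    frame resolution.
    """
    n = photo.n_fluorophores
    emitting = np.zeros((n, n_frames), dtype=bool)
    bleach_frame = np.full(n, -1, dtype=int)
    p_bleach = 1.0 - np.exp(-photo.bleach_rate * dt)
    p_dark = 1.0 - np.exp(-photo.dark_on_rate * dt)
    p_recover = 1.0 - np.exp(-photo.dark_off_rate * dt)
    for f in range(n):
        on = True
        for i in range(n_frames):
            emitting[f, i] = on
            if rng.random() < p_bleach:
                bleach_frame[f] = i + 1
                emitting[f, i + 1:] = False
                break
            if on and rng.random() < p_dark:
                on = False
            elif not on and rng.random() < p_recover:
                on = True
    return emitting, bleach_frame


def _pixel_integrated_gaussian(shape: tuple[int, int], x0: float, y0: float,
                               sigma_px: float, photons: float) -> np.ndarray:
    """Render a 2-D Gaussian of total mass ``photons`` integrated per pixel.

    Only a local window (+-5 sigma) is computed for speed; pixel (c, r)
    spans [c-0.5, c+0.5] x [r-0.5, r+0.5].
    """
    img = np.zeros(shape)
    half = max(3, int(np.ceil(5 * sigma_px)))
    c0, r0 = int(round(x0)), int(round(y0))
    cs = np.arange(max(0, c0 - half), min(shape[1], c0 + half + 1))
    rs = np.arange(max(0, r0 - half), min(shape[0], r0 + half + 1))
    if cs.size == 0 or rs.size == 0:
        return img
    z = np.sqrt(2.0) * sigma_px
    fx = 0.5 * (erf((cs + 0.5 - x0) / z) - erf((cs - 0.5 - x0) / z))
    fy = 0.5 * (erf((rs + 0.5 - y0) / z) - erf((rs - 0.5 - y0) / z))
    img[np.ix_(rs, cs)] = photons * np.outer(fy, fx)
    return img


def simulate_movie(
    config: SimulationConfig,
    geometry: StereociliumGeometry,
    emitters: Sequence[tuple[MotilityModel, PhotophysicsModel, float]] = (),
) -> tuple[Movie, GroundTruth]:
    """Simulate a single-plane time-lapse movie with full ground truth.

    Each entry of ``emitters`` is ``(motility, photophysics, start)`` with
    ``start`` in nm along the axis.  The pixel-value model is::

        counts = offset + gain * Poisson(signal + background) + N(0, read_noise_sd)

    where the per-fluorophore signal is ``quantal_yield`` photons spread over
    a pixel-integrated 2-D Gaussian PSF centered at the emitter's drifted
    position.  One master seed drives everything; per-emitter substreams are
    spawned deterministically so adding an emitter does not perturb others.
    """
    rows, cols = config.image_shape
    n, dt = config.n_frames, config.frame_interval
    ss = np.random.SeedSequence(config.seed)
    drift_ss, camera_ss, emitter_root = ss.spawn(3)
    emitter_streams = emitter_root.spawn(max(1, len(emitters)))

    # cumulative drift trajectory (nm)
    drift_rng = np.random.default_rng(drift_ss)
    v = np.asarray(config.drift_model.velocity, dtype=float)
    walk = drift_rng.normal(0.0, config.drift_model.random_walk_sd, (n, 2))
    walk[0] = 0.0
    drift_nm = np.arange(n)[:, None] * v[None, :] * dt + np.cumsum(walk, axis=0)

    sigma_px = config.psf_sigma / config.pixel_size
    signal = np.zeros((n, rows, cols))
    truth_emitters: list[EmitterTruth] = []
    for (motility, photo, start), sub_ss in zip(emitters, emitter_streams):
        if not 0 <= start <= geometry.length:
            raise ValueError(
                f"emitter start {start} nm outside geometry axis "
                f"[0, {geometry.length:.1f}] nm")
        traj_ss, photo_ss, lat_ss = sub_ss.spawn(3)
        axial = sample_trajectory(motility, geometry, start, n, dt,
                                  np.random.default_rng(traj_ss))
        # fixed per-emitter lateral offset within the confinement tube
        lateral = (float(np.random.default_rng(lat_ss).uniform(
            -geometry.radius, geometry.radius))
            if geometry.radius > 0 else 0.0)
        xy_nm = geometry.axial_to_xy(axial, lateral)
        emitting, bleach_frame = _sample_photophysics(
            photo, n, dt, np.random.default_rng(photo_ss))
        truth_emitters.append(EmitterTruth(
            motility=motility, photophysics=photo, start_s=float(start),
            axial_nm=axial, xy_nm=xy_nm, emitting=emitting,
            bleach_frame=bleach_frame))
        n_emit = emitting.sum(axis=0)
        for t in np.flatnonzero(n_emit):
            x_px = (xy_nm[t, 0] + drift_nm[t, 0]) / config.pixel_size
            y_px = (xy_nm[t, 1] + drift_nm[t, 1]) / config.pixel_size
            signal[t] += _pixel_integrated_gaussian(
                (rows, cols), x_px, y_px, sigma_px,
                config.quantal_yield * n_emit[t])

    cam_rng = np.random.default_rng(camera_ss)
    photons = cam_rng.poisson(signal + config.background_rate)
    frames = (config.camera_offset + config.camera_gain * photons
              + cam_rng.normal(0.0, config.read_noise_sd, signal.shape))
    movie = Movie(frames=frames, pixel_size=config.pixel_size,
                  frame_interval=config.frame_interval)
    truth = GroundTruth(emitters=truth_emitters, drift_nm=drift_nm,
                        config=config, geometry=geometry)
    return movie, truth
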