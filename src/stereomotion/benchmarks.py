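"""Seeded parameter-recovery benchmarks over the full analysis pipeline.

Each benchmark simulates a study condition of the imaging experiments this
package models — quantal puncta counting, stage-drift registration,
processive/step-wise/diffusive motility, photobleaching — runs the package's
own estimators on the synthetic data, and reports recovery statistics
against the simulator's ground truth.  They are used by the acceptance
checks and are convenient as reproducible demos.

All randomness derives from a single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .simcore import (DriftModel, MotilityModel, PhotophysicsModel,
                      SimulationConfig, StereociliumGeometry, sample_trajectory,
                      simulate_movie)
from .register import correct_movie, estimate_shift, _shift_bilinear
from .spots import classify_populations, detect_puncta, sum_intensity
from .kinetics import (bleaching_survival, classify_motility, detect_steps,
                       msd_curve)
from .pipeline import (EmitterSpec, PipelineConfig, SimulationBlock,
                       run_pipeline)

PIXEL_SIZE = 162.5  # nm, 40x objective with 6.5 um camera pixels
PSF_SIGMA = 152.0  # nm, 0.21 * lambda / NA at 580 nm, NA 0.8

_LONG_AXIS = dict(axis_base_nm=(500.0, 4000.0), axis_tip_nm=(81000.0, 4000.0))


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# quantal intensity ratio (one- vs two-fluorophore puncta)

def quantal_ratio_benchmark(seed: int, n_puncta: int = 40,
                            n_frames: int = 10) -> dict:
    """Simulate mixed 1-/2-fluorophore static puncta and recover the 2x ratio.

    Detects puncta per frame, measures background-subtracted summed
    intensities and fits the two-population classifier; reports the
    Pop2/Pop1 mean-intensity ratio and the label agreement with truth.
    """
    rng = np.random.default_rng(_sub_seed(seed, 1))
    geo = StereociliumGeometry((1000.0, 4000.0), (80000.0, 4000.0))
    starts = np.linspace(1000, 79000, n_puncta)
    rng.shuffle(starts)
    n_single = int(0.6 * n_puncta)
    emitters = [(MotilityModel(mode="static"),
                 PhotophysicsModel(n_fluorophores=1 if i < n_single else 2),
                 float(s))
                for i, s in enumerate(starts)]
    cfg = SimulationConfig(image_shape=(48, 512), n_frames=n_frames,
                           pixel_size=PIXEL_SIZE, psf_sigma=PSF_SIGMA,
                           seed=_sub_seed(seed, 2))
    movie, truth = simulate_movie(cfg, geo, emitters)

    true_x = np.array([e.xy_nm[0, 0] / PIXEL_SIZE for e in truth.emitters])
    true_nf = np.array([e.photophysics.n_fluorophores for e in truth.emitters])
    intensities, labels_true = [], []
    for t in range(movie.n_frames):
        for d in detect_puncta(movie.frames[t],
                               psf_sigma_px=PSF_SIGMA / PIXEL_SIZE):
            sum_intensity(movie.frames[t], d)
            intensities.append(d.intensity)
            labels_true.append(true_nf[np.argmin(np.abs(true_x - d.x))] - 1)
    fit = classify_populations(np.asarray(intensities))
    agreement = float(np.mean(np.asarray(labels_true) == fit.labels))
    return {"mean_ratio": fit.mean_ratio,
            "bimodal": fit.bimodal,
            "label_agreement": max(agreement, 1 - agreement),
            "n_measurements": len(intensities)}


# ---------------------------------------------------------------------------
# drift recovery

def _structured_scene(seed: int, n_frames: int, drift: DriftModel,
                      n_spots: int = 150) -> tuple:
    rng = np.random.default_rng(_sub_seed(seed, 3))
    geo = StereociliumGeometry((500.0, 5200.0), (41000.0, 5200.0), radius=2500.0)
    emitters = [(MotilityModel(mode="static"), PhotophysicsModel(),
                 float(s)) for s in rng.uniform(200, 40000, n_spots)]
    cfg = SimulationConfig(image_shape=(64, 256), n_frames=n_frames,
                           pixel_size=PIXEL_SIZE, psf_sigma=PSF_SIGMA,
                           quantal_yield=2000.0, drift_model=drift,
                           seed=_sub_seed(seed, 4))
    return simulate_movie(cfg, geo, emitters)


def drift_recovery_benchmark(seed: int, n_frames: int = 100) -> dict:
    """Recover known linear (subpixel and integer-step) and random-walk drift.

    Reports the RMS error (pixels) of the estimated cumulative shift against
    the simulator's drift record, per scenario and worst-case.
    """
    scenarios = {
        "subpixel": DriftModel(velocity=(40.0, -25.0)),
        "integer": DriftModel(velocity=(162.5, 0.0)),  # 1 px/frame along x
        "random_walk": DriftModel(random_walk_sd=8.0),
    }
    out = {}
    for name, drift in scenarios.items():
        nf = n_frames if name != "integer" else min(n_frames, 60)
        movie, truth = _structured_scene(seed, nf, drift)
        _, trace = correct_movie(movie)
        true_px = truth.drift_nm / PIXEL_SIZE
        true_px = true_px - true_px[0]
        err = np.column_stack([trace.dx_px, trace.dy_px]) - true_px
        out[f"rms_{name}"] = float(np.sqrt(np.mean(np.sum(err ** 2, axis=1))))
    out["rms_worst"] = max(out.values())
    return out


# ---------------------------------------------------------------------------
# subpixel oracle equivalence

def _fourier_shift(img: np.ndarray, dx: float, dy: float) -> np.ndarray:
    return np.real(np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(img),
                                                      (dy, dx))))


def ssd_grid_search(frame_a: np.ndarray, frame_b: np.ndarray,
                    center: tuple[float, float], half: float = 0.6,
                    steps: tuple[float, ...] = (0.1, 0.01)
                    ) -> tuple[float, float]:
    """Coarse-to-fine exhaustive search of the bilinear-resampling SSD.

    Independent oracle for the least-squares matcher: evaluates the mean
    squared difference between ``frame_b`` and ``frame_a`` resampled at every
    candidate shift on successively finer grids (final pitch 0.01 px).
    """
    cx, cy = center
    for step in steps:
        xs = np.arange(cx - half, cx + half + step / 2, step)
        ys = np.arange(cy - half, cy + half + step / 2, step)
        best = (np.inf, cx, cy)
        for x in xs:
            for y in ys:
                warped, mask = _shift_bilinear(frame_a, x, y)
                mask &= ndimage.binary_erosion(mask)
                v = float(np.mean((frame_b - warped)[mask] ** 2))
                if v < best[0]:
                    best = (v, x, y)
        _, cx, cy = best
        half = step
    return cx, cy


def subpixel_oracle_benchmark(seed: int) -> dict:
    """POC + least-squares shifts vs exhaustive SSD grid search, noise-free.

    Reports the maximum per-axis disagreement (pixels) over a set of
    subpixel translations of a smooth test image.
    """
    rng = np.random.default_rng(_sub_seed(seed, 5))
    img = ndimage.gaussian_filter(rng.normal(size=(64, 64)), 2.0)
    worst = 0.0
    for true in [(2.4, -1.6), (0.5, 0.5), (-1.25, 0.75)]:
        shifted = _fourier_shift(img, *true)
        (dx, dy), _, _, _ = estimate_shift(img, shifted)
        gx, gy = ssd_grid_search(img, shifted, (round(dx), round(dy)))
        worst = max(worst, abs(dx - gx), abs(dy - gy))
    return {"max_disagreement_px": float(worst)}


# ---------------------------------------------------------------------------
# end-to-end processive velocity recovery

def processive_velocity_benchmark(seed: int, v_true: float = 100.0,
                                  n_movies: int = 5,
                                  per_movie: int = 20) -> dict:
    """Full pipeline (simulate -> register -> detect -> link -> fit) velocity.

    ``n_movies * per_movie`` processive emitters walk tip-ward at ``v_true``
    nm/s; reports the mean recovered velocity over tracks classified as
    processive and its relative error.
    """
    vels = []
    for m in range(n_movies):
        cfg = PipelineConfig(
            pixel_size=PIXEL_SIZE, frame_interval=1.0,
            seed=_sub_seed(seed, 10 + m),
            simulation=SimulationBlock(
                image_shape=(48, 512), n_frames=100, psf_sigma=PSF_SIGMA,
                **_LONG_AXIS,
                emitters=[EmitterSpec(mode="processive",
                                      start_nm=1000.0 + i * 3500.0,
                                      speed=v_true)
                          for i in range(per_movie)]))
        res = run_pipeline(cfg, write_outputs=False)
        vels += [r["v_nm_s"] for r in res.per_track
                 if r["mode"] == "processive" and r["n_points"] >= 20]
    v = np.asarray(vels)
    return {"mean_velocity_nm_s": float(v.mean()),
            "sd_velocity_nm_s": float(v.std(ddof=1)),
            "n_tracks": int(v.size),
            "relative_error": float(abs(v.mean() - v_true) / v_true)}


# ---------------------------------------------------------------------------
# step-size recovery (staircase trajectories, 100-200 nm regime)

def step_recovery_benchmark(seed: int, n_tracks: int = 50,
                            noise_nm: float = 30.0) -> dict:
    """Staircases of 5 steps of 100-200 nm with plateaus >= 5 frames.

    Reports the fraction of true steps detected (change point within 2
    frames), the mean absolute step-size error over matched steps, and the
    false-positive step rate on flat noise.
    """
    rng = np.random.default_rng(_sub_seed(seed, 6))
    found, total, size_errs = 0, 0, []
    for _ in range(n_tracks):
        sizes = rng.uniform(100, 200, 5)
        plateaus = rng.integers(5, 11, 6)
        levels = np.concatenate([[0.0], np.cumsum(sizes)])
        s = np.concatenate([np.full(p, lv) for p, lv in zip(plateaus, levels)])
        true_cp = np.cumsum(plateaus[:-1])
        noisy = s + rng.normal(0, noise_nm, len(s))
        fit = detect_steps(noisy, noise_sd=noise_nm, min_plateau=3)
        total += len(true_cp)
        for j, cp in enumerate(true_cp):
            k = np.where(np.abs(fit.changepoints - cp) <= 2)[0]
            if k.size:
                found += 1
                size_errs.append(abs(fit.step_sizes[k[0]] - sizes[j]))
    flat_fp = 0
    for _ in range(100):
        flat = rng.normal(0, 20.0, 50)
        flat_fp += detect_steps(flat, noise_sd=20.0).n_steps > 0
    return {"detection_fraction": found / total,
            "mean_size_error_nm": float(np.mean(size_errs)),
            "flat_false_positive_rate": flat_fp / 100}


# ---------------------------------------------------------------------------
# diffusion coefficient recovery

def diffusion_recovery_benchmark(seed: int, d_true: float = 1.0e5,
                                 n_tracks: int = 50, n_frames: int = 200,
                                 noise_nm: float = 30.0) -> dict:
    """MSD-based D on simulated 1-D diffusion with localization noise."""
    rng = np.random.default_rng(_sub_seed(seed, 7))
    geo = StereociliumGeometry((0.0, 0.0), (1.0e6, 0.0))
    ds = []
    for _ in range(n_tracks):
        s = sample_trajectory(MotilityModel(mode="diffusive",
                                            diffusion_coeff=d_true),
                              geo, 5.0e5, n_frames, 1.0,
                              rng.integers(2 ** 31))
        s = s + rng.normal(0, noise_nm, n_frames)
        ds.append(msd_curve(s, 1.0).diffusion_coeff)
    ds = np.asarray(ds)
    return {"median_D_nm2_s": float(np.median(ds)),
            "relative_error": float(abs(np.median(ds) - d_true) / d_true),
            "within_30pct_fraction": float(np.mean(np.abs(ds - d_true)
                                                   < 0.3 * d_true))}


# ---------------------------------------------------------------------------
# photobleaching rate recovery

def bleach_recovery_benchmark(seed: int, k_true: float = 0.05,
                              n_emitters: int = 500,
                              n_frames: int = 100) -> dict:
    """Censored-exponential rate fit on simulated visible lifetimes."""
    geo = StereociliumGeometry((500.0, 2600.0), (40000.0, 2600.0),
                               radius=1500.0)
    rng = np.random.default_rng(_sub_seed(seed, 8))
    emitters = [(MotilityModel(mode="static"),
                 PhotophysicsModel(bleach_rate=k_true),
                 float(s)) for s in rng.uniform(200, 39000, n_emitters)]
    cfg = SimulationConfig(image_shape=(32, 256), n_frames=n_frames,
                           pixel_size=PIXEL_SIZE, psf_sigma=PSF_SIGMA,
                           seed=_sub_seed(seed, 9))
    _, truth = simulate_movie(cfg, geo, emitters)
    durations, censored = truth.visible_lifetimes()
    fit = bleaching_survival(durations, censored)
    return {"rate_per_s": fit.rate,
            "relative_error": float(abs(fit.rate - k_true) / k_true),
            "n_events": fit.n_events, "n_censored": fit.n_censored}


# ---------------------------------------------------------------------------
# control phenotypes (static under drift; free diffusion at 1 s intervals)

def control_phenotypes_benchmark(seed: int) -> dict:
    """Reproduce the behavior of the two imaging controls.

    Anchored molecules in a drifting movie must trace horizontal kymograph
    streaks after correction (|v| below 5 nm/s); freely diffusing molecules
    that exchange with the out-of-focus pool at 1 s frame intervals must
    mostly appear as single-frame tracks.
    """
    rng = np.random.default_rng(_sub_seed(seed, 11))
    starts = rng.uniform(1000, 79000, 30)
    cfg = PipelineConfig(
        pixel_size=PIXEL_SIZE, frame_interval=1.0, seed=_sub_seed(seed, 12),
        simulation=SimulationBlock(
            image_shape=(48, 512), n_frames=60, psf_sigma=PSF_SIGMA,
            drift_velocity=(30.0, -20.0), quantal_yield=800.0, **_LONG_AXIS,
            emitters=[EmitterSpec(mode="static", start_nm=float(s))
                      for s in starts]))
    res = run_pipeline(cfg, write_outputs=False)
    v_static = [abs(r["v_nm_s"]) for r in res.per_track
                if r["n_points"] >= 30 and np.isfinite(r["v_nm_s"])]

    starts = rng.uniform(2000, 78000, 30)
    cfg2 = PipelineConfig(
        pixel_size=PIXEL_SIZE, frame_interval=1.0, seed=_sub_seed(seed, 13),
        registration={"enabled": False},
        simulation=SimulationBlock(
            image_shape=(48, 512), n_frames=30, psf_sigma=PSF_SIGMA,
            **_LONG_AXIS,
            # free cytosolic tag: fast 1-D diffusion plus exchange with the
            # out-of-plane pool (most molecules vanish between 1 s frames)
            emitters=[EmitterSpec(mode="diffusive", start_nm=float(s),
                                  diffusion_coeff=1.0e6,
                                  dark_on_rate=3.0, dark_off_rate=0.3)
                      for s in starts]))
    res2 = run_pipeline(cfg2, write_outputs=False)
    lengths = np.array([tr.n_frames for tr in res2.tracks])
    return {"static_max_abs_velocity_nm_s": float(np.max(v_static)),
            "n_static_tracks": len(v_static),
            "single_frame_fraction": float(np.mean(lengths == 1)),
            "n_diffusive_tracks": int(lengths.size)}


# ---------------------------------------------------------------------------
# motility-mode classifier confusion

def classifier_benchmark(seed: int, per_mode: int = 100,
                         n_frames: int = 100,
                         noise_nm: float = 30.0) -> dict:
    """Per-mode accuracy on a 4-mode trajectory benchmark.

    100-frame observations at 1 s intervals (the movie length used
    throughout these benchmarks) at 30 nm localization noise; parameters
    follow the module defaults (v = 100 nm/s, D = 1e5 nm^2/s, 150 nm steps
    at 0.1 /s).
    """
    geo = StereociliumGeometry((0.0, 0.0), (60000.0, 0.0))
    rng = np.random.default_rng(_sub_seed(seed, 14))
    models = {
        "static": MotilityModel(mode="static"),
        "diffusive": MotilityModel(mode="diffusive", diffusion_coeff=1.0e5),
        "processive": MotilityModel(mode="processive", speed=100.0),
        "stepwise": MotilityModel(mode="stepwise", step_size=150.0,
                                  step_rate=0.1),
    }
    out = {}
    confusion = {}
    for true_mode, model in models.items():
        counts: dict[str, int] = {}
        for _ in range(per_mode):
            s = sample_trajectory(model, geo, rng.uniform(5000, 30000),
                                  n_frames, 1.0, rng.integers(2 ** 31))
            s = s + rng.normal(0, noise_nm, n_frames)
            call = classify_motility(s, 1.0, loc_noise_nm=noise_nm)
            counts[call.mode] = counts.get(call.mode, 0) + 1
        confusion[true_mode] = counts
        out[f"accuracy_{true_mode}"] = counts.get(true_mode, 0) / per_mode
    out["accuracy_min"] = min(out[f"accuracy_{m}"] for m in models)
    out["confusion"] = confusion
    return out
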