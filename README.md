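# stereomotion

Single-molecule motility analysis for light-sheet time-lapse movies of
stereocilia — the actin-cored protrusions on the apical surface of inner-ear
hair cells along which unconventional myosins (MYO7A, MYO10) traffic cargo.
The package reconstructs the full quantitative workflow of such experiments:

1. **Drift correction** — phase-only correlation (POC) with subpixel
   refinement, followed by iterative least-squares image matching, chained
   frame-to-frame and re-anchored to a reference frame.
2. **Punctum detection and quantal photometry** — band-pass detection of
   diffraction-limited spots, background-subtracted summed intensities
   `S = Σ(window) − b·area`, and an equal-variance two-component mixture
   that splits puncta into quantal populations: single-fluorophore spots of
   mean `q` and double-fluorophore spots of mean `≈ 2q`.
3. **Kymographs and tracking** — line-scan kymographs along the
   stereocilium axis (position vertical, time horizontal), greedy
   nearest-neighbor linking with gap closing, and projection of tracks to
   an axial coordinate `s(t)` in nm (0 at the base, positive toward the tip).
4. **Kinetics** — per-track velocities `v` from least-squares slopes of
   `s(t)`, step detection by piecewise-constant change-point fitting
   (binary segmentation, BIC penalty `2σ²ln n`), MSD scaling exponents
   `α` and diffusion coefficients `D` (1-D, `MSD = 2Dτ`), motility-mode
   classification (static / diffusive / processive / step-wise), and
   photobleaching rates from censored exponential survival fits.
5. **Simulation** — a synthetic movie generator with emitters confined to a
   1-D axis in 2-D frames, quantal per-fluorophore brightness,
   photobleaching and blinking, five motility modes, stage drift, and a
   Poisson + Gaussian camera model, with complete per-emitter ground truth.
   Every analysis stage is validated by parameter recovery against it.

Intended users: microscopists and image analysts quantifying molecular
motor movement in linear organelles (stereocilia, filopodia, microvilli)
from single-plane time-lapse TIFF data.

## Worked example

Write a pipeline configuration `demo.yaml`:

```yaml
pixel_size: 162.5        # nm per pixel
frame_interval: 1.0      # s
seed: 11
output_dir: demo_out
registration:
  enabled: false         # this movie has no injected drift
simulation:
  image_shape: [48, 512]
  n_frames: 60
  axis_base_nm: [500.0, 4000.0]
  axis_tip_nm: [81000.0, 4000.0]
  emitters:
    - {mode: processive, start_nm: 2000.0, speed: 100.0, n: 3, start_spacing_nm: 20000.0}
    - {mode: static, start_nm: 70000.0}
    - {mode: stepwise, start_nm: 30000.0, step_size: 150.0, step_rate: 0.1}
```

and run the full pipeline:

```sh
stereomotion run --config demo.yaml
```

which simulates the movie, detects and links puncta, builds the kymograph
and prints the kinetics summary:

```json
{
  "n_tracks": 7,
  "mode_counts": {"static": 1, "stepwise": 1, "processive": 3, "unclassified": 2},
  "tipward_velocity_mean_nm_s": 80.59,
  "tipward_velocity_sd_nm_s": 38.53,
  "tipward_n": 4,
  "config_hash": "5753956d4b7e",
  "seed": 11
}
```

`demo_out/kinetics_<hash>_seed11.csv` holds the per-track calls:

```
track_id  mode        v_nm_s   r2    n_steps  mean_step_nm  n_points
0         static       -0.10   0.00  0        -             60
1         stepwise     22.80   0.94  7        170.2         60
2         processive   99.80   1.00  0        -             60
3         processive  100.00   1.00  0        -             60
4         processive   99.76   1.00  0        -             60
```

The three processive emitters (simulated at 100 nm/s) are recovered at
99.8–100.0 nm/s; the anchored emitter reads −0.1 nm/s (a horizontal
kymograph streak); the tethered stepper yields 7 steps of 170 nm mean size
(simulated: 150 nm jumps at 0.1 /s). The two single-point tracks are
blinking remnants that no mode rule can (or should) classify. The tip-ward
summary mean (80.6 ± 38.5 nm/s, n = 4) averages the three movers with the
slower stepper, the same statistic one would quote for a population of
directionally moving molecules.

`demo_out/` also contains the drift trace, detections, tracks, kymograph
TIFF/PNG, ground truth, and a provenance record (config hash + seed) that
makes the run exactly reproducible.

Real movies are analyzed the same way with `input_movie: movie.tif` instead
of the `simulation:` block and a `path:` block giving the stereocilium axis
as pixel control points. Individual stages are exposed as `stereomotion
simulate | register | detect | track | kymo | kinetics`.

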