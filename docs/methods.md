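# Methods

This note documents the models, estimators and numerical choices behind
`stereomotion`, and what the synthetic benchmarks do and do not establish
about real data.

## Imaging model (simulator)

Emitters live on a straight stereocilium axis (base → tip, coordinates in
nm) embedded in a 2-D image plane; a confinement radius > 0 adds a fixed
per-emitter lateral offset within the tube. Single-plane frames are
acquired every `frame_interval` (0.1–1 s regime) with a 100 ms exposure.
Motion and photophysics are updated once per frame — no intra-exposure
blur, justified because the exposure is short relative to the motion
timescales at the speeds of interest (100 nm/s ≈ 0.01 px per exposure).

Each fluorophore contributes `quantal_yield` expected photons per frame,
spread over a pixel-integrated 2-D Gaussian PSF. Defaults: pixel size
162.5 nm (40× objective, 6.5 µm sCMOS pixels) and PSF σ = 0.21·λ/NA ≈
152 nm (λ = 580 nm, NA = 0.8), both configurable. The camera applies

    counts = offset + gain · Poisson(signal + background) + N(0, read_noise²).

`quantal_yield` is in arbitrary detected-photon units; absolute intensity
calibration requires a user-supplied gain standard, but all ratio-based
analyses (quantal populations) are calibration-free.

Photophysics: per-fluorophore bleaching at rate `k_b` (absorbing) and
dark-state blinking as a two-state Markov chain (`dark_on`, `dark_off`),
sampled at frame resolution. Motility modes: static; reflected 1-D Brownian
motion (increments N(0, 2DΔt)); processive tip-ward drift at `v`, absorbed
at the tip (motors accumulate there); step-wise tip-ward jumps of `Δ` with
exponential waiting times; intermittent run/pause switching. One master
seed; per-emitter substreams are spawned deterministically, so the same
seed is bit-reproducible and adding an emitter does not perturb the others.

**Free cytosolic molecules.** A tag diffusing at D ≈ 1 µm²/s crosses a
0.5 µm light sheet in tens of milliseconds, so at 1 s frame intervals it
is effectively replaced by an independent molecule each frame. The 2-D
simulator represents this sheet escape/return with the blinking machinery
(`dark_on ≈ 3 /s`, `dark_off ≈ 0.3 /s`) rather than simulating axial
diffusion explicitly — sufficient for the phenomenology that matters here
(mostly single-frame tracks), but not a model of axial optics.

## Drift registration

Shifts are estimated in three stages:

1. **Phase-only correlation.** The normalized cross-power spectrum
   `R = F_b·conj(F_a)/|·|` is inverse-transformed; the argmax gives the
   integer shift, the peak height ∈ [0, 1] a coherence score. Frames are
   mean-subtracted and apodized with a raised-cosine window to suppress
   edge ringing.
2. **Subpixel refinement.** Closed-form one-sided ratio estimator on the
   3×3 peak neighborhood (`frac = c₁/(c₀+c₁)`), exact for the sinc-shaped
   peak of an ideal band-limited translation. This is an approximation to
   published POC-fitting schemes; its residual error (≲ 0.1 px on clean
   inputs) is removed by the next stage.
3. **Least-squares image matching.** Gauss–Newton minimization of the sum
   of squared differences under bilinear resampling, convergence when the
   update norm < 10⁻³ px, at most 50 iterations. Degenerate (flat) overlap
   raises; non-convergence returns best-so-far with a flag.

`correct_movie` chains consecutive-frame estimates (robust to
photobleaching decay), then **re-anchors** each frame to the reference:
walking outward from the reference frame, each frame's direct
reference-match is initialized at the previous refined shift plus the
chained step and accepted only if it lowers the residual. Without
re-anchoring, per-step bilinear interpolation bias (~0.02 px/step,
systematic for constant subpixel drift) accumulates linearly. Frames are
variance-normalized for the reference match so intensity decay does not
bias it. Corrected frames are bilinearly resampled; out-of-field pixels are
filled with the frame median.

**Confidence gating.** For diffraction-limited images most of the Fourier
band carries only shot noise, so the whitened POC peak of a *valid* pair
with realistic texture reaches ~0.3–0.6, while two frames with no common
structure stay below ~0.1. Steps whose peak falls below `min_peak = 0.1`
are flagged and contribute zero shift: a movie containing only sparse,
moving single molecules is deliberately left uncorrected rather than
"registered" to its own molecules. Registration needs static scene
content — in practice the structural (EGFP) channel; both chained and
direct-to-reference modes are exposed.

## Punctum photometry and quantal populations

Detection: difference-of-Gaussians at the PSF scale, local maxima above
`threshold_sd` (default 5) times the robust (MAD) noise of the band-passed
image, intensity-weighted subpixel centroids in a window of radius 3 px
(≈ 3σ_PSF at default calibration). Summed intensity uses a square window
(radius 3 px) minus an annulus-median background (5–7 px) times the window
area; the annulus median is robust to neighboring puncta. S saturates once
the window exceeds ~3σ_PSF, so the Pop2/Pop1 ratio is insensitive to the
exact window; absolute S values are not.

Quantal classification fits an equal-variance two-component 1-D Gaussian
mixture by EM with deterministic moment initialization (split at the
median), so results are reproducible without random restarts. Bimodality
is declared when the two-component fit beats a single Gaussian by BIC;
puncta above mean(Pop2) + 3 SD are flagged as probable >2-fluorophore
outliers. The quantal intensity `q` is the Pop1 mean.

Line-scan profiles are sampled bilinearly, averaged after centroid
alignment, and compared with a PSF profile via normalized RMS difference
and the ratio of Gaussian-fitted FWHMs; a width ratio within 0.8–1.25
flags "point-source consistent". Profiles whose peak does not exceed 3×
their own scatter are flagged not-a-punctum.

## Kymographs, linking, projection

Kymograph columns are per-frame line scans along the axis polyline at
1 px pitch; the perpendicular reduction is the **maximum** over the scan
half-width, which keeps faint single molecules visible when the path is
slightly off-center (a mean would dilute them). Linking is greedy
nearest-neighbor: candidate links sorted by displacement, accepted if both
ends are free and the displacement ≤ `max_jump` (500 nm/frame default),
with gap closing up to 2 frames at proportionally scaled limits. Any
automated linker substitutes for the by-eye tracking such data was
originally analyzed with; parameters are exposed and recorded. Projection
maps each detection to the arc length of the nearest path point (0.25 px
search pitch); detections beyond the scan half-width are excluded and
flagged. Pixel coordinates are 0-based with pixel centers at integers;
tip-ward velocities are positive.

## Kinetics

*Velocity* is the OLS slope of `s(t)` (≥ 4 points); slope fitting has lower
variance than endpoint differencing, which is also provided via the net
`displacement` field. Population summaries (mean ± SD, n) apply
configurable filters — minimum duration, minimum R², direction — standing
in for the manual selection of "directionally moving" molecules.

*Step detection* fits a piecewise-constant model by binary segmentation:
repeatedly place the change point with the largest RSS reduction, stop when
the gain falls below the penalty `2σ²ln n` (the BIC cost of one added
change point with a known noise scale σ — taken from the robust MAD of
first differences when not supplied). Steps smaller than 2σ are merged;
plateaus shorter than `min_plateau` (2 frames) are not split. On flat noise
this yields ≤ 5 % false step calls; on staircases of 100–200 nm steps with
≥ 5-frame plateaus at σ = 30 nm it recovers ≈ 100 % of steps with ~13 nm
mean size error.

*MSD*: time-averaged, lags ≤ ¼ track length. The scaling exponent α comes
from a log-log fit weighted by the inverse of the approximate TA-MSD
variance (∝ k²/(n−k)), because high-lag points of a single track are very
noisy; D uses only lags ≤ 4 (origin-constrained least squares on
`MSD = 2Dτ`). Both choices were selected by comparing estimator variants
against exact Brownian simulations.

*Motility classification* applies deterministic rules in order:

1. **static** if the series SD < 1.5·σ_loc (a purely static molecule
   scatters only by its localization error; a peak-to-peak criterion would
   mis-reject long static tracks, whose expected range grows like
   σ√(2 ln n));
2. **step-wise** if ≥ 2 steps are found *and* the staircase beats a straight
   line by BIC *and* plateaus are flat at the noise level (median
   within-plateau SD < 2σ_loc) — the last two guards prevent ramps and
   Brownian paths, which binary segmentation happily segments, from being
   called staircases;
3. **processive** if the linear fit has R² ≥ 0.8 and |v| ≥ 20 nm/s and the
   MSD exponent is super-diffusive (α > 1.3) when measurable — a Brownian
   track fits a line with R² ≥ 0.8 about 16 % of the time ("spurious
   regression"), so fit quality alone is not evidence of directed motion;
4. **diffusive** if α ∈ [0.7, 1.3]; otherwise **unclassified**.

All thresholds are configurable and recorded. At 100-frame/1 s tracks with
σ_loc = 30 nm the 4-mode benchmark accuracy is ≥ 94 % per mode; at 60
frames the single-track α estimate (SD ≈ 0.2) makes the diffusive band a
±1.5σ test and accuracy drops to ~85–90 % — a track-length limitation of
single-trajectory MSD analysis, not of the implementation.

*Bleaching survival*: maximum likelihood for right-censored exponential
lifetimes, `rate = events / Σ durations`, with a Kaplan–Meier curve for
display. Frame quantization biases the rate low by ~k·Δt/2 (≈ 2.5 % at
k = 0.05 /s, Δt = 1 s), well inside the recovery tolerance.

## Benchmarks and their scope

`stereomotion.benchmarks` fixes the study conditions: 100-frame movies at
1 s intervals, 162.5 nm pixels, σ_PSF = 152 nm, 200 photons/fluorophore/
frame (≈ 25–30 nm localization precision), v = 100 nm/s processive motion,
100–200 nm steps, D = 10⁵ nm²/s confined diffusion, k_b = 0.05 /s
bleaching, drifts of tens of nm per frame. Published live-cell measurements
of this kind (e.g. mean dimer velocities of ~100 ± 50 nm/s) are
measurements on real cells and are *not* reproduced here; their values
serve as simulation settings so that recovery is tested in the relevant
regime.

What passing benchmarks do show: the pipeline's estimators are unbiased
and within stated tolerances *under the simulator's assumptions* — Gaussian
PSF, Markovian photophysics, straight axis, translational drift, Poisson +
Gaussian camera. What they do not show: robustness to curved or moving
stereocilia, non-Gaussian PSF tails, structured background (neighboring
stereocilia, cuticular-plate autofluorescence), rotational drift, or
detector artifacts. Real-data use should start from the drift-trace
diagnostics (peak heights, residuals, flags) and the per-track quality
fields rather than trusting mode calls blindly.

## Degenerate inputs and tie-breaks

Constant frames raise degenerate-input errors in registration; a POC peak
on the surface border returns the integer shift with a warning flag.
Detection on a noise-free frame falls back from MAD (which collapses to 0)
to the standard deviation. Equal-distance linking candidates resolve by
insertion order (stable sort). The EM mixture bounds its SD away from 0 to
survive identical-value inputs, which are reported unimodal. Tracks alive
in the last movie frame are censored, never treated as bleached; fits with
zero uncensored events raise. Shifts below 10⁻⁹ px are snapped to zero so
that an uncorrected frame is returned byte-identical.
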