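"""Punctum detection, summed-intensity photometry and quantal classification.

A punctum is a diffraction-limited spot from one or a few fluorophores.  Its
background-subtracted summed intensity is proportional to the number of
emitting fluorophores, so a histogram of summed intensities over many puncta
splits into quantal populations: Pop1 (single fluorophore, mean = the
quantal intensity q) and Pop2 (two fluorophores, mean ~= 2q).  This module
detects puncta, measures S = sum(window) - b * area with an annulus-median
background b, fits the two-population mixture, and compares punctum
line-scan profiles with the optical PSF to confirm point-source origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians

__all__ = [
    "SpotDetection",
    "QuantalFit",
    "detect_puncta",
    "sum_intensity",
    "classify_populations",
    "line_scan",
    "average_line_scan",
    "compare_to_psf",
    "detections_to_csv",
]


@dataclass
class SpotDetection:
    """One punctum in one frame."""

    frame: int
    x: float  # subpixel centroid, pixels (column)
    y: float  # subpixel centroid, pixels (row)
    intensity: float = np.nan  # S: background-subtracted summed counts
    background: float = np.nan  # b: local background, counts/pixel
    window_radius: int = 3
    quality: float = np.nan  # detection score (band-passed peak height / noise)
    clipped: bool = False  # window clipped by the frame border


@dataclass
class QuantalFit:
    """Two-population classification of punctum summed intensities."""

    labels: np.ndarray  # 0 = Pop1, 1 = Pop2 per punctum
    means: tuple[float, float]  # (Pop1, Pop2), Pop1 <= Pop2
    sd: float  # shared (equal-variance) standard deviation
    weights: tuple[float, float]
    quantal_intensity: float  # mean of Pop1
    bimodal: bool  # two components beat one by BIC
    outlier: np.ndarray = field(default=None)  # > mean(Pop2) + 3 SD
    n_iter: int = 0

    @property
    def mean_ratio(self) -> float:
        return self.means[1] / self.means[0]

    def to_json(self, path: str | Path) -> None:
        d = {"means": list(self.means), "sd": self.sd,
             "weights": list(self.weights),
             "quantal_intensity": self.quantal_intensity,
             "mean_ratio": self.mean_ratio, "bimodal": self.bimodal,
             "n_pop1": int(np.sum(self.labels == 0)),
             "n_pop2": int(np.sum(self.labels == 1)),
             "labels": self.labels.tolist(),
             "outlier": self.outlier.tolist()}
        Path(path).write_text(json.dumps(d, indent=2))


def _noise_sigma(image: np.ndarray) -> float:
    """Robust noise scale from the median absolute deviation."""
    med = np.median(image)
    return float(1.4826 * np.median(np.abs(image - med)))


def detect_puncta(frame: np.ndarray, psf_sigma_px: float = 1.0,
                  min_separation: int = 5, threshold_sd: float = 5.0,
                  window_radius: int = 3) -> list[SpotDetection]:
    """Detect diffraction-limited puncta in one frame.

    Difference-of-Gaussians band-pass at the PSF scale, local maxima above
    ``threshold_sd`` times the robust noise of the band-passed image, then
    intensity-weighted subpixel centroids in a ``window_radius`` window of
    the background-subtracted frame.  Maxima closer than ``min_separation``
    pixels are merged keeping the brighter.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2 or not np.isfinite(frame).all():
        raise ValueError("frame must be a finite 2-D array")
    bp = difference_of_gaussians(frame, psf_sigma_px, 2.0 * psf_sigma_px)
    sigma = _noise_sigma(bp)
    if sigma == 0:  # noise-free frame: MAD collapses, fall back to std
        sigma = float(bp.std())
    if sigma == 0:
        return []
    peaks = peak_local_max(bp, min_distance=int(min_separation),
                           threshold_abs=threshold_sd * sigma, exclude_border=False)
    detections: list[SpotDetection] = []
    bg = float(np.median(frame))
    r = int(window_radius)
    rows, cols = frame.shape
    for pr, pc in peaks:
        r0, r1 = pr - r, pr + r + 1
        c0, c1 = pc - r, pc + r + 1
        clipped = r0 < 0 or c0 < 0 or r1 > rows or c1 > cols
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, rows), min(c1, cols)
        win = frame[r0:r1, c0:c1] - bg
        win = np.clip(win, 0, None)
        total = win.sum()
        if total <= 0:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        detections.append(SpotDetection(
            frame=0, x=float((win * xx).sum() / total),
            y=float((win * yy).sum() / total),
            window_radius=r, quality=float(bp[pr, pc] / sigma),
            clipped=clipped))
    return detections


def sum_intensity(frame: np.ndarray, detection: SpotDetection,
                  window_radius: int = 3,
                  annulus: tuple[float, float] = (5.0, 7.0)
                  ) -> tuple[float, float]:
    """Background-subtracted summed intensity of one punctum.

    S = sum of pixel values in the (2r+1)^2 window around the centroid minus
    the annulus-median background times the window area.  The annulus median
    is robust to neighboring puncta.  A window clipped by the frame border is
    flagged on the detection but S is still returned over the clipped area.
    """
    frame = np.asarray(frame, dtype=np.float64)
    rows, cols = frame.shape
    cx, cy = int(round(detection.x)), int(round(detection.y))
    r = int(window_radius)
    r0, r1 = cy - r, cy + r + 1
    c0, c1 = cx - r, cx + r + 1
    clipped = r0 < 0 or c0 < 0 or r1 > rows or c1 > cols
    r0c, c0c = max(r0, 0), max(c0, 0)
    r1c, c1c = min(r1, rows), min(c1, cols)
    window = frame[r0c:r1c, c0c:c1c]

    yy, xx = np.mgrid[0:rows, 0:cols]
    dist = np.hypot(xx - detection.x, yy - detection.y)
    ann = frame[(dist > annulus[0]) & (dist <= annulus[1])]
    b = float(np.median(ann)) if ann.size else float(np.median(frame))
    s = float(window.sum() - b * window.size)
    detection.intensity = s
    detection.background = b
    detection.window_radius = r
    detection.clipped = detection.clipped or clipped
    return s, b


def _em_two_gaussian(x: np.ndarray, max_iter: int = 500,
                     tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, float,
                                                 np.ndarray, float, int]:
    """Equal-variance two-component 1-D Gaussian mixture by EM.

    Deterministic moment-based initialization: components start at the means
    of the lower and upper halves split at the median.  Returns
    (means, weights, sd, responsibilities, loglik, n_iter).
    """
    x = np.asarray(x, dtype=np.float64)
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # all values at/below the median (e.g. all identical)
        mu = np.array([x.mean(), x.mean()])
    else:
        mu = np.array([lo.mean(), hi.mean()])
    sd = max(x.std(), 1e-12 + 1e-6 * max(abs(mu[1]), 1.0))
    w = np.array([0.5, 0.5])
    ll_old = -np.inf
    resp = np.full((x.size, 2), 0.5)
    it = 0
    for it in range(1, max_iter + 1):
        logp = (np.log(np.maximum(w, 1e-300))[None, :]
                - 0.5 * ((x[:, None] - mu[None, :]) / sd) ** 2
                - np.log(sd) - 0.5 * np.log(2 * np.pi))
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logp - lse[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            break
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = float((resp * (x[:, None] - mu[None, :]) ** 2).sum() / x.size)
        sd = max(np.sqrt(var), 1e-12 + 1e-9 * max(abs(mu).max(), 1.0))
        w = nk / x.size
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    order = np.argsort(mu)
    return mu[order], w[order], sd, resp[:, order], ll, it


def classify_populations(intensities: np.ndarray) -> QuantalFit:
    """Split punctum summed intensities into quantal populations Pop1/Pop2.

    Fits an equal-variance two-component Gaussian mixture by EM with
    deterministic moment initialization and assigns each punctum to the more
    probable component.  The bimodality flag is set when the two-component
    fit beats a single Gaussian by BIC.  Puncta brighter than
    mean(Pop2) + 3 SD are flagged as likely >2-fluorophore outliers.
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if x.size < 6:
        raise ValueError(f"need at least 6 intensities, got {x.size}")
    mu, w, sd, resp, ll2, it = _em_two_gaussian(x)
    labels = (resp[:, 1] > 0.5).astype(int)

    # one-component reference: Gaussian MLE
    sd1 = max(x.std(), 1e-12)
    ll1 = float(np.sum(-0.5 * ((x - x.mean()) / sd1) ** 2
                       - np.log(sd1) - 0.5 * np.log(2 * np.pi)))
    n = x.size
    bic1 = -2 * ll1 + 2 * np.log(n)  # mean + sd
    bic2 = -2 * ll2 + 4 * np.log(n)  # 2 means + shared sd + weight
    bimodal = bool(bic2 < bic1)
    if not bimodal:
        labels = np.zeros(n, dtype=int)
        mu = (x.mean(), x.mean())
        w = (1.0, 0.0)
        sd = sd1
    outlier = x > mu[1] + 3 * sd
    return QuantalFit(labels=labels, means=(float(mu[0]), float(mu[1])),
                      sd=float(sd), weights=(float(w[0]), float(w[1])),
                      quantal_intensity=float(mu[0]), bimodal=bimodal,
                      outlier=outlier, n_iter=it)


def line_scan(frame: np.ndarray, center: tuple[float, float],
              direction: tuple[float, float], half_length: float,
              step: float = 1.0) -> np.ndarray:
    """1-D intensity profile through ``center`` along ``direction``.

    Bilinear sampling at ``step``-pixel pitch over +-``half_length`` pixels.
    Raises if the segment leaves the frame.
    """
    frame = np.asarray(frame, dtype=np.float64)
    d = np.asarray(direction, dtype=float)
    d = d / np.hypot(*d)
    offsets = np.arange(-half_length, half_length + step / 2, step)
    xs = center[0] + offsets * d[0]
    ys = center[1] + offsets * d[1]
    if (xs.min() < 0 or ys.min() < 0 or xs.max() > frame.shape[1] - 1
            or ys.max() > frame.shape[0] - 1):
        raise ValueError("line-scan segment extends outside the frame")
    return ndimage.map_coordinates(frame, np.array([ys, xs]), order=1)


def average_line_scan(profiles: list[np.ndarray]) -> np.ndarray:
    """Average profiles after aligning each on its intensity centroid."""
    if not profiles:
        raise ValueError("no profiles to average")
    n = min(len(p) for p in profiles)
    center = (n - 1) / 2.0
    aligned = []
    for p in profiles:
        p = np.asarray(p, dtype=np.float64)[:n]
        base = p.min()
        mass = (p - base).sum()
        cm = float(((p - base) * np.arange(n)).sum() / mass) if mass > 0 else center
        aligned.append(ndimage.shift(p, center - cm, order=1, mode="nearest"))
    return np.mean(aligned, axis=0)


def _gaussian_fwhm(profile: np.ndarray, step: float = 1.0) -> float:
    """FWHM from a least-squares Gaussian fit (with offset) to a profile."""
    x = np.arange(len(profile)) * step

    def model(x, a, mu, sigma, c):
        return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + c

    i0 = int(np.argmax(profile))
    p0 = (profile.max() - profile.min(), x[i0], max(step, len(profile) * step / 8),
          profile.min())
    popt, _ = optimize.curve_fit(model, x, profile, p0=p0, maxfev=5000)
    return float(2 * np.sqrt(2 * np.log(2)) * abs(popt[2]))


@dataclass
class PsfComparison:
    """Similarity of a punctum profile to the optical PSF profile."""

    nrms: float  # RMS difference after peak normalization, in [0, inf)
    width_ratio: float  # fitted FWHM(profile) / FWHM(psf model)
    point_source: bool  # width ratio inside the acceptance band
    not_a_punctum: bool = False  # flat or unfittable profile


def compare_to_psf(profile: np.ndarray, psf_profile: np.ndarray,
                   band: tuple[float, float] = (0.8, 1.25),
                   step: float = 1.0) -> PsfComparison:
    """Compare a measured punctum profile with the PSF line profile.

    Both profiles are baseline-subtracted, peak-normalized and aligned on
    their centroids before computing the normalized RMS difference; widths
    are compared through Gaussian FWHM fits.  A profile without significant
    structure (peak below 3x its own residual scatter) is flagged
    not-a-punctum.
    """
    p = np.asarray(profile, dtype=np.float64)
    m = np.asarray(psf_profile, dtype=np.float64)
    n = min(len(p), len(m))
    p, m = p[:n].copy(), m[:n].copy()
    p -= np.median(p)
    m -= np.median(m)
    scatter = _noise_sigma(np.diff(p)) / np.sqrt(2) if n > 3 else 0.0
    if p.max() <= 0 or (scatter > 0 and p.max() < 3 * scatter):
        return PsfComparison(nrms=np.inf, width_ratio=np.nan,
                             point_source=False, not_a_punctum=True)
    p /= p.max()
    m /= m.max()
    # centroid alignment
    for arr in (p, m):
        mass = np.clip(arr, 0, None).sum()
        cm = float((np.clip(arr, 0, None) * np.arange(n)).sum() / mass)
        arr[:] = ndimage.shift(arr, (n - 1) / 2 - cm, order=1, mode="nearest")
    nrms = float(np.sqrt(np.mean((p - m) ** 2)))
    try:
        ratio = _gaussian_fwhm(p, step) / _gaussian_fwhm(m, step)
    except RuntimeError:
        return PsfComparison(nrms=nrms, width_ratio=np.nan,
                             point_source=False, not_a_punctum=True)
    return PsfComparison(nrms=nrms, width_ratio=float(ratio),
                         point_source=bool(band[0] <= ratio <= band[1]))


def detections_to_csv(detections: list[SpotDetection], path: str | Path) -> None:
    pd.DataFrame([asdict(d) for d in detections]).to_csv(path, index=False)
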