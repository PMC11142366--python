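"""Lateral drift correction by phase-only correlation and least-squares matching.

The per-frame shift estimate proceeds in three stages: an integer shift from
phase-only correlation (POC) of the Fourier cross-power spectrum, a
closed-form subpixel refinement on the 3x3 neighborhood of the POC peak, and
an iterative Gauss-Newton least-squares image-matching refinement under
bilinear resampling.  Frame-to-frame shifts are chained and accumulated to a
reference frame, which keeps registration robust to slow intensity decay
from photobleaching.

Shifts are reported as ``(dx, dy)`` in pixels, x = column, y = row: the
shift such that ``frame_b(x, y) ~= frame_a(x - dx, y - dy)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .simcore import Movie

__all__ = [
    "DegenerateFrameError",
    "DriftTrace",
    "phase_only_correlation",
    "subpixel_refine_poc",
    "lsq_image_matching",
    "estimate_shift",
    "correct_movie",
]


class DegenerateFrameError(ValueError):
    """Raised for frames with no usable texture (constant intensity)."""


@dataclass
class DriftTrace:
    """Estimated cumulative shift per frame relative to the reference."""

    dx_px: np.ndarray
    dy_px: np.ndarray
    peak: np.ndarray  # POC peak height of the frame-to-frame step
    residual: np.ndarray  # final mean squared difference of LSQ matching
    iterations: np.ndarray
    flag: np.ndarray  # per-frame status string ("", "degenerate", ...)
    reference: int

    def __len__(self) -> int:
        return len(self.dx_px)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(len(self)),
            "dx_px": self.dx_px, "dy_px": self.dy_px,
            "peak": self.peak, "residual": self.residual,
            "iterations": self.iterations, "flag": self.flag,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _as_float(frame: np.ndarray) -> np.ndarray:
    a = np.asarray(frame, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError("frame must be 2-D")
    return a


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b = _as_float(a), _as_float(b)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if min(a.shape) < 16:
        raise ValueError("frames must be at least 16x16 pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateFrameError("constant frame has no registrable texture")
    return a, b


def _raised_cosine(shape: tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def poc_surface(frame_a: np.ndarray, frame_b: np.ndarray,
                window: bool = True) -> np.ndarray:
    """Real part of the inverse transform of the normalized cross-power spectrum.

    Returned in fftshifted layout so the zero-shift peak sits at the array
    center; a raised-cosine apodization (on by default) suppresses ringing
    from the periodic boundary.
    """
    a, b = _check_pair(frame_a, frame_b)
    a = a - a.mean()
    b = b - b.mean()
    if window:
        w = _raised_cosine(a.shape)
        a, b = a * w, b * w
    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    # conj on frame_a so the peak sits at +shift of b relative to a
    cross = fb * np.conj(fa)
    mag = np.abs(cross)
    mag[mag == 0] = 1.0
    return np.fft.fftshift(np.real(np.fft.ifft2(cross / mag)))


def phase_only_correlation(frame_a: np.ndarray, frame_b: np.ndarray,
                           window: bool = True
                           ) -> tuple[tuple[int, int], float, np.ndarray]:
    """Integer shift of ``frame_b`` relative to ``frame_a`` by POC.

    Returns ``((dx, dy), peak_height, surface)``; the shift is mapped to the
    signed range (-N/2, N/2] per axis and the peak height lies in [0, 1]
    (1 for a pure translation of identical content).
    """
    surface = poc_surface(frame_a, frame_b, window=window)
    r0, c0 = np.unravel_index(np.argmax(surface), surface.shape)
    dy = r0 - surface.shape[0] // 2
    dx = c0 - surface.shape[1] // 2
    return (int(dx), int(dy)), float(surface[r0, c0]), surface


def subpixel_refine_poc(surface: np.ndarray,
                        integer_peak: tuple[int, int]
                        ) -> tuple[tuple[float, float], bool]:
    """Refine a POC peak to fractional precision from its 3x3 neighborhood.

    ``integer_peak`` is the (dx, dy) integer shift.  Uses the closed-form
    one-sided ratio estimator per axis, exact for the sinc-shaped peak of an
    ideal band-limited translation: with center value c0 and larger neighbor
    c1 at offset +-1, the fractional offset is c1 / (c0 + c1).  Returns the
    refined (dx, dy) and a border flag; on the border the integer shift is
    returned unchanged with the flag set.
    """
    dx, dy = integer_peak
    r0 = dy + surface.shape[0] // 2
    c0 = dx + surface.shape[1] // 2
    if not (1 <= r0 < surface.shape[0] - 1 and 1 <= c0 < surface.shape[1] - 1):
        warnings.warn("POC peak on surface border; returning integer shift",
                      stacklevel=2)
        return (float(dx), float(dy)), True

    def _axis_offset(cm: float, cc: float, cp: float) -> float:
        cm, cc, cp = max(cm, 0.0), max(cc, 0.0), max(cp, 0.0)
        if cc == 0:
            return 0.0
        if cp >= cm:
            frac = cp / (cc + cp) if cc + cp > 0 else 0.0
        else:
            frac = -cm / (cc + cm) if cc + cm > 0 else 0.0
        return float(np.clip(frac, -0.999, 0.999))

    off_x = _axis_offset(surface[r0, c0 - 1], surface[r0, c0], surface[r0, c0 + 1])
    off_y = _axis_offset(surface[r0 - 1, c0], surface[r0, c0], surface[r0 + 1, c0])
    return (dx + off_x, dy + off_y), False


def _normalize(frame: np.ndarray) -> np.ndarray:
    f = np.asarray(frame, dtype=np.float64)
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else f - f.mean()


def _shift_bilinear(frame: np.ndarray, dx: float, dy: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``frame`` at positions (x - dx, y - dy) with bilinear weights.

    Returns the shifted frame and a validity mask (False where sampling left
    the field of view).
    """
    rows, cols = frame.shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    coords = np.array([yy - dy, xx - dx])
    shifted = ndimage.map_coordinates(frame, coords, order=1, mode="constant",
                                      cval=np.nan)
    mask = ~np.isnan(shifted)
    return np.nan_to_num(shifted), mask


def lsq_image_matching(frame_a: np.ndarray, frame_b: np.ndarray,
                       initial_shift: tuple[float, float] = (0.0, 0.0),
                       tol: float = 1e-3, max_iter: int = 50
                       ) -> tuple[tuple[float, float], float, int, bool]:
    """Refine a translation by iterative least-squares image matching.

    Gauss-Newton minimization of the summed squared intensity difference
    between ``frame_b`` and ``frame_a`` resampled (bilinear) at the candidate
    shift; converges when the update norm drops below ``tol`` pixels.

    Returns ``((dx, dy), residual, iterations, converged)`` with the residual
    the final mean squared difference over the overlap region.
    """
    a, b = _check_pair(frame_a, frame_b)
    dx, dy = float(initial_shift[0]), float(initial_shift[1])
    converged = False
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        warped, mask = _shift_bilinear(a, dx, dy)
        # interior gradients only: border pixels of the overlap are biased
        mask &= ndimage.binary_erosion(mask)
        if mask.sum() < 0.5 * a.size:
            raise ValueError("overlap region below 50% of frame; shift too large")
        gy, gx = np.gradient(warped)
        r = (b - warped)[mask]
        jx, jy = gx[mask], gy[mask]
        h = np.array([[np.dot(jx, jx), np.dot(jx, jy)],
                      [np.dot(jx, jy), np.dot(jy, jy)]])
        if np.linalg.cond(h) > 1e12 or not np.isfinite(h).all():
            raise DegenerateFrameError("flat overlap: zero intensity gradient")
        # d warped / d shift = -grad, hence the negated update
        g = np.array([np.dot(jx, r), np.dot(jy, r)])
        ddx, ddy = -np.linalg.solve(h, g)
        dx += ddx
        dy += ddy
        residual = float(np.mean(r ** 2))
        if np.hypot(ddx, ddy) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("least-squares matching did not converge; "
                      "returning best-so-far", stacklevel=2)
    warped, mask = _shift_bilinear(a, dx, dy)
    residual = float(np.mean((b - warped)[mask] ** 2)) if mask.any() else residual
    return (dx, dy), residual, it, converged


def estimate_shift(frame_a: np.ndarray, frame_b: np.ndarray,
                   window: bool = True, refine: bool = True
                   ) -> tuple[tuple[float, float], float, float, int]:
    """Full shift pipeline: POC integer -> subpixel POC -> least-squares.

    Returns ``((dx, dy), poc_peak, residual, iterations)``.
    """
    (dx_i, dy_i), peak, surface = phase_only_correlation(frame_a, frame_b,
                                                         window=window)
    (dx, dy), _border = subpixel_refine_poc(surface, (dx_i, dy_i))
    residual, iters = np.nan, 0
    if refine:
        try:
            (dx, dy), residual, iters, _ = lsq_image_matching(
                frame_a, frame_b, initial_shift=(dx, dy))
        except DegenerateFrameError:
            raise
        except ValueError:
            pass  # overlap too small at POC estimate: keep subpixel POC
    return (dx, dy), peak, residual, iters


def correct_movie(movie: Movie, reference: int | str = "first",
                  mode: str = "chained",
                  min_peak: float = 0.1) -> tuple[Movie, DriftTrace]:
    """Estimate and remove lateral drift from a movie.

    ``mode='chained'`` (default) registers consecutive frames and accumulates
    the shifts; ``mode='reference'`` registers every frame directly against
    the reference frame.  Corrected frames are resampled with bilinear
    interpolation; pixels that leave the field of view are filled with the
    frame's median background.

    A registration step whose POC peak falls below ``min_peak`` carries no
    evidence of a common shift (two independent noise frames peak well below
    0.1); such frames keep the previous cumulative shift and are flagged
    ``low_peak``.  Registration needs static scene content — in practice the
    structural (e.g. EGFP) channel, not the sparse single-molecule channel.
    """
    if movie.n_frames < 2:
        raise ValueError("drift correction needs at least 2 frames")
    ref = 0 if reference == "first" else int(reference)
    if not 0 <= ref < movie.n_frames:
        raise ValueError(f"reference frame {ref} out of range")
    if mode not in ("chained", "reference"):
        raise ValueError("mode must be 'chained' or 'reference'")

    n = movie.n_frames
    dx = np.zeros(n)
    dy = np.zeros(n)
    peak = np.full(n, np.nan)
    resid = np.full(n, np.nan)
    iters = np.zeros(n, dtype=int)
    flags = np.array([""] * n, dtype=object)

    def _step(frame_a, frame_b, t):
        try:
            (dxi, dyi), pk, surface = phase_only_correlation(frame_a, frame_b)
            peak[t] = pk
            if pk < min_peak:
                flags[t] = "low_peak"
                return 0.0, 0.0
            (sx, sy), _ = subpixel_refine_poc(surface, (dxi, dyi))
            try:
                (sx, sy), rs, its, _ = lsq_image_matching(
                    frame_a, frame_b, initial_shift=(sx, sy))
                resid[t], iters[t] = rs, its
            except ValueError:
                pass  # keep subpixel POC estimate
            return sx, sy
        except (DegenerateFrameError, ValueError):
            flags[t] = "degenerate"
            return None

    if mode == "chained":
        step = np.zeros((n, 2))
        for t in range(1, n):
            res = _step(movie.frames[t - 1], movie.frames[t], t)
            step[t] = res if res is not None else (0.0, 0.0)
        cum = np.cumsum(step, axis=0)
        cum -= cum[ref]
        dx, dy = cum[:, 0], cum[:, 1]
        # re-anchor to the reference frame so per-step interpolation bias
        # does not accumulate: walking outward from the reference, each
        # frame's refinement starts at the previous refined shift plus the
        # chained step, and is kept only if it lowers the matching residual.
        # Frames are normalized to tolerate photobleaching decay.
        refn = _normalize(movie.frames[ref])

        def _resid_at(fb, sx, sy):
            warped, m = _shift_bilinear(refn, sx, sy)
            m &= ndimage.binary_erosion(m)
            return float(np.mean((fb - warped)[m] ** 2)) if m.any() else np.inf

        for order in (range(ref + 1, n), range(ref - 1, -1, -1)):
            prev = np.zeros(2)
            prev_t = ref
            for t in order:
                init = prev + (cum[t] - cum[prev_t])
                dx[t], dy[t] = init
                if not flags[t]:
                    fb = _normalize(movie.frames[t])
                    try:
                        (rx, ry), rs, its, conv = lsq_image_matching(
                            refn, fb, initial_shift=tuple(init))
                        if conv and rs < _resid_at(fb, *init):
                            dx[t], dy[t] = rx, ry
                            resid[t], iters[t] = rs, its
                    except (DegenerateFrameError, ValueError):
                        pass  # keep the propagated estimate
                prev = np.array([dx[t], dy[t]])
                prev_t = t
    else:
        for t in range(n):
            if t == ref:
                continue
            res = _step(movie.frames[ref], movie.frames[t], t)
            dx[t], dy[t] = res if res is not None else (dx[t - 1], dy[t - 1])

    dx[np.abs(dx) < 1e-9] = 0.0
    dy[np.abs(dy) < 1e-9] = 0.0
    corrected = np.empty_like(movie.frames)
    for t in range(n):
        if dx[t] == 0.0 and dy[t] == 0.0:
            corrected[t] = movie.frames[t]
            continue
        fill = float(np.median(movie.frames[t]))
        shifted, mask = _shift_bilinear(movie.frames[t], -dx[t], -dy[t])
        corrected[t] = np.where(mask, shifted, fill)
    trace = DriftTrace(dx_px=dx, dy_px=dy, peak=peak, residual=resid,
                       iterations=iters, flag=flags, reference=ref)
    out = Movie(frames=corrected, pixel_size=movie.pixel_size,
                frame_interval=movie.frame_interval)
    return out, trace
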