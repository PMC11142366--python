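"""Motility kinetics from axial trajectories: velocities, steps, MSD, modes.

Works on axial position series s(t) in nm (tip-positive convention).
Velocities come from ordinary least-squares slopes; step-wise movement is
found by piecewise-constant change-point fitting (binary segmentation with
a BIC-style per-changepoint penalty); motility modes are called by
deterministic decision rules over displacement, fit quality, step count and
MSD scaling; photobleaching-limited track survival is fit by a censored
exponential maximum-likelihood estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VelocityEstimate",
    "VelocitySummary",
    "StepFit",
    "MsdResult",
    "MotilityCall",
    "SurvivalFit",
    "velocity_of_track",
    "summarize_velocities",
    "detect_steps",
    "msd_curve",
    "classify_motility",
    "bleaching_survival",
]


@dataclass
class VelocityEstimate:
    """Least-squares velocity of one track (nm/s, tip-positive)."""

    velocity: float
    stderr: float
    r_squared: float
    duration: float  # s
    n_points: int
    displacement: float = np.nan  # net s(end) - s(start), nm


def velocity_of_track(s_nm: np.ndarray, t_s: np.ndarray,
                      min_frames: int = 4) -> VelocityEstimate:
    """OLS slope of axial position versus time.

    Tip-ward movement gives positive velocity; retrograde movement negative.
    """
    s = np.asarray(s_nm, dtype=np.float64)
    t = np.asarray(t_s, dtype=np.float64)
    ok = np.isfinite(s) & np.isfinite(t)
    s, t = s[ok], t[ok]
    if s.size < min_frames:
        raise ValueError(f"need at least {min_frames} points, got {s.size}")
    res = stats.linregress(t, s)
    r2 = res.rvalue ** 2 if np.std(s) > 0 else 1.0  # constant series: exact fit
    return VelocityEstimate(velocity=float(res.slope),
                            stderr=float(res.stderr),
                            r_squared=float(r2),
                            duration=float(t[-1] - t[0]), n_points=int(s.size),
                            displacement=float(s[-1] - s[0]))


@dataclass
class VelocitySummary:
    mean: float
    sd: float  # NaN when n == 1
    n: int
    histogram: tuple[np.ndarray, np.ndarray] | None = None  # (counts, edges)
    empty: bool = False


def summarize_velocities(estimates: list[VelocityEstimate],
                         min_duration: float = 0.0,
                         min_r_squared: float = 0.0,
                         direction: str | None = None,
                         bins: int | np.ndarray = 10) -> VelocitySummary:
    """Mean +- SD over velocity estimates surviving the quality filters.

    ``direction`` of "tipward"/"retrograde" keeps only positive/negative
    velocities (matching selection of directionally moving molecules).
    """
    vs = [e.velocity for e in estimates
          if e.duration >= min_duration and e.r_squared >= min_r_squared
          and (direction is None
               or (direction == "tipward" and e.velocity > 0)
               or (direction == "retrograde" and e.velocity < 0))]
    if not vs:
        return VelocitySummary(mean=np.nan, sd=np.nan, n=0, empty=True)
    v = np.asarray(vs)
    counts, edges = np.histogram(v, bins=bins)
    return VelocitySummary(mean=float(v.mean()),
                           sd=float(v.std(ddof=1)) if v.size > 1 else np.nan,
                           n=int(v.size), histogram=(counts, edges))


@dataclass
class StepFit:
    """Piecewise-constant change-point fit of an axial series."""

    changepoints: np.ndarray  # frame indices where a new plateau starts
    levels: np.ndarray  # plateau means, nm, time-ordered
    step_sizes: np.ndarray  # signed nm, len(levels) - 1
    penalty: float
    noise_sd: float

    @property
    def n_steps(self) -> int:
        return len(self.step_sizes)


def _best_split(x: np.ndarray) -> tuple[int, float]:
    """Best single change point of a series by RSS reduction.

    Returns (index of the first point of the right segment, RSS gain).
    """
    n = len(x)
    cs = np.cumsum(x)
    cs2 = np.cumsum(x ** 2)
    total = cs2[-1] - cs[-1] ** 2 / n
    ks = np.arange(1, n)
    left = cs2[ks - 1] - cs[ks - 1] ** 2 / ks
    right_sum = cs[-1] - cs[ks - 1]
    right_sq = cs2[-1] - cs2[ks - 1]
    right = right_sq - right_sum ** 2 / (n - ks)
    gains = total - (left + right)
    k = int(np.argmax(gains))
    return int(ks[k]), float(gains[k])


def detect_steps(s_nm: np.ndarray, noise_sd: float | None = None,
                 penalty: float | None = None,
                 min_step: float | None = None,
                 min_plateau: int = 2) -> StepFit:
    """Detect plateau-to-plateau steps in an axial position series.

    Binary segmentation: recursively place the change point with the largest
    residual-sum-of-squares reduction and stop when the reduction no longer
    exceeds the penalty (default the BIC cost of one extra changepoint,
    2 * sigma^2 * ln(n)).  The noise scale defaults to a robust estimate
    from first differences; detected steps smaller than ``min_step``
    (default 2x the noise scale) are merged into their neighbor plateau.
    """
    x = np.asarray(s_nm, dtype=np.float64)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 6:
        raise ValueError(f"need at least 6 points, got {n}")
    if noise_sd is None:
        d = np.diff(x)
        noise_sd = float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2))
        noise_sd = max(noise_sd, 1e-9)
    if penalty is None:
        penalty = 2.0 * noise_sd ** 2 * np.log(n)
    if min_step is None:
        min_step = 2.0 * noise_sd

    breakpoints = [0, n]
    while True:
        best = None
        for i in range(len(breakpoints) - 1):
            a, b = breakpoints[i], breakpoints[i + 1]
            if b - a < 2 * min_plateau:
                continue
            k, gain = _best_split(x[a:b])
            if k < min_plateau or (b - a) - k < min_plateau:
                # constrained search respecting the plateau minimum
                seg = x[a:b]
                kk_range = range(min_plateau, len(seg) - min_plateau + 1)
                gains = []
                for kk in kk_range:
                    l, r = seg[:kk], seg[kk:]
                    g = (np.sum((seg - seg.mean()) ** 2)
                         - np.sum((l - l.mean()) ** 2)
                         - np.sum((r - r.mean()) ** 2))
                    gains.append(g)
                if not gains:
                    continue
                j = int(np.argmax(gains))
                k, gain = list(kk_range)[j], gains[j]
            if gain > penalty and (best is None or gain > best[0]):
                best = (gain, a + k)
        if best is None:
            break
        breakpoints.append(best[1])
        breakpoints.sort()

    levels = np.array([x[a:b].mean()
                       for a, b in zip(breakpoints[:-1], breakpoints[1:])])
    # merge steps below the minimum size
    while len(levels) > 1:
        steps = np.diff(levels)
        j = int(np.argmin(np.abs(steps)))
        if abs(steps[j]) >= min_step:
            break
        del breakpoints[j + 1]
        levels = np.array([x[a:b].mean()
                           for a, b in zip(breakpoints[:-1], breakpoints[1:])])
    return StepFit(changepoints=np.asarray(breakpoints[1:-1], dtype=int),
                   levels=levels, step_sizes=np.diff(levels),
                   penalty=float(penalty), noise_sd=float(noise_sd))


@dataclass
class MsdResult:
    lags_s: np.ndarray
    msd: np.ndarray  # nm^2
    alpha: float  # log-log scaling exponent
    diffusion_coeff: float  # nm^2/s, from 1-D MSD = 2 D lag


def msd_curve(s_nm: np.ndarray, frame_interval: float,
              max_lag_fraction: float = 0.25,
              max_lag: int | None = None) -> MsdResult:
    """Time-averaged 1-D mean squared displacement and its scaling.

    MSD(k dt) averaged over all start times, for lags up to a quarter of the
    track length (or an explicit ``max_lag``); alpha from a log-log linear
    fit and D from the least-squares slope of MSD versus lag through the
    origin (MSD = 2 D t).  Time-averaged MSD errors grow strongly with lag,
    so scaling-exponent estimates are most reliable from the shortest lags.
    """
    x = np.asarray(s_nm, dtype=np.float64)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 8:
        raise ValueError(f"need at least 8 points, got {n}")
    if max_lag is None:
        max_lag = max(2, int(n * max_lag_fraction))
    max_lag = min(max_lag, n - 2)
    lags = np.arange(1, max_lag + 1)
    msd = np.array([np.mean((x[k:] - x[:-k]) ** 2) for k in lags])
    t = lags * frame_interval
    pos = msd > 0
    if pos.sum() >= 2:
        # the variance of a time-averaged MSD point grows roughly as
        # k^2 / (n - k), so weight the log-log fit by its inverse
        w = np.sqrt((n - lags[pos]) / lags[pos] ** 2)
        alpha = float(np.polyfit(np.log(t[pos]), np.log(msd[pos]), 1, w=w)[0])
    else:
        alpha = 0.0
    # D from the shortest lags only (origin-constrained least squares);
    # high-lag MSD points are too noisy for a per-track estimate
    kd = min(4, max_lag)
    d = float(np.sum(msd[:kd] * t[:kd]) / (2.0 * np.sum(t[:kd] ** 2)))
    return MsdResult(lags_s=t, msd=msd, alpha=alpha, diffusion_coeff=d)


@dataclass
class MotilityCall:
    mode: str  # static | diffusive | processive | stepwise | unclassified
    velocity: float = np.nan
    r_squared: float = np.nan
    msd_alpha: float = np.nan
    n_steps: int = 0
    reason: str = ""


def classify_motility(s_nm: np.ndarray, frame_interval: float,
                      loc_noise_nm: float = 30.0,
                      min_frames: int = 6,
                      static_k: float = 1.5,
                      v_min: float = 20.0,
                      r2_min: float = 0.8,
                      dwell_min: int = 2,
                      alpha_band: tuple[float, float] = (0.7, 1.3)
                      ) -> MotilityCall:
    """Call the motility mode of one axial trajectory.

    Decision rules, in order: static when the series SD stays below
    ``static_k`` times the localization noise (a purely static molecule only
    scatters by its localization error); step-wise when the change-point fit
    finds >= 2 steps, beats a straight line by BIC and leaves plateaus flat
    at the noise level; processive when the linear fit is good
    (R^2 >= ``r2_min``) and faster than ``v_min``; diffusive when the MSD
    exponent is near 1; otherwise unclassified.  Deterministic given the
    series and settings.
    """
    x = np.asarray(s_nm, dtype=np.float64)
    x = x[np.isfinite(x)]
    if len(x) < min_frames:
        return MotilityCall(mode="unclassified",
                            reason=f"fewer than {min_frames} points")
    n = len(x)
    t = np.arange(n) * frame_interval
    if float(x.std()) < static_k * loc_noise_nm:
        return MotilityCall(mode="static", velocity=0.0, reason="low excursion")
    vel = velocity_of_track(x, t, min_frames=min(4, n))
    steps = (detect_steps(x, noise_sd=loc_noise_nm, min_plateau=dwell_min)
             if n >= 6 else None)
    if steps is not None and steps.n_steps >= 2:
        bounds = np.concatenate([[0], steps.changepoints, [n]])
        seg = [x[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
        rss_pw = sum(float(np.sum((s - s.mean()) ** 2)) for s in seg)
        plateau_sd = float(np.median([s.std() for s in seg]))
        rss_lin = float(np.sum((x - np.polyval(np.polyfit(t, x, 1), t)) ** 2))
        k = steps.n_steps
        bic_pw = n * np.log(max(rss_pw, 1e-12) / n) + (2 * k + 2) * np.log(n)
        bic_lin = n * np.log(max(rss_lin, 1e-12) / n) + 3 * np.log(n)
        if bic_pw < bic_lin and plateau_sd < 2.0 * loc_noise_nm:
            return MotilityCall(mode="stepwise", velocity=vel.velocity,
                                r_squared=vel.r_squared, n_steps=steps.n_steps,
                                reason=f"{steps.n_steps} steps beat linear fit")
    try:
        # short lags only: the scaling exponent of a single track is far
        # less noisy there (time-averaged MSD errors grow with lag)
        alpha = msd_curve(x, frame_interval, max_lag=5).alpha
    except ValueError:
        alpha = np.nan
    if (vel.r_squared >= r2_min and abs(vel.velocity) >= v_min
            and not (np.isfinite(alpha) and alpha <= alpha_band[1])):
        # a Brownian track can fit a line spuriously well, so a processive
        # call also requires super-diffusive MSD scaling when measurable
        return MotilityCall(mode="processive", velocity=vel.velocity,
                            r_squared=vel.r_squared, msd_alpha=alpha,
                            reason="good linear fit")
    if np.isfinite(alpha) and alpha_band[0] <= alpha <= alpha_band[1]:
        return MotilityCall(mode="diffusive", velocity=vel.velocity,
                            r_squared=vel.r_squared, msd_alpha=alpha,
                            reason="MSD exponent near 1")
    return MotilityCall(mode="unclassified", velocity=vel.velocity,
                        r_squared=vel.r_squared, msd_alpha=alpha,
                        reason="no rule matched")


@dataclass
class SurvivalFit:
    """Censored exponential fit of track lifetimes."""

    rate: float  # 1/s
    mean_lifetime: float  # s
    n_events: int
    n_censored: int
    survival_times: np.ndarray  # sorted observed durations
    survival_prob: np.ndarray  # Kaplan-Meier style empirical survival


def bleaching_survival(durations_s: np.ndarray,
                       censored: np.ndarray | None = None,
                       min_tracks: int = 10) -> SurvivalFit:
    """Exponential disappearance rate from track durations.

    Maximum likelihood for right-censored exponential data:
    rate = (number of uncensored ends) / (total observed time).  Tracks
    still alive at the end of the movie enter as censored exposure.
    """
    d = np.asarray(durations_s, dtype=np.float64)
    if censored is None:
        censored = np.zeros(d.size, dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    if d.size < min_tracks:
        raise ValueError(f"need at least {min_tracks} tracks, got {d.size}")
    n_events = int((~censored).sum())
    if n_events == 0:
        raise ValueError("all tracks censored: rate not identifiable")
    rate = n_events / float(d.sum())
    order = np.argsort(d)
    ds = d[order]
    # Kaplan-Meier product-limit over event times
    at_risk = d.size - np.arange(d.size)
    ev = (~censored)[order].astype(float)
    km = np.cumprod(1.0 - ev / at_risk)
    return SurvivalFit(rate=float(rate), mean_lifetime=float(1.0 / rate),
                       n_events=n_events, n_censored=int(censored.sum()),
                       survival_times=ds, survival_prob=km)


def kinetics_table(results: list[dict], path: str | Path) -> None:
    """Write a per-track kinetics CSV."""
    pd.DataFrame(results).to_csv(path, index=False)


def summary_to_json(summary: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return asdict(o)
    Path(path).write_text(json.dumps(summary, indent=2, default=_default))
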