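"""Kymographs along an organelle path and frame-to-frame track linking.

The organelle (stereocilium) axis is a polyline from base to tip.  A
kymograph stacks line scans along that path over frames — position along
the path on the vertical axis, time on the horizontal axis — so a static
molecule draws a horizontal streak, a processive one a sloped streak and a
stepping one a staircase.  Detections are linked into tracks by greedy
nearest-neighbor assignment with gap closing, substituting for manual
tracking, and tracks are projected onto the path to get axial positions
s(t) in nm (0 at the base, increasing toward the tip, so tip-ward velocity
is positive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .simcore import Movie
from .spots import SpotDetection

__all__ = [
    "OrganellePath",
    "Track",
    "Kymograph",
    "build_kymograph",
    "link_tracks",
    "project_to_axis",
    "tracks_to_csv",
]


@dataclass
class OrganellePath:
    """Base-to-tip polyline in pixel coordinates with a scan half-width."""

    control_points: np.ndarray  # (k, 2) of (x, y) pixels, base first
    half_width: float = 2.0  # perpendicular scan half-width, pixels
    pixel_size: float = 162.5  # nm / pixel

    def __post_init__(self) -> None:
        self.control_points = np.atleast_2d(
            np.asarray(self.control_points, dtype=float))
        if len(self.control_points) < 2:
            raise ValueError("path needs at least 2 control points")
        seg = np.diff(self.control_points, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        if seglen.sum() <= 0:
            raise ValueError("path has zero arc length")
        self._cum_px = np.concatenate([[0.0], np.cumsum(seglen)])

    @property
    def length_px(self) -> float:
        return float(self._cum_px[-1])

    @property
    def length_nm(self) -> float:
        return self.length_px * self.pixel_size

    def sample(self, step_px: float = 1.0
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Resample at ``step_px`` pitch: (points (m,2), normals (m,2), arc px)."""
        s = np.arange(0.0, self.length_px + step_px / 2, step_px)
        s = np.minimum(s, self.length_px)
        xs = np.interp(s, self._cum_px, self.control_points[:, 0])
        ys = np.interp(s, self._cum_px, self.control_points[:, 1])
        pts = np.column_stack([xs, ys])
        tang = np.gradient(pts, axis=0)
        norm = np.hypot(tang[:, 0], tang[:, 1])
        norm[norm == 0] = 1.0
        tang /= norm[:, None]
        normals = np.column_stack([-tang[:, 1], tang[:, 0]])
        return pts, normals, s

    def arc_length_of(self, x: float, y: float,
                      step_px: float = 0.25) -> tuple[float, float]:
        """Arc length (nm) of the nearest path point and the distance to it (px)."""
        pts, _, s = self.sample(step_px)
        d = np.hypot(pts[:, 0] - x, pts[:, 1] - y)
        i = int(np.argmin(d))
        return float(s[i] * self.pixel_size), float(d[i])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "control_points": self.control_points.tolist(),
            "half_width": self.half_width,
            "pixel_size": self.pixel_size}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "OrganellePath":
        d = json.loads(Path(path).read_text())
        return cls(control_points=np.asarray(d["control_points"]),
                   half_width=d.get("half_width", 2.0),
                   pixel_size=d.get("pixel_size", 162.5))


@dataclass
class Track:
    """Time-ordered chain of detections for one molecule."""

    track_id: int
    detections: list[SpotDetection] = field(default_factory=list)
    s_nm: np.ndarray | None = None  # axial positions after projection
    excluded: np.ndarray | None = None  # detections beyond the scan half-width

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections])

    @property
    def xy(self) -> np.ndarray:
        return np.array([[d.x, d.y] for d in self.detections])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([d.intensity for d in self.detections])

    @property
    def n_frames(self) -> int:
        return len(self.detections)

    @property
    def n_gaps(self) -> int:
        f = self.frames
        return int(np.sum(np.diff(f) - 1)) if len(f) > 1 else 0

    def times(self, frame_interval: float) -> np.ndarray:
        return self.frames * frame_interval


@dataclass
class Kymograph:
    """Space-time image: rows = path positions, columns = frames."""

    data: np.ndarray  # (n_rows, n_frames)
    nm_per_row: float
    s_per_col: float

    def to_tiff(self, path: str | Path) -> None:
        lo = self.data.min()
        span = max(np.ptp(self.data), 1e-12)
        scaled = np.clip((self.data - lo) / span * 65535, 0, 65535)
        tifffile.imwrite(path, scaled.astype(np.uint16))

    def to_png(self, path: str | Path, cmap: str = "gray") -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        n_rows, n_cols = self.data.shape
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.imshow(self.data, cmap=cmap, aspect="auto", origin="lower",
                  extent=[0, n_cols * self.s_per_col,
                          0, n_rows * self.nm_per_row / 1000.0])
        ax.set_xlabel("time (s)")
        ax.set_ylabel("position along path (μm)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def build_kymograph(movie: Movie, path: OrganellePath,
                    step_px: float = 1.0,
                    lateral_step_px: float = 0.5) -> Kymograph:
    """Line-scan kymograph along ``path`` for every frame of ``movie``.

    The intensity at each path sample is the maximum over the perpendicular
    scan half-width (bilinear sampling), which keeps faint single molecules
    visible when the path is not perfectly centered on the organelle.
    """
    pts, normals, s = path.sample(step_px)
    rows, cols = movie.shape
    if (pts[:, 0].min() < 0 or pts[:, 1].min() < 0
            or pts[:, 0].max() > cols - 1 or pts[:, 1].max() > rows - 1):
        raise ValueError("path extends outside the frame bounds")
    hw = path.half_width
    offsets = (np.arange(-hw, hw + lateral_step_px / 2, lateral_step_px)
               if hw > 0 else np.array([0.0]))
    # (n_samples, n_offsets, 2) sampling grid, shared across frames
    grid = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    coords = np.array([grid[..., 1].ravel(), grid[..., 0].ravel()])
    kymo = np.empty((len(pts), movie.n_frames))
    for t in range(movie.n_frames):
        vals = ndimage.map_coordinates(movie.frames[t], coords, order=1,
                                       mode="nearest")
        kymo[:, t] = vals.reshape(len(pts), len(offsets)).max(axis=1)
    return Kymograph(data=kymo, nm_per_row=step_px * path.pixel_size,
                     s_per_col=movie.frame_interval)


def link_tracks(detections_by_frame: dict[int, list[SpotDetection]]
                | list[list[SpotDetection]],
                max_jump_nm: float = 500.0, max_gap: int = 2,
                pixel_size: float = 162.5) -> list[Track]:
    """Link per-frame detections into tracks by greedy nearest neighbor.

    Candidate links between active track ends and detections in the current
    frame are taken in order of increasing displacement and accepted when
    both partners are still free and the displacement does not exceed
    ``max_jump_nm`` (scaled proportionally for links across ``gap`` skipped
    frames, up to ``max_gap``).  Unlinked detections start new tracks.
    """
    if isinstance(detections_by_frame, list):
        detections_by_frame = {t: ds for t, ds in enumerate(detections_by_frame)}
    frames = sorted(detections_by_frame)
    max_jump_px = max_jump_nm / pixel_size
    tracks: list[Track] = []
    active: list[Track] = []
    for t in frames:
        dets = detections_by_frame[t]
        for d in dets:
            d.frame = t
        # candidate (distance, track index, detection index)
        cands = []
        for ti, tr in enumerate(active):
            last = tr.detections[-1]
            gap = t - last.frame - 1
            if gap > max_gap:
                continue
            limit = max_jump_px * (gap + 1)
            for di, d in enumerate(dets):
                dist = np.hypot(d.x - last.x, d.y - last.y)
                if dist <= limit:
                    cands.append((dist, ti, di))
        cands.sort(key=lambda c: c[0])
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in cands:
            if ti in used_t or di in used_d:
                continue
            active[ti].detections.append(dets[di])
            used_t.add(ti)
            used_d.add(di)
        for di, d in enumerate(dets):
            if di not in used_d:
                tr = Track(track_id=len(tracks), detections=[d])
                tracks.append(tr)
                active.append(tr)
        active = [tr for tr in active if t - tr.detections[-1].frame <= max_gap]
    return tracks


def project_to_axis(track: Track, path: OrganellePath) -> np.ndarray:
    """Axial positions s(t) in nm by nearest-point projection onto the path.

    Detections farther than the scan half-width from the path are excluded
    (NaN position, flagged in ``track.excluded``).
    """
    s = np.empty(track.n_frames)
    excluded = np.zeros(track.n_frames, dtype=bool)
    for i, d in enumerate(track.detections):
        arc, dist = path.arc_length_of(d.x, d.y)
        if dist > path.half_width:
            s[i] = np.nan
            excluded[i] = True
        else:
            s[i] = arc
    track.s_nm = s
    track.excluded = excluded
    return s


def tracks_to_csv(tracks: list[Track], path: str | Path,
                  frame_interval: float = 1.0) -> None:
    rows = []
    for tr in tracks:
        s = tr.s_nm if tr.s_nm is not None else np.full(tr.n_frames, np.nan)
        for i, d in enumerate(tr.detections):
            rows.append((tr.track_id, d.frame, d.frame * frame_interval,
                         d.x, d.y, s[i], d.intensity))
    pd.DataFrame(rows, columns=["track_id", "frame", "t_s", "x_px", "y_px",
                                "s_nm", "intensity"]).to_csv(path, index=False)
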