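"""Trajectory analytics for freely moving animals.

Consumes already-tracked per-frame (x, y) coordinates (e.g. pose-tracker
exports), and computes the locomotion metrics used to assess whether a
head-mounted device changes open-field behavior: average speed, cumulative
travel distance, and Gaussian-weighted occupancy maps (sigma = 1 cm per
frame).  No smoothing is applied to the trajectory before the speed and
distance computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

DEFAULT_SIGMA_CM = 1.0
DEFAULT_PITCH_CM = 0.5


@dataclass
class Trajectory:
    """Per-frame positions in arena coordinates (cm)."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    confidence: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if not (self.times.shape == self.x.shape == self.y.shape):
            raise ValueError("times, x, y must have identical shapes")
        if self.times.size < 2:
            raise ValueError("trajectory needs at least 2 frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for arr in (self.x, self.y):
            if not np.all(np.isfinite(arr)):
                raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def step_lengths(self) -> np.ndarray:
        return np.hypot(np.diff(self.x), np.diff(self.y))

    @property
    def elapsed(self) -> float:
        return float(self.times[-1] - self.times[0])


def average_speed(traj: Trajectory) -> float:
    """Aggregate step length divided by total elapsed time, cm/s."""
    return float(traj.step_lengths.sum() / traj.elapsed)


def cumulative_distance(traj: Trajectory) -> float:
    """Total path length (not displacement), cm."""
    return float(traj.step_lengths.sum())


@dataclass
class OccupancyMap:
    """Accumulated Gaussian occupancy per arena pixel (dimensionless)."""

    values: np.ndarray
    pitch: float               # cm
    x_edges: tuple             # (x0, x1) arena extent, cm
    y_edges: tuple
    n_clipped: int = 0         # frames outside the arena (excluded, warned)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if np.any(self.values < 0):
            raise ValueError("occupancy must be non-negative")

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.attrs["pitch"] = self.pitch
            f.attrs["x_edges"] = self.x_edges
            f.attrs["y_edges"] = self.y_edges
            f.attrs["n_clipped"] = self.n_clipped


def occupancy_map(traj: Trajectory, arena_size, sigma: float = DEFAULT_SIGMA_CM,
                  pitch: float = DEFAULT_PITCH_CM,
                  origin=(0.0, 0.0)) -> OccupancyMap:
    """Gaussian occupancy accumulated over frames.

    For every frame, each arena pixel at offset (dx, dy) from the animal
    receives ``A = exp(-(dx^2 + dy^2) / (2 sigma^2))``; per-frame maps are
    summed over all frames.  Frames outside the arena are excluded and
    counted in ``n_clipped``.
    """
    if sigma <= 0 or pitch <= 0:
        raise ValueError("sigma and pitch must be positive")
    w, h = float(arena_size[0]), float(arena_size[1])
    x0, y0 = origin
    nx = int(np.ceil(w / pitch))
    ny = int(np.ceil(h / pitch))
    xc = x0 + (np.arange(nx) + 0.5) * pitch
    yc = y0 + (np.arange(ny) + 0.5) * pitch

    inside = ((traj.x >= x0) & (traj.x <= x0 + w) &
              (traj.y >= y0) & (traj.y <= y0 + h))
    n_clipped = int((~inside).sum())
    gx = np.exp(-((xc[None, :] - traj.x[inside, None]) ** 2) / (2 * sigma ** 2))
    gy = np.exp(-((yc[None, :] - traj.y[inside, None]) ** 2) / (2 * sigma ** 2))
    values = np.einsum("fi,fj->ij", gx, gy)
    return OccupancyMap(values, pitch, (x0, x0 + w), (y0, y0 + h), n_clipped)


def total_occupancy(omap: OccupancyMap) -> float:
    """Occupancy integrated over the arena (sum over pixels).

    A single frame far from the walls sums to ~``2 pi sigma^2 / pitch^2``
    (the Gaussian integral divided by the pixel area); multiply by
    ``pitch**2`` for the area-weighted integral.
    """
    return float(omap.values.sum())


def load_trajectory(path, frame_rate: float, scale_cm: float = 1.0,
                    confidence_min: float | None = None,
                    max_gap: int = 5) -> Trajectory:
    """Read a pose-tracker CSV export (columns: frame, x, y[, confidence]).

    Coordinates are multiplied by ``scale_cm`` (cm per coordinate unit).
    Frames with confidence below ``confidence_min`` are dropped and linearly
    interpolated across gaps of at most ``max_gap`` frames; longer gaps raise.
    """
    df = pd.read_csv(path)
    required = {"frame", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    frames = df["frame"].to_numpy(float)
    if np.any(np.diff(frames) <= 0):
        raise ValueError("frame numbers must be strictly increasing")
    x = df["x"].to_numpy(float) * scale_cm
    y = df["y"].to_numpy(float) * scale_cm
    conf = df["confidence"].to_numpy(float) if "confidence" in df.columns else None

    if confidence_min is not None and conf is not None:
        bad = conf < confidence_min
        if bad.any():
            runs = np.diff(np.concatenate([[0], bad.astype(int), [0]]))
            starts = np.where(runs == 1)[0]
            ends = np.where(runs == -1)[0]
            if np.any(ends - starts > max_gap):
                raise ValueError("low-confidence gap exceeds max_gap frames")
            good = ~bad
            x = np.interp(frames, frames[good], x[good])
            y = np.interp(frames, frames[good], y[good])
    times = frames / frame_rate
    return Trajectory(times, x, y, conf)


def synthetic_trajectory(n_frames: int, frame_rate: float, arena_size,
                         step_sigma: float = 0.5, persistence: float = 0.6,
                         seed: int = 0, origin=(0.0, 0.0)) -> Trajectory:
    """Bounded correlated random walk emulating open-field exploration.

    Steps are 2D Gaussian increments of scale ``step_sigma`` (cm/frame),
    blended with the previous step direction by ``persistence`` in [0, 1);
    the walk reflects off the arena walls.  Deterministic per seed.
    """
    if not 0 <= persistence < 1:
        raise ValueError("persistence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    w, h = float(arena_size[0]), float(arena_size[1])
    x0, y0 = origin
    pos = np.empty((n_frames, 2))
    pos[0] = (x0 + w / 2, y0 + h / 2)
    vel = np.zeros(2)
    for i in range(1, n_frames):
        innov = rng.normal(0.0, step_sigma, 2)
        vel = persistence * vel + np.sqrt(1 - persistence ** 2) * innov
        p = pos[i - 1] + vel
        # reflective walls
        for d, lo, hi in ((0, x0, x0 + w), (1, y0, y0 + h)):
            if p[d] < lo:
                p[d] = 2 * lo - p[d]
                vel[d] = -vel[d]
            elif p[d] > hi:
                p[d] = 2 * hi - p[d]
                vel[d] = -vel[d]
        pos[i] = p
    times = np.arange(n_frames) / frame_rate
    return Trajectory(times, pos[:, 0], pos[:, 1])


def metrics_report(traj: Trajectory, arena_size, sigma: float = DEFAULT_SIGMA_CM,
                   pitch: float = DEFAULT_PITCH_CM) -> dict:
    """Per-trajectory metrics table (suitable for downstream group statistics)."""
    omap = occupancy_map(traj, arena_size, sigma=sigma, pitch=pitch)
    return {
        "n_frames": int(traj.n_frames),
        "elapsed_s": traj.elapsed,
        "average_speed_cm_s": average_speed(traj),
        "cumulative_distance_cm": cumulative_distance(traj),
        "total_occupancy": total_occupancy(omap),
        "clipped_frames": omap.n_clipped,
    }
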