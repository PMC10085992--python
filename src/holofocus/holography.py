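"""Time-reversal recording, phase conjugation, and refocusing verification.

The design loop mirrors a physical time-reversal mirror: drive monochromatic
point sources at the intended focal target(s) inside the aberrator, record the
steady-state pressure phase on the plane where the transducer will sit, and
conjugate that phase.  A lens (or phased source) re-emitting the conjugated
phase from the same plane retraces the recorded propagation and refocuses at
the target(s), skull aberration included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .grid_medium import MediumMap, SimGrid
from .wave_sim import (SourceSpec, compute_dt, demod_phase_amplitude,
                       run_simulation, steady_state_phase, tone_burst)

MIN_RECORD_CYCLES = 20  # sinusoidal steady state needs at least this many


def wrap_phase(phi):
    """Wrap to (-pi, pi]; -pi maps to +pi."""
    phi = np.asarray(phi, float)
    out = np.angle(np.exp(1j * phi))
    if out.ndim == 0:
        return float(np.pi if out == -np.pi else out)
    out[out == -np.pi] = np.pi
    return out


@dataclass(frozen=True)
class TargetSet:
    """Focal targets: physical coordinates (m), relative weights, frequency."""

    points: tuple
    f0: float
    weights: tuple | None = None

    def __post_init__(self):
        if len(self.points) < 1:
            raise ValueError("need at least one target point")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        w = self.weights
        if w is None:
            object.__setattr__(self, "weights", tuple(1.0 for _ in self.points))
        elif len(w) != len(self.points) or any(x <= 0 for x in w):
            raise ValueError("weights must be positive, one per point")


@dataclass(frozen=True)
class RecordingPlane:
    """Axis-aligned recording plane: ``normal_axis`` fixed at voxel ``index``.

    Pixels are the grid voxels of the transverse axes; the pixel pitch is the
    simulation grid spacing.  ``aperture`` optionally restricts the active
    pixels to ``(lo, hi)`` voxel ranges per transverse axis — the physical
    transducer aperture, which must not extend past the aberrator's shadow.
    """

    normal_axis: int
    index: int
    aperture: tuple | None = None

    def pixel_positions(self, grid: SimGrid):
        """Voxel indices of every active plane pixel, plus the transverse shape."""
        t_axes = [a for a in range(3) if a != self.normal_axis and grid.shape[a] > 1]
        if not 0 <= self.index < grid.shape[self.normal_axis]:
            raise ValueError("plane index outside grid")
        if self.aperture is not None:
            bounds = list(self.aperture)
            ranges = [np.arange(max(lo, 0), min(hi, grid.shape[a]))
                      for a, (lo, hi) in zip(t_axes, bounds)]
        else:
            ranges = [np.arange(grid.shape[a]) for a in t_axes]
        shape = tuple(len(r) for r in ranges)
        mesh = np.meshgrid(*ranges, indexing="ij") if ranges else []
        n_pix = int(np.prod(shape)) if shape else 1
        positions = []
        flat = [m.ravel() for m in mesh]
        for i in range(n_pix):
            idx = [0, 0, 0]
            idx[self.normal_axis] = self.index
            for ax, vals in zip(t_axes, flat):
                idx[ax] = int(vals[i])
            positions.append(tuple(idx))
        return positions, shape, t_axes


@dataclass
class PhaseMap:
    """Wrapped phase (and optional relative amplitude) on the recording plane."""

    phase: np.ndarray
    pitch: float
    amplitude: np.ndarray | None = None
    f0: float | None = None

    def __post_init__(self):
        self.phase = np.asarray(self.phase, float)
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase must be finite")
        self.phase = wrap_phase(self.phase)
        if self.amplitude is not None:
            self.amplitude = np.asarray(self.amplitude, float)
            if self.amplitude.shape != self.phase.shape:
                raise ValueError("amplitude shape mismatch")

    @property
    def complex_field(self) -> np.ndarray:
        amp = self.amplitude if self.amplitude is not None else 1.0
        return amp * np.exp(1j * self.phase)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("phase", data=self.phase)
            if self.amplitude is not None:
                f.create_dataset("amplitude", data=self.amplitude)
            f.attrs["pitch"] = self.pitch
            if self.f0 is not None:
                f.attrs["f0"] = self.f0

    @classmethod
    def load(cls, path) -> "PhaseMap":
        with h5py.File(path, "r") as f:
            amp = f["amplitude"][...] if "amplitude" in f else None
            f0 = float(f.attrs["f0"]) if "f0" in f.attrs else None
            return cls(f["phase"][...], float(f.attrs["pitch"]), amp, f0)


def _sim_times(medium: MediumMap, f0: float, n_cycles: int, cfl: float):
    """Run duration: worst-case transit plus the requested steady cycles."""
    grid = medium.grid
    diag = np.sqrt(sum((grid.shape[a] * grid.dx) ** 2
                       for a in range(3) if grid.shape[a] > 1))
    transit = diag / medium.c_min
    duration = transit + n_cycles / f0
    return duration, transit


def record_time_reversal(
    medium: MediumMap,
    targets: TargetSet,
    plane: RecordingPlane,
    n_cycles: int = MIN_RECORD_CYCLES,
    cfl: float = 0.3,
) -> PhaseMap:
    """Record the steady-state phase map on the plane from the target sources.

    All targets are driven simultaneously as monochromatic pressure sources at
    ``targets.f0`` with zero relative phase and the given amplitude weights;
    because the solver injects sources additively, this equals the coherent
    sum of per-target recordings.

    ``n_cycles`` below 20 is rejected: fewer cycles do not reach a clean
    sinusoidal steady state.
    """
    if n_cycles < MIN_RECORD_CYCLES:
        raise ValueError(
            f"n_cycles = {n_cycles} < {MIN_RECORD_CYCLES}: steady-state "
            "recording requires at least 20 drive cycles"
        )
    grid = medium.grid
    f0 = targets.f0
    src_idx = [grid.index_of(p) for p in targets.points]
    for idx in src_idx:
        if idx[plane.normal_axis] == plane.index:
            raise ValueError("target lies on the recording plane")
    positions, shape, _ = plane.pixel_positions(grid)

    dt = compute_dt(cfl, grid.dx, medium.c_max, f0)
    duration, transit = _sim_times(medium, f0, n_cycles, cfl)
    wave = tone_burst(f0, dt, duration * f0)
    sources = SourceSpec(src_idx, wave, amplitudes=np.asarray(targets.weights))
    rec = run_simulation(medium, sources, positions, duration, cfl=cfl, f0=f0)
    discard = max(0.6, transit / duration)
    phase, amp = steady_state_phase(rec, f0, discard=discard)
    return PhaseMap(phase.reshape(shape), grid.dx,
                    amp.reshape(shape), f0)


def conjugate_phase(pmap: PhaseMap) -> PhaseMap:
    """Negate (conjugate) the phase; amplitude untouched.  Involutive."""
    return PhaseMap(wrap_phase(-pmap.phase), pmap.pitch,
                    None if pmap.amplitude is None else pmap.amplitude.copy(),
                    pmap.f0)


def fresnel_phase(grid: SimGrid, plane: RecordingPlane, focus, f0: float,
                  c: float) -> PhaseMap:
    """Geometric focusing phase with no aberration compensation.

    ``phase(x, y) = +k (sqrt(z^2 + r^2) - z)`` where ``z`` is the axial
    distance from the plane to the focus and ``r`` the lateral offset of each
    pixel — the acoustic Fresnel-lens reference.  The sign follows this
    package's convention that a pixel's phase is the initial phase of its
    drive ``sin(w t + phi)``: a farther pixel must lead, so its phase is
    positive (equivalently, it is the *delay* ``-k (r - z)`` negated).
    """
    positions, shape, t_axes = plane.pixel_positions(grid)
    focus = np.asarray(focus, float)
    z = abs(focus[plane.normal_axis]
            - (grid.origin[plane.normal_axis] + plane.index * grid.dx))
    if z <= 0:
        raise ValueError("focus must lie off the plane")
    k = 2 * np.pi * f0 / c
    phases = np.empty(len(positions))
    for i, idx in enumerate(positions):
        r2 = sum((grid.origin[a] + idx[a] * grid.dx - focus[a]) ** 2
                 for a in t_axes)
        phases[i] = k * (np.sqrt(z ** 2 + r2) - z)
    return PhaseMap(phases.reshape(shape), grid.dx, None, f0)


def steer_map(pmap: PhaseMap, offset_m, axis: int = 0) -> PhaseMap:
    """Translate the map laterally by a whole number of pixels.

    Mimics physically sliding the printed lens across a fixed aperture;
    vacated pixels replicate the nearest edge value.
    """
    shift = offset_m / pmap.pitch
    n = int(round(shift))
    if abs(shift - n) > 1e-9:
        raise ValueError(
            f"offset {offset_m} is not an integer multiple of the pixel "
            f"pitch {pmap.pitch}"
        )
    def shift_edge(arr):
        if n == 0 or arr is None:
            return None if arr is None else arr.copy()
        out = np.roll(arr, n, axis=axis)
        sl = [slice(None)] * arr.ndim
        edge = [slice(None)] * arr.ndim
        if n > 0:
            sl[axis] = slice(0, n)
            edge[axis] = slice(n, n + 1)
        else:
            sl[axis] = slice(arr.shape[axis] + n, None)
            edge[axis] = slice(arr.shape[axis] + n - 1, arr.shape[axis] + n)
        out[tuple(sl)] = out[tuple(edge)]
        return out
    return PhaseMap(shift_edge(pmap.phase), pmap.pitch,
                    shift_edge(pmap.amplitude), pmap.f0)


def verify_refocus(
    medium: MediumMap,
    conj: PhaseMap,
    plane: RecordingPlane,
    n_cycles: int = MIN_RECORD_CYCLES,
    cfl: float = 0.3,
    use_amplitude: bool = False,
    region=None,
):
    """Re-emit the conjugated map from the plane and return the focal field.

    Every plane pixel becomes a monochromatic source with the map's phase;
    amplitudes are uniform by default (phase-only lens over a uniform planar
    transducer) or taken from the map with ``use_amplitude=True``.  Returns a
    :class:`beam_metrics.FieldVolume` of steady-state pressure amplitude,
    demodulated at the drive frequency.

    ``region`` — optional ``((lo, hi), ...)`` voxel bounds per axis — zeroes
    the amplitude outside the requested evaluation volume (e.g. the skull
    cavity), so focal metrics ignore fields on the aberrator itself; indices
    stay on the full grid.
    """
    from .beam_metrics import FieldVolume

    grid = medium.grid
    f0 = conj.f0
    if f0 is None:
        raise ValueError("phase map carries no design frequency")
    positions, shape, _ = plane.pixel_positions(grid)
    if tuple(conj.phase.shape) != tuple(shape):
        raise ValueError(
            f"phase map shape {conj.phase.shape} does not match plane {shape}"
        )
    dt = compute_dt(cfl, grid.dx, medium.c_max, f0)
    duration, transit = _sim_times(medium, f0, n_cycles, cfl)
    n_t = int(np.ceil(duration / dt))
    t = np.arange(n_t) * dt
    phases = conj.phase.ravel()
    # per-pixel phased drives with a shared cosine onset ramp
    ramp = np.ones(n_t)
    n_ramp = int(round(3.0 / (f0 * dt)))
    ramp[:n_ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    waveforms = np.sin(2 * np.pi * f0 * t[None, :] + phases[:, None]) * ramp[None, :]
    amps = (conj.amplitude.ravel() if use_amplitude and conj.amplitude is not None
            else None)
    sources = SourceSpec(positions, waveforms, amplitudes=amps)
    demod_start = duration - min(8, n_cycles - 2) / f0
    rec = run_simulation(medium, sources, None, duration, cfl=cfl, f0=f0,
                         field_demod=(f0, demod_start))
    phase, amp = demod_phase_amplitude(rec.field_complex)
    amp = amp.reshape(grid.shape)
    if region is not None:
        mask = np.zeros(grid.shape, dtype=bool)
        sl = []
        for a in range(3):
            if a < len(region) and region[a] is not None:
                lo, hi = region[a]
                sl.append(slice(max(int(lo), 0), min(int(hi), grid.shape[a])))
            else:
                sl.append(slice(None))
        mask[tuple(sl)] = True
        amp = np.where(mask, amp, 0.0)
    return FieldVolume(grid, amp)
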