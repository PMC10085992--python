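"""Time-domain k-space pseudospectral solver for linear acoustics.

Solves the coupled first-order equations for sound propagation in a
heterogeneous absorbing medium,

    du/dt   = -(1/rho0) grad p                      (momentum)
    drho/dt = -rho0 div u                           (mass, linearized)
    p       = c0^2 (rho + heterogeneity and absorption corrections)

with spatial derivatives computed by Fourier collocation on a staggered grid
and a k-space temporal correction factor sinc(c_ref k dt / 2), which makes the
scheme exactly dispersion-free in a homogeneous medium for any CFL <= 1.

Power-law absorption alpha(f) = alpha0 f^gamma is modeled with two
fractional-Laplacian terms in the equation of state (one for absorption, one
for the dispersion Kramers-Kronig demands); ``alpha0`` is supplied in the
conventional dB MHz^-gamma cm^-1 and converted to Np (rad/s)^-gamma m^-1
internally.

Outgoing waves are absorbed in a split-field perfectly matched layer (PML)
occupying the outermost voxels of the grid; sources and sensors should stay
clear of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .grid_medium import MediumMap, SimGrid

DB_PER_NEPER = 20.0 / np.log(10.0)  # 8.6858...


def db_cm_mhz_to_nepers(alpha0, gamma: float):
    """Convert dB MHz^-gamma cm^-1 to Np (rad/s)^-gamma m^-1."""
    return 100.0 * np.asarray(alpha0, float) * (1e-6 / (2 * np.pi)) ** gamma \
        / DB_PER_NEPER


def compute_dt(cfl: float, dx: float, c_max: float, f0: float | None = None) -> float:
    """Stable time step, snapped so the drive period is a whole number of steps.

    ``dt = cfl * dx / c_max`` and, when a drive frequency is given, reduced to
    the nearest value with ``1/f0`` an exact integer multiple of ``dt`` so that
    steady-state phase extraction can window whole periods exactly.
    """
    if not 0 < cfl <= 1:
        raise ValueError(f"CFL number must be in (0, 1], got {cfl}")
    if dx <= 0 or c_max <= 0:
        raise ValueError("dx and c_max must be positive")
    dt = cfl * dx / c_max
    if f0 is not None:
        if f0 <= 0:
            raise ValueError("f0 must be positive")
        steps_per_period = int(np.ceil(1.0 / (f0 * dt) - 1e-12))
        dt = 1.0 / (f0 * steps_per_period)
    return dt


@dataclass
class SourceSpec:
    """Additive pressure sources.

    ``waveform`` is either one time series shared by all positions (with
    optional per-position ``phase_offsets`` applied by resampling a
    monochromatic drive) or a (n_positions, n_t) array.  Additive injection
    keeps the solver linear in its sources, so multi-target recordings
    superpose exactly.
    """

    positions: list
    waveform: np.ndarray
    amplitudes: np.ndarray | None = None

    def series_for(self, n_pos: int, n_t: int) -> np.ndarray:
        w = np.asarray(self.waveform, float)
        if w.ndim == 1:
            w = np.broadcast_to(w, (n_pos, w.size))
        if w.shape[0] != n_pos:
            raise ValueError("waveform rows do not match positions")
        if not np.all(np.isfinite(w)):
            raise ValueError("source waveform must be finite")
        out = np.zeros((n_pos, n_t))
        m = min(n_t, w.shape[1])
        out[:, :m] = w[:, :m]
        if self.amplitudes is not None:
            out = out * np.asarray(self.amplitudes, float)[:, None]
        return out


def tone_burst(f0: float, dt: float, n_cycles: float, phase: float = 0.0,
               ramp_cycles: float = 3.0) -> np.ndarray:
    """Sinusoidal drive with a cosine-tapered onset to limit broadband startup."""
    n = int(round(n_cycles / (f0 * dt)))
    t = np.arange(n) * dt
    w = np.sin(2 * np.pi * f0 * t + phase)
    n_ramp = int(round(ramp_cycles / (f0 * dt)))
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        w[:n_ramp] *= ramp
    return w


@dataclass
class SensorRecord:
    """Pressure time series at a list of sensor voxels."""

    positions: list
    dt: float
    pressures: np.ndarray  # (n_t, n_sensors)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.pressures = np.asarray(self.pressures, float)
        if self.pressures.ndim != 2 or self.pressures.shape[1] != len(self.positions):
            raise ValueError("pressures must be (n_t, n_sensors)")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.pressures.shape[0]) * self.dt

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("pressures", data=self.pressures)
            f.create_dataset("positions", data=np.asarray(self.positions))
            f.attrs["dt"] = self.dt

    @classmethod
    def load(cls, path) -> "SensorRecord":
        with h5py.File(path, "r") as f:
            return cls([tuple(p) for p in f["positions"][...]],
                       float(f.attrs["dt"]), f["pressures"][...])


class SimulationUnstableError(RuntimeError):
    pass


def _pml_sigma(n: int, width: int, dx: float, c_ref: float,
               order: int = 4, target_reflection: float = 1e-4) -> np.ndarray:
    """Polynomial-graded PML absorption profile (Np/s) along one axis."""
    sigma = np.zeros(n)
    if width <= 0 or n <= 2 * width:
        return sigma
    sigma_max = -(order + 1) * c_ref * np.log(target_reflection) / (2 * width * dx)
    ramp = sigma_max * ((np.arange(1, width + 1)) / width) ** order
    sigma[:width] = ramp[::-1]
    sigma[-width:] = ramp
    return sigma


def run_simulation(
    medium: MediumMap,
    sources: SourceSpec,
    sensors: list | None,
    duration: float,
    cfl: float = 0.3,
    f0: float | None = None,
    pml_width: int = 10,
    record_field: bool = False,
    field_demod: tuple[float, float] | None = None,
    dt: float | None = None,
) -> SensorRecord:
    """Advance the acoustic field and record pressure at the sensors.

    Parameters
    ----------
    sensors : list of voxel indices, or None
        ``None`` records nothing (useful with ``field_demod``).
    duration : float
        Physical simulated time, seconds.
    f0 : float, optional
        Drive frequency used to snap ``dt`` to an integer number of steps per
        period (see :func:`compute_dt`).
    field_demod : (f0_demod, t_start), optional
        Accumulate in-phase/quadrature sums of the full pressure field at
        ``f0_demod`` from ``t_start`` to the end of the run; the complex field
        (amplitude and phase per voxel) is attached to the returned record as
        ``record.field_complex``.  The demodulation window is truncated to a
        whole number of periods.

    Raises
    ------
    SimulationUnstableError
        If any field value becomes non-finite.
    """
    grid = medium.grid
    axes = [a for a in range(3) if grid.shape[a] > 1]
    if not axes:
        axes = [0]
    shape = tuple(grid.shape[a] for a in axes)
    nd = len(axes)
    dx = grid.dx

    c0 = medium.c0.reshape(shape)
    rho0 = medium.rho0.reshape(shape)
    alpha0 = medium.alpha0.reshape(shape)
    gamma = medium.gamma
    c_ref = float(c0.max())

    if dt is None:
        dt = compute_dt(cfl, dx, c_ref, f0)
    elif dt > cfl * dx / c_ref * (1 + 1e-12):
        raise ValueError(
            f"supplied dt = {dt:.3e} s exceeds the stability bound "
            f"cfl*dx/c_max = {cfl * dx / c_ref:.3e} s"
        )
    n_t = int(np.ceil(duration / dt))

    def squeeze_idx(idx):
        full = tuple(idx) + (0,) * (3 - len(idx))
        for a in range(3):
            if not 0 <= full[a] < grid.shape[a]:
                raise ValueError(f"voxel index {idx} outside grid")
        return tuple(full[a] for a in axes)

    src_idx = [squeeze_idx(p) for p in sources.positions]
    sens_idx = [squeeze_idx(p) for p in sensors] if sensors else []
    src_series = sources.series_for(len(src_idx), n_t)

    # spectral operators on the real-FFT half spectrum (fields are real)
    ks = [2 * np.pi * (np.fft.rfftfreq(shape[i], dx) if i == nd - 1
                       else np.fft.fftfreq(shape[i], dx)) for i in range(nd)]
    kmesh = np.meshgrid(*ks, indexing="ij")
    k = np.sqrt(sum(kk ** 2 for kk in kmesh))
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.sinc(c_ref * k * dt / 2 / np.pi)  # sin(x)/x, x = c_ref k dt/2
    deriv_pos = [1j * kmesh[i] * kappa * np.exp(+1j * kmesh[i] * dx / 2)
                 for i in range(nd)]
    deriv_neg = [1j * kmesh[i] * kappa * np.exp(-1j * kmesh[i] * dx / 2)
                 for i in range(nd)]

    # absorption operators (k-space fractional Laplacians)
    absorbing = bool(np.any(alpha0 > 0))
    if absorbing:
        alpha_np = db_cm_mhz_to_nepers(alpha0, gamma)
        tau = -2.0 * alpha_np * c0 ** (gamma - 1)
        eta = 2.0 * alpha_np * c0 ** gamma * np.tan(np.pi * gamma / 2)
        with np.errstate(divide="ignore"):
            nabla1 = k ** (gamma - 2.0)
            nabla2 = k ** (gamma - 1.0)
        nabla1[k == 0] = 0.0
        nabla2[k == 0] = 0.0

    # staggered density (midpoint average toward +axis)
    rho0_sg = [0.5 * (rho0 + np.roll(rho0, -1, axis=i)) for i in range(nd)]

    # PML attenuation factors per axis, applied twice per update
    pml = []
    for i in range(nd):
        sigma = _pml_sigma(shape[i], pml_width, dx, c_ref)
        shape_i = [1] * nd
        shape_i[i] = shape[i]
        pml.append(np.exp(-sigma * dt / 2).reshape(shape_i))

    def fftn(a):
        return np.fft.rfftn(a)

    axes_all = tuple(range(nd))

    def ifftn(a):
        return np.fft.irfftn(a, s=shape, axes=axes_all)

    u = [np.zeros(shape) for _ in range(nd)]
    rho_split = [np.zeros(shape) for _ in range(nd)]
    p = np.zeros(shape)

    n_sens = len(sens_idx)
    traces = np.zeros((n_t, n_sens))
    sens_flat = (np.ravel_multi_index(np.array(sens_idx).T, shape)
                 if n_sens else None)
    src_flat = np.ravel_multi_index(np.array(src_idx).T, shape) if src_idx else None

    demod_cos = demod_sin = None
    demod_count = 0
    if field_demod is not None:
        fd, t_start = field_demod
        steps_per_period = int(round(1.0 / (fd * dt)))
        start_step = int(np.ceil(t_start / dt))
        n_periods = (n_t - start_step) // steps_per_period
        if n_periods < 1:
            raise ValueError("field_demod window shorter than one period")
        start_step = n_t - n_periods * steps_per_period
        demod_cos = np.zeros(shape)
        demod_sin = np.zeros(shape)

    field_frames = [] if record_field else None

    for step in range(n_t):
        p_hat = fftn(p)
        for i in range(nd):
            grad = ifftn(deriv_pos[i] * p_hat)
            u[i] = pml[i] * (pml[i] * u[i] - dt / rho0_sg[i] * grad)
        div_terms = []
        for i in range(nd):
            dudx = ifftn(deriv_neg[i] * fftn(u[i]))
            div_terms.append(dudx)
            rho_split[i] = pml[i] * (pml[i] * rho_split[i] - dt * rho0 * dudx)
        if src_flat is not None:
            # the mass added during this step appears in p half a step later;
            # sample the drive at t - dt/2 (trapezoidal centering) so the
            # injected phase matches the pressure time base
            w_mid = 0.5 * (src_series[:, step]
                           + (src_series[:, step - 1] if step > 0
                              else 0.0))
            inj = w_mid / (np.take(c0.ravel(), src_flat) ** 2 * nd)
            for i in range(nd):
                np.add.at(rho_split[i].ravel(), src_flat, inj)
        rho_sum = sum(rho_split)
        if absorbing:
            div_total = rho0 * sum(div_terms)
            p = c0 ** 2 * (
                rho_sum
                + tau * ifftn(nabla1 * fftn(div_total))
                + eta * ifftn(nabla2 * fftn(rho_sum))
            )
        else:
            p = c0 ** 2 * rho_sum
        if n_sens:
            traces[step] = np.take(p.ravel(), sens_flat)
        if demod_cos is not None and step >= start_step:
            ph = 2 * np.pi * fd * (step * dt)
            demod_cos += p * np.cos(ph)
            demod_sin += p * np.sin(ph)
            demod_count += 1
        if record_field:
            field_frames.append(p.copy())
        if step % 200 == 0 and not np.isfinite(p).all():
            raise SimulationUnstableError(
                f"non-finite pressure at step {step} (t = {step * dt:.3e} s)"
            )

    if not np.isfinite(traces).all() or not np.isfinite(p).all():
        raise SimulationUnstableError("non-finite field at end of run")

    record = SensorRecord(sens_idx if sensors else [(0,) * nd],
                          dt,
                          traces if n_sens else np.zeros((n_t, 1)))
    if field_demod is not None:
        # p(t) ~ A sin(w t + phi): I = sum p cos, Q = sum p sin
        # => complex field A e^{i phi} = 2 (I + i Q') / N with quadrature algebra
        scale = 2.0 / demod_count
        record.field_complex = (scale * (demod_sin + 1j * demod_cos)).reshape(
            tuple(grid.shape[a] if a in axes else 1 for a in range(3))
        )
    if record_field:
        record.field_frames = np.array(field_frames)
    return record


def steady_state_phase(record: SensorRecord, f0: float,
                       discard: float = 0.6) -> tuple[np.ndarray, np.ndarray]:
    """Phase and amplitude per sensor by quadrature demodulation at ``f0``.

    The first ``discard`` fraction of the trace is dropped (start-up
    transient), and the retained window is truncated to a whole number of
    drive periods so that harmonics and DC are exactly orthogonal to the
    demodulation kernels.  A sensor trace ``A sin(2 pi f0 t + phi)`` yields
    phase ``phi`` in (-pi, pi] and amplitude ``A``.

    Raises if the retained window spans fewer than 5 periods or if the
    sampling does not resolve ``f0`` (fewer than 3 samples per period).
    """
    dt = record.dt
    p = record.pressures
    n_t = p.shape[0]
    steps_per_period = 1.0 / (f0 * dt)
    if steps_per_period < 3:
        raise ValueError(f"f0 = {f0:.3g} Hz not resolvable at dt = {dt:.3g} s")
    spp = int(round(steps_per_period))
    if abs(spp - steps_per_period) > 1e-6 * steps_per_period:
        raise ValueError(
            "drive period is not an integer number of samples; "
            "use compute_dt(..., f0=f0) when generating the record"
        )
    start = int(np.ceil(discard * n_t))
    n_periods = (n_t - start) // spp
    if n_periods < 5:
        raise ValueError(
            f"retained trace spans {n_periods} periods; need >= 5 "
            "(lengthen the run or reduce the discard fraction)"
        )
    n_keep = n_periods * spp
    window = p[n_t - n_keep:]
    t = np.arange(n_t - n_keep, n_t) * dt
    c = np.cos(2 * np.pi * f0 * t)
    s = np.sin(2 * np.pi * f0 * t)
    i_comp = 2.0 / n_keep * (window * s[:, None]).sum(axis=0)   # in-phase (sin)
    q_comp = 2.0 / n_keep * (window * c[:, None]).sum(axis=0)   # quadrature (cos)
    amplitude = np.hypot(i_comp, q_comp)
    phase = np.arctan2(q_comp, i_comp)
    return phase, amplitude


def demod_phase_amplitude(field_complex: np.ndarray):
    """Split a complex demodulated field into wrapped phase and amplitude."""
    return np.angle(field_complex), np.abs(field_complex)
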