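"""Lumped electromechanical model of a capacitive micromachined ultrasound
transducer (CMUT) and its equivalent-circuit impedance.

The vibrating element is a clamped circular silicon plate over a vacuum gap.
Its fundamental resonance, DC-bias spring softening, and electrostatic
pull-in are described by a single-degree-of-freedom mass-spring model whose
equivalent stiffness and mass come from the Rayleigh quotient of the clamped
plate mode shape ``(1 - (r/a)^2)^2``:

    f_plate = (10.21 / (2 pi a^2)) sqrt(D / (rho_m h)),  D = E h^3 / (12 (1 - nu^2))
    m_eff   = rho_m h pi a^2 / 5
    k_eff   = (2 pi f_plate)^2 m_eff

The electrostatic load uses the parallel-plate approximation with the
vacuum-equivalent gap ``g_eff = g + t_i / eps_r``.  Spring softening is
evaluated at the *deflected* static equilibrium, so the softened frequency
reaches zero exactly at the pull-in voltage
``V_pi = sqrt(8 k_eff g_eff^3 / (27 eps0 A))`` — the standard lumped-model
consistency between dynamic softening and static instability.

Electrically, the device near resonance is the 6-element Butterworth-Van
Dyke-style circuit of a static capacitance C0 in parallel with a series
mechanical branch (Rm, Lm, Cm), behind series parasitics (Rs, Cs); Cs = 0
denotes an absent (shorted) series capacitor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

EPS0 = 8.8541878128e-12  # F/m

# plate fundamental eigenvalue: (lambda_01)^2 = 10.21 for a clamped disk
_PLATE_EIGEN = 10.21
# Rayleigh-quotient modal mass fraction for the shape (1 - (r/a)^2)^2
_MASS_FRACTION = 1.0 / 5.0


@dataclass(frozen=True)
class PlateMaterial:
    """Isotropic plate material (default: single-crystal silicon)."""

    e_young: float = 150e9
    nu: float = 0.27
    rho_m: float = 2330.0

    def __post_init__(self):
        if self.e_young <= 0 or self.rho_m <= 0 or not 0 <= self.nu < 0.5:
            raise ValueError("invalid plate material constants")


@dataclass(frozen=True)
class CmutGeometry:
    """Cell and device geometry, SI meters."""

    radius: float
    thickness: float
    gap: float
    t_insulator: float = 120e-9
    eps_r_insulator: float = 3.9
    n_cells: int = 1
    aperture_diameter: float | None = None
    substrate_thickness: float = 725e-6

    def __post_init__(self):
        for name in ("radius", "thickness", "gap", "t_insulator",
                     "eps_r_insulator", "substrate_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.aperture_diameter is not None:
            cell_area = self.n_cells * np.pi * self.radius ** 2
            aperture = np.pi * (self.aperture_diameter / 2) ** 2
            if cell_area > aperture:
                raise ValueError("total cell area exceeds the aperture")

    @property
    def g_eff(self) -> float:
        """Vacuum-equivalent electrostatic gap."""
        return self.gap + self.t_insulator / self.eps_r_insulator

    @property
    def electrode_area(self) -> float:
        """Electrode area per cell (full cell area by default)."""
        return np.pi * self.radius ** 2


def flexural_rigidity(geom: CmutGeometry, mat: PlateMaterial) -> float:
    return mat.e_young * geom.thickness ** 3 / (12 * (1 - mat.nu ** 2))


def plate_resonance_air(geom: CmutGeometry, mat: PlateMaterial = PlateMaterial()) -> float:
    """Fundamental in-air resonance of the clamped circular plate, Hz."""
    d_rig = flexural_rigidity(geom, mat)
    return _PLATE_EIGEN / (2 * np.pi * geom.radius ** 2) * \
        np.sqrt(d_rig / (mat.rho_m * geom.thickness))


def effective_mass(geom: CmutGeometry, mat: PlateMaterial = PlateMaterial()) -> float:
    return _MASS_FRACTION * mat.rho_m * geom.thickness * np.pi * geom.radius ** 2


def effective_stiffness(geom: CmutGeometry, mat: PlateMaterial = PlateMaterial()) -> float:
    w0 = 2 * np.pi * plate_resonance_air(geom, mat)
    return w0 ** 2 * effective_mass(geom, mat)


def pull_in_voltage(geom: CmutGeometry, mat: PlateMaterial = PlateMaterial()) -> float:
    """Static pull-in voltage of the parallel-plate lumped model, volts."""
    k = effective_stiffness(geom, mat)
    g = geom.g_eff
    return float(np.sqrt(8 * k * g ** 3 / (27 * EPS0 * geom.electrode_area)))


def static_deflection(geom: CmutGeometry, mat: PlateMaterial, v_dc: float) -> float:
    """Stable equilibrium deflection x solving k x (g - x)^2 = eps0 A V^2 / 2.

    The stable branch lives in [0, g/3]; beyond pull-in no solution exists.
    """
    if v_dc < 0:
        raise ValueError("V_dc must be non-negative")
    if v_dc == 0:
        return 0.0
    k = effective_stiffness(geom, mat)
    g = geom.g_eff
    a_el = geom.electrode_area
    rhs = EPS0 * a_el * v_dc ** 2 / 2.0

    def f(x):
        return k * x * (g - x) ** 2 - rhs

    x_max = g / 3.0
    if f(x_max) < 0:  # electrostatic force exceeds restoring force everywhere
        raise ValueError(
            f"V_dc = {v_dc:.3g} V is at or above pull-in "
            f"({pull_in_voltage(geom, mat):.3g} V)"
        )
    return float(optimize.brentq(f, 0.0, x_max, xtol=1e-18, rtol=1e-14))


def softened_resonance(geom: CmutGeometry, mat: PlateMaterial, v_dc: float) -> float:
    """Bias-softened resonance f(V) = f(0) sqrt(1 - k_e(V)/k_eff), Hz.

    The electrostatic stiffness ``k_e = eps0 A V^2 / (g_eff - x)^3`` is
    evaluated at the static equilibrium deflection ``x``, so ``f`` decreases
    monotonically with bias and reaches zero exactly at pull-in.
    """
    f0 = plate_resonance_air(geom, mat)
    if v_dc == 0:
        return f0
    x = static_deflection(geom, mat, v_dc)
    k = effective_stiffness(geom, mat)
    k_e = EPS0 * geom.electrode_area * v_dc ** 2 / (geom.g_eff - x) ** 3
    arg = 1.0 - k_e / k
    if arg <= 0:
        return 0.0
    return float(f0 * np.sqrt(arg))


# ---------------------------------------------------------------------------
# equivalent circuit


@dataclass(frozen=True)
class CircuitParams:
    """Six-element equivalent circuit of the biased CMUT.

    C0: static capacitance (F); Rm, Lm, Cm: mechanical branch; Rs, Cs: series
    parasitics.  ``Cs = 0`` means the series capacitor is absent (a short).
    """

    c0: float
    rm: float
    lm: float
    cm: float
    rs: float = 0.0
    cs: float = 0.0

    def __post_init__(self):
        for name in ("c0", "rm", "lm", "cm", "rs", "cs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.lm * self.cm <= 0:
            raise ValueError("Lm * Cm must be positive for a resonant branch")

    @property
    def f_series(self) -> float:
        """Mechanical (series) resonance 1 / (2 pi sqrt(Lm Cm)), Hz."""
        return 1.0 / (2 * np.pi * np.sqrt(self.lm * self.cm))

    @property
    def f_parallel(self) -> float:
        """Antiresonance f_s sqrt(1 + Cm/C0), Hz."""
        return self.f_series * np.sqrt(1 + self.cm / self.c0)

    def as_array(self) -> np.ndarray:
        return np.array([self.c0, self.rm, self.lm, self.cm, self.rs, self.cs])


def circuit_impedance(params: CircuitParams, f) -> np.ndarray:
    """Complex input impedance of the 6-element circuit at frequency ``f`` (Hz)."""
    f = np.asarray(f, float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    w = 2 * np.pi * f
    z_mech = params.rm + 1j * w * params.lm + 1.0 / (1j * w * params.cm)
    z_c0 = 1.0 / (1j * w * params.c0)
    z_par = z_c0 * z_mech / (z_c0 + z_mech)
    z = z_par + params.rs
    if params.cs > 0:
        z = z + 1.0 / (1j * w * params.cs)
    z = np.asarray(z)
    return z if z.shape else complex(z)


@dataclass
class ImpedanceSpectrum:
    """Measured (or synthetic) complex impedance vs frequency at one DC bias."""

    frequencies: np.ndarray
    z: np.ndarray
    bias: float = 0.0

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, float)
        self.z = np.asarray(self.z, complex)
        if self.frequencies.ndim != 1 or self.frequencies.shape != self.z.shape:
            raise ValueError("frequencies and Z must be matching 1D arrays")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("impedance must be finite")

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "frequency_hz": self.frequencies,
            "re_ohm": self.z.real,
            "im_ohm": self.z.imag,
            "bias_v": self.bias,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ImpedanceSpectrum":
        df = pd.read_csv(path)
        required = {"frequency_hz", "re_ohm", "im_ohm"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"spectrum CSV missing columns: {sorted(missing)}")
        bias = float(df["bias_v"].iloc[0]) if "bias_v" in df.columns else 0.0
        return cls(df["frequency_hz"].to_numpy(),
                   df["re_ohm"].to_numpy() + 1j * df["im_ohm"].to_numpy(),
                   bias)


@dataclass
class CircuitFit:
    params: CircuitParams
    residual_norm: float
    rel_uncertainty: dict


def _auto_init(spectrum: ImpedanceSpectrum) -> CircuitParams:
    """Initial guess from the capacitive baseline and resonance landmarks."""
    f = spectrum.frequencies
    z = spectrum.z
    w = 2 * np.pi * f
    # C0 from the low-frequency capacitive limit
    c0 = float(np.median(-1.0 / (w[:max(3, f.size // 10)]
                                 * z.imag[:max(3, f.size // 10)])))
    c0 = abs(c0)
    # resonance: extremum of d|Z|/df beyond the smooth 1/f baseline
    mag = np.abs(z)
    baseline = 1.0 / (w * c0)
    dev = mag / baseline
    i_min = int(np.argmin(dev))
    i_max = int(np.argmax(dev))
    f_s = f[i_min]
    f_p = f[i_max] if f[i_max] > f_s else f_s * 1.02
    if dev.max() - dev.min() < 0.02:
        raise ValueError("no resonance in band: impedance is purely capacitive")
    cm = c0 * max((f_p / f_s) ** 2 - 1.0, 1e-4)
    lm = 1.0 / ((2 * np.pi * f_s) ** 2 * cm)
    rm = max(float(z.real[i_min]), 1.0)
    rs = max(float(np.median(z.real[:max(3, f.size // 10)])), 0.1)
    return CircuitParams(c0, rm, lm, cm, rs, 0.0)


def fit_circuit(spectrum: ImpedanceSpectrum,
                init: CircuitParams | None = None,
                fit_cs: bool = False,
                n_restarts: int = 3) -> CircuitFit:
    """Least-squares fit of the 6-element circuit to an impedance spectrum.

    Stacked real/imaginary residuals are weighted by 1/|Z| (log-magnitude
    weighting), parameters are fit in log space to stay positive, and the fit
    restarts from perturbed initials if the optimizer stalls.  The series
    capacitor is fixed absent (Cs = 0) unless ``fit_cs``; measured CMUT
    spectra typically fit Cs ~ 0.

    Returns the parameters, the residual norm, and per-parameter relative
    uncertainties from the Jacobian at the optimum.
    """
    if init is None:
        init = _auto_init(spectrum)
    f = spectrum.frequencies
    z_obs = spectrum.z
    weight = 1.0 / np.abs(z_obs)
    names = ["c0", "rm", "lm", "cm", "rs"] + (["cs"] if fit_cs else [])

    def unpack(theta):
        vals = dict(zip(names, np.exp(np.clip(theta, -80.0, 80.0))))
        vals.setdefault("cs", 0.0)
        return CircuitParams(**vals)

    def residuals(theta):
        zm = circuit_impedance(unpack(theta), f)
        r = (zm - z_obs) * weight
        return np.concatenate([r.real, r.imag])

    theta0 = np.log(np.array([getattr(init, n) if getattr(init, n) > 0 else 1e-15
                              for n in names]))
    best = None
    rng = np.random.default_rng(0)
    for attempt in range(n_restarts):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.2, theta0.size)
        sol = optimize.least_squares(residuals, start, method="lm",
                                     max_nfev=20000)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-16:
            break
    if best is None or not best.success and best.cost > 1e-6:
        raise RuntimeError("circuit fit did not converge after restarts")

    params = unpack(best.x)
    # relative confidence: sqrt of diagonal of (J^T J)^-1 scaled by residual
    jac = best.jac
    dof = max(len(best.fun) - len(best.x), 1)
    s2 = 2 * best.cost / dof
    try:
        cov = np.linalg.inv(jac.T @ jac) * s2
        rel_unc = dict(zip(names, np.sqrt(np.maximum(np.diag(cov), 0.0))))
    except np.linalg.LinAlgError:
        rel_unc = {n: np.nan for n in names}
    return CircuitFit(params, float(np.sqrt(2 * best.cost)), rel_unc)


def synthetic_spectrum(params: CircuitParams, f_lo: float, f_hi: float,
                       n: int = 400, noise: float = 0.0,
                       seed: int | None = None, bias: float = 0.0
                       ) -> ImpedanceSpectrum:
    """Synthetic impedance spectrum from known circuit parameters.

    ``noise`` is the standard deviation of multiplicative complex Gaussian
    noise (e.g. 0.01 for 1%).
    """
    f = np.linspace(f_lo, f_hi, n)
    z = circuit_impedance(params, f)
    if noise > 0:
        rng = np.random.default_rng(seed)
        z = z * (1 + noise * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
                 / np.sqrt(2))
    return ImpedanceSpectrum(f, z, bias)


# ---------------------------------------------------------------------------
# device-level derived quantities


def impulse_spectrum(trace: np.ndarray, dt: float, db_down: float = 6.0,
                     pad_factor: int = 8) -> tuple[float, float]:
    """Center frequency and bandwidth of an impulse response.

    The magnitude spectrum of the (zero-padded) trace is scanned for the band
    within ``db_down`` dB of its maximum; the center frequency is the midpoint
    of that band and the bandwidth its width, both via linear interpolation
    of the band edges.  The -6 dB convention is the default; pass
    ``db_down=3`` for -3 dB figures.  Time-shifting the trace does not change
    either value.
    """
    trace = np.asarray(trace, float)
    if trace.size < 64:
        raise ValueError("trace too short (need >= 64 samples)")
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace must be finite")
    n = int(2 ** np.ceil(np.log2(trace.size * pad_factor)))
    spec = np.abs(np.fft.rfft(trace - trace.mean(), n))
    freqs = np.fft.rfftfreq(n, dt)
    i_pk = int(np.argmax(spec))
    level = spec[i_pk] * 10 ** (-db_down / 20.0)
    i = i_pk
    while i > 0 and spec[i] > level:
        i -= 1
    if spec[i] > level:
        raise ValueError("lower band edge below the sampled range")
    f_lo = np.interp(level, [spec[i], spec[i + 1]], [freqs[i], freqs[i + 1]])
    j = i_pk
    while j < spec.size - 1 and spec[j] > level:
        j += 1
    if spec[j] > level:
        raise ValueError("upper band edge above the sampled range")
    f_hi = np.interp(level, [spec[j], spec[j - 1]], [freqs[j], freqs[j - 1]])
    return float((f_lo + f_hi) / 2), float(f_hi - f_lo)


def areal_mass(substrate_thickness: float, density: float) -> float:
    """Areal mass of the chip in g/cm^2 (thickness in m, density in kg/m^3)."""
    if substrate_thickness < 0 or density <= 0:
        raise ValueError("thickness must be >= 0 and density > 0")
    return substrate_thickness * density * 0.1  # kg/m^2 -> g/cm^2
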