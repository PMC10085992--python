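"""CMUT lumped model, equivalent circuit, and derived quantities."""

import numpy as np
import pytest

from holofocus.cmut_model import (CircuitParams, CmutGeometry,
                                  ImpedanceSpectrum, PlateMaterial, areal_mass,
                                  circuit_impedance, fit_circuit,
                                  impulse_spectrum, plate_resonance_air,
                                  pull_in_voltage, softened_resonance,
                                  synthetic_spectrum)

GEOM = CmutGeometry(radius=18e-6, thickness=1e-6, gap=200e-9,
                    t_insulator=120e-9, eps_r_insulator=3.9)
SILICON = PlateMaterial()  # E = 150 GPa, nu = 0.27, rho = 2330
MEASURED_FIT = CircuitParams(c0=131e-12, rm=137.0, lm=0.36e-3, cm=1.45e-12,
                             rs=8.53, cs=0.0)


class TestPlateResonance:
    def test_reference_geometry_near_12_mhz(self):
        # clamped-plate closed form for a = 18 um, h = 1 um silicon
        assert plate_resonance_air(GEOM, SILICON) == pytest.approx(1.2e7, rel=0.02)

    def test_frequency_scales_linearly_with_thickness(self):
        thick = CmutGeometry(18e-6, 2e-6, 200e-9)
        assert plate_resonance_air(thick, SILICON) == pytest.approx(
            2 * plate_resonance_air(GEOM, SILICON), rel=1e-9)

    def test_frequency_scales_inverse_square_with_radius(self):
        big = CmutGeometry(36e-6, 1e-6, 200e-9)
        assert plate_resonance_air(big, SILICON) == pytest.approx(
            plate_resonance_air(GEOM, SILICON) / 4, rel=1e-9)


class TestSoftening:
    def test_zero_bias_equals_plate_resonance(self):
        assert softened_resonance(GEOM, SILICON, 0.0) == \
            plate_resonance_air(GEOM, SILICON)

    def test_strictly_decreasing_up_to_pull_in(self):
        v_pi = pull_in_voltage(GEOM, SILICON)
        f = [softened_resonance(GEOM, SILICON, v)
             for v in np.linspace(0, 0.995 * v_pi, 30)]
        assert np.all(np.diff(f) < 0)

    def test_frequency_vanishes_at_pull_in(self):
        v_pi = pull_in_voltage(GEOM, SILICON)
        f0 = plate_resonance_air(GEOM, SILICON)
        assert softened_resonance(GEOM, SILICON, 0.99999 * v_pi) < 0.1 * f0

    def test_softening_and_static_instability_agree_within_1_percent(self):
        # the bias where the softened frequency hits zero is the same
        # pull-in voltage as the static stability criterion
        v_pi = pull_in_voltage(GEOM, SILICON)
        assert softened_resonance(GEOM, SILICON, 0.99 * v_pi) > 0
        with pytest.raises(ValueError):
            softened_resonance(GEOM, SILICON, 1.01 * v_pi)


class TestPullIn:
    def test_gap_three_halves_scaling(self):
        g4 = CmutGeometry(18e-6, 1e-6, 200e-9 * 4,
                          t_insulator=120e-9 * 4, eps_r_insulator=3.9)
        # g_eff scales by exactly 4 -> V_pi by 8
        assert pull_in_voltage(g4, SILICON) == pytest.approx(
            8 * pull_in_voltage(GEOM, SILICON), rel=1e-9)

    def test_reference_geometry_is_tens_of_volts(self):
        v_pi = pull_in_voltage(GEOM, SILICON)
        assert 10.0 < v_pi < 100.0


class TestCircuit:
    def test_low_frequency_limit_is_capacitive(self):
        f = 1e5
        z = circuit_impedance(MEASURED_FIT, f)
        assert abs(z) == pytest.approx(1 / (2 * np.pi * f * MEASURED_FIT.c0), rel=0.02)

    def test_series_resonance_from_fitted_values(self):
        assert MEASURED_FIT.f_series == pytest.approx(6.97e6, rel=1e-3)

    def test_antiresonance_above_series_resonance(self):
        assert MEASURED_FIT.f_parallel == pytest.approx(
            MEASURED_FIT.f_series * np.sqrt(1 + MEASURED_FIT.cm / MEASURED_FIT.c0), rel=1e-12)
        assert MEASURED_FIT.f_parallel > MEASURED_FIT.f_series

    def test_hermitian_symmetry(self):
        # real time-domain response: Z(-w) = conj(Z(w))
        f = np.linspace(5e6, 9e6, 50)
        z = circuit_impedance(MEASURED_FIT, f)

        def z_at(w):  # impedance evaluated directly at signed angular frequency
            p = MEASURED_FIT
            z_mech = p.rm + 1j * w * p.lm + 1 / (1j * w * p.cm)
            z_c0 = 1 / (1j * w * p.c0)
            return z_c0 * z_mech / (z_c0 + z_mech) + p.rs

        z_neg = z_at(-2 * np.pi * f)
        np.testing.assert_allclose(z_neg, z.conj(), rtol=1e-12)


class TestFit:
    def test_noiseless_recovery_within_0p1_percent(self):
        spec = synthetic_spectrum(MEASURED_FIT, 4e6, 10e6, n=400)
        fit = fit_circuit(spec)
        rec, true = fit.params.as_array(), MEASURED_FIT.as_array()
        assert np.all(np.abs(rec[:5] - true[:5]) / true[:5] < 1e-3)

    def test_noisy_recovery_within_5_percent_over_20_replicates(self):
        true = MEASURED_FIT.as_array()
        for seed in range(20):
            spec = synthetic_spectrum(MEASURED_FIT, 4e6, 10e6, n=400,
                                      noise=0.01, seed=seed)
            rec = fit_circuit(spec).params.as_array()
            assert np.all(np.abs(rec[:4] - true[:4]) / true[:4] < 0.05)

    def test_pure_capacitor_has_no_resonance(self):
        f = np.linspace(4e6, 10e6, 200)
        spec = ImpedanceSpectrum(f, 1 / (1j * 2 * np.pi * f * 131e-12))
        with pytest.raises(ValueError, match="resonance"):
            fit_circuit(spec)

    def test_csv_roundtrip(self, tmp_path):
        spec = synthetic_spectrum(MEASURED_FIT, 4e6, 10e6, n=50, bias=47.0)
        spec.to_csv(tmp_path / "z.csv")
        back = ImpedanceSpectrum.from_csv(tmp_path / "z.csv")
        np.testing.assert_allclose(back.z, spec.z)
        assert back.bias == 47.0

    def test_missing_columns_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text("frequency_hz,re_ohm\n1e6,5\n")
        with pytest.raises(ValueError, match="im_ohm"):
            ImpedanceSpectrum.from_csv(tmp_path / "bad.csv")


class TestImpulseSpectrum:
    def _gaussian_burst(self, dt=5e-9, n=4096, f0=2e6, sigma_t=0.4e-6):
        t = np.arange(n) * dt
        return np.exp(-(t - t.mean()) ** 2 / (2 * sigma_t ** 2)) * \
            np.sin(2 * np.pi * f0 * t)

    def test_gaussian_burst_center_and_bandwidth(self):
        dt, sigma_t = 5e-9, 0.4e-6
        fc, bw = impulse_spectrum(self._gaussian_burst(dt=dt, sigma_t=sigma_t), dt)
        sigma_f = 1 / (2 * np.pi * sigma_t)
        bw_true = 2 * sigma_f * np.sqrt(2 * np.log(10 ** (6 / 20)))
        assert fc == pytest.approx(2e6, rel=0.01)
        assert bw == pytest.approx(bw_true, rel=0.03)

    def test_time_shift_invariance(self):
        dt = 5e-9
        tr = self._gaussian_burst(dt=dt)
        fc1, bw1 = impulse_spectrum(tr, dt)
        fc2, bw2 = impulse_spectrum(np.roll(tr, 500), dt)
        assert fc2 == pytest.approx(fc1, rel=1e-3)
        assert bw2 == pytest.approx(bw1, rel=0.02)

    def test_long_tone_bandwidth_hits_resolution_floor(self):
        dt = 5e-9
        t = np.arange(8192) * dt
        _, bw = impulse_spectrum(np.sin(2 * np.pi * 2e6 * t), dt)
        resolution = 1 / (8192 * dt)
        assert bw < 3 * resolution


class TestArealMass:
    def test_silicon_substrate_reference(self):
        assert areal_mass(725e-6, 2330.0) == pytest.approx(0.169, abs=5e-4)

    def test_zero_thickness_is_zero(self):
        assert areal_mass(0.0, 2330.0) == 0.0

    def test_linear_in_density(self):
        assert areal_mass(725e-6, 4660.0) == pytest.approx(
            2 * areal_mass(725e-6, 2330.0))
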