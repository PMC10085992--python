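"""k-space pseudospectral solver: analytic oracles and invariants."""

import numpy as np
import pytest

from holofocus.grid_medium import MaterialPreset, SimGrid, homogeneous_medium
from holofocus.wave_sim import (SensorRecord, SourceSpec, compute_dt,
                                run_simulation, steady_state_phase, tone_burst)

F0 = 1e6
C = 1482.0
LAM = C / F0
DX = LAM / 8
WATER0 = MaterialPreset("w", 1000.0, C, 0.0)


def wrap_deg(x):
    return np.degrees(np.angle(np.exp(1j * np.asarray(x))))


class TestComputeDt:
    def test_base_step_is_cfl_dx_over_cmax(self):
        assert compute_dt(0.3, 1e-4, 3000.0) == pytest.approx(1e-8)

    def test_step_snapped_to_integer_divisor_of_drive_period(self):
        dt = compute_dt(0.3, 1e-4, 3000.0, f0=2e6)
        assert dt == pytest.approx(1e-8)
        assert (1 / 2e6) / dt == pytest.approx(50)

    def test_cfl_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_dt(1.5, 1e-4, 3000.0)


class TestSteadyStatePhase:
    def _record(self, f0, dt, signal):
        return SensorRecord([(0,)], dt, signal[:, None])

    def test_pure_tone_phase_recovered(self):
        dt = compute_dt(0.3, DX, C, F0)
        t = np.arange(4000) * dt
        rec = self._record(F0, dt, 2.5 * np.sin(2 * np.pi * F0 * t + 0.7))
        phase, amp = steady_state_phase(rec, F0)
        assert phase[0] == pytest.approx(0.7, abs=1e-6)
        assert amp[0] == pytest.approx(2.5, rel=1e-6)

    def test_third_harmonic_is_orthogonal(self):
        dt = compute_dt(0.3, DX, C, F0)
        t = np.arange(4000) * dt
        sig = np.sin(2 * np.pi * F0 * t + 0.7) + 0.8 * np.sin(2 * np.pi * 3 * F0 * t + 1.1)
        phase, _ = steady_state_phase(self._record(F0, dt, sig), F0)
        assert phase[0] == pytest.approx(0.7, abs=1e-6)

    def test_quarter_period_shift_is_half_pi(self):
        dt = compute_dt(0.3, DX, C, F0)
        t = np.arange(4000) * dt
        sig = np.stack([np.sin(2 * np.pi * F0 * t),
                        np.sin(2 * np.pi * F0 * (t + 0.25 / F0))], axis=1)
        rec = SensorRecord([(0,), (1,)], dt, sig)
        phase, _ = steady_state_phase(rec, F0)
        assert wrap_deg(phase[1] - phase[0]) == pytest.approx(90.0, abs=1e-6)

    def test_short_trace_rejected(self):
        dt = compute_dt(0.3, DX, C, F0)
        t = np.arange(100) * dt
        with pytest.raises(ValueError, match="periods"):
            steady_state_phase(self._record(F0, dt, np.sin(2 * np.pi * F0 * t)), F0)


class TestRunSimulation:
    def test_zero_amplitude_source_gives_zero_record(self):
        grid = SimGrid(64, dx=DX)
        med = homogeneous_medium(grid, WATER0)
        rec = run_simulation(med, SourceSpec([(30,)], np.zeros(200)), [(50,)],
                             20 / F0, f0=F0)
        assert np.all(rec.pressures == 0)

    def test_sensor_outside_grid_rejected(self):
        grid = SimGrid(64, dx=DX)
        med = homogeneous_medium(grid, WATER0)
        with pytest.raises(ValueError, match="outside"):
            run_simulation(med, SourceSpec([(30,)], np.zeros(10)), [(70,)],
                           20 / F0, f0=F0)

    def test_free_field_phase_matches_analytic_within_2_degrees(self):
        # 1D plane-wave free field at dx = lambda/10, CFL 0.3
        dx = LAM / 10
        grid = SimGrid(300, dx=dx)
        med = homogeneous_medium(grid, WATER0)
        dt = compute_dt(0.3, dx, C, F0)
        d = 100
        travel = d * dx / C
        duration = travel + 30 / F0
        wave = tone_burst(F0, dt, duration * F0)
        rec = run_simulation(med, SourceSpec([(30,)], wave), [(30 + d,)],
                             duration, f0=F0)
        phase, _ = steady_state_phase(rec, F0)
        expected_lag = -2 * np.pi * F0 * d * dx / C
        assert abs(wrap_deg(phase[0] - expected_lag)) < 2.0

    def test_power_law_attenuation_matches_analytic_within_3_percent(self):
        # gamma = 1.5 absorbing medium, 1D plane wave, dB-convention law
        gamma, a0 = 1.5, 2.0  # dB MHz^-1.5 cm^-1, muscle-like
        grid = SimGrid(300, dx=LAM / 10)
        med = homogeneous_medium(grid, MaterialPreset("abs", 1000.0, C, a0, gamma))
        dt = compute_dt(0.3, grid.dx, C, F0)
        d1, d2 = 60, 160
        duration = 200 * grid.dx / C + 30 / F0
        wave = tone_burst(F0, dt, duration * F0)
        rec = run_simulation(med, SourceSpec([(30,)], wave),
                             [(30 + d1,), (30 + d2,)], duration, f0=F0)
        _, amp = steady_state_phase(rec, F0)
        x_cm = (d2 - d1) * grid.dx * 100
        expected = 10 ** (-a0 * (F0 / 1e6) ** gamma * x_cm / 20)
        assert amp[1] / amp[0] == pytest.approx(expected, rel=0.03)

    def test_lossless_run_conserves_energy_within_1_percent(self):
        grid = SimGrid(400, dx=DX)
        med = homogeneous_medium(grid, WATER0)
        dt = compute_dt(0.3, DX, C, F0)
        wave = tone_burst(F0, dt, 8)  # burst, then free propagation
        rec = run_simulation(med, SourceSpec([(200,)], wave), None, 24 / F0,
                             f0=F0, record_field=True)
        spp = int(round(1 / (F0 * dt)))
        e = [(rec.field_frames[k * spp] ** 2).sum() for k in (10, 22)]
        assert e[1] / e[0] == pytest.approx(1.0, rel=0.01)

    def test_reciprocity_in_heterogeneous_lossless_medium(self):
        grid = SimGrid(400, dx=DX)
        med = homogeneous_medium(grid, WATER0)
        med.c0[180:220] = 2400.0
        med.rho0[180:220] = 1800.0
        a, b = (100,), (320,)
        dt = compute_dt(0.3, DX, 2400.0, F0)
        duration = 400 * DX / C + 30 / F0
        wave = tone_burst(F0, dt, duration * F0)
        p_ab, _ = steady_state_phase(
            run_simulation(med, SourceSpec([a], wave), [b], duration, f0=F0, dt=dt), F0)
        p_ba, _ = steady_state_phase(
            run_simulation(med, SourceSpec([b], wave), [a], duration, f0=F0, dt=dt), F0)
        assert abs(wrap_deg(p_ab[0] - p_ba[0])) < 2.0

    def test_whole_scene_translation_leaves_output_unchanged(self):
        grid = SimGrid(128, 128, dx=DX)

        def run(shift):
            sx, sy = shift
            med = homogeneous_medium(grid, WATER0)
            med.c0[60 + sx:70 + sx, 60 + sy:70 + sy] = 1600.0
            med.rho0[60 + sx:70 + sx, 60 + sy:70 + sy] = 1100.0
            dt = compute_dt(0.3, DX, 1600.0, F0)
            duration = 128 * DX * 1.4 / C + 25 / F0
            wave = tone_burst(F0, dt, duration * F0)
            rec = run_simulation(med, SourceSpec([(40 + sx, 44 + sy)], wave),
                                 [(88 + sx, 78 + sy)], duration, f0=F0, dt=dt,
                                 pml_width=20)
            return steady_state_phase(rec, F0)

        p0, a0 = run((0, 0))
        p1, a1 = run((3, 2))
        assert abs(wrap_deg(p1[0] - p0[0])) < 0.5
        assert a1[0] == pytest.approx(a0[0], rel=0.01)

    def test_phase_error_decreases_from_quarter_to_twelfth_wavelength(self):
        # transmission through a contrasting slab: the k-space correction is
        # exact only at c_ref, so the water-side dispersion error shrinks
        # with dx (and the proportional dt)
        errs = []
        for div in (4, 8, 12):
            dx = LAM / div
            n = 50 * div  # 50 wavelengths of domain
            grid = SimGrid(n, dx=dx)
            med = homogeneous_medium(grid, WATER0)
            s0, w_sl = 25 * div, 3 * div  # slab: 3 wavelengths at 25 lambda
            med.c0[s0:s0 + w_sl] = 1600.0
            med.rho0[s0:s0 + w_sl] = 1100.0
            dt = compute_dt(0.3, dx, 1600.0, F0)
            src, sens = 10 * div, 37 * div
            duration = n * dx / C + 30 / F0
            wave = tone_burst(F0, dt, duration * F0)
            base = homogeneous_medium(grid, WATER0)
            pb, _ = steady_state_phase(run_simulation(
                base, SourceSpec([(src,)], wave), [(sens,)], duration,
                f0=F0, dt=dt, pml_width=20), F0)
            pa, _ = steady_state_phase(run_simulation(
                med, SourceSpec([(src,)], wave), [(sens,)], duration,
                f0=F0, dt=dt, pml_width=20), F0)
            pred = (2 * np.pi * F0 / C - 2 * np.pi * F0 / 1600.0) * w_sl * dx
            errs.append(abs(wrap_deg((pa[0] - pb[0]) - pred)))
        assert errs[2] < errs[1] < errs[0]
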