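"""Time-reversal recording, conjugation, steering, and refocusing."""

import numpy as np
import pytest

from holofocus import (TargetSet, conjugate_phase, record_time_reversal,
                       steer_map, verify_refocus)
from holofocus.beam_metrics import focal_position, fwhm, pressure_squared_profile
from holofocus.grid_medium import MaterialPreset, SimGrid, homogeneous_medium
from holofocus.holography import (PhaseMap, RecordingPlane, fresnel_phase,
                                  wrap_phase)

F0 = 1e6
C_WATER = 1482.0
LAM = C_WATER / F0
WATER_LOSSLESS = MaterialPreset("water_lossless", 1000.0, C_WATER, 0.0)


def wrap_deg(x):
    return np.degrees(np.angle(np.exp(1j * np.asarray(x))))


class TestConjugate:
    def test_negates_phase(self):
        pm = PhaseMap(np.array([0.3]), 1e-4)
        assert conjugate_phase(pm).phase[0] == pytest.approx(-0.3)

    def test_wrap_boundary_pi_maps_to_pi(self):
        pm = PhaseMap(np.array([np.pi]), 1e-4)
        assert conjugate_phase(pm).phase[0] == pytest.approx(np.pi)

    def test_involution(self):
        rng = np.random.default_rng(0)
        pm = PhaseMap(wrap_phase(rng.uniform(-np.pi, np.pi, (8, 8))), 1e-4)
        np.testing.assert_allclose(
            conjugate_phase(conjugate_phase(pm)).phase, pm.phase)


class TestTargetSetAndPlane:
    def test_too_few_cycles_rejected(self, free_water_run):
        r = free_water_run
        with pytest.raises(ValueError, match="20"):
            record_time_reversal(r["medium"], TargetSet((r["target"],), F0),
                                 r["plane"], n_cycles=10)

    def test_target_on_plane_rejected(self, free_water_run):
        r = free_water_run
        bad = (80 * r["dx"], 140 * r["dx"])  # lies on the recording plane
        with pytest.raises(ValueError, match="plane"):
            record_time_reversal(r["medium"], TargetSet((bad,), F0), r["plane"])

    def test_non_positive_weights_rejected(self):
        with pytest.raises(ValueError):
            TargetSet(((0.0, 0.0),), F0, weights=(0.0,))


class TestRecording:
    def test_recorded_phase_matches_spherical_wavefront(self, free_water_run):
        r = free_water_run
        dx = r["dx"]
        xs = np.arange(160)
        radius = np.hypot((xs - 80) * dx, (140 - 50) * dx)
        k = 2 * np.pi * F0 / C_WATER
        pred = -k * (radius - radius[80])
        rel = r["pmap"].phase - r["pmap"].phase[80]
        err = wrap_deg(rel - pred)[12:-12]  # active aperture, clear of the PML
        assert np.abs(err).max() < 5.0

    def test_symmetric_targets_give_mirror_symmetric_map(self):
        dx = LAM / 8
        grid = SimGrid(128, 128, dx=dx)
        med = homogeneous_medium(grid, WATER_LOSSLESS)
        # two targets mirror-symmetric about the plane's center column
        t1 = (48 * dx, 40 * dx)
        t2 = ((127 - 48) * dx, 40 * dx)
        pm = record_time_reversal(med, TargetSet((t1, t2), F0),
                                  RecordingPlane(1, 110))
        err = wrap_deg(pm.phase - pm.phase[::-1])[14:-14]
        # phase is ill-conditioned at interference nulls, and the half-voxel
        # stagger of the scheme is not exactly reflection-symmetric: compare
        # pixels carrying meaningful amplitude, at discretization tolerance
        amp = pm.amplitude[14:-14]
        strong = amp > 0.3 * amp.max()
        assert np.abs(err[strong]).max() < 5.0

    def test_joint_recording_equals_complex_sum_of_singles(self):
        # linearity of the recording path: < 3 degrees RMS
        dx = LAM / 8
        grid = SimGrid(128, 128, dx=dx)
        med = homogeneous_medium(grid, WATER_LOSSLESS)
        plane = RecordingPlane(1, 110)
        t1, t2 = (50 * dx, 40 * dx), (84 * dx, 46 * dx)
        pm1 = record_time_reversal(med, TargetSet((t1,), F0), plane)
        pm2 = record_time_reversal(med, TargetSet((t2,), F0), plane)
        pm12 = record_time_reversal(med, TargetSet((t1, t2), F0), plane)
        sum_phase = np.angle(pm1.complex_field + pm2.complex_field)
        err = wrap_deg(sum_phase - pm12.phase)[12:-12]
        assert np.sqrt((err ** 2).mean()) < 3.0


class TestFresnel:
    def test_on_axis_pixel_has_zero_phase(self, free_water_run):
        r = free_water_run
        fm = fresnel_phase(r["grid"], r["plane"], r["target"], F0, C_WATER)
        assert fm.phase[80] == pytest.approx(0.0, abs=1e-9)

    def test_half_wavelength_path_difference_gives_pi(self):
        grid = SimGrid(101, 101, dx=1e-4)
        plane = RecordingPlane(1, 100)
        z = 90 * 1e-4
        # lateral offset with path difference exactly lambda/2
        lat = np.sqrt((z + LAM / 2) ** 2 - z ** 2)
        focus = (50 * 1e-4, 10 * 1e-4)
        fm = fresnel_phase(grid, plane, focus, F0, C_WATER)
        i = int(round((focus[0] + lat) / 1e-4))
        expect = 2 * np.pi * F0 / C_WATER * (np.hypot(z, (i * 1e-4 - focus[0])) - z)
        assert abs(wrap_deg(fm.phase[i] - expect)) < 1e-6
        assert abs(expect - np.pi) < 0.1  # the chosen pixel sits near pi

    def test_equals_time_reversal_in_free_water(self, free_water_run):
        r = free_water_run
        fm = fresnel_phase(r["grid"], r["plane"], r["target"], F0, C_WATER)
        d = wrap_deg(r["conj"].phase - fm.phase)[12:-12]
        d = d - d.mean()  # common phase offset is physically irrelevant
        assert np.sqrt((d ** 2).mean()) < 10.0


class TestSteering:
    def test_zero_offset_is_identity(self):
        pm = PhaseMap(np.linspace(-3, 3, 32), 1e-4)
        np.testing.assert_allclose(steer_map(pm, 0.0).phase, pm.phase,
                                   atol=1e-12)

    def test_steer_and_unsteer_restores_interior(self):
        pm = PhaseMap(np.linspace(-3, 3, 32), 1e-4)
        back = steer_map(steer_map(pm, 2e-4), -2e-4)
        np.testing.assert_allclose(back.phase[2:-2], pm.phase[2:-2])

    def test_non_integer_offset_rejected(self):
        pm = PhaseMap(np.zeros(16), 1e-4)
        with pytest.raises(ValueError, match="pitch"):
            steer_map(pm, 1.5e-4)

    def test_steering_moves_focus_by_the_offset(self, free_water_run):
        r = free_water_run
        off_pix = 8
        steered = steer_map(r["conj"], off_pix * r["dx"], axis=0)
        field = verify_refocus(r["medium"], steered, r["plane"])
        p0 = focal_position(r["field"])
        p1 = focal_position(field)
        prof, dx = pressure_squared_profile(r["field"], 0, p0)
        width = fwhm(prof, dx)
        moved = (p1[0] - p0[0]) * r["dx"]
        assert abs(moved - off_pix * r["dx"]) <= width / 2


class TestRefocus:
    def test_free_water_peak_within_half_wavelength(self, free_water_run):
        r = free_water_run
        peak = focal_position(r["field"])
        tidx = r["grid"].index_of(r["target"])
        dist = np.hypot(peak[0] - tidx[0], peak[1] - tidx[1]) * r["dx"]
        assert dist <= LAM / 2

    def test_all_zero_map_gives_no_off_axis_focus(self, free_water_run):
        r = free_water_run
        flat = PhaseMap(np.zeros_like(r["conj"].phase), r["dx"], None, F0)
        field = verify_refocus(r["medium"], flat, r["plane"])
        # plane-wave-like: the lateral profile mid-depth has no dominant peak
        prof, _ = pressure_squared_profile(field, 0, (0, 70))
        interior = prof[20:-20]
        assert interior.max() < 4 * np.median(interior)

    def test_mismatched_map_shape_rejected(self, free_water_run):
        r = free_water_run
        bad = PhaseMap(np.zeros(10), r["dx"], None, F0)
        with pytest.raises(ValueError, match="shape"):
            verify_refocus(r["medium"], bad, r["plane"])
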