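"""Shared fixtures.

The expensive 2D holography simulations (time-reversal recording plus
refocus verification through the synthetic skull cap) are computed once per
session and shared between the module tests and the acceptance suite.
"""

import numpy as np
import pytest

from holofocus import (TargetSet, conjugate_phase, record_time_reversal,
                       verify_refocus)
from holofocus.grid_medium import MaterialPreset, SimGrid, homogeneous_medium
from holofocus.holography import RecordingPlane, fresnel_phase
from holofocus.pipeline import MM, build_medium, demo_config, evaluation_region, make_plane

F0 = 1e6
C_WATER = 1482.0
LAM = C_WATER / F0
WATER_LOSSLESS = MaterialPreset("water_lossless", 1000.0, C_WATER, 0.0)


@pytest.fixture(scope="session")
def free_water_run():
    """Single-target recording and refocus in free water (160^2, lossless)."""
    dx = LAM / 8
    grid = SimGrid(160, 160, dx=dx)
    med = homogeneous_medium(grid, WATER_LOSSLESS)
    target = (80 * dx, 50 * dx)
    plane = RecordingPlane(1, 140)
    pmap = record_time_reversal(med, TargetSet((target,), F0), plane)
    conj = conjugate_phase(pmap)
    field = verify_refocus(med, conj, plane)
    return {
        "grid": grid, "medium": med, "target": target, "plane": plane,
        "pmap": pmap, "conj": conj, "field": field, "dx": dx,
    }


@pytest.fixture(scope="session")
def multifocus_run():
    """Dual-target recording through the moderate skull cap (256^2, 1 MHz)."""
    cfg = demo_config(two_targets=True)
    med = build_medium(cfg)
    targets = TargetSet(tuple(tuple(np.atleast_1d(t) * MM)
                              for t in cfg["targets_mm"]), F0)
    plane = make_plane(cfg, med)
    region = evaluation_region(cfg, med)
    pmap = record_time_reversal(med, targets, plane)
    field = verify_refocus(med, conjugate_phase(pmap), plane, region=region)
    target_idx = [med.grid.index_of(p) for p in targets.points]
    return {"cfg": cfg, "medium": med, "targets": targets, "plane": plane,
            "region": region, "field": field, "target_idx": target_idx}


@pytest.fixture(scope="session")
def strong_aberrator_run():
    """Corrected vs Fresnel refocus through the strong aberrator (256^2)."""
    cfg = demo_config(two_targets=False, aberration="strong")
    med = build_medium(cfg)
    target = tuple(np.atleast_1d(cfg["targets_mm"][0]) * MM)
    tidx = med.grid.index_of(target)
    plane = make_plane(cfg, med)
    region = evaluation_region(cfg, med)
    pmap = record_time_reversal(med, TargetSet((target,), F0), plane)
    corrected = verify_refocus(med, conjugate_phase(pmap), plane, region=region)
    fresnel = verify_refocus(
        med, fresnel_phase(med.grid, plane, target, F0, C_WATER),
        plane, region=region)
    return {"cfg": cfg, "medium": med, "target_idx": tidx, "plane": plane,
            "corrected": corrected, "fresnel": fresnel}
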