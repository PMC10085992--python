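"""End-to-end workflow: medium -> record -> conjugate -> lens -> verify -> metrics.

A single structured YAML/JSON config drives each run; outputs (phase map,
lens STL, verification field, metrics JSON) land in a run directory together
with a provenance log recording the config hash, package version, and every
resolved default, so that two runs from the same config and seed are
numerically identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .beam_metrics import FieldVolume, count_foci, focal_deviation
from .grid_medium import (MaterialPreset, MediumMap, PRESETS, SimGrid,
                          homogeneous_medium, make_grid, synthetic_skull_shell)
from .holography import (PhaseMap, RecordingPlane, TargetSet, conjugate_phase,
                         record_time_reversal, verify_refocus)
from .lens_design import (LensMaterials, phase_to_thickness, quantize_phase,
                          export_stl)

MM = 1e-3

_REQUIRED_FIELDS = ("frequency_hz", "grid", "targets_mm")

_DEFAULTS = {
    "cfl": 0.3,                 # time-step Courant number
    "n_cycles": 20,             # steady-state drive cycles (floor)
    "pml_width": 10,            # absorbing boundary, voxels
    "phase_step": 2 * np.pi / 10,
    "seed": 0,
}


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as f:
        cfg = yaml.safe_load(f) if path.suffix in (".yaml", ".yml") \
            else json.load(f)
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    for field_name in _REQUIRED_FIELDS:
        if field_name not in cfg:
            raise ValueError(f"config missing required field: {field_name!r}")
    grid = cfg["grid"]
    for sub in ("extent_mm", "dx_mm"):
        if sub not in grid:
            raise ValueError(f"config missing required field: grid.{sub!r}")
    out = dict(_DEFAULTS)
    out.update(cfg)
    return out


def _material(spec) -> MaterialPreset:
    if isinstance(spec, str):
        return PRESETS[spec]
    return MaterialPreset(**spec)


def build_medium(cfg: dict) -> MediumMap:
    gspec = cfg["grid"]
    medium_spec = cfg.get("medium", {"kind": "water"})
    background = _material(medium_spec.get("background", "water"))
    grid = make_grid([e * MM for e in np.atleast_1d(gspec["extent_mm"])],
                     gspec["dx_mm"] * MM, cfg["frequency_hz"], background.c0)
    kind = medium_spec.get("kind", "water")
    if kind in ("water", "homogeneous"):
        return homogeneous_medium(grid, background)
    if kind == "skull_shell":
        shell = medium_spec["shell"]
        return synthetic_skull_shell(
            grid,
            center=[c * MM for c in shell["center_mm"]],
            semi_axes=[s * MM for s in shell["semi_axes_mm"]],
            thickness=shell["thickness_mm"] * MM,
            inner=_material(medium_spec.get("inner", "water")),
            shell_mat=_material(medium_spec.get("shell_material", "skull_bone")),
            outer=_material(medium_spec.get("outer", "water")),
            cap_axis=shell.get("cap_axis"),
            cap_sign=shell.get("cap_sign", 1),
            thickness_variation=shell.get("thickness_variation_mm", 0.0) * MM,
            n_lobes=shell.get("n_lobes", 5),
            harmonics=[(m, a * MM, ph)
                       for m, a, ph in shell.get("harmonics_mm", [])] or None,
        )
    raise ValueError(f"unknown medium kind: {kind!r}")


@dataclass
class PipelineResult:
    run_dir: Path
    metrics: dict
    phase_map: PhaseMap
    field: FieldVolume


def run_pipeline(cfg: dict, run_dir) -> PipelineResult:
    """Execute the full design-and-verify loop described by ``cfg``.

    Stages: build medium, time-reversal record from the targets, conjugate
    and quantize the phase, synthesize the lens thickness (when lens
    materials are configured), re-emit to verify refocusing, and score the
    foci.  Any stage failure raises with the stage name; outputs written so
    far are retained in ``run_dir``.
    """
    cfg = validate_config(cfg)
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stage = "config"
    try:
        provenance = {
            "config": _jsonable(cfg),
            "config_sha256": hashlib.sha256(
                json.dumps(_jsonable(cfg), sort_keys=True).encode()).hexdigest(),
            "package_version": __version__,
            "resolved_defaults": {k: _jsonable(v) for k, v in _DEFAULTS.items()
                                  if k not in cfg},
        }
        stage = "medium"
        medium = build_medium(cfg)
        medium.save(run_dir / "medium.h5")

        stage = "record"
        f0 = cfg["frequency_hz"]
        targets = TargetSet(tuple(tuple(np.atleast_1d(t) * MM)
                                  for t in cfg["targets_mm"]), f0,
                            tuple(cfg.get("target_weights", [])) or None)
        plane = make_plane(cfg, medium)
        pmap = record_time_reversal(medium, targets, plane,
                                    n_cycles=cfg["n_cycles"], cfl=cfg["cfl"])
        pmap.save(run_dir / "phasemap.h5")

        stage = "conjugate"
        conj = conjugate_phase(pmap)
        conj_q = quantize_phase(conj, cfg["phase_step"])

        stage = "lens"
        if "lens" in cfg:
            lens_cfg = cfg["lens"]
            mats = LensMaterials.with_full_wrap(lens_cfg["c_lens"],
                                                lens_cfg["c_interface"], f0)
            tmap = phase_to_thickness(conj_q, mats, f0)
            tmap.save(run_dir / "thickness.h5")
            export_stl(tmap, run_dir / "lens.stl")

        stage = "verify"
        region = evaluation_region(cfg, medium)
        field = verify_refocus(medium, conj_q, plane,
                               n_cycles=cfg["n_cycles"], cfl=cfg["cfl"],
                               region=region)
        field.save(run_dir / "field.h5")

        stage = "metrics"
        target_idx = [medium.grid.index_of(p) for p in targets.points]
        n_foci, foci = count_foci(field, threshold_db=-6.0)
        per_target = []
        for idx in target_idx:
            dev, widths, within = focal_deviation(field, idx)
            per_target.append({
                "target_index": list(idx),
                "deviation_mm": (dev / MM).tolist(),
                "fwhm_mm": (widths / MM).tolist(),
                "within_fwhm": bool(within),
            })
        metrics = {
            "n_foci_minus6db": n_foci,
            "foci_indices": [list(fx) for fx in foci],
            "targets": per_target,
            "peak_amplitude": float(field.amplitude.max()),
        }
        with open(run_dir / "metrics.json", "w") as f:
            json.dump(metrics, f, indent=2, sort_keys=True)
        with open(run_dir / "provenance.json", "w") as f:
            json.dump(provenance, f, indent=2, sort_keys=True)
        return PipelineResult(run_dir, metrics, pmap, field)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def make_plane(cfg: dict, medium: MediumMap) -> RecordingPlane:
    aperture = cfg.get("aperture")
    if aperture is not None:
        aperture = tuple(tuple(b) for b in aperture)
    return RecordingPlane(cfg.get("plane_axis", 1),
                          cfg.get("plane_index", medium.grid.shape[1] - 15),
                          aperture)


def evaluation_region(cfg: dict, medium: MediumMap):
    """Voxel bounds of the focal evaluation (scan) volume.

    Explicit ``eval_region`` (voxel ``[lo, hi]`` per axis) wins.  Otherwise
    the region emulates a hydrophone raster referenced to the targets: the
    target bounding box expanded by ``scan_margin_lam`` wavelengths per axis
    (default 2), clipped to the skull-cavity inscribed box for shell media
    and to the grid interior (outside the absorbing boundary and the source
    plane) otherwise.
    """
    if "eval_region" in cfg:
        return [tuple(b) for b in cfg["eval_region"]]
    grid = medium.grid
    medium_spec = cfg.get("medium", {})
    margin = cfg.get("pml_width", 10) + 5
    lam = medium.c_min / cfg["frequency_hz"]
    scan = int(np.ceil(cfg.get("scan_margin_lam", 2.0) * lam / grid.dx))
    t_idx = np.array([grid.index_of(np.atleast_1d(t) * MM)
                      for t in cfg["targets_mm"]])
    plane_axis = cfg.get("plane_axis", 1)
    plane_index = cfg.get("plane_index", grid.shape[1] - 15)

    region = []
    for a in range(3):
        if grid.shape[a] == 1:
            region.append(None)
            continue
        lo = int(t_idx[:, a].min()) - scan
        hi = int(t_idx[:, a].max()) + scan + 1
        # clip to the cavity (shell media) or to the interior
        if medium_spec.get("kind") == "skull_shell":
            shell = medium_spec["shell"]
            center = np.atleast_1d(shell["center_mm"]) * MM
            inner = (np.atleast_1d(shell["semi_axes_mm"])
                     - shell["thickness_mm"]) * MM / np.sqrt(2)
            lo = max(lo, int(np.ceil((center[a] - inner[a]) / grid.dx)))
            hi = min(hi, int(np.floor((center[a] + inner[a]) / grid.dx)) + 1)
        lo = max(lo, margin)
        hi = min(hi, grid.shape[a] - margin)
        if a == plane_axis:
            if plane_index > grid.shape[a] // 2:
                hi = min(hi, plane_index - 8)
            else:
                lo = max(lo, plane_index + 8)
        region.append((lo, hi))
    return region


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# fixture generation


def make_fixtures(kind: str, out_dir, seed: int = 0) -> list[Path]:
    """Write the synthetic inputs used by the test suite and demos."""
    from .behavior import synthetic_trajectory
    from .cmut_model import CircuitParams, synthetic_spectrum

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if kind == "impedance":
        # representative measured-fit values: C0 131 pF, Rm 137 ohm,
        # Lm 0.36 mH, Cm 1.45 pF, Rs 8.53 ohm, Cs absent
        params = CircuitParams(131e-12, 137.0, 0.36e-3, 1.45e-12, 8.53, 0.0)
        spec = synthetic_spectrum(params, 4e6, 10e6, n=400, noise=0.01,
                                  seed=seed, bias=47.0)
        path = out_dir / "impedance.csv"
        spec.to_csv(path)
        written.append(path)
    elif kind == "trajectory":
        traj = synthetic_trajectory(1800, 10.0, (30.0, 30.0), seed=seed)
        import pandas as pd
        path = out_dir / "trajectory.csv"
        pd.DataFrame({"frame": np.arange(traj.n_frames),
                      "x": traj.x, "y": traj.y}).to_csv(path, index=False)
        written.append(path)
    elif kind == "skull_shell":
        cfg = demo_config(two_targets=False)
        medium = build_medium(cfg)
        path = out_dir / "skull_shell.h5"
        medium.save(path)
        written.append(path)
    elif kind == "dual_focus_demo":
        cfg = demo_config(two_targets=True)
        path = out_dir / "dual_focus.yaml"
        with open(path, "w") as f:
            yaml.safe_dump(_jsonable(cfg), f)
        medium = build_medium(cfg)
        mpath = out_dir / "dual_focus_medium.h5"
        medium.save(mpath)
        written.extend([path, mpath])
    else:
        raise ValueError(f"unknown fixture kind: {kind!r}")
    return written


def demo_config(two_targets: bool = True, f0: float = 1e6,
                aberration: str = "moderate", grid_n: int = 256) -> dict:
    """Desk-scale 2D demo: half-skull cap aberrator, transducer plane above,
    target(s) in the cavity below.

    ``aberration`` selects the wall-thickness screen: ``"moderate"`` (the
    standard demo; phase conjugation recovers diffraction-limited single and
    dual foci) or ``"strong"`` (a deliberately aberrating configuration with
    multi-scale thickness harmonics, used to quantify the correction gain of
    the conjugated lens over an uncompensated Fresnel lens).
    """
    lam_mm = 1482.0 / f0 * 1e3
    dx_mm = lam_mm / 8
    extent = grid_n * dx_mm
    cx = extent / 2
    scale = grid_n / 256.0
    targets = [[cx - 2.2 * lam_mm, extent * 0.32],
               [cx + 2.2 * lam_mm, extent * 0.32]] if two_targets \
        else [[cx, extent * 0.32]]
    return {
        "frequency_hz": f0,
        "grid": {"extent_mm": [extent, extent], "dx_mm": dx_mm},
        "medium": {
            "kind": "skull_shell",
            "shell": {
                # the cap must span the whole transducer aperture: no clear
                # water path may bypass the aberrator
                "center_mm": [cx - 1.5, extent * 0.40],
                "semi_axes_mm": [extent * 0.44, extent * 0.22],
                # azimuthal wall-thickness screen: the wedge-like m = 1 term
                # steers an uncompensated beam off target, higher terms
                # defocus and spread it; all are smooth (refractive), which a
                # phase-conjugating lens corrects cleanly
                **({"thickness_mm": 2.6,
                    "harmonics_mm": [[1, 0.9, 0.0], [4, 1.0, 1.0],
                                     [7, 0.6, 2.4]]}
                   if aberration == "strong" else
                   {"thickness_mm": 2.1,
                    "harmonics_mm": [[1, 0.9, 0.0], [3, 0.7, 0.8]]}),
                # dorsal half-skull cap facing the transducer plane
                "cap_axis": 1,
                "cap_sign": 1,
            },
        },
        "targets_mm": targets,
        "plane_axis": 1,
        "plane_index": grid_n - 20,
        # finite transducer aperture inside the aberrator's shadow
        "aperture": [[int(28 * scale), int(228 * scale)]],
        "n_cycles": 20,
        "cfl": 0.3,
    }
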