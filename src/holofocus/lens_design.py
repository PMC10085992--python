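"""Printable acoustic lens synthesis from a conjugated phase map.

A passive lens imposes a position-dependent phase delay by varying the local
thickness of the lens material (medium A) against the interfacing medium B.
For thin lenses transmission is modeled as one-dimensional propagation with a
pure phase delay:

    delta_phi(x, y) = (k_B - k_A) (T0 - T(x, y))

so each pixel's thickness follows from the wrapped target phase.  The
thickness map is quantized to the printer's phase resolution and exported as
a watertight STL heightfield in millimeters.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .holography import PhaseMap, wrap_phase

MIN_PIXEL_AREA = 0.01e-6  # m^2; ~0.01 mm^2 printable pixel floor
DEFAULT_PHASE_STEP = 2 * np.pi / 10  # printer phase modulation unit


def wavenumber(c: float, f0: float) -> float:
    """k = 2 pi f0 / c (rad/m)."""
    if c <= 0 or f0 <= 0:
        raise ValueError("sound speed and frequency must be positive")
    return 2 * np.pi * f0 / c


@dataclass(frozen=True)
class LensMaterials:
    """Lens material pair and thickness budget.

    ``c_a`` is the speed in the lens (printed resin; derivable as Z/rho from
    the resin impedance and density), ``c_b`` in the interfacing medium
    (elastomer couplant or water).  ``t0`` is the reference (maximum)
    thickness and ``t_min`` the thinnest printable feature.
    """

    c_a: float
    c_b: float
    t0: float
    t_min: float = 0.0

    def __post_init__(self):
        if self.c_a <= 0 or self.c_b <= 0:
            raise ValueError("sound speeds must be positive")
        if self.c_a == self.c_b:
            raise ValueError("lens and interface media must differ in speed")
        if not self.t0 > self.t_min >= 0:
            raise ValueError("need t0 > t_min >= 0")

    def delta_k(self, f0: float) -> float:
        return wavenumber(self.c_b, f0) - wavenumber(self.c_a, f0)

    @classmethod
    def with_full_wrap(cls, c_a: float, c_b: float, f0: float,
                       t_min: float = 2e-4, granularity: float = 5e-5):
        """Thinnest lens covering a full 2 pi of phase at ``f0``.

        ``t0 = t_min + 2 pi / |k_B - k_A|`` rounded up to the printer's
        ``granularity`` (default 0.05 mm).
        """
        dk = abs(wavenumber(c_b, f0) - wavenumber(c_a, f0))
        t0 = t_min + 2 * np.pi / dk
        t0 = np.ceil(t0 / granularity) * granularity
        return cls(c_a, c_b, t0, t_min)


@dataclass
class ThicknessMap:
    """Per-pixel lens thickness (m) realizing a phase map at ``f0``."""

    thickness: np.ndarray
    pitch: float
    f0: float

    def __post_init__(self):
        self.thickness = np.asarray(self.thickness, float)
        if self.pitch <= 0 or self.f0 <= 0:
            raise ValueError("pitch and f0 must be positive")
        if self.pitch ** 2 < MIN_PIXEL_AREA:
            raise ValueError(
                f"pixel area {self.pitch ** 2:.2e} m^2 below the printable "
                f"floor {MIN_PIXEL_AREA:.2e} m^2"
            )

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("thickness", data=self.thickness)
            f.attrs["pitch"] = self.pitch
            f.attrs["f0"] = self.f0

    @classmethod
    def load(cls, path) -> "ThicknessMap":
        with h5py.File(path, "r") as f:
            return cls(f["thickness"][...], float(f.attrs["pitch"]),
                       float(f.attrs["f0"]))


def phase_to_thickness(pmap: PhaseMap, mats: LensMaterials,
                       f0: float | None = None) -> ThicknessMap:
    """Invert the thin-lens phase relation pixel by pixel.

    The target phase is wrapped into ``[0, 2 pi) * sign(k_B - k_A)`` so that
    thickness stays within ``(T0 - 2 pi / |k_B - k_A|, T0]``; the design
    errors out if that full-wrap span would dip below ``t_min``.
    """
    if f0 is None:
        f0 = pmap.f0
    if f0 is None:
        raise ValueError("no design frequency available")
    dk = mats.delta_k(f0)
    # wrap so that (T0 - T) = wrapped/dk is in [0, 2pi/|dk|)
    wrapped = np.mod(pmap.phase, 2 * np.pi) if dk > 0 \
        else -np.mod(-pmap.phase, 2 * np.pi)
    thickness = mats.t0 - wrapped / dk
    span = 2 * np.pi / abs(dk)
    if mats.t0 - span < mats.t_min - 1e-12:
        raise ValueError(
            f"full 2 pi thickness span {span * 1e3:.2f} mm exceeds the budget "
            f"t0 - t_min = {(mats.t0 - mats.t_min) * 1e3:.2f} mm"
        )
    return ThicknessMap(thickness, pmap.pitch, f0)


def thickness_to_phase(tmap: ThicknessMap, mats: LensMaterials) -> PhaseMap:
    """Forward thin-lens relation: the wrapped phase a thickness map imparts."""
    dk = mats.delta_k(tmap.f0)
    return PhaseMap(wrap_phase(dk * (mats.t0 - tmap.thickness)),
                    tmap.pitch, None, tmap.f0)


def quantize_phase(pmap: PhaseMap, step: float = DEFAULT_PHASE_STEP) -> PhaseMap:
    """Round each phase to the printer's phase modulation unit.

    Ties (exactly halfway between levels) round to the lower level;
    ``step = 2 pi`` collapses the map to zero.
    """
    if not 0 < step <= 2 * np.pi:
        raise ValueError("step must be in (0, 2 pi]")
    levels = np.floor(pmap.phase / step + 0.5 - 1e-12)
    q = wrap_phase(levels * step)
    return PhaseMap(q, pmap.pitch,
                    None if pmap.amplitude is None else pmap.amplitude.copy(),
                    pmap.f0)


def export_stl(tmap: ThicknessMap, path, base_thickness: float = 5e-4):
    """Write the lens as a watertight STL heightfield (millimeter units).

    The solid is a base plate slab plus one closed rectangular column per
    pixel (height ``T``) sitting on the slab — the printer-conventional
    "column soup" whose shells are individually closed, so the mesh is
    watertight and its volume is exactly ``area * base + pitch^2 * sum(T)``.
    Coincident faces between neighboring columns are retained; slicers union
    them.  Returns the trimesh object (also written to ``path`` when given).
    """
    import trimesh

    if base_thickness < 0:
        raise ValueError("base_thickness must be non-negative")
    t_mm = np.atleast_2d(np.asarray(tmap.thickness, float)) * 1e3
    pitch = tmap.pitch * 1e3
    base = base_thickness * 1e3
    nx, ny = t_mm.shape

    def box(x0, x1, y0, y1, z0, z1, v, f):
        i = len(v)
        v.extend([(x0, y0, z0), (x1, y0, z0), (x1, y1, z0), (x0, y1, z0),
                  (x0, y0, z1), (x1, y0, z1), (x1, y1, z1), (x0, y1, z1)])
        quads = [(0, 3, 2, 1), (4, 5, 6, 7), (0, 1, 5, 4),
                 (1, 2, 6, 5), (2, 3, 7, 6), (3, 0, 4, 7)]
        for a, b, c, d in quads:
            f.append((i + a, i + b, i + c))
            f.append((i + a, i + c, i + d))

    verts, faces = [], []
    if base > 0:
        box(0.0, nx * pitch, 0.0, ny * pitch, 0.0, base, verts, faces)
    for i in range(nx):
        for j in range(ny):
            if t_mm[i, j] > 0:
                box(i * pitch, (i + 1) * pitch, j * pitch, (j + 1) * pitch,
                    base, base + t_mm[i, j], verts, faces)

    mesh = trimesh.Trimesh(vertices=np.array(verts, float),
                           faces=np.array(faces, int), process=False)
    if not mesh.is_watertight:
        raise RuntimeError("exported lens mesh is not watertight")
    if path is not None:
        mesh.export(str(path))
    return mesh


def sample_stl_thickness(mesh_or_path, tmap_like: ThicknessMap,
                         base_thickness: float = 5e-4) -> np.ndarray:
    """Re-sample an exported lens mesh back to per-pixel thickness (m).

    Evaluates the top-surface height at each pixel center by a vertical
    ray-parity scan of the mesh triangles (max z hit), subtracting the base
    plate.  Used to verify export fidelity.
    """
    import trimesh

    mesh = mesh_or_path
    if not isinstance(mesh, trimesh.Trimesh):
        mesh = trimesh.load_mesh(str(mesh))
    t = np.atleast_2d(tmap_like.thickness)
    nx, ny = t.shape
    pitch = tmap_like.pitch * 1e3
    verts = np.asarray(mesh.vertices, float)
    tri = verts[np.asarray(mesh.faces)]
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    out = np.zeros((nx, ny))
    eps = pitch * 1e-6
    for i in range(nx):
        for j in range(ny):
            px = (i + 0.5) * pitch + eps
            py = (j + 0.5) * pitch + 2 * eps
            d0 = (v1[:, 0] - v0[:, 0]) * (py - v0[:, 1]) - (v1[:, 1] - v0[:, 1]) * (px - v0[:, 0])
            d1 = (v2[:, 0] - v1[:, 0]) * (py - v1[:, 1]) - (v2[:, 1] - v1[:, 1]) * (px - v1[:, 0])
            d2 = (v0[:, 0] - v2[:, 0]) * (py - v2[:, 1]) - (v0[:, 1] - v2[:, 1]) * (px - v2[:, 0])
            covers = ((d0 >= 0) & (d1 >= 0) & (d2 >= 0)) | ((d0 <= 0) & (d1 <= 0) & (d2 <= 0))
            area2 = d0 + d1 + d2
            ok = covers & (np.abs(area2) > 0)
            if not ok.any():
                continue
            w0 = d1[ok] / area2[ok]
            w1 = d2[ok] / area2[ok]
            w2 = d0[ok] / area2[ok]
            zhit = w0 * v0[ok, 2] + w1 * v1[ok, 2] + w2 * v2[ok, 2]
            out[i, j] = zhit.max()
    return (out * 1e-3) - base_thickness
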