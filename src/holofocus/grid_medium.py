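"""Simulation grids and voxelized acoustic property maps.

The propagation domain is a rectilinear grid of cubic voxels carrying static
density ``rho0`` (kg/m^3), sound speed ``c0`` (m/s), and a power-law absorption
coefficient ``alpha0`` (dB MHz^-gamma cm^-1).  Aberrators — skull-like shells —
are built either parametrically (ellipsoidal shells) or by voxelizing a
watertight triangle mesh onto the grid.

All lengths are SI meters internally.  Voxel indices are 0-based; the physical
coordinate of voxel ``(i, j, k)`` is ``origin + index * dx`` (voxel centers).
STL meshes are assumed to be in millimeters unless stated otherwise, the
convention of desktop 3D printers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np


@dataclass(frozen=True)
class SimGrid:
    """Rectilinear simulation grid of cubic voxels.

    ``n_z = 1`` (and/or ``n_y = 1``) gives a first-class 2D or 1D domain.
    """

    n_x: int
    n_y: int = 1
    n_z: int = 1
    dx: float = 1e-4
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.dx <= 0:
            raise ValueError(f"dx must be positive, got {self.dx}")
        for name, n in (("n_x", self.n_x), ("n_y", self.n_y), ("n_z", self.n_z)):
            if n < 1:
                raise ValueError(f"{name} must be >= 1, got {n}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_x, self.n_y, self.n_z)

    @property
    def ndim(self) -> int:
        """Number of non-singleton axes."""
        return sum(n > 1 for n in self.shape) or 1

    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple(n * self.dx for n in self.shape)

    def coordinates(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along ``axis``."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.dx

    def index_of(self, point) -> tuple[int, ...]:
        """Nearest voxel index of a physical point; raises if outside."""
        point = np.atleast_1d(np.asarray(point, dtype=float))
        idx = []
        for ax in range(len(point)):
            i = int(round((point[ax] - self.origin[ax]) / self.dx))
            if not 0 <= i < self.shape[ax]:
                raise ValueError(
                    f"point {point} outside grid along axis {ax} (index {i})"
                )
            idx.append(i)
        while len(idx) < 3:
            idx.append(0)
        return tuple(idx)


def make_grid(extent, dx: float, f0: float, c_min: float, origin=None) -> SimGrid:
    """Build a grid fine enough to resolve ``f0`` in the slowest medium.

    Construction *fails* if ``dx`` is not strictly below half the shortest
    wavelength ``c_min / (2 f0)`` — a coarser grid cannot represent the
    propagating field.

    Parameters
    ----------
    extent : sequence of float
        Physical lengths per axis, meters (1-3 entries).
    dx : float
        Isotropic voxel spacing, meters.
    f0 : float
        Drive frequency, Hz.
    c_min : float
        Minimum sound speed anywhere in the medium, m/s.
    """
    extent = np.atleast_1d(np.asarray(extent, dtype=float))
    if dx <= 0 or f0 <= 0 or c_min <= 0 or np.any(extent <= 0):
        raise ValueError("extent, dx, f0 and c_min must all be positive")
    half_wavelength = c_min / (2.0 * f0)
    if dx >= half_wavelength:
        raise ValueError(
            f"dx = {dx:.4g} m does not resolve the field: need dx < "
            f"c_min/(2 f0) = {half_wavelength:.4g} m"
        )
    counts = [int(np.ceil(e / dx)) for e in extent]
    while len(counts) < 3:
        counts.append(1)
    if origin is None:
        origin = (0.0, 0.0, 0.0)
    return SimGrid(counts[0], counts[1], counts[2], dx=dx, origin=tuple(origin))


@dataclass(frozen=True)
class MaterialPreset:
    """Homogeneous acoustic material: density, speed, power-law absorption."""

    name: str
    rho0: float
    c0: float
    alpha0: float = 0.0
    gamma: float = 1.1

    def __post_init__(self):
        if self.rho0 <= 0 or self.c0 <= 0:
            raise ValueError(f"{self.name}: rho0 and c0 must be positive")
        if self.alpha0 < 0:
            raise ValueError(f"{self.name}: alpha0 must be non-negative")


# Literature-typical transcranial simulation values; overridable everywhere.
WATER = MaterialPreset("water", rho0=1000.0, c0=1482.0, alpha0=0.0022, gamma=2.0)
SKULL_BONE = MaterialPreset("skull_bone", rho0=1900.0, c0=2800.0, alpha0=8.0, gamma=1.1)
SOFT_TISSUE = MaterialPreset("soft_tissue", rho0=1040.0, c0=1560.0, alpha0=0.6, gamma=1.1)
# Stereolithography resin (speed from Z/rho = 3.03 MRayl / 1170 kg m^-3) and PDMS.
PRINT_RESIN = MaterialPreset("print_resin", rho0=1170.0, c0=3.03e6 / 1170.0, alpha0=2.0, gamma=1.1)
PDMS = MaterialPreset("pdms", rho0=1030.0, c0=1.1e6 / 1030.0, alpha0=3.5, gamma=1.1)

PRESETS = {m.name: m for m in (WATER, SKULL_BONE, SOFT_TISSUE, PRINT_RESIN, PDMS)}


@dataclass
class MediumMap:
    """Per-voxel acoustic properties on a :class:`SimGrid`.

    ``gamma`` (the power-law exponent) is shared across voxels; the absorption
    operator requires 1 < gamma < 3 wherever absorption is non-zero.
    """

    grid: SimGrid
    rho0: np.ndarray
    c0: np.ndarray
    alpha0: np.ndarray = None
    gamma: float = 1.1

    def __post_init__(self):
        shape = self.grid.shape
        self.rho0 = np.broadcast_to(np.asarray(self.rho0, float), shape).copy()
        self.c0 = np.broadcast_to(np.asarray(self.c0, float), shape).copy()
        if self.alpha0 is None:
            self.alpha0 = np.zeros(shape)
        self.alpha0 = np.broadcast_to(np.asarray(self.alpha0, float), shape).copy()
        if np.any(self.rho0 <= 0) or np.any(self.c0 <= 0):
            raise ValueError("rho0 and c0 must be positive everywhere")
        if np.any(self.alpha0 < 0):
            raise ValueError("alpha0 must be non-negative")
        if np.any(self.alpha0 > 0) and not (1.0 < self.gamma < 3.0):
            raise ValueError(
                f"power-law exponent gamma = {self.gamma} must lie in (1, 3) "
                "for the absorption operator to be well defined"
            )

    @property
    def c_min(self) -> float:
        return float(self.c0.min())

    @property
    def c_max(self) -> float:
        return float(self.c0.max())

    def copy(self) -> "MediumMap":
        return MediumMap(self.grid, self.rho0.copy(), self.c0.copy(),
                         self.alpha0.copy(), self.gamma)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("rho0", data=self.rho0)
            f.create_dataset("c0", data=self.c0)
            f.create_dataset("alpha0", data=self.alpha0)
            f.attrs["gamma"] = self.gamma
            f.attrs["dx"] = self.grid.dx
            f.attrs["origin"] = self.grid.origin

    @classmethod
    def load(cls, path) -> "MediumMap":
        with h5py.File(path, "r") as f:
            rho0 = f["rho0"][...]
            c0 = f["c0"][...]
            alpha0 = f["alpha0"][...]
            gamma = float(f.attrs["gamma"])
            dx = float(f.attrs["dx"])
            origin = tuple(f.attrs["origin"])
        grid = SimGrid(*rho0.shape, dx=dx, origin=origin)
        return cls(grid, rho0, c0, alpha0, gamma)


def homogeneous_medium(grid: SimGrid, mat: MaterialPreset) -> MediumMap:
    return MediumMap(grid, mat.rho0, mat.c0, mat.alpha0, mat.gamma)


def _normalized_radius(grid: SimGrid, center, semi_axes) -> np.ndarray:
    """Per-voxel ellipsoidal radius (1.0 on the ellipsoid surface)."""
    center = np.asarray(center, float)
    semi = np.asarray(semi_axes, float)
    axes = []
    for ax in range(3):
        x = grid.coordinates(ax) - (center[ax] if ax < len(center) else 0.0)
        a = semi[ax] if ax < len(semi) else grid.dx  # singleton axes collapse
        if grid.shape[ax] == 1:
            x = np.zeros(1)
            a = 1.0
        axes.append((x / a) ** 2)
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(xx + yy + zz)


def synthetic_skull_shell(
    grid: SimGrid,
    center,
    semi_axes,
    thickness: float,
    inner: MaterialPreset = WATER,
    shell_mat: MaterialPreset = SKULL_BONE,
    outer: MaterialPreset = WATER,
    gamma: float | None = None,
    cap_axis: int | None = None,
    cap_sign: int = 1,
    thickness_variation: float = 0.0,
    n_lobes: int = 5,
    harmonics: list | None = None,
) -> MediumMap:
    """Ellipsoidal skull-like shell aberrator.

    Voxel centers with normalized ellipsoid radius in ``[r_inner, 1]`` receive
    the shell material, where the inner surface is the ellipsoid shrunk by
    ``thickness`` along every semi-axis.  ``thickness = 0`` degenerates to a
    homogeneous map (inner/outer materials only).

    ``thickness_variation`` adds an azimuthal wall-thickness modulation
    ``t(theta) = thickness + variation * cos(n_lobes * theta)`` (theta in the
    x-y plane around the shell center); ``harmonics`` generalizes this to a
    sum of terms ``(m, amplitude, phase)`` -> ``amp * cos(m theta + phase)``.
    A uniform-thickness shell is mostly a weak lens; it is the thickness
    *variation* that aberrates the beam the way real cranial bone does — the
    odd (m = 1, wedge-like) terms steer the uncompensated focus off target
    laterally, the higher terms defocus and spread it.

    ``cap_axis``/``cap_sign`` keep only the half of the shell on the
    ``cap_sign`` side of the center along ``cap_axis`` — a cranial-cap
    aberrator like an excised dorsal half-skull, leaving the far side open.

    The shell must fit inside the grid; a shell surface crossing the domain
    boundary is an error.
    """
    semi = np.asarray(semi_axes, float)
    center = np.asarray(center, float)
    if thickness < 0:
        raise ValueError("thickness must be non-negative")
    if np.any(semi <= 0):
        raise ValueError("semi-axes must be positive")
    for ax in range(grid.ndim):
        lo = center[ax] - semi[ax]
        hi = center[ax] + semi[ax]
        cmin = grid.origin[ax]
        cmax = grid.origin[ax] + (grid.shape[ax] - 1) * grid.dx
        if lo < cmin or hi > cmax:
            raise ValueError(
                f"shell exceeds grid bounds along axis {ax}: "
                f"[{lo:.4g}, {hi:.4g}] vs [{cmin:.4g}, {cmax:.4g}]"
            )

    if gamma is None:
        gamma = shell_mat.gamma
    r = _normalized_radius(grid, center, semi)
    inside = r < 1.0
    med = MediumMap(
        grid,
        np.where(inside, inner.rho0, outer.rho0),
        np.where(inside, inner.c0, outer.c0),
        np.where(inside, inner.alpha0, outer.alpha0),
        gamma,
    )
    if thickness > 0:
        if harmonics is None and thickness_variation != 0.0:
            harmonics = [(n_lobes, thickness_variation, 0.0)]
        amp_total = sum(abs(a) for _, a, _ in harmonics) if harmonics else 0.0
        if np.any(semi - (thickness + amp_total) <= 0):
            raise ValueError("thickness exceeds a semi-axis")
        if harmonics:
            if thickness - amp_total < 0:
                raise ValueError("harmonic amplitudes exceed the mean thickness")
            xs = [grid.coordinates(a) - center[a] for a in range(2)]
            xx, yy = np.meshgrid(
                xs[0] if grid.shape[0] > 1 else np.zeros(1),
                xs[1] if grid.shape[1] > 1 else np.zeros(1),
                indexing="ij")
            theta = np.arctan2(yy, xx)
            t_eff = thickness + sum(a * np.cos(m * theta + ph)
                                    for m, a, ph in harmonics)
            t_eff = t_eff.reshape(t_eff.shape + (1,) * (3 - t_eff.ndim))
            # per-voxel inner surface: ellipsoid shrunk by the local thickness
            axes_sq = []
            for ax in range(3):
                x = grid.coordinates(ax) - (center[ax] if ax < len(center) else 0.0)
                if grid.shape[ax] == 1:
                    x = np.zeros(1)
                shp = [1, 1, 1]
                shp[ax] = -1
                axes_sq.append(x.reshape(shp))
            semi_full = [semi[ax] if ax < len(semi) else 1.0 for ax in range(3)]
            r_in = np.sqrt(sum(
                (axes_sq[ax] / np.maximum(semi_full[ax] - t_eff, 1e-9)) ** 2
                if grid.shape[ax] > 1 else np.zeros((1, 1, 1))
                for ax in range(3)))
        else:
            inner_semi = semi - thickness
            r_in = _normalized_radius(grid, center, inner_semi)
        shell = (r <= 1.0) & (r_in >= 1.0)
        if cap_axis is not None:
            coord = grid.coordinates(cap_axis)
            reshape = [1, 1, 1]
            reshape[cap_axis] = -1
            half = cap_sign * (coord.reshape(reshape) - center[cap_axis]) >= 0
            shell &= np.broadcast_to(half, shell.shape)
        med.rho0[shell] = shell_mat.rho0
        med.c0[shell] = shell_mat.c0
        med.alpha0[shell] = shell_mat.alpha0
    return med


def _ray_parity_inside(vertices: np.ndarray, faces: np.ndarray,
                       points: np.ndarray) -> np.ndarray:
    """Point-in-mesh by z-ray crossing parity.

    Casts a ray along +z from each point and counts proper triangle
    crossings; odd count = inside.  Points lying exactly on the surface
    count as inside (boundary hits at t == 0 are included).
    """
    tri = vertices[faces]  # (F, 3, 3)
    inside = np.zeros(len(points), dtype=bool)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    # Nudge the ray's xy origin off exact edge/vertex alignments (grid-aligned
    # meshes otherwise double-count triangles sharing an edge on the ray).
    diag = float(np.linalg.norm(vertices.max(0) - vertices.min(0))) or 1.0
    points = points + diag * np.array([1.0e-9, 2.718e-9, 0.0])
    # 2D edge functions in the xy plane, evaluated per point (chunked).
    chunk = max(1, int(2e7 // max(len(tri), 1)))
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk]
        px = p[:, 0][:, None]
        py = p[:, 1][:, None]
        pz = p[:, 2][:, None]
        d0 = (v1[None, :, 0] - v0[None, :, 0]) * (py - v0[None, :, 1]) - \
             (v1[None, :, 1] - v0[None, :, 1]) * (px - v0[None, :, 0])
        d1 = (v2[None, :, 0] - v1[None, :, 0]) * (py - v1[None, :, 1]) - \
             (v2[None, :, 1] - v1[None, :, 1]) * (px - v1[None, :, 0])
        d2 = (v0[None, :, 0] - v2[None, :, 0]) * (py - v2[None, :, 1]) - \
             (v0[None, :, 1] - v2[None, :, 1]) * (px - v2[None, :, 0])
        covers = ((d0 >= 0) & (d1 >= 0) & (d2 >= 0)) | \
                 ((d0 <= 0) & (d1 <= 0) & (d2 <= 0))
        area2 = d0 + d1 + d2
        ok = covers & (np.abs(area2) > 0)
        # barycentric z of the triangle plane at (px, py)
        with np.errstate(divide="ignore", invalid="ignore"):
            w0 = np.where(ok, d1 / area2, 0.0)
            w1 = np.where(ok, d2 / area2, 0.0)
            w2 = np.where(ok, d0 / area2, 0.0)
        zhit = w0 * v0[None, :, 2] + w1 * v1[None, :, 2] + w2 * v2[None, :, 2]
        crossings = (ok & (zhit >= pz)).sum(axis=1)
        inside[s:s + chunk] = (crossings % 2) == 1
    return inside


def voxelize_mesh(
    grid: SimGrid,
    mesh,
    mat_inside: MaterialPreset,
    mat_outside: MaterialPreset = WATER,
    units: str = "mm",
    gamma: float | None = None,
) -> MediumMap:
    """Voxelize a closed triangle surface onto the grid.

    Inside/outside is decided by a ray-parity test at voxel centers; centers
    exactly on the surface are assigned inside.

    Parameters
    ----------
    mesh : trimesh.Trimesh or path
        Watertight surface.  STL files are read with trimesh.
    units : {"mm", "m"}
        Unit of the mesh coordinates; "mm" (printer convention) is converted
        to meters.
    """
    import trimesh

    if not isinstance(mesh, trimesh.Trimesh):
        mesh = trimesh.load_mesh(str(mesh))
    if not mesh.is_watertight:
        raise ValueError("mesh is not watertight; voxelization undefined")
    scale = 1e-3 if units == "mm" else 1.0
    vertices = np.asarray(mesh.vertices, float) * scale
    faces = np.asarray(mesh.faces, np.int64)

    lo = vertices.min(axis=0)
    hi = vertices.max(axis=0)
    gmin = np.array([grid.origin[a] for a in range(3)])
    gmax = gmin + (np.array(grid.shape) - 1) * grid.dx
    if np.any(hi < gmin) or np.any(lo > gmax):
        raise ValueError("mesh lies entirely outside the grid")

    xs = [grid.coordinates(a) for a in range(3)]
    xx, yy, zz = np.meshgrid(*xs, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    # only test points inside the mesh bounding box (others are outside)
    bbox = np.all((pts >= lo - 1e-12) & (pts <= hi + 1e-12), axis=1)
    inside = np.zeros(len(pts), dtype=bool)
    if bbox.any():
        inside[bbox] = _ray_parity_inside(vertices, faces, pts[bbox])
    inside = inside.reshape(grid.shape)
    if not inside.any():
        raise ValueError("mesh encloses no voxel centers on this grid")

    if gamma is None:
        gamma = mat_inside.gamma
    return MediumMap(
        grid,
        np.where(inside, mat_inside.rho0, mat_outside.rho0),
        np.where(inside, mat_inside.c0, mat_outside.c0),
        np.where(inside, mat_inside.alpha0, mat_outside.alpha0),
        gamma,
    )


def ellipsoid_shell_mesh(center, semi_axes, thickness: float, subdivisions: int = 3):
    """Export the parametric shell as a watertight mesh pair (outer - inner).

    Returns a single trimesh whose inside region is the shell wall: outer
    ellipsoid with an inner ellipsoid cavity (inverted normals).  Units are
    meters (pass ``units="m"`` when re-voxelizing).
    """
    import trimesh

    center = np.asarray(center, float)
    semi = np.asarray(semi_axes, float)
    outer = trimesh.creation.icosphere(subdivisions=subdivisions)
    outer.apply_scale(semi)
    inner = trimesh.creation.icosphere(subdivisions=subdivisions)
    inner.apply_scale(semi - thickness)
    inner.invert()
    shell = trimesh.util.concatenate([outer, inner])
    shell.apply_translation(center)
    return shell
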