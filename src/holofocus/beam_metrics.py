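"""Quantitative evaluation of pressure fields.

Beam quality is judged on the pressure-squared field |p|^2: profiles along
grid axes, full width at half maximum (FWHM) of the main lobe, focal position
and its per-axis deviation from the intended target (accepted when within the
local FWHM), counting of distinct foci above a relative-dB threshold, and the
intensity reflection coefficient of a material interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .grid_medium import SimGrid


@dataclass
class FieldVolume:
    """Steady-state pressure amplitude |p| per voxel on a grid."""

    grid: SimGrid
    amplitude: np.ndarray

    def __post_init__(self):
        self.amplitude = np.asarray(self.amplitude, float).reshape(self.grid.shape)
        if np.any(self.amplitude < 0) or not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitude must be finite and non-negative")

    @property
    def pressure_squared(self) -> np.ndarray:
        return self.amplitude ** 2

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("amplitude", data=self.amplitude)
            f.attrs["dx"] = self.grid.dx
            f.attrs["origin"] = self.grid.origin

    @classmethod
    def load(cls, path) -> "FieldVolume":
        with h5py.File(path, "r") as f:
            amp = f["amplitude"][...]
            grid = SimGrid(*amp.shape, dx=float(f.attrs["dx"]),
                           origin=tuple(f.attrs["origin"]))
            return cls(grid, amp)


def pressure_squared_profile(field: FieldVolume, axis: int,
                             through: tuple) -> tuple[np.ndarray, float]:
    """|p|^2 along ``axis`` through the voxel ``through``; returns (profile, dx)."""
    idx = list(through) + [0] * (3 - len(through))
    for a in range(3):
        if not 0 <= idx[a] < field.grid.shape[a]:
            raise ValueError(f"profile line outside grid at axis {a}")
    sl = [i for i in idx]
    sl[axis] = slice(None)
    return field.pressure_squared[tuple(sl)], field.grid.dx


def fwhm(profile: np.ndarray, spacing: float) -> float:
    """Linear-interpolated full width at half maximum of the main lobe.

    With multiple half-maximum crossings (side lobes), the pair bracketing the
    global peak is used; ties in the peak go to the lowest index.
    """
    profile = np.asarray(profile, float)
    if profile.size < 3 or np.all(profile == 0):
        raise ValueError("profile is degenerate (all zero or too short)")
    i_pk = int(np.argmax(profile))
    if i_pk == 0 or i_pk == profile.size - 1:
        raise ValueError("peak lies on the profile boundary; widen the window")
    half = profile[i_pk] / 2.0

    # march outward from the peak to the first crossings
    i = i_pk
    while i > 0 and profile[i] > half:
        i -= 1
    if profile[i] > half:
        raise ValueError("no left half-maximum crossing inside the profile")
    left = i + (half - profile[i]) / (profile[i + 1] - profile[i])

    j = i_pk
    while j < profile.size - 1 and profile[j] > half:
        j += 1
    if profile[j] > half:
        raise ValueError("no right half-maximum crossing inside the profile")
    right = j - 1 + (half - profile[j - 1]) / (profile[j] - profile[j - 1])
    return (right - left) * spacing


def focal_position(field: FieldVolume) -> tuple[int, ...]:
    """Voxel index of the |p|^2 maximum; ties resolve to the lowest flat index."""
    if np.all(field.amplitude == 0):
        raise ValueError("field is identically zero")
    return tuple(int(i) for i in
                 np.unravel_index(int(np.argmax(field.amplitude)), field.grid.shape))


def focal_deviation(field: FieldVolume, target_index: tuple):
    """Per-axis focal offset vs the target, compared to the local FWHM.

    Returns ``(deviation_m, fwhm_m, within)``: per-axis distances between the
    |p|^2 peak and the target (meters), the FWHM of the profile through the
    peak along each axis, and whether every axis deviation is within its FWHM
    (the localization acceptance used throughout).
    """
    peak = focal_position(field)
    target_index = tuple(target_index) + (0,) * (3 - len(target_index))
    deviations, widths = [], []
    for a in range(3):
        if field.grid.shape[a] == 1:
            continue
        prof, dx = pressure_squared_profile(field, a, peak)
        widths.append(fwhm(prof, dx))
        deviations.append(abs(peak[a] - target_index[a]) * dx)
    within = all(d <= w for d, w in zip(deviations, widths))
    return np.array(deviations), np.array(widths), within


def count_foci(field: FieldVolume, threshold_db: float = -6.0,
               min_separation: float | None = None,
               min_prominence_db: float = 3.0):
    """Count distinct foci of |p|^2 above a threshold relative to the peak.

    A focus is a local maximum of |p|^2 that (a) lies above ``threshold_db``
    of the global |p|^2 peak, (b) has topographic prominence of at least
    ``min_prominence_db`` — i.e. the saddle connecting it to any stronger
    maximum sits that far below it, so diffraction ripples riding on a lobe's
    shoulder do not count — and (c) is farther than ``min_separation``
    (default: one FWHM of the global main lobe, sharpest axis) from every
    stronger focus.  Prominence is computed by a descending flood fill
    (persistence of super-level-set components).

    Returns ``(count, foci_indices)`` sorted by descending intensity.
    """
    if threshold_db >= 0:
        raise ValueError("threshold_db must be negative (relative dB)")
    p2 = field.pressure_squared
    peak_val = p2.max()
    if peak_val == 0:
        return 0, []
    thresh = peak_val * 10 ** (threshold_db / 10.0)
    # flood down far enough to resolve the prominence of threshold-level peaks
    stop = thresh * 10 ** (-min_prominence_db / 10.0)

    axes = [a for a in range(3) if field.grid.shape[a] > 1]
    squeezed = p2.reshape([field.grid.shape[a] for a in axes])
    shape = squeezed.shape
    flat = squeezed.ravel()
    active_idx = np.where(flat >= stop)[0]
    order = active_idx[np.argsort(flat[active_idx])[::-1]]

    parent = {}
    comp_peak = {}          # root -> flat index of component maximum
    merged_at = {}          # peak flat index -> saddle value (merge level)

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    strides = np.array([int(np.prod(shape[d + 1:], dtype=int))
                        for d in range(len(shape))])

    for fi in order:
        parent[fi] = fi
        comp_peak[fi] = fi
        coords = np.unravel_index(fi, shape)
        v = flat[fi]
        for d in range(len(shape)):
            for step in (-1, 1):
                c = coords[d] + step
                if not 0 <= c < shape[d]:
                    continue
                nb = fi + step * strides[d]
                if nb not in parent:
                    continue
                ra, rb = find(fi), find(nb)
                if ra == rb:
                    continue
                pa, pb = comp_peak[ra], comp_peak[rb]
                if flat[pa] >= flat[pb]:
                    winner, loser_peak = ra, pb
                else:
                    winner, loser_peak = rb, pa
                if loser_peak not in merged_at:
                    merged_at[loser_peak] = v  # saddle level
                parent[ra if winner == rb else rb] = winner
                comp_peak[winner] = pa if flat[pa] >= flat[pb] else pb

    candidates = [pk for pk in comp_peak.values()]
    # unique peaks: every component ever born has its peak recorded once
    candidates = sorted(set(merged_at) | set(comp_peak[find(i)] for i in parent),
                        key=lambda i: -flat[i])
    kept_flat = []
    for pk in candidates:
        v = flat[pk]
        if v < thresh:
            continue
        saddle = merged_at.get(pk)
        if saddle is not None and v < saddle * 10 ** (min_prominence_db / 10.0):
            continue
        kept_flat.append(pk)

    if min_separation is None:
        peak_sq = tuple(int(i) for i in np.unravel_index(int(np.argmax(squeezed)),
                                                         shape))
        widths = []
        for ax in range(len(shape)):
            sl = list(peak_sq)
            sl[ax] = slice(None)
            try:
                widths.append(fwhm(squeezed[tuple(sl)], field.grid.dx))
            except ValueError:
                pass
        min_separation = min(widths) if widths else field.grid.dx

    kept = []
    for pk in kept_flat:
        idx = np.array(np.unravel_index(pk, shape))
        pos = idx * field.grid.dx
        if all(np.linalg.norm(pos - np.asarray(k) * field.grid.dx) >= min_separation
               for k in kept):
            kept.append(tuple(int(i) for i in idx))
    # re-inflate indices to full 3-tuples
    full = []
    for k in kept:
        idx = [0, 0, 0]
        for ax, v in zip(axes, k):
            idx[ax] = v
        full.append(tuple(idx))
    return len(full), full


def reflection_coefficient_intensity(z1: float, z2: float) -> float:
    """Intensity reflection coefficient ((Z1 - Z2)/(Z1 + Z2))^2 at an interface.

    Impedances in any consistent unit (conventionally MRayl); symmetric in its
    arguments and zero for matched media.
    """
    if z1 <= 0 or z2 <= 0:
        raise ValueError("acoustic impedances must be positive")
    return float(((z1 - z2) / (z1 + z2)) ** 2)
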