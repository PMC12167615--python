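"""Standardized uptake value (SUV) conversion and spherical-kernel statistics.

A PET scanner reports activity concentration :math:`A_c` (kBq/mL).  The
standardized uptake value normalizes it by the administered activity per unit
body mass,

.. math:: \\mathrm{SUV} = \\frac{A_c}{A_i / w},

where :math:`A_i` is the administered activity decay-corrected to the start of
imaging and :math:`w` the patient weight.  Assuming a tissue density of
1 g/cm^3 the quantity is unitless.

This module also provides the spherical-neighbourhood primitives used for
local uptake statistics: discretization of a sphere onto an (anisotropic)
voxel grid, the SUVpeak map (mean SUV in a 1 cm^3 sphere centred at each
voxel of a mask), and mean/max/SD over a sphere at a given centre.

Internal canonical units are mm, kBq, g and minutes; converters live at the
I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Literal, NamedTuple

import numpy as np

#: Physical half-life of fluorine-18, minutes.
F18_HALF_LIFE_MIN = 109.77

#: Diameter (mm) of the sphere whose volume is exactly 1 cm^3, used for the
#: SUVpeak kernel: d = 2 * (3 * 1000 / (4 pi))^(1/3).
PEAK_SPHERE_DIAMETER_MM = 2.0 * (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class ScanMeta:
    """Per-scan metadata needed for the SUV conversion.

    Parameters
    ----------
    injected_activity_mbq : float
        Administered activity at injection time, MBq.
    injection_time, scan_time : datetime
        Injection and start-of-acquisition timestamps; the scan must not
        precede the injection.
    weight_kg : float
        Patient body weight, kg.
    isotope_half_life_min : float
        Physical half-life of the radionuclide, minutes (F-18 by default).
    """

    injected_activity_mbq: float
    injection_time: datetime
    scan_time: datetime
    weight_kg: float
    isotope_half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.injected_activity_mbq <= 0:
            raise ValueError("injected activity must be positive")
        if self.weight_kg <= 0:
            raise ValueError("weight must be positive")
        if self.isotope_half_life_min <= 0:
            raise ValueError("half-life must be positive")
        if self.scan_time < self.injection_time:
            raise ValueError("scan precedes injection")

    @property
    def uptake_minutes(self) -> float:
        """Elapsed time from injection to start of imaging, minutes."""
        return (self.scan_time - self.injection_time).total_seconds() / 60.0


@dataclass
class PETVolume:
    """A 3D scalar PET grid with voxel spacing and a voxel-to-world affine.

    ``value_kind`` distinguishes raw activity concentration (kBq/mL) from the
    unitless SUV representation produced by :func:`to_suv`.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None
    value_kind: Literal["activity", "suv"] = "activity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("PET volume must be a non-empty 3D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        if self.affine is None:
            self.affine = np.diag((*self.spacing, 1.0))
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PET values must be finite")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def voxel_to_world(self, index) -> np.ndarray:
        """World coordinates (mm) of a voxel centre."""
        idx = np.asarray(index, dtype=float)
        return (self.affine @ np.append(idx, 1.0))[:3]

    def with_values(self, values: np.ndarray, value_kind: str) -> "PETVolume":
        return PETVolume(values, self.spacing, self.affine.copy(), value_kind)


@dataclass(frozen=True)
class SphereSpec:
    """A spherical VOI given by its diameter in mm."""

    diameter_mm: float
    purpose: Literal["peak_kernel", "measurement"] = "measurement"

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("sphere diameter must be positive")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


#: 1 cm^3 kernel used for SUVpeak.
PEAK_SPHERE = SphereSpec(PEAK_SPHERE_DIAMETER_MM, "peak_kernel")


@dataclass
class PeakMap:
    """SUVpeak values defined on (exactly) the voxels of a mask.

    ``values`` is NaN outside the mask; ``mask`` is the domain of definition.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("PeakMap values and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("PeakMap must be finite on its mask")


class SphereStats(NamedTuple):
    mean: float
    max: float
    sd: float


def decay_correct(meta: ScanMeta) -> float:
    """Administered activity decay-corrected to the start of imaging, MBq.

    Returns ``A_i * 2**(-dt / T_half)`` with dt the uptake time in minutes.
    """
    dt = meta.uptake_minutes
    if dt < 0:
        raise ValueError("scan precedes injection")
    return meta.injected_activity_mbq * 2.0 ** (-dt / meta.isotope_half_life_min)


def suv_scale_factor(meta: ScanMeta) -> float:
    """kBq/mL activity concentration corresponding to SUV = 1.

    Equals ``A_i' [kBq] / w [g]``; dividing an activity image by this factor
    yields unitless SUV (tissue density taken as 1 g/cm^3).
    """
    ai_kbq = decay_correct(meta) * 1000.0
    w_g = meta.weight_kg * 1000.0
    return ai_kbq / w_g


def to_suv(vol: PETVolume, meta: ScanMeta) -> PETVolume:
    """Convert an activity-concentration volume (kBq/mL) to unitless SUV."""
    if vol.value_kind != "activity":
        raise ValueError("volume is already in SUV units")
    return vol.with_values(vol.values / suv_scale_factor(meta), "suv")


def sphere_offsets(diameter_mm: float, spacing) -> np.ndarray:
    """Integer voxel offsets forming the discretized sphere.

    A voxel offset belongs to the sphere when the Euclidean world distance of
    its centre from the sphere centre is <= diameter/2 (voxel-centre rule).
    Returned as an (N, 3) int array in lexicographic order; always contains
    (0, 0, 0) and is symmetric under negation.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    sp = np.asarray(spacing, dtype=float)
    if sp.shape != (3,) or np.any(sp <= 0):
        raise ValueError("spacing must be three positive components")
    r = diameter_mm / 2.0
    nmax = np.floor(r / sp).astype(int)
    axes = [np.arange(-n, n + 1) for n in nmax]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    offs = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    d2 = np.sum((offs * sp) ** 2, axis=1)
    offs = offs[d2 <= r * r]
    # meshgrid ravel in "ij" indexing is already lexicographic
    return offs


def _gather_neighbourhood(values: np.ndarray, coords: np.ndarray,
                          offsets: np.ndarray):
    """Gather ``values`` at ``coords + offsets`` with grid-bounds handling.

    Returns ``(vals, in_grid)`` of shape (n_coords, n_offsets); out-of-grid
    entries of ``vals`` are 0 and flagged False in ``in_grid``.
    """
    shape = np.asarray(values.shape)
    neigh = coords[:, None, :] + offsets[None, :, :]
    in_grid = np.all((neigh >= 0) & (neigh < shape), axis=2)
    clipped = np.clip(neigh, 0, shape - 1)
    vals = values[clipped[..., 0], clipped[..., 1], clipped[..., 2]]
    return np.where(in_grid, vals, 0.0), in_grid


def suv_peak_map(vol: PETVolume, mask: np.ndarray,
                 chunk: int = 8192) -> PeakMap:
    """SUVpeak (mean SUV in a 1 cm^3 sphere) for every voxel of ``mask``.

    The kernel may extend outside the mask (the local mean is over the image,
    not the organ); neighbours falling outside the image grid are excluded
    from the mean.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.values.shape:
        raise ValueError("mask and volume shapes differ")
    if not mask.any():
        raise ValueError("empty organ mask")
    offsets = sphere_offsets(PEAK_SPHERE_DIAMETER_MM, vol.spacing)
    coords = np.argwhere(mask)
    out = np.full(vol.values.shape, np.nan)
    for start in range(0, len(coords), chunk):
        c = coords[start:start + chunk]
        vals, in_grid = _gather_neighbourhood(vol.values, c, offsets)
        means = vals.sum(axis=1) / in_grid.sum(axis=1)
        out[c[:, 0], c[:, 1], c[:, 2]] = means
    return PeakMap(out, mask)


def sphere_stats(field: np.ndarray, center, sphere: SphereSpec | float,
                 spacing) -> SphereStats:
    """Mean, max and population SD of ``field`` over a sphere at ``center``.

    The sphere must lie fully inside the grid; SD divides by N (population
    convention).
    """
    diameter = sphere.diameter_mm if isinstance(sphere, SphereSpec) else float(sphere)
    offsets = sphere_offsets(diameter, spacing)
    pts = np.asarray(center, dtype=int) + offsets
    if np.any(pts < 0) or np.any(pts >= np.asarray(field.shape)):
        raise ValueError("sphere exits grid")
    vals = field[pts[:, 0], pts[:, 1], pts[:, 2]]
    return SphereStats(float(vals.mean()), float(vals.max()),
                       float(vals.std(ddof=0)))
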