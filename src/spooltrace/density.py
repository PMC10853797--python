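"""Density grids, MRC/CCP4 I/O, trilinear interpolation and fitting energy.

Internal lengths are nm; MRC headers are written/read in Angstrom per the
MRC2014 standard.  Grids are kept in canonical X,Y,Z axis order regardless
of the on-disk ``mapc/mapr/maps`` permutation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import mrcfile
import numpy as np

from .spiral import SpiralSpec, Trace

__all__ = [
    "DensityGrid",
    "FitResult",
    "MapFormatError",
    "read_map",
    "write_map",
    "interpolate",
    "fitting_energy",
    "synth_map",
]

_ANGSTROM_PER_NM = 10.0


class MapFormatError(ValueError):
    """Raised when an MRC/CCP4 file cannot be interpreted."""


@dataclass
class DensityGrid:
    """Regular 3D scalar field.

    ``values[ix, iy, iz]`` is the density at the voxel center
    ``origin + (ix, iy, iz) * spacing`` (nm).  ``origin`` is the center of
    voxel (0, 0, 0).
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise MapFormatError(f"values must be a 3D array, got ndim={self.values.ndim}")
        if min(self.values.shape) < 2:
            raise MapFormatError(f"dims must be >= 2 on all axes, got {self.values.shape}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise MapFormatError(f"spacing must be > 0 on all axes, got {self.spacing}")

    @property
    def dims(self):
        return self.values.shape

    @property
    def upper(self) -> np.ndarray:
        """Position of the last voxel center along each axis, nm."""
        return self.origin + (np.array(self.dims) - 1) * self.spacing


@dataclass(frozen=True)
class FitResult:
    """Fitting energy of one trace against one map (lower = better fit)."""

    spec: SpiralSpec
    energy_total: float
    energy_per_atom: float
    n_points: int
    outside_fraction: float

    def objective(self, which: str = "per_atom") -> float:
        if which == "per_atom":
            return self.energy_per_atom
        if which == "total":
            return self.energy_total
        raise ValueError(f"objective must be 'per_atom' or 'total', got {which!r}")


# ---------------------------------------------------------------------------
# MRC/CCP4 I/O


def read_map(path) -> DensityGrid:
    """Read an MRC/CCP4 2014 map into a canonical X,Y,Z grid (nm units).

    Axis permutation declared in ``mapc/mapr/maps`` is undone; the origin is
    taken from the ``origin`` header record when set, else from
    ``nstart * spacing``.
    """
    try:
        with mrcfile.open(path, mode="r", permissive=False) as mrc:
            header = mrc.header
            data = np.asarray(mrc.data)
            crs_to_xyz = (int(header.mapc) - 1, int(header.mapr) - 1, int(header.maps) - 1)
            if sorted(crs_to_xyz) != [0, 1, 2]:
                raise MapFormatError(
                    f"mapc/mapr/maps must be a permutation of 1,2,3, got "
                    f"({header.mapc}, {header.mapr}, {header.maps})"
                )
            voxel = mrc.voxel_size
            spacing_ang = np.array([voxel.x, voxel.y, voxel.z], dtype=float)
            origin_ang = np.array(
                [header.origin.x, header.origin.y, header.origin.z], dtype=float
            )
            nstart_crs = (int(header.nxstart), int(header.nystart), int(header.nzstart))
    except MapFormatError:
        raise
    except Exception as exc:  # pragma: no cover - exact message is mrcfile's
        raise MapFormatError(f"cannot read MRC map {path}: {exc}") from exc

    # data is stored [sections, rows, columns]; axis_of_dim maps each data
    # dimension to its spatial axis (0=X, 1=Y, 2=Z)
    axis_of_dim = (crs_to_xyz[2], crs_to_xyz[1], crs_to_xyz[0])
    transpose = [axis_of_dim.index(ax) for ax in (0, 1, 2)]
    values = np.ascontiguousarray(np.transpose(data, transpose))

    nstart_xyz = np.zeros(3, dtype=int)
    for crs_index, ax in enumerate(crs_to_xyz):
        nstart_xyz[ax] = nstart_crs[crs_index]

    if not np.all(spacing_ang > 0):
        raise MapFormatError(f"cella/(mx,my,mz) yields non-positive voxel size {spacing_ang}")
    if np.any(origin_ang != 0.0):
        origin_nm = origin_ang / _ANGSTROM_PER_NM
    else:
        origin_nm = nstart_xyz * spacing_ang / _ANGSTROM_PER_NM
    return DensityGrid(values, origin_nm, spacing_ang / _ANGSTROM_PER_NM)


def write_map(grid: DensityGrid, path) -> None:
    """Write ``grid`` as an MRC2014 mode-2 (float32) map in canonical order."""
    data = np.ascontiguousarray(np.transpose(grid.values, (2, 1, 0)).astype(np.float32))
    with mrcfile.new(path, overwrite=True) as mrc:
        mrc.set_data(data)
        mrc.voxel_size = tuple(grid.spacing * _ANGSTROM_PER_NM)
        mrc.header.origin.x = grid.origin[0] * _ANGSTROM_PER_NM
        mrc.header.origin.y = grid.origin[1] * _ANGSTROM_PER_NM
        mrc.header.origin.z = grid.origin[2] * _ANGSTROM_PER_NM
        mrc.update_header_stats()


# ---------------------------------------------------------------------------
# interpolation and fitting energy


def interpolate(grid: DensityGrid, points):
    """Trilinear interpolation of the grid at one or many points.

    Returns ``(values, inside)``: interpolated values (0 outside) and a
    boolean mask flagging points inside the outermost voxel centers.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    t = (pts - grid.origin) / grid.spacing
    dims = np.array(grid.dims)
    inside = np.all((t >= 0.0) & (t <= dims - 1), axis=1)

    tc = np.clip(t, 0.0, dims - 1)
    i0 = np.minimum(tc.astype(int), dims - 2)
    f = tc - i0
    v = grid.values
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]

    c00 = v[ix, iy, iz] * (1 - fx) + v[ix + 1, iy, iz] * fx
    c10 = v[ix, iy + 1, iz] * (1 - fx) + v[ix + 1, iy + 1, iz] * fx
    c01 = v[ix, iy, iz + 1] * (1 - fx) + v[ix + 1, iy, iz + 1] * fx
    c11 = v[ix, iy + 1, iz + 1] * (1 - fx) + v[ix + 1, iy + 1, iz + 1] * fx
    out = ((c00 * (1 - fy) + c10 * fy) * (1 - fz) + (c01 * (1 - fy) + c11 * fy) * fz)
    out = np.where(inside, out, 0.0)
    if np.asarray(points).ndim == 1:
        return float(out[0]), bool(inside[0])
    return out, inside


def fitting_energy(trace: Trace, grid: DensityGrid) -> FitResult:
    """Summed fitting energy of a pseudoatom trace against a density map.

    ``energy_total = -sum(rho)`` over the trilinear density at points inside
    the grid; outside points contribute zero and are reported through
    ``outside_fraction``.  Lower energy means a better fit.
    """
    if len(trace) == 0:
        raise ValueError("trace is empty: cannot compute a fitting energy")
    values, inside = interpolate(grid, trace.points)
    total = -float(np.sum(values))
    n = len(trace)
    return FitResult(
        spec=trace.source_spec,
        energy_total=total,
        energy_per_atom=total / n,
        n_points=n,
        outside_fraction=1.0 - float(np.count_nonzero(inside)) / n,
    )


# ---------------------------------------------------------------------------
# synthetic planted-spiral maps


def synth_map(
    trace: Trace,
    sigma: float = 0.6,
    voxel: float = 0.4,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    padding: float = 2.0,
) -> DensityGrid:
    """Gaussian-splat a trace into a synthetic density map.

    Each pseudoatom deposits an isotropic Gaussian (std ``sigma`` nm, peak
    ``amplitude``) truncated at 4 sigma; the grid bounds the trace plus
    ``padding``.  Optional i.i.d. Gaussian noise (std ``noise_sd``) is added
    with the given ``seed``; output is bit-reproducible for a fixed seed.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if not voxel > 0:
        raise ValueError(f"voxel must be > 0, got {voxel}")
    if not padding > 0:
        raise ValueError(f"padding must be > 0, got {padding}")
    if sigma < voxel / 2:
        warnings.warn(
            f"sigma={sigma} nm is below half the voxel size ({voxel} nm): splats are undersampled",
            stacklevel=2,
        )
    pts = trace.points
    lo = pts.min(axis=0) - padding
    hi = pts.max(axis=0) + padding
    dims = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 2)
    values = np.zeros(tuple(dims), dtype=np.float64)

    cutoff = 4.0 * sigma
    w = int(math.ceil(cutoff / voxel))
    offsets = np.arange(-w, w + 1)
    ox, oy, oz = np.meshgrid(offsets, offsets, offsets, indexing="ij")

    inv_two_sigma2 = 1.0 / (2.0 * sigma * sigma)
    for pt in pts:
        nearest = np.round((pt - lo) / voxel).astype(int)
        ix, iy, iz = nearest[0] + ox, nearest[1] + oy, nearest[2] + oz
        valid = (
            (ix >= 0) & (ix < dims[0]) & (iy >= 0) & (iy < dims[1]) & (iz >= 0) & (iz < dims[2])
        )
        cx = lo[0] + ix * voxel - pt[0]
        cy = lo[1] + iy * voxel - pt[1]
        cz = lo[2] + iz * voxel - pt[2]
        d2 = cx * cx + cy * cy + cz * cz
        contrib = amplitude * np.exp(-d2 * inv_two_sigma2) * (d2 <= cutoff * cutoff) * valid
        np.add.at(values, (ix[valid], iy[valid], iz[valid]), contrib[valid])

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return DensityGrid(values, lo, np.full(3, voxel))
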