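"""Coarse-grained pseudoatom traces along spherical and cylindrical spirals.

A trace places one pseudoatom per DNA base pair along an ideal spiral wound
on a sphere or a cylinder.  Both spiral families share the pitch ``p``
(distance between consecutive turns measured along constant azimuth), the
winding radius ``r``, the initial azimuthal offset ``phi0`` and the center.
Multi-entry families (``n_entries`` parallel strands, like a multi-start
screw thread) and harmonic modulation of the winding radius are supported.

Angles are radians internally; all lengths are nm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "Harmonic",
    "SpiralSpec",
    "Trace",
    "SpiralSpecError",
    "axis_rotation",
    "make_spherical_trace",
    "make_cylindrical_trace",
    "make_multi_entry",
]

#: default arc-length spacing between pseudoatoms: canonical B-DNA rise, nm/bp
DEFAULT_RISE = 0.34

_TWO_PI = 2.0 * math.pi
_AXIS_TOL = 1e-9


class SpiralSpecError(ValueError):
    """A spiral parameterization violates its invariants.

    The message always starts with the name of the offending field so that
    callers (e.g. the CLI) can surface it directly.
    """


def axis_rotation(axis) -> np.ndarray:
    """Rotation matrix taking the +z unit vector onto ``axis``.

    The minimal rotation (about ``z x axis``) is used; for ``axis == -z``
    the convention is a 180 degree rotation about x.  All traces are
    generated in the canonical frame (axis = +z, center = origin) and then
    mapped through this rotation, which makes axis handling exactly
    equivariant.
    """
    a = np.asarray(axis, dtype=float)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, a))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, a)
    k = np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])
    return np.eye(3) + k + (k @ k) * ((1.0 - c) / float(np.dot(v, v)))


@dataclass(frozen=True)
class Harmonic:
    """One term of the radius modulation r(phi) = r + a*cos(k*phi + psi)."""

    order: int
    amplitude: float
    phase: float = 0.0


@dataclass(frozen=True)
class SpiralSpec:
    """Full parameterization of one spiral family.

    Parameters
    ----------
    geometry : {"spherical", "cylindrical"}
    r : float
        Winding radius, nm.
    p : float
        Pitch: distance between consecutive turns along constant azimuth
        (great-circle arc on the sphere, axial distance on the cylinder), nm.
    phi0 : float
        Initial azimuthal offset, radians.
    center : 3-tuple of float
        Spiral center, nm.
    axis : 3-tuple of float
        Unit spiral/polar axis.
    theta_start, theta_end : float
        Polar-angle bounds measured from the axis ("north pole"), radians.
        Spherical geometry only.
    h : float or None
        Cylinder height, nm.  Cylindrical geometry only.
    n_entries : int
        Number of entry strands of the multi-start family (>= 1).
    rise : float
        Arc-length spacing between consecutive pseudoatoms, nm.
    harmonics : tuple of Harmonic
        Radius modulation terms.
    """

    geometry: str
    r: float
    p: float
    phi0: float = 0.0
    center: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    theta_start: float = 0.0
    theta_end: float = math.pi
    h: float | None = None
    n_entries: int = 1
    rise: float = DEFAULT_RISE
    harmonics: Tuple[Harmonic, ...] = ()

    def __post_init__(self):
        if self.geometry not in ("spherical", "cylindrical"):
            raise SpiralSpecError(
                f"geometry must be 'spherical' or 'cylindrical', got {self.geometry!r}"
            )
        if not self.r > 0:
            raise SpiralSpecError(f"r must be > 0, got {self.r}")
        if not self.p > 0:
            raise SpiralSpecError(f"p must be > 0, got {self.p}")
        if not self.rise > 0:
            raise SpiralSpecError(f"rise must be > 0, got {self.rise}")
        if int(self.n_entries) != self.n_entries or self.n_entries < 1:
            raise SpiralSpecError(f"n_entries must be an integer >= 1, got {self.n_entries}")
        axis = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(axis) - 1.0) > _AXIS_TOL:
            raise SpiralSpecError(f"axis must be a unit vector, |axis| = {np.linalg.norm(axis)}")
        if len(np.asarray(self.center, dtype=float)) != 3:
            raise SpiralSpecError("center must be a 3-vector")
        if self.geometry == "spherical":
            if not (0.0 <= self.theta_start <= self.theta_end <= math.pi + 1e-12):
                raise SpiralSpecError(
                    "theta_start/theta_end must satisfy 0 <= theta_start <= theta_end <= pi, "
                    f"got ({self.theta_start}, {self.theta_end})"
                )
        else:
            if self.h is None or not self.h > 0:
                raise SpiralSpecError(f"h must be > 0 for cylindrical spirals, got {self.h}")
        for harm in self.harmonics:
            if int(harm.order) != harm.order or harm.order < 1:
                raise SpiralSpecError(f"harmonics order must be a positive integer, got {harm.order}")

    # -- geometry helpers ---------------------------------------------------

    def radius_at(self, phi):
        """Winding radius at azimuth ``phi`` including harmonic modulation."""
        phi = np.asarray(phi, dtype=float)
        rad = np.full_like(phi, self.r, dtype=float)
        for harm in self.harmonics:
            rad = rad + harm.amplitude * np.cos(harm.order * phi + harm.phase)
        return rad

    def phi_range(self) -> Tuple[float, float]:
        """Azimuth interval swept by a single strand starting at ``phi0``."""
        if self.geometry == "spherical":
            scale = _TWO_PI * self.r / self.p
            return (self.phi0 + scale * self.theta_start, self.phi0 + scale * self.theta_end)
        return (self.phi0, self.phi0 + _TWO_PI * self.h / self.p)


@dataclass(frozen=True)
class Trace:
    """Ordered pseudoatom positions, one per base pair.

    ``points`` are emitted leading-end (5') first: from ``theta_start`` for
    spherical spirals and from z = 0 for cylindrical ones.  ``entry_index``
    labels the strand of a multi-entry family; within one strand the points
    stay in curve order.
    """

    points: np.ndarray
    entry_index: np.ndarray
    source_spec: SpiralSpec

    def __post_init__(self):
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float).reshape(-1, 3))
        object.__setattr__(self, "entry_index", np.asarray(self.entry_index, dtype=int).reshape(-1))
        if len(self.points) != len(self.entry_index):
            raise ValueError("points and entry_index must have equal length")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_strands(self) -> int:
        return int(self.entry_index.max()) + 1 if len(self) else 0

    def strand(self, k: int) -> np.ndarray:
        """Points of entry strand ``k`` in curve order."""
        return self.points[self.entry_index == k]

    def transformed(self, rotation=None, translation=None) -> "Trace":
        pts = self.points
        if rotation is not None:
            pts = pts @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            pts = pts + np.asarray(translation, dtype=float)
        return Trace(pts, self.entry_index.copy(), self.source_spec)

    def to_text(self, path) -> None:
        """Write a plain whitespace-delimited ``x y z entry_index`` file."""
        with open(path, "w") as fh:
            fh.write("# x_nm y_nm z_nm entry_index\n")
            for pt, k in zip(self.points, self.entry_index):
                fh.write(f"{pt[0]:.6f} {pt[1]:.6f} {pt[2]:.6f} {k:d}\n")


# ---------------------------------------------------------------------------
# curve evaluation


def _canonical_curve(spec: SpiralSpec, phis: np.ndarray) -> np.ndarray:
    """Evaluate the spiral in the canonical frame (axis = +z, center = 0)."""
    phis = np.asarray(phis, dtype=float)
    rad = spec.radius_at(phis)
    if spec.geometry == "spherical":
        theta = spec.p / (_TWO_PI * spec.r) * (phis - spec.phi0)
        st, ct = np.sin(theta), np.cos(theta)
        return np.stack([rad * st * np.cos(phis), rad * st * np.sin(phis), rad * ct], axis=-1)
    z = spec.p / _TWO_PI * (phis - spec.phi0)
    return np.stack([rad * np.cos(phis), rad * np.sin(phis), z], axis=-1)


def _world_curve(spec: SpiralSpec, phis: np.ndarray) -> np.ndarray:
    rot = axis_rotation(spec.axis)
    return _canonical_curve(spec, phis) @ rot.T + np.asarray(spec.center, dtype=float)


_MAX_DENSE = 1 << 20


def _equal_arc_phis(spec: SpiralSpec, phi_lo: float, phi_hi: float) -> np.ndarray:
    """Azimuth values giving points at equal arc-length steps of ``spec.rise``.

    The arc length is accumulated over a dense polyline (refined so the
    inversion error stays far below the 1% spacing tolerance) and inverted
    by monotone interpolation; returned azimuths are then evaluated on the
    exact curve, so every point lies on the spiral surface exactly.
    """
    if phi_hi - phi_lo < 1e-15:
        warnings.warn("degenerate spiral extent: emitting a single-point trace", stacklevel=3)
        return np.array([phi_lo])

    # first pass: crude length estimate to choose the dense resolution
    probe = np.linspace(phi_lo, phi_hi, 4097)
    length_est = float(np.sum(np.linalg.norm(np.diff(_canonical_curve(spec, probe), axis=0), axis=1)))
    n_dense = int(np.clip(24.0 * length_est / spec.rise, 4096, _MAX_DENSE))

    phis = np.linspace(phi_lo, phi_hi, n_dense + 1)
    pts = _canonical_curve(spec, phis)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(s[-1])
    n_points = int(math.floor(total / spec.rise + 1e-9)) + 1
    targets = np.arange(n_points) * spec.rise
    return np.interp(targets, s, phis)


def _check_radius_positive(spec: SpiralSpec, phi_lo: float, phi_hi: float) -> None:
    if not spec.harmonics:
        return
    probe = np.linspace(phi_lo, phi_hi, 8192)
    if float(spec.radius_at(probe).min()) <= 0.0:
        raise SpiralSpecError("harmonics drive the modulated radius r(phi) <= 0 within the spiral extent")


def _single_strand(spec: SpiralSpec) -> np.ndarray:
    phi_lo, phi_hi = spec.phi_range()
    _check_radius_positive(spec, phi_lo, phi_hi)
    phis = _equal_arc_phis(spec, phi_lo, phi_hi)
    return _world_curve(spec, phis)


# ---------------------------------------------------------------------------
# public generators


def make_spherical_trace(spec: SpiralSpec) -> Trace:
    """Trace a single spherical spiral.

    The polar angle follows ``theta = p/(2*pi*r) * (phi - phi0)`` so the
    great-circle distance between consecutive turns is the constant pitch
    ``p``.  Points are placed at equal arc-length steps of ``spec.rise``
    from ``theta_start`` (leading end) to ``theta_end``; point count is
    ``floor(L/rise) + 1`` with ``L`` the curve arc length.
    """
    if spec.geometry != "spherical":
        raise SpiralSpecError(f"geometry must be 'spherical', got {spec.geometry!r}")
    pts = _single_strand(spec)
    return Trace(pts, np.zeros(len(pts), dtype=int), spec)


def make_cylindrical_trace(spec: SpiralSpec) -> Trace:
    """Trace a single cylindrical spiral.

    The axial coordinate follows ``z = p/(2*pi) * (phi - phi0)`` from z = 0
    (leading end) to z = h, measured from ``center`` along ``axis``; each
    point sits at perpendicular distance ``r(phi)`` from the axis.
    """
    if spec.geometry != "cylindrical":
        raise SpiralSpecError(f"geometry must be 'cylindrical', got {spec.geometry!r}")
    pts = _single_strand(spec)
    return Trace(pts, np.zeros(len(pts), dtype=int), spec)


def make_multi_entry(spec: SpiralSpec) -> Trace:
    """Trace the full ``n_entries``-start family of ``spec``.

    Strand ``k`` uses initial offset ``phi0 + 2*pi*k/n_entries``; strands are
    concatenated in order and labelled through ``entry_index``.
    """
    single = make_spherical_trace if spec.geometry == "spherical" else make_cylindrical_trace
    chunks, labels = [], []
    for k in range(spec.n_entries):
        strand_spec = replace(spec, phi0=spec.phi0 + _TWO_PI * k / spec.n_entries)
        pts = single(strand_spec).points
        chunks.append(pts)
        labels.append(np.full(len(pts), k, dtype=int))
    return Trace(np.concatenate(chunks), np.concatenate(labels), spec)
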