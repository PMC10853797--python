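"""Analytic geometry of multi-start DNA spooling and capsid-size quantization.

These closed forms relate the spiral parameters (pitch ``p``, radius ``r``,
points of entry ``n_pe``) to interhelical packing distances, the number of
DNA turns in each end-cap dome, and the discrete spectrum of capsid inner
diameters set by the two integers ``n_pe`` and ``n_s``.

Note on the slope formula: the self-consistent form is
``theta_s = atan(p / (2*pi*r))`` — the rise of one turn over its
circumference.  (A variant without the ``2*pi`` factor does not reproduce
the 12 degree slope and the 2.46 nm intrashell distance that go with
``p = 25.1`` nm, ``r = 18.84`` nm, ``n_pe = 10``.)

Angles are degrees at this interface; lengths are nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "CapsidParams",
    "slope_angle",
    "intrashell_distance",
    "intershell_distance",
    "hexagonal_offset",
    "dome_turns",
    "min_conserving_radius",
    "portal_major_diameter",
    "capsid_inner_diameter",
    "diameter_survey",
    "DEFAULT_SHELL_SPACING",
    "DEFAULT_ARC_SPACING",
]

#: default intershell spacing, nm
DEFAULT_SHELL_SPACING = 2.3
#: default dome arc (turnaround ring) spacing, nm
DEFAULT_ARC_SPACING = 2.48


def slope_angle(p: float, r: float) -> float:
    """DNA slope (axial over tangential travel) of a winding with pitch ``p``
    and radius ``r``: ``atan(p / (2*pi*r))``, degrees."""
    if not p > 0:
        raise ValueError(f"p must be > 0, got {p}")
    if not r > 0:
        raise ValueError(f"r must be > 0, got {r}")
    return math.degrees(math.atan(p / (2.0 * math.pi * r)))


def intrashell_distance(p: float, n_pe: int, theta_s: float) -> float:
    """Perpendicular axis-to-axis distance between adjacent strands within
    one shell: ``(p / n_pe) * cos(theta_s)``; ``theta_s`` in degrees."""
    if n_pe < 1:
        raise ValueError(f"n_pe must be >= 1, got {n_pe}")
    return p / n_pe * math.cos(math.radians(theta_s))


def intershell_distance(d_intra: float, dr: float) -> float:
    """Perpendicular distance between nearest helices of adjacent shells.

    In hexagonally staggered packing a helix of the inner shell sits between
    two of the outer shell, half an intrashell spacing away laterally and
    ``dr`` away radially: ``sqrt((d_intra/2)**2 + dr**2)``.
    """
    if d_intra < 0 or dr < 0:
        raise ValueError("d_intra and dr must be >= 0")
    return math.hypot(d_intra / 2.0, dr)


def hexagonal_offset(n_pe: int) -> float:
    """Azimuthal offset between consecutive shells for hexagonal packing:
    ``360 / (2 * n_pe)`` degrees."""
    if n_pe < 1:
        raise ValueError(f"n_pe must be >= 1, got {n_pe}")
    return 360.0 / (2 * n_pe)


def dome_turns(n_pe: int) -> tuple[int, int]:
    """Turn counts in the two end-cap domes under nested-arc turnarounds.

    With an even number of entry points and the leading end sharing a cap
    with the shell-1-to-2 crossover, the opposite (distal) dome carries
    ``n_pe / 2`` turns and the tail dome ``(n_pe - 2) / 2`` — the leading
    and crossover ends account for the remaining two entry points.
    """
    if n_pe < 2 or n_pe % 2 != 0:
        raise ValueError(
            f"n_pe must be an even integer >= 2 (the dome-turn rules assume an even "
            f"number of entry points), got {n_pe}"
        )
    return n_pe // 2, (n_pe - 2) // 2


def min_conserving_radius(strand_sep: float, n_pe: int) -> float:
    """Smallest shell radius that can still host ``n_pe`` parallel strands
    separated by ``strand_sep``: ``strand_sep * n_pe / (2*pi)``."""
    if not strand_sep > 0:
        raise ValueError(f"strand_sep must be > 0, got {strand_sep}")
    if n_pe < 0:
        raise ValueError(f"n_pe must be >= 0, got {n_pe}")
    return strand_sep * n_pe / (2.0 * math.pi)


def _conical_slope_length(
    L_cs: Optional[float],
    n_s: Optional[int],
    s_shell: float,
    C_cs: Optional[float],
) -> float:
    if L_cs is not None:
        return L_cs
    if n_s is None or C_cs is None:
        raise ValueError("provide either L_cs or the pair (n_s, C_cs)")
    return n_s * s_shell + C_cs


def portal_major_diameter(
    L_cs: Optional[float] = None,
    theta_f: float = 51.0,
    D_mp: float = 4.7,
    n_s: Optional[int] = None,
    s_shell: float = DEFAULT_SHELL_SPACING,
    C_cs: Optional[float] = None,
) -> float:
    """Major diameter of the conical portal funnel.

    ``D_p = 2 * L_cs * sin(theta_f) + D_mp`` with the conical slope length
    given directly or through ``L_cs = n_s * s_shell + C_cs``.
    """
    length = _conical_slope_length(L_cs, n_s, s_shell, C_cs)
    return 2.0 * length * math.sin(math.radians(theta_f)) + D_mp


@dataclass(frozen=True)
class CapsidParams:
    """Quantization parameters of a spooled capsid.

    Either ``L_cs`` or the pair ``(n_s, C_cs)`` must be given; when both are
    present ``L_cs`` wins (the two printed parameterizations are not exactly
    consistent with each other).
    """

    n_pe: int
    theta_f: float
    D_mp: float
    w_tr: float
    n_s: Optional[int] = None
    C_cs: Optional[float] = None
    L_cs: Optional[float] = None
    s_shell: float = DEFAULT_SHELL_SPACING
    d_arc: float = DEFAULT_ARC_SPACING

    def __post_init__(self):
        if self.n_pe < 2 or self.n_pe % 2 != 0:
            raise ValueError(f"n_pe must be an even integer >= 2, got {self.n_pe}")
        if not 0.0 < self.theta_f < 90.0:
            raise ValueError(f"theta_f must be in (0, 90) degrees, got {self.theta_f}")
        for name in ("D_mp", "w_tr", "s_shell", "d_arc"):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.L_cs is None and (self.n_s is None or self.C_cs is None):
            raise ValueError("provide either L_cs or the pair (n_s, C_cs)")
        if self.n_s is not None and self.n_s < 1:
            raise ValueError(f"n_s must be >= 1, got {self.n_s}")

    @property
    def conical_slope_length(self) -> float:
        return _conical_slope_length(self.L_cs, self.n_s, self.s_shell, self.C_cs)


def capsid_inner_diameter(cp: CapsidParams) -> float:
    """Capsid inner diameter quantized in ``(n_pe, n_s)``.

    ``2 * d_arc * (n_pe/2 - 1) * cos(theta_f)
    + 2 * L_cs * sin(theta_f) + D_mp + w_tr``
    — the stacked dome turnaround arcs contribute the first term, the portal
    funnel the rest.
    """
    theta = math.radians(cp.theta_f)
    arcs = 2.0 * cp.d_arc * (cp.n_pe / 2.0 - 1.0) * math.cos(theta)
    funnel = 2.0 * cp.conical_slope_length * math.sin(theta)
    return arcs + funnel + cp.D_mp + cp.w_tr


def diameter_survey(
    n_pe_values: Iterable[int],
    n_s_values: Iterable[int],
    theta_f: float = 51.0,
    D_mp: float = 4.7,
    w_tr: float = 8.3,
    C_cs: float = -2.0,
    s_shell: float = DEFAULT_SHELL_SPACING,
    d_arc: float = DEFAULT_ARC_SPACING,
) -> pd.DataFrame:
    """Tabulate the discrete inner-diameter spectrum over (n_pe, n_s)."""
    rows = []
    for n_pe in n_pe_values:
        for n_s in n_s_values:
            cp = CapsidParams(
                n_pe=n_pe, theta_f=theta_f, D_mp=D_mp, w_tr=w_tr,
                n_s=n_s, C_cs=C_cs, s_shell=s_shell, d_arc=d_arc,
            )
            rows.append(
                {
                    "n_pe": n_pe,
                    "n_s": n_s,
                    "L_cs": cp.conical_slope_length,
                    "portal_major_diameter": portal_major_diameter(
                        n_s=n_s, s_shell=s_shell, C_cs=C_cs, theta_f=theta_f, D_mp=D_mp
                    ),
                    "inner_diameter": capsid_inner_diameter(cp),
                }
            )
    return pd.DataFrame(rows)
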