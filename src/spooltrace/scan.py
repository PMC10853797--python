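"""Grid scans and coordinate descent of spiral parameters against a map.

The optimization primitive is the systematic one-parameter grid scan;
coordinate descent cycles a list of scans until a full round moves no
parameter by more than its step.  Shell structure is read off the
objective-vs-radius curve as prominence-filtered local minima.

Angular scan bounds (phi0, theta_start, theta_end) are in degrees at this
interface; the underlying spec stores radians.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .density import DensityGrid, FitResult, fitting_energy
from .spiral import SpiralSpec, make_multi_entry

__all__ = [
    "ScanPlan",
    "ShellTable",
    "DescentResult",
    "scan_parameter",
    "coordinate_descent",
    "detect_shells",
    "results_frame",
]

#: scannable parameters; True marks angular parameters exposed in degrees
SCAN_PARAMETERS = {
    "r": False,
    "p": False,
    "phi0": True,
    "center_x": False,
    "center_y": False,
    "center_z": False,
    "theta_start": True,
    "theta_end": True,
    "h": False,
}

_MAX_STEPS = 10**6


@dataclass(frozen=True)
class ScanPlan:
    """One-parameter scan: ``parameter`` over [lo, hi] in steps of ``step``."""

    parameter: str
    lo: float
    hi: float
    step: float
    objective: str = "per_atom"

    def __post_init__(self):
        if self.parameter not in SCAN_PARAMETERS:
            raise ValueError(
                f"parameter must be one of {sorted(SCAN_PARAMETERS)}, got {self.parameter!r}"
            )
        if not self.lo < self.hi:
            raise ValueError(f"lo must be < hi, got ({self.lo}, {self.hi})")
        if not self.step > 0:
            raise ValueError(f"step must be > 0, got {self.step}")
        if (self.hi - self.lo) / self.step > _MAX_STEPS:
            raise ValueError("scan would exceed 10^6 grid points; increase step")
        if self.objective not in ("per_atom", "total"):
            raise ValueError(f"objective must be 'per_atom' or 'total', got {self.objective!r}")

    @property
    def values(self) -> np.ndarray:
        n = int(math.floor((self.hi - self.lo) / self.step + 1e-9)) + 1
        return self.lo + self.step * np.arange(n)


def apply_parameter(spec: SpiralSpec, parameter: str, value: float) -> SpiralSpec:
    """Return ``spec`` with one scannable parameter replaced.

    Angular parameters are given in degrees and stored in radians.
    """
    if parameter in ("center_x", "center_y", "center_z"):
        center = list(spec.center)
        center["xyz".index(parameter[-1])] = value
        return replace(spec, center=tuple(center))
    if SCAN_PARAMETERS.get(parameter, False):
        return replace(spec, **{parameter: math.radians(value)})
    return replace(spec, **{parameter: value})


def read_parameter(spec: SpiralSpec, parameter: str) -> float:
    if parameter in ("center_x", "center_y", "center_z"):
        return spec.center["xyz".index(parameter[-1])]
    value = getattr(spec, parameter)
    return math.degrees(value) if SCAN_PARAMETERS.get(parameter, False) else value


def scan_parameter(base: SpiralSpec, plan: ScanPlan, grid: DensityGrid) -> List[FitResult]:
    """Evaluate the fitting energy at every grid value of ``plan``.

    Results come back in ascending parameter order; the best is the lowest
    objective, with ties broken toward the lowest parameter value (which
    ``argmin_result`` implements by taking the first minimum).
    """
    results = []
    for value in plan.values:
        spec = apply_parameter(base, plan.parameter, value)
        trace = make_multi_entry(spec)
        results.append(fitting_energy(trace, grid))
    if all(res.outside_fraction >= 1.0 for res in results):
        raise ValueError(
            "every scanned trace lies fully outside the map; "
            "check the spiral center and extent against the map bounds"
        )
    return results


def argmin_result(results: Sequence[FitResult], objective: str = "per_atom") -> int:
    energies = np.array([res.objective(objective) for res in results])
    return int(np.argmin(energies))  # first occurrence = lowest parameter value


def results_frame(plan: ScanPlan, results: Sequence[FitResult]) -> pd.DataFrame:
    """Tabulate a scan as (value, energy_total, energy_per_atom, outside_fraction)."""
    return pd.DataFrame(
        {
            plan.parameter: plan.values[: len(results)],
            "energy_total": [r.energy_total for r in results],
            "energy_per_atom": [r.energy_per_atom for r in results],
            "outside_fraction": [r.outside_fraction for r in results],
        }
    )


@dataclass(frozen=True)
class DescentResult:
    """Outcome of a coordinate-descent run.

    ``rounds`` counts executed rounds including the final fixed-point
    confirmation; ``active_rounds`` counts only rounds that moved some
    parameter by more than its step (the optimization work proper).
    """

    fit: FitResult
    spec: SpiralSpec
    rounds: int
    active_rounds: int
    converged: bool
    trail: Tuple[Tuple[str, float, float], ...]  # (parameter, value, objective)


def coordinate_descent(
    base: SpiralSpec,
    plans: Sequence[ScanPlan],
    grid: DensityGrid,
    max_rounds: int = 8,
) -> DescentResult:
    """Cycle one-parameter scans, updating the spec to each scan argmin.

    Stops when a full round changes no parameter by more than its step, or
    after ``max_rounds`` rounds (flagged unconverged, no exception).
    """
    if not plans:
        raise ValueError("coordinate_descent needs at least one ScanPlan")
    spec = base
    trail: List[Tuple[str, float, float]] = []
    converged = False
    rounds = 0
    active_rounds = 0
    best_fit = None
    for rounds in range(1, max_rounds + 1):
        max_rel_change = 0.0
        for plan in plans:
            before = read_parameter(spec, plan.parameter)
            results = scan_parameter(spec, plan, grid)
            idx = argmin_result(results, plan.objective)
            value = float(plan.values[idx])
            spec = apply_parameter(spec, plan.parameter, value)
            best_fit = results[idx]
            trail.append((plan.parameter, value, results[idx].objective(plan.objective)))
            max_rel_change = max(max_rel_change, abs(value - before) / plan.step)
        if max_rel_change <= 1.0 + 1e-9:
            converged = True
            break
        active_rounds += 1
    return DescentResult(best_fit, spec, rounds, active_rounds, converged, tuple(trail))


@dataclass(frozen=True)
class ShellTable:
    """Detected winding shells from an objective-vs-radius curve."""

    radii: Tuple[float, ...]
    phi0_deg: Tuple[float, ...]
    energies: Tuple[float, ...]

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.radii, self.radii[1:])):
            raise ValueError("shell radii must be strictly increasing")

    def __len__(self) -> int:
        return len(self.radii)

    @property
    def mean_spacing(self) -> float:
        """Mean of consecutive radius differences, nm (nan for < 2 shells)."""
        if len(self.radii) < 2:
            return float("nan")
        return float(np.mean(np.diff(self.radii)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r": self.radii, "phi0_deg": self.phi0_deg, "energy": self.energies}
        )


def detect_shells(
    base: SpiralSpec,
    r_plan: ScanPlan,
    grid: DensityGrid,
    min_prominence: float = 0.05,
    phi0_step: float = 2.0,
) -> ShellTable:
    """Locate winding shells as prominent local minima of the r-scan curve.

    Minima must have prominence >= ``min_prominence * (max - min)`` of the
    curve.  Each detected radius is refined by a local phi0 scan over one
    multi-entry period (360 / n_entries degrees).
    """
    if r_plan.parameter != "r":
        raise ValueError(f"r_plan must scan parameter 'r', got {r_plan.parameter!r}")
    results = scan_parameter(base, r_plan, grid)
    curve = np.array([res.objective(r_plan.objective) for res in results])
    span = float(curve.max() - curve.min())
    if span == 0.0:
        warnings.warn("flat energy curve: no shells detected", stacklevel=2)
        return ShellTable((), (), ())
    minima, _ = find_peaks(-curve, prominence=min_prominence * span)
    if len(minima) == 0:
        warnings.warn("no local minima with requested prominence: no shells detected", stacklevel=2)
        return ShellTable((), (), ())

    period = 360.0 / base.n_entries
    radii, phis, energies = [], [], []
    for idx in minima:
        r_value = float(r_plan.values[idx])
        shell_spec = apply_parameter(base, "r", r_value)
        phi_plan = ScanPlan("phi0", 0.0, period, phi0_step, objective=r_plan.objective)
        phi_results = scan_parameter(shell_spec, phi_plan, grid)
        best = argmin_result(phi_results, r_plan.objective)
        radii.append(r_value)
        phis.append(float(phi_plan.values[best] % period))
        energies.append(phi_results[best].objective(r_plan.objective))
    return ShellTable(tuple(radii), tuple(phis), tuple(energies))
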