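"""In-silico experiment batteries: injection timing, location, diffusivity.

Each battery runs a matched vehicle simulation plus labelled treatment
scenarios on identical grid/solver settings and summarises every scenario
by the shift in time to 50% closure,

    shift = t50(scenario) - t50(vehicle),

so negative shifts are accelerations. Default scenario settings follow the
murine protocol: 100 ug per injection at the wound border (r = 5 mm) with
the literature mRNA diffusivity 3e-9 cm^2/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import SimulationResult, solve, time_to_closure
from .mrna import InjectionEvent
from .params import MRNAParameters, RadialGrid, ScaleSet, WoundModelParameters

__all__ = [
    "Scenario",
    "ClosureShift",
    "run_battery",
    "timing_sweep",
    "location_sweep",
    "diffusivity_sweep",
    "chemoattractant_peak_depth",
    "shifts_frame",
]

DEFAULT_TIMING_DAYS = (0.0, 3.0, 6.0, (0.0, 3.0))
DEFAULT_RADII_MM = (5.0, 4.0, 3.0, 2.0, 1.0)
DEFAULT_DIFFUSIVITIES = (0.0, 3e-9, 1e-7, 1e-5)


@dataclass(frozen=True)
class Scenario:
    label: str
    params: WoundModelParameters = field(default_factory=WoundModelParameters)
    mrna_params: MRNAParameters = field(default_factory=MRNAParameters)
    injections: tuple = ()
    t_end_days: float = 36.0
    output_dt_days: float = 0.1
    snapshot_days: tuple = ()

    def run(self, grid: RadialGrid, scales: ScaleSet,
            stop_open_frac: float | None = None) -> SimulationResult:
        return solve(self.params, self.mrna_params, self.injections,
                     self.t_end_days, self.output_dt_days,
                     self.snapshot_days, grid, scales,
                     stop_open_frac=stop_open_frac)


@dataclass(frozen=True)
class ClosureShift:
    label: str
    t50_vehicle: float
    t50_scenario: float

    @property
    def reached(self) -> bool:
        return math.isfinite(self.t50_vehicle) and math.isfinite(
            self.t50_scenario)

    @property
    def shift_days(self) -> float:
        """t50(scenario) - t50(vehicle); negative = acceleration; NaN if
        either run never reaches 50% closure ("not reached")."""
        return self.t50_scenario - self.t50_vehicle


def _dedupe_labels(scenarios: Sequence[Scenario]) -> None:
    labels = [s.label for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate scenario labels in battery: {labels}")


def run_battery(
    scenarios: Sequence[Scenario],
    vehicle: Scenario | None = None,
    grid: RadialGrid | None = None,
    scales: ScaleSet | None = None,
    remaining_fraction: float = 0.5,
) -> list[tuple[Scenario, SimulationResult, ClosureShift]]:
    """Run the vehicle once and every scenario once; summarise t50 shifts.

    All runs share the grid and scales. Scenarios with snapshots requested
    are integrated to their full horizon; otherwise runs stop shortly after
    the closure target to save time (the shift only needs t50).
    """
    grid = grid or RadialGrid()
    scales = scales or ScaleSet()
    scenarios = list(scenarios)
    _dedupe_labels(scenarios)
    if vehicle is None:
        base = scenarios[0]
        vehicle = Scenario("vehicle", base.params, MRNAParameters.none(),
                           (), base.t_end_days, base.output_dt_days)
    stop = 0.9 * remaining_fraction
    veh_res = vehicle.run(grid, scales,
                          stop_open_frac=None if vehicle.snapshot_days
                          else stop)
    t50_veh = time_to_closure(veh_res, remaining_fraction)
    out = []
    for sc in scenarios:
        res = sc.run(grid, scales,
                     stop_open_frac=None if sc.snapshot_days else stop)
        t50 = time_to_closure(res, remaining_fraction)
        out.append((sc, res, ClosureShift(sc.label, t50_veh, t50)))
    return out


def shifts_frame(battery: list) -> pd.DataFrame:
    rows = []
    for _, _, shift in battery:
        rows.append({
            "scenario": shift.label,
            "t50_vehicle_days": shift.t50_vehicle,
            "t50_scenario_days": shift.t50_scenario,
            "shift_days": shift.shift_days,
            "reached": shift.reached,
        })
    return pd.DataFrame(rows)


def _day_label(days) -> str:
    if np.isscalar(days):
        days = (days,)
    return "day " + "+".join(f"{d:g}" for d in days)


def timing_sweep(
    days: Sequence = DEFAULT_TIMING_DAYS,
    dose_ug: float = 100.0,
    radius_mm: float = 5.0,
    params: WoundModelParameters | None = None,
    mrna_params: MRNAParameters | None = None,
    t_end_days: float = 36.0,
) -> list[Scenario]:
    """Border injections delivered on day 0 / 3 / 6 / 0 and 3."""
    params = params or WoundModelParameters()
    mrna_params = mrna_params or MRNAParameters()
    out = []
    for d in days:
        sched = (d,) if np.isscalar(d) else tuple(d)
        inj = tuple(InjectionEvent(day, radius_mm, dose_ug) for day in sched)
        out.append(Scenario(_day_label(d), params, mrna_params, inj,
                            t_end_days))
    return out


def location_sweep(
    radii_mm: Sequence[float] = DEFAULT_RADII_MM,
    days: Sequence[float] = (0.0,),
    dose_ug: float = 100.0,
    params: WoundModelParameters | None = None,
    mrna_params: MRNAParameters | None = None,
    t_end_days: float = 36.0,
) -> list[Scenario]:
    """Injections at radii from the border (5 mm) toward the centre (1 mm)."""
    params = params or WoundModelParameters()
    mrna_params = mrna_params or MRNAParameters()
    out = []
    for r in radii_mm:
        inj = tuple(InjectionEvent(d, r, dose_ug) for d in days)
        out.append(Scenario(f"r={r:g}mm {_day_label(tuple(days))}",
                            params, mrna_params, inj, t_end_days))
    return out


def diffusivity_sweep(
    diffusivities_cm2_s: Sequence[float] = DEFAULT_DIFFUSIVITIES,
    days: Sequence[float] = (0.0,),
    dose_ug: float = 100.0,
    radius_mm: float = 5.0,
    params: WoundModelParameters | None = None,
    mrna_params: MRNAParameters | None = None,
    t_end_days: float = 36.0,
) -> list[Scenario]:
    """Border injections under perturbed mRNA diffusion coefficients."""
    params = params or WoundModelParameters()
    mrna_params = mrna_params or MRNAParameters()
    inj = tuple(InjectionEvent(d, radius_mm, dose_ug) for d in days)
    out = []
    for dm in diffusivities_cm2_s:
        out.append(Scenario(
            f"Dm={dm:g} {_day_label(tuple(days))}",
            params, mrna_params.replace(D_m_cm2_s=dm), inj, t_end_days))
    return out


def chemoattractant_peak_depth(
    result: SimulationResult,
    day: float,
    scales: ScaleSet | None = None,
    min_prominence: float = 1e-9,
) -> float:
    """Depth (mm inside the border) of the chemoattractant maximum at a
    snapshot day: R * (1 - argmax_r a).

    The peak node is refined by parabolic interpolation. A profile that is
    maximal at the border gives depth 0; a flat profile has no interior
    peak and raises.
    """
    scales = scales or ScaleSet()
    if day not in result.snapshots:
        raise KeyError(f"no snapshot stored at day {day}")
    a = result.snapshots[day].a
    N = a.shape[0]
    if float(a.max() - a.min()) <= min_prominence:
        raise ValueError("flat chemoattractant profile: no interior peak")
    j = int(np.argmax(a))
    r = np.linspace(0.0, 1.0, N)
    r_peak = r[j]
    if 0 < j < N - 1:
        y0, y1, y2 = a[j - 1], a[j], a[j + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0.0:
            r_peak += 0.5 * (y0 - y2) / denom * (r[1] - r[0])
    return float(scales.R_mm * (1.0 - r_peak))
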