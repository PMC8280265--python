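"""Local sensitivity analysis of percent open wound area to model parameters.

Each parameter is perturbed by +/-10% one at a time and the normalized
sensitivity coefficient

    S = (y_i - y_o) / |p_i - p_o| * p_o / y_o

is computed, where y is the percent open wound area of the vehicle run at
the evaluation day (default 18). The absolute value in the denominator
makes the sign of S follow the sign of the output change: S > 0 means the
perturbation enlarges the open wound (slows healing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BlowupError, solve
from .params import MRNAParameters, RadialGrid, ScaleSet, WoundModelParameters

__all__ = ["SensitivityRecord", "sensitivity_coefficient", "sensitivity_scan"]


@dataclass(frozen=True)
class SensitivityRecord:
    parameter: str
    direction: str          # "+10%" or "-10%"
    S: float                # NaN if the perturbed run was infeasible
    y_base: float
    y_pert: float
    note: str = ""

    @property
    def feasible(self) -> bool:
        return np.isfinite(self.S)


def sensitivity_coefficient(y_base: float, y_pert: float,
                            p_base: float, p_pert: float) -> float:
    if y_base <= 0:
        raise ValueError("y_base must be > 0 (S undefined at zero output)")
    if p_base <= 0:
        raise ValueError("p_base must be > 0")
    if p_pert == p_base:
        raise ValueError("perturbed parameter equals baseline")
    return (y_pert - y_base) / abs(p_pert - p_base) * p_base / y_base


def _percent_open_at(params: WoundModelParameters, eval_day: float,
                     grid: RadialGrid, scales: ScaleSet,
                     output_dt_days: float) -> float:
    res = solve(params, MRNAParameters.none(), t_end_days=eval_day,
                output_dt_days=output_dt_days, grid=grid, scales=scales)
    return float(res.percent_open[-1])


def sensitivity_scan(
    params: WoundModelParameters | None = None,
    eval_day: float = 18.0,
    rel_step: float = 0.10,
    grid: RadialGrid | None = None,
    scales: ScaleSet | None = None,
    names: tuple[str, ...] | None = None,
    output_dt_days: float = 0.25,
) -> list[SensitivityRecord]:
    """One-at-a-time +/-10% scan over the model constants (vehicle runs).

    A perturbation that produces an invalid parameter set (e.g. r_tilde
    pushed to >= 1) or a blow-up is flagged with S = NaN and the scan
    continues. Deterministic: repeated scans are bit-identical.
    """
    params = params or WoundModelParameters()
    grid = grid or RadialGrid()
    scales = scales or ScaleSet()
    names = names or WoundModelParameters.SCAN_NAMES
    y_base = _percent_open_at(params, eval_day, grid, scales, output_dt_days)
    records: list[SensitivityRecord] = []
    for name in names:
        p_base = getattr(params, name)
        for sign, label in ((+1.0, "+10%"), (-1.0, "-10%")):
            p_pert = p_base * (1.0 + sign * rel_step)
            try:
                pert = params.replace(**{name: p_pert})
                y_pert = _percent_open_at(pert, eval_day, grid, scales,
                                          output_dt_days)
            except (ValueError, BlowupError) as exc:
                records.append(SensitivityRecord(
                    name, label, float("nan"), y_base, float("nan"),
                    note=f"infeasible: {exc}"))
                continue
            if p_base == 0.0:
                # a zero baseline cannot be perturbed multiplicatively
                records.append(SensitivityRecord(
                    name, label, float("nan"), y_base, y_pert,
                    note="zero baseline"))
                continue
            S = sensitivity_coefficient(y_base, y_pert, p_base, p_pert)
            records.append(SensitivityRecord(name, label, S, y_base, y_pert))
    return records


def to_frame(records: list[SensitivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "direction": r.direction,
                "S": r.S,
                "y_base": r.y_base,
                "y_pert": r.y_pert,
                "note": r.note,
            }
            for r in records
        ]
    )


def rank_by_magnitude(records: list[SensitivityRecord]) -> list[str]:
    """Parameter names ordered by the larger |S| of the two directions."""
    best: dict[str, float] = {}
    for r in records:
        if r.feasible:
            best[r.parameter] = max(best.get(r.parameter, 0.0), abs(r.S))
    return sorted(best, key=best.get, reverse=True)
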