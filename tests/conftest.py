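"""Shared fixtures. Heavy PDE runs are session-scoped and reused."""

from __future__ import annotations

import pytest

from woundangio import (
    InjectionEvent,
    MRNAParameters,
    RadialGrid,
    ScaleSet,
    WoundModelParameters,
    solve,
)


@pytest.fixture(scope="session")
def grid201():
    return RadialGrid(n_nodes=201)


@pytest.fixture(scope="session")
def grid101():
    return RadialGrid(n_nodes=101)


@pytest.fixture(scope="session")
def grid61():
    return RadialGrid(n_nodes=61)


@pytest.fixture(scope="session")
def scales():
    return ScaleSet()


@pytest.fixture(scope="session")
def fitted_params():
    return WoundModelParameters()


@pytest.fixture(scope="session")
def vehicle_result(fitted_params, grid201, scales):
    """Full 36-day vehicle run at production resolution, with snapshots
    every two days for front/crowding checks."""
    return solve(
        fitted_params,
        MRNAParameters.none(),
        t_end_days=36.0,
        output_dt_days=0.1,
        snapshot_days=tuple(float(d) for d in range(2, 37, 2)) + (35.0,),
        grid=grid201,
        scales=scales,
    )


@pytest.fixture(scope="session")
def timing_battery(fitted_params, grid201, scales):
    """Border-injection timing scenarios (full default conditions)."""
    mr = MRNAParameters()
    out = {}
    for label, events in {
        "day0": (InjectionEvent(0.0),),
        "day3": (InjectionEvent(3.0),),
        "day6": (InjectionEvent(6.0),),
        "day0+3": (InjectionEvent(0.0), InjectionEvent(3.0)),
    }.items():
        out[label] = solve(
            fitted_params, mr, events, t_end_days=36.0, output_dt_days=0.1,
            grid=grid201, scales=scales, stop_open_frac=0.4,
        )
    return out
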