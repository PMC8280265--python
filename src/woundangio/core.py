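"""Cylindrical reaction-diffusion-chemotaxis model of wound angiogenesis.

Dimensionless fields on the unit disc (radius scaled by R = 5 mm, time by
R^2/D_a = 2.89 days):

* ``n`` -- sprouting capillary-tip density,
* ``a`` -- chemoattractant (macrophage-derived proangiogenic factors plus
  VEGF-A translated from injected mRNA),
* ``b`` -- blood vessel density,
* ``m`` -- injected mRNA concentration (scaled by 2500 ug/cm^3).

Tips diffuse weakly and chemotax up the chemoattractant gradient; the
chemoattractant is produced wherever the tissue is unvascularised
(b < 1, a tanh switch of width delta), removed by the vasculature, and lost
through the wound edge; vessels are laid down by the inward-sweeping tip
flux ("snail trail"); mRNA diffuses slowly, degrades first order, and
generates chemoattractant at rate k_gen. The wound is "open" where
b < 0.1, and percent open wound area is tracked against its day-0 value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .params import (
    FieldState,
    MRNAParameters,
    RadialGrid,
    ScaleSet,
    WoundModelParameters,
)

__all__ = [
    "initial_conditions",
    "rhs",
    "apply_boundary",
    "step",
    "solve",
    "open_wound_fraction",
    "time_to_closure",
    "SimulationResult",
    "BlowupError",
]

_FIELD_NAMES = ("n", "a", "b", "m")
MAX_FIELD = 1e6


class BlowupError(RuntimeError):
    """Raised when an explicit step produces a non-finite or huge field value."""


def _edge_polynomial(r: np.ndarray, amplitude: float, r_tilde: float) -> np.ndarray:
    """Cubic margin profile: amplitude/r_tilde^3 (r - r~)(2r^2 - r~ r - r~^2).

    Zero for r <= r_tilde, monotone on the inflammation annulus (r_tilde, 1].
    """
    out = np.zeros_like(r)
    mask = r > r_tilde
    rr = r[mask]
    out[mask] = (amplitude / r_tilde**3) * (rr - r_tilde) * (
        2.0 * rr**2 - r_tilde * rr - r_tilde**2
    )
    return out


def initial_conditions(
    params: WoundModelParameters, grid: RadialGrid
) -> FieldState:
    """Fields at t = 0: tip/vessel margin profiles, no chemoattractant or mRNA.

    The wound margin has penetrated to the dimensionless radius r_tilde, so
    tips and vessels follow cubic profiles across the annulus (r_tilde, 1]
    and the interior holds n = 0, b = b_tilde. The edge node carries the
    Dirichlet boundary values (n_hat, b_hat), which override the polynomials
    at r = 1.
    """
    r = grid.r
    n = _edge_polynomial(r, params.n_hat, params.r_tilde)
    b = _edge_polynomial(r, params.b_hat - params.b_tilde, params.r_tilde)
    b[r <= params.r_tilde] = params.b_tilde
    b[r > params.r_tilde] += params.b_tilde
    a = np.zeros_like(r)
    m = np.zeros_like(r)
    n[-1] = params.n_hat
    b[-1] = params.b_hat
    return FieldState(0.0, n, a, b, m)


def _kernel_args(params: WoundModelParameters, mrna: MRNAParameters,
                 scales: ScaleSet):
    return (
        params.lambda0, params.lambda1, params.lambda2, params.mu_n,
        params.chi, params.n_hat, params.alpha,
        params.lambda4, params.lambda5, params.lambda7, params.delta,
        params.mu_b, params.b_hat,
        mrna.dm_ratio(scales), mrna.k1_dimless(scales), mrna.lambda8,
        mrna.k_gen,
    )


def rhs(
    state: FieldState,
    params: WoundModelParameters,
    mrna_params: MRNAParameters | None = None,
    grid: RadialGrid | None = None,
    scales: ScaleSet | None = None,
):
    """Time derivatives (dn, da, db, dm) of all fields at the current state.

    Interior nodes receive the full discretised operators; the edge entries
    of dn and db are zero because n(1, t) and b(1, t) are Dirichlet values.
    """
    scales = scales or ScaleSet()
    mrna_params = mrna_params or MRNAParameters.none()
    N = state.n.shape[0]
    grid = grid or RadialGrid(n_nodes=N)
    if grid.n_nodes != N:
        raise ValueError("grid size does not match state arrays")
    for name in _FIELD_NAMES:
        u = getattr(state, name)
        if not np.all(np.isfinite(u)):
            j = int(np.argmax(~np.isfinite(u)))
            raise BlowupError(f"non-finite value in field '{name}' at node {j}")
    (lam0, lam1, lam2, mu_n, chi, _n_hat, _alpha, lam4, lam5, lam7, delta,
     mu_b, b_hat, dm_ratio, k1_nd, lam8, k_gen) = _kernel_args(
        params, mrna_params, scales)
    Jn = np.empty(N - 1)
    dn, da, db, dm = (np.empty(N) for _ in range(4))
    _kernels.compute_rhs(
        state.n, state.a, state.b, state.m, grid.dr,
        lam0, lam1, lam2, mu_n, chi, lam4, lam5, lam7, delta, mu_b, b_hat,
        dm_ratio, k1_nd, lam8, k_gen, Jn, dn, da, db, dm,
    )
    return dn, da, db, dm


def apply_boundary(
    state: FieldState,
    params: WoundModelParameters,
    mrna_params: MRNAParameters | None = None,
    t: float | None = None,
) -> FieldState:
    """Impose boundary values on a state (in place) and return it.

    r = 0 carries symmetry (zero gradient) for every field -- built into the
    interior operators, nothing to set. At r = 1, n and b take their
    Dirichlet values n_hat e^{-alpha t} and b_hat; the Robin conditions for
    a and m are flux conditions applied inside the update stencils.
    """
    if t is None:
        t = state.t
    state.n[-1] = params.n_hat * math.exp(-params.alpha * t)
    state.b[-1] = params.b_hat
    return state


def step(
    state: FieldState,
    params: WoundModelParameters,
    mrna_params: MRNAParameters | None = None,
    grid: RadialGrid | None = None,
    scales: ScaleSet | None = None,
    dt: float | None = None,
):
    """One explicit step; returns (new_state, info dict).

    ``info`` reports the dt used and the clipped negative mass per field.
    With dt = 0 the state is returned unchanged (identity).
    """
    scales = scales or ScaleSet()
    mrna_params = mrna_params or MRNAParameters.none()
    grid = grid or RadialGrid(n_nodes=state.n.shape[0])
    new = state.copy()
    args = _kernel_args(params, mrna_params, scales)
    clip = np.zeros(4)
    if dt is None:
        dt = _kernels._stable_dt(
            new.n, new.a, new.b, grid.dr, params.mu_n, params.chi,
            params.mu_b, mrna_params.dm_ratio(scales), params.lambda0,
            params.lambda2, params.lambda4, params.lambda5,
            grid.safety, grid.adv_safety,
        )
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt > 0:
        t, _, sf, sj = _kernels.advance(
            new.n, new.a, new.b, new.m, new.t, new.t + dt, grid.dr,
            *args, grid.safety, grid.adv_safety, MAX_FIELD, clip,
        )
        new.t = t
        if sf >= 0:
            raise BlowupError(
                f"field '{_FIELD_NAMES[sf]}' blew up at node {sj}, t={t:.6g}"
            )
    info = {"dt": dt, "clipped_mass": dict(zip(_FIELD_NAMES, clip))}
    return new, info


def open_wound_fraction(state_or_b, threshold: float = 0.1) -> float:
    """Open-wound area fraction: measure of the region where b < threshold,
    as a fraction of the full initial wound area pi R^2.

    The open region is the (possibly disconnected) set {r : b(r) < threshold};
    its area is integrated with b taken piecewise linear between nodes, so
    threshold crossings land at sub-cell positions. For a monotone front this
    reduces to r*^2 with r* the outermost crossing radius. Returns 0 if
    b >= threshold everywhere and 1 if b < threshold on the whole disc.
    """
    b = state_or_b.b if isinstance(state_or_b, FieldState) else np.asarray(
        state_or_b, dtype=float)
    N = b.shape[0]
    dr = 1.0 / (N - 1)
    area = 0.0
    for j in range(N - 1):
        b0, b1 = b[j], b[j + 1]
        r0 = j * dr
        lo, hi = 0.0, 1.0  # open sub-interval of the cell, in local coords
        if b0 < threshold and b1 < threshold:
            pass
        elif b0 >= threshold and b1 >= threshold:
            continue
        else:
            s = (threshold - b0) / (b1 - b0)
            if b0 < threshold:
                hi = s
            else:
                lo = s
        # integral of 2 r dr over [r0 + lo*dr, r0 + hi*dr]
        ra, rb = r0 + lo * dr, r0 + hi * dr
        area += rb * rb - ra * ra
    return float(min(area, 1.0))


def time_to_closure(result: "SimulationResult", remaining_fraction: float = 0.5
                    ) -> float:
    """First time (days) the open area falls to ``remaining_fraction`` of its
    initial value, linearly interpolated between output points.

    Returns 0.0 if already at/below the target at t = 0, and NaN (sentinel
    "not reached") if the series never crosses; the last value is available
    as ``result.open_area_fraction[-1]``.
    """
    if not 0.0 < remaining_fraction <= 1.0:
        raise ValueError("remaining_fraction must be in (0, 1]")
    f = np.asarray(result.open_area_fraction, dtype=float)
    t = np.asarray(result.times_days, dtype=float)
    if f.size == 0:
        raise ValueError("empty result")
    target = remaining_fraction * f[0]
    if f[0] <= target:
        return 0.0
    idx = np.nonzero(f <= target)[0]
    if idx.size == 0:
        return float("nan")
    i = int(idx[0])
    f0, f1 = f[i - 1], f[i]
    if f1 == f0:
        return float(t[i])
    return float(t[i - 1] + (t[i] - t[i - 1]) * (f0 - target) / (f0 - f1))


@dataclass
class SimulationResult:
    """Time series of the open-wound metric plus requested field snapshots."""

    times_days: np.ndarray
    open_area_fraction: np.ndarray
    snapshots: dict = field(default_factory=dict)   # day -> FieldState
    a_total: np.ndarray | None = None               # dimensionless mass of a
    m_total: np.ndarray | None = None
    clipped_mass: dict | None = None
    n_steps: int = 0
    stopped_early: bool = False

    @property
    def percent_open(self) -> np.ndarray:
        """Open area as percent of the day-0 open area (day 0 = 100%)."""
        f = self.open_area_fraction
        return 100.0 * f / f[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.times_days, "open_area_pct": self.percent_open}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def solve(
    params: WoundModelParameters,
    mrna_params: MRNAParameters | None = None,
    injections: Sequence = (),
    t_end_days: float = 36.0,
    output_dt_days: float = 0.1,
    snapshot_days: Sequence[float] = (),
    grid: RadialGrid | None = None,
    scales: ScaleSet | None = None,
    stop_open_frac: float | None = None,
) -> SimulationResult:
    """Integrate the coupled system from t = 0, applying injections on schedule.

    ``injections`` is a sequence of :class:`~woundangio.mrna.InjectionEvent`;
    each deposit is applied exactly when the solver reaches its day. Output
    (open-area fraction and the a/m mass ledgers) is recorded every
    ``output_dt_days``; full field snapshots at ``snapshot_days``. If
    ``stop_open_frac`` is given, integration stops once the open fraction
    falls to that multiple of its initial value (used for closure-time
    scans).
    """
    from .mrna import deposit_dose  # local import to avoid a cycle

    scales = scales or ScaleSet()
    mrna_params = mrna_params or MRNAParameters.none()
    grid = grid or RadialGrid()
    if t_end_days <= 0:
        raise ValueError("t_end_days must be > 0")

    state = initial_conditions(params, grid)
    args = _kernel_args(params, mrna_params, scales)
    clip = np.zeros(4)
    vols = grid.cell_volumes

    out_days = np.arange(0.0, t_end_days + 1e-9, output_dt_days)
    snapshot_days = sorted(set(float(d) for d in snapshot_days))
    events = sorted(injections, key=lambda e: e.day)
    for e in events:
        if e.day > t_end_days:
            raise ValueError(f"injection at day {e.day} beyond t_end_days")

    # breakpoints: output times, snapshot times and injection times (days)
    breaks = sorted(set(out_days.tolist())
                    | set(snapshot_days)
                    | set(float(e.day) for e in events))

    times, fractions, a_tot, m_tot = [], [], [], []
    snapshots = {}
    n_steps = 0
    stopped = False
    f0 = None

    def record(day):
        nonlocal f0
        f = open_wound_fraction(state, params.closure_threshold)
        if f0 is None:
            f0 = f
        times.append(day)
        fractions.append(f)
        a_tot.append(float(vols @ state.a))
        m_tot.append(float(vols @ state.m))
        return f

    is_out = {float(d) for d in out_days}
    for day in breaks:
        t_target = day / scales.time_scale_days
        if t_target > state.t:
            t, steps, sf, sj = _kernels.advance(
                state.n, state.a, state.b, state.m, state.t, t_target,
                grid.dr, *args, grid.safety, grid.adv_safety, MAX_FIELD, clip,
            )
            state.t = t
            n_steps += steps
            if sf >= 0:
                raise BlowupError(
                    f"field '{_FIELD_NAMES[sf]}' blew up at node {sj}, "
                    f"day {t * scales.time_scale_days:.3f}"
                )
        for e in events:
            if e.day == day:
                deposit_dose(state, e, scales, grid)
        if day in is_out:
            f = record(day)
            if (stop_open_frac is not None and f0 is not None
                    and f <= stop_open_frac * f0 and day > 0):
                stopped = True
        if day in snapshot_days:
            snapshots[day] = state.copy()
        if stopped:
            break

    return SimulationResult(
        times_days=np.asarray(times),
        open_area_fraction=np.asarray(fractions),
        snapshots=snapshots,
        a_total=np.asarray(a_tot),
        m_total=np.asarray(m_tot),
        clipped_mass=dict(zip(_FIELD_NAMES, clip)),
        n_steps=n_steps,
        stopped_early=stopped,
    )
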