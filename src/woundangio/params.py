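"""Parameter containers and physical scales for the wound angiogenesis model.

All PDE parameters are dimensionless. The radial coordinate is scaled by the
wound radius R (5 mm) and time by R^2/D_a, the diffusion time of the
chemoattractant across the wound (2.89 days for D_a = 1e-6 cm^2/s). mRNA
concentration is scaled by the injectate concentration, 100 ug in 40 uL
(2500 ug/cm^3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "ScaleSet",
    "WoundModelParameters",
    "MRNAParameters",
    "RadialGrid",
    "FieldState",
    "CLOSURE_THRESHOLD",
]

#: Dimensionless vessel density below which tissue counts as open wound.
CLOSURE_THRESHOLD = 0.1

_SECONDS_PER_DAY = 86400.0
_SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class ScaleSet:
    """Dimensional scales bridging dimensionless model units and lab units.

    Attributes
    ----------
    R_mm : wound radius in mm (initial wound edge sits at r = R).
    D_a_cm2_s : chemoattractant diffusivity, cm^2/s.
    mrna_conc_scale : mRNA concentration scale, ug/cm^3 (100 ug / 40 uL).
    thickness_mm : effective tissue thickness used to lump the depth
        dimension; converts deposited ug into a depth-averaged concentration.
        The default is calibrated so that the healed-wound uniform-dose fit
        of the VEGF generation rate reproduces the published dimensionless
        value 1.53e5 under the identity chemoattractant <-> pg/mg reading
        (see docs/methods.md).
    """

    R_mm: float = 5.0
    D_a_cm2_s: float = 1e-6
    mrna_conc_scale: float = 2500.0
    thickness_mm: float = 2.50721

    def __post_init__(self):
        if self.R_mm <= 0 or self.D_a_cm2_s <= 0 or self.mrna_conc_scale <= 0:
            raise ValueError("scales must be positive")
        if self.thickness_mm <= 0:
            raise ValueError("thickness_mm must be positive")

    @property
    def R_cm(self) -> float:
        return self.R_mm / 10.0

    @property
    def time_scale_s(self) -> float:
        """R^2/D_a in seconds."""
        return self.R_cm**2 / self.D_a_cm2_s

    @property
    def time_scale_hours(self) -> float:
        return self.time_scale_s / _SECONDS_PER_HOUR

    @property
    def time_scale_days(self) -> float:
        """Days per dimensionless time unit (2.89 d with defaults)."""
        return self.time_scale_s / _SECONDS_PER_DAY

    @property
    def v_eff_cm3(self) -> float:
        """Effective lumped tissue volume: domain area x thickness."""
        return math.pi * self.R_cm**2 * (self.thickness_mm / 10.0)

    def days_to_dimless(self, days):
        return np.asarray(days, dtype=float) / self.time_scale_days

    def dimless_to_days(self, t):
        return np.asarray(t, dtype=float) * self.time_scale_days


# Table of dimensionless model constants, cylindrical geometry. The three
# bracketed entries (lambda0, lambda1, chi) default to the values obtained by
# calibrating the vehicle model against the murine wound-closure data; the
# pre-calibration cylindrical values are available via `unfitted()`.
@dataclass(frozen=True)
class WoundModelParameters:
    lambda0: float = 856.0      # tip-tip anastomosis rate [fitted; baseline 200]
    lambda1: float = 3860.0     # tip production (budding) rate [fitted; baseline 800]
    lambda2: float = 40.0       # sprouting-tip decay rate
    mu_n: float = 1e-3          # tip random motility
    chi: float = 0.146          # chemotaxis coefficient [fitted; baseline 0.1]
    n_hat: float = 2.0          # tip density at the wound edge
    alpha: float = 10.0         # decay rate of edge tip density
    lambda4: float = 400.0      # chemoattractant decay
    lambda5: float = 40.0       # chemoattractant removal via vasculature
    lambda7: float = 20.0       # blood-borne removal rate at the edge
    delta: float = 0.01         # width of the chemoattractant production switch
    mu_b: float = 0.5e-3        # vessel random motility
    b_hat: float = 1.5          # vessel density at the wound edge
    r_tilde: float = 0.95       # dimensionless radius of the open wound at t=0
    b_tilde: float = 0.0        # interior vessel density at t=0 (avascular wound)
    closure_threshold: float = CLOSURE_THRESHOLD

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v}")
        if not 0.0 < self.r_tilde < 1.0:
            raise ValueError(f"r_tilde must lie in (0, 1), got {self.r_tilde}")
        if self.b_tilde >= self.closure_threshold:
            raise ValueError(
                "b_tilde must be below the closure threshold "
                f"({self.closure_threshold}), else the wound starts closed"
            )

    @classmethod
    def unfitted(cls, **overrides) -> "WoundModelParameters":
        """Cylindrical parameter column before calibration."""
        base = dict(lambda0=200.0, lambda1=800.0, chi=0.1)
        base.update(overrides)
        return cls(**base)

    def replace(self, **kw) -> "WoundModelParameters":
        return replace(self, **kw)

    #: names scanned by the sensitivity analysis (the Table-3 rows).
    SCAN_NAMES = (
        "lambda0", "lambda1", "lambda2", "mu_n", "chi", "n_hat", "alpha",
        "lambda4", "lambda5", "lambda7", "delta", "mu_b", "b_hat", "r_tilde",
    )


@dataclass(frozen=True)
class MRNAParameters:
    """Transport/coupling constants for the injected mRNA field.

    D_m is the mRNA diffusivity in cm^2/s (literature intracellular values are
    2-4e-9; default 3e-9). k1 is the first-order mRNA degradation rate from
    the PK model. lambda8 is the dimensionless edge clearance rate, assumed
    equal to the chemoattractant blood-borne removal rate lambda7. k_gen is
    the dimensionless VEGF (chemoattractant) generation rate per unit mRNA.
    """

    D_m_cm2_s: float = 3e-9
    k1_per_h: float = 0.055
    lambda8: float = 20.0
    k_gen: float = 1.53e5

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v}")

    def dm_ratio(self, scales: ScaleSet) -> float:
        """Dimensionless mRNA diffusivity D_m/D_a."""
        return self.D_m_cm2_s / scales.D_a_cm2_s

    def k1_dimless(self, scales: ScaleSet) -> float:
        """Dimensionless degradation rate (R^2/D_a) * k1."""
        return scales.time_scale_hours * self.k1_per_h

    def replace(self, **kw) -> "MRNAParameters":
        return replace(self, **kw)

    @classmethod
    def none(cls) -> "MRNAParameters":
        """No-mRNA configuration (vehicle runs)."""
        return cls(D_m_cm2_s=0.0, k_gen=0.0)


@dataclass(frozen=True)
class RadialGrid:
    """Uniform node-centred grid on the dimensionless radius [0, 1]."""

    n_nodes: int = 201
    safety: float = 0.2        # diffusive stability safety factor
    adv_safety: float = 0.5    # advective (CFL) safety factor

    def __post_init__(self):
        if self.n_nodes < 5:
            raise ValueError("need at least 5 radial nodes")
        if not 0 < self.safety <= 0.25:
            raise ValueError("safety must be in (0, 0.25]")
        if not 0 < self.adv_safety <= 1.0:
            raise ValueError("adv_safety must be in (0, 1]")

    @property
    def dr(self) -> float:
        return 1.0 / (self.n_nodes - 1)

    @property
    def r(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_nodes)

    @property
    def cell_volumes(self) -> np.ndarray:
        """Finite-volume cell measures: integral of 2 r dr over each cell.

        They sum to exactly 1, so ``volumes @ u`` is the area-average of u
        (= dimensionless mass on the unit disc).
        """
        dr = self.dr
        v = 2.0 * self.r * dr
        v[0] = dr * dr / 4.0
        v[-1] = dr - dr * dr / 4.0
        return v


@dataclass
class FieldState:
    """Radial profiles of all four fields at one dimensionless time."""

    t: float
    n: np.ndarray
    a: np.ndarray
    b: np.ndarray
    m: np.ndarray

    def copy(self) -> "FieldState":
        return FieldState(self.t, self.n.copy(), self.a.copy(),
                          self.b.copy(), self.m.copy())

    def validate(self):
        for name in ("n", "a", "b", "m"):
            u = getattr(self, name)
            if not np.all(np.isfinite(u)):
                j = int(np.argmax(~np.isfinite(u)))
                raise FloatingPointError(
                    f"non-finite value in field '{name}' at node {j}"
                )
            if np.any(u < 0):
                j = int(np.argmax(u < 0))
                raise ValueError(f"negative value in field '{name}' at node {j}")
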