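"""Validated run configuration (YAML) and deterministic run manifests.

All user-facing quantities are in natural units (days, mm, ug, cm^2/s);
nondimensionalization happens inside the library and is logged once per
run. Unknown keys are rejected so typos fail loudly with the field path.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .params import MRNAParameters, RadialGrid, ScaleSet, WoundModelParameters

__all__ = ["RunConfig", "load_config", "ConfigError", "RunManifest"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PKConfig(_Strict):
    k1: float = Field(0.055, ge=0)
    k2: float = Field(0.16, ge=0)
    k3: float = Field(0.23, ge=0)
    doses: list["DoseConfig"] = []


class DoseConfig(_Strict):
    time_h: float = Field(0.0, ge=0)
    amount_ug: float = Field(100.0, ge=0)


class ModelConfig(_Strict):
    lambda0: float = Field(856.0, ge=0)
    lambda1: float = Field(3860.0, ge=0)
    lambda2: float = Field(40.0, ge=0)
    mu_n: float = Field(1e-3, ge=0)
    chi: float = Field(0.146, ge=0)
    n_hat: float = Field(2.0, ge=0)
    alpha: float = Field(10.0, ge=0)
    lambda4: float = Field(400.0, ge=0)
    lambda5: float = Field(40.0, ge=0)
    lambda7: float = Field(20.0, ge=0)
    delta: float = Field(0.01, gt=0)
    mu_b: float = Field(0.5e-3, ge=0)
    b_hat: float = Field(1.5, ge=0)
    r_tilde: float = Field(0.95, gt=0, lt=1)
    b_tilde: float = Field(0.0, ge=0, lt=0.1)

    def build(self) -> WoundModelParameters:
        return WoundModelParameters(**self.model_dump())


class GridConfig(_Strict):
    n_nodes: int = Field(201, ge=5)
    safety_factor: float = Field(0.2, gt=0, le=0.25)

    def build(self) -> RadialGrid:
        return RadialGrid(n_nodes=self.n_nodes, safety=self.safety_factor)


class ScalesConfig(_Strict):
    R_mm: float = Field(5.0, gt=0)
    D_a_cm2_s: float = Field(1e-6, gt=0)
    thickness_mm: float = Field(2.50721, gt=0)

    def build(self) -> ScaleSet:
        return ScaleSet(R_mm=self.R_mm, D_a_cm2_s=self.D_a_cm2_s,
                        thickness_mm=self.thickness_mm)


class MRNAConfig(_Strict):
    D_m_cm2_s: float = Field(3e-9, ge=0)
    lambda8: float = Field(20.0, ge=0)
    k_gen: float = Field(1.53e5, ge=0)

    def build(self) -> MRNAParameters:
        return MRNAParameters(D_m_cm2_s=self.D_m_cm2_s, lambda8=self.lambda8,
                              k_gen=self.k_gen)


class InjectionConfig(_Strict):
    day: float = Field(ge=0)
    radius_mm: float = Field(5.0, ge=0)
    dose_ug: float = Field(100.0, ge=0)
    sigma_mm: float = Field(0.25, gt=0)


class SolveConfig(_Strict):
    t_end_days: float = Field(36.0, gt=0)
    output_dt_days: float = Field(0.1, gt=0)
    snapshot_days: list[float] = []


class FitConfig(_Strict):
    free_params: list[str] = ["lambda0", "lambda1", "chi"]
    bounds_scale: tuple[float, float] = (0.1, 10.0)
    maxiter: int = Field(25, ge=1)
    popsize: int = Field(8, ge=4)
    per_animal: bool = False


class SensitivityConfig(_Strict):
    eval_day: float = Field(18.0, gt=0)
    rel_step: float = Field(0.10, gt=0, lt=1)
    use_unfitted_baseline: bool = True


class SweepConfig(_Strict):
    kind: Literal["timing", "location", "diffusivity"] = "timing"
    days: list[float] = [0.0]
    radii_mm: list[float] = [5.0, 4.0, 3.0, 2.0, 1.0]
    diffusivities_cm2_s: list[float] = [0.0, 3e-9, 1e-7, 1e-5]
    dose_ug: float = Field(100.0, ge=0)


class SyntheticConfig(_Strict):
    animals_per_group: int = Field(8, ge=1)
    noise_cv: float = Field(0.10, ge=0)
    rate_spread: float = Field(0.15, ge=0, lt=1)
    recoil_amp: float = Field(15.0, ge=0)


class RunConfig(_Strict):
    pk: PKConfig = PKConfig()
    model: ModelConfig = ModelConfig()
    grid: GridConfig = GridConfig()
    scales: ScalesConfig = ScalesConfig()
    mrna: MRNAConfig = MRNAConfig()
    injections: list[InjectionConfig] = []
    solve: SolveConfig = SolveConfig()
    fit: FitConfig = FitConfig()
    sensitivity: SensitivityConfig = SensitivityConfig()
    sweep: SweepConfig = SweepConfig()
    synthetic: SyntheticConfig = SyntheticConfig()
    seed: int = 0

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; None gives all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration ({paths})") from exc


class RunManifest:
    """Index of a run's numeric outputs with content hashes.

    Identical config + seed reproduce byte-identical outputs, hence an
    identical manifest hash.
    """

    def __init__(self, config: RunConfig, command: str):
        self.command = command
        self.config_hash = config.config_hash
        self.seed = config.seed
        self.outputs: dict[str, str] = {}

    def add(self, path: str | Path) -> None:
        p = Path(path)
        self.outputs[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    def write(self, path: str | Path) -> None:
        from . import __version__

        payload = {
            "command": self.command,
            "version": __version__,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "outputs": dict(sorted(self.outputs.items())),
        }
        payload["manifest_hash"] = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
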