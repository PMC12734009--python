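"""Schema-validated run configuration.

A ``RunConfig`` gathers every tunable of the library behind one YAML file.
Each field carries a provenance tag — ``published`` (a printed constant),
``derived`` (recovered by calibration against published tables) or
``assumed`` (a documented modelling assumption) — retrievable with
:func:`field_provenance`.  Unknown keys are rejected with their location.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import closed_loop, growth_value, thermo_energy

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "field_provenance"]


def _f(default: float, provenance: str, description: str = "") -> Any:
    return Field(default=default, description=description, json_schema_extra={"provenance": provenance})


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PlantConfig(_Model):
    heater_total_power_w: float = _f(38_000.0, "published", "total heater rod power")
    chiller_total_capacity_w: float = _f(27_000.0, "published", "chiller refrigeration capacity")
    chiller_efficiency: float = _f(0.9, "published", "empirical chiller loss coefficient")
    water_mass_kg: float = _f(8_000.0, "published", "tank water mass")
    specific_heat_j_per_kg_k: float = _f(4_200.0, "derived", "water specific heat (calibration anchor)")
    loss_coef_air_w_m2k: float = _f(17.0, "published", "surface loss coefficient")
    area_air_m2: float = _f(12.0, "published", "water-air dissipation area")
    loss_coef_wall_w_m2k: float = _f(40.0, "published", "wall loss coefficient")
    area_wall_m2: float = _f(22.72, "published", "water-container dissipation area")
    electricity_price_rmb_kwh: float = _f(0.5, "derived", "tariff recovered from published cost rows")

    def to_params(self) -> thermo_energy.ThermalPlantParams:
        return thermo_energy.ThermalPlantParams(
            heater_total_power=self.heater_total_power_w,
            chiller_total_capacity=self.chiller_total_capacity_w,
            chiller_efficiency=self.chiller_efficiency,
            water_mass=self.water_mass_kg,
            specific_heat=self.specific_heat_j_per_kg_k,
            loss_coef_air=self.loss_coef_air_w_m2k,
            area_air=self.area_air_m2,
            loss_coef_wall=self.loss_coef_wall_w_m2k,
            area_wall=self.area_wall_m2,
            electricity_price=self.electricity_price_rmb_kwh,
        )


class GrowthConfig(_Model):
    intercept: float = _f(-1.355, "published")
    coef_t: float = _f(0.108, "published")
    coef_do: float = _f(0.479, "published")
    coef_t_do: float = _f(4.3e-3, "published")
    coef_t2: float = _f(-3.125e-3, "published")
    coef_do2: float = _f(-0.043, "published")

    def to_params(self) -> growth_value.GrowthSurfaceParams:
        return growth_value.GrowthSurfaceParams(
            intercept=self.intercept,
            coef_t=self.coef_t,
            coef_do=self.coef_do,
            coef_t_do=self.coef_t_do,
            coef_t2=self.coef_t2,
            coef_do2=self.coef_do2,
        )


class ValueConfig(_Model):
    # None -> calibrate from the packaged anchor rows at load time
    alpha_rmb_per_sgr: float | None = _f(None, "derived", "cycle value slope; calibrated when null")
    beta_rmb: float | None = _f(None, "derived", "fixed cycle cost; calibrated when null")

    def to_params(self, growth: growth_value.GrowthSurfaceParams) -> growth_value.ValueModelParams:
        if self.alpha_rmb_per_sgr is None or self.beta_rmb is None:
            return growth_value.default_value_params(growth)
        return growth_value.ValueModelParams(alpha=self.alpha_rmb_per_sgr, beta=self.beta_rmb)


class AerationConfig(_Model):
    amplitude_mg_l_min: float = _f(0.36, "published")
    decay_scale_c: float = _f(8.17, "published")
    floor_mg_l_min: float = _f(0.18, "published")

    def to_params(self) -> thermo_energy.AerationModelParams:
        return thermo_energy.AerationModelParams(
            amplitude=self.amplitude_mg_l_min,
            decay_scale=self.decay_scale_c,
            floor=self.floor_mg_l_min,
        )


class PolicyConfig(_Model):
    low_band_top_c: float = _f(14.0, "published", "heat-until limit of the low band")
    reassess_interval_min: float = _f(10.0, "assumed", "dwell between control steps")
    night_rate_cap_c_per_h: float = _f(4.0, "published", "max hourly temperature command change")
    night_drop_c: float = _f(4.0, "published", "night floor below dusk entry temperature")


class HazardConfig(_Model):
    base_rate_per_h: float = _f(0.05, "assumed")
    hypoxia_gain_per_h_mg_l: float = _f(2.0, "assumed")
    thermal_gain_per_h_c: float = _f(1.0, "assumed")
    comfort_margin_c: float = _f(2.0, "assumed")
    refractory_min: float = _f(5.0, "assumed")

    def to_params(self) -> closed_loop.BehaviorHazardParams:
        return closed_loop.BehaviorHazardParams(
            base_rate=self.base_rate_per_h,
            hypoxia_gain=self.hypoxia_gain_per_h_mg_l,
            thermal_gain=self.thermal_gain_per_h_c,
            comfort_margin=self.comfort_margin_c,
            refractory_min=self.refractory_min,
        )


class OxygenBudgetConfig(_Model):
    consumption_ref_mg_kg_h: float = _f(250.0, "assumed", "fish O2 uptake at 20 °C")
    q10: float = _f(2.0, "assumed")
    ref_t_c: float = _f(20.0, "assumed")
    tank_volume_l: float = _f(8000.0, "published")
    aerator_power_kw: float = _f(0.75, "assumed")

    def to_params(self) -> closed_loop.OxygenBudgetParams:
        return closed_loop.OxygenBudgetParams(
            consumption_ref=self.consumption_ref_mg_kg_h,
            q10=self.q10,
            ref_T=self.ref_t_c,
            tank_volume_l=self.tank_volume_l,
            aerator_power_kw=self.aerator_power_kw,
        )


class RunConfig(_Model):
    seed: int = _f(0, "assumed")
    plant: PlantConfig = Field(default_factory=PlantConfig)
    growth: GrowthConfig = Field(default_factory=GrowthConfig)
    value: ValueConfig = Field(default_factory=ValueConfig)
    aeration: AerationConfig = Field(default_factory=AerationConfig)
    policy: PolicyConfig = Field(default_factory=PolicyConfig)
    hazard: HazardConfig = Field(default_factory=HazardConfig)
    oxygen: OxygenBudgetConfig = Field(default_factory=OxygenBudgetConfig)


class ConfigError(ValueError):
    """Config failed validation; message lists each offending field."""


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [f"invalid config {path}:"]
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"  {loc}: {err['msg']}")
        raise ConfigError("\n".join(lines)) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config as YAML; load_config(save_config(c)) is identity."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


def field_provenance(model: type[BaseModel] = RunConfig, prefix: str = "") -> dict[str, str]:
    """Map of dotted field path -> provenance tag (published/derived/assumed)."""
    out: dict[str, str] = {}
    for name, f in model.model_fields.items():
        path = f"{prefix}{name}"
        ann = f.annotation
        sub = None
        if isinstance(ann, type) and issubclass(ann, BaseModel):
            sub = ann
        if sub is not None:
            out.update(field_provenance(sub, prefix=f"{path}."))
        else:
            extra = f.json_schema_extra or {}
            out[path] = extra.get("provenance", "assumed") if isinstance(extra, dict) else "assumed"
    return out
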