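"""Tank heating, cooling, aeration and device-cost models.

Heat exchange with the surroundings follows Newton's law of cooling with a
lumped loss coefficient k = U_air*S_air + U_wall*S_wall (1112.8 W/K with the
default geometry).  By the published convention, losses during a heating or
cooling run are charged at the *full* set-point difference, so the net powers
are constants::

    P_heat_net = Pz - k*(T2 - T1)          (heating, T2 >= T1)
    P_cool_net = 0.9*Pzz - k*(T1 - T2)     (cooling, T1 >= T2)

and a run to move m kg of water by dT takes t = m*c*dT / (3600 * P_net)
hours, billed at the electrical draw (Pz or Pzz) times the tariff C1.
The instantaneous-temperature ODE variant lives in :mod:`rasctl.closed_loop`.

The aerator's mean oxygen transfer rate falls with temperature,
``rate = a*10^(-T/s) + floor`` (mg/L/min), and dissolved-oxygen saturation
uses the Benson-Krause freshwater formula at 1 atm, zero salinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ThermalPlantParams",
    "AerationModelParams",
    "DeviceCostParams",
    "UnreachableTargetError",
    "DEFAULT_PLANT",
    "DEFAULT_AERATION",
    "lumped_loss_coefficient",
    "actual_heating_power",
    "heating_time_hours",
    "heating_cost",
    "effective_cooling_power",
    "cooling_time_hours",
    "cooling_cost",
    "aeration_rate",
    "aeration_time",
    "dissolved_oxygen_saturation",
    "device_cost",
    "calibrate_energy_price",
]


class UnreachableTargetError(ValueError):
    """Steady-state losses exceed the plant's net power: set-point unreachable."""


def _positive(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class ThermalPlantParams:
    """Heating/cooling plant and tank geometry.

    Powers in W, masses in kg, areas in m², loss coefficients in W/(m²·K).
    ``specific_heat`` (J/(kg·K)) and ``electricity_price`` (RMB/kWh) are
    calibrated values (see :func:`calibrate_energy_price`).
    """

    heater_total_power: float = 38_000.0
    chiller_total_capacity: float = 27_000.0
    chiller_efficiency: float = 0.9
    water_mass: float = 8_000.0
    specific_heat: float = 4_200.0
    loss_coef_air: float = 17.0
    area_air: float = 12.0
    loss_coef_wall: float = 40.0
    area_wall: float = 22.72
    electricity_price: float = 0.5

    def __post_init__(self) -> None:
        for f in (
            "heater_total_power", "chiller_total_capacity", "chiller_efficiency",
            "water_mass", "specific_heat", "loss_coef_air", "area_air",
            "loss_coef_wall", "area_wall", "electricity_price",
        ):
            _positive(f, getattr(self, f))

    @property
    def loss_coefficient(self) -> float:
        """Lumped heat-loss coefficient k (W/K)."""
        return self.loss_coef_air * self.area_air + self.loss_coef_wall * self.area_wall


DEFAULT_PLANT = ThermalPlantParams()


def lumped_loss_coefficient(plant: ThermalPlantParams = DEFAULT_PLANT) -> float:
    return plant.loss_coefficient


def actual_heating_power(t_ambient: float, t_target: float, plant: ThermalPlantParams = DEFAULT_PLANT) -> float:
    """Net heating power (W) after steady losses at the full set-point lift."""
    if not (math.isfinite(t_ambient) and math.isfinite(t_target)):
        raise ValueError("temperatures must be finite")
    if t_target < t_ambient:
        raise ValueError(f"heating requires t_target >= t_ambient, got {t_target} < {t_ambient}")
    net = plant.heater_total_power - plant.loss_coefficient * (t_target - t_ambient)
    if net <= 0:
        raise UnreachableTargetError(
            f"target {t_target} °C unreachable from {t_ambient} °C: "
            f"losses {plant.loss_coefficient * (t_target - t_ambient):.0f} W >= "
            f"heater {plant.heater_total_power:.0f} W"
        )
    return net


def heating_time_hours(t_ambient: float, t_target: float, plant: ThermalPlantParams = DEFAULT_PLANT) -> float:
    """Hours to lift the water mass from ambient to target at constant net power."""
    dt = t_target - t_ambient
    if dt == 0:
        return 0.0
    net = actual_heating_power(t_ambient, t_target, plant)
    return plant.water_mass * plant.specific_heat * dt / (3600.0 * net)


def heating_cost(t_ambient: float, t_target: float, plant: ThermalPlantParams = DEFAULT_PLANT) -> float:
    """Electricity cost (RMB) of one heating run; 0 at zero lift."""
    hours = heating_time_hours(t_ambient, t_target, plant)
    return plant.electricity_price * (plant.heater_total_power / 1000.0) * hours


def effective_cooling_power(t_ambient: float, t_target: float, plant: ThermalPlantParams = DEFAULT_PLANT) -> float:
    """Net cooling power (W): efficiency-derated capacity minus heat gain."""
    if not (math.isfinite(t_ambient) and math.isfinite(t_target)):
        raise ValueError("temperatures must be finite")
    if t_ambient < t_target:
        raise ValueError(f"cooling requires t_ambient >= t_target, got {t_ambient} < {t_target}")
    net = plant.chiller_efficiency * plant.chiller_total_capacity - plant.loss_coefficient * (t_ambient - t_target)
    if net <= 0:
        raise UnreachableTargetError(
            f"target {t_target} °C unreachable from {t_ambient} °C: heat gain exceeds "
            f"effective capacity {plant.chiller_efficiency * plant.chiller_total_capacity:.0f} W"
        )
    return net


def cooling_time_hours(t_ambient: float, t_target: float, plant: ThermalPlantParams = DEFAULT_PLANT) -> float:
    dt = t_ambient - t_target
    if dt == 0:
        return 0.0
    net = effective_cooling_power(t_ambient, t_target, plant)
    return plant.water_mass * plant.specific_heat * dt / (3600.0 * net)


def cooling_cost(t_ambient: float, t_target: float, plant: ThermalPlantParams = DEFAULT_PLANT) -> float:
    """Electricity cost (RMB) of one cooling run, billed at the chiller draw."""
    hours = cooling_time_hours(t_ambient, t_target, plant)
    return plant.electricity_price * (plant.chiller_total_capacity / 1000.0) * hours


@dataclass(frozen=True)
class AerationModelParams:
    """Mean aerator oxygen-transfer model ``rate = amplitude*10^(-T/decay) + floor``."""

    amplitude: float = 0.36      # mg/(L·min)
    decay_scale: float = 8.17    # °C
    floor: float = 0.18          # mg/(L·min)

    #: temperature range the model was fitted on
    fitted_range: tuple[float, float] = (13.0, 23.0)


DEFAULT_AERATION = AerationModelParams()


def aeration_rate(temperature: float, params: AerationModelParams = DEFAULT_AERATION) -> float:
    """Mean DO rise delivered by the aerator (mg/L/min) at the given temperature."""
    if not math.isfinite(temperature):
        raise ValueError("temperature must be finite")
    return params.amplitude * 10.0 ** (-temperature / params.decay_scale) + params.floor


def aeration_time(
    do_from: float,
    do_to: float,
    temperature: float,
    params: AerationModelParams = DEFAULT_AERATION,
) -> float:
    """Minutes to raise DO from ``do_from`` to ``do_to`` at the mean rate."""
    if do_to <= do_from:
        raise ValueError(f"do_to must exceed do_from, got {do_to} <= {do_from}")
    return (do_to - do_from) / aeration_rate(temperature, params)


# Benson & Krause (1984) freshwater oxygen solubility at 1 atm, zero salinity.
_BK = (-139.34411, 1.575701e5, -6.642308e7, 1.2438e10, -8.621949e11)


def dissolved_oxygen_saturation(temperature: float) -> float:
    """Freshwater DO saturation (mg/L) at 1 atm for 0 < T < 40 °C."""
    if not (0.0 < temperature < 40.0):
        raise ValueError(f"temperature out of range (0, 40) °C: {temperature}")
    tk = temperature + 273.15
    ln_c = _BK[0] + _BK[1] / tk + _BK[2] / tk**2 + _BK[3] / tk**3 + _BK[4] / tk**4
    return math.exp(ln_c)


@dataclass(frozen=True)
class DeviceCostParams:
    """Intermittent (laser curtain) and continuous device ratings.

    The laser runs at a fixed duty cycle; continuous devices are
    (name, rated power kW, duty fraction) triples.
    """

    laser_power: float = 5e-4    # kW
    laser_duty: float = 0.4      # fraction of each hour
    continuous_devices: tuple[tuple[str, float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.laser_duty <= 1.0:
            raise ValueError("laser_duty must be in [0, 1]")
        if self.laser_power < 0:
            raise ValueError("laser_power must be >= 0")
        for name, power, duty in self.continuous_devices:
            if power < 0 or not 0.0 <= duty <= 1.0:
                raise ValueError(f"device {name!r}: power must be >= 0 and duty in [0, 1]")


def device_cost(params: DeviceCostParams, price: float, hours: float) -> dict[str, float]:
    """Per-device electricity cost (RMB) over ``hours``, plus a ``total`` entry."""
    if hours < 0:
        raise ValueError("hours must be >= 0")
    out = {"laser": params.laser_duty * params.laser_power * price * hours}
    for name, power, duty in params.continuous_devices:
        out[name] = duty * power * price * hours
    out["total"] = sum(out.values())
    return out


def calibrate_energy_price(
    rows: list[tuple[float, float, float]],
    plant: ThermalPlantParams = DEFAULT_PLANT,
) -> tuple[ThermalPlantParams, list[float]]:
    """Solve the electricity tariff from published heating-cost rows.

    The heating cost depends on ``specific_heat`` and ``electricity_price``
    only through their product, so with c fixed at the standard 4200 J/(kg·K)
    the rows ``(t_ambient, t_target, cost_rmb)`` identify C1 by a one-parameter
    least-squares fit (exact for a single row).  Returns the re-parameterized
    plant and the per-row residuals (RMB).
    """
    if not rows:
        raise ValueError("need at least one calibration row")
    bases = [heating_cost(t1, t2, plant) / plant.electricity_price for t1, t2, _ in rows]
    price = sum(b * c for b, (_, _, c) in zip(bases, rows)) / sum(b * b for b in bases)
    plant2 = ThermalPlantParams(
        heater_total_power=plant.heater_total_power,
        chiller_total_capacity=plant.chiller_total_capacity,
        chiller_efficiency=plant.chiller_efficiency,
        water_mass=plant.water_mass,
        specific_heat=plant.specific_heat,
        loss_coef_air=plant.loss_coef_air,
        area_air=plant.area_air,
        loss_coef_wall=plant.loss_coef_wall,
        area_wall=plant.area_wall,
        electricity_price=price,
    )
    residuals = [cost_i - heating_cost(a, b, plant2) for a, b, cost_i in rows]
    return plant2, residuals
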