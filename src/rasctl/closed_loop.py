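"""Closed-loop tank digital twin with a stochastic stress-behavior generator.

The twin integrates the tank's thermal and dissolved-oxygen balance with
explicit Euler steps::

    dT/dt  = (P_heater - P_chiller_eff - k * dT_loss) / (m * c)
    dDO/dt = aerator_on * rate(T)/60 - consumption(biomass, T)

where k is the lumped loss coefficient (W/K).  Two loss conventions are
implemented: ``"instantaneous"`` (physical ODE, loss against the current
water temperature) and ``"fixed-delta"`` (the published costing convention:
loss charged at the full set-point lift for the whole run).  Fish oxygen
consumption is a Q10-scaled per-kg rate; its coefficients are assumptions,
not published values.

Behavior events arrive as an inhomogeneous Poisson process whose hazard
rises with the DO deficit below 5 mg/L and with temperature excursions
toward the envelope bounds; events are typed hypoxic (2) or thermal (1)
according to the dominating hazard term, with a refractory period between
detections.  ``run_trial`` exercises a full day/night controller against the
twin and reports cost, growth and stress exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import control_policy, growth_value, strategy_optimizer, thermo_energy
from .control_policy import ControlAction, ControlState, StressEvent
from .growth_value import GrowthSurfaceParams, ValueModelParams
from .thermo_energy import AerationModelParams, ThermalPlantParams

__all__ = [
    "TwinState",
    "BehaviorHazardParams",
    "OxygenBudgetParams",
    "AmbientProfile",
    "TankTwin",
    "BehaviorGenerator",
    "emit_behaviors",
    "TrialReport",
    "run_trial",
]


@dataclass
class TwinState:
    """Full simulator state; cumulative meters never decrease."""

    water_T: float
    DO: float
    ambient_T: float
    biomass: float = 300.0            # kg
    cumulative_energy: float = 0.0    # kWh
    cumulative_cost: float = 0.0      # RMB
    accrued_growth: float = 0.0       # SGR-percent·days
    clock: float = 0.0                # s


@dataclass(frozen=True)
class OxygenBudgetParams:
    """Fish oxygen drawdown and aerator rating (assumed, config-overridable).

    ``consumption_ref`` is mg O2 per kg fish per hour at ``ref_T``; drawdown
    scales with Q10 and is spread over the tank volume.
    """

    consumption_ref: float = 250.0    # mg/(kg·h) at ref_T
    q10: float = 2.0
    ref_T: float = 20.0               # °C
    tank_volume_l: float = 8000.0
    aerator_power_kw: float = 0.75

    def drawdown(self, biomass: float, temperature: float) -> float:
        """DO drawdown (mg/L per minute)."""
        rate = self.consumption_ref * self.q10 ** ((temperature - self.ref_T) / 10.0)
        return biomass * rate / self.tank_volume_l / 60.0


@dataclass(frozen=True)
class AmbientProfile:
    """Diel ambient-air trajectory: mean + sinusoid, warmest at ``peak_hour``."""

    mean: float
    amplitude: float = 0.0
    period_h: float = 24.0
    peak_hour: float = 15.0

    def __call__(self, t_s: float) -> float:
        if self.amplitude == 0.0:
            return self.mean
        phase = 2.0 * math.pi * (t_s / 3600.0 - self.peak_hour) / self.period_h
        return self.mean + self.amplitude * math.cos(phase)


LossConvention = Literal["instantaneous", "fixed-delta"]


class TankTwin:
    """Explicit-Euler tank simulator.

    ``dt`` should stay well below the thermal time constant
    m·c / k ≈ 8.4 h; the default 60 s is conservative.
    """

    def __init__(
        self,
        state: TwinState,
        *,
        plant: ThermalPlantParams = thermo_energy.DEFAULT_PLANT,
        aeration: AerationModelParams = thermo_energy.DEFAULT_AERATION,
        oxygen: OxygenBudgetParams = OxygenBudgetParams(),
        growth: GrowthSurfaceParams = growth_value.DEFAULT_GROWTH,
        loss_convention: LossConvention = "instantaneous",
        fixed_delta_setpoint: float | None = None,
    ) -> None:
        if state.biomass < 0:
            raise ValueError("biomass must be >= 0")
        if not (0.0 <= state.DO):
            raise ValueError("DO must be >= 0")
        self.state = state
        self.plant = plant
        self.aeration = aeration
        self.oxygen = oxygen
        self.growth = growth
        self.loss_convention: LossConvention = loss_convention
        #: set-point the fixed-delta loss is charged against
        self.fixed_delta_setpoint = fixed_delta_setpoint

    def advance(
        self,
        dt: float,
        *,
        heater_on: bool = False,
        chiller_on: bool = False,
        aerator_on: bool = False,
        ambient: float | None = None,
    ) -> TwinState:
        """Advance one Euler step and return the updated state."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        s = self.state
        if ambient is not None:
            s.ambient_T = float(ambient)
        k = self.plant.loss_coefficient

        if self.loss_convention == "fixed-delta":
            ref = self.fixed_delta_setpoint if self.fixed_delta_setpoint is not None else s.water_T
            loss = k * (ref - s.ambient_T)
        else:
            loss = k * (s.water_T - s.ambient_T)

        p_heat = self.plant.heater_total_power if heater_on else 0.0
        p_cool = (
            self.plant.chiller_efficiency * self.plant.chiller_total_capacity if chiller_on else 0.0
        )
        # with everything off the tank still relaxes toward ambient
        if not heater_on and not chiller_on and self.loss_convention == "fixed-delta":
            loss = k * (s.water_T - s.ambient_T)
        dT = (p_heat - p_cool - loss) / (self.plant.water_mass * self.plant.specific_heat) * dt
        s.water_T += dT

        d_do = 0.0  # mg/L per minute
        if aerator_on:
            d_do += thermo_energy.aeration_rate(s.water_T, self.aeration)
        d_do -= self.oxygen.drawdown(s.biomass, s.water_T)
        s.DO = max(0.0, s.DO + d_do * dt / 60.0)
        sat = thermo_energy.dissolved_oxygen_saturation(min(max(s.water_T, 0.1), 39.9))
        s.DO = min(s.DO, sat)

        electrical_w = (
            (self.plant.heater_total_power if heater_on else 0.0)
            + (self.plant.chiller_total_capacity if chiller_on else 0.0)
            + (self.oxygen.aerator_power_kw * 1000.0 if aerator_on else 0.0)
        )
        d_kwh = electrical_w / 1000.0 * dt / 3600.0
        s.cumulative_energy += d_kwh
        s.cumulative_cost += d_kwh * self.plant.electricity_price

        s.accrued_growth += growth_value.sgr(s.water_T, s.DO, self.growth) * dt / 86400.0
        s.clock += dt
        return s


@dataclass(frozen=True)
class BehaviorHazardParams:
    """Stress-behavior emission hazard (events/h); purely synthetic.

    hazard = base_rate + hypoxia_gain*max(0, 5 - DO)
             + thermal_gain*(distance outside the comfort band
               [T_MIN + margin, T_MAX - margin])
    """

    base_rate: float = 0.05       # events/h
    hypoxia_gain: float = 2.0     # events/h per mg/L of DO deficit below 5
    thermal_gain: float = 1.0     # events/h per °C beyond the comfort margin
    comfort_margin: float = 2.0   # °C inside the envelope bounds
    refractory_min: float = 5.0

    def __post_init__(self) -> None:
        if min(self.base_rate, self.hypoxia_gain, self.thermal_gain) < 0:
            raise ValueError("hazard rates must be >= 0")

    def terms(self, water_T: float, DO: float) -> tuple[float, float]:
        """(thermal, hypoxic) hazard contributions, events/h."""
        lo = control_policy.T_MIN + self.comfort_margin
        hi = control_policy.T_MAX - self.comfort_margin
        thermal = self.thermal_gain * (max(0.0, lo - water_T) + max(0.0, water_T - hi))
        hypoxic = self.hypoxia_gain * max(0.0, control_policy.DO_MIN - DO)
        return thermal, hypoxic


def emit_behaviors(
    state: TwinState,
    params: BehaviorHazardParams,
    dt: float,
    rng: np.random.Generator,
    last_event_time: float | None = None,
) -> list[StressEvent]:
    """Sample stress events over one step by Poisson thinning.

    At most one event per step is emitted (dt is assumed small against the
    hazard); the refractory window suppresses retriggering.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if last_event_time is not None and (state.clock - last_event_time) < params.refractory_min * 60.0:
        return []
    thermal, hypoxic = params.terms(state.water_T, state.DO)
    lam = params.base_rate + thermal + hypoxic
    if lam <= 0:
        return []
    p = 1.0 - math.exp(-lam * dt / 3600.0)
    if rng.random() >= p:
        return []
    if hypoxic > thermal:
        behavior = control_policy.HYPOXIC
    elif thermal > hypoxic:
        behavior = control_policy.THERMAL
    else:
        behavior = int(rng.choice([control_policy.THERMAL, control_policy.HYPOXIC]))
    return [StressEvent(behavior=behavior, timestamp=state.clock)]


class BehaviorGenerator:
    """Stateful wrapper around :func:`emit_behaviors` (refractory + RNG)."""

    def __init__(self, params: BehaviorHazardParams, seed: int) -> None:
        self.params = params
        self.rng = np.random.default_rng(seed)
        self.last_event_time: float | None = None

    def sample(self, state: TwinState, dt: float) -> list[StressEvent]:
        events = emit_behaviors(state, self.params, dt, self.rng, self.last_event_time)
        if events:
            self.last_event_time = events[-1].timestamp
        return events


@dataclass
class TrialReport:
    """Summary of one closed-loop trial."""

    policy: str
    days: float
    seed: int
    total_cost: float              # RMB
    total_energy_kwh: float
    accrued_growth: float          # SGR-percent·days
    n_events: int
    n_actions: int
    time_in_stress_h: float        # time with DO < 5 or T outside [10, 30]
    final_water_T: float
    final_DO: float
    events: list[dict] = field(default_factory=list)
    actions: list[dict] = field(default_factory=list)

    def to_dict(self, include_logs: bool = True) -> dict:
        d = {
            "policy": self.policy,
            "days": self.days,
            "seed": self.seed,
            "total_cost_rmb": self.total_cost,
            "total_energy_kwh": self.total_energy_kwh,
            "accrued_growth_sgr_days": self.accrued_growth,
            "n_events": self.n_events,
            "n_actions": self.n_actions,
            "time_in_stress_h": self.time_in_stress_h,
            "final_water_T": self.final_water_T,
            "final_DO": self.final_DO,
        }
        if include_logs:
            d["events"] = self.events
            d["actions"] = self.actions
        return d


def _is_day(t_s: float, day_start_h: float, night_start_h: float) -> bool:
    hour = (t_s / 3600.0) % 24.0
    return day_start_h <= hour < night_start_h


def run_trial(
    policy: Literal["multi", "threshold"],
    days: float,
    ambient: AmbientProfile | float,
    seed: int = 0,
    *,
    plant: ThermalPlantParams = thermo_energy.DEFAULT_PLANT,
    growth: GrowthSurfaceParams = growth_value.DEFAULT_GROWTH,
    value: ValueModelParams | None = None,
    hazard: BehaviorHazardParams = BehaviorHazardParams(),
    oxygen: OxygenBudgetParams = OxygenBudgetParams(),
    aeration: AerationModelParams = thermo_energy.DEFAULT_AERATION,
    dt: float = 120.0,
    control_interval_s: float = 600.0,
    threshold_setpoint: tuple[float, float] = (20.0, 5.0),
    init_DO: float = 6.0,
    day_start_h: float = 6.0,
    night_start_h: float = 18.0,
    keep_logs: bool = True,
) -> TrialReport:
    """Run a seeded closed-loop trial and report cost, growth and stress.

    ``policy="multi"`` tracks the optimizer's profit-maximizing set-point
    with stress-behavior feedback and the night policy; ``"threshold"``
    holds the fixed set-point regardless of ambient or behavior.
    Identical seeds give bit-identical logs.
    """
    if isinstance(ambient, (int, float)):
        ambient = AmbientProfile(mean=float(ambient))
    if value is None:
        value = growth_value.default_value_params(growth)

    amb0 = ambient(0.0)
    state = TwinState(water_T=amb0, DO=init_DO, ambient_T=amb0)
    twin = TankTwin(state, plant=plant, aeration=aeration, oxygen=oxygen, growth=growth)
    gen = BehaviorGenerator(hazard, seed)

    def economic_target(amb: float) -> strategy_optimizer.ScenarioResult:
        t_lo = max(control_policy.T_MIN, math.floor(amb))
        rows = strategy_optimizer.sweep(
            amb, state.DO, (t_lo, control_policy.T_MAX), plant=plant, growth=growth, value=value
        )
        return strategy_optimizer.select_optimal(rows, "profit")

    if policy == "multi":
        target = economic_target(amb0)
        t_set, do_set = target.target_T, target.target_DO
    elif policy == "threshold":
        t_set, do_set = threshold_setpoint
    else:
        raise ValueError(f"unknown policy {policy!r}")

    n_steps = int(round(days * 86400.0 / dt))
    buffer: list[StressEvent] = []
    events_log: list[dict] = []
    actions_log: list[dict] = []
    n_events = 0
    n_actions = 0
    time_in_stress = 0.0
    was_day = _is_day(0.0, day_start_h, night_start_h)
    night_entry_T: float | None = None
    last_target_amb = round(amb0)
    next_control = 0.0

    for _ in range(n_steps):
        now = state.clock
        amb = ambient(now)
        is_day = _is_day(now, day_start_h, night_start_h)
        if was_day and not is_day:
            night_entry_T = state.water_T
        was_day = is_day

        new_events = gen.sample(state, dt)
        for e in new_events:
            n_events += 1
            if keep_logs:
                events_log.append({"timestamp": e.timestamp, "behavior": e.behavior})
        buffer.extend(new_events)

        if now >= next_control:
            next_control = now + control_interval_s
            if policy == "multi":
                if is_day and round(amb) != last_target_amb:
                    last_target_amb = round(amb)
                    target = economic_target(amb)
                cs = ControlState(
                    water_T=state.water_T,
                    DO=state.DO,
                    ambient_T=amb,
                    mode="day" if is_day else "night",
                    night_entry_T=night_entry_T,
                )
                action = control_policy.step(cs, buffer, target)
                t_set, do_set = _apply(action, t_set, do_set, cs, target)
                if not buffer and action.actuator == "none":
                    # relax stress-driven DO raises back toward the economic target
                    if do_set > target.target_DO:
                        do_set -= 1.0
                if action.actuator != "none":
                    n_actions += 1
                    if keep_logs:
                        actions_log.append(
                            {
                                "timestamp": now,
                                "actuator": action.actuator,
                                "delta": action.delta,
                                "reason": action.reason,
                            }
                        )
                buffer.clear()
            # threshold policy: set-points never move

        heater_on = state.water_T < t_set - 0.1
        chiller_on = state.water_T > t_set + 0.1
        aerator_on = state.DO < do_set - 0.05
        twin.advance(dt, heater_on=heater_on, chiller_on=chiller_on, aerator_on=aerator_on, ambient=amb)

        if (
            state.DO < control_policy.DO_MIN
            or state.water_T < control_policy.T_MIN
            or state.water_T > control_policy.T_MAX
        ):
            time_in_stress += dt

    return TrialReport(
        policy=policy,
        days=days,
        seed=seed,
        total_cost=state.cumulative_cost,
        total_energy_kwh=state.cumulative_energy,
        accrued_growth=state.accrued_growth,
        n_events=n_events,
        n_actions=n_actions,
        time_in_stress_h=time_in_stress / 3600.0,
        final_water_T=state.water_T,
        final_DO=state.DO,
        events=events_log,
        actions=actions_log,
    )


def _apply(
    action: ControlAction,
    t_set: float,
    do_set: float,
    cs: ControlState,
    target: strategy_optimizer.ScenarioResult,
) -> tuple[float, float]:
    """Apply a unit-step action to the commanded set-points.

    Envelope actions only pull set-points inside the survival envelope;
    tracking actions step toward (and never past) the economic target;
    stress actions may push beyond it, clamped to the envelope/saturation.
    """
    reason = action.reason
    floor = control_policy.T_MIN
    if cs.mode == "night" and cs.night_entry_T is not None:
        floor = control_policy.night_floor(cs.night_entry_T)

    if action.actuator == "heater":
        if reason.startswith("envelope"):
            t_set = max(t_set, control_policy.T_MIN)
        elif reason.startswith(("track", "night")):
            if t_set < float(target.target_T):
                t_set = min(t_set + 1.0, float(target.target_T), control_policy.T_MAX)
        else:
            t_set = min(control_policy.T_MAX, t_set + 1.0)
    elif action.actuator == "chiller":
        if reason.startswith("envelope"):
            t_set = min(t_set, control_policy.T_MAX)
        elif reason.startswith(("track", "night")):
            if t_set > float(target.target_T):
                t_set = max(t_set - 1.0, float(target.target_T), floor)
        else:
            t_set = max(floor, t_set - 1.0)
    elif action.actuator == "aerator":
        sat = thermo_energy.dissolved_oxygen_saturation(min(max(cs.water_T, 0.1), 39.9))
        if reason.startswith("envelope"):
            do_set = max(do_set, control_policy.DO_MIN)
        elif reason.startswith(("track", "night")):
            if do_set < float(target.target_DO):
                do_set = min(do_set + 1.0, float(target.target_DO), sat)
        else:
            do_set = min(sat, do_set + 1.0)
    return t_set, do_set
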