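"""Scenario enumeration and selection of the economic optimum.

For a given ambient temperature and current DO, every candidate set-point
(T, DO) on an integer grid is priced (heating or cooling energy to reach and
hold it under the published fixed-lift convention, optional aeration energy)
and valued through the cycle-value model.  Each scenario row carries

    profit = Fn - En        and        Dn = Fn / En,

the output-input ratio that is the control strategy's objective.  The
optimizer reproduces the published sweeps and picks the best row by profit
(the convention behind the published optima) or by Dn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

from . import growth_value, thermo_energy
from ._common import round_half_up
from .growth_value import GrowthSurfaceParams, ValueModelParams
from .thermo_energy import AerationModelParams, ThermalPlantParams, UnreachableTargetError

__all__ = ["ScenarioResult", "sweep", "select_optimal", "threshold_baseline", "profit_advantage"]

Criterion = Literal["profit", "ratio"]


@dataclass(frozen=True)
class ScenarioResult:
    """One costed control scenario (a row of a published-style sweep)."""

    plan_id: int
    ambient_T: float
    current_DO: float
    target_T: float
    target_DO: float
    control_cost: float      # En, RMB
    value_increment: float   # Fn, RMB

    @property
    def profit(self) -> float:
        return self.value_increment - self.control_cost

    @property
    def ratio(self) -> float:
        """Output-input ratio Dn = Fn / En; NaN (undefined) when En == 0."""
        if self.control_cost == 0:
            return math.nan
        return self.value_increment / self.control_cost

    @property
    def ratio_defined(self) -> bool:
        return self.control_cost != 0


def _scenario_cost(
    ambient_T: float,
    current_DO: float,
    target_T: float,
    target_DO: float,
    plant: ThermalPlantParams,
    aeration: AerationModelParams,
    aerator_power_kw: float | None,
) -> float:
    if target_T > ambient_T:
        cost = thermo_energy.heating_cost(ambient_T, target_T, plant)
    elif target_T < ambient_T:
        cost = thermo_energy.cooling_cost(ambient_T, target_T, plant)
    else:
        cost = 0.0
    # DO-raising energy is excluded unless an aerator rating is supplied: the
    # published sweeps are reproduced by temperature control alone.
    if aerator_power_kw is not None and target_DO > current_DO:
        minutes = thermo_energy.aeration_time(current_DO, target_DO, target_T, aeration)
        cost += plant.electricity_price * aerator_power_kw * minutes / 60.0
    return cost


def sweep(
    ambient_T: float,
    current_DO: float,
    t_range: tuple[float, float] = (10.0, 30.0),
    do_range: tuple[float, float] = (5.0, 5.0),
    *,
    plant: ThermalPlantParams = thermo_energy.DEFAULT_PLANT,
    growth: GrowthSurfaceParams = growth_value.DEFAULT_GROWTH,
    value: ValueModelParams | None = None,
    aeration: AerationModelParams = thermo_energy.DEFAULT_AERATION,
    aerator_power_kw: float | None = None,
    t_step: float = 1.0,
    do_step: float = 1.0,
) -> list[ScenarioResult]:
    """Enumerate and cost every feasible (T, DO) set-point on the grid.

    Set-points whose DO exceeds saturation at that temperature, or whose
    temperature the plant cannot reach, are skipped.  Plans are numbered
    1-based in sweep order (temperature-major), matching the published
    tables' row order.
    """
    if value is None:
        value = growth_value.default_value_params(growth)
    t_lo, t_hi = t_range
    do_lo, do_hi = do_range
    if t_lo > t_hi or do_lo > do_hi:
        raise ValueError("ranges must be (low, high)")

    results: list[ScenarioResult] = []
    plan = 0
    n_t = int(math.floor((t_hi - t_lo) / t_step + 1e-9)) + 1
    n_do = int(math.floor((do_hi - do_lo) / do_step + 1e-9)) + 1
    for i in range(n_t):
        t = t_lo + i * t_step
        sat = thermo_energy.dissolved_oxygen_saturation(t)
        for j in range(n_do):
            do = do_lo + j * do_step
            if do > sat:
                continue
            try:
                cost = _scenario_cost(ambient_T, current_DO, t, do, plant, aeration, aerator_power_kw)
            except UnreachableTargetError:
                continue
            plan += 1
            fn = growth_value.cycle_value_increment(t, do, value, growth)
            results.append(
                ScenarioResult(
                    plan_id=plan,
                    ambient_T=ambient_T,
                    current_DO=current_DO,
                    target_T=t,
                    target_DO=do,
                    control_cost=cost,
                    value_increment=fn,
                )
            )
    if not results:
        raise ValueError("empty feasible domain: no reachable (T, DO) set-point on the grid")
    return results


def select_optimal(results: Sequence[ScenarioResult], criterion: Criterion = "profit") -> ScenarioResult:
    """Argmax row under the criterion, with deterministic tie-breaking.

    Ties resolve to the smallest temperature move from ambient, then the
    lowest target DO.
    """
    if not results:
        raise ValueError("select_optimal needs a non-empty result list")
    if criterion == "profit":
        pool = list(results)
        metric = lambda r: r.profit  # noqa: E731
    elif criterion == "ratio":
        pool = [r for r in results if r.ratio_defined]
        if not pool:
            raise ValueError("ratio criterion undefined for every row (all zero-cost)")
        metric = lambda r: r.ratio  # noqa: E731
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return max(pool, key=lambda r: (metric(r), -abs(r.target_T - r.ambient_T), -r.target_DO))


def threshold_baseline(
    ambient_T: float,
    setpoint_T: float = 20.0,
    setpoint_DO: float = 5.0,
    *,
    current_DO: float = 5.0,
    plant: ThermalPlantParams = thermo_energy.DEFAULT_PLANT,
    growth: GrowthSurfaceParams = growth_value.DEFAULT_GROWTH,
    value: ValueModelParams | None = None,
    aeration: AerationModelParams = thermo_energy.DEFAULT_AERATION,
    aerator_power_kw: float | None = None,
) -> ScenarioResult:
    """Cost/value of the fixed-set-point strategy (default 20 °C, 5 mg/L)."""
    if value is None:
        value = growth_value.default_value_params(growth)
    cost = _scenario_cost(ambient_T, current_DO, setpoint_T, setpoint_DO, plant, aeration, aerator_power_kw)
    fn = growth_value.cycle_value_increment(setpoint_T, setpoint_DO, value, growth)
    return ScenarioResult(
        plan_id=0,
        ambient_T=ambient_T,
        current_DO=current_DO,
        target_T=setpoint_T,
        target_DO=setpoint_DO,
        control_cost=cost,
        value_increment=fn,
    )


def profit_advantage(
    ambient_T: float,
    *,
    current_DO: float = 5.0,
    t_range: tuple[float, float] = (10.0, 30.0),
    setpoint_T: float = 20.0,
    setpoint_DO: float = 5.0,
    plant: ThermalPlantParams = thermo_energy.DEFAULT_PLANT,
    growth: GrowthSurfaceParams = growth_value.DEFAULT_GROWTH,
    value: ValueModelParams | None = None,
) -> float:
    """Best sweep profit divided by the fixed-set-point profit.

    Both profits are rounded half-up to 2 decimals before dividing — the
    published convention, which reports table-cell ratios.  NaN when the
    baseline profit is non-positive (ratio undefined).  Sweeps that start
    below the envelope floor are clipped to it.
    """
    t_lo = max(t_range[0], ambient_T)
    rows = sweep(ambient_T, current_DO, (t_lo, t_range[1]), plant=plant, growth=growth, value=value)
    best = select_optimal(rows, "profit")
    base = threshold_baseline(
        ambient_T, setpoint_T, setpoint_DO, current_DO=current_DO,
        plant=plant, growth=growth, value=value,
    )
    base_profit = round_half_up(base.profit)
    if base_profit <= 0:
        return math.nan
    return round_half_up(best.profit) / base_profit
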