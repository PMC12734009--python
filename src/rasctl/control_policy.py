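"""Rule-based stress-feedback control state machine.

Three prioritized processes drive the actuators, one unit step at a time
(+1 °C, -1 °C, or +1 mg/L):

1. **Envelope restoration** — if the water leaves the survival envelope
   (T in [10, 30] °C, DO >= 5 mg/L), temperature is corrected first, then
   oxygen.
2. **Stress response** — detected behaviors (1 = thermal: loss of
   equilibrium / rollover; 2 = hypoxic: surfacing / surface swimming)
   dispatch on the current temperature band:

   * 10-14 °C: behavior 1 heats until the band top, then aerates; behavior 2
     aerates up to saturation; both together aerate first (oxygen priority).
   * 15-25 °C: any behavior aerates.
   * 26-30 °C: aerate first; once DO is pinned at saturation, cool.

3. **Economic tracking** — with no violations or behaviors, step toward the
   optimizer's set-point.

At night there is no behavior feedback; the temperature floor is the dusk
entry temperature minus 4 °C (never below 10 °C) and commanded temperature
changes are capped at 4 °C per hour.

DO commands are clamped at saturation: a clamped command is logged as a
no-op, never emitted.  Fractional temperatures dispatch bands by ``floor``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

from .thermo_energy import dissolved_oxygen_saturation

__all__ = [
    "T_MIN",
    "T_MAX",
    "DO_MIN",
    "ControlState",
    "StressEvent",
    "ControlAction",
    "restore_envelope",
    "respond_to_stress",
    "night_floor",
    "night_setpoint",
    "night_policy",
    "step",
]

T_MIN, T_MAX = 10.0, 30.0
DO_MIN = 5.0
NIGHT_DROP = 4.0          # °C below the dusk entry temperature
NIGHT_RATE_CAP = 4.0      # °C per hour
LOW_BAND_TOP = 14.0       # heat-until limit of the 10-14 °C rule

Mode = Literal["day", "night"]

THERMAL = 1   # loss of equilibrium / rollover
HYPOXIC = 2   # surfacing / surface swimming


@dataclass
class ControlState:
    """Controller view of the tank."""

    water_T: float
    DO: float
    ambient_T: float
    mode: Mode = "day"
    night_entry_T: float | None = None

    @property
    def delta_T_b(self) -> float:
        """Signed distance to the nearer survival-envelope temperature bound.

        Negative when outside the envelope.
        """
        return min(self.water_T - T_MIN, T_MAX - self.water_T)

    @property
    def delta_DO_b(self) -> float:
        """DO margin above the survival minimum (negative when hypoxic)."""
        return self.DO - DO_MIN


@dataclass(frozen=True, order=True)
class StressEvent:
    behavior: int
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if self.behavior not in (THERMAL, HYPOXIC):
            raise ValueError(f"behavior must be 1 (thermal) or 2 (hypoxic), got {self.behavior}")


@dataclass(frozen=True)
class ControlAction:
    """Exactly one actuator, one unit step."""

    actuator: Literal["heater", "chiller", "aerator", "none"]
    delta: float
    reason: str


def _none(reason: str) -> ControlAction:
    return ControlAction("none", 0.0, reason)


def _heat(state: ControlState, reason: str, top: float = T_MAX) -> ControlAction:
    if state.water_T + 1.0 > top + 1e-9:
        return _none(f"{reason}:clamped-at-{top:g}C")
    return ControlAction("heater", +1.0, reason)


def _cool(state: ControlState, reason: str, floor: float = T_MIN) -> ControlAction:
    if state.water_T - 1.0 < floor - 1e-9:
        return _none(f"{reason}:clamped-at-{floor:g}C")
    return ControlAction("chiller", -1.0, reason)


def _aerate(state: ControlState, reason: str) -> ControlAction:
    sat = dissolved_oxygen_saturation(state.water_T)
    if state.DO + 1.0 > sat + 1e-9:
        return _none(f"{reason}:do-clamped-at-saturation")
    return ControlAction("aerator", +1.0, reason)


def restore_envelope(state: ControlState) -> ControlAction:
    """Process 1: bring the tank back inside the survival envelope.

    Temperature correction has priority over oxygen correction.
    """
    if state.water_T < T_MIN:
        return ControlAction("heater", +1.0, "envelope:T-below-min")
    if state.water_T > T_MAX:
        return ControlAction("chiller", -1.0, "envelope:T-above-max")
    if state.DO < DO_MIN:
        return _aerate(state, "envelope:DO-below-min")
    return _none("envelope:satisfied")


def respond_to_stress(
    state: ControlState,
    events: Iterable[StressEvent | int],
    *,
    low_band_top: float = LOW_BAND_TOP,
) -> ControlAction:
    """Process 2: behavior-triggered stepping by temperature band."""
    behaviors = {e.behavior if isinstance(e, StressEvent) else int(e) for e in events}
    unknown = behaviors - {THERMAL, HYPOXIC}
    if unknown:
        raise ValueError(f"unknown behaviors: {sorted(unknown)}")
    if not behaviors:
        return _none("stress:no-events")

    band = math.floor(state.water_T)
    if band < T_MIN or band > T_MAX:
        return _none("stress:outside-envelope")

    if band <= 14:
        if HYPOXIC in behaviors and THERMAL in behaviors:
            # rule B1-both: oxygen priority until behavior 2 clears
            action = _aerate(state, "low-band:both:oxygen-first")
            if action.actuator == "none":
                return _heat(state, "low-band:both:do-saturated-heat", top=low_band_top)
            return action
        if HYPOXIC in behaviors:
            return _aerate(state, "low-band:hypoxic:oxygen")
        # thermal only: heat up to the band top, then switch to oxygen
        if state.water_T + 1.0 <= low_band_top + 1e-9:
            return ControlAction("heater", +1.0, "low-band:thermal:heat")
        return _aerate(state, "low-band:thermal:at-top-oxygen")

    if band <= 25:
        return _aerate(state, "mid-band:any:oxygen")

    # 26-30 °C: aerate first; at saturation, cool (rule B3 — behaviors
    # treated identically in this band)
    action = _aerate(state, "high-band:any:oxygen-first")
    if action.actuator == "none":
        return _cool(state, "high-band:persisting:cool")
    return action


def night_floor(entry_T: float) -> float:
    """Night temperature floor: dusk entry temperature minus 4 °C, >= 10 °C."""
    return max(T_MIN, entry_T - NIGHT_DROP)


def night_setpoint(current_T: float, desired_T: float, entry_T: float) -> float:
    """Clip a night temperature command to the floor and the 4 °C/h rate cap."""
    lo = night_floor(entry_T)
    desired = min(max(desired_T, lo), T_MAX)
    return min(max(desired, current_T - NIGHT_RATE_CAP), current_T + NIGHT_RATE_CAP)


def night_policy(state: ControlState, target) -> ControlAction:
    """Process 3: economics-driven tracking without behavior feedback.

    ``target`` is a scenario row (or any object with ``target_T``/``target_DO``,
    or a bare temperature).  The commanded set-point honors the night floor
    and the hourly rate cap.
    """
    if state.mode != "night":
        raise ValueError("night_policy requires mode == 'night'")
    entry = state.night_entry_T if state.night_entry_T is not None else state.water_T
    target_T = getattr(target, "target_T", target)
    target_DO = getattr(target, "target_DO", DO_MIN)
    setpoint = night_setpoint(state.water_T, float(target_T), entry)
    if state.water_T < setpoint - 0.5:
        return _heat(state, "night:track-heat")
    if state.water_T > setpoint + 0.5:
        return _cool(state, "night:track-cool", floor=night_floor(entry))
    if state.DO < float(target_DO) - 0.25:
        return _aerate(state, "night:track-oxygen")
    return _none("night:at-setpoint")


def step(
    state: ControlState,
    events: Iterable[StressEvent | int],
    target=None,
    *,
    low_band_top: float = LOW_BAND_TOP,
) -> ControlAction:
    """One controller tick: envelope > stress response > economic tracking.

    Emits exactly one action.  ``target`` is the optimizer's chosen scenario
    (ignored for stress response, required for tracking).
    """
    env = restore_envelope(state)
    if env.actuator != "none":
        return env
    if state.mode == "night":
        if target is None:
            return _none("night:no-target")
        return night_policy(state, target)
    action = respond_to_stress(state, events, low_band_top=low_band_top)
    if action.actuator != "none":
        return action
    if target is None:
        return _none("track:no-target")
    target_T = float(getattr(target, "target_T", target))
    target_DO = float(getattr(target, "target_DO", DO_MIN))
    if state.water_T < target_T - 0.5:
        return _heat(state, "track:heat")
    if state.water_T > target_T + 0.5:
        return _cool(state, "track:cool")
    if state.DO < target_DO - 0.25:
        return _aerate(state, "track:oxygen")
    return _none("track:at-setpoint")
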