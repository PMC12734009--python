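"""Control state machine tests: rules, safety, liveness, decision table."""

import itertools

import pytest

from rasctl import control_policy as cp
from rasctl import thermo_energy as te
from rasctl.strategy_optimizer import ScenarioResult


def state(t, do, amb=15.0, mode="day", entry=None):
    return cp.ControlState(water_T=t, DO=do, ambient_T=amb, mode=mode, night_entry_T=entry)


def target(t=17.0, do=5.0):
    return ScenarioResult(1, 8, 5, t, do, control_cost=1.0, value_increment=2.0)


class TestEnvelopeRestoration:
    @pytest.mark.parametrize(
        "t, do, actuator",
        [
            (8, 6, "heater"),    # temperature priority
            (8, 4, "heater"),    # temperature before oxygen
            (32, 6, "chiller"),
            (20, 4, "aerator"),
            (20, 6, "none"),
        ],
    )
    def test_priority_and_direction(self, t, do, actuator):
        assert cp.restore_envelope(state(t, do)).actuator == actuator

    def test_derived_envelope_distances(self):
        s = state(12, 7)
        assert s.delta_T_b == pytest.approx(2.0)
        assert s.delta_DO_b == pytest.approx(2.0)
        assert state(8, 4).delta_T_b < 0


class TestStressResponse:
    def test_low_band_thermal_heats_then_aerates(self):
        assert cp.respond_to_stress(state(12, 6), {1}).actuator == "heater"
        # at the band top further behavior-1 events switch to oxygen
        assert cp.respond_to_stress(state(14, 6), {1}).actuator == "aerator"

    def test_low_band_hypoxic_aerates_to_saturation(self):
        assert cp.respond_to_stress(state(12, 6), {2}).actuator == "aerator"
        sat = te.dissolved_oxygen_saturation(12.0)
        clamped = cp.respond_to_stress(state(12, sat - 0.5), {2})
        assert clamped.actuator == "none"
        assert "saturation" in clamped.reason

    def test_low_band_both_prioritizes_oxygen(self):
        assert cp.respond_to_stress(state(12, 6), {1, 2}).actuator == "aerator"

    def test_mid_band_any_behavior_aerates(self):
        for events in ({1}, {2}, {1, 2}):
            assert cp.respond_to_stress(state(20, 6), events).actuator == "aerator"

    def test_high_band_aerates_then_cools(self):
        assert cp.respond_to_stress(state(28, 6), {2}).actuator == "aerator"
        sat = te.dissolved_oxygen_saturation(28.0)
        assert cp.respond_to_stress(state(28, sat), {2}).actuator == "chiller"

    def test_no_events_is_noop(self):
        assert cp.respond_to_stress(state(20, 6), set()).actuator == "none"

    def test_unknown_behavior_rejected(self):
        with pytest.raises(ValueError):
            cp.respond_to_stress(state(20, 6), {3})

    def test_decision_table_total_and_deterministic(self):
        """Every (band x behavior subset) cell maps to exactly one rule."""
        subsets = [{1}, {2}, {1, 2}]
        for t in [x + f for x in range(10, 30) for f in (0.0, 0.5)] + [30.0]:
            for events in subsets:
                for do in (5.5, te.dissolved_oxygen_saturation(t)):
                    a1 = cp.respond_to_stress(state(t, do), events)
                    a2 = cp.respond_to_stress(state(t, do), events)
                    assert a1 == a2
                    assert a1.actuator in ("heater", "chiller", "aerator", "none")


class TestNightPolicy:
    def test_night_floor_examples(self):
        assert cp.night_floor(18.0) == 14.0
        assert cp.night_floor(12.0) == 10.0  # envelope dominates

    def test_rate_cap_clips_commands(self):
        # dropping 19 -> 13 in one hourly command is clipped to 15
        assert cp.night_setpoint(19.0, 13.0, entry_T=19.0) == 15.0
        assert cp.night_setpoint(19.0, 18.0, entry_T=19.0) == 18.0

    def test_night_tracking_respects_floor(self):
        s = state(18.0, 6.0, mode="night", entry=18.0)
        act = cp.night_policy(s, target(t=10.0))
        # desired 10 °C, floor is 14 -> cool, but never command below 14
        assert act.actuator == "chiller"
        s14 = state(14.2, 6.0, mode="night", entry=18.0)
        assert cp.night_policy(s14, target(t=10.0)).actuator == "none"

    def test_consecutive_hourly_commands_within_cap(self):
        temp, entry = 26.0, 26.0
        commands = []
        for _ in range(6):
            sp = cp.night_setpoint(temp, 10.0, entry)
            commands.append(sp)
            temp = sp  # assume the hour realizes the command
        assert all(abs(b - a) <= 4.0 for a, b in zip([26.0] + commands, commands))
        assert commands[-1] == cp.night_floor(entry)

    def test_day_mode_rejected(self):
        with pytest.raises(ValueError):
            cp.night_policy(state(18, 6, mode="day"), target())


class TestStepArbitration:
    def test_envelope_beats_stress(self):
        act = cp.step(state(8, 4), {2}, target())
        assert act.actuator == "heater"
        assert act.reason.startswith("envelope")

    def test_stress_beats_tracking(self):
        act = cp.step(state(12, 6), {1}, target(t=12.0))
        assert act.actuator == "heater"
        assert act.reason.startswith("low-band")

    def test_tracking_toward_economic_target(self):
        assert cp.step(state(12, 6), set(), target(t=17.0)).actuator == "heater"
        assert cp.step(state(22, 6), set(), target(t=17.0)).actuator == "chiller"
        assert cp.step(state(17, 4.5 + 1), set(), target(t=17.0, do=7.0)).actuator == "aerator"

    def test_fixed_point_at_target(self):
        assert cp.step(state(17, 5.0), set(), target(t=17.0, do=5.0)).actuator == "none"

    def test_exactly_one_actuator_per_tick(self):
        for t, do, events in itertools.product((8, 12, 20, 28), (4.0, 6.0), (set(), {1}, {2})):
            act = cp.step(state(t, do), events, target())
            assert act.actuator in ("heater", "chiller", "aerator", "none")


class TestSafetyAndLiveness:
    def _advance(self, s, act):
        """Idealized plant: each action realizes its unit step."""
        if act.actuator == "heater":
            s.water_T += 1.0
        elif act.actuator == "chiller":
            s.water_T -= 1.0
        elif act.actuator == "aerator":
            s.DO += 1.0
        # supersaturated water outgasses when temperature rises
        s.DO = min(s.DO, te.dissolved_oxygen_saturation(s.water_T))
        return s

    def test_safety_setpoints_never_leave_envelope(self):
        """Exhaustive small-state enumeration: from any in-envelope state,
        any event sequence keeps commands inside T in [10,30], DO <= sat."""
        for t0 in range(10, 31):
            for do0 in (5.0, 7.0):
                for events in (set(), {1}, {2}, {1, 2}):
                    s = state(float(t0), min(do0, te.dissolved_oxygen_saturation(t0)))
                    for _ in range(25):
                        act = cp.step(s, events, target(t=20.0, do=5.0))
                        s = self._advance(s, act)
                        assert cp.T_MIN <= s.water_T <= cp.T_MAX
                        assert s.DO <= te.dissolved_oxygen_saturation(s.water_T) + 1e-9

    def test_liveness_quiesces_when_stressors_clear(self):
        """With events that clear once their trigger is removed, the machine
        reaches action 'none' in finitely many steps."""
        s = state(8.0, 4.0)  # outside the envelope on both axes
        for i in range(50):
            events = {2} if s.DO < 5.5 else set()
            act = cp.step(s, events, target(t=15.0, do=5.0))
            if act.actuator == "none":
                break
            s = self._advance(s, act)
        else:
            pytest.fail("machine did not quiesce within 50 steps")
        assert cp.step(s, set(), target(t=15.0, do=5.0)).actuator == "none"
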