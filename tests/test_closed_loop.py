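"""Digital-twin and behavior-generator tests."""

import math

import numpy as np
import pytest

from rasctl import closed_loop as cl
from rasctl import thermo_energy as te


def make_twin(t=20.0, do=8.0, amb=20.0, biomass=0.0, **kw):
    state = cl.TwinState(water_T=t, DO=do, ambient_T=amb, biomass=biomass)
    return cl.TankTwin(state, **kw), state


class TestTwinDynamics:
    def test_equilibrium_without_actuation(self):
        twin, s = make_twin(t=20.0, amb=20.0)
        for _ in range(100):
            twin.advance(60.0)
        assert s.water_T == pytest.approx(20.0)

    def test_relaxation_toward_ambient(self):
        twin, s = make_twin(t=25.0, amb=15.0)
        for _ in range(60):
            twin.advance(60.0)
        assert 15.0 < s.water_T < 25.0

    def test_heating_time_matches_closed_form(self):
        """Under the fixed-lift loss convention, time to heat 2 -> 15 °C
        matches the closed-form m·c·ΔT/(3600·Pj) within 2%."""
        twin, s = make_twin(t=2.0, amb=2.0, loss_convention="fixed-delta")
        twin.fixed_delta_setpoint = 15.0
        seconds = 0.0
        while s.water_T < 15.0:
            twin.advance(60.0, heater_on=True)
            seconds += 60.0
        closed = te.heating_time_hours(2.0, 15.0) * 3600.0
        assert seconds == pytest.approx(closed, rel=0.02)

    def test_heating_cost_matches_closed_form_oracle(self):
        """Metered cost of the fixed-lift heat-up agrees with the closed-form
        run cost within 2% (cross-module oracle)."""
        twin, s = make_twin(t=2.0, amb=2.0, loss_convention="fixed-delta")
        twin.fixed_delta_setpoint = 15.0
        while s.water_T < 15.0:
            twin.advance(60.0, heater_on=True)
        assert s.cumulative_cost == pytest.approx(te.heating_cost(2.0, 15.0), rel=0.02)

    def test_do_rises_to_saturation_and_clamps(self):
        twin, s = make_twin(t=15.0, do=6.0, amb=15.0, biomass=0.0)
        for _ in range(600):
            twin.advance(60.0, aerator_on=True)
        sat = te.dissolved_oxygen_saturation(15.0)
        assert s.DO == pytest.approx(sat, abs=1e-9)

    def test_fish_draw_down_oxygen(self):
        twin, s = make_twin(t=20.0, do=8.0, amb=20.0, biomass=300.0)
        for _ in range(120):
            twin.advance(60.0)
        assert s.DO < 8.0

    def test_energy_meter_integrates_commanded_power(self, plant):
        twin, s = make_twin(t=10.0, amb=10.0)
        steps, dt = 30, 60.0
        for _ in range(steps):
            twin.advance(dt, heater_on=True)
        expected_kwh = plant.heater_total_power / 1000.0 * steps * dt / 3600.0
        assert s.cumulative_energy == pytest.approx(expected_kwh, rel=1e-12)
        assert s.cumulative_cost == pytest.approx(expected_kwh * plant.electricity_price)

    def test_invalid_dt_rejected(self):
        twin, _ = make_twin()
        with pytest.raises(ValueError):
            twin.advance(0.0)


class TestBehaviorGenerator:
    def test_comfortable_state_zero_base_rate_emits_nothing(self):
        params = cl.BehaviorHazardParams(base_rate=0.0)
        state = cl.TwinState(water_T=20.0, DO=8.0, ambient_T=20.0)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            assert cl.emit_behaviors(state, params, 60.0, rng) == []

    def test_hypoxia_raises_event_count(self):
        """Same seed grid: DO=3 must produce strictly more events than DO=5."""
        params = cl.BehaviorHazardParams(base_rate=0.05, refractory_min=0.0)
        counts = {}
        for do in (3.0, 5.0):
            rng = np.random.default_rng(42)
            state = cl.TwinState(water_T=20.0, DO=do, ambient_T=20.0)
            counts[do] = sum(
                len(cl.emit_behaviors(state, params, 60.0, rng)) for _ in range(10_000)
            )
        assert counts[3.0] > counts[5.0]

    def test_event_type_follows_dominant_hazard(self):
        params = cl.BehaviorHazardParams(base_rate=0.0, refractory_min=0.0)
        rng = np.random.default_rng(1)
        hypoxic_state = cl.TwinState(water_T=20.0, DO=3.0, ambient_T=20.0)
        thermal_state = cl.TwinState(water_T=30.0, DO=8.0, ambient_T=30.0)
        hyp = [e for _ in range(5000) for e in cl.emit_behaviors(hypoxic_state, params, 60.0, rng)]
        th = [e for _ in range(5000) for e in cl.emit_behaviors(thermal_state, params, 60.0, rng)]
        assert hyp and all(e.behavior == 2 for e in hyp)
        assert th and all(e.behavior == 1 for e in th)

    def test_empirical_rate_within_three_standard_errors(self):
        """Poisson count check over a long constant-state run."""
        lam = 2.0  # events/h
        params = cl.BehaviorHazardParams(
            base_rate=lam, hypoxia_gain=0.0, thermal_gain=0.0, refractory_min=0.0
        )
        rng = np.random.default_rng(7)
        state = cl.TwinState(water_T=20.0, DO=8.0, ambient_T=20.0)
        dt, steps = 30.0, 120_000  # 1000 h
        n = sum(len(cl.emit_behaviors(state, params, dt, rng)) for _ in range(steps))
        hours = steps * dt / 3600.0
        expected = lam * hours * (1 - math.exp(-lam * dt / 3600.0)) / (lam * dt / 3600.0)
        assert abs(n - expected) < 3.0 * math.sqrt(expected)

    def test_refractory_period_enforced(self):
        params = cl.BehaviorHazardParams(base_rate=1000.0, refractory_min=5.0)
        gen = cl.BehaviorGenerator(params, seed=3)
        state = cl.TwinState(water_T=20.0, DO=8.0, ambient_T=20.0)
        stamps = []
        for _ in range(60):
            for e in gen.sample(state, 60.0):
                stamps.append(e.timestamp)
            state.clock += 60.0
        assert len(stamps) >= 2
        assert min(np.diff(stamps)) >= 5.0 * 60.0


class TestRunTrial:
    def test_same_seed_bit_identical_logs(self):
        kw = dict(days=0.5, ambient=2.0, seed=11, dt=120.0)
        r1 = cl.run_trial("multi", **kw)
        r2 = cl.run_trial("multi", **kw)
        assert r1.to_dict() == r2.to_dict()

    def test_different_seeds_differ(self):
        r1 = cl.run_trial("multi", days=0.5, ambient=2.0, seed=1, dt=120.0)
        r2 = cl.run_trial("multi", days=0.5, ambient=2.0, seed=2, dt=120.0)
        assert r1.events != r2.events

    def test_multi_cheaper_than_threshold_at_cold_ambient(self):
        """Paired same-seed trials: the adaptive policy heats to ~15 °C, the
        threshold policy to 20 °C, so its cost must be lower."""
        for seed in (0, 1):
            multi = cl.run_trial("multi", days=2.0, ambient=2.0, seed=seed, dt=300.0)
            thresh = cl.run_trial("threshold", days=2.0, ambient=2.0, seed=seed, dt=300.0)
            assert multi.total_cost < thresh.total_cost

    def test_zero_hazard_at_economic_optimum_converges_cheaply(self):
        """Ambient already at the optimum set-point: after envelope entry the
        policy quiesces and only maintenance-scale cost accrues."""
        hazard = cl.BehaviorHazardParams(base_rate=0.0, hypoxia_gain=0.0, thermal_gain=0.0)
        r = cl.run_trial("multi", days=1.0, ambient=18.0, seed=0, hazard=hazard, dt=120.0)
        assert r.n_events == 0
        assert abs(r.final_water_T - 18.0) < 1.0
        # maintenance only: far below a cold-start heat-up bill
        assert r.total_cost < 0.25 * cl.run_trial(
            "multi", days=1.0, ambient=2.0, seed=0, hazard=hazard, dt=120.0
        ).total_cost

    def test_cumulative_meters_non_decreasing_and_consistent(self, plant):
        r = cl.run_trial("multi", days=0.5, ambient=8.0, seed=5, dt=120.0)
        assert r.total_energy_kwh >= 0
        assert r.total_cost == pytest.approx(r.total_energy_kwh * plant.electricity_price)

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            cl.run_trial("pid", days=0.1, ambient=10.0)


class TestAmbientProfile:
    def test_constant_profile(self):
        p = cl.AmbientProfile(mean=8.0)
        assert p(0) == p(3600 * 12) == 8.0

    def test_sinusoid_peaks_at_peak_hour(self):
        p = cl.AmbientProfile(mean=8.0, amplitude=6.0, peak_hour=15.0)
        assert p(15 * 3600.0) == pytest.approx(14.0)
        assert p(3 * 3600.0) == pytest.approx(2.0)
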