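"""Time integration, scenarios, and outcome classification."""

import numpy as np
import pytest

from gliostem import (ModelParameters, SystemState, classify_outcome,
                      coexistence_equilibria, generate_fixtures, integrate,
                      integrate_reduced, scenario)
from gliostem.exceptions import ConfigurationError, DomainError
from gliostem.simulate import DEFAULT_ATOL, Trajectory

from conftest import random_states


class TestScenarioDefinitions:
    def test_published_initial_conditions(self):
        f1 = scenario("fig1")
        assert f1.init.T == 70.0 and f1.init.S == 30.0
        assert f1.params.N == 0.0
        f2 = scenario("fig2")
        assert f2.init.C == 2.5e10 and f2.params.N == 1.0
        f3 = scenario("fig3")
        assert f3.init.T == 7e5 and f3.init.S == 3e5
        assert f3.params.N == pytest.approx(1.08783e15)

    def test_unknown_name_rejected(self):
        with pytest.raises(ConfigurationError):
            scenario("fig9")


class TestIntegration:
    def test_untreated_ctl_decay_is_closed_form(self, scenario_runs):
        """With N = 0 the CTL equation decouples: C(t) = C0 e^{-muC t}."""
        _, traj, _ = scenario_runs["fig1"]
        c100 = float(np.interp(100.0, traj.times, traj.states[:, 2]))
        assert c100 == pytest.approx(250.0 * np.exp(-0.7), abs=0.01)

    def test_untreated_tumor_reaches_capacity(self, scenario_runs):
        sc, traj, _ = scenario_runs["fig1"]
        T, S = traj.final_state()[:2]
        assert T >= 0.99 * sc.params.K1
        assert S >= 0.99 * sc.params.K2

    def test_cure_dose_clears_tumor_within_ten_hours(self, scenario_runs):
        _, traj, _ = scenario_runs["fig3"]
        i = int(np.searchsorted(traj.times, 10.0))
        assert traj.states[i, 0] < 1.0 and traj.states[i, 1] < 1.0

    def test_sampling_contract(self, scenario_runs):
        for _, traj, _ in scenario_runs.values():
            assert traj.times[0] == 0.0
            assert np.all(np.diff(traj.times) > 0)
            assert traj.times.size >= 1000

    def test_orthant_invariance_for_random_initial_conditions(self, params,
                                                              rng):
        for y0 in random_states(rng, 20, scales=(1e7, 1e6, 1e6, 1e4, 1e3,
                                                 300.0, 1e4)):
            p = params.replace(N=float(rng.uniform(0.0, 10.0)))
            traj = integrate(p, SystemState.from_array(y0), 100.0)
            scales = np.maximum(np.abs(traj.states).max(axis=0), 1.0)
            assert float((traj.states / scales).min()) >= -1e-10

    def test_tolerance_halving_leaves_endpoint_unchanged(self,
                                                         scenario_runs):
        for name, (sc, traj, _) in scenario_runs.items():
            tight = integrate(sc.params, sc.init, sc.t_end, rtol=5e-11,
                              atol=tuple(a / 2 for a in DEFAULT_ATOL))
            a, b = traj.final_state(), tight.final_state()
            for i in (0, 1):
                change = abs(a[i] - b[i]) / max(abs(a[i]), abs(b[i]), 1.0)
                assert change <= 1e-4, name

    def test_invalid_horizon_rejected(self, params):
        with pytest.raises(DomainError):
            integrate(params, scenario("fig1").init, -1.0)


class TestReducedFlow:
    def test_tumor_axis_invariant(self, params):
        traj = integrate_reduced(params, (0.0, 5e6), N=3.0, t_end=500.0)
        assert np.all(traj.states[:, 0] == 0.0)

    def test_untreated_flow_converges_to_capacities(self, params):
        traj = integrate_reduced(params, (70.0, 30.0), N=0.0, t_end=30_000.0)
        T, S = traj.final_state()
        assert T == pytest.approx(params.K1, rel=1e-6)
        assert S == pytest.approx(params.K2, rel=1e-6)

    def test_attractor_matches_coexistence_search(self, params):
        traj = integrate_reduced(params, (70.0, 30.0), N=0.0, t_end=30_000.0)
        pts = coexistence_equilibria(params, 0.0)
        T, S = traj.final_state()
        assert any(abs(p.T - T) <= 1e-6 * params.K1
                   and abs(p.S - S) <= 1e-6 * params.K2 for p in pts)


class TestOutcomeClassification:
    def test_scenario_outcomes(self, scenario_runs):
        expected = {"fig1": "coexistence", "fig2": "recurrence",
                    "fig3": "cure"}
        for name, (sc, traj, _) in scenario_runs.items():
            assert classify_outcome(traj) == expected[name]

    def test_recurrence_is_stem_only(self, scenario_runs):
        _, traj, _ = scenario_runs["fig2"]
        T, S = traj.final_state()[:2]
        assert T < 1.0 <= S

    def test_transient_reported_undecided(self):
        t = np.linspace(0.0, 100.0, 50)
        states = np.zeros((t.size, 7))
        states[:, 0] = 10.0 * np.exp(0.05 * t)   # still growing strongly
        states[:, 1] = 5.0
        traj = Trajectory(times=t, states=states)
        assert classify_outcome(traj) == "undecided"

    def test_subcell_noise_does_not_trigger_undecided(self):
        t = np.linspace(0.0, 100.0, 50)
        states = np.zeros((t.size, 7))
        states[:, 0] = 1e-200 * np.exp(0.05 * t)  # far below one cell
        states[:, 1] = 2.0
        traj = Trajectory(times=t, states=states)
        assert classify_outcome(traj) == "recurrence"

    def test_empty_trajectory_rejected(self):
        with pytest.raises(DomainError):
            Trajectory(times=np.array([]), states=np.zeros((0, 7)))


class TestPerturbedParameterSets:
    def test_state_sum_bound_on_perturbed_models(self):
        from gliostem import dissipativity_constants
        fx = generate_fixtures(11)
        for name, cfg in fx.items():
            if not name.startswith("perturbed"):
                continue
            traj = integrate(cfg.parameters, cfg.initial_state, cfg.t_end)
            d = dissipativity_constants(cfg.parameters,
                                        C0=cfg.initial_state.C)
            W = traj.states.sum(axis=1)
            assert np.all(W <= max(W[0], d.A / d.delta) * (1 + 1e-6)), name
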