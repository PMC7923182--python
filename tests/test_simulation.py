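"""Integrator, events, steady-state detection and percent differences."""

import numpy as np
import pytest

from wntrho import (
    Event,
    NetworkModel,
    RateLaw,
    ReactionDef,
    Schedule,
    Simulator,
    SpeciesDef,
    find_steady_state,
    percent_difference,
    simulate,
)
from wntrho.simulation import SteadyStateError
from wntrho.wnt import WntVariantConfig, build_wnt_model, default_wnt_schedule


def decay_model(k=0.1, y0=10.0):
    return NetworkModel(
        "decay", [SpeciesDef("A", y0)],
        [ReactionDef("d", [("A", 1)], [], RateLaw("mass_action", {"k": k}))],
    )


def test_constant_model_flat_trajectory():
    model = NetworkModel("flat", [SpeciesDef("A", 2.5)])
    traj = simulate(model, Schedule(0, 100))
    np.testing.assert_allclose(traj.series("A"), 2.5)


def test_exponential_decay_closed_form():
    traj = simulate(decay_model(), Schedule(0, 10, output_times=np.array([0.0, 10.0])))
    assert traj.series("A")[-1] == pytest.approx(10 * np.exp(-1), rel=1e-6)


def test_event_is_hard_reset():
    model = decay_model()
    model_events = [Event(5.0, "A", 10.0)]
    traj = simulate(model, Schedule(0, 10, events=model_events,
                                    output_times=np.array([0.0, 5.0, 10.0])))
    # at t=5 the state is reset to 10, then decays for 5 more minutes
    assert traj.series("A")[1] == pytest.approx(10.0)
    assert traj.series("A")[2] == pytest.approx(10 * np.exp(-0.5), rel=1e-6)


def test_event_setting_current_value_is_identity():
    """An event that resets a species to its exact current value does not
    change the trajectory (beyond integrator reproducibility)."""
    grid = np.linspace(0, 10, 21)
    plain = simulate(decay_model(), Schedule(0, 10, output_times=grid))
    noop = simulate(
        decay_model(),
        Schedule(0, 10, events=[Event(5.0, "A", 10 * np.exp(-0.5))], output_times=grid),
    )
    np.testing.assert_allclose(plain.values, noop.values, rtol=1e-6, atol=1e-12)


def test_wnt_step_schedule_boundary_series(wnt_sim):
    """The Wnt input is piecewise constant: 0, then 1 nM on [4000, 15000), then 0."""
    traj = wnt_sim.simulate(default_wnt_schedule(), n_out=261)
    wnt = traj.series("Wnt")
    t = traj.times
    np.testing.assert_allclose(wnt[t < 4000], 0.0, atol=1e-9)
    np.testing.assert_allclose(wnt[(t >= 4000) & (t < 15000)], 1.0, rtol=1e-9)
    np.testing.assert_allclose(wnt[t >= 15000], 0.0, atol=1e-9)


def test_nonnegativity_of_shipped_model_trajectory(wnt_sim):
    traj = wnt_sim.simulate(default_wnt_schedule(), n_out=200)
    assert traj.values.min() >= -1e-8


class TestSteadyState:
    def test_reversible_pair_symmetry(self):
        model = NetworkModel(
            "ab",
            [SpeciesDef("A", 10.0), SpeciesDef("B", 0.0)],
            [
                ReactionDef("f", [("A", 1)], [("B", 1)], RateLaw("mass_action", {"k": 0.3})),
                ReactionDef("r", [("B", 1)], [("A", 1)], RateLaw("mass_action", {"k": 0.3})),
            ],
        )
        ss = find_steady_state(model)
        assert ss["A"] == pytest.approx(5.0, rel=1e-6)
        assert ss["B"] == pytest.approx(5.0, rel=1e-6)

    def test_synthesis_decay_closed_form(self):
        model = NetworkModel(
            "sd", [SpeciesDef("Y", 0.0)],
            [
                ReactionDef("s", [], [("Y", 1)], RateLaw("constant_synthesis", {"k": 1.0})),
                ReactionDef("d", [("Y", 1)], [], RateLaw("mass_action", {"k": 0.1})),
            ],
        )
        assert find_steady_state(model)["Y"] == pytest.approx(10.0, rel=1e-6)

    def test_two_start_agreement(self, rho_sim):
        """The steady state is locally stable: a start redistributing mass
        within the conserved pools converges to the same state."""
        inputs = {"RhoGEF": 100.0, "RhoGAP": 0.0}
        a = rho_sim.steady_state(inputs=inputs)
        perturbed = rho_sim.state_vector(
            {"RhoGDP": 0.0, "RhoGTP": 100.0, "MKL1c": 0.0, "MKL1n": 100.0}
        )
        b = rho_sim.steady_state(y0=perturbed, inputs=inputs)
        for name in rho_sim.species:
            assert b[name] == pytest.approx(a[name], rel=1e-5, abs=1e-8)

    def test_nonconvergence_reported(self):
        model = NetworkModel(
            "drift", [SpeciesDef("Y", 0.0)],
            [ReactionDef("s", [], [("Y", 1)], RateLaw("constant_synthesis", {"k": 1.0}))],
        )
        with pytest.raises(SteadyStateError, match="no steady state"):
            find_steady_state(model, t_max=1e4)
        ss = find_steady_state(model, t_max=1e4, raise_on_failure=False)
        assert not ss.converged

    def test_tolerance_tightening_stability(self, rho_sim):
        """10x tighter integration tolerances move steady states by < 0.1%."""
        inputs = {"RhoGEF": 100.0, "RhoGAP": 0.0}
        loose = rho_sim.steady_state(inputs=inputs)
        tight = rho_sim.steady_state(inputs=inputs, rtol=1e-9, atol=1e-11)
        for name in rho_sim.species:
            if loose[name] > 1e-6:
                assert tight[name] == pytest.approx(loose[name], rel=1e-3)


class TestPercentDifference:
    def test_equal_states_zero(self):
        assert percent_difference(0.3, 0.3) == 0.0

    def test_off_referenced_arithmetic(self):
        assert percent_difference(2.0, 1.0) == pytest.approx(50.0)

    def test_range_referenced(self):
        assert percent_difference(0.3, 0.1, "range_referenced", reference=0.4444444444) \
            == pytest.approx(45.0, rel=1e-6)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 0.1)
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.5, "range_referenced", reference=0.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown mode"):
            percent_difference(1.0, 0.5, "scaled")
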