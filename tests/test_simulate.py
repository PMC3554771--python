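"""Integration, steady-state location, and dose-response sweeps."""

import numpy as np
import pytest

from mapkscreen.config import SolverConfig, default_s_grid
from mapkscreen.network import (ConcentrationVector, KineticRates,
                                RATE_NAMES, build_network)
from mapkscreen.simulate import (NonStationaryError, UnreachableOutputError,
                                 dose_response_sweep, find_steady_state,
                                 integrate, invert_response,
                                 steady_state_course)
from mapkscreen.synth import synth_curves, hill_inverse

from conftest import SCREEN_SOLVER


def test_no_stimulus_quiescent_stays_flat(fixture_catalog):
    """At S = 0 nothing is ever produced: O(t) = 0 throughout."""
    fix = fixture_catalog["linear-responder"]
    net = build_network(fix.topology)
    traj = integrate(net, fix.rates, fix.cv.quiescent_state(), 0.0, 100.0)
    assert np.all(traj.output == 0.0)
    # untouched pools stay put
    assert traj.final_state[2] == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("name", ["linear-responder", "ultrasensitive",
                                  "bistable", "oscillator"])
def test_conservation_along_trajectories(fixture_catalog, name):
    """All six moiety totals drift by < 1e-8 relative over long runs."""
    fix = fixture_catalog[name]
    net = build_network(fix.topology)
    s = float(fix.expected["stimulus"])
    traj = integrate(net, fix.rates, fix.cv.quiescent_state(), s, 500.0)
    assert traj.conservation_drift(net) <= 1e-8


def test_cross_integrator_agreement(fixture_catalog):
    """LSODA trajectory matches a BDF run at 10x tighter tolerance."""
    from scipy.integrate import solve_ivp
    from mapkscreen.simulate import _make_funcs
    fix = fixture_catalog["ultrasensitive"]
    net = build_network(fix.topology)
    x0 = fix.cv.quiescent_state()
    traj = integrate(net, fix.rates, x0, 10.0, 200.0,
                     SolverConfig(rtol=1e-8, atol=1e-10))
    f, j = _make_funcs(net, fix.rates, 10.0)
    ref = solve_ivp(f, (0.0, 200.0), x0, method="BDF", jac=j,
                    rtol=1e-9, atol=1e-11, t_eval=traj.t)
    o_ref = np.clip(ref.y[9], 0.0, None) / fix.cv.mapk
    assert np.max(np.abs(traj.output - o_ref)) <= 1e-6


def test_integrate_rejects_nonpositive_horizon(fixture_catalog):
    fix = fixture_catalog["linear-responder"]
    net = build_network(fix.topology)
    with pytest.raises(ValueError):
        integrate(net, fix.rates, fix.cv.quiescent_state(), 1.0, 0.0)


def test_steady_state_zero_stimulus_no_output(fixture_catalog):
    fix = fixture_catalog["ultrasensitive"]
    net = build_network(fix.topology)
    ss = find_steady_state(net, fix.rates, fix.cv.quiescent_state(), 0.0,
                           SCREEN_SOLVER)
    assert ss[9] == pytest.approx(0.0, abs=1e-12)


def test_steady_state_agrees_with_long_integration(fixture_catalog):
    fix = fixture_catalog["linear-responder"]
    net = build_network(fix.topology)
    ss = find_steady_state(net, fix.rates, fix.cv.quiescent_state(), 10.0)
    traj = integrate(net, fix.rates, fix.cv.quiescent_state(), 10.0, 5000.0,
                     SolverConfig(rtol=1e-10, atol=1e-12))
    assert np.max(np.abs(ss - traj.final_state)) <= 1e-7


def test_oscillator_flagged_non_stationary(fixture_catalog):
    """A sustained limit cycle is a named outcome, not a solver failure."""
    fix = fixture_catalog["oscillator"]
    net = build_network(fix.topology)
    s = float(fix.expected["stimulus"])
    with pytest.raises(NonStationaryError) as exc:
        find_steady_state(net, fix.rates, fix.cv.quiescent_state(), s,
                          SCREEN_SOLVER)
    tail = exc.value.trajectory
    assert tail is not None and np.ptp(tail.output) > 0.05
    # course interface reports the same as a status, state is None
    state, course, status = steady_state_course(
        net, fix.rates, fix.cv.quiescent_state(), s, SCREEN_SOLVER)
    assert status == "oscillating" and state is None


def test_dose_response_monostable_branches_coincide(fixture_catalog):
    fix = fixture_catalog["linear-responder"]
    net = build_network(fix.topology)
    dr = dose_response_sweep(net, fix.rates, fix.cv,
                             default_s_grid(10.0, 16), SCREEN_SOLVER)
    assert dr.up_output[0] == pytest.approx(0.0, abs=1e-9)
    assert dr.up_mask.all() and dr.down_mask.all()
    assert np.max(np.abs(dr.up_output - dr.down_output)) <= 1e-6


def test_dose_response_deterministic(fixture_catalog):
    fix = fixture_catalog["ultrasensitive"]
    net = build_network(fix.topology)
    grid = default_s_grid(10.0, 10)
    a = dose_response_sweep(net, fix.rates, fix.cv, grid, SCREEN_SOLVER)
    b = dose_response_sweep(net, fix.rates, fix.cv, grid, SCREEN_SOLVER)
    assert np.array_equal(a.up_states, b.up_states)
    assert np.array_equal(a.down_states, b.down_states)


def test_dose_response_grid_validation(fixture_catalog):
    fix = fixture_catalog["linear-responder"]
    net = build_network(fix.topology)
    with pytest.raises(ValueError):
        dose_response_sweep(net, fix.rates, fix.cv, np.array([0.1, 1.0, 10.0]))


def test_bistable_fixture_shows_branch_separation(fixture_catalog):
    """Hysteresis: down branch exceeds up branch over a stimulus range."""
    fix = fixture_catalog["bistable"]
    net = build_network(fix.topology)
    dr = dose_response_sweep(net, fix.rates, fix.cv,
                             default_s_grid(10.0, 20), SCREEN_SOLVER)
    gap = np.nanmax(dr.down_output - dr.up_output)
    assert gap > 0.1


def test_invert_response_basics():
    dr = synth_curves("hill", K=1.0, n=2.0)
    assert invert_response(dr, "up", 0.0) == 0.0
    with pytest.raises(UnreachableOutputError):
        invert_response(dr, "up", 2.0)
    # closed-form agreement, refined by bisection on the analytic curve
    target = 0.4
    analytic = hill_inverse(target, 1.0, 1.0, 2.0)
    hill = lambda s: s ** 2 / (1 + s ** 2)  # noqa: E731
    s_ref = invert_response(dr, "up", target, refine=hill)
    assert s_ref == pytest.approx(analytic, rel=1e-3)
    # interpolation alone is close on a dense grid
    s_interp = invert_response(dr, "up", target)
    assert s_interp == pytest.approx(analytic, rel=0.05)


def test_invert_response_smallest_crossing_tie_break():
    """Non-monotone branch: the smallest crossing stimulus is returned."""
    dr = synth_curves("hill", K=1.0, n=2.0)
    o = dr.up_output.copy()
    # carve a dip so 0.5 is crossed three times
    n = len(o)
    o[2 * n // 3: 2 * n // 3 + 3] = 0.2
    dr.up_output = o
    first = invert_response(dr, "up", 0.5)
    hill_s = hill_inverse(0.5, 1.0, 1.0, 2.0)
    assert first == pytest.approx(hill_s, rel=0.1)


def test_gradient_stable_under_grid_refinement(fixture_catalog):
    """Doubling the stimulus grid changes Gradient by < 2%."""
    from mapkscreen.indicators import gradient
    fix = fixture_catalog["linear-responder"]
    net = build_network(fix.topology)
    g = {}
    for n_pts in (20, 40):
        dr = dose_response_sweep(net, fix.rates, fix.cv,
                                 default_s_grid(10.0, n_pts), SCREEN_SOLVER)
        g[n_pts] = gradient(dr, refine=True).value
    assert g[40] == pytest.approx(g[20], rel=0.02)
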