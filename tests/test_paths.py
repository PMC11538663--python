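"""Action quadrature, minimum action paths, and the gradient-system oracle.

For gradient flows F = -V' the minimized uphill action equals twice the
barrier height, which gives closed-form targets for every assertion here.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from caclandscape import (
    action,
    action_matrix,
    find_attractors,
    make_toy,
    minimize_action,
    pseudotime_profiles,
)
from caclandscape.paths import TransitionPath, _line_init


def _dw_V(x, tilt=0.0):
    return x ** 4 / 4 - x ** 2 / 2 + tilt * x


def test_action_along_deterministic_flow_is_zero(toggle, toggle_attractors):
    saddle = next(p for p in toggle_attractors.points if not p.stable)
    x0 = saddle.state + np.array([1e-3, -1e-3])
    sol = solve_ivp(lambda t, y: toggle.rhs(y), (0, 40.0), x0,
                    t_eval=np.linspace(0, 40.0, 401), rtol=1e-10, atol=1e-12)
    S = action(sol.y.T, toggle, T=40.0)
    assert S < 1e-4


def test_uphill_action_equals_twice_barrier(double_well):
    """Path traversed with phi_dot = +V' from -1 to 0 has S = 2*[V(0)-V(-1)]."""
    # time-reverse the downhill trajectory from just left of the saddle
    sol = solve_ivp(lambda t, y: double_well.rhs(y), (0, 60.0),
                    np.array([-1e-4]), t_eval=np.linspace(0, 60.0, 2001),
                    rtol=1e-11, atol=1e-13)
    path = sol.y.T[::-1]
    S = action(path, double_well, T=60.0)
    assert S == pytest.approx(2 * (_dw_V(0) - _dw_V(-1.0)), rel=2e-3)


def test_straight_line_action_matches_fine_quadrature(toggle, toggle_attractors):
    a, b = [p.state for p in toggle_attractors.stable_points]
    T = 10.0
    coarse = action(_line_init(a, b, 400), toggle, T=T)
    fine = action(_line_init(a, b, 4000), toggle, T=T)
    assert coarse == pytest.approx(fine, rel=1e-4)


def test_degenerate_paths_rejected(toggle):
    with pytest.raises(ValueError):
        action(np.zeros((5, 2)), toggle, T=0.0)
    with pytest.raises(ValueError):
        action(np.zeros((1, 2)), toggle, T=1.0)


def test_map_double_well_action_and_saddle_passage(dw_attractors, double_well):
    left, right = dw_attractors.stable_points
    p = minimize_action(double_well, left, right, N=201)
    assert p.converged
    assert p.action == pytest.approx(0.5, rel=0.02)
    # the optimal path crosses the saddle at x = 0
    assert np.min(np.abs(p.states[:, 0])) < 0.02
    # endpoints pinned
    assert p.states[0, 0] == pytest.approx(-1.0, abs=1e-6)
    assert p.states[-1, 0] == pytest.approx(1.0, abs=1e-6)


def test_map_refinement_converged(dw_attractors, double_well):
    left, right = dw_attractors.stable_points
    s101 = minimize_action(double_well, left, right, N=101).action
    s201 = minimize_action(double_well, left, right, N=201).action
    assert abs(s201 - s101) / s101 < 0.005


def test_toggle_forward_reverse_symmetry(toggle, toggle_attractors):
    a, b = toggle_attractors.stable_points
    fwd = minimize_action(toggle, a, b, N=101)
    rev = minimize_action(toggle, b, a, N=101)
    assert fwd.action == pytest.approx(rev.action, rel=0.01)


def test_minimization_ordering(toggle, toggle_attractors):
    """S(MAP) <= S(straight line) <= S(perturbed line)."""
    a, b = [p.state for p in toggle_attractors.stable_points]
    T = 20.0
    line = _line_init(a, b, 101)
    rng = np.random.default_rng(0)
    pert = line.copy()
    pert[1:-1] += 0.08 * np.abs(rng.standard_normal(pert[1:-1].shape))
    s_map = minimize_action(toggle, a, b, N=101, T_values=(T,)).action
    s_line = action(line, toggle, T=T)
    s_pert = action(pert, toggle, T=T)
    assert s_map <= s_line + 1e-9
    assert s_line <= s_pert + 1e-9


def test_action_matrix_trivial_and_tilted():
    sys = make_toy("tilted_well", tilt=0.1)
    aset = find_attractors(sys, n_starts=30, seed=2)
    aset.points.sort(key=lambda p: p.state[0])
    am = action_matrix(sys, aset.stable_points, N=151)
    assert am.S.shape == (2, 2)
    assert np.allclose(np.diag(am.S), 0.0)
    # closed form: S(i->j) = 2*[V(saddle) - V(i)] on the tilted potential
    saddle = next(p.state[0] for p in aset.points if not p.stable)
    xs = [p.state[0] for p in aset.stable_points]
    expect = [2 * (_dw_V(saddle, 0.1) - _dw_V(x, 0.1)) for x in xs]
    assert am.S[0, 1] == pytest.approx(expect[0], rel=0.03)
    assert am.S[1, 0] == pytest.approx(expect[1], rel=0.03)
    # escaping the shallow well costs less than escaping the deep well
    deep = int(np.argmin([_dw_V(x, 0.1) for x in xs]))
    shallow = 1 - deep
    assert am.S[shallow, deep] < am.S[deep, shallow]


def test_action_matrix_single_attractor():
    sys = make_toy("ou1d")
    aset = find_attractors(sys, n_starts=10, seed=0)
    am = action_matrix(sys, aset.stable_points)
    assert am.S.shape == (1, 1) and am.S[0, 0] == 0.0


def test_pseudotime_profiles_flat_and_pinned(toggle, toggle_attractors):
    a, b = toggle_attractors.stable_points
    const = TransitionPath(states=np.tile(a.state, (11, 1)), T=1.0, action=0.0)
    prof = pseudotime_profiles(const, toggle)
    assert prof["x1"].std() < 1e-12
    p = minimize_action(toggle, a, b, N=61)
    prof = pseudotime_profiles(p, toggle)
    np.testing.assert_allclose(prof.iloc[0][["x1", "x2"]], a.state, atol=1e-8)
    np.testing.assert_allclose(prof.iloc[-1][["x1", "x2"]], b.state, atol=1e-8)
    assert prof["arclength"].iloc[0] == 0.0
    assert prof["arclength"].iloc[-1] == 1.0
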