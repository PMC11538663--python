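"""Mean-field moments, mixture quasi-potential, projections."""

import numpy as np
import pytest

from caclandscape import (
    NoiseConfig,
    build_landscape,
    count_minima,
    find_attractors,
    make_toy,
    project_landscape,
    simulate,
    solve_moments,
)
from caclandscape.io import loads_config


def test_noise_config_positive():
    with pytest.raises(ValueError):
        NoiseConfig(D=0.0)


def test_ou_stationary_variance_closed_form():
    """1-D linear relaxation F = g - k*x: stationary variance D/k."""
    sys = make_toy("ou1d", k=2.0, g=1.0)
    aset = find_attractors(sys, n_starts=10, seed=0)
    mom = solve_moments(sys, aset.stable_points[0], D=0.01)
    assert mom.converged
    assert mom.var[0] == pytest.approx(0.01 / 2.0, rel=1e-12)


def test_decoupled_two_gene_variances():
    net = loads_config(
        "nodes: [{name: a, g: 1.0, k: 0.5}, {name: b, g: 2.0, k: 4.0}]\n"
        "regulations: []"
    )
    aset = find_attractors(net, n_starts=10, seed=0)
    mom = solve_moments(net, aset.stable_points[0], D=0.02)
    np.testing.assert_allclose(mom.var, [0.02 / 0.5, 0.02 / 4.0], rtol=1e-10)


def test_moments_reject_unstable_point(dw_attractors, double_well):
    saddle = next(p for p in dw_attractors.points if not p.stable)
    with pytest.raises(ValueError):
        solve_moments(double_well, saddle, D=0.01)


def test_toggle_variance_matches_langevin(toggle, toggle_attractors):
    """Mean-field diagonal variances within 15% of the Langevin marginal
    variances inside the basin (rare hops to the other well are excluded,
    since the linearized moments describe within-basin fluctuations)."""
    D = 0.01
    fp = toggle_attractors.stable_points[0]
    mom = solve_moments(toggle, fp, D)
    ens = simulate(toggle, D=D, n_traj=300, dt=0.005, T=30.0, seed=9,
                   x0=fp.state)
    final = ens.final_states
    in_basin = np.max(np.abs(final - fp.state), axis=1) < 0.6
    assert in_basin.mean() > 0.9
    emp = final[in_basin].var(axis=0)
    np.testing.assert_allclose(mom.var, emp, rtol=0.15)


def test_single_attractor_quadratic_potential():
    """-ln of one Gaussian: minimum at g/k, curvature 1/sigma = k/D."""
    sys = make_toy("ou1d", k=1.0, g=1.0)
    aset = find_attractors(sys, n_starts=10, seed=0)
    D = 0.01
    L = build_landscape(sys, aset, D=D, weights="equal")
    grids, U = project_landscape(L, ["x"], grid_size=401,
                                 extent=[(0.8, 1.2)])
    x = grids[0]
    coef = np.polyfit(x - 1.0, U - U.min(), 2)
    assert abs(x[np.argmin(U)] - 1.0) < 2e-3
    assert coef[0] == pytest.approx(0.5 / (D / 1.0), rel=1e-3)


def test_toggle_landscape_symmetry_and_normalization(toggle, toggle_attractors):
    L = build_landscape(toggle, toggle_attractors, D=0.01, weights="equal")
    grids, U = project_landscape(L, ("x1", "x2"), grid_size=160,
                                 extent=[(-0.5, 5.5), (-0.5, 5.5)])
    # swap symmetry of the symmetric switch
    np.testing.assert_allclose(U, U.T, atol=1e-8)
    assert count_minima(U) == 2
    # both minima equally deep
    half = U[: U.shape[0] // 2, :]
    assert U.min() == pytest.approx(half.min(), abs=1e-8)
    # quadrature normalization of exp(-U)
    dx = grids[0][1] - grids[0][0]
    dy = grids[1][1] - grids[1][0]
    assert np.exp(-U).sum() * dx * dy == pytest.approx(1.0, rel=0.01)


def test_marginal_of_single_component_is_gaussian():
    sys = make_toy("ou1d", k=1.0, g=1.0)
    aset = find_attractors(sys, n_starts=10, seed=0)
    L = build_landscape(sys, aset, D=0.02, weights="equal")
    x = np.linspace(0.5, 1.5, 101)
    pdf = L.marginal_pdf(["x"], [x])
    s2 = 0.02
    ref = np.exp(-((x - 1.0) ** 2) / (2 * s2)) / np.sqrt(2 * np.pi * s2)
    np.testing.assert_allclose(pdf, ref, rtol=1e-10)


def test_unknown_coordinate_rejected(toggle, toggle_attractors):
    L = build_landscape(toggle, toggle_attractors, D=0.01, weights="equal")
    with pytest.raises(KeyError):
        project_landscape(L, ("x1", "zzz"))


def test_zero_attractors_rejected(toggle):
    with pytest.raises(ValueError):
        build_landscape(toggle, [], D=0.01)


def test_action_weight_depths_scale_inversely_with_D():
    """Tilted double well: ln-weight (basin depth) differences from
    transition actions scale ~1/D at fixed dynamics."""
    sys = make_toy("tilted_well", tilt=0.1)
    aset = find_attractors(sys, n_starts=30, seed=2)
    aset.points.sort(key=lambda p: p.state[0])
    diffs = {}
    for D in (0.05, 0.025):
        L = build_landscape(sys, aset, D=D, weights="action")
        w = L.weights
        diffs[D] = np.log(w.max() / w.min())
        # minima of the projected landscape stay put as D shrinks
        grids, U = project_landscape(L, ["x"], grid_size=301,
                                     extent=[(-1.6, 1.6)])
        x = grids[0]
        mins = x[(U < np.roll(U, 1)) & (U < np.roll(U, -1))]
        assert np.min(np.abs(mins - aset.points[0].state[0])) < 0.02
    assert diffs[0.025] / diffs[0.05] == pytest.approx(2.0, rel=0.15)


def test_langevin_histogram_agrees_with_mean_field(toggle, toggle_attractors):
    """-ln(histogram) from simulation matches the mean-field potential:
    minima in the same cells and well-depth difference within 0.5 nats."""
    D = 0.01
    stable = toggle_attractors.stable_points
    x0 = np.vstack([np.tile(stable[0].state, (60, 1)),
                    np.tile(stable[1].state, (60, 1))])
    ens = simulate(toggle, D=D, n_traj=120, dt=0.005, T=60.0, seed=4, x0=x0)
    X = ens.samples()
    edges = np.linspace(0, 5.2, 27)
    H, _, _ = np.histogram2d(X[:, 0], X[:, 1], bins=[edges, edges])
    centers = 0.5 * (edges[1:] + edges[:-1])
    L = build_landscape(toggle, toggle_attractors, D=D, weights="equal")
    Umf = L.potential(("x1", "x2"), [centers, centers])
    # each empirical density peak sits within one grid cell of a
    # mean-field minimum
    half = len(centers) // 2
    i1 = np.unravel_index(np.argmax(H[:half, :]), H[:half, :].shape)
    i2 = np.unravel_index(np.argmax(H[half:, :]), H[half:, :].shape)
    i2 = (i2[0] + half, i2[1])
    m1 = np.unravel_index(np.argmin(Umf[:half, :]), Umf[:half, :].shape)
    m2 = np.unravel_index(np.argmin(Umf[half:, :]), Umf[half:, :].shape)
    m2 = (m2[0] + half, m2[1])
    for emp, mf in ((i1, m1), (i2, m2)):
        assert abs(emp[0] - mf[0]) <= 1 and abs(emp[1] - mf[1]) <= 1
    # equal-depth wells: empirical depth difference below 0.5 nats, as in
    # the mean-field mixture with equal weights
    depth_emp = abs(np.log(H[i1] / H[i2]))
    depth_mf = abs(Umf[m1] - Umf[m2])
    assert depth_mf < 1e-6
    assert depth_emp < 0.5
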