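"""Fixed-point search, stability, phenotype rules, bifurcation scans."""

import numpy as np
import pytest

from caclandscape import (
    FixedPoint,
    bifurcation_scan,
    classify_phenotype,
    find_attractors,
    make_toy,
)
from caclandscape.attractors import _settle


def brute_force_attractors(net, n_grid=9, box=6.0):
    """Oracle: settle a dense regular grid of starts, collect unique ends."""
    from caclandscape.attractors import _merge, state_scales

    grid = np.linspace(0.01, box, n_grid)
    pts = []
    for a in grid:
        for b in grid:
            fp = _settle(net, np.array([a, b]))
            if fp is not None and fp.stable:
                pts.append(fp)
                pts = _merge(pts, state_scales(net))
    return pts


def test_toggle_attractor_count_vs_brute_force(toggle, toggle_attractors):
    oracle = brute_force_attractors(toggle)
    assert len(oracle) == 2
    assert toggle_attractors.n_stable == 2
    saddles = [p for p in toggle_attractors.points if not p.stable]
    assert len(saddles) == 1
    # symmetric pair: coordinates swap
    a, b = [p.state for p in toggle_attractors.stable_points]
    np.testing.assert_allclose(sorted(a), sorted(b), rtol=1e-6)


def test_stable_points_reintegrate_to_themselves(toggle, toggle_attractors):
    from scipy.integrate import solve_ivp

    for p in toggle_attractors.stable_points:
        sol = solve_ivp(lambda t, y: toggle.rhs(y), (0, 200.0), p.state,
                        rtol=1e-9, atol=1e-12)
        assert np.max(np.abs(sol.y[:, -1] - p.state)) < 1e-3


def test_attractor_search_seed_stability(toggle):
    a1 = find_attractors(toggle, n_starts=80, seed=3, include_unstable=False)
    a2 = find_attractors(toggle, n_starts=80, seed=12345,
                         include_unstable=False)
    assert a1.n_stable == a2.n_stable == 2
    s1 = sorted(tuple(np.round(p.state, 6)) for p in a1.stable_points)
    s2 = sorted(tuple(np.round(p.state, 6)) for p in a2.stable_points)
    np.testing.assert_allclose(s1, s2, atol=1e-5)


def test_fold_normal_form_detected_at_zero():
    """dx/dt = r + x^2 has its saddle-node at exactly r = 0."""
    sys = make_toy("fold_normal_form")
    values = np.arange(-1.0, 0.5001, 0.05)
    d = bifurcation_scan(sys, "r", values, n_fresh_starts=8,
                         n_starts_first=20, seed=0)
    folds = d.fold_locations()
    assert len(folds) >= 1
    assert np.min(np.abs(folds - 0.0)) <= 0.05
    # brute-force confirmation at 10x finer resolution around the fold
    fine = np.arange(-0.2, 0.2001, 0.005)
    dfine = bifurcation_scan(sys, "r", fine, n_fresh_starts=8,
                             n_starts_first=20, seed=1)
    assert np.min(np.abs(dfine.fold_locations() - 0.0)) <= 0.005


def test_bifurcation_unknown_parameter(toggle):
    with pytest.raises(KeyError):
        bifurcation_scan(toggle, "nonexistent", np.linspace(0, 1, 3))


def _fp(cac, **markers):
    x = cac.input_state()
    for nm, v in markers.items():
        x[cac.index(nm)] = v
    return FixedPoint(state=x, residual=0.0, eigenvalues=np.array([-1.0]),
                      stable=True)


def test_phenotype_rules_on_constructed_states(cac):
    """Marker logic: A by top adipogenic markers, E by P53/miR145, M vs P1
    by ERK on the ZEB1-high background, P2 by elevated C/EBPalpha."""
    assert classify_phenotype(
        _fp(cac, PPARG=2.5, CEBPA=1.5, ZEB1=0.2), cac) == "A"
    assert classify_phenotype(
        _fp(cac, P53=0.8, miR145=0.7, ZEB1=0.1), cac) == "E"
    assert classify_phenotype(
        _fp(cac, ZEB1=1.8, ERK=1.4, CEBPA=0.2, PPARG=0.05), cac) == "M"
    assert classify_phenotype(
        _fp(cac, ZEB1=1.8, ERK=0.5, RKIP=1.0, CEBPA=0.1), cac) == "P1"
    assert classify_phenotype(
        _fp(cac, ZEB1=1.8, ERK=1.4, CEBPA=1.2, PPARG=0.2), cac) == "P2"
    # all-zero state matches no rule
    assert classify_phenotype(_fp(cac), cac) == "unclassified"


def test_classification_requires_marker_nodes(toggle):
    fp = FixedPoint(state=np.array([1.0, 0.1]), residual=0.0,
                    eigenvalues=np.array([-1.0]), stable=True)
    with pytest.raises(KeyError):
        classify_phenotype(fp, toggle)


def test_five_state_condition_phenotypes(cac_five_state):
    """At moderate TGF-beta with MEKi and Rosi the model is pentastable with
    one attractor of each phenotype, and the adipose state carries the top
    PPARgamma and C/EBPalpha levels."""
    net, aset = cac_five_state
    assert aset.n_stable == 5
    assert sorted(aset.labels()) == ["A", "E", "M", "P1", "P2"]
    ip, ic = net.index("PPARG"), net.index("CEBPA")
    a = aset.by_phenotype("A")
    for p in aset.stable_points:
        if p is not a:
            assert a.state[ip] > p.state[ip]
            assert a.state[ic] > p.state[ic]
    e = aset.by_phenotype("E")
    i53 = net.index("P53")
    assert e.state[i53] == max(p.state[i53] for p in aset.stable_points)
    # P2 sits above P1 on the adipogenic axis
    assert aset.by_phenotype("P2").state[ip] > aset.by_phenotype("P1").state[ip]
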