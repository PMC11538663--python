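"""Shifted-Hill regulation, vector field, Jacobian, and config round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from caclandscape import NetworkSpec, dump_config, shifted_hill
from caclandscape.io import loads_config
from caclandscape.network import shifted_hill_deriv


@pytest.mark.parametrize(
    "Y, S, lam, n, expected",
    [
        (0.0, 1.0, 2.0, 4, 1.0),                 # zero-input limit
        (0.7, 0.7, 3.0, 5, (1 + 3.0) / 2),       # half-saturation symmetry
        (1e6, 1.0, 0.1, 2, 0.1),                 # saturation limit -> lam
        (2.3, 1.0, 1.0, 3, 1.0),                 # neutral fold change
    ],
)
def test_shifted_hill_values(Y, S, lam, n, expected):
    assert shifted_hill(Y, S, lam, n) == pytest.approx(expected, abs=1e-6)


def test_shifted_hill_domain_errors():
    with pytest.raises(ValueError):
        shifted_hill(-0.1, 1.0, 2.0, 2)
    with pytest.raises(ValueError):
        shifted_hill(0.5, 0.0, 2.0, 2)


@settings(deadline=None, max_examples=60)
@given(
    y1=st.floats(0.0, 50.0), y2=st.floats(0.0, 50.0),
    S=st.floats(0.05, 10.0), lam=st.floats(0.02, 20.0),
    n=st.integers(1, 6),
)
def test_shifted_hill_monotone_and_bounded(y1, y2, S, lam, n):
    """Monotone increasing iff lam > 1, decreasing iff lam < 1; bounded by
    min(1, lam) and max(1, lam)."""
    lo, hi = sorted([y1, y2])
    f_lo, f_hi = shifted_hill(lo, S, lam, n), shifted_hill(hi, S, lam, n)
    if lam > 1:
        assert f_hi >= f_lo - 1e-12
    elif lam < 1:
        assert f_hi <= f_lo + 1e-12
    for f in (f_lo, f_hi):
        assert min(1.0, lam) - 1e-12 <= f <= max(1.0, lam) + 1e-12


def test_hill_derivative_flat_at_origin():
    assert shifted_hill_deriv(0.0, 1.0, 3.0, 2) == 0.0
    assert shifted_hill_deriv(0.0, 2.0, 3.0, 1) == pytest.approx((3.0 - 1) / 2.0)


def test_unregulated_node_steady_state():
    net = loads_config(
        "nodes: [{name: x, g: 1.5, k: 0.5}]\nregulations: []"
    )
    assert net.rhs(np.array([3.0])) == pytest.approx(0.0)
    assert net.jacobian(np.array([3.0]))[0, 0] == pytest.approx(-0.5)


def test_neutral_fold_change_reduces_to_linear(toggle):
    """With every lam = 1 the rhs is g - k*x regardless of regulator levels."""
    neutral = toggle.with_params(
        {"lam:x2->x1": 1.0, "lam:x1->x2": 1.0})
    x = np.array([0.3, 1.7])
    g = np.array([nd.g for nd in neutral.nodes])
    k = np.array([nd.k for nd in neutral.nodes])
    np.testing.assert_allclose(neutral.rhs(x), g - k * x, rtol=1e-12)


def test_symmetric_toggle_root_is_fixed_point(toggle):
    """The symmetric state x1 = x2 = x* solving g*Hs(x*) = k*x* (1-D root
    find oracle) must be a zero of the full 2-D vector field."""
    g, k = toggle.nodes[0].g, toggle.nodes[0].k
    rg = toggle.regulations[0]
    xstar = brentq(
        lambda x: g * shifted_hill(x, rg.S, rg.lam, rg.n) - k * x,
        1e-6, 2.0 * g / k)
    rate = toggle.rhs(np.array([xstar, xstar]))
    np.testing.assert_allclose(rate, 0.0, atol=1e-10)


@pytest.mark.parametrize("system", ["toggle", "cac"])
def test_jacobian_matches_finite_differences(system, toggle, cac, request):
    net = {"toggle": toggle, "cac": cac}[system]
    rng = np.random.default_rng(11)
    scales = np.ones(net.n_nodes)
    for _ in range(3):
        x = net.clamp_inputs(rng.uniform(0.05, 2.0, net.n_nodes))
        A = net.jacobian(x)
        h = 1e-6
        num = np.zeros_like(A)
        for j in range(net.n_nodes):
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            num[:, j] = (net.rhs(xp) - net.rhs(xm)) / (2 * h)
        denom = np.maximum(np.abs(num).max(), 1.0)
        assert np.max(np.abs(A - num)) / denom < 1e-6


def test_rhs_dimension_mismatch(toggle):
    with pytest.raises(ValueError):
        toggle.rhs(np.zeros(3))


def test_trajectories_stay_non_negative(cac):
    """Degradation proportional to X keeps the non-negative orthant invariant."""
    from scipy.integrate import solve_ivp

    rng = np.random.default_rng(5)
    x0 = cac.clamp_inputs(rng.uniform(0, 2, cac.n_nodes))
    sol = solve_ivp(lambda t, y: cac.rhs(y), (0, 50.0), x0, rtol=1e-8,
                    atol=1e-10)
    assert sol.success
    assert sol.y.min() > -1e-7


def test_config_round_trip_identity(toggle, cac):
    for net in (toggle, cac):
        text = dump_config(net)
        again = dump_config(loads_config(text))
        assert text == again


def test_parameter_get_set_roundtrip(cac):
    names = cac.parameter_names()
    assert len(names) == len(set(names))
    net = cac.copy()
    for nm in names[::23]:
        v = net.get_param(nm)
        net.set_param(nm, v * 1.5)
        assert net.get_param(nm) == pytest.approx(v * 1.5)
    with pytest.raises(KeyError):
        net.get_param("g:NOSUCHNODE")


def test_validation_errors():
    with pytest.raises(ValueError, match="missing rate 'k'"):
        NetworkSpec.from_dict(
            {"nodes": [{"name": "x", "g": 1.0}], "regulations": []})
    with pytest.raises(ValueError, match="not a declared node"):
        NetworkSpec.from_dict({
            "nodes": [{"name": "x", "g": 1.0, "k": 1.0}],
            "regulations": [
                {"source": "y", "target": "x", "lam": 2.0, "S": 1.0, "n": 2}],
        })


def test_tgfb_autoregulation_variant(cac):
    """The robustness variant promotes TGFB to a dynamical self-activating
    node; by default the variant edge is inactive."""
    assert all(r.variant is None for r in cac.active_regulations())
    d = cac.to_dict()
    d["options"]["tgfb_autoregulation"] = True
    var = NetworkSpec.from_dict(d)
    assert not var.node("TGFB").is_input
    assert any(r.source == "TGFB" and r.target == "TGFB"
               for r in var.active_regulations())
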