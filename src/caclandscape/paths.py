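"""Freidlin-Wentzell transition actions and minimum action paths.

The action of a path ``phi(t)`` over horizon ``T`` is

    S_T[phi] = 1/2 * integral_0^T |dphi/dt - F(phi)|^2 dt

and the most probable noise-driven transition between two attractors is
the path minimizing it.  Paths are discretized on N+1 points; the action
uses a midpoint/segment scheme whose gradient is available analytically
through the network Jacobian, so the minimization runs under L-BFGS-B
with pinned endpoints.  Since transitions between attractors favour
long horizons, the horizon is swept geometrically and the minimizing T
is kept.

For 1-D (and separable) gradient systems ``F = -dV/dx`` the minimized
uphill action equals ``2 * [V(saddle) - V(start)]``, which serves as the
closed-form oracle throughout the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .attractors import AttractorSet, FixedPoint, _dyn_idx

__all__ = [
    "TransitionPath",
    "ActionMatrix",
    "action",
    "minimize_action",
    "action_matrix",
    "pseudotime_profiles",
]


@dataclass
class TransitionPath:
    """Discretized path phi[0..N] with horizon T and its action."""

    states: np.ndarray      # (N+1, n_nodes)
    T: float
    action: float
    converged: bool = True

    @property
    def N(self) -> int:
        return self.states.shape[0] - 1

    def arclength(self) -> np.ndarray:
        """Normalized cumulative arc length along the path."""
        seg = np.linalg.norm(np.diff(self.states, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1] if s[-1] > 0 else 1.0
        return s / total


@dataclass
class ActionMatrix:
    """Pairwise minimized actions between attractors (diagonal 0)."""

    labels: list
    S: np.ndarray
    paths: dict = field(default_factory=dict)   # (i, j) -> TransitionPath


def _action_and_grad(phi_dyn, net, dyn, template, h, with_grad=True):
    """Discrete action and its gradient w.r.t. interior dynamical coords.

    phi_dyn: (N+1, d) path on dynamical coordinates (endpoints included).
    Segment scheme: v_i = (phi_{i+1}-phi_i)/h at midpoints m_i.
    """
    Np1, d = phi_dyn.shape
    full = np.tile(template, (Np1, 1))
    full[:, dyn] = phi_dyn
    mids = 0.5 * (full[1:] + full[:-1])
    v = (phi_dyn[1:] - phi_dyn[:-1]) / h
    Fm = net.rhs(mids)[:, dyn]
    r = v - Fm
    S = 0.5 * h * float(np.sum(r * r))
    if not with_grad:
        return S, None
    # dS/dphi_j = (r_{j-1} - r_j) - h/2 * (J_{j-1}^T r_{j-1} + J_j^T r_j)
    JTr = np.empty_like(r)
    for i in range(Np1 - 1):
        J = net.jacobian(mids[i])[np.ix_(dyn, dyn)]
        JTr[i] = J.T @ r[i]
    grad = np.zeros_like(phi_dyn)
    grad[1:] += r
    grad[:-1] -= r
    grad[1:] -= 0.5 * h * JTr
    grad[:-1] -= 0.5 * h * JTr
    return S, grad[1:-1]


def action(path, net, T: float | None = None) -> float:
    """Action of a discretized path (trapezoidal/midpoint quadrature).

    ``path`` is a :class:`TransitionPath` or an (N+1, n) array with ``T``
    supplied.  Degenerate paths (fewer than 2 points or T <= 0) raise.
    """
    if isinstance(path, TransitionPath):
        states, T = path.states, path.T
    else:
        states = np.asarray(path, dtype=float)
    if T is None or T <= 0:
        raise ValueError("path horizon T must be positive")
    if states.ndim != 2 or states.shape[0] < 2:
        raise ValueError("path needs at least 2 points")
    dyn = _dyn_idx(net)
    h = T / (states.shape[0] - 1)
    template = net.clamp_inputs(states[0])
    S, _ = _action_and_grad(states[:, dyn], net, dyn, template, h,
                            with_grad=False)
    return S


def _line_init(a: np.ndarray, b: np.ndarray, N: int, via=None) -> np.ndarray:
    """Linear interpolation a -> b, optionally through an intermediate."""
    if via is None:
        t = np.linspace(0.0, 1.0, N + 1)[:, None]
        return a[None, :] * (1 - t) + b[None, :] * t
    half = N // 2
    first = _line_init(a, np.asarray(via, dtype=float), half)
    second = _line_init(np.asarray(via, dtype=float), b, N - half)
    return np.vstack([first, second[1:]])


def minimize_action(net, from_point, to_point, N: int = 101,
                    T_values=(5.0, 10.0, 20.0, 40.0, 80.0),
                    via=None, seed: int = 0, maxiter: int = 500,
                    rel_tol: float = 1e-4, init_states=None) -> TransitionPath:
    """Minimum action path between two fixed points.

    The path vector (interior points, dynamical coordinates) is
    optimized by L-BFGS-B with the analytic action gradient, starting
    from linear interpolation (optionally through ``via``).  The horizon
    sweep keeps the minimizing T and stops early once lengthening the
    horizon improves the action by less than ``rel_tol`` relatively.
    Non-convergence of the optimizer flags the returned path.
    """
    a = np.asarray(getattr(from_point, "state", from_point), dtype=float)
    b = np.asarray(getattr(to_point, "state", to_point), dtype=float)
    dyn = _dyn_idx(net)
    template = net.clamp_inputs(a.copy())
    init_full = (np.asarray(init_states, dtype=float) if init_states is not None
                 else _line_init(a, b, N, via=via))
    non_neg = getattr(net, "non_negative", True)
    best = None
    prev_S = None
    warm = init_full[:, dyn]
    for T in T_values:
        h = T / N
        x0 = warm[1:-1].ravel()
        bounds = [(0.0, None)] * x0.size if non_neg else None

        def fun(z, h=h):
            phi = np.vstack([warm[:1], z.reshape(N - 1, len(dyn)), warm[-1:]])
            S, g = _action_and_grad(phi, net, dyn, template, h)
            return S, g.ravel()

        res = minimize(fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-12,
                                "gtol": 1e-10})
        phi = np.vstack([warm[:1], res.x.reshape(N - 1, len(dyn)), warm[-1:]])
        S = float(res.fun)
        if best is None or S < best[0]:
            full = np.tile(template, (N + 1, 1))
            full[:, dyn] = phi
            best = (S, T, full, bool(res.success))
            warm = phi  # warm-start the next horizon from the current optimum
        if prev_S is not None and prev_S - S < rel_tol * max(abs(prev_S), 1e-12):
            prev_S = min(prev_S, S)
            break
        prev_S = S
    S, T, full, ok = best
    return TransitionPath(states=full, T=T, action=S, converged=ok)


def action_matrix(net, attractors, N: int = 101,
                  T_values=(5.0, 10.0, 20.0, 40.0), seed: int = 0,
                  maxiter: int = 500, pairs=None, via=None) -> ActionMatrix:
    """Pairwise minimized actions between all (or selected) attractors.

    ``pairs`` restricts computation to the listed (i, j) index pairs;
    ``via`` optionally maps pairs to an intermediate attractor index for
    multi-hop initialization.  Diagonal entries are 0.
    """
    if isinstance(attractors, AttractorSet):
        stable = attractors.stable_points
        labels = [p.phenotype for p in stable]
    else:
        stable = list(attractors)
        labels = [getattr(p, "phenotype", str(i)) for i, p in enumerate(stable)]
    if len(stable) < 1:
        raise ValueError("need at least one attractor")
    n = len(stable)
    S = np.zeros((n, n))
    paths = {}
    todo = pairs if pairs is not None else [
        (i, j) for i in range(n) for j in range(n) if i != j]
    via = via or {}
    for (i, j) in todo:
        v = via.get((i, j))
        v_state = stable[v].state if v is not None else None
        p = minimize_action(net, stable[i], stable[j], N=N, T_values=T_values,
                            seed=seed, maxiter=maxiter, via=v_state)
        S[i, j] = p.action
        paths[(i, j)] = p
    return ActionMatrix(labels=labels, S=S, paths=paths)


def pseudotime_profiles(path: TransitionPath, net, nodes=None) -> pd.DataFrame:
    """Per-node expression along the path vs normalized arc length.

    Endpoints equal the pinned attractor states by construction.
    """
    names = list(net.node_names)
    nodes = nodes or names
    idx = [names.index(nm) for nm in nodes]
    s = path.arclength()
    df = pd.DataFrame(path.states[:, idx], columns=nodes)
    df.insert(0, "arclength", s)
    return df
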