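"""Stochastic simulation oracle: Langevin dynamics with additive noise.

Trajectories follow ``dx = F(x) dt + sqrt(2 D dt) eta`` (Euler-Maruyama)
with Gaussian white noise of intensity ``E[zeta_i(t) zeta_j(0)] =
2 D delta_ij delta(t)``.  Concentration variables are reflected at zero;
drug input coordinates are clamped and receive no noise.  Ensembles are
the independent check on the mean-field landscape (via histograms) and
the source of basin-occupancy statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TrajectoryEnsemble", "simulate", "occupancy"]


@dataclass
class TrajectoryEnsemble:
    """Thinned stored states of a batch of Langevin trajectories."""

    states: np.ndarray      # (n_stored, n_traj, n_nodes)
    times: np.ndarray
    dt: float
    D: float
    seed: int
    burn_in_frac: float = 0.2

    @property
    def n_traj(self) -> int:
        return self.states.shape[1]

    @property
    def final_states(self) -> np.ndarray:
        return self.states[-1]

    def samples(self, burn_in_frac: float | None = None) -> np.ndarray:
        """Post-burn-in states flattened to (n_samples, n_nodes)."""
        frac = self.burn_in_frac if burn_in_frac is None else burn_in_frac
        start = int(np.ceil(frac * self.states.shape[0]))
        kept = self.states[start:]
        return kept.reshape(-1, kept.shape[-1])


def simulate(net, D: float, n_traj: int = 100, dt: float = 0.01,
             T: float = 100.0, seed: int = 0, x0=None, thin: int = 10,
             burn_in_frac: float = 0.2) -> TrajectoryEnsemble:
    """Euler-Maruyama ensemble simulation of the network Langevin equation.

    ``x0`` may be a single state (replicated), an (n_traj, n) array, or
    None (starts drawn uniformly in the invariant box).  Noise is applied
    only to dynamical coordinates; for non-negative systems, coordinates
    are reflected at 0.  Blow-ups (states leaving 100x the system scale)
    abort with a diagnostic.
    """
    from .attractors import _dyn_idx, state_scales

    if D < 0:
        raise ValueError("diffusion coefficient D must be >= 0")
    rng = np.random.default_rng(seed)
    dyn = _dyn_idx(net)
    scales = state_scales(net)
    n = net.n_nodes
    if x0 is None:
        x = np.tile(net.input_state(), (n_traj, 1))
        lo = 0.0 if getattr(net, "non_negative", True) else -2.0 * scales[dyn]
        x[:, dyn] = lo + rng.random((n_traj, len(dyn))) * (2.0 * scales[dyn] - lo)
    else:
        x0 = np.asarray(x0, dtype=float)
        x = np.tile(x0, (n_traj, 1)) if x0.ndim == 1 else x0.copy()
        if x.shape != (n_traj, n):
            raise ValueError(f"x0 shape {x.shape} != ({n_traj}, {n})")
        x = net.clamp_inputs(x)
    n_steps = int(round(T / dt))
    store_every = max(int(thin), 1)
    stored = [x.copy()]
    times = [0.0]
    amp = np.sqrt(2.0 * D * dt)
    blow = 100.0 * np.max(scales)
    non_neg = getattr(net, "non_negative", True)
    for step in range(1, n_steps + 1):
        drift = net.rhs(x)
        x = x + drift * dt
        if D > 0:
            x[:, dyn] += amp * rng.standard_normal((n_traj, len(dyn)))
        if non_neg:
            x[:, dyn] = np.abs(x[:, dyn])  # reflecting boundary at 0
        x = net.clamp_inputs(x)
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > blow:
            raise FloatingPointError(
                f"Langevin blow-up at t={step * dt:.3f}: max |x| exceeds "
                f"{blow:.3g}; reduce dt or check the vector field"
            )
        if step % store_every == 0:
            stored.append(x.copy())
            times.append(step * dt)
    return TrajectoryEnsemble(states=np.array(stored), times=np.array(times),
                              dt=dt, D=D, seed=seed, burn_in_frac=burn_in_frac)


def occupancy(ensemble: TrajectoryEnsemble, attractors, scales=None,
              max_dist: float = 3.0):
    """Fraction of post-burn-in samples per attractor basin.

    Samples are assigned to the nearest attractor in rescaled state
    space (per-coordinate spread of the attractor means, floored at 5%
    of the system scale).  Samples whose RMS rescaled distance to every
    attractor exceeds ``max_dist`` count as transient and are reported
    separately rather than forced into a basin.  Returns ``(fractions, transient_fraction)``
    with fractions summing to 1 over assigned samples.
    """
    from .attractors import AttractorSet

    if isinstance(attractors, AttractorSet):
        means = np.array([p.state for p in attractors.stable_points])
        sys_scales = attractors.scales
    else:
        means = np.asarray(attractors, dtype=float)
        sys_scales = np.ones(means.shape[1]) if scales is None else np.asarray(scales)
    if means.ndim != 2 or len(means) == 0:
        raise ValueError("need at least one attractor state")
    spread = means.std(axis=0)
    norm = np.maximum(spread, 0.05 * sys_scales)
    X = ensemble.samples()
    # RMS of per-coordinate distances in units of attractor spread
    d = np.linalg.norm((X[:, None, :] - means[None, :, :]) / norm, axis=2)
    d /= np.sqrt(means.shape[1])
    nearest = np.argmin(d, axis=1)
    dmin = d[np.arange(len(X)), nearest]
    assigned = dmin <= max_dist
    if not np.any(assigned):
        return np.zeros(len(means)), 1.0
    counts = np.bincount(nearest[assigned], minlength=len(means)).astype(float)
    fractions = counts / counts.sum()
    transient = 1.0 - assigned.mean()
    return fractions, float(transient)
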