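"""Self-consistent mean-field quasi-potential landscapes.

Around each stable attractor the stationary distribution is approximated
by a product of per-coordinate Gaussians: the mean sits at the attractor
and the variances solve the diagonal of the fluctuation (Lyapunov)
relation ``0 = sigma A^T + A sigma + 2 D I`` with off-diagonal elements
dropped (mean-field truncation), i.e. ``sigma_i = -D / A_ii``.  The
steady-state probability is the weighted mixture over attractors and the
quasi-potential is ``U(x) = -ln P_ss(x)``.  Mixture weights default to
long-run basin occupancies estimated by the Langevin oracle; equal
weights are available for quick looks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_continuous_lyapunov

from .attractors import AttractorSet, FixedPoint, _dyn_idx, state_scales

__all__ = [
    "NoiseConfig",
    "MomentSolution",
    "LandscapeResult",
    "solve_moments",
    "build_landscape",
    "project_landscape",
    "count_minima",
]


@dataclass
class NoiseConfig:
    """Constant isotropic diffusion coefficient (concentration^2 / time)."""

    D: float = 0.01

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("diffusion coefficient D must be > 0")


@dataclass
class MomentSolution:
    """Gaussian moments of one attractor: mean vector and diagonal variance."""

    mean: np.ndarray
    var: np.ndarray          # full length; 0 on input coordinates
    converged: bool
    attractor: FixedPoint | None = None


def solve_moments(net, attractor: FixedPoint, D: float) -> MomentSolution:
    """Steady-state Gaussian moments at a stable attractor.

    The mean is the attractor state; the diagonal variance solves the
    diagonal restriction of the Lyapunov relation, ``sigma_i = -D/A_ii``.
    If a diagonal Jacobian entry is non-negative (possible at a stable
    point with strong rotational coupling) the diagonal of the full
    Lyapunov solution is used instead.  Raises for unstable points,
    whose linearized variance diverges.
    """
    if not attractor.stable:
        raise ValueError("moment equations diverge at an unstable fixed point")
    if D <= 0:
        raise ValueError("diffusion coefficient D must be > 0")
    dyn = _dyn_idx(net)
    A = net.jacobian(attractor.state)[np.ix_(dyn, dyn)]
    diag = np.diag(A)
    converged = True
    if np.all(diag < 0):
        var_dyn = -D / diag
    else:
        sigma = solve_continuous_lyapunov(A, -2.0 * D * np.eye(len(dyn)))
        var_dyn = np.diag(sigma).copy()
        converged = bool(np.all(var_dyn > 0))
    var = np.zeros(net.n_nodes)
    var[dyn] = var_dyn
    return MomentSolution(mean=np.array(attractor.state, dtype=float),
                          var=var, converged=converged, attractor=attractor)


@dataclass
class LandscapeResult:
    """Gaussian-mixture steady state and its quasi-potential."""

    components: list            # list of (MomentSolution, weight)
    D: float
    node_names: list
    dyn_idx: np.ndarray
    scales: np.ndarray
    transient_fraction: float = 0.0

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([m.mean for m, _ in self.components])

    def _coord_index(self, coord) -> int:
        if isinstance(coord, str):
            if coord not in self.node_names:
                raise KeyError(f"unknown coordinate {coord!r}")
            i = self.node_names.index(coord)
        else:
            i = int(coord)
        if i not in self.dyn_idx:
            raise KeyError(f"coordinate {coord!r} is not a dynamical node")
        return i

    def marginal_pdf(self, coords, grids) -> np.ndarray:
        """Exact marginal of the product-form mixture on a mesh.

        ``coords`` is a list of node names/indices, ``grids`` matching
        1-D arrays; returns the joint marginal density on the outer
        product mesh (shape ``len(grids[0]) x len(grids[1]) x ...``).
        """
        idxs = [self._coord_index(c) for c in coords]
        mesh = np.meshgrid(*grids, indexing="ij")
        out = np.zeros_like(mesh[0], dtype=float)
        for mom, w in self.components:
            comp = np.ones_like(out)
            for ax, i in enumerate(idxs):
                mu, s2 = mom.mean[i], mom.var[i]
                comp *= np.exp(-((mesh[ax] - mu) ** 2) / (2.0 * s2)) / np.sqrt(
                    2.0 * np.pi * s2)
            out += w * comp
        return out

    def potential(self, coords, grids, floor: float = 1e-300) -> np.ndarray:
        """U = -ln of the marginal density (floored to stay finite)."""
        return -np.log(np.maximum(self.marginal_pdf(coords, grids), floor))


def build_landscape(net, attractors, D: float = 0.01, weights="occupancy",
                    seed: int = 0, n_traj: int = 200, T: float = 200.0,
                    dt: float = 0.01) -> LandscapeResult:
    """Assemble the mixture quasi-potential over a set of stable attractors.

    ``weights`` is ``"occupancy"`` (Langevin long-run basin occupancy,
    the default), ``"equal"``, or an explicit sequence.  At least one
    stable attractor with converged moments is required.
    """
    if isinstance(attractors, AttractorSet):
        stable = attractors.stable_points
    else:
        stable = [p for p in attractors if p.stable]
    if not stable:
        raise ValueError("landscape needs at least one stable attractor")
    moments = [solve_moments(net, p, D) for p in stable]
    transient = 0.0
    if isinstance(weights, str) and weights == "equal":
        w = np.full(len(stable), 1.0 / len(stable))
    elif isinstance(weights, str) and weights == "occupancy":
        if len(stable) == 1:
            w = np.array([1.0])
        else:
            from .langevin import occupancy as _occ
            from .langevin import simulate as _sim

            ens = _sim(net, D=D, n_traj=n_traj, dt=dt, T=T, seed=seed)
            means = np.array([p.state for p in stable])
            w, transient = _occ(ens, means, scales=state_scales(net))
            if w.sum() <= 0:
                w = np.full(len(stable), 1.0 / len(stable))
            # never let a live attractor carry exactly zero weight
            w = np.maximum(w, 1e-6)
            w = w / w.sum()
    elif isinstance(weights, str) and weights == "action":
        # Freidlin-Wentzell stationary weights: transition rates
        # ~ exp(-S_ij / 2D) between attractors, stationary distribution of
        # the resulting master equation.  ln-weight differences scale ~1/D.
        if len(stable) == 1:
            w = np.array([1.0])
        else:
            from .paths import action_matrix as _am

            am = _am(net, stable, N=61, T_values=(5.0, 10.0, 20.0, 40.0))
            S = am.S - am.S.min()
            R = np.exp(-S / (2.0 * D))
            np.fill_diagonal(R, 0.0)
            Q = R.T - np.diag(R.sum(axis=1))
            vals, vecs = np.linalg.eig(Q)
            idx = int(np.argmin(np.abs(vals)))
            w = np.abs(np.real(vecs[:, idx]))
            w = np.maximum(w / w.sum(), 1e-300)
    elif isinstance(weights, str):
        raise ValueError(f"unknown weights policy {weights!r}")
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(stable),) or np.any(w < 0):
            raise ValueError("weights must be non-negative, one per attractor")
        w = w / w.sum()
    return LandscapeResult(components=list(zip(moments, w)), D=D,
                           node_names=list(net.node_names),
                           dyn_idx=_dyn_idx(net), scales=state_scales(net),
                           transient_fraction=transient)


def _default_extent(landscape: LandscapeResult, i: int) -> tuple[float, float]:
    mus = landscape.means[:, i]
    sds = np.sqrt([max(m.var[i], 1e-12) for m, _ in landscape.components])
    hi = 1.2 * float(np.max(mus + 4.0 * sds))
    lo = float(np.min(mus - 4.0 * sds))
    return (min(0.0, lo), hi)


def project_landscape(landscape: LandscapeResult, coords, grid_size: int = 200,
                      extent=None, pc_basis=None, n_samples: int = 20000,
                      seed: int = 0):
    """Project the quasi-potential to 1-D or 2-D for visualization.

    For named coordinate pairs the projection is the analytic marginal
    of the product-form mixture (exact).  For ``coords="pca"`` (or an
    explicit 2-column basis) the mixture is sampled, projected onto the
    principal-component basis fitted to the samples, and the density is
    estimated by a Gaussian KDE before taking ``-ln``.

    Returns ``(grids, U)``: the list of grid axes and the potential.
    """
    if isinstance(coords, str) and coords != "pca":
        coords = [coords]
    if coords == "pca" or pc_basis is not None:
        return _project_pca(landscape, grid_size, pc_basis, n_samples, seed)
    idxs = [landscape._coord_index(c) for c in coords]
    grids = []
    for ax, i in enumerate(idxs):
        lo, hi = extent[ax] if extent is not None else _default_extent(landscape, i)
        grids.append(np.linspace(lo, hi, grid_size))
    U = landscape.potential(coords, grids)
    return grids, U


def _sample_mixture(landscape: LandscapeResult, n: int, rng) -> np.ndarray:
    w = landscape.weights
    choices = rng.choice(len(w), size=n, p=w / w.sum())
    dyn = landscape.dyn_idx
    out = np.empty((n, len(dyn)))
    for k, (mom, _) in enumerate(landscape.components):
        mask = choices == k
        m = int(mask.sum())
        if m == 0:
            continue
        mu = mom.mean[dyn]
        sd = np.sqrt(np.maximum(mom.var[dyn], 1e-12))
        out[mask] = mu + rng.standard_normal((m, len(dyn))) * sd
    return out


def _project_pca(landscape, grid_size, pc_basis, n_samples, seed):
    from scipy.stats import gaussian_kde

    rng = np.random.default_rng(seed)
    X = _sample_mixture(landscape, n_samples, rng)
    Xc = X - X.mean(axis=0)
    if pc_basis is None:
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        basis = vt[:2].T
    else:
        basis = np.asarray(pc_basis, dtype=float)
        if basis.shape != (X.shape[1], 2):
            raise ValueError("pc_basis must be (n_dyn_nodes, 2)")
    P = Xc @ basis
    kde = gaussian_kde(P.T)
    gx = np.linspace(P[:, 0].min(), P[:, 0].max(), grid_size)
    gy = np.linspace(P[:, 1].min(), P[:, 1].max(), grid_size)
    mesh = np.meshgrid(gx, gy, indexing="ij")
    dens = kde(np.vstack([mesh[0].ravel(), mesh[1].ravel()]))
    U = -np.log(np.maximum(dens.reshape(grid_size, grid_size), 1e-300))
    return [gx, gy], U


def count_minima(U: np.ndarray, p_floor: float = 1e-10) -> int:
    """Count local minima of a gridded potential where the density is
    non-negligible (``exp(-U)`` above ``p_floor`` of its maximum)."""
    from scipy.ndimage import minimum_filter

    P = np.exp(-(U - U.min()))
    local_min = (U == minimum_filter(U, size=3, mode="nearest")) & (P > p_floor)
    # merge plateau-adjacent minima
    from scipy.ndimage import label

    _, n = label(local_min)
    return int(n)
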