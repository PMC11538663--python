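"""Toy systems with closed-form answers, and synthetic expression data.

The toy systems (:func:`make_toy`) carry their analytic facts — fixed
points, barrier heights, stationary variances — so that every numerical
stage of the package can be checked against a known answer.  The
expression generator emulates the statistical structure of clustered
bulk RNA-seq data: per-gene state means taken from model attractors,
multiplicative log-normal noise, and state labels attached per sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .network import NetworkSpec, NodeSpec, RegulationSpec

__all__ = [
    "VectorFieldSystem",
    "make_toy",
    "SyntheticExpressionMatrix",
    "generate_expression",
    "compare_states_to_data",
]

log = logging.getLogger(__name__)


class VectorFieldSystem:
    """A generic dynamical system with the same interface as NetworkSpec.

    Used for gradient-system toys whose states may be negative and whose
    parameters are a flat name->value mapping.  ``rhs_fn(x, params)``
    must broadcast over a leading batch axis.
    """

    def __init__(self, name: str, node_names: list[str], params: dict,
                 rhs_fn: Callable, jac_fn: Callable,
                 state_scale, non_negative: bool = False,
                 facts: dict | None = None):
        self.name = name
        self.node_names = list(node_names)
        self.params = dict(params)
        self._rhs_fn = rhs_fn
        self._jac_fn = jac_fn
        self.state_scale = np.asarray(state_scale, dtype=float)
        self.non_negative = non_negative
        self.facts = dict(facts or {})
        self.input_levels: dict = {}

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def dynamical_indices(self) -> np.ndarray:
        return np.arange(self.n_nodes)

    def index(self, name: str) -> int:
        return self.node_names.index(name)

    def clamp_inputs(self, state):
        return np.array(state, dtype=float)

    def input_state(self) -> np.ndarray:
        return np.zeros(self.n_nodes)

    def rhs(self, state):
        x = np.asarray(state, dtype=float)
        return self._rhs_fn(x, self.params)

    def jacobian(self, state):
        x = np.asarray(state, dtype=float)
        return self._jac_fn(x, self.params)

    def parameter_names(self) -> list[str]:
        return sorted(self.params)

    def get_param(self, name: str) -> float:
        return self.params[name]

    def set_param(self, name: str, value: float) -> None:
        if name not in self.params:
            raise KeyError(name)
        self.params[name] = float(value)

    def with_params(self, updates: Mapping[str, float]) -> "VectorFieldSystem":
        new = self.copy()
        for k, v in updates.items():
            new.set_param(k, v)
        return new

    def scale_params(self, multipliers: Mapping[str, float]) -> "VectorFieldSystem":
        new = self.copy()
        for k, fac in multipliers.items():
            if fac <= 0:
                raise ValueError(f"multiplier for {k} must be > 0")
            new.set_param(k, new.get_param(k) * fac)
        return new

    def copy(self) -> "VectorFieldSystem":
        return VectorFieldSystem(self.name, self.node_names, self.params,
                                 self._rhs_fn, self._jac_fn, self.state_scale,
                                 self.non_negative, self.facts)


# ----------------------------------------------------------------------
# toy factory

def _ou1d(k: float = 1.0, g: float = 0.0) -> VectorFieldSystem:
    def rhs(x, p):
        return p["g"] - p["k"] * x

    def jac(x, p):
        return np.array([[-p["k"]]])

    return VectorFieldSystem(
        "ou1d", ["x"], {"k": k, "g": g}, rhs, jac, [max(abs(g / k), 1.0) * 2],
        facts={"fixed_point": g / k,
               "stationary_variance": lambda D, k=k: D / k},
    )


def _double_well_1d(tilt: float = 0.0, inert: float = 1.0) -> VectorFieldSystem:
    """Gradient flow of V(x) = x^4/4 - x^2/2 + tilt*x.

    At tilt = 0: minima at +-1, saddle at 0, barrier V(0)-V(-1) = 1/4.
    The ``inert`` parameter does not enter the dynamics (used as a
    negative control in sensitivity tests).
    """
    def V(x, tilt=tilt):
        return x ** 4 / 4.0 - x ** 2 / 2.0 + tilt * x

    def rhs(x, p):
        return -(x ** 3 - x + p["tilt"]) + 0.0 * p["inert"]

    def jac(x, p):
        return np.array([[-(3.0 * x[0] ** 2 - 1.0)]])

    return VectorFieldSystem(
        "double_well_1d" if tilt == 0 else "tilted_well",
        ["x"], {"tilt": tilt, "inert": inert}, rhs, jac, [2.0],
        facts={"potential": V, "minima": (-1.0, 1.0), "saddle": 0.0,
               "barrier": 0.25},
    )


def _normal_form_fold(r: float = -1.0) -> VectorFieldSystem:
    """dx/dt = r + x^2: saddle-node at r = 0 (stable branch -sqrt(-r))."""
    def rhs(x, p):
        return p["r"] + x ** 2

    def jac(x, p):
        return np.array([[2.0 * x[0]]])

    return VectorFieldSystem("fold_normal_form", ["x"], {"r": r}, rhs, jac,
                             [2.0], facts={"fold_at": 0.0})


def _toggle_switch(g: float = 4.0, k: float = 1.0, lam: float = 0.1,
                   S: float = 2.0, n: int = 4) -> NetworkSpec:
    """Symmetric two-gene toggle switch (mutual shifted-Hill inhibition).

    Default parameters put the wells ~3.3 concentration units apart with a
    transition action ~1.5, so the default noise D = 0.01 is deep in the
    small-noise regime the mean-field approximation assumes.
    """
    nodes = [NodeSpec("x1", g=g, k=k), NodeSpec("x2", g=g, k=k)]
    regs = [
        RegulationSpec("x2", "x1", lam=lam, S=S, n=n),
        RegulationSpec("x1", "x2", lam=lam, S=S, n=n),
    ]
    return NetworkSpec(nodes, regs, name="toggle_switch")


def make_toy(name: str, **kwargs):
    """Return a named toy system with documented closed-form properties.

    Known names: ``ou1d``, ``double_well_1d``, ``tilted_well``,
    ``toggle_switch``, ``fold_normal_form``.
    """
    factories = {
        "ou1d": _ou1d,
        "double_well_1d": _double_well_1d,
        "tilted_well": lambda **kw: _double_well_1d(**{"tilt": 0.1, **kw}),
        "toggle_switch": _toggle_switch,
        "fold_normal_form": _normal_form_fold,
    }
    if name not in factories:
        raise KeyError(f"unknown toy system {name!r}; known: {sorted(factories)}")
    return factories[name](**kwargs)


# ----------------------------------------------------------------------
# synthetic expression matrices

@dataclass
class SyntheticExpressionMatrix:
    """Genes-by-samples matrix with per-sample state labels."""

    values: pd.DataFrame          # genes x samples
    sample_labels: list           # state label per sample (column)
    state_means: pd.DataFrame     # genes x states used as generative means
    noise_sd: float
    seed: int

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.columns = [f"{lbl}_{i}" for i, lbl in enumerate(self.sample_labels)]
        out.to_csv(path, sep="\t")


def generate_expression(state_means, labels=None, n_per_state: int = 20,
                        noise_sd: float = 0.3, seed: int = 0,
                        gene_names=None) -> SyntheticExpressionMatrix:
    """Emulate cluster-structured bulk expression around model attractors.

    ``state_means`` is a (genes x states) DataFrame or an array with
    ``gene_names``/``labels`` supplied.  Each sample is drawn as
    ``exp(log(mean) + eps)`` with ``eps ~ N(0, noise_sd^2)`` i.i.d. per
    gene (multiplicative log-normal noise).  Zero noise reproduces the
    state means exactly.  Non-positive means are offset by a small
    pseudocount (logged) so the log transform is defined.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if isinstance(state_means, pd.DataFrame):
        means = state_means.copy()
    else:
        arr = np.asarray(state_means, dtype=float)
        if labels is None or gene_names is None:
            raise ValueError("array input needs gene_names and labels")
        means = pd.DataFrame(arr, index=gene_names, columns=labels)
    if means.shape[1] < 2:
        raise ValueError("need at least 2 states")
    labels = list(means.columns)
    mvals = means.to_numpy()
    if np.any(mvals <= 0):
        offset = max(1e-6, 1e-4 * np.abs(mvals).max())
        log.info("non-positive state means: applying pseudocount offset %.3g", offset)
        warnings.warn(f"non-positive state means offset by {offset:.3g}")
        mvals = mvals + offset
    rng = np.random.default_rng(seed)
    cols, col_labels = [], []
    for j, lbl in enumerate(labels):
        eps = rng.normal(0.0, noise_sd, size=(means.shape[0], n_per_state)) \
            if noise_sd > 0 else np.zeros((means.shape[0], n_per_state))
        samples = np.exp(np.log(mvals[:, [j]]) + eps)
        cols.append(samples)
        col_labels.extend([lbl] * n_per_state)
    values = pd.DataFrame(np.hstack(cols), index=means.index)
    return SyntheticExpressionMatrix(values=values, sample_labels=col_labels,
                                     state_means=means, noise_sd=noise_sd,
                                     seed=seed)


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0).replace(0.0, 1.0)
    return df.sub(mu, axis=0).div(sd, axis=0)


def compare_states_to_data(model_states: pd.DataFrame, matrix, gene_map=None):
    """Compare model attractor states with (synthetic) expression data.

    ``model_states`` is genes x states; ``matrix`` a
    :class:`SyntheticExpressionMatrix` or a genes x samples DataFrame
    with labels in the column names (``LABEL_i``).  Both sides are
    z-scored per gene across states before comparison.  Returns
    ``(diff, corr)``: the per-gene per-state absolute difference table
    (model state vs matching data centroid) and the Pearson correlation
    matrix of model states against all data centroids.
    """
    if isinstance(matrix, SyntheticExpressionMatrix):
        data = matrix.values
        labels = matrix.sample_labels
    else:
        data = matrix
        labels = [str(c).rsplit("_", 1)[0] for c in matrix.columns]
    gene_map = gene_map or {}
    model = model_states.rename(index=gene_map)
    shared = [g for g in model.index if g in data.index]
    if not shared:
        raise ValueError("no shared gene names between model and data")
    model = model.loc[shared]
    centroids = {}
    for lbl in dict.fromkeys(labels):
        idx = [i for i, l in enumerate(labels) if l == lbl]
        centroids[lbl] = data.loc[shared].iloc[:, idx].mean(axis=1)
    cent = pd.DataFrame(centroids)
    mz = _zscore_rows(model)
    cz = _zscore_rows(cent)
    common = [s for s in mz.columns if s in cz.columns]
    diff = (mz[common] - cz[common]).abs() if common else pd.DataFrame(index=shared)
    corr = pd.DataFrame(
        {dl: {ml: _pearson(mz[ml].to_numpy(), cz[dl].to_numpy())
              for ml in mz.columns} for dl in cz.columns}
    )
    return diff, corr


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
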