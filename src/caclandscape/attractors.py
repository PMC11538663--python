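"""Fixed points, stability, phenotypes, and one-parameter bifurcation scans.

Stable states of the network ODE are found by a multi-start protocol:
Latin-hypercube initial conditions drawn inside the invariant box of the
dynamics, forward integration until the flow settles, then Newton
polishing of the candidate root.  Fixed points closer than a merge
tolerance (relative L-infinity) are deduplicated.  Saddles are located
by root finding from midpoints between stable states.

Phenotype labels follow the marker logic of the cancer-adipose
conversion circuit: E (epithelial; P53/miR145 high), M (mesenchymal;
ZEB1 high with active MEK/ERK), A (adipose; PPARgamma and C/EBPalpha
top-ranked), and the partial-EMT intermediates P1 (ZEB1 high, ERK shut
off by re-expressed RKIP) and P2 (ZEB1 high with elevated adipogenic
markers, PPARgamma above P1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.stats import qmc

from .network import NetworkSpec

__all__ = [
    "FixedPoint",
    "AttractorSet",
    "BifurcationDiagram",
    "find_attractors",
    "classify_phenotype",
    "classify_attractors",
    "bifurcation_scan",
    "DEFAULT_PHENOTYPE_RULES",
]

MERGE_TOL = 1e-3


@dataclass(eq=False)
class FixedPoint:
    """A root of the vector field with its stability spectrum."""

    state: np.ndarray
    residual: float
    eigenvalues: np.ndarray
    stable: bool
    phenotype: str = "unclassified"

    def distance(self, other_state: np.ndarray, scales: np.ndarray) -> float:
        return float(np.max(np.abs(self.state - other_state) / scales))


@dataclass
class AttractorSet:
    """Deduplicated fixed points of one network condition."""

    points: list
    scales: np.ndarray
    n_starts: int = 0
    n_converged: int = 0

    @property
    def stable_points(self) -> list:
        return [p for p in self.points if p.stable]

    @property
    def n_stable(self) -> int:
        return len(self.stable_points)

    def by_phenotype(self, label: str) -> FixedPoint | None:
        for p in self.stable_points:
            if p.phenotype == label:
                return p
        return None

    def labels(self) -> list[str]:
        return [p.phenotype for p in self.stable_points]


@dataclass
class BifurcationDiagram:
    """One-parameter scan: attractor sets per grid value and fold locations."""

    parameter: str
    values: np.ndarray
    attractor_sets: list
    folds: list = field(default_factory=list)  # (location, count_before, count_after)

    @property
    def stable_counts(self) -> np.ndarray:
        return np.array([s.n_stable for s in self.attractor_sets])

    def fold_locations(self) -> np.ndarray:
        return np.array([f[0] for f in self.folds])

    def branch_table(self):
        import pandas as pd

        rows = []
        for v, aset in zip(self.values, self.attractor_sets):
            for p in aset.stable_points:
                rows.append({"value": v, "phenotype": p.phenotype,
                             **{f"x_{i}": x for i, x in enumerate(p.state)}})
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# fixed-point search

def state_scales(net) -> np.ndarray:
    """Per-node upper bound of the invariant box of the dynamics.

    Each node is bounded by g/k times the largest attainable synthesis
    Hill product divided by the smallest attainable degradation product.
    Input nodes get their configured level (or 1) as scale.  Generic
    vector-field systems supply an explicit ``state_scale``.
    """
    if hasattr(net, "state_scale"):
        return np.maximum(np.asarray(net.state_scale, dtype=float), 1e-6)
    scales = np.ones(net.n_nodes)
    regs = net.active_regulations()
    for i, nd in enumerate(net.nodes):
        if nd.is_input:
            scales[i] = max(abs(net.input_levels.get(nd.name, 1.0)), 1e-6)
            continue
        gmax, kmin = 1.0, 1.0
        for rg in regs:
            if rg.target != nd.name:
                continue
            if rg.mode == "synthesis":
                gmax *= max(1.0, rg.lam)
            else:
                kmin *= min(1.0, rg.lam)
        scales[i] = max(nd.g / nd.k * gmax / kmin, 1e-6)
    return scales


def _dyn_idx(net) -> np.ndarray:
    if hasattr(net, "dynamical_indices"):
        return np.asarray(net.dynamical_indices, dtype=int)
    return np.array([i for i, nd in enumerate(net.nodes) if not nd.is_input], dtype=int)


def _polish(net: NetworkSpec, x0: np.ndarray, tol: float = 1e-11):
    """Newton-polish a candidate fixed point on the dynamical coordinates."""
    dyn = _dyn_idx(net)
    template = net.clamp_inputs(np.asarray(x0, dtype=float))

    def fun(xd):
        x = template.copy()
        x[dyn] = xd
        return net.rhs(x)[dyn]

    def jac(xd):
        x = template.copy()
        x[dyn] = xd
        return net.jacobian(x)[np.ix_(dyn, dyn)]

    sol = root(fun, template[dyn], jac=jac, method="hybr", tol=tol)
    if not sol.success:
        return None
    x = template.copy()
    x[dyn] = sol.x
    if getattr(net, "non_negative", True):
        if np.any(x[dyn] < -1e-8):
            return None
        x[dyn] = np.clip(x[dyn], 0.0, None)
    res = float(np.linalg.norm(net.rhs(x)[dyn]))
    A = net.jacobian(x)[np.ix_(dyn, dyn)]
    eig = np.linalg.eigvals(A)
    return FixedPoint(state=x, residual=res,
                      eigenvalues=eig, stable=bool(np.max(eig.real) < 0))


def _settle(net: NetworkSpec, x0: np.ndarray, t_chunk: float = 60.0,
            max_chunks: int = 10, rtol: float = 1e-7):
    """Integrate forward until the flow is nearly stationary, then polish."""
    dyn = _dyn_idx(net)
    x = net.clamp_inputs(np.asarray(x0, dtype=float))
    scale = np.maximum(np.abs(x), 1.0)
    escape = 50.0 * max(float(np.max(state_scales(net))), 1.0)
    def _escaped(t, y):
        return escape - float(np.max(np.abs(y)))

    _escaped.terminal = True
    for _ in range(max_chunks):
        sol = solve_ivp(lambda t, y: net.rhs(y), (0.0, t_chunk), x,
                        method="LSODA", jac=lambda t, y: net.jacobian(y),
                        rtol=rtol, atol=1e-9, events=_escaped)
        if not sol.success or (sol.t_events and len(sol.t_events[0])):
            return None
        x = sol.y[:, -1]
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > escape:
            return None  # divergent start (no attractor in range)
        if getattr(net, "non_negative", True):
            x = np.clip(x, 0.0, None)
        x = net.clamp_inputs(x)
        rate = np.max(np.abs(net.rhs(x)[dyn]) / np.maximum(scale[dyn], 1e-6))
        if rate < 1e-5:
            fp = _polish(net, x)
            if fp is not None and fp.stable:
                return fp
            if rate < 1e-8 and fp is not None:
                return fp
    return _polish(net, x)


def _merge(points: Sequence[FixedPoint], scales: np.ndarray,
           tol: float = MERGE_TOL) -> list[FixedPoint]:
    kept: list[FixedPoint] = []
    for p in points:
        dup = None
        for q in kept:
            if q.distance(p.state, scales) < tol and q.stable == p.stable:
                dup = q
                break
        if dup is None:
            kept.append(p)
        elif p.residual < dup.residual:  # tie-break: smaller residual wins
            kept[kept.index(dup)] = p
    return kept


def find_attractors(net: NetworkSpec, n_starts: int = 200, seed: int = 0,
                    include_unstable: bool = True, merge_tol: float = MERGE_TOL,
                    rules: dict | None = None) -> AttractorSet:
    """Multi-start search for all stable (and saddle) fixed points.

    Latin-hypercube starts over ``[0, 2 * scale]`` per coordinate are
    integrated forward and polished; results are deduplicated at the
    merge tolerance.  Saddles are sought by root finding from midpoints
    of stable-state pairs and flagged unstable.  Stable points are
    phenotype-labelled with the default marker rules when the network
    carries the CAC marker nodes.
    """
    scales = state_scales(net)
    dyn = _dyn_idx(net)
    if getattr(net, "non_negative", True):
        lo, hi = np.zeros(len(dyn)), 2.0 * scales[dyn]
    else:
        lo, hi = -2.0 * scales[dyn], 2.0 * scales[dyn]
    sampler = qmc.LatinHypercube(d=len(dyn), seed=seed)
    samples = sampler.random(n=n_starts)
    found: list[FixedPoint] = []
    n_conv = 0
    base = net.input_state()
    for row in samples:
        x0 = base.copy()
        x0[dyn] = lo + row * (hi - lo)
        fp = _settle(net, x0)
        if fp is not None and fp.stable:
            n_conv += 1
            found.append(fp)
            found = _merge(found, scales, merge_tol)
    stable = [p for p in found if p.stable]
    points = list(stable)
    if include_unstable and len(stable) >= 2:
        saddle_seeds = []
        for i in range(len(stable)):
            for j in range(i + 1, len(stable)):
                saddle_seeds.append(0.5 * (stable[i].state + stable[j].state))
        for s in saddle_seeds:
            fp = _polish(net, s)
            if fp is not None and not fp.stable:
                points.append(fp)
        points = _merge(points, scales, merge_tol)
    aset = AttractorSet(points=points, scales=scales,
                        n_starts=n_starts, n_converged=n_conv)
    try:
        classify_attractors(aset, net, rules=rules)
    except KeyError:
        pass  # networks without the CAC marker nodes stay unclassified
    return aset


# ----------------------------------------------------------------------
# phenotype classification

#: Absolute marker cutoffs calibrated to the packaged CAC model scales.
#: ``zscore`` mode (cutoffs on per-marker z-scores across the stable set)
#: is available for data-driven use on other parameterizations.
DEFAULT_PHENOTYPE_RULES = {
    "mode": "absolute",
    "markers": {
        "P53": "P53", "miR145": "miR145", "ZEB1": "ZEB1", "SNAIL1": "SNAIL1",
        "MEK": "MEK", "ERK": "ERK", "PPARG": "PPARG", "CEBPA": "CEBPA",
    },
    "cutoffs": {  # absolute concentrations separating low/high
        "PPARG_high": 1.30, "CEBPA_high": 0.80, "ZEB1_high": 1.00,
        "P53_high": 0.55, "miR145_high": 0.50, "ERK_high": 0.90,
    },
    "z_threshold": 0.5,
}


def _marker_values(fp: FixedPoint, net: NetworkSpec, rules: dict) -> dict:
    vals = {}
    for key, node_name in rules["markers"].items():
        if node_name not in net.node_names:
            raise KeyError(f"marker node {node_name!r} missing from network")
        vals[key] = float(fp.state[net.index(node_name)])
    return vals


def classify_phenotype(fp: FixedPoint, net: NetworkSpec,
                       rules: dict | None = None) -> str:
    """Label one fixed point by absolute marker cutoffs.

    Rule order: A (adipogenic markers high) before P2 (elevated C/EBPalpha
    on a ZEB1-high background) before M (ZEB1 and ERK high) before P1
    (ZEB1 high, ERK low) before E (P53/miR145 high); otherwise
    unclassified.  The A-first ordering makes forced-ZEB1 interventions
    with saturating PPARgamma classify as adipose.
    """
    rules = rules or DEFAULT_PHENOTYPE_RULES
    v = _marker_values(fp, net, rules)
    c = rules["cutoffs"]
    if v["PPARG"] > c["PPARG_high"] and v["CEBPA"] > c["CEBPA_high"]:
        return "A"
    if v["ZEB1"] > c["ZEB1_high"]:
        if v["CEBPA"] > c["CEBPA_high"]:
            return "P2"
        if v["ERK"] > c["ERK_high"]:
            return "M"
        return "P1"
    if v["P53"] > c["P53_high"] and v["miR145"] > c["miR145_high"]:
        return "E"
    return "unclassified"


def classify_attractors(aset: AttractorSet, net: NetworkSpec,
                        rules: dict | None = None) -> AttractorSet:
    """Label every stable point of a set; saddles stay unclassified.

    In ``zscore`` mode markers are z-scored across the stable set and the
    same rule order is applied to z-values (data-driven variant for
    parameterizations whose absolute scales differ).
    """
    rules = rules or DEFAULT_PHENOTYPE_RULES
    stable = aset.stable_points
    if not stable:
        return aset
    if rules.get("mode", "absolute") == "absolute" or len(stable) < 3:
        for p in stable:
            p.phenotype = classify_phenotype(p, net, rules)
        return aset
    # z-score mode
    theta = rules.get("z_threshold", 0.5)
    vals = {m: np.array([_marker_values(p, net, rules)[m] for p in stable])
            for m in rules["markers"]}
    z = {}
    for m, arr in vals.items():
        sd = arr.std()
        z[m] = (arr - arr.mean()) / sd if sd > 1e-12 else np.zeros_like(arr)
    for i, p in enumerate(stable):
        if z["PPARG"][i] > theta and z["CEBPA"][i] > theta and \
                vals["PPARG"][i] == vals["PPARG"].max():
            p.phenotype = "A"
        elif z["ZEB1"][i] > theta:
            if z["CEBPA"][i] > theta:
                p.phenotype = "P2"
            elif z["ERK"][i] > theta:
                p.phenotype = "M"
            else:
                p.phenotype = "P1"
        elif z["P53"][i] > theta:
            p.phenotype = "E"
        else:
            p.phenotype = "unclassified"
    return aset


# ----------------------------------------------------------------------
# bifurcation scan

def bifurcation_scan(net: NetworkSpec, parameter: str, values,
                     n_fresh_starts: int = 24, n_starts_first: int = 200,
                     seed: int = 0, merge_tol: float = MERGE_TOL,
                     rules: dict | None = None) -> BifurcationDiagram:
    """One-parameter continuation with fresh multi-starts per grid point.

    ``parameter`` is a parameter name (``input:TGFB``, ``g:ZEB1``, ...);
    a bare input-node name is also accepted.  At each grid value the
    fixed points of the previous value are Newton-continued and a small
    Latin-hypercube batch of fresh starts detects newborn branches.
    Folds are reported as midpoints of the bracketing grid cells where
    the stable-branch count changes.
    """
    values = np.asarray(values, dtype=float)
    if parameter in net.input_levels:
        parameter = f"input:{parameter}"
    net.get_param(parameter)  # raises KeyError for unknown names
    sets: list[AttractorSet] = []
    prev: AttractorSet | None = None
    for i, v in enumerate(values):
        nv = net.with_params({parameter: v})
        scales = state_scales(nv)
        n_starts = n_starts_first if i == 0 else n_fresh_starts
        aset = find_attractors(nv, n_starts=n_starts, seed=seed + i,
                               include_unstable=False, merge_tol=merge_tol,
                               rules=rules)
        points = list(aset.stable_points)
        if prev is not None:
            for p in prev.points:
                fp = _polish(nv, p.state)
                if fp is not None and fp.stable:
                    points.append(fp)
        points = _merge(points, scales, merge_tol)
        cont = AttractorSet(points=points, scales=scales,
                            n_starts=n_starts, n_converged=aset.n_converged)
        try:
            classify_attractors(cont, nv, rules=rules)
        except KeyError:
            pass
        sets.append(cont)
        prev = cont
    folds = []
    counts = [s.n_stable for s in sets]
    for i in range(1, len(values)):
        if counts[i] != counts[i - 1]:
            mid = 0.5 * (values[i] + values[i - 1])
            folds.append((float(mid), counts[i - 1], counts[i]))
    return BifurcationDiagram(parameter=parameter, values=values,
                              attractor_sets=sets, folds=folds)
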