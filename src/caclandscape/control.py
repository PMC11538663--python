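"""Landscape control: drive the adipose attractor by parameter tuning.

The control objective sums forward-minus-reverse transition-action
differences toward the adipose (A) state,

    dS_A = (S_M->A - S_A->M) + (S_E->A - S_A->E)
         + (S_P1->A - S_A->P1) + (S_P2->A - S_A->P2),

and minimizing it simultaneously lowers the barriers into A and raises
the barriers out of it, which maximizes A-state occupancy.  Source
states that vanish during optimization contribute 0 (a vanished tumor
state is the desired outcome, not a penalty); a vanished target A makes
the objective undefined and is penalized inside the optimizer.

Sensitivities follow the multi-restart protocol: each restart perturbs
the initial parameter vector, the per-restart relative changes
``(p_opt - p_base)/p_base`` are averaged, and parameters are ranked by
the magnitude of the averaged change.  Hill exponents ``n`` and fold
changes ``lam`` stay in the search but are flagged non-druggable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .attractors import AttractorSet, find_attractors
from .paths import action, action_matrix, minimize_action, _line_init

__all__ = [
    "ControlProblem",
    "ControlResult",
    "free_parameters",
    "delta_S_A",
    "optimize",
    "sensitivity_ranking",
    "apply_intervention",
]

DEFAULT_SOURCES = ("E", "M", "P1", "P2")


def free_parameters(net) -> list[str]:
    """All tunable parameters of the network (the control search space)."""
    return net.parameter_names()


def is_druggable(name: str) -> bool:
    """Rates and drug levels are actionable; Hill n and fold change lam
    (cooperativity and regulatory strength) are not."""
    fld = name.partition(":")[0]
    return fld in {"g", "k", "input"}


def _pair_actions(net, aset: AttractorSet, target: str, sources, N, T_values,
                  maxiter, exact: bool):
    """Forward/reverse actions between each present source and the target.

    ``exact=False`` uses the straight-line path action (no optimization)
    as a fast surrogate with the same barrier ordering on the systems
    treated here.
    """
    tgt = aset.by_phenotype(target)
    if tgt is None:
        raise ValueError(f"target state {target!r} not among the attractors")
    total = 0.0
    terms = {}
    for lbl in sources:
        src = aset.by_phenotype(lbl)
        if src is None:
            continue
        if exact:
            fwd = minimize_action(net, src, tgt, N=N, T_values=T_values,
                                  maxiter=maxiter).action
            rev = minimize_action(net, tgt, src, N=N, T_values=T_values,
                                  maxiter=maxiter).action
        else:
            line_f = _line_init(src.state, tgt.state, N)
            line_r = line_f[::-1].copy()
            fwd = min(action(line_f, net, T=T) for T in T_values)
            rev = min(action(line_r, net, T=T) for T in T_values)
        terms[lbl] = (fwd, rev)
        total += fwd - rev
    return total, terms


def delta_S_A(net, attractors: AttractorSet | None = None,
              target: str = "A", sources=DEFAULT_SOURCES, N: int = 61,
              T_values=(5.0, 10.0, 20.0, 40.0), maxiter: int = 300,
              exact: bool = True, n_starts: int = 120, seed: int = 0,
              rules=None) -> float:
    """The control objective: sum of (S_src->A - S_A->src) over present
    source states.  A monostable-A system (no sources left) scores 0."""
    if attractors is None:
        attractors = find_attractors(net, n_starts=n_starts, seed=seed,
                                     include_unstable=False, rules=rules)
    total, _ = _pair_actions(net, attractors, target, sources, N, T_values,
                             maxiter, exact)
    return total


@dataclass
class ControlProblem:
    """Bound-constrained minimization of dS_A over chosen parameters."""

    net: object
    param_names: list
    bounds_mult: tuple = (0.1, 10.0)     # multiplicative range around baseline
    n_bounds: tuple = (1.0, 6.0)         # absolute bounds for Hill exponents
    target: str = "A"
    sources: tuple = DEFAULT_SOURCES
    restarts: int = 7
    seed: int = 11
    budget: int = 200                    # objective evaluations per restart
    exact_actions: bool = True
    N: int = 61
    T_values: tuple = (5.0, 10.0, 20.0, 40.0)
    n_starts: int = 120
    rules: dict | None = None
    labeler: object = None               # callable(aset, net) assigning labels
    restart_jitter: float = 0.2          # log10 spread of restart initials

    def baseline(self) -> np.ndarray:
        return np.array([self.net.get_param(p) for p in self.param_names])

    def bounds(self) -> list[tuple[float, float]]:
        out = []
        for name, p in zip(self.param_names, self.baseline()):
            lo, hi = p * self.bounds_mult[0], p * self.bounds_mult[1]
            if name.startswith("n:"):
                lo, hi = max(lo, self.n_bounds[0]), min(hi, self.n_bounds[1])
            if not lo < hi:
                raise ValueError(f"empty bound interval for {name}")
            if not lo <= p <= hi:
                raise ValueError(f"baseline of {name} outside its bounds")
            out.append((lo, hi))
        return out


@dataclass
class ControlResult:
    """Optimized parameters, objective trajectory, and sensitivities."""

    problem: ControlProblem
    params_base: np.ndarray
    params_opt: np.ndarray
    delta_base: float
    delta_opt: float
    sensitivity: np.ndarray          # averaged (p_opt - p_base)/p_base
    per_restart: list = field(default_factory=list)
    attractors_before: AttractorSet | None = None
    attractors_after: AttractorSet | None = None

    def table(self) -> pd.DataFrame:
        rows = []
        for name, base, opt, s in zip(self.problem.param_names,
                                      self.params_base, self.params_opt,
                                      self.sensitivity):
            rows.append({"parameter": name, "baseline": base, "optimized": opt,
                         "sensitivity": s, "druggable": is_druggable(name)})
        return pd.DataFrame(rows)


def _objective_factory(problem: ControlProblem):
    names = problem.param_names
    counter = {"n": 0}

    def objective(x: np.ndarray) -> float:
        counter["n"] += 1
        net = problem.net.with_params(dict(zip(names, x)))
        aset = find_attractors(net, n_starts=problem.n_starts,
                               seed=problem.seed, include_unstable=False,
                               rules=problem.rules)
        if problem.labeler is not None:
            problem.labeler(aset, net)
        tgt = aset.by_phenotype(problem.target)
        if tgt is None:
            # target attractor lost: heavily penalized, never accepted
            return 1e6
        total, _ = _pair_actions(net, aset, problem.target, problem.sources,
                                 problem.N, problem.T_values, maxiter=200,
                                 exact=problem.exact_actions)
        return total

    return objective, counter


def optimize(problem: ControlProblem) -> ControlResult:
    """Multi-restart bound-constrained minimization of dS_A.

    Each restart starts from a jittered copy of the baseline parameters
    (restart rngs derive from the problem seed) and runs bounded
    finite-difference L-BFGS-B within the evaluation budget, keeping the
    best point evaluated (the objective jumps where attractors are born
    or destroyed).
    Failed restarts are dropped with a warning; sensitivities are the
    across-restart average of the per-restart relative changes.
    """
    base = problem.baseline()
    bounds = problem.bounds()
    obj, _ = _objective_factory(problem)
    delta_base = obj(base)
    if delta_base >= 1e6:
        raise ValueError("objective undefined at baseline (no target state)")
    if problem.budget <= 0:
        zeros = np.zeros_like(base)
        return ControlResult(problem=problem, params_base=base,
                             params_opt=base.copy(), delta_base=delta_base,
                             delta_opt=delta_base, sensitivity=zeros,
                             per_restart=[])
    results = []
    for r in range(problem.restarts):
        rng = np.random.default_rng(problem.seed + 1000 * r)
        x0 = base.copy()
        if r > 0:  # restart 0 starts exactly at baseline
            jitter = rng.uniform(-problem.restart_jitter,
                                 problem.restart_jitter, size=base.size)
            x0 = np.clip(base * 10.0 ** jitter,
                         [b[0] for b in bounds], [b[1] for b in bounds])
        best_seen = {"x": x0.copy(), "f": np.inf}

        def tracked(x, _b=best_seen):
            f = obj(x)
            if f < _b["f"]:
                _b["x"], _b["f"] = np.array(x, dtype=float), f
            return f

        try:
            eps = np.maximum(1e-3 * np.abs(base), 1e-6)
            res = minimize(tracked, x0, method="L-BFGS-B", bounds=bounds,
                           jac=None,
                           options={"maxfun": problem.budget, "ftol": 1e-8,
                                    "gtol": 1e-8, "eps": eps})
            # the objective can be discontinuous (attractors appear and
            # vanish); keep the best point actually evaluated
            if best_seen["f"] < float(res.fun):
                xo, fo = best_seen["x"], float(best_seen["f"])
            else:
                xo, fo = res.x, float(res.fun)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"restart {r} failed ({exc}); dropped")
            continue
        if fo >= 1e6:
            warnings.warn(f"restart {r} lost the target state; dropped")
            continue
        if fo > delta_base:  # never accept an iterate worse than baseline
            xo, fo = base.copy(), delta_base
        results.append({"restart": r, "params": xo, "delta": fo,
                        "sensitivity": (xo - base) / base})
    if not results:
        raise RuntimeError("all restarts failed")
    sens = np.mean([r["sensitivity"] for r in results], axis=0)
    best = min(results, key=lambda r: r["delta"])
    net_opt = problem.net.with_params(
        dict(zip(problem.param_names, best["params"])))
    aset_before = find_attractors(problem.net, n_starts=problem.n_starts,
                                  seed=problem.seed, include_unstable=False,
                                  rules=problem.rules)
    aset_after = find_attractors(net_opt, n_starts=problem.n_starts,
                                 seed=problem.seed, include_unstable=False,
                                 rules=problem.rules)
    if problem.labeler is not None:
        problem.labeler(aset_before, problem.net)
        problem.labeler(aset_after, net_opt)
    return ControlResult(problem=problem, params_base=base,
                         params_opt=best["params"], delta_base=delta_base,
                         delta_opt=best["delta"], sensitivity=sens,
                         per_restart=results, attractors_before=aset_before,
                         attractors_after=aset_after)


def sensitivity_ranking(result: ControlResult, k: int = 10,
                        druggable_only: bool = False) -> pd.DataFrame:
    """Top-k parameters by |averaged relative change|, sign retained."""
    df = result.table()
    if druggable_only:
        df = df[df["druggable"]]
    df = df.reindex(df["sensitivity"].abs().sort_values(ascending=False).index)
    return df.head(min(k, len(df))).reset_index(drop=True)


def apply_intervention(net, multipliers: dict):
    """New network with the named parameters scaled (original untouched).

    Bare input-node names are accepted for drug-level multipliers
    (e.g. ``{"g:ZEB1": 500, "ROSI": 500}``).
    """
    resolved = {}
    for name, fac in multipliers.items():
        if ":" not in name and name in getattr(net, "input_levels", {}):
            name = f"input:{name}"
        resolved[name] = fac
    return net.scale_params(resolved)
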