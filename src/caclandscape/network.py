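"""Hill-regulation gene network models with drug input nodes.

The dynamics of every non-input node follow

    dX/dt = g_X * G - k_X * K * X

where ``g_X`` and ``k_X`` are basal synthesis and degradation rates and
``G`` and ``K`` are products of shifted Hill factors

    Hs(Y; S, lam, n) = 1 + (lam - 1) * Y^n / (S^n + Y^n)

over the regulations acting on the synthesis side (``G``) or the
degradation side (``K``) of the node.  ``lam > 1`` is activation,
``lam < 1`` inhibition, and ``lam = 1`` leaves the target unregulated.
Drug nodes (e.g. TGF-beta, a MEK inhibitor, rosiglitazone) are input
nodes held at fixed concentrations; they regulate other nodes but have
no dynamics of their own.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RegulationSpec",
    "NodeSpec",
    "NetworkSpec",
    "shifted_hill",
    "shifted_hill_deriv",
]

SYNTHESIS = "synthesis"
DEGRADATION = "degradation"


def shifted_hill(Y, S, lam, n):
    """Shifted Hill regulation factor ``1 + (lam-1) Y^n / (S^n + Y^n)``.

    Bounded between ``min(1, lam)`` and ``max(1, lam)``; equals 1 at
    ``Y = 0`` and approaches ``lam`` at saturation.  ``Y`` may be a
    scalar or array; ``S`` must be positive and ``Y`` non-negative.
    """
    Y = np.asarray(Y, dtype=float)
    if np.any(Y < 0):
        raise ValueError("regulator level Y must be non-negative")
    if S <= 0:
        raise ValueError("Hill threshold S must be positive")
    u = (Y / S) ** n
    out = 1.0 + (lam - 1.0) * u / (1.0 + u)
    # saturate cleanly if Y/S overflowed
    if np.isscalar(out) or out.ndim == 0:
        return float(lam) if not np.isfinite(u) else float(out)
    out[~np.isfinite(u)] = lam
    return out


def shifted_hill_deriv(Y, S, lam, n):
    """d/dY of :func:`shifted_hill`: ``(lam-1) n S^n Y^(n-1) / (S^n+Y^n)^2``."""
    Y = np.asarray(Y, dtype=float)
    if np.any(Y < 0):
        raise ValueError("regulator level Y must be non-negative")
    if S <= 0:
        raise ValueError("Hill threshold S must be positive")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        u = (Y / S) ** n
        d = (lam - 1.0) * n * u / (Y * (1.0 + u) ** 2)
    # limits at Y = 0: slope is 0 for n > 1, (lam-1)/S for n == 1
    zero_slope = 0.0 if n > 1 else (lam - 1.0) / S
    if np.isscalar(d) or d.ndim == 0:
        if Y == 0:
            return zero_slope
        return 0.0 if not np.isfinite(u) else float(d)
    d = np.where(Y == 0, zero_slope, d)
    d[~np.isfinite(u)] = 0.0
    return d


@dataclass
class RegulationSpec:
    """One signed regulation edge ``source -> target``.

    ``mode`` selects whether the shifted-Hill factor multiplies the
    synthesis term G or the degradation term K of the target.
    ``variant`` tags optional edges that are only active when the
    corresponding config flag is set (e.g. TGF-beta autoregulation).
    """

    source: str
    target: str
    lam: float
    S: float
    n: float
    mode: str = SYNTHESIS
    variant: str | None = None

    def validate(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"{self.source}->{self.target}: fold change lam must be > 0")
        if self.S <= 0:
            raise ValueError(f"{self.source}->{self.target}: threshold S must be > 0")
        if self.n < 1:
            raise ValueError(f"{self.source}->{self.target}: Hill exponent n must be >= 1")
        if self.mode not in (SYNTHESIS, DEGRADATION):
            raise ValueError(f"{self.source}->{self.target}: unknown mode {self.mode!r}")

    @property
    def is_activation(self) -> bool:
        return self.lam > 1.0


@dataclass
class NodeSpec:
    """A network node: a gene/protein/miRNA, or a drug input held fixed."""

    name: str
    g: float = 0.0
    k: float = 1.0
    is_input: bool = False

    def validate(self) -> None:
        if not self.is_input:
            if self.g < 0:
                raise ValueError(f"node {self.name}: synthesis rate g must be >= 0")
            if self.k <= 0:
                raise ValueError(f"node {self.name}: degradation rate k must be > 0")


class NetworkSpec:
    """A complete regulatory network: nodes, regulations, drug levels.

    The state vector covers every node in declaration order; input-node
    coordinates are clamped at their configured level and have zero rate.
    """

    def __init__(
        self,
        nodes: Sequence[NodeSpec],
        regulations: Sequence[RegulationSpec],
        input_levels: Mapping[str, float] | None = None,
        name: str = "network",
        options: Mapping[str, object] | None = None,
    ):
        self.name = name
        self.nodes = list(nodes)
        self.regulations = list(regulations)
        self.input_levels = dict(input_levels or {})
        self.options = dict(options or {})
        self.validate()
        self._compiled = None

    # ------------------------------------------------------------------
    # validation / bookkeeping

    def validate(self) -> None:
        names = [nd.name for nd in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        for nd in self.nodes:
            nd.validate()
        if not any(not nd.is_input for nd in self.nodes):
            raise ValueError("network needs at least one non-input node")
        name_set = set(names)
        for rg in self.regulations:
            rg.validate()
            if rg.source not in name_set:
                raise ValueError(f"regulation source {rg.source!r} not a declared node")
            if rg.target not in name_set:
                raise ValueError(f"regulation target {rg.target!r} not a declared node")
            if self.node(rg.target).is_input and self._edge_active(rg):
                raise ValueError(f"input node {rg.target!r} cannot be a regulation target")
        for nm in self.input_levels:
            if nm not in name_set:
                raise ValueError(f"input level for undeclared node {nm!r}")
        for nd in self.nodes:
            if nd.is_input and nd.name not in self.input_levels:
                raise ValueError(f"input node {nd.name!r} has no configured level")

    def _edge_active(self, rg: RegulationSpec) -> bool:
        if rg.variant is None:
            return True
        return bool(self.options.get(rg.variant, False))

    @property
    def node_names(self) -> list[str]:
        return [nd.name for nd in self.nodes]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node(self, name: str) -> NodeSpec:
        for nd in self.nodes:
            if nd.name == name:
                return nd
        raise KeyError(name)

    def index(self, name: str) -> int:
        return self.node_names.index(name)

    def active_regulations(self) -> list[RegulationSpec]:
        return [rg for rg in self.regulations if self._edge_active(rg)]

    # ------------------------------------------------------------------
    # compiled evaluation

    def _compile(self):
        if self._compiled is not None:
            return self._compiled
        idx = {nm: i for i, nm in enumerate(self.node_names)}
        regs = self.active_regulations()
        src = np.array([idx[r.source] for r in regs], dtype=int)
        tgt = np.array([idx[r.target] for r in regs], dtype=int)
        lam = np.array([r.lam for r in regs], dtype=float)
        S = np.array([r.S for r in regs], dtype=float)
        n = np.array([r.n for r in regs], dtype=float)
        syn = np.array([r.mode == SYNTHESIS for r in regs], dtype=bool)
        g = np.array([nd.g for nd in self.nodes], dtype=float)
        k = np.array([nd.k for nd in self.nodes], dtype=float)
        dyn = np.array([not nd.is_input for nd in self.nodes], dtype=bool)
        self._compiled = (src, tgt, lam, S, n, syn, g, k, dyn)
        return self._compiled

    def _invalidate(self):
        self._compiled = None

    def input_state(self) -> np.ndarray:
        """Zero state with input coordinates set to their levels."""
        x = np.zeros(self.n_nodes)
        for nm, v in self.input_levels.items():
            x[self.index(nm)] = v
        return x

    def clamp_inputs(self, state: np.ndarray) -> np.ndarray:
        state = np.array(state, dtype=float)
        for nm, v in self.input_levels.items():
            state[..., self.index(nm)] = v
        return state

    def rhs(self, state: np.ndarray) -> np.ndarray:
        """Deterministic vector field F(x); zero on input coordinates."""
        src, tgt, lam, S, n, syn, g, k, dyn = self._compile()
        x = np.asarray(state, dtype=float)
        if x.shape[-1] != self.n_nodes:
            raise ValueError(
                f"state has {x.shape[-1]} entries, network has {self.n_nodes} nodes"
            )
        single = x.ndim == 1
        x2 = np.atleast_2d(x)
        G = np.ones_like(x2)
        K = np.ones_like(x2)
        Y = np.clip(x2[:, src], 0.0, None)
        with np.errstate(over="ignore"):
            u = (Y / S) ** n
        hs = 1.0 + (lam - 1.0) * u / (1.0 + u)
        hs = np.where(np.isfinite(u), hs, lam)
        for e in range(len(src)):
            if syn[e]:
                G[:, tgt[e]] *= hs[:, e]
            else:
                K[:, tgt[e]] *= hs[:, e]
        F = g * G - k * K * x2
        F[:, ~dyn] = 0.0
        return F[0] if single else F

    def jacobian(self, state: np.ndarray) -> np.ndarray:
        """Analytic Jacobian A with ``A[i, j] = dF_i/dx_j``."""
        src, tgt, lam, S, n, syn, g, k, dyn = self._compile()
        x = np.asarray(state, dtype=float)
        if x.ndim != 1 or x.shape[0] != self.n_nodes:
            raise ValueError("jacobian expects a single state vector")
        N = self.n_nodes
        G = np.ones(N)
        K = np.ones(N)
        E = len(src)
        hs = np.empty(E)
        dhs = np.empty(E)
        for e in range(E):
            y = max(x[src[e]], 0.0)
            hs[e] = shifted_hill(y, S[e], lam[e], n[e])
            dhs[e] = shifted_hill_deriv(y, S[e], lam[e], n[e])
            if syn[e]:
                G[tgt[e]] *= hs[e]
            else:
                K[tgt[e]] *= hs[e]
        A = np.zeros((N, N))
        A[np.arange(N), np.arange(N)] = -k * K
        for e in range(E):
            i, j = tgt[e], src[e]
            ratio = dhs[e] / hs[e]
            if syn[e]:
                A[i, j] += g[i] * G[i] * ratio
            else:
                A[i, j] += -k[i] * K[i] * x[i] * ratio
        A[~dyn, :] = 0.0
        return A

    # ------------------------------------------------------------------
    # parameter access (used by landscape control)

    _EDGE_FIELDS = {"lam", "S", "n"}
    _NODE_FIELDS = {"g", "k"}

    def _edge_key(self, rg_index: int) -> str:
        rg = self.regulations[rg_index]
        nth = sum(
            1
            for other in self.regulations[:rg_index]
            if other.source == rg.source and other.target == rg.target
        )
        suffix = f"#{nth}" if nth else ""
        return f"{rg.source}->{rg.target}{suffix}"

    def parameter_names(self, include_variants: bool = False) -> list[str]:
        """All tunable parameter names.

        ``g:<node>`` / ``k:<node>`` for non-input node rates,
        ``lam:<src>-><tgt>`` / ``S:...`` / ``n:...`` per regulation,
        and ``input:<node>`` for drug levels.
        """
        names: list[str] = []
        for nd in self.nodes:
            if not nd.is_input:
                names.append(f"g:{nd.name}")
                names.append(f"k:{nd.name}")
        for i, rg in enumerate(self.regulations):
            if not include_variants and not self._edge_active(rg):
                continue
            key = self._edge_key(i)
            names.extend([f"lam:{key}", f"S:{key}", f"n:{key}"])
        for nm in sorted(self.input_levels):
            names.append(f"input:{nm}")
        return names

    def _locate(self, name: str):
        field_, _, rest = name.partition(":")
        if field_ in self._NODE_FIELDS:
            return ("node", self.node(rest), field_)
        if field_ == "input":
            if rest not in self.input_levels:
                raise KeyError(name)
            return ("input", rest, None)
        if field_ in self._EDGE_FIELDS:
            m = re.fullmatch(r"(.+?)->(.+?)(?:#(\d+))?", rest)
            if not m:
                raise KeyError(name)
            srcn, tgtn, nth = m.group(1), m.group(2), int(m.group(3) or 0)
            count = 0
            for rg in self.regulations:
                if rg.source == srcn and rg.target == tgtn:
                    if count == nth:
                        return ("edge", rg, field_)
                    count += 1
            raise KeyError(name)
        raise KeyError(name)

    def get_param(self, name: str) -> float:
        kind, obj, fld = self._locate(name)
        if kind == "input":
            return self.input_levels[obj]
        if kind == "node":
            return getattr(obj, fld)
        return getattr(obj, "lam" if fld == "lam" else fld)

    def set_param(self, name: str, value: float) -> None:
        kind, obj, fld = self._locate(name)
        if kind == "input":
            self.input_levels[obj] = float(value)
        else:
            setattr(obj, fld, float(value))
        self._invalidate()

    def with_params(self, updates: Mapping[str, float]) -> "NetworkSpec":
        """Copy of the network with the named parameters replaced."""
        new = self.copy()
        for nm, v in updates.items():
            new.set_param(nm, v)
        return new

    def with_inputs(self, **levels: float) -> "NetworkSpec":
        """Copy with drug input levels replaced (e.g. ``TGFB=4.3``)."""
        new = self.copy()
        for nm, v in levels.items():
            if nm not in new.input_levels:
                raise KeyError(f"{nm} is not an input node")
            new.input_levels[nm] = float(v)
        new._invalidate()
        return new

    def scale_params(self, multipliers: Mapping[str, float]) -> "NetworkSpec":
        """Copy with the named parameters multiplied (intervention helper)."""
        new = self.copy()
        for nm, fac in multipliers.items():
            if fac <= 0:
                raise ValueError(f"multiplier for {nm} must be > 0")
            new.set_param(nm, new.get_param(nm) * fac)
        return new

    def copy(self) -> "NetworkSpec":
        return NetworkSpec(
            nodes=[copy.copy(nd) for nd in self.nodes],
            regulations=[copy.copy(rg) for rg in self.regulations],
            input_levels=dict(self.input_levels),
            name=self.name,
            options=dict(self.options),
        )

    # ------------------------------------------------------------------
    # serialization

    def to_dict(self) -> dict:
        d: dict = {"name": self.name}
        if self.options:
            d["options"] = dict(self.options)
        d["nodes"] = []
        for nd in self.nodes:
            if nd.is_input:
                d["nodes"].append({"name": nd.name, "input": True})
            else:
                d["nodes"].append({"name": nd.name, "g": nd.g, "k": nd.k})
        if self.input_levels:
            d["inputs"] = dict(self.input_levels)
        d["regulations"] = []
        for rg in self.regulations:
            n = float(rg.n)
            e = {
                "source": rg.source,
                "target": rg.target,
                "lam": float(rg.lam),
                "S": float(rg.S),
                "n": int(n) if n.is_integer() else n,
                "mode": rg.mode,
            }
            if rg.variant is not None:
                e["variant"] = rg.variant
            d["regulations"].append(e)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkSpec":
        missing = [k for k in ("nodes", "regulations") if k not in d]
        if missing:
            raise ValueError(f"config missing required keys: {missing}")
        nodes = []
        for nd in d["nodes"]:
            if "name" not in nd:
                raise ValueError(f"node entry missing 'name': {nd}")
            if nd.get("input"):
                nodes.append(NodeSpec(name=nd["name"], is_input=True))
            else:
                for key in ("g", "k"):
                    if key not in nd:
                        raise ValueError(f"node {nd['name']!r} missing rate {key!r}")
                nodes.append(NodeSpec(name=nd["name"], g=float(nd["g"]), k=float(nd["k"])))
        regs = []
        for e in d["regulations"]:
            for key in ("source", "target", "lam", "S", "n"):
                if key not in e:
                    raise ValueError(f"regulation entry missing {key!r}: {e}")
            regs.append(
                RegulationSpec(
                    source=e["source"],
                    target=e["target"],
                    lam=float(e["lam"]),
                    S=float(e["S"]),
                    n=float(e["n"]),
                    mode=e.get("mode", SYNTHESIS),
                    variant=e.get("variant"),
                )
            )
        input_levels = {k: float(v) for k, v in dict(d.get("inputs", {})).items()}
        options = dict(d.get("options", {}))
        if options.get("tgfb_autoregulation"):
            # robustness variant: TGF-beta becomes a dynamical node with a
            # self-activation loop (the variant-tagged edge), seeded at its
            # former input level
            for nd in nodes:
                if nd.name == "TGFB" and nd.is_input:
                    nd.is_input = False
                    nd.g = input_levels.pop("TGFB", 1.0)
                    nd.k = 1.0
        return cls(
            nodes=nodes,
            regulations=regs,
            input_levels=input_levels,
            name=d.get("name", "network"),
            options=options,
        )


def ode_rhs(state: np.ndarray, net: NetworkSpec) -> np.ndarray:
    """Functional alias for :meth:`NetworkSpec.rhs`."""
    return net.rhs(state)


def jacobian(state: np.ndarray, net: NetworkSpec) -> np.ndarray:
    """Functional alias for :meth:`NetworkSpec.jacobian`."""
    return net.jacobian(state)
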