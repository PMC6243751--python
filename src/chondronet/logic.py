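"""Additive, multi-valued, asynchronous logical GRN simulator.

Each node carries a *fast* variable (protein activity) and a *slow* variable
(gene expression); the node's total activity is always their product.  Edges
belong to a fast or slow priority class.  One macro-step of the dynamics
first relaxes all fast variables to quasi-steady state by random-order
asynchronous updates, then updates exactly one randomly chosen slow
variable — fast processes always take precedence over slow ones.

A variable with incoming edges of its class is updated to f(s) where s is
the normalized signed weighted sum of the upstream total activities

    s = (Σ_activators w·x_src − Σ_inhibitors w·x_src) / Σ |w|   ∈ [−1, 1]

and f is the activation function (logistic in s by default; a step function
recovers the Boolean limit).  Variables with no incoming edges of their
class hold their value, so input nodes behave as clamped external stimuli.

Stable states (fixed points) are discovered by simulating from many initial
conditions; the share of initial conditions reaching a fixed point is its
basin-of-attraction fraction, interpreted as how likely the cell is to adopt
that phenotype.  Knockout and over-activation screens clamp one node at a
time and ask whether marker-positive states (e.g. RUNX2+, the hypertrophic
phenotype) remain reachable.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import Edge, Node, RegulatoryNetwork


@dataclass(frozen=True)
class ActivationSpec:
    """Maps the normalized regulatory input s ∈ [−1, 1] into [0, 1].

    ``logistic``: f(s) = 1/(1+exp(−steepness·(s−threshold))), clipped to
    [0, 1].  ``step``: f(s) = 1 if s > threshold else 0 (the Boolean limit
    of the logistic as steepness → ∞).
    """

    kind: str = "logistic"
    steepness: float = 10.0
    threshold: float = 0.0

    def __call__(self, s: float) -> float:
        if self.kind == "step":
            return 1.0 if s > self.threshold else 0.0
        if self.kind == "logistic":
            z = self.steepness * (s - self.threshold)
            if z >= 0:
                v = 1.0 / (1.0 + math.exp(-z))
            else:
                ez = math.exp(z)
                v = ez / (1.0 + ez)
            return min(1.0, max(0.0, v))
        raise ValueError(f"unknown activation kind {self.kind!r}")


@dataclass(frozen=True)
class PerturbationSpec:
    """Clamp of one node: knockout pins it to 0, over-activation to 1."""

    node: str
    mode: str  # "knockout" | "overactivation"

    @property
    def clamp_value(self) -> float:
        if self.mode == "knockout":
            return 0.0
        if self.mode == "overactivation":
            return 1.0
        raise ValueError(f"unknown perturbation mode {self.mode!r}")


@dataclass
class AdditiveModel:
    """The simulator: topology plus activation and convergence parameters."""

    network: RegulatoryNetwork
    activation: ActivationSpec = field(default_factory=ActivationSpec)
    fast_relaxation_max_iters: int = 1000
    convergence_tol: float = 1e-6
    markers: list[str] = field(default_factory=list)
    clamps: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        names = self.network.node_names
        self._index = {n: i for i, n in enumerate(names)}
        self.markers = [self.network.aliases.canonicalize(m) for m in self.markers]
        for m in self.markers:
            if m not in self._index:
                raise ValueError(f"marker node {m!r} not in network")
        self.clamps = {
            self.network.aliases.canonicalize(k): float(v) for k, v in self.clamps.items()
        }
        for c in self.clamps:
            if c not in self._index:
                raise ValueError(f"clamped node {c!r} not in network")
        # incoming (source index, signed weight) lists per node per class
        self._incoming: dict[str, list[list[tuple[int, float]]]] = {
            "fast": [[] for _ in names],
            "slow": [[] for _ in names],
        }
        for e in self.network.edges:
            self._incoming[e.kinetics][self._index[e.target]].append(
                (self._index[e.source], e.sign * e.weight)
            )

    @property
    def node_names(self) -> list[str]:
        return self.network.node_names

    def node_index(self, name: str) -> int:
        name = self.network.aliases.canonicalize(name)
        if name not in self._index:
            raise KeyError(f"unknown node {name!r}")
        return self._index[name]

    def has_inputs(self, node_idx: int, kinetics: str) -> bool:
        return bool(self._incoming[kinetics][node_idx])


@dataclass
class SystemState:
    """Per-node fast (protein activity) and slow (gene expression) values."""

    node_names: list[str]
    fast: np.ndarray
    slow: np.ndarray

    def __post_init__(self):
        self.fast = np.asarray(self.fast, dtype=float)
        self.slow = np.asarray(self.slow, dtype=float)

    @property
    def total(self) -> np.ndarray:
        """Total activity: always the product of the fast and slow variable."""
        return self.fast * self.slow

    def copy(self) -> "SystemState":
        return SystemState(self.node_names, self.fast.copy(), self.slow.copy())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.node_names, self.total))


@dataclass
class StableState:
    state: SystemState
    label: str
    basin_fraction: float
    converged: bool = True

    @property
    def totals(self) -> dict[str, float]:
        return self.state.as_dict()


# ---------------------------------------------------------------------------
# Update rule
# ---------------------------------------------------------------------------

def regulatory_input(
    node: str | int, state: SystemState, model: AdditiveModel, kinetics: str
) -> float:
    """Normalized signed weighted sum of upstream total activities.

    Nodes with no incoming edge of the requested class return their current
    value of that class's variable unchanged (input nodes hold their level).
    """
    i = node if isinstance(node, int) else model.node_index(node)
    incoming = model._incoming[kinetics][i]
    if not incoming:
        return float(state.fast[i] if kinetics == "fast" else state.slow[i])
    total = state.total
    num = 0.0
    denom = 0.0
    for src, w in incoming:
        num += w * total[src]
        denom += abs(w)
    return num / denom


def _check_finite(value: float, name: str) -> float:
    if not math.isfinite(value):
        raise FloatingPointError(f"non-finite value produced for node {name!r}")
    return value


def relax_fast(state: SystemState, model: AdditiveModel, rng: np.random.Generator) -> SystemState:
    """Random-order asynchronous fast updates until quiescent (in place)."""
    clamped = {model.node_index(c) for c in model.clamps}
    active = [
        i
        for i in range(len(state.node_names))
        if i not in clamped and model.has_inputs(i, "fast")
    ]
    if not active:
        return state
    f = model.activation
    for _ in range(model.fast_relaxation_max_iters):
        max_delta = 0.0
        for i in rng.permutation(active):
            s = regulatory_input(int(i), state, model, "fast")
            new = _check_finite(f(s), state.node_names[i])
            max_delta = max(max_delta, abs(new - state.fast[i]))
            state.fast[i] = new
        if max_delta <= model.convergence_tol:
            break
    return state


def update_step(
    state: SystemState, model: AdditiveModel, rng: np.random.Generator | int
) -> SystemState:
    """One slow macro-step: relax fast variables, then update one random
    slow variable.  Clamped nodes are never touched."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    new = state.copy()
    relax_fast(new, model, rng)
    clamped = {model.node_index(c) for c in model.clamps}
    slow_active = [
        i
        for i in range(len(new.node_names))
        if i not in clamped and model.has_inputs(i, "slow")
    ]
    if slow_active:
        i = int(rng.choice(slow_active))
        s = regulatory_input(i, new, model, "slow")
        new.slow[i] = _check_finite(model.activation(s), new.node_names[i])
    return new


def is_fixed_point(state: SystemState, model: AdditiveModel, tol: float | None = None) -> bool:
    """Certificate: every unclamped variable with inputs is self-consistent."""
    tol = model.convergence_tol if tol is None else tol
    clamped = {model.node_index(c) for c in model.clamps}
    for i in range(len(state.node_names)):
        if i in clamped:
            continue
        if model.has_inputs(i, "fast"):
            s = regulatory_input(i, state, model, "fast")
            if abs(model.activation(s) - state.fast[i]) > tol:
                return False
        if model.has_inputs(i, "slow"):
            s = regulatory_input(i, state, model, "slow")
            if abs(model.activation(s) - state.slow[i]) > tol:
                return False
    return True


# ---------------------------------------------------------------------------
# Stable-state discovery
# ---------------------------------------------------------------------------

def initial_state(model: AdditiveModel, totals: Sequence[float]) -> SystemState:
    """State at prescribed total levels: fast = level, slow = 1 (full
    expression); clamped nodes pinned to their clamp value."""
    names = model.node_names
    fast = np.asarray(totals, dtype=float)
    slow = np.ones(len(names))
    state = SystemState(names, fast, slow)
    for c, v in model.clamps.items():
        i = model.node_index(c)
        state.fast[i] = v
        state.slow[i] = v
    return state


def marker_label(state: SystemState, model: AdditiveModel) -> str:
    """A state is "M+" when marker M's total exceeds 0.5 and all rival
    markers are at or below 0.5; otherwise markers are listed jointly."""
    if not model.markers:
        return ""
    totals = state.as_dict()
    positive = [m for m in model.markers if totals[m] > 0.5]
    if not positive:
        return "none"
    return "/".join(f"{m}+" for m in positive)


def find_stable_states(
    model: AdditiveModel,
    n_initial_states: int = 64,
    max_steps: int | None = None,
    seed: int = 0,
    group_tol: float = 1e-3,
) -> list[StableState]:
    """Simulate from many initial conditions and group the fixed points.

    When 2**n_nodes ≤ n_initial_states all Boolean corners are used as
    initial total levels, otherwise uniform random levels in [0, 1].
    Endpoints within ``group_tol`` (max-norm on totals) are grouped; each
    group's basin fraction is its share of initial conditions.  Trajectories
    that do not reach a fixed point within ``max_steps`` raise a warning and
    are reported (grouped) as non-converged states.
    """
    if n_initial_states < 1:
        raise ValueError("n_initial_states must be >= 1")
    n = len(model.node_names)
    if max_steps is None:
        max_steps = max(10 * n * n, 20)
    rng = np.random.default_rng(seed)
    if 2**n <= n_initial_states:
        inits = [
            [(corner >> k) & 1 for k in range(n)] for corner in range(2**n)
        ]
    else:
        inits = [rng.uniform(0.0, 1.0, size=n).tolist() for _ in range(n_initial_states)]

    groups: list[dict] = []  # {"state":, "count":, "converged":}
    n_unconverged = 0
    for totals in inits:
        state = initial_state(model, totals)
        converged = is_fixed_point(state, model)
        if not converged:
            for _ in range(max_steps):
                state = update_step(state, model, rng)
                if is_fixed_point(state, model):
                    converged = True
                    break
        if not converged:
            n_unconverged += 1
        endpoint = state.total
        for grp in groups:
            if (
                grp["converged"] == converged
                and np.max(np.abs(grp["state"].total - endpoint)) <= group_tol
            ):
                grp["count"] += 1
                break
        else:
            groups.append({"state": state, "count": 1, "converged": converged})

    if n_unconverged:
        warnings.warn(
            f"{n_unconverged}/{len(inits)} trajectories did not reach a fixed "
            f"point within {max_steps} steps; partial result flagged non-converged",
            RuntimeWarning,
            stacklevel=2,
        )
    total_inits = len(inits)
    states = [
        StableState(
            state=g["state"],
            label=marker_label(g["state"], model),
            basin_fraction=g["count"] / total_inits if g["converged"] else 0.0,
            converged=g["converged"],
        )
        for g in groups
    ]
    states.sort(key=lambda s: -s.basin_fraction)
    return states


# ---------------------------------------------------------------------------
# Perturbation screens and dose responses
# ---------------------------------------------------------------------------

def apply_perturbation(model: AdditiveModel, spec: PerturbationSpec) -> AdditiveModel:
    """Model copy with the node clamped at 0 (KO) or 1 (over-activation)."""
    name = model.network.aliases.canonicalize(spec.node)
    if name not in model.node_names:
        raise ValueError(f"unknown node {spec.node!r}")
    clamps = dict(model.clamps)
    clamps[name] = spec.clamp_value
    return AdditiveModel(
        network=model.network,
        activation=model.activation,
        fast_relaxation_max_iters=model.fast_relaxation_max_iters,
        convergence_tol=model.convergence_tol,
        markers=list(model.markers),
        clamps=clamps,
    )


def _marker_positive_fraction(states: list[StableState], marker: str) -> float:
    return sum(
        s.basin_fraction for s in states if s.converged and s.totals[marker] > 0.5
    )


def perturbation_screen(
    model: AdditiveModel,
    marker_node: str,
    seed: int = 0,
    n_initial_states: int = 64,
) -> pd.DataFrame:
    """Single-node KO and over-activation screen against a marker phenotype.

    One row per perturbation (plus the unperturbed baseline); the
    ``required`` flag marks factors whose knockout leaves no marker-positive
    stable state, i.e. factors absolutely required to reach the phenotype.
    """
    marker = model.network.aliases.canonicalize(marker_node)
    if marker not in model.node_names:
        raise ValueError(f"unknown marker node {marker_node!r}")
    rows = []
    base = find_stable_states(model, n_initial_states=n_initial_states, seed=seed)
    base_frac = _marker_positive_fraction(base, marker)
    rows.append(
        {
            "node": "(none)",
            "mode": "baseline",
            "marker_basin_fraction": base_frac,
            "reachable": base_frac > 0,
            "required": False,
        }
    )
    for node in model.node_names:
        for mode in ("knockout", "overactivation"):
            pert = apply_perturbation(model, PerturbationSpec(node, mode))
            states = find_stable_states(pert, n_initial_states=n_initial_states, seed=seed)
            frac = _marker_positive_fraction(states, marker)
            rows.append(
                {
                    "node": node,
                    "mode": mode,
                    "marker_basin_fraction": frac,
                    "reachable": frac > 0,
                    "required": mode == "knockout" and frac == 0,
                }
            )
    return pd.DataFrame(rows)


def dose_response(
    model: AdditiveModel,
    input_node: str,
    levels: Sequence[float],
    seed: int = 0,
    n_initial_states: int = 64,
) -> pd.DataFrame:
    """Clamp ``input_node`` at each stimulus level and tabulate the stable
    states; rows are (level, label, basin_fraction, totals...)."""
    if len(levels) == 0:
        raise ValueError("levels must be non-empty")
    name = model.network.aliases.canonicalize(input_node)
    if name not in model.node_names:
        raise ValueError(f"unknown node {input_node!r}")
    for lv in levels:
        if not 0.0 <= lv <= 1.0:
            raise ValueError(f"level {lv} outside [0, 1]")
    rows = []
    for lv in levels:
        clamps = dict(model.clamps)
        clamps[name] = float(lv)
        clamped = AdditiveModel(
            network=model.network,
            activation=model.activation,
            fast_relaxation_max_iters=model.fast_relaxation_max_iters,
            convergence_tol=model.convergence_tol,
            markers=list(model.markers),
            clamps=clamps,
        )
        for s in find_stable_states(clamped, n_initial_states=n_initial_states, seed=seed):
            rows.append(
                {
                    "level": float(lv),
                    "label": s.label,
                    "basin_fraction": s.basin_fraction,
                    "converged": s.converged,
                    **{f"total_{k}": v for k, v in s.totals.items()},
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model spec I/O (JSON)
# ---------------------------------------------------------------------------

def model_to_json(model: AdditiveModel, path: str | Path) -> None:
    doc = {
        "nodes": [{"name": n.name, "category": n.category} for n in model.network.nodes],
        "edges": [
            {
                "source": e.source,
                "target": e.target,
                "sign": e.sign,
                "weight": e.weight,
                "kinetics": e.kinetics,
            }
            for e in model.network.edges
        ],
        "activation": {
            "kind": model.activation.kind,
            "steepness": model.activation.steepness,
            "threshold": model.activation.threshold,
        },
        "fast_relaxation_max_iters": model.fast_relaxation_max_iters,
        "convergence_tol": model.convergence_tol,
        "markers": model.markers,
        "clamps": model.clamps,
    }
    Path(path).write_text(json.dumps(doc, indent=2, ensure_ascii=False) + "\n")


def model_from_json(path: str | Path) -> AdditiveModel:
    doc = json.loads(Path(path).read_text())
    net = RegulatoryNetwork(
        [Node(n["name"], n.get("category", "other")) for n in doc["nodes"]],
        [
            Edge(
                e["source"],
                e["target"],
                int(e["sign"]),
                float(e.get("weight", 1.0)),
                e.get("kinetics", "slow"),
            )
            for e in doc["edges"]
        ],
    )
    act = doc.get("activation", {})
    return AdditiveModel(
        network=net,
        activation=ActivationSpec(
            kind=act.get("kind", "logistic"),
            steepness=float(act.get("steepness", 10.0)),
            threshold=float(act.get("threshold", 0.0)),
        ),
        fast_relaxation_max_iters=int(doc.get("fast_relaxation_max_iters", 1000)),
        convergence_tol=float(doc.get("convergence_tol", 1e-6)),
        markers=list(doc.get("markers", [])),
        clamps=dict(doc.get("clamps", {})),
    )


def stable_states_to_dataframe(states: list[StableState]) -> pd.DataFrame:
    rows = []
    for s in states:
        rows.append(
            {
                "label": s.label,
                "basin_fraction": s.basin_fraction,
                "converged": s.converged,
                **{f"total_{k}": v for k, v in s.totals.items()},
            }
        )
    return pd.DataFrame(rows)
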