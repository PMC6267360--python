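"""Discrete Bayesian-network types and the fixed accident-risk network.

The model links six safety-climate factors and three personal factors of
electrical & mechanical (E&M) repair-and-maintenance workers to a binary
outcome, the number of accidents suffered in the past twelve months
(``High``: two or more; ``Low``: at most one).  The graph structure is fixed
from the safety literature rather than learned from data; only the
conditional probability tables (CPTs) are estimated.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

ROW_SUM_TOL = 1e-9

ROLE_CLIMATE = "climate_factor"
ROLE_PERSONAL = "personal_factor"
ROLE_OUTCOME = "outcome"

OUTCOME_NODE = "number_of_accidents"

# Canonical state labels, ordered.  Three-state nodes are ordered best->worst
# except working_experience, which keeps its natural short->long order.
NODE_STATES: dict[str, tuple[str, ...]] = {
    "working_experience": ("Short", "Medium", "Long"),
    "workmate_influences": ("Positive", "Neutral", "Negative"),
    "management_commitment": ("Good", "Average", "Poor"),
    "safety_attitude": ("Good", "Average", "Poor"),
    "understanding_of_work_risk": ("Good", "Average", "Poor"),
    "safety_resources_equipment": ("Good", "Average", "Poor"),
    "safety_procedures": ("Good", "Average", "Poor"),
    "smoking_habit": ("Not smoking", "Smoking, but not at work", "Smoking at work"),
    "drinking_habit": ("Not drinking", "Drinking, but not at work", "Drinking at work"),
    OUTCOME_NODE: ("High", "Low"),
}

NODE_PARENTS: dict[str, tuple[str, ...]] = {
    "working_experience": (),
    "workmate_influences": (),
    "management_commitment": (),
    "safety_attitude": ("working_experience", "workmate_influences"),
    "understanding_of_work_risk": ("working_experience", "safety_attitude"),
    "safety_resources_equipment": ("management_commitment",),
    "safety_procedures": ("management_commitment", "safety_resources_equipment"),
    "smoking_habit": ("workmate_influences",),
    "drinking_habit": ("workmate_influences",),
    OUTCOME_NODE: (
        "safety_attitude",
        "understanding_of_work_risk",
        "management_commitment",
        "safety_resources_equipment",
        "safety_procedures",
        "smoking_habit",
        "drinking_habit",
    ),
}

NODE_ROLES: dict[str, str] = {
    "working_experience": ROLE_PERSONAL,
    "workmate_influences": ROLE_CLIMATE,
    "management_commitment": ROLE_CLIMATE,
    "safety_attitude": ROLE_CLIMATE,
    "understanding_of_work_risk": ROLE_CLIMATE,
    "safety_resources_equipment": ROLE_CLIMATE,
    "safety_procedures": ROLE_CLIMATE,
    "smoking_habit": ROLE_PERSONAL,
    "drinking_habit": ROLE_PERSONAL,
    OUTCOME_NODE: ROLE_OUTCOME,
}

#: The state each controllable node takes under an intervention strategy.
BEST_STATE: dict[str, str] = {
    "working_experience": "Long",
    "workmate_influences": "Positive",
    "management_commitment": "Good",
    "safety_attitude": "Good",
    "understanding_of_work_risk": "Good",
    "safety_resources_equipment": "Good",
    "safety_procedures": "Good",
    "smoking_habit": "Not smoking",
    "drinking_habit": "Not drinking",
}

# Label aliases: survey instruments and reports mix e.g. "Bad" and "Poor".
_STATE_ALIASES: dict[str, str] = {
    "bad": "Poor",
    "poor": "Poor",
    "good": "Good",
    "average": "Average",
    "high": "High",
    "low": "Low",
    "short": "Short",
    "medium": "Medium",
    "long": "Long",
    "positive": "Positive",
    "neutral": "Neutral",
    "negative": "Negative",
}


class CPTShapeError(ValueError):
    """A conditional probability table does not match its node's dimensions."""


class CPTNormalizationError(ValueError):
    """A CPT row does not sum to one."""


@dataclass(frozen=True)
class NodeSpec:
    """One variable of the network: its states, parents, and role."""

    name: str
    states: tuple[str, ...]
    parents: tuple[str, ...] = ()
    role: str = ROLE_CLIMATE

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "parents", tuple(self.parents))

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, label: str) -> int:
        return self.states.index(resolve_state(self, label))


def resolve_state(spec: NodeSpec, label: str) -> str:
    """Map a (possibly aliased) state label to the node's canonical label."""
    if label in spec.states:
        return label
    canon = _STATE_ALIASES.get(str(label).strip().lower())
    if canon is not None and canon in spec.states:
        return canon
    for s in spec.states:
        if s.lower() == str(label).strip().lower():
            return s
    raise ValueError(f"unknown state {label!r} for node {spec.name!r}; "
                     f"valid states: {list(spec.states)}")


@dataclass(frozen=True)
class ConditionalProbabilityTable:
    """P(node | parents): one row per parent configuration.

    ``parent_states`` lists the parent configurations in row order (a single
    empty tuple for a parentless node); ``probabilities`` is a
    (n_rows, n_child_states) matrix whose rows each sum to one.
    """

    node: str
    parent_states: tuple[tuple[str, ...], ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "parent_states",
                           tuple(tuple(c) for c in self.parent_states))
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2:
            raise CPTShapeError(
                f"CPT for {self.node!r}: probabilities must be 2-D, got {p.ndim}-D")
        object.__setattr__(self, "probabilities", p)

    @property
    def n_rows(self) -> int:
        return len(self.parent_states)

    def row(self, config: Sequence[str]) -> np.ndarray:
        return self.probabilities[self.parent_states.index(tuple(config))]


@dataclass
class BayesianNetwork:
    """A node map plus one CPT per node, jointly defining P(all nodes)."""

    nodes: dict[str, NodeSpec]
    cpts: dict[str, ConditionalProbabilityTable] = field(default_factory=dict)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for name, spec in self.nodes.items():
            for p in spec.parents:
                g.add_edge(p, name)
        return g

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph()))

    def copy(self) -> "BayesianNetwork":
        return BayesianNetwork(dict(self.nodes), dict(self.cpts))

    def parent_configurations(self, node: str) -> list[tuple[str, ...]]:
        parents = self.nodes[node].parents
        if not parents:
            return [()]
        return [tuple(c) for c in
                itertools.product(*(self.nodes[p].states for p in parents))]


def parent_configurations(bn: BayesianNetwork, node: str) -> list[tuple[str, ...]]:
    return bn.parent_configurations(node)


def uniform_cpt(bn: BayesianNetwork, node: str) -> ConditionalProbabilityTable:
    spec = bn.nodes[node]
    rows = bn.parent_configurations(node)
    p = np.full((len(rows), spec.n_states), 1.0 / spec.n_states)
    return ConditionalProbabilityTable(node, tuple(rows), p)


def cpt_from_function(bn: BayesianNetwork, node: str, fn) -> ConditionalProbabilityTable:
    """Build a CPT by evaluating ``fn(parent_config) -> probability vector``."""
    rows = bn.parent_configurations(node)
    p = np.array([np.asarray(fn(c), dtype=float) for c in rows])
    return ConditionalProbabilityTable(node, tuple(rows), p)


def build_accident_network() -> BayesianNetwork:
    """The fixed 10-node E&M accident-risk network with uniform CPTs.

    Roots: working_experience, workmate_influences, management_commitment.
    The outcome node ``number_of_accidents`` has seven parents and hence
    3**7 = 2187 CPT rows.
    """
    nodes = {
        name: NodeSpec(name, NODE_STATES[name], NODE_PARENTS[name], NODE_ROLES[name])
        for name in NODE_STATES
    }
    bn = BayesianNetwork(nodes)
    bn.cpts = {name: uniform_cpt(bn, name) for name in nodes}
    return bn


def _validate_cpt(bn: BayesianNetwork, node: str,
                  cpt: ConditionalProbabilityTable) -> list[str]:
    spec = bn.nodes[node]
    out: list[str] = []
    expected_rows = bn.parent_configurations(node)
    if cpt.node != node:
        out.append(f"{node}: CPT is labeled for node {cpt.node!r}")
    if list(cpt.parent_states) != expected_rows:
        out.append(f"{node}: CPT has {cpt.n_rows} rows / unexpected parent "
                   f"configurations; expected {len(expected_rows)} rows over "
                   f"parents {list(spec.parents)}")
        return out
    if cpt.probabilities.shape != (len(expected_rows), spec.n_states):
        out.append(f"{node}: CPT shape {cpt.probabilities.shape} != "
                   f"({len(expected_rows)}, {spec.n_states})")
        return out
    p = cpt.probabilities
    if np.any(p < -ROW_SUM_TOL) or np.any(p > 1 + ROW_SUM_TOL):
        out.append(f"{node}: CPT entries outside [0, 1]")
    bad = np.where(np.abs(p.sum(axis=1) - 1.0) > ROW_SUM_TOL)[0]
    for i in bad:
        out.append(f"{node}: row-normalization violated at row {i} "
                   f"(sum={p[i].sum():.6g})")
    return out


def validate_network(bn: BayesianNetwork) -> list[str]:
    """Return a list of invariant violations; empty iff the network is valid."""
    out: list[str] = []
    for name, spec in bn.nodes.items():
        if spec.name != name:
            out.append(f"{name}: spec name mismatch ({spec.name!r})")
        if len(set(spec.states)) != len(spec.states) or not spec.states:
            out.append(f"{name}: states must be unique and non-empty")
        if spec.role == ROLE_OUTCOME and spec.n_states != 2:
            out.append(f"{name}: outcome node must have exactly 2 states")
        if spec.role != ROLE_OUTCOME and spec.n_states != 3:
            out.append(f"{name}: non-outcome node must have exactly 3 states")
        if len(set(spec.parents)) != len(spec.parents):
            out.append(f"{name}: duplicate parents")
        if name in spec.parents:
            out.append(f"{name}: node is its own parent")
        for p in spec.parents:
            if p not in bn.nodes:
                out.append(f"{name}: unknown parent {p!r}")
    if all(p in bn.nodes for s in bn.nodes.values() for p in s.parents):
        if not nx.is_directed_acyclic_graph(bn.graph()):
            cyc = nx.find_cycle(bn.graph())
            out.append("cycle in parent graph: " +
                       " -> ".join(e[0] for e in cyc) + f" -> {cyc[-1][1]}")
    for name in bn.nodes:
        cpt = bn.cpts.get(name)
        if cpt is None:
            out.append(f"{name}: missing CPT")
            continue
        out.extend(_validate_cpt(bn, name, cpt))
    return out


def set_cpt(bn: BayesianNetwork, node: str,
            table: ConditionalProbabilityTable) -> BayesianNetwork:
    """Return a copy of ``bn`` with ``table`` installed at ``node``.

    Raises :class:`CPTShapeError` on dimension mismatch and
    :class:`CPTNormalizationError` (naming the row) on a non-normalized row.
    """
    if node not in bn.nodes:
        raise KeyError(f"unknown node {node!r}")
    spec = bn.nodes[node]
    expected_rows = bn.parent_configurations(node)
    if table.n_rows != len(expected_rows) or \
            table.probabilities.shape != (len(expected_rows), spec.n_states):
        raise CPTShapeError(
            f"CPT for {node!r}: expected shape "
            f"({len(expected_rows)}, {spec.n_states}), got "
            f"({table.n_rows}, {table.probabilities.shape[-1]})")
    sums = table.probabilities.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > ROW_SUM_TOL)[0]
    if bad.size:
        raise CPTNormalizationError(
            f"CPT for {node!r}: row {bad[0]} sums to {sums[bad[0]]:.6g}, not 1")
    table = ConditionalProbabilityTable(node, tuple(expected_rows),
                                        table.probabilities)
    new = bn.copy()
    new.cpts[node] = table
    violations = validate_network(new)
    if violations:
        raise ValueError("network invalid after set_cpt: " + "; ".join(violations))
    return new


def cpt_from_rows(bn: BayesianNetwork, node: str,
                  rows: Mapping[tuple[str, ...], Sequence[float]]
                  ) -> ConditionalProbabilityTable:
    """Assemble a CPT from a {parent_config: probability vector} mapping."""
    configs = bn.parent_configurations(node)
    specs = [bn.nodes[p] for p in bn.nodes[node].parents]
    canon = {}
    for cfg, vec in rows.items():
        key = tuple(resolve_state(s, lab) for s, lab in zip(specs, cfg))
        canon[key] = vec
    missing = [c for c in configs if c not in canon]
    if missing:
        raise CPTShapeError(f"CPT for {node!r}: missing rows for {missing[:3]}...")
    p = np.array([canon[c] for c in configs], dtype=float)
    return ConditionalProbabilityTable(node, tuple(configs), p)


# ---------------------------------------------------------------------------
# Serialization (JSON or YAML by file suffix).

def network_to_dict(bn: BayesianNetwork) -> dict:
    return {
        "nodes": [
            {"name": s.name, "states": list(s.states),
             "parents": list(s.parents), "role": s.role}
            for s in bn.nodes.values()
        ],
        "cpts": {
            name: {
                "parent_states": [list(c) for c in cpt.parent_states],
                "probabilities": cpt.probabilities.tolist(),
            }
            for name, cpt in bn.cpts.items()
        },
    }


def network_from_dict(doc: Mapping) -> BayesianNetwork:
    nodes = {
        d["name"]: NodeSpec(d["name"], tuple(d["states"]),
                            tuple(d.get("parents", ())),
                            d.get("role", ROLE_CLIMATE))
        for d in doc["nodes"]
    }
    bn = BayesianNetwork(nodes)
    for name, c in doc.get("cpts", {}).items():
        bn.cpts[name] = ConditionalProbabilityTable(
            name, tuple(tuple(r) for r in c["parent_states"]),
            np.asarray(c["probabilities"], dtype=float))
    return bn


def save_network(bn: BayesianNetwork, path: str | Path) -> Path:
    path = Path(path)
    doc = network_to_dict(bn)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=1))
    return path


def load_network(path: str | Path) -> BayesianNetwork:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return network_from_dict(doc)
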