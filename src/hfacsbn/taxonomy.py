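"""HFACS taxonomy as a layered directed acyclic graph.

The Human Factors Analysis and Classification System (HFACS) arranges
contributing factors of safety incidents into four levels:

* Level 4 — organizational influences: resource management (RM),
  organizational climate (OC), organizational process (OP)
* Level 3 — unsafe supervision: inadequate supervision (IS), planned
  inappropriate operations (PIO), failure to correct known problems (FCP),
  supervisory violations (SV)
* Level 2 — preconditions for unsafe acts: condition of operators (CO),
  personnel factors (PF), environmental factors (EF)
* Level 1 — unsafe acts: error type (ERR: skill / decision / perception /
  none) and violation type (VIO: routine / exceptional / none)

The causal structure is *layered-complete*: every factor at level L+1 is a
direct parent of every factor at level L, and no other edges exist.  Factors
within a level are conditionally independent given the level above.  Level
numbering runs bottom-up (1 = unsafe acts ... 4 = organizational
influences), matching how sensitivity tables in the field are laid out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import yaml

__all__ = [
    "FactorNode",
    "HfacsNetwork",
    "build_default_network",
    "validate_network",
    "network_to_yaml",
    "network_from_yaml",
    "BINARY_STATES",
    "ERROR_STATES",
    "VIOLATION_STATES",
]

BINARY_STATES = ("yes", "no")
ERROR_STATES = ("skill", "decision", "perception", "none")
VIOLATION_STATES = ("routine", "exceptional", "none")

#: canonical factor labels used by the default network
_DEFAULT_LABELS = {
    "RM": "resource management",
    "OC": "organizational climate",
    "OP": "organizational process",
    "IS": "inadequate supervision",
    "PIO": "planned inappropriate operations",
    "FCP": "failure to correct known problems",
    "SV": "supervisory violations",
    "CO": "condition of operators",
    "PF": "personnel factors",
    "EF": "environmental factors",
    "ERR": "error type",
    "VIO": "violation type",
}


@dataclass(frozen=True)
class FactorNode:
    """One HFACS factor: a categorical random variable in the network."""

    code: str
    label: str
    level: int
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3, 4):
            raise ValueError(f"level must be 1..4, got {self.level}")
        if len(set(self.states)) != len(self.states) or not self.states:
            raise ValueError(f"states of {self.code!r} must be non-empty and unique")


@dataclass(frozen=True)
class HfacsNetwork:
    """Layered DAG over :class:`FactorNode` objects (structure only).

    ``edges`` are (parent_code, child_code) pairs; in a valid network they
    are exactly the complete bipartite connections between adjacent levels.
    """

    nodes: tuple[FactorNode, ...]
    edges: tuple[tuple[str, str], ...] = field(default=())

    # -- lookups -----------------------------------------------------------
    def node(self, code: str) -> FactorNode:
        for n in self.nodes:
            if n.code == code:
                return n
        raise KeyError(f"no node with code {code!r}")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(n.code for n in self.nodes)

    def level_codes(self, level: int) -> tuple[str, ...]:
        return tuple(n.code for n in self.nodes if n.level == level)

    def parents(self, code: str) -> tuple[str, ...]:
        """Parent codes of ``code``, in node-declaration order."""
        parent_set = {p for p, c in self.edges if c == code}
        return tuple(n.code for n in self.nodes if n.code in parent_set)

    def children(self, code: str) -> tuple[str, ...]:
        child_set = {c for p, c in self.edges if p == code}
        return tuple(n.code for n in self.nodes if n.code in child_set)

    def states(self, code: str) -> tuple[str, ...]:
        return self.node(code).states

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.codes)
        g.add_edges_from(self.edges)
        return g

    def topological_order(self) -> tuple[str, ...]:
        """Deterministic topological order (level descending, then code)."""
        order = sorted(self.nodes, key=lambda n: (-n.level, n.code))
        return tuple(n.code for n in order)

    @property
    def joint_size(self) -> int:
        size = 1
        for n in self.nodes:
            size *= len(n.states)
        return size


def _layered_edges(nodes: Sequence[FactorNode]) -> tuple[tuple[str, str], ...]:
    """Complete bipartite edges from each level L+1 down to level L."""
    by_level: dict[int, list[str]] = {}
    for n in nodes:
        by_level.setdefault(n.level, []).append(n.code)
    edges: list[tuple[str, str]] = []
    for upper in sorted(by_level, reverse=True):
        lower = upper - 1
        if lower in by_level:
            for p in by_level[upper]:
                for c in by_level[lower]:
                    edges.append((p, c))
    return tuple(edges)


def build_default_network() -> HfacsNetwork:
    """The canonical 12-node HFACS network.

    Ten binary yes/no factors plus the two multi-state unsafe-act nodes;
    30 edges; joint state space 2^10 * 4 * 3 = 12,288.
    """
    nodes = []
    for level, codes in ((4, ("RM", "OC", "OP")), (3, ("IS", "PIO", "FCP", "SV")),
                         (2, ("CO", "PF", "EF"))):
        for code in codes:
            nodes.append(FactorNode(code, _DEFAULT_LABELS[code], level, BINARY_STATES))
    nodes.append(FactorNode("ERR", _DEFAULT_LABELS["ERR"], 1, ERROR_STATES))
    nodes.append(FactorNode("VIO", _DEFAULT_LABELS["VIO"], 1, VIOLATION_STATES))
    nodes = tuple(nodes)
    return HfacsNetwork(nodes=nodes, edges=_layered_edges(nodes))


def validate_network(net: HfacsNetwork) -> list[str]:
    """Check all structural invariants; return one message per violation.

    An empty list means the network is a valid layered HFACS structure.
    Violations are reported, never raised, so callers can present them all.
    """
    msgs: list[str] = []

    codes = [n.code for n in net.nodes]
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        msgs.append(f"duplicate node codes: {', '.join(dupes)}")

    for n in net.nodes:
        if n.level in (2, 3, 4) and n.states != BINARY_STATES:
            msgs.append(f"node {n.code} at level {n.level} must have states "
                        f"{list(BINARY_STATES)}, has {list(n.states)}")
        if n.level == 1 and n.states not in (ERROR_STATES, VIOLATION_STATES):
            msgs.append(f"level-1 node {n.code} must have error states "
                        f"{list(ERROR_STATES)} or violation states "
                        f"{list(VIOLATION_STATES)}, has {list(n.states)}")

    level_of = {n.code: n.level for n in net.nodes}
    for p, c in net.edges:
        if p not in level_of or c not in level_of:
            msgs.append(f"edge ({p}, {c}) references an unknown node")
            continue
        if level_of[p] != level_of[c] + 1:
            msgs.append(f"edge ({p}, {c}) connects level {level_of[p]} to level "
                        f"{level_of[c]}; only level L+1 -> L edges are allowed")

    # layered completeness: every adjacent-level pair must be present
    present = set(net.edges)
    by_level: dict[int, list[str]] = {}
    for n in net.nodes:
        by_level.setdefault(n.level, []).append(n.code)
    for upper in sorted(by_level, reverse=True):
        if upper - 1 not in by_level:
            continue
        for p in by_level[upper]:
            for c in by_level[upper - 1]:
                if (p, c) not in present:
                    msgs.append(f"missing layered edge ({p}, {c})")

    g = nx.DiGraph()
    g.add_nodes_from(codes)
    g.add_edges_from((p, c) for p, c in net.edges if p in level_of and c in level_of)
    if not nx.is_directed_acyclic_graph(g):
        msgs.append("network contains a directed cycle")

    return msgs


# -- serialization ---------------------------------------------------------
# The config format lists nodes per level with their states; edges are
# implied by layered completeness and never written out.

def network_to_yaml(net: HfacsNetwork) -> str:
    doc = {"levels": [
        {"level": lvl,
         "nodes": [{"code": n.code, "label": n.label, "states": list(n.states)}
                   for n in net.nodes if n.level == lvl]}
        for lvl in sorted({n.level for n in net.nodes}, reverse=True)
    ]}
    return yaml.safe_dump(doc, sort_keys=False)


def network_from_yaml(text: str) -> HfacsNetwork:
    doc = yaml.safe_load(text)
    nodes: list[FactorNode] = []
    for lvl_block in doc["levels"]:
        lvl = int(lvl_block["level"])
        for nd in lvl_block["nodes"]:
            nodes.append(FactorNode(nd["code"], nd.get("label", nd["code"]), lvl,
                                    tuple(nd["states"])))
    nodes_t = tuple(nodes)
    return HfacsNetwork(nodes=nodes_t, edges=_layered_edges(nodes_t))
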