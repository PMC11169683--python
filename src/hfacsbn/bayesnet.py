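"""Discrete Bayesian network machinery: CPTs, exact inference, serialization.

A network ``N = <G, P>`` couples the layered DAG (:mod:`hfacsbn.taxonomy`)
with one conditional probability table per node.  The joint distribution
factorizes as

    P(x_1, ..., x_n) = prod_i P(x_i | Pa(x_i))

where ``Pa(x_i)`` are the parents of node i.  Inference is exact: posterior
queries run variable elimination (min-degree ordering, lexicographic
tie-break); :func:`enumerate_joint` provides the brute-force oracle, feasible
because the default joint space has only 12,288 states.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

from .taxonomy import HfacsNetwork, network_from_yaml, network_to_yaml

__all__ = [
    "Cpt",
    "DiscreteBn",
    "Evidence",
    "Distribution",
    "InconsistentEvidenceError",
    "bn_to_yaml",
    "bn_from_yaml",
]

PROB_ATOL = 1e-9

Evidence = Mapping[str, str]


class InconsistentEvidenceError(ValueError):
    """Raised when asserted evidence has probability zero under the model."""


@dataclass(frozen=True)
class Distribution:
    """Categorical distribution over one node's states."""

    node: str
    probs: Mapping[str, float]

    def __post_init__(self) -> None:
        total = float(sum(self.probs.values()))
        if any(p < -PROB_ATOL for p in self.probs.values()):
            raise ValueError(f"negative probability in distribution over {self.node}")
        if abs(total - 1.0) > PROB_ATOL:
            raise ValueError(f"distribution over {self.node} sums to {total}, not 1")

    def __getitem__(self, state: str) -> float:
        return self.probs[state]

    def as_array(self, states: Iterable[str]) -> np.ndarray:
        return np.array([self.probs[s] for s in states], dtype=float)


@dataclass(frozen=True)
class Cpt:
    """Conditional probability table P(node | parents).

    ``table`` maps each parent configuration — a tuple of parent states in
    ``parents`` order — to a probability vector over ``states``.  A root
    node has the single empty configuration ``()``.  ``counts`` carries the
    per-configuration observation totals from fitting (empty for authored
    tables) and ``alpha`` the Dirichlet pseudo-count used.
    """

    node: str
    states: tuple[str, ...]
    parents: tuple[str, ...]
    parent_states: tuple[tuple[str, ...], ...]
    table: Mapping[tuple[str, ...], tuple[float, ...]]
    alpha: float = 0.0
    counts: Mapping[tuple[str, ...], int] = field(default_factory=dict)
    unobserved_uniform: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        expected = set(itertools.product(*self.parent_states)) if self.parents else {()}
        got = set(self.table)
        if got != expected:
            raise ValueError(
                f"CPT for {self.node}: table must cover exactly the parent-state "
                f"product space ({len(expected)} configurations, got {len(got)})")
        for cfg, vec in self.table.items():
            if len(vec) != len(self.states):
                raise ValueError(f"CPT for {self.node}: row {cfg} has wrong length")
            if any(p < 0 for p in vec):
                raise ValueError(f"CPT for {self.node}: negative probability in row {cfg}")
            if abs(sum(vec) - 1.0) > 1e-12:
                raise ValueError(
                    f"CPT for {self.node}: row {cfg} sums to {sum(vec)!r}, not 1")

    def configurations(self) -> list[tuple[str, ...]]:
        """Parent configurations in row-major order of the parent state lists."""
        if not self.parents:
            return [()]
        return list(itertools.product(*self.parent_states))

    def prob(self, state: str, config: tuple[str, ...] = ()) -> float:
        return self.table[config][self.states.index(state)]

    def as_array(self) -> np.ndarray:
        """Dense array with axes (parent_1, ..., parent_k, node)."""
        shape = tuple(len(s) for s in self.parent_states) + (len(self.states),)
        arr = np.empty(shape, dtype=float)
        for idx, cfg in enumerate(self.configurations()):
            arr.reshape(-1, len(self.states))[idx, :] = self.table[cfg]
        return arr


class DiscreteBn:
    """A fully specified discrete BN: layered structure plus one CPT per node."""

    def __init__(self, network: HfacsNetwork, cpts: Mapping[str, Cpt]):
        missing = set(network.codes) - set(cpts)
        extra = set(cpts) - set(network.codes)
        if missing or extra:
            raise ValueError(f"CPT set mismatch: missing {sorted(missing)}, "
                             f"extra {sorted(extra)}")
        for code, cpt in cpts.items():
            want = network.parents(code)
            if tuple(cpt.parents) != want:
                raise ValueError(f"CPT for {code} declares parents {cpt.parents}, "
                                 f"network requires {want}")
            if tuple(cpt.states) != network.states(code):
                raise ValueError(f"CPT for {code} has states {cpt.states}, "
                                 f"network requires {network.states(code)}")
        self.network = network
        self.cpts = dict(cpts)

    # -- joint -------------------------------------------------------------
    def joint_probability(self, assignment: Mapping[str, str]) -> float:
        """Probability of one complete assignment, per the factorization."""
        missing = set(self.network.codes) - set(assignment)
        if missing:
            raise ValueError(f"assignment incomplete: missing {sorted(missing)}")
        p = 1.0
        for code in self.network.codes:
            cpt = self.cpts[code]
            cfg = tuple(assignment[par] for par in cpt.parents)
            p *= cpt.prob(assignment[code], cfg)
        return p

    def enumerate_joint(self, cap: int = 10**6):
        """Exhaustive (assignment, probability) table — the inference oracle.

        Returns a list of ``(dict, float)`` pairs covering every joint state.
        Refuses joint spaces larger than ``cap``.
        """
        size = self.network.joint_size
        if size > cap:
            raise ValueError(f"joint space has {size} states, above the cap {cap}")
        codes = self.network.codes
        state_lists = [self.network.states(c) for c in codes]
        rows = []
        for combo in itertools.product(*state_lists):
            assignment = dict(zip(codes, combo))
            rows.append((assignment, self.joint_probability(assignment)))
        return rows

    # -- inference ---------------------------------------------------------
    def query(self, target: str, evidence: Evidence | None = None) -> Distribution:
        """Exact posterior P(target | evidence) by variable elimination.

        Empty evidence yields the prior marginal.  Evidence with zero
        probability under the model raises :class:`InconsistentEvidenceError`.
        """
        evidence = dict(evidence or {})
        if target in evidence:
            raise ValueError(f"target {target} cannot also appear in evidence")
        self._check_states({target: self.network.states(target)[0], **evidence})

        factors = []
        for code in self.network.codes:
            cpt = self.cpts[code]
            vars_ = tuple(cpt.parents) + (code,)
            factors.append(_Factor(vars_, cpt.as_array()))
        # incorporate evidence by slicing factors
        reduced = [f.reduce(evidence, self._state_index) for f in factors]

        hidden = sorted(set(self.network.codes) - set(evidence) - {target})
        order = _min_degree_order(reduced, hidden)
        for var in order:
            touching = [f for f in reduced if var in f.vars]
            reduced = [f for f in reduced if var not in f.vars]
            reduced.append(_Factor.multiply_all(touching).marginalize(var))

        result = _Factor.multiply_all([f for f in reduced if f.vars == (target,)]
                                      + [f for f in reduced if f.vars != (target,)])
        # any remaining scalar factors were absorbed by multiply_all
        vec = result.values if result.vars == (target,) else result.values.reshape(-1)
        total = float(vec.sum())
        if total <= 0.0:
            raise InconsistentEvidenceError(
                f"evidence {evidence} has probability zero under the model")
        states = self.network.states(target)
        return Distribution(target, dict(zip(states, (vec / total).tolist())))

    def prior_marginals(self) -> dict[str, Distribution]:
        """Prior marginal of every node (empty-evidence queries)."""
        return {code: self.query(code) for code in self.network.codes}

    # -- helpers -----------------------------------------------------------
    def _state_index(self, code: str, state: str) -> int:
        states = self.network.states(code)
        try:
            return states.index(state)
        except ValueError:
            raise ValueError(f"state {state!r} is not legal for node {code} "
                             f"(legal: {list(states)})") from None

    def _check_states(self, assignment: Mapping[str, str]) -> None:
        for code, state in assignment.items():
            self._state_index(code, state)


@dataclass(frozen=True)
class _Factor:
    """Dense factor over an ordered tuple of variables."""

    vars: tuple[str, ...]
    values: np.ndarray

    def reduce(self, evidence: Mapping[str, str], state_index) -> "_Factor":
        vars_, vals = self.vars, self.values
        for code, state in evidence.items():
            if code in vars_:
                axis = vars_.index(code)
                vals = np.take(vals, state_index(code, state), axis=axis)
                vars_ = vars_[:axis] + vars_[axis + 1:]
        return _Factor(vars_, vals)

    def marginalize(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(self.vars[:axis] + self.vars[axis + 1:],
                       self.values.sum(axis=axis))

    @staticmethod
    def multiply_all(factors: list["_Factor"]) -> "_Factor":
        if not factors:
            return _Factor((), np.array(1.0))
        out_vars = tuple(sorted({v for f in factors for v in f.vars}))
        out = np.array(1.0)
        for f in factors:
            if f.vars:
                # align f's axes with out_vars, broadcasting over absent vars
                perm = sorted(range(len(f.vars)),
                              key=lambda i: out_vars.index(f.vars[i]))
                vals = np.transpose(f.values, perm)
                shape = [1] * len(out_vars)
                for axis_pos, size in zip((out_vars.index(f.vars[i]) for i in perm),
                                          vals.shape):
                    shape[axis_pos] = size
                vals = vals.reshape(shape)
            else:
                vals = f.values
            out = out * vals
        return _Factor(out_vars, np.asarray(out))


def _min_degree_order(factors: list[_Factor], hidden: list[str]) -> list[str]:
    """Min-degree elimination order over the factor graph; ties by code."""
    neighbors: dict[str, set[str]] = {v: set() for v in hidden}
    cliques = [set(f.vars) for f in factors]
    order: list[str] = []
    remaining = set(hidden)
    while remaining:
        for v in remaining:
            nb = set()
            for cl in cliques:
                if v in cl:
                    nb |= cl
            neighbors[v] = (nb - {v}) & remaining
        var = min(remaining, key=lambda v: (len(neighbors[v]), v))
        order.append(var)
        merged = {var}
        new_cliques = []
        for cl in cliques:
            if var in cl:
                merged |= cl
            else:
                new_cliques.append(cl)
        merged.discard(var)
        new_cliques.append(merged)
        cliques = new_cliques
        remaining.discard(var)
    return order


# -- serialization ---------------------------------------------------------
# YAML layout: the network (nodes per level) plus, per node, the ordered
# parent list and CPT rows keyed by parent configuration in row-major order
# of the parent state lists.

def bn_to_yaml(bn: DiscreteBn, provenance: Mapping | None = None) -> str:
    doc: dict = {"network": yaml.safe_load(network_to_yaml(bn.network))}
    cpts = []
    for code in bn.network.codes:
        cpt = bn.cpts[code]
        rows = []
        for cfg in cpt.configurations():
            rows.append({"given": list(cfg),
                         "probs": [float(p) for p in cpt.table[cfg]]})
        entry: dict = {"node": code, "parents": list(cpt.parents),
                       "alpha": float(cpt.alpha), "rows": rows}
        if cpt.counts:
            entry["counts"] = [{"given": list(cfg), "n": int(n)}
                               for cfg, n in sorted(cpt.counts.items())]
        if cpt.unobserved_uniform:
            entry["unobserved_uniform"] = [list(c) for c in cpt.unobserved_uniform]
        cpts.append(entry)
    doc["cpts"] = cpts
    if provenance:
        doc["provenance"] = dict(provenance)
    return yaml.safe_dump(doc, sort_keys=False)


def bn_from_yaml(text: str) -> tuple[DiscreteBn, dict]:
    doc = yaml.safe_load(text)
    net = network_from_yaml(yaml.safe_dump(doc["network"], sort_keys=False))
    cpts: dict[str, Cpt] = {}
    for entry in doc["cpts"]:
        code = entry["node"]
        parents = tuple(entry["parents"])
        parent_states = tuple(net.states(p) for p in parents)
        table = {tuple(r["given"]): tuple(float(p) for p in r["probs"])
                 for r in entry["rows"]}
        counts = {tuple(c["given"]): int(c["n"]) for c in entry.get("counts", [])}
        cpts[code] = Cpt(node=code, states=net.states(code), parents=parents,
                         parent_states=parent_states, table=table,
                         alpha=float(entry.get("alpha", 0.0)), counts=counts,
                         unobserved_uniform=tuple(
                             tuple(c) for c in entry.get("unobserved_uniform", [])))
    return DiscreteBn(net, cpts), doc.get("provenance", {})
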