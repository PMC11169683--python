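"""Shared fixtures: small hand-built networks, toy databases, oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from hfacsbn import (CaseDatabase, Cpt, DiscreteBn, FactorNode, HfacsNetwork,
                     build_default_network, case_database_from_dataframe)


@pytest.fixture(scope="session")
def default_net():
    return build_default_network()


def make_cpt(net: HfacsNetwork, code: str, rows) -> Cpt:
    """Build a Cpt for ``code`` from {config: prob-vector} (or a single row)."""
    parents = net.parents(code)
    parent_states = tuple(net.states(p) for p in parents)
    if not isinstance(rows, dict):
        rows = {(): rows}
    table = {cfg: tuple(float(p) for p in vec) for cfg, vec in rows.items()}
    return Cpt(node=code, states=net.states(code), parents=parents,
               parent_states=parent_states, table=table)


def uniform_bn(net: HfacsNetwork) -> DiscreteBn:
    cpts = {}
    for node in net.nodes:
        k = len(node.states)
        parents = net.parents(node.code)
        parent_states = tuple(net.states(p) for p in parents)
        configs = list(itertools.product(*parent_states)) if parents else [()]
        cpts[node.code] = Cpt(node=node.code, states=node.states, parents=parents,
                              parent_states=parent_states,
                              table={c: tuple([1.0 / k] * k) for c in configs})
    return DiscreteBn(net, cpts)


def random_bn(net: HfacsNetwork, seed: int) -> DiscreteBn:
    """Valid random CPTs (Dirichlet(1) rows) on the given structure."""
    rng = np.random.default_rng(seed)
    cpts = {}
    for node in net.nodes:
        parents = net.parents(node.code)
        parent_states = tuple(net.states(p) for p in parents)
        configs = list(itertools.product(*parent_states)) if parents else [()]
        table = {}
        for cfg in configs:
            vec = rng.dirichlet(np.ones(len(node.states)))
            table[cfg] = tuple(vec.tolist())
        cpts[node.code] = Cpt(node=node.code, states=node.states, parents=parents,
                              parent_states=parent_states, table=table)
    return DiscreteBn(net, cpts)


def posterior_by_enumeration(bn: DiscreteBn, target: str, evidence=None) -> dict:
    """Brute-force posterior over the full joint — the inference oracle."""
    evidence = evidence or {}
    totals = {s: 0.0 for s in bn.network.states(target)}
    for assignment, p in bn.enumerate_joint():
        if all(assignment[k] == v for k, v in evidence.items()):
            totals[assignment[target]] += p
    z = sum(totals.values())
    return {s: v / z for s, v in totals.items()}


@pytest.fixture(scope="session")
def chain_bn():
    """Hand-built 3-node chain A -> B -> C of binary factors."""
    nodes = (FactorNode("A", "a", 4, ("yes", "no")),
             FactorNode("B", "b", 3, ("yes", "no")),
             FactorNode("C", "c", 2, ("yes", "no")))
    net = HfacsNetwork(nodes=nodes, edges=(("A", "B"), ("B", "C")))
    cpts = {
        "A": make_cpt(net, "A", (0.3, 0.7)),
        "B": make_cpt(net, "B", {("yes",): (0.5, 0.5), ("no",): (0.1, 0.9)}),
        "C": make_cpt(net, "C", {("yes",): (0.2, 0.8), ("no",): (0.4, 0.6)}),
    }
    return DiscreteBn(net, cpts)


def toy_dataframe(net: HfacsNetwork, assignments: list[dict],
                  phases=None, error_types=None) -> pd.DataFrame:
    """DataFrame of complete codings; unspecified nodes default to no/none."""
    rows = []
    for i, partial in enumerate(assignments):
        row = {"incident_id": f"case-{i + 1}"}
        if phases:
            row["phase"] = phases[i]
        if error_types:
            row["error_type"] = error_types[i]
        for node in net.nodes:
            default = "none" if "none" in node.states else "no"
            row[node.code] = partial.get(node.code, default)
        rows.append(row)
    columns = ["incident_id"]
    if phases:
        columns.append("phase")
    if error_types:
        columns.append("error_type")
    columns += [n.code for n in net.nodes]
    return pd.DataFrame(rows, columns=columns)


@pytest.fixture()
def toy_db(default_net) -> CaseDatabase:
    """Two incidents used by the hand-counted frequency example."""
    df = toy_dataframe(default_net, [
        {"ERR": "skill"},
        {"VIO": "routine", "CO": "yes"},
    ])
    return case_database_from_dataframe(df, default_net)
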