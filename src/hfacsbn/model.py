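"""CPT learning from coded cases, statsmodels-style.

:class:`HfacsBnModel` wraps a case database and a layered network;
``fit(alpha=...)`` estimates every conditional probability table by
Dirichlet-smoothed maximum likelihood,

    P(s | c) = (n_{s|c} + alpha) / (sum_s' n_{s'|c} + alpha * |states|),

and returns :class:`HfacsBnResults`, which carries the fitted tables plus
all downstream analysis: joint probabilities, exact posterior queries,
prior marginals, the sensitivity matrix, and a text summary.

``alpha`` is the pseudo-count added to every state of every parent
configuration.  The default ``alpha=1`` (add-one smoothing) keeps rare
parent configurations away from degenerate 0/1 probabilities; ``alpha=0``
gives the pure maximum-likelihood estimate, with parent configurations never
observed in the data set to a uniform row and flagged in the provenance.
"""

from __future__ import annotations

import datetime
import itertools
from typing import Mapping

import pandas as pd

from . import sensitivity as _sensitivity
from .bayesnet import Cpt, DiscreteBn, Distribution, Evidence, bn_from_yaml, bn_to_yaml
from .coding import CaseDatabase, case_database_from_dataframe
from .taxonomy import HfacsNetwork, build_default_network, validate_network

__all__ = ["HfacsBnModel", "HfacsBnResults", "fit_cpts"]


class HfacsBnModel:
    """A layered-BN model of HFACS-coded incidents, ready to fit.

    Parameters
    ----------
    data
        A validated :class:`~hfacsbn.coding.CaseDatabase` of complete
        incident codings.
    network
        The layered structure; defaults to the database's own network.
    """

    def __init__(self, data: CaseDatabase, network: HfacsNetwork | None = None):
        network = network or data.network
        problems = validate_network(network)
        if problems:
            raise ValueError("invalid network: " + "; ".join(problems))
        if len(data) == 0:
            raise ValueError("cannot fit a model to an empty case database")
        self.data = data
        self.network = network

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       network: HfacsNetwork | None = None) -> "HfacsBnModel":
        network = network or build_default_network()
        return cls(case_database_from_dataframe(df, network), network)

    def fit(self, alpha: float = 1.0) -> "HfacsBnResults":
        """Estimate all CPTs; returns the fitted results object."""
        if alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {alpha}")
        cpts: dict[str, Cpt] = {}
        records = self.data.records
        for code in self.network.codes:
            states = self.network.states(code)
            parents = self.network.parents(code)
            parent_states = tuple(self.network.states(p) for p in parents)
            configs = (list(itertools.product(*parent_states)) if parents else [()])

            counts = {cfg: {s: 0 for s in states} for cfg in configs}
            for r in records:
                cfg = tuple(r.assignment[p] for p in parents)
                counts[cfg][r.assignment[code]] += 1

            table: dict[tuple[str, ...], tuple[float, ...]] = {}
            row_totals: dict[tuple[str, ...], int] = {}
            unobserved: list[tuple[str, ...]] = []
            k = len(states)
            for cfg in configs:
                n_cfg = sum(counts[cfg].values())
                row_totals[cfg] = n_cfg
                denom = n_cfg + alpha * k
                if denom == 0:          # alpha == 0 and configuration unseen
                    table[cfg] = tuple(1.0 / k for _ in states)
                    unobserved.append(cfg)
                else:
                    table[cfg] = tuple((counts[cfg][s] + alpha) / denom
                                       for s in states)
            cpts[code] = Cpt(node=code, states=states, parents=parents,
                             parent_states=parent_states, table=table,
                             alpha=alpha, counts=row_totals,
                             unobserved_uniform=tuple(unobserved))

        provenance = {
            "n_records": len(records),
            "alpha": alpha,
            "fitted_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "uniform_fallback_rows": sorted(
                [code, list(cfg)] for code, cpt in cpts.items()
                for cfg in cpt.unobserved_uniform),
        }
        return HfacsBnResults(self.network, cpts, provenance, model=self)


class HfacsBnResults(DiscreteBn):
    """Fitted network: CPTs plus inference and sensitivity analysis.

    Inherits exact inference (:meth:`query`, :meth:`joint_probability`,
    :meth:`enumerate_joint`, :meth:`prior_marginals`) from
    :class:`~hfacsbn.bayesnet.DiscreteBn`; adds fitting provenance,
    sensitivity analysis and reporting.
    """

    def __init__(self, network: HfacsNetwork, cpts: Mapping[str, Cpt],
                 provenance: Mapping | None = None, model: HfacsBnModel | None = None):
        super().__init__(network, cpts)
        self.provenance = dict(provenance or {})
        self.model = model

    # -- sensitivity -------------------------------------------------------
    def sensitivity(self, upper: str, lower: str, lower_state: str) -> float:
        return _sensitivity.sensitivity(
            self, _sensitivity.SensitivityQuery(upper, lower, lower_state))

    def sensitivity_matrix(self) -> pd.DataFrame:
        return _sensitivity.sensitivity_matrix(self)

    def overall_sensitivity(self) -> pd.DataFrame:
        return _sensitivity.overall_sensitivity(self)

    # -- reporting ---------------------------------------------------------
    def prior_table(self) -> pd.DataFrame:
        """Prior marginals of every node as a long DataFrame."""
        rows = []
        for node in self.network.nodes:
            dist = self.query(node.code)
            for state in node.states:
                rows.append({"node": node.code, "level": node.level,
                             "state": state, "probability": dist[state]})
        return pd.DataFrame(rows)

    def summary(self, digits: int = 3) -> str:
        """Human-readable fit summary: provenance and prior marginals."""
        lines = ["Layered HFACS Bayesian network — fit results",
                 "=" * 46,
                 f"nodes: {len(self.network.nodes)}    "
                 f"edges: {len(self.network.edges)}    "
                 f"joint states: {self.network.joint_size}"]
        if self.provenance:
            lines.append(f"records: {self.provenance.get('n_records', '?')}    "
                         f"alpha: {self.provenance.get('alpha', '?')}")
            fallback = self.provenance.get("uniform_fallback_rows") or []
            if fallback:
                lines.append(f"uniform-fallback CPT rows (unseen parent "
                             f"configurations): {len(fallback)}")
        lines.append("")
        lines.append("Prior marginal of factor presence:")
        for node in self.network.nodes:
            dist = self.query(node.code)
            shown = ", ".join(f"{s}={dist[s]:.{digits}f}" for s in node.states
                              if s not in ("no",))
            lines.append(f"  L{node.level} {node.code:<4} {shown}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(bn_to_yaml(self, provenance=self.provenance))

    @classmethod
    def load(cls, path) -> "HfacsBnResults":
        with open(path, encoding="utf-8") as fh:
            bn, provenance = bn_from_yaml(fh.read())
        return cls(bn.network, bn.cpts, provenance)


def fit_cpts(db: CaseDatabase, net: HfacsNetwork | None = None,
             alpha: float = 1.0) -> HfacsBnResults:
    """Functional form of :meth:`HfacsBnModel.fit`."""
    return HfacsBnModel(db, net).fit(alpha=alpha)
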