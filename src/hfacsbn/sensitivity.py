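"""Relative risk-change sensitivity of lower HFACS factors to upper ones.

For an upper-level binary factor ``x_i`` and a lower-level factor state
``x_j`` ("occurrence"), the sensitivity is the truncated relative change

    S_ij = (P(x_j=1 | x_i=1) - P(x_j=1 | x_i=0)) / P(x_j=1 | x_i=0)

when the numerator is non-negative, and 0 otherwise.  The two conditional
probabilities come from evidence propagation in the fitted network: the
upper factor is asserted "yes" or "no" and the lower factor's posterior is
read off (observational conditioning, one evidence node at a time).  The
statistic therefore captures the relative increase in occurrence risk of a
downstream factor when an upstream factor is known present.

The full matrix mirrors the customary presentation: columns are upper
factors, rows are lower factors grouped by level with the multi-state
unsafe-act nodes expanded into subtype rows (SBE/DE/PE for error types,
RV/EV for violation types); cells where the column's level is not strictly
above the row's level are structurally empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .bayesnet import DiscreteBn
from .coding import SUBTYPE_LABELS

__all__ = [
    "SensitivityQuery",
    "UndefinedSensitivityError",
    "sensitivity_from_probs",
    "sensitivity",
    "sensitivity_matrix",
    "overall_sensitivity",
    "round_half_up",
]

logger = logging.getLogger(__name__)


class UndefinedSensitivityError(ZeroDivisionError):
    """Raised when the baseline probability P(lower | upper absent) is zero."""


@dataclass(frozen=True)
class SensitivityQuery:
    """One (upper factor, lower factor state) sensitivity request.

    ``lower_state`` is the state counting as occurrence: "yes" for binary
    factors, a named subtype (e.g. "skill") for a multi-state node.
    """

    upper: str
    lower: str
    lower_state: str = "yes"

    def validate(self, bn: DiscreteBn) -> None:
        net = bn.network
        up, lo = net.node(self.upper), net.node(self.lower)
        if set(up.states) != {"yes", "no"}:
            raise ValueError(f"upper factor {self.upper} must be binary yes/no")
        if up.level <= lo.level:
            raise ValueError(f"upper factor {self.upper} (level {up.level}) must be "
                             f"strictly above {self.lower} (level {lo.level})")
        if self.lower_state in ("no", "none"):
            raise ValueError(f"lower_state {self.lower_state!r} does not denote "
                             f"an occurrence")
        if self.lower_state not in lo.states:
            raise ValueError(f"state {self.lower_state!r} is not legal for "
                             f"node {self.lower}")


def sensitivity_from_probs(p1: float, p0: float) -> float:
    """Truncated relative change computed from the two posteriors.

    ``p1`` = P(lower occurs | upper present), ``p0`` = P(lower occurs |
    upper absent).  Returns ``(p1 - p0) / p0`` when p1 >= p0, else 0.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p0 <= 1.0):
        raise ValueError(f"posteriors must lie in [0, 1], got p1={p1}, p0={p0}")
    if p1 <= p0:
        return 0.0
    if p0 == 0.0:
        raise UndefinedSensitivityError(
            f"baseline probability is zero with p1={p1} > 0: relative "
            f"sensitivity undefined")
    return (p1 - p0) / p0


def sensitivity(bn: DiscreteBn, q: SensitivityQuery) -> float:
    """Eq.-style sensitivity of one lower factor state to one upper factor."""
    q.validate(bn)
    p1 = bn.query(q.lower, {q.upper: "yes"})[q.lower_state]
    p0 = bn.query(q.lower, {q.upper: "no"})[q.lower_state]
    return sensitivity_from_probs(p1, p0)


def _row_spec(bn: DiscreteBn) -> list[tuple[str, str, str, int]]:
    """(row label, node code, occurrence state, level) for every matrix row."""
    rows = []
    for node in sorted(bn.network.nodes, key=lambda n: -n.level):
        if node.level == max(n.level for n in bn.network.nodes):
            continue  # top level appears only as columns
        if set(node.states) == {"yes", "no"}:
            rows.append((node.code, node.code, "yes", node.level))
        else:
            for state in node.states:
                if state == "none":
                    continue
                label = SUBTYPE_LABELS.get((node.code, state),
                                           f"{node.code}={state}")
                rows.append((label, node.code, state, node.level))
    return rows


def _column_spec(bn: DiscreteBn) -> list[tuple[str, int]]:
    """(code, level) of every binary factor usable as an upper factor."""
    return [(n.code, n.level) for n in sorted(bn.network.nodes,
                                              key=lambda n: -n.level)
            if set(n.states) == {"yes", "no"} and n.level >= 2]


def sensitivity_matrix(bn: DiscreteBn) -> pd.DataFrame:
    """Sensitivity of every lower factor/state to every strictly-upper factor.

    Returns a DataFrame with one row per lower factor (subtype rows for the
    multi-state nodes) and one column per upper binary factor, full
    precision.  Structurally empty cells (upper level <= lower level) are
    NaN; cells whose baseline probability is zero are also NaN, with a
    logged warning.  Round only for presentation.
    """
    rows = _row_spec(bn)
    cols = _column_spec(bn)
    data = np.full((len(rows), len(cols)), np.nan)
    for i, (label, lower, state, lo_level) in enumerate(rows):
        for j, (upper, up_level) in enumerate(cols):
            if up_level <= lo_level:
                continue
            try:
                data[i, j] = sensitivity(
                    bn, SensitivityQuery(upper, lower, state))
            except UndefinedSensitivityError as exc:
                logger.warning("sensitivity %s -> %s=%s undefined: %s",
                               upper, lower, state, exc)
    df = pd.DataFrame(data, index=[r[0] for r in rows],
                      columns=[c[0] for c in cols])
    df.index.name = "lower"
    df.columns.name = "upper"
    return df


def overall_sensitivity(bn: DiscreteBn) -> pd.DataFrame:
    """Mean sensitivity per upper factor over error and violation subtypes.

    The errors score averages the three error-type rows (SBE, DE, PE), the
    violations score the two violation-type rows (RV, EV).  Values are
    already non-negative by the truncation, so this is the absolute mean.
    NaN cells are excluded with a warning; an all-NaN group scores NaN.
    """
    matrix = sensitivity_matrix(bn)
    err_rows = [r for r in ("SBE", "DE", "PE") if r in matrix.index]
    vio_rows = [r for r in ("RV", "EV") if r in matrix.index]
    out = []
    for upper in matrix.columns:
        scores = {}
        for name, group in (("errors", err_rows), ("violations", vio_rows)):
            vals = matrix.loc[group, upper].to_numpy(dtype=float)
            if np.isnan(vals).any() and not np.isnan(vals).all():
                logger.warning("excluding NA cells from %s score of %s",
                               name, upper)
            scores[name] = (float(np.nanmean(vals))
                            if not np.isnan(vals).all() else np.nan)
        out.append({"upper": upper, "errors": scores["errors"],
                    "violations": scores["violations"]})
    return pd.DataFrame(out).set_index("upper")


def round_half_up(value: float, digits: int = 2) -> float:
    """Decimal half-up rounding used when rendering tables."""
    if value != value:  # NaN
        return value
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
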