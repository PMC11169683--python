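"""Reading, validating and summarizing HFACS-coded incident case databases.

A case database is one fully observed categorical assignment per incident:
a CSV with columns ``incident_id``, optional ``phase`` and ``error_type``
metadata, and one column per network node (binary columns hold yes/no; the
error-type column holds skill|decision|perception|none; the violation-type
column holds routine|exceptional|none).  State strings are matched
case-insensitively and whitespace-trimmed; canonical forms are lowercase.

The descriptive summaries mirror the frequency analysis customarily reported
for incident-learning data: per-factor occurrence counts, per-level shares
of all factor occurrences, and the distribution of factors per incident.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping

import pandas as pd

from .taxonomy import HfacsNetwork, build_default_network

__all__ = [
    "IncidentRecord",
    "CaseDatabase",
    "FrequencySummary",
    "read_case_database",
    "write_case_database",
    "case_database_from_dataframe",
    "summarize_frequencies",
    "summarize_phases",
    "load_phase_error_table",
    "SUBTYPE_LABELS",
]

logger = logging.getLogger(__name__)

#: conventional abbreviations for the unsafe-act subtypes (states of the
#: multi-state nodes): skill-based error, decision error, perceptual error,
#: routine violation, exceptional violation.
SUBTYPE_LABELS = {
    ("ERR", "skill"): "SBE",
    ("ERR", "decision"): "DE",
    ("ERR", "perception"): "PE",
    ("VIO", "routine"): "RV",
    ("VIO", "exceptional"): "EV",
}

#: states that mean "this factor did not occur in the incident"
_ABSENT_STATES = {"no", "none"}


@dataclass(frozen=True)
class IncidentRecord:
    incident_id: str
    assignment: Mapping[str, str]
    phase: str | None = None
    error_type: str | None = None


@dataclass(frozen=True)
class CaseDatabase:
    network: HfacsNetwork
    records: tuple[IncidentRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        codes = self.network.codes
        rows = []
        for r in self.records:
            row = {"incident_id": r.incident_id, "phase": r.phase,
                   "error_type": r.error_type}
            row.update({c: r.assignment[c] for c in codes})
            rows.append(row)
        return pd.DataFrame(rows, columns=["incident_id", "phase", "error_type",
                                           *codes])


@dataclass(frozen=True)
class FrequencySummary:
    """Descriptive statistics of factor occurrences in a case database."""

    factor_counts: Mapping[str, int]          # keyed by code or subtype label
    level_counts: Mapping[int, int]
    level_proportions: Mapping[int, float] | None  # None when no occurrences
    per_incident_histogram: Mapping[int, int]
    total_occurrences: int
    total_incidents: int


def _normalize(value: str) -> str:
    return str(value).strip().lower()


def case_database_from_dataframe(df: pd.DataFrame,
                                 net: HfacsNetwork | None = None,
                                 missing_policy: Literal["strict", "drop-record"] = "strict",
                                 ) -> CaseDatabase:
    """Validate a DataFrame of coded incidents into a :class:`CaseDatabase`.

    ``missing_policy`` controls rows with an empty cell in a node column:
    ``"strict"`` (default) rejects the database, ``"drop-record"`` skips the
    row with a logged warning.  There is no missing-data learning: incident
    coding is assumed to yield complete assignments.
    """
    net = net or build_default_network()
    if "incident_id" not in df.columns:
        raise ValueError("missing required column 'incident_id'")
    for code in net.codes:
        if code not in df.columns:
            raise ValueError(f"missing required column '{code}'")

    records: list[IncidentRecord] = []
    seen: set[str] = set()
    for pos, row in enumerate(df.to_dict(orient="records")):
        incident_id = str(row["incident_id"]).strip()
        if incident_id in seen:
            raise ValueError(f"duplicate incident_id {incident_id!r}")
        seen.add(incident_id)

        assignment: dict[str, str] = {}
        dropped = False
        for code in net.codes:
            raw = row[code]
            if raw is None or (isinstance(raw, float) and pd.isna(raw)) \
                    or str(raw).strip() == "":
                if missing_policy == "drop-record":
                    logger.warning("dropping incident %s: empty cell in column %s",
                                   incident_id, code)
                    dropped = True
                    break
                raise ValueError(f"row {pos} (incident {incident_id!r}): empty cell "
                                 f"in node column {code}")
            state = _normalize(raw)
            if state not in net.states(code):
                raise ValueError(f"row {pos} (incident {incident_id!r}): illegal "
                                 f"state {raw!r} for node {code} "
                                 f"(legal: {list(net.states(code))})")
            assignment[code] = state
        if dropped:
            continue

        def _meta(col: str) -> str | None:
            v = row.get(col)
            if v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == "":
                return None
            return str(v).strip()

        records.append(IncidentRecord(incident_id=incident_id, assignment=assignment,
                                      phase=_meta("phase"), error_type=_meta("error_type")))
    return CaseDatabase(network=net, records=tuple(records))


def read_case_database(path, net: HfacsNetwork | None = None,
                       missing_policy: Literal["strict", "drop-record"] = "strict",
                       ) -> CaseDatabase:
    """Read a coded-incident CSV (UTF-8, comma-separated, header required)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return case_database_from_dataframe(df, net, missing_policy=missing_policy)


def write_case_database(db: CaseDatabase, path) -> None:
    df = db.to_dataframe()
    df = df.fillna("")
    df.to_csv(path, index=False)


def _occurrences(record: IncidentRecord, net: HfacsNetwork) -> list[tuple[str, int]]:
    """(factor key, level) pairs that occurred in one incident.

    A binary factor occurs when its state is "yes"; a multi-state unsafe-act
    node occurs once, under its subtype label, when its state is not "none".
    """
    out = []
    for node in net.nodes:
        state = record.assignment[node.code]
        if state in _ABSENT_STATES:
            continue
        if len(node.states) == 2:
            out.append((node.code, node.level))
        else:
            key = SUBTYPE_LABELS.get((node.code, state), f"{node.code}={state}")
            out.append((key, node.level))
    return out


def summarize_frequencies(db: CaseDatabase) -> FrequencySummary:
    """Factor-occurrence counts, level shares and the per-incident histogram."""
    if len(db) == 0:
        raise ValueError("cannot summarize an empty case database")

    factor_counts: dict[str, int] = {}
    level_counts: dict[int, int] = {lvl: 0 for lvl in
                                    sorted({n.level for n in db.network.nodes})}
    histogram: dict[int, int] = {}
    for record in db.records:
        occ = _occurrences(record, db.network)
        histogram[len(occ)] = histogram.get(len(occ), 0) + 1
        for key, level in occ:
            factor_counts[key] = factor_counts.get(key, 0) + 1
            level_counts[level] += 1

    total = sum(level_counts.values())
    proportions = ({lvl: c / total for lvl, c in level_counts.items()}
                   if total > 0 else None)
    return FrequencySummary(factor_counts=factor_counts, level_counts=level_counts,
                            level_proportions=proportions,
                            per_incident_histogram=histogram,
                            total_occurrences=total, total_incidents=len(db))


def summarize_phases(db: CaseDatabase) -> pd.DataFrame:
    """Incident counts by (phase, error_type), with ratios of all incidents.

    Records without phase/error-type metadata are pooled under
    ``"unspecified"``.  The grand total of ``count`` equals the number of
    records.
    """
    rows = [{"phase": r.phase or "unspecified",
             "error_type": r.error_type or "unspecified"} for r in db.records]
    df = pd.DataFrame(rows)
    out = (df.groupby(["phase", "error_type"], sort=True).size()
             .rename("count").reset_index())
    out["ratio"] = out["count"] / len(db)
    return out


def load_synthetic_cases() -> CaseDatabase:
    """The packaged frozen demonstration database of 81 *synthetic* incidents.

    Drawn once from the packaged ground-truth network
    (:func:`hfacsbn.simulate.default_truth`) with seed 42 and sized to the
    published study (81 incidents).  It is simulated data for demonstration
    and testing, not real incident codings.
    """
    with resources.files("hfacsbn.data").joinpath(
            "synthetic_cases_81.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    return case_database_from_dataframe(df)


def load_phase_error_table() -> pd.DataFrame:
    """The packaged phase/error-type incident-count table (81 incidents).

    Columns ``phase``, ``error_type``, ``count``: the published breakdown of
    the 81 RO-ILS radiotherapy incidents by treatment phase and error type,
    used as the default phase/error-type label distribution for simulation.
    """
    with resources.files("hfacsbn.data").joinpath(
            "phase_error_counts.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    df["count"] = df["count"].astype(int)
    return df
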