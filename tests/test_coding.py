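"""Case-database IO, validation, and descriptive summaries."""

import numpy as np
import pandas as pd
import pytest

from hfacsbn import (case_database_from_dataframe, load_phase_error_table,
                     load_synthetic_cases, read_case_database,
                     summarize_frequencies, summarize_phases,
                     write_case_database)

from conftest import toy_dataframe


class TestReading:
    def test_csv_round_trip(self, default_net, toy_db, tmp_path):
        path = tmp_path / "cases.csv"
        write_case_database(toy_db, path)
        again = read_case_database(path, default_net)
        assert again == toy_db

    def test_states_normalized_case_and_whitespace(self, default_net):
        df = toy_dataframe(default_net, [{"ERR": "skill"}])
        df.loc[0, "ERR"] = " Skill "
        df.loc[0, "CO"] = "YES"
        db = case_database_from_dataframe(df, default_net)
        assert db.records[0].assignment["ERR"] == "skill"
        assert db.records[0].assignment["CO"] == "yes"

    def test_missing_node_column_named(self, default_net):
        df = toy_dataframe(default_net, [{}]).drop(columns=["PF"])
        with pytest.raises(ValueError, match="PF"):
            case_database_from_dataframe(df, default_net)

    def test_illegal_state_names_row_and_value(self, default_net):
        df = toy_dataframe(default_net, [{}, {}])
        df.loc[1, "ERR"] = "slip"
        with pytest.raises(ValueError, match="slip"):
            case_database_from_dataframe(df, default_net)

    def test_duplicate_incident_id_rejected(self, default_net):
        df = toy_dataframe(default_net, [{}, {}])
        df["incident_id"] = ["x", "x"]
        with pytest.raises(ValueError, match="duplicate"):
            case_database_from_dataframe(df, default_net)

    def test_empty_cell_strict_vs_drop(self, default_net):
        df = toy_dataframe(default_net, [{}, {}])
        df.loc[0, "IS"] = ""
        with pytest.raises(ValueError, match="IS"):
            case_database_from_dataframe(df, default_net)
        db = case_database_from_dataframe(df, default_net,
                                          missing_policy="drop-record")
        assert len(db) == 1


class TestFrequencies:
    def test_hand_counted_two_incident_example(self, toy_db):
        # incident 1: ERR=skill only; incident 2: VIO=routine, CO=yes
        s = summarize_frequencies(toy_db)
        assert s.total_occurrences == 3
        assert s.per_incident_histogram == {1: 1, 2: 1}
        assert s.level_proportions[1] == pytest.approx(2 / 3)
        assert s.factor_counts == {"SBE": 1, "RV": 1, "CO": 1}

    def test_all_absent_database_has_undefined_proportions(self, default_net):
        df = toy_dataframe(default_net, [{}, {}])
        s = summarize_frequencies(case_database_from_dataframe(df, default_net))
        assert s.total_occurrences == 0
        assert s.level_proportions is None

    def test_saturated_incident_counts_twelve_factors(self, default_net):
        full = {c: "yes" for c in default_net.codes}
        full["ERR"] = "skill"
        full["VIO"] = "routine"
        df = toy_dataframe(default_net, [full])
        s = summarize_frequencies(case_database_from_dataframe(df, default_net))
        assert s.per_incident_histogram == {12: 1}

    def test_totals_invariant_under_record_order(self, default_net):
        rng = np.random.default_rng(5)
        assignments = []
        for _ in range(12):
            a = {}
            for node in default_net.nodes:
                a[node.code] = str(rng.choice(node.states))
            assignments.append(a)
        df = toy_dataframe(default_net, assignments)
        base = summarize_frequencies(case_database_from_dataframe(df, default_net))
        shuffled = df.sample(frac=1, random_state=7)
        perm = summarize_frequencies(
            case_database_from_dataframe(shuffled, default_net))
        assert base.factor_counts == perm.factor_counts
        assert base.per_incident_histogram == perm.per_incident_histogram
        # per-level totals partition the grand total
        assert sum(base.level_counts.values()) == base.total_occurrences
        assert sum(base.factor_counts.values()) == base.total_occurrences

    def test_empty_database_rejected(self, default_net):
        df = toy_dataframe(default_net, [])
        db = case_database_from_dataframe(df, default_net)
        with pytest.raises(ValueError, match="empty"):
            summarize_frequencies(db)


class TestPhaseSummary:
    def test_grouping_and_ratios(self, default_net):
        df = toy_dataframe(default_net, [{}, {}, {}],
                           phases=["treatment planning", "treatment planning",
                                   "simulation"],
                           error_types=["wrong data transfer or setting"] * 2
                                       + ["machine breakdown"])
        table = summarize_phases(case_database_from_dataframe(df, default_net))
        assert table["count"].sum() == 3
        row = table[(table.phase == "treatment planning")]
        assert row["count"].iloc[0] == 2
        assert row["ratio"].iloc[0] == pytest.approx(2 / 3)

    def test_missing_metadata_pooled_as_unspecified(self, default_net):
        df = toy_dataframe(default_net, [{}, {}])
        table = summarize_phases(case_database_from_dataframe(df, default_net))
        assert list(table.phase.unique()) == ["unspecified"]
        assert table["count"].sum() == 2


class TestPackagedData:
    def test_phase_error_table_totals(self):
        table = load_phase_error_table()
        assert len(table) == 16
        assert table["count"].sum() == 81
        wrong = table[table.error_type == "wrong data transfer or setting"]
        assert wrong["phase"].iloc[0] == "treatment planning"
        assert wrong["count"].iloc[0] == 17

    def test_frozen_synthetic_database_loads_and_matches_regeneration(self):
        from hfacsbn import default_truth, sample_incidents
        db = load_synthetic_cases()
        assert len(db) == 81
        regen = sample_incidents(default_truth(), n=81, seed=42)
        assert regen == db
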