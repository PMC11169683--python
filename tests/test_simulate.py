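"""Ancestral sampling, the packaged ground truth, and parameter recovery."""

import io

import numpy as np
import pytest

from hfacsbn import (GroundTruthSpec, default_truth, fit_cpts,
                     recovery_experiment, sample_incidents,
                     write_case_database)

from conftest import make_cpt, uniform_bn


class TestGroundTruth:
    def test_marginals_match_published_prior_bands(self):
        """Exact marginals of the packaged truth vs the five published priors."""
        truth = default_truth()
        bands = {("ERR", "skill"): 0.375, ("CO", "yes"): 0.496,
                 ("PF", "yes"): 0.598, ("IS", "yes"): 0.576,
                 ("OC", "yes"): 0.253}
        for (code, state), target in bands.items():
            marginal = truth.bn.query(code)[state]
            assert abs(marginal - target) <= 0.05, (code, state, marginal)

    def test_routine_violations_above_exceptional(self):
        dist = default_truth().bn.query("VIO")
        assert dist["routine"] > dist["exceptional"]

    def test_cpts_normalized(self):
        truth = default_truth()
        for cpt in truth.bn.cpts.values():
            for vec in cpt.table.values():
                assert sum(vec) == pytest.approx(1.0, abs=1e-12)
                assert min(vec) >= 0.0

    def test_invalid_incident_count_rejected(self):
        with pytest.raises(ValueError, match="n_incidents"):
            GroundTruthSpec(bn=default_truth().bn, n_incidents=0)


class TestSampling:
    def test_seed_determinism_byte_identical_csv(self):
        truth = default_truth()
        outs = []
        for _ in range(2):
            db = sample_incidents(truth, n=40, seed=7)
            buf = io.StringIO()
            write_case_database(db, buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_different_seeds_differ(self):
        truth = default_truth()
        assert sample_incidents(truth, n=40, seed=1) != \
            sample_incidents(truth, n=40, seed=2)

    def test_degenerate_cpts_force_every_record(self, default_net):
        cpts = {}
        for node in default_net.nodes:
            rows = {cfg: tuple(1.0 if i == 0 else 0.0
                               for i in range(len(node.states)))
                    for cfg in uniform_bn(default_net).cpts[node.code].configurations()}
            cpts[node.code] = make_cpt(default_net, node.code, rows)
        spec = GroundTruthSpec(bn=type(default_truth().bn)(default_net, cpts))
        db = sample_incidents(spec, n=5, seed=0)
        forced = {c: default_net.states(c)[0] for c in default_net.codes}
        for record in db.records:
            assert dict(record.assignment) == forced

    def test_empirical_frequency_concentrates_on_root_prior(self):
        # P(RM=yes)=0.2, n=10,000: 3-sigma binomial band is +/-0.012
        truth = default_truth()
        db = sample_incidents(truth, n=10_000, seed=7)
        freq = np.mean([r.assignment["RM"] == "yes" for r in db.records])
        assert abs(freq - 0.2) <= 0.012

    def test_sampling_matches_exact_marginals_of_truth(self):
        # every node state, 3-sigma binomial tolerance at n=10,000
        truth = default_truth()
        db = sample_incidents(truth, n=10_000, seed=13)
        n = len(db)
        for code in truth.bn.network.codes:
            exact = truth.bn.query(code)
            for state in truth.bn.network.states(code):
                p = exact[state]
                freq = np.mean([r.assignment[code] == state for r in db.records])
                tol = 3 * np.sqrt(p * (1 - p) / n)
                assert abs(freq - p) <= max(tol, 1e-3), (code, state)

    def test_labels_drawn_from_packaged_phase_table(self):
        truth = default_truth()
        db = sample_incidents(truth, n=300, seed=5)
        legal = set(zip(truth.label_weights["phase"],
                        truth.label_weights["error_type"]))
        assert {(r.phase, r.error_type) for r in db.records} <= legal

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            sample_incidents(default_truth(), n=0, seed=1)


class TestRecovery:
    def test_report_invariants(self):
        report = recovery_experiment(default_truth(), n=500, alpha=1.0, seed=3)
        assert ((report.rows["tv"] >= 0) & (report.rows["tv"] <= 1)).all()
        assert (report.rows["n_obs"] >= 0).all()
        assert report.rows["n_obs"].groupby(report.rows["node"]).sum().eq(500).all()

    def test_well_observed_rows_recovered_within_concentration_bound(self):
        # rows with >= 50 observations: 3-sigma binomial bound at the
        # minimum qualifying count is 3 * 0.5 / sqrt(50) ~= 0.21
        report = recovery_experiment(default_truth(), n=5000, alpha=1.0, seed=11)
        assert report.headline_max_tv <= 0.25

    def test_mean_recovery_error_decreases_with_n(self):
        truth = default_truth()
        violations = 0
        for seed in (101, 102, 103, 104, 105):
            small = recovery_experiment(truth, n=200, alpha=1.0, seed=seed)
            large = recovery_experiment(truth, n=5000, alpha=1.0, seed=seed)
            violations += large.mean_tv > small.mean_tv
        assert violations <= 1

    def test_uniform_truth_recovered(self, default_net):
        spec = GroundTruthSpec(bn=uniform_bn(default_net))
        report = recovery_experiment(spec, n=5000, alpha=1.0, seed=2)
        well = report.rows[report.rows["n_obs"] >= 400]
        assert (well["tv"] <= 0.05).all()

    def test_refit_consistency_with_fit_cpts(self):
        # the experiment's refit equals fitting the same sample directly
        truth = default_truth()
        db = sample_incidents(truth, n=300, seed=21)
        direct = fit_cpts(db, truth.bn.network, alpha=1.0)
        report = recovery_experiment(truth, n=300, alpha=1.0, seed=21)
        row = report.rows[(report.rows.node == "RM")].iloc[0]
        expect = 0.5 * sum(abs(a - b) for a, b in
                           zip(truth.bn.cpts["RM"].table[()],
                               direct.cpts["RM"].table[()]))
        assert row["tv"] == pytest.approx(expect, abs=1e-12)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            recovery_experiment(default_truth(), n=0)
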