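"""The synthetic-data generator: design structure, determinism, noise model."""

import numpy as np
import pytest

from solvent_eval.annotation import PROTON_MASS, annotate_table
from solvent_eval.preprocess import apply_qc_filters, compute_dilution_r, compute_qc_rsd
from solvent_eval.synthetic import (
    SimulationConfig,
    generate_compound_db,
    generate_experiment,
    max_compounds_at_spacing,
    reactor_a_config,
    reactor_b_config,
    truth_report,
)


class TestCompoundDb:
    def test_requested_counts_and_spacing(self):
        compounds, pathways = generate_compound_db(50, 5, seed=1)
        assert len(compounds) == 50 and len(pathways) == 5
        masses = np.sort(compounds.masses.to_numpy())
        rel = np.diff(masses) / masses[:-1]
        assert (rel > 25e-6).all()
        covered = set().union(*[pathways.members(p) for p in pathways.pathway_ids])
        assert covered == set(compounds.compound_ids)

    def test_deterministic_under_seed(self):
        a = generate_compound_db(10, 2, seed=7)
        b = generate_compound_db(10, 2, seed=7)
        assert a[0].table.equals(b[0].table)
        assert a[1].table.equals(b[1].table)

    def test_pigeonhole_bound_rejects_impossible_count(self):
        cap = max_compounds_at_spacing()
        assert cap < 10**6
        with pytest.raises(ValueError, match="mass range"):
            generate_compound_db(10**6, 1, seed=0)


class TestDesignStructure:
    def test_reactor_a_sample_counts(self, small_experiment):
        meta = small_experiment["metadata"]
        assert len(meta.biological) == 60  # 5 solvents x 4 stages x 3 replicates
        assert len(meta.dilution_qc) == 46  # printed per-level injection counts
        assert len(meta.pooled_qc) == 13  # one before run 1, then every 5 runs

    def test_reactor_b_sample_counts(self):
        cfg = reactor_b_config(seed=2, n_true_compounds=10, n_noise_features=10)
        db, _ = generate_compound_db(10, 2, seed=2)
        _, meta, _ = generate_experiment(cfg, db)
        assert len(meta.biological) == 36  # 3 solvents x 2 stages x 2 compartments x 3

    def test_run_order_unique_and_qc_interleaved(self, small_experiment):
        meta = small_experiment["metadata"].table
        assert meta["run_order"].is_unique
        bio_orders = np.sort(meta.loc[meta["role"] == "biological", "run_order"].to_numpy())
        qc_orders = np.sort(meta.loc[meta["role"] == "pooled_qc", "run_order"].to_numpy())
        assert qc_orders[0] < bio_orders[0]  # one QC before the first sample run

    def test_determinism_end_to_end(self):
        cfg = reactor_a_config(seed=9, n_true_compounds=8, n_noise_features=8)
        db, _ = generate_compound_db(8, 2, seed=9)
        t1, m1, g1 = generate_experiment(cfg, db)
        t2, m2, g2 = generate_experiment(cfg, db)
        for mode in t1:
            assert t1[mode].intensities.equals(t2[mode].intensities)
        assert m1.table.equals(m2.table)
        assert g1.frame("positive").equals(g2.frame("positive"))


class TestIntensityModel:
    def test_noiseless_limit_passes_both_filters(self):
        cfg = reactor_a_config(seed=4, n_true_compounds=10, n_noise_features=10,
                               sigma_analytical=0.0, sigma_biological=0.0,
                               frac_contaminant=0.0, frac_unstable=0.0,
                               detection_limit=0.0)
        db, _ = generate_compound_db(10, 2, seed=4)
        tables, meta, _ = generate_experiment(cfg, db)
        table = tables["positive"]
        assert compute_qc_rsd(table, meta).max() < 1e-9
        assert compute_dilution_r(table, meta).min() > 1 - 1e-9
        _, report = apply_qc_filters(table, meta)
        assert report.n_retained == report.n_input

    def test_mz_follows_adduct_rule(self, small_experiment):
        db = small_experiment["compound_db"]
        truth = small_experiment["truth"]
        for mode, sign in [("positive", 1.0), ("negative", -1.0)]:
            table = small_experiment["tables"][mode]
            tf = truth.frame(mode)
            cmpd = tf[tf["compound_id"] != ""]
            expected = db.masses.loc[cmpd["compound_id"]].to_numpy() + sign * PROTON_MASS
            np.testing.assert_allclose(
                table.features.loc[cmpd.index, "mz"].to_numpy(), expected, atol=1e-9)

    def test_noise_features_never_annotated(self, small_experiment):
        db = small_experiment["compound_db"]
        truth = small_experiment["truth"].frame("positive")
        results = annotate_table(small_experiment["tables"]["positive"], db)
        for res in results:
            row = truth.loc[res.feature_id]
            if row["compound_id"]:
                assert [m.compound_id for m in res.matches] == [row["compound_id"]]
            else:
                assert res.matches == []

    def test_solvent_efficiency_orders_mean_intensity(self, small_experiment):
        cfg = small_experiment["config"]
        meta = small_experiment["metadata"]
        table = small_experiment["tables"]["positive"]
        truth = small_experiment["truth"].frame("positive")
        genuine = truth.index[(truth["compound_id"] != "") & ~truth["is_contaminant"]]
        bio = meta.biological
        means = {}
        for s in cfg.solvents:
            ids = list(bio.loc[bio["solvent"] == s, "sample_id"])
            x = table.intensities.loc[genuine, ids].to_numpy()
            means[s] = np.log(x[x > 0]).mean()
        eff_order = sorted(cfg.solvents, key=cfg.solvents.get)
        mean_order = sorted(means, key=means.get)
        assert eff_order == mean_order

    def test_contaminants_flat_across_dilution(self, small_experiment):
        meta = small_experiment["metadata"]
        table = small_experiment["tables"]["positive"]
        truth = small_experiment["truth"].frame("positive")
        r = compute_dilution_r(table, meta)
        contaminants = truth.index[truth["is_contaminant"]]
        clean = truth.index[~truth["is_contaminant"] & ~truth["is_unstable"]
                            & (truth["baseline_log"] > np.log(5000))]
        if len(contaminants):
            # none reaches the linearity threshold (NaN = undefined, also fails)
            assert not (r[contaminants] >= 0.8).any()
        assert (r[clean] > 0.9).mean() > 0.95


class TestTruthReport:
    def test_noiseless_specificity_is_one(self):
        cfg = reactor_a_config(seed=6, n_true_compounds=10, n_noise_features=10,
                               sigma_analytical=0.0, sigma_biological=0.0,
                               frac_contaminant=0.0, frac_unstable=0.0,
                               detection_limit=0.0)
        db, _ = generate_compound_db(10, 2, seed=6)
        tables, meta, truth = generate_experiment(cfg, db)
        _, report = apply_qc_filters(tables["positive"], meta)
        out = truth_report(truth, "positive", qc_report=report)
        assert out["dilution_filter"]["specificity"] == 1.0
        assert out["rsd_filter"]["specificity"] == 1.0

    def test_no_planted_differentials_reported_as_none(self):
        cfg = reactor_a_config(seed=8, n_true_compounds=6, n_noise_features=6,
                               frac_differential=0.0, detection_limit=0.0)
        db, _ = generate_compound_db(6, 2, seed=8)
        tables, meta, truth = generate_experiment(cfg, db)
        from solvent_eval.preprocess import log_transform
        from solvent_eval.diffabund import differential_features
        bio = tables["positive"].subset_samples(list(meta.biological["sample_id"]))
        logged, _ = log_transform(bio)
        res = differential_features(logged, meta, "stage")
        out = truth_report(truth, "positive", diff_result=res)
        assert out["differential"]["recall"] is None

    def test_mismatched_universe_rejected(self, small_experiment):
        meta = small_experiment["metadata"]
        table = small_experiment["tables"]["positive"]
        _, report = apply_qc_filters(table, meta)
        report.per_feature = report.per_feature.iloc[:5]
        with pytest.raises(ValueError, match="different features"):
            truth_report(small_experiment["truth"], "positive", qc_report=report)
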