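"""QC filtration, internal-standard normalisation and log transform."""

import numpy as np
import pandas as pd
import pytest

from solvent_eval.core_io import FeatureTable
from solvent_eval.preprocess import (
    apply_qc_filters,
    compute_dilution_r,
    compute_qc_rsd,
    log_transform,
    normalize_to_internal_standards,
)

from conftest import make_metadata, make_table

SAMPLES = ["q0", "q1", "q2", "d1.0", "d0.5", "d0.0", "b0", "b1", "b2", "b3"]


def qc_table(rows):
    """Feature table over the qc_metadata fixture's 10 samples."""
    return make_table(rows, SAMPLES)


class TestQcRsd:
    @pytest.mark.parametrize(
        "qc_values, expected",
        [((100.0, 100.0, 100.0), 0.0), ((90.0, 100.0, 110.0), 10.0)],
    )
    def test_rsd_formula(self, qc_metadata, qc_values, expected):
        table = qc_table({"F1": list(qc_values) + [1.0] * 7})
        rsd = compute_qc_rsd(table, qc_metadata)
        assert rsd["F1"] == pytest.approx(expected)

    def test_zero_mean_gives_infinite_rsd(self, qc_metadata):
        table = qc_table({"F1": [0.0, 0.0, 0.0] + [1.0] * 7})
        assert np.isinf(compute_qc_rsd(table, qc_metadata)["F1"])

    def test_requires_two_pooled_qcs(self):
        meta = make_metadata([
            dict(sample_id="q0", role="pooled_qc", solvent="n/a", stage="n/a",
                 compartment="n/a", replicate=0, run_order=1, dilution_fraction=np.nan),
            dict(sample_id="b0", role="biological", solvent="M", stage="S1",
                 compartment="n/a", replicate=1, run_order=2, dilution_fraction=np.nan),
        ])
        table = make_table({"F1": [1.0, 1.0]}, ["q0", "b0"])
        with pytest.raises(ValueError, match="pooled-QC"):
            compute_qc_rsd(table, meta)


class TestDilutionR:
    @pytest.mark.parametrize(
        "dilution_values, expected",
        [((10.0, 5.0, 0.0), 1.0), ((0.0, 5.0, 10.0), -1.0)],
    )
    def test_exact_linearity(self, qc_metadata, dilution_values, expected):
        table = qc_table({"F1": [1.0] * 3 + list(dilution_values) + [1.0] * 4})
        r = compute_dilution_r(table, qc_metadata)
        assert r["F1"] == pytest.approx(expected)

    def test_constant_feature_undefined(self, qc_metadata):
        table = qc_table({"F1": [1.0] * 3 + [5.0, 5.0, 5.0] + [1.0] * 4})
        assert np.isnan(compute_dilution_r(table, qc_metadata)["F1"])


class TestApplyFilters:
    def test_joint_rule_on_five_feature_toy(self, qc_metadata):
        # RSDs ~ (0, 10, 35, 5, 5); r = (1, 1, 1, 0.5, 1) -> keep F1, F2, F5
        rows = {
            "F1": [100, 100, 100, 10, 5, 0, 1, 1, 1, 1],
            "F2": [90, 100, 110, 10, 5, 0, 1, 1, 1, 1],
            "F3": [65, 100, 135, 10, 5, 0, 1, 1, 1, 1],
            "F4": [95, 100, 105, 10, 0, 8, 1, 1, 1, 1],
            "F5": [95, 100, 105, 10, 5, 0, 1, 1, 1, 1],
        }
        table = qc_table(rows)
        filtered, report = apply_qc_filters(table, qc_metadata)
        assert list(filtered.intensities.index) == ["F1", "F2", "F5"]
        assert report.n_retained == 3
        # QC/dilution columns dropped from the output table
        assert filtered.sample_ids == ["b0", "b1", "b2", "b3"]

    def test_vacuous_thresholds_keep_defined_features(self, qc_metadata):
        rows = {
            "F1": [65, 100, 135, 10, 5, 0, 1, 1, 1, 1],   # high RSD
            "F2": [95, 100, 105, 0, 5, 10, 1, 1, 1, 1],   # anti-linear
        }
        table = qc_table(rows)
        _, report = apply_qc_filters(table, qc_metadata, rsd_max=np.inf, r_min=-1.0)
        assert report.n_retained == 2

    def test_filters_idempotent_and_monotone(self, qc_metadata):
        rng = np.random.default_rng(3)
        rows = {f"F{i}": rng.uniform(1, 100, 10) for i in range(20)}
        table = qc_table(rows)
        retained = {}
        for r_min in (0.0, 0.5, 0.9):
            _, rep = apply_qc_filters(table, qc_metadata, r_min=r_min)
            retained[r_min] = rep.n_retained
        assert retained[0.0] >= retained[0.5] >= retained[0.9]
        filt, rep1 = apply_qc_filters(table, qc_metadata)
        assert rep1.per_feature.loc[filt.intensities.index, "retained"].all()


class TestNormalization:
    def _bio_meta(self, n=3):
        return make_metadata([
            dict(sample_id=f"s{i}", role="biological", solvent="M", stage="S1",
                 compartment="n/a", replicate=i + 1, run_order=i + 1,
                 dilution_fraction=np.nan)
            for i in range(n)
        ])

    def test_worked_example_scales(self):
        # IS medians 2 and 8; sample 2 carries double spike -> s = (1, 2, 1)
        meta = self._bio_meta()
        table = make_table({"IS1": [2, 4, 2], "IS2": [8, 16, 8], "F1": [10, 10, 10]},
                           ["s0", "s1", "s2"])
        norm = normalize_to_internal_standards(table, meta, ["IS1", "IS2"])
        np.testing.assert_allclose(norm.intensities.loc["F1"], [10.0, 5.0, 10.0])

    def test_constant_standards_identity(self):
        meta = self._bio_meta()
        table = make_table({"IS1": [3, 3, 3], "F1": [7, 8, 9]}, ["s0", "s1", "s2"])
        norm = normalize_to_internal_standards(table, meta, ["IS1"])
        np.testing.assert_allclose(norm.intensities.to_numpy(),
                                   table.intensities.to_numpy())

    def test_per_sample_scaling_removed_exactly(self):
        meta = self._bio_meta()
        rng = np.random.default_rng(0)
        base = {f"F{i}": rng.uniform(1, 100, 3) for i in range(5)}
        base["IS1"] = np.array([10.0, 10.0, 10.0])
        table = make_table(base, ["s0", "s1", "s2"])
        scaled = table.intensities.copy()
        scaled["s1"] *= 3.7  # arbitrary per-sample multiplicative factor
        table2 = FeatureTable("positive", table.features, scaled)
        n1 = normalize_to_internal_standards(table, meta, ["IS1"])
        n2 = normalize_to_internal_standards(table2, meta, ["IS1"])
        np.testing.assert_allclose(n1.intensities.to_numpy(),
                                   n2.intensities.to_numpy(), rtol=1e-12)

    def test_zero_standard_reports_sample(self):
        meta = self._bio_meta()
        table = make_table({"IS1": [1, 0, 1], "F1": [1, 1, 1]}, ["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="s1"):
            normalize_to_internal_standards(table, meta, ["IS1"])


class TestLogTransform:
    def test_half_minimum_zero_replacement(self):
        table = make_table({"F1": [0.0, 2.0, 4.0]}, ["s0", "s1", "s2"])
        logged, n_dropped = log_transform(table)
        np.testing.assert_allclose(logged.loc["F1"],
                                   [0.0, np.log(2.0), np.log(4.0)])
        assert n_dropped == 0

    def test_all_zero_feature_dropped_and_counted(self):
        table = make_table({"F1": [0.0, 0.0], "F2": [1.0, np.e]}, ["s0", "s1"])
        logged, n_dropped = log_transform(table)
        assert n_dropped == 1
        np.testing.assert_allclose(logged.loc["F2"], [0.0, 1.0])
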