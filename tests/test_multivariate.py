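"""Bray-Curtis, PCoA and the multi-factor PERMANOVA engine."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
import skbio.stats.distance as sk_distance

from solvent_eval.multivariate import (
    DesignSpec,
    bray_curtis,
    pairwise_posthoc,
    pcoa,
    permanova,
    reactor_a_design,
)

from conftest import make_table


def euclidean_dm(points, ids=None):
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


def one_way_meta(labels):
    ids = [f"s{i}" for i in range(len(labels))]
    return pd.DataFrame({"sample_id": ids, "g": labels}, index=ids)


def brute_force_f(d, labels):
    """Distance-based one-way pseudo-F from within-group squared distances."""
    n = len(labels)
    k = len(set(labels))
    ss_total = (d**2).sum() / (2 * n)
    ss_within = 0.0
    for g in set(labels):
        idx = [i for i, l in enumerate(labels) if l == g]
        ss_within += (d[np.ix_(idx, idx)] ** 2).sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    return (ss_between / (k - 1)) / (ss_within / (n - k))


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        t = make_table({"F1": [2.0, 2.0], "F2": [5.0, 5.0]}, ["a", "b"])
        assert bray_curtis(t)["a", "b"] == pytest.approx(0.0)

    def test_disjoint_support_distance_one(self):
        t = make_table({"F1": [4.0, 0.0], "F2": [0.0, 9.0]}, ["a", "b"])
        assert bray_curtis(t)["a", "b"] == pytest.approx(1.0)

    def test_sqrt_transform_worked_example(self):
        t = make_table({"F1": [1.0, 4.0], "F2": [1.0, 4.0]}, ["a", "b"])
        assert bray_curtis(t)["a", "b"] == pytest.approx(1.0 / 3.0)

    def test_all_zero_pair_defined_as_zero(self):
        t = make_table({"F1": [0.0, 0.0, 1.0]}, ["a", "b", "c"])
        assert bray_curtis(t)["a", "b"] == 0.0


class TestPcoa:
    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(2)
        points = rng.normal(size=(9, 3))
        res = pcoa(euclidean_dm(points))
        rec = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(rec, squareform(pdist(points)), atol=1e-8)

    def test_collinear_points_one_positive_axis(self):
        d = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float),
                           ids=["a", "b", "c"])
        res = pcoa(d)
        assert res.coordinates.shape[1] == 1
        spacing = np.abs(np.diff(np.sort(res.coordinates["PC1"])))
        np.testing.assert_allclose(spacing, [1.0, 1.0], atol=1e-10)

    def test_duplicate_samples_identical_coordinates(self):
        points = np.array([[0.0, 0], [0, 0], [3, 4], [1, 1]])
        res = pcoa(euclidean_dm(points))
        np.testing.assert_allclose(res.coordinates.iloc[0], res.coordinates.iloc[1],
                                   atol=1e-10)

    def test_eigenvalue_sum_matches_trace_with_negatives_reported(self):
        t = make_table({f"F{i}": np.random.default_rng(i).uniform(0, 5, 6)
                        for i in range(8)},
                       [f"s{i}" for i in range(6)])
        dm = bray_curtis(t)
        res = pcoa(dm)
        from solvent_eval.multivariate import gower_center
        trace = np.trace(gower_center(np.asarray(dm.data) ** 2))
        assert res.eigenvalues.sum() == pytest.approx(trace, abs=1e-10)

    def test_matches_skbio_ordination(self):
        rng = np.random.default_rng(4)
        points = rng.normal(size=(8, 4))
        dm = euclidean_dm(points)
        ours = pcoa(dm)
        theirs = __import__("skbio").stats.ordination.pcoa(dm, method="eigh")
        n_axes = ours.coordinates.shape[1]
        np.testing.assert_allclose(
            np.abs(ours.coordinates.to_numpy()),
            np.abs(theirs.samples.to_numpy()[:, :n_axes]), atol=1e-8)


class TestPermanovaStructure:
    def test_reactor_a_df_partition(self, small_experiment):
        meta = small_experiment["metadata"]
        table = small_experiment["tables"]["positive"].subset_samples(
            list(meta.biological["sample_id"]))
        res = permanova(bray_curtis(table), meta, reactor_a_design(), n_perm=9, seed=0)
        df = res.table.set_index("term")["df"]
        assert df["solvent"] == 4 and df["stage"] == 3
        assert df["solvent x stage"] == 12
        assert df["replicate(stage)"] == 8 and df["Residuals"] == 32

    def test_ss_additivity_on_balanced_design(self, small_experiment):
        meta = small_experiment["metadata"]
        table = small_experiment["tables"]["negative"].subset_samples(
            list(meta.biological["sample_id"]))
        res = permanova(bray_curtis(table), meta, reactor_a_design(), n_perm=9, seed=0)
        total = res.extras["ss_total"]
        assert abs(total - res.table["ss"].sum()) / total < 1e-10

    def test_unbalanced_design_rejected(self):
        labels = ["x", "x", "x", "y", "y"]
        d = euclidean_dm(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError, match="unbalanced"):
            permanova(d, one_way_meta(labels), DesignSpec(fixed_terms=[("g",)]))

    def test_undeclared_factor_rejected(self):
        d = euclidean_dm(np.random.default_rng(0).normal(size=(4, 2)))
        meta = one_way_meta(["x", "x", "y", "y"])
        with pytest.raises(ValueError, match="nope"):
            permanova(d, meta, DesignSpec(fixed_terms=[("nope",)]))


class TestPermanovaInference:
    def test_exhaustive_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for trial in range(3):
            x = rng.normal(size=(6, 3))
            x[:3] += trial  # varying separation
            d = squareform(pdist(x))
            labels = ["x"] * 3 + ["y"] * 3
            res = permanova(DistanceMatrix(d, ids=[f"s{i}" for i in range(6)]),
                            one_way_meta(labels), DesignSpec(fixed_terms=[("g",)]),
                            n_perm="exhaustive")
            f_obs = brute_force_f(d, labels)
            fs = [brute_force_f(d, p) for p in itertools.permutations(labels)]
            p_oracle = np.mean([f >= f_obs - 1e-12 for f in fs])
            row = res.table.set_index("term").loc["g"]
            assert row["pseudo_f"] == pytest.approx(f_obs)
            assert row["p_value"] == pytest.approx(p_oracle)

    def test_matches_skbio_statistic_one_way(self):
        rng = np.random.default_rng(12)
        d = euclidean_dm(rng.normal(size=(12, 4)))
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        meta = one_way_meta(labels)
        ours = permanova(d, meta, DesignSpec(fixed_terms=[("g",)]), n_perm=99, seed=0)
        theirs = sk_distance.permanova(d, meta, column="g", permutations=99)
        assert ours.table.set_index("term").loc["g", "pseudo_f"] == pytest.approx(
            theirs["test statistic"], rel=1e-10)

    def test_p_values_bounded_and_reproducible(self, small_experiment):
        meta = small_experiment["metadata"]
        table = small_experiment["tables"]["positive"].subset_samples(
            list(meta.biological["sample_id"]))
        d = bray_curtis(table)
        r1 = permanova(d, meta, reactor_a_design(), n_perm=49, seed=5)
        r2 = permanova(d, meta, reactor_a_design(), n_perm=49, seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        pvals = r1.table["p_value"].dropna()
        assert ((pvals >= 1 / 50) & (pvals <= 1)).all()

    def test_strong_solvent_effect_detected(self, small_experiment):
        meta = small_experiment["metadata"]
        table = small_experiment["tables"]["positive"].subset_samples(
            list(meta.biological["sample_id"]))
        res = permanova(bray_curtis(table), meta, reactor_a_design(),
                        n_perm=199, seed=3, test_terms=["solvent"])
        assert res.table.set_index("term").loc["solvent", "p_value"] == 1 / 200


class TestPosthoc:
    def test_three_level_factor_yields_three_rows(self):
        rng = np.random.default_rng(9)
        x = np.vstack([rng.normal(loc=i * 5, size=(4, 3)) for i in range(3)])
        d = euclidean_dm(x)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        out = pairwise_posthoc(d, one_way_meta(labels), "g", n_perm=99, seed=0)
        assert len(out) == 3
        assert set(zip(out["level_a"], out["level_b"])) == {
            ("a", "b"), ("a", "c"), ("b", "c")}

    def test_separated_clouds_reach_floor_p(self):
        rng = np.random.default_rng(10)
        x = np.vstack([rng.normal(0, 0.1, size=(4, 2)),
                       rng.normal(50, 0.1, size=(4, 2))])
        d = euclidean_dm(x)
        out = pairwise_posthoc(d, one_way_meta(["a"] * 4 + ["b"] * 4), "g",
                               n_perm=199, seed=0)
        assert out.loc[0, "p_perm"] == pytest.approx(1 / 200)
        # C(8,4)=70 < 100 distinct relabellings triggers the Monte-Carlo p
        assert out.loc[0, "n_distinct_perms"] == 70
        assert out.loc[0, "p_mc"] < 0.01

    def test_pseudo_t_is_sqrt_of_f(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(8, 3))
        d = euclidean_dm(x)
        meta = one_way_meta(["a"] * 4 + ["b"] * 4)
        out = pairwise_posthoc(d, meta, "g", n_perm=49, seed=1)
        res = permanova(d, meta, DesignSpec(fixed_terms=[("g",)]), n_perm=9, seed=0)
        f = res.table.set_index("term").loc["g", "pseudo_f"]
        assert out.loc[0, "pseudo_t"] == pytest.approx(np.sqrt(f))
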