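"""Expression profiling: thresholding, classes, breadth, core set,
resampling, gated tests, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgenescape.profiling import (
    EXPRESSION_CLASSES,
    apply_off_threshold,
    classify_expression,
    core_set,
    expression_breadth,
    gated_two_sample_test,
    library_summary,
    off_in_A_on_in_B,
    random_set_resampling,
    spearman_correlation,
    top_fraction_mean,
)

from conftest import toy_annotation, toy_matrix


class TestOffThreshold:
    @pytest.mark.parametrize("value,expected", [(0.5, 0.0), (1.0, 1.0), (0.999, 0.0), (5.0, 5.0)])
    def test_boundary_is_strictly_below_one(self, value, expected):
        out = apply_off_threshold(toy_matrix([[value]]))
        assert out.values[0, 0] == expected

    def test_all_zero_unchanged(self):
        m = toy_matrix(np.zeros((3, 2)))
        assert apply_off_threshold(m).equals(m)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            apply_off_threshold(toy_matrix([[1.0]]), threshold=-1)


class TestClassify:
    @pytest.mark.parametrize(
        "tpm,cls",
        [(0.0, "off"), (0.5, "off"), (1.0, "low"), (9.99, "low"), (10.0, "modest"),
         (50.0, "medium"), (199.9, "medium"), (200.0, "high"), (250.0, "high"),
         (999.9, "high"), (1000.0, "very_high"), (1e7, "very_high")],
    )
    def test_bin_edges_lower_inclusive(self, tpm, cls):
        out = classify_expression(toy_matrix([[tpm]]))
        assert out.iloc[0, 0] == cls

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        m = toy_matrix(rng.gamma(0.3, 200, size=(100, 5)))
        classes = classify_expression(m)
        counts = sum((classes == c).to_numpy().sum(axis=0) for c in EXPRESSION_CLASSES)
        assert (counts == 100).all()


class TestBreadthAndCore:
    def test_breadth_arithmetic(self):
        m = toy_matrix([[0.0, 4.0, 6.0]])
        b = expression_breadth(m)
        assert b["breadth"].iloc[0] == pytest.approx(2 / 3)
        assert b["mean_expressed"].iloc[0] == pytest.approx(5.0)
        assert b["mean_all"].iloc[0] == pytest.approx(10 / 3)

    def test_all_zero_gene(self):
        b = expression_breadth(toy_matrix([[0.0, 0.0]]))
        assert b["breadth"].iloc[0] == 0 and b["mean_expressed"].iloc[0] == 0

    def test_core_strict_inequality(self):
        b = pd.DataFrame({"breadth": [0.95, 0.90, 0.0]}, index=["hi", "edge", "lo"])
        assert core_set(b, 0.90) == ["hi"]

    def test_core_empty_when_all_zero(self):
        b = pd.DataFrame({"breadth": [0.0, 0.0]}, index=["a", "b"])
        assert core_set(b) == []

    def test_core_monotone_in_min_fraction(self):
        rng = np.random.default_rng(1)
        b = pd.DataFrame({"breadth": rng.random(50)}, index=[f"g{i}" for i in range(50)])
        prev = set(core_set(b, 0.0))
        for f in (0.25, 0.5, 0.75, 0.9, 1.0):
            cur = set(core_set(b, f))
            assert cur <= prev
            prev = cur

    def test_bad_min_fraction_rejected(self):
        with pytest.raises(ValueError):
            core_set(pd.DataFrame({"breadth": [0.5]}, index=["a"]), 1.5)


class TestLibrarySummary:
    def test_hand_counted_toy(self):
        m = toy_matrix([[0.0], [5.0], [2.0], [0.5]])
        ann = toy_annotation(
            [("g1", "chr1", 0, 10, True, True), ("g2", "chr1", 20, 30, True, False),
             ("g3", "chr1", 40, 50, False, False), ("g4", "chr1", 60, 70, False, False)]
        )
        out = library_summary(m, ann)
        assert out["n_expressed"].iloc[0] == 2
        assert out["n_expressed_r"].iloc[0] == 1
        assert out["prop_expressed_r"].iloc[0] == pytest.approx(0.5)

    def test_no_r_genes_reports_missing_proportion(self):
        m = toy_matrix([[5.0]])
        ann = toy_annotation([("g1", "chr1", 0, 10, False, False)])
        assert np.isnan(library_summary(m, ann)["prop_expressed_r"].iloc[0])

    def test_class_counts_sum_to_n_genes(self, small_dataset):
        ds, _ = small_dataset
        out = library_summary(ds.matrix, ds.annotation)
        class_cols = [c for c in out.columns if c.startswith("n_") and
                      c.removeprefix("n_") in EXPRESSION_CLASSES]
        assert (out[class_cols].sum(axis=1) == ds.matrix.n_genes).all()


class TestResampling:
    def test_constant_matrix_replicates_equal_constant(self):
        m = toy_matrix(np.full((20, 3), 5.0))
        res = random_set_resampling(m, set_size=7, replicates=10, seed=0)
        assert np.allclose(res.replicate_means.to_numpy(), 5.0)

    def test_replicate_count_and_determinism(self, small_dataset):
        ds, _ = small_dataset
        a = random_set_resampling(ds.matrix, 30, replicates=100, seed=42)
        b = random_set_resampling(ds.matrix, 30, replicates=100, seed=42)
        assert a.replicate_means.shape == (ds.matrix.n_libraries, 100)
        pd.testing.assert_frame_equal(a.replicate_means, b.replicate_means)

    def test_replicate_means_within_library_range(self, small_dataset):
        ds, _ = small_dataset
        res = random_set_resampling(ds.matrix, 30, replicates=20, seed=3, expressed_only=False)
        lo = ds.matrix.values.min(axis=0)
        hi = ds.matrix.values.max(axis=0)
        means = res.replicate_means.to_numpy().T
        assert (means >= lo - 1e-9).all() and (means <= hi + 1e-9).all()

    def test_set_size_too_large_rejected(self):
        with pytest.raises(ValueError):
            random_set_resampling(toy_matrix([[1.0]]), set_size=2)

    def test_observed_set_comparison(self, small_dataset):
        ds, truth = small_dataset
        res = random_set_resampling(
            ds.matrix, 30, replicates=25, seed=1, observed_gene_ids=truth.core_gene_ids
        )
        assert res.observed_means is not None
        assert ((res.empirical_quantile >= 0) & (res.empirical_quantile <= 1)).all()


class TestGatedTest:
    def test_identical_samples_p_one(self):
        res = gated_two_sample_test([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_mann_whitney_separated(self):
        # force the U-branch with clearly non-normal (heavily skewed) samples
        res = gated_two_sample_test([1, 2, 3], [10, 11, 12], alpha_gate=1.0)
        assert res.test == "mann_whitney_u"
        # U = 0, exact two-sided p = 2 * 1/C(6,3) * ... = 0.1
        assert res.p_value == pytest.approx(0.1)

    def test_symmetric_in_samples(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(1.0, 2.0, size=25)
        a = gated_two_sample_test(x, y)
        b = gated_two_sample_test(y, x)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.test == b.test

    def test_gaussian_samples_take_t_branch(self):
        rng = np.random.default_rng(1)
        res = gated_two_sample_test(rng.normal(size=100), rng.normal(size=100))
        assert res.test == "t_test"

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            gated_two_sample_test([1, 2], [1, 2, 3])

    def test_t_pvalues_roughly_uniform_under_null(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(200):
            res = gated_two_sample_test(rng.normal(size=40), rng.normal(size=40))
            if res.test == "t_test":
                ps.append(res.p_value)
        ps = np.asarray(ps)
        assert len(ps) > 150                 # the gate rarely misfires on Gaussians
        assert abs(ps.mean() - 0.5) < 0.08   # ~3 sigma of a uniform mean at n=150
        assert abs((ps < 0.5).mean() - 0.5) < 0.12


class TestSpearman:
    def test_perfect_and_inverse(self):
        assert spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
        assert spearman_correlation([1, 2, 3, 4], [-1, -2, -3, -4]).rho == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        # rho = 1 - 6 * sum(d^2) / (n (n^2 - 1)) with d^2 sum = 6
        res = spearman_correlation([1, 2, 3], [3, 1, 2])
        assert res.rho == pytest.approx(-0.5)

    def test_constant_input_missing_with_warning(self):
        with pytest.warns(RuntimeWarning):
            res = spearman_correlation([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(res.rho)


class TestTopFractionMean:
    @pytest.mark.parametrize(
        "fraction,expected", [(0.10, 10.0), (0.50, 8.0), (1.0, 5.5)]
    )
    def test_on_one_to_ten(self, fraction, expected):
        assert top_fraction_mean(range(1, 11), fraction) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            top_fraction_mean([], 0.5)


class TestOffOnContrast:
    def test_threshold_is_strict(self):
        a = pd.Series([0.0, 0.0, 0.01], index=["g1", "g2", "g3"], name="breadth")
        b = pd.Series([0.35, 0.30, 0.9], index=["g1", "g2", "g3"], name="breadth")
        assert off_in_A_on_in_B(a, b, 0.30) == ["g1"]

    def test_disjoint_universes_rejected(self):
        a = pd.Series([0.0], index=["g1"])
        b = pd.Series([0.5], index=["g2"])
        with pytest.raises(ValueError):
            off_in_A_on_in_B(a, b)

    def test_recovers_planted_wild_only_genes(self, small_dataset):
        ds, truth = small_dataset
        breadth_crop = expression_breadth(ds.matrix)
        # a "wild" condition where the planted-off genes are broadly on
        wild = ds.matrix.data.copy()
        wild.loc[truth.off_gene_ids, :] = 5.0
        from rgenescape.datamodel import ExpressionMatrix

        breadth_wild = expression_breadth(ExpressionMatrix(wild))
        got = off_in_A_on_in_B(breadth_crop, breadth_wild, 0.30)
        assert got == sorted(truth.off_gene_ids)
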