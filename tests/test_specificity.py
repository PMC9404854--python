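import itertools

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from glycoreg.simulate import SpecDesign, simulate_tissue_expression
from glycoreg.specificity import (
    SpecificityCall,
    classify_one,
    classify_specificity,
    mean_by_tissue,
    multiclass_mcc,
    predictive_benchmark,
    specificity_summary,
)
from tests.conftest import random_confusion


def brute_force_classify(means, fold=5.0, floor=1.0, max_group=7):
    """Independent oracle: exhaustive enumeration of all tissue subsets.

    A subset S (|S| = 1 for Enriched, 2..max_group for Group Enriched)
    qualifies when every member is >= fold x the maximum outside S and >=
    the expression floor; Enhanced compares a single tissue against the
    mean of the others. Precedence Enriched > Group > Enhanced.
    """
    means = np.asarray(means, dtype=float)
    n = means.size
    if means.max() < floor:
        return "NotSpecific"
    for i in range(n):
        others = np.delete(means, i)
        if means[i] >= floor and means[i] >= fold * others.max():
            return "TissueEnriched"
    for k in range(2, min(max_group, n - 1) + 1):
        for S in itertools.combinations(range(n), k):
            outside = np.delete(means, list(S))
            members = means[list(S)]
            if members.min() >= floor and members.min() >= fold * outside.max():
                return "GroupEnriched"
    for i in range(n):
        others = np.delete(means, i)
        if means[i] >= floor and means[i] >= fold * others.mean():
            return "TissueEnhanced"
    return "NotSpecific"


class TestMeanByTissue:
    def test_single_sample_identity(self):
        m, _ = simulate_tissue_expression(4, 1, 5, seed=0)
        means = mean_by_tissue(m)
        assert np.allclose(means.to_numpy(), m.values.to_numpy())

    def test_two_sample_average(self):
        m, _ = simulate_tissue_expression(2, 2, 1, seed=0)
        m.values.iloc[0] = [2.0, 4.0, 10.0, 20.0]
        means = mean_by_tissue(m)
        assert means.loc["G0001", "T01"] == 3.0
        assert means.loc["G0001", "T02"] == 15.0

    def test_sample_order_invariant(self):
        m, _ = simulate_tissue_expression(3, 4, 5, seed=1)
        perm = np.random.default_rng(0).permutation(m.values.columns)
        m2 = type(m)(values=m.values[perm], samples=m.samples.loc[perm],
                     dialect=m.dialect)
        assert np.allclose(mean_by_tissue(m).to_numpy(),
                           mean_by_tissue(m2).to_numpy())


class TestClassifyRules:
    @pytest.mark.parametrize("means,expected,tissues", [
        ([5, 1, 1, 1, 1], "TissueEnriched", ("t1",)),       # boundary exactly 5x
        ([4.9, 1, 1, 1, 1], "NotSpecific", ()),
        ([5, 5, 1, 1, 1], "GroupEnriched", ("t1", "t2")),
        ([4, 1, 1, 1, 1], "NotSpecific", ()),
        ([6, 1, 1, 1, 2], "NotSpecific", ()),               # 6 < 5x2 and 6 < 6.25
        ([10, 3, 1, 1, 1], "TissueEnhanced", ("t1",)),      # 10 >= 5x1.5, not 5x3
        ([0.5, 0.1, 0.1, 0.1], "NotSpecific", ()),          # below floor
    ])
    def test_rule_examples(self, means, expected, tissues):
        labels = [f"t{i + 1}" for i in range(len(means))]
        cat, tset, _ = classify_one(np.array(means, float), labels)
        assert cat == expected
        assert tset == tissues

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(3, 9))
            means = rng.gamma(1.0, 3.0, size=n).round(2)
            got, _, _ = classify_one(means, [f"t{i}" for i in range(n)])
            assert got == brute_force_classify(means), means

    def test_precedence_enriched_over_group(self):
        cat, tset, _ = classify_one(np.array([25.0, 5, 1, 1, 1]),
                                    ["a", "b", "c", "d", "e"])
        assert cat == "TissueEnriched" and tset == ("a",)

    def test_single_tissue_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError, match="2 tissues"):
            classify_specificity(pd.DataFrame({"t1": [1.0]}, index=["g"]))

    def test_call_invariants_enforced(self):
        with pytest.raises(ValueError):
            SpecificityCall("g", "GroupEnriched", ("t1",), 5.0)
        with pytest.raises(ValueError):
            SpecificityCall("g", "NotSpecific", ("t1",), 0.0)


class TestSpecificitySummary:
    def test_quarter_specific(self):
        calls = [SpecificityCall("g1", "TissueEnriched", ("t1",), 6.0)] + [
            SpecificityCall(f"g{i}", "NotSpecific", (), 1.0) for i in range(2, 5)]
        summ = specificity_summary(calls)
        assert summ.loc["all", "specific_fraction"] == pytest.approx(0.25)
        assert summ.loc["all", list(summ.columns[:4])].sum() == pytest.approx(1.0)

    def test_all_not_specific(self):
        calls = [SpecificityCall(f"g{i}", "NotSpecific", (), 1.0) for i in range(3)]
        assert specificity_summary(calls).loc["all", "specific_fraction"] == 0.0

    def test_planted_design_fraction_recovered(self):
        n_genes, n_spec = 50, 10
        design = [SpecDesign(f"G{i + 1:04d}", "TissueEnriched", ("T01",), 10.0)
                  for i in range(n_spec)]
        m, _ = simulate_tissue_expression(8, 15, n_genes, spec_design=design,
                                          noise_sd=0.2, seed=5)
        calls = classify_specificity(mean_by_tissue(m))
        frac = specificity_summary(calls).loc["all", "specific_fraction"]
        assert frac == pytest.approx(n_spec / n_genes, abs=0.05)


class TestMulticlassMCC:
    def test_perfect_diagonal(self):
        assert multiclass_mcc(np.diag([3, 4, 5])) == pytest.approx(1.0)

    def test_uniform_2x2_is_zero(self):
        assert multiclass_mcc([[1, 1], [1, 1]]) == pytest.approx(0.0)

    def test_matches_sklearn_label_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            k = int(rng.integers(2, 6))
            conf = random_confusion(rng, k)
            y_true, y_pred = [], []
            for i in range(k):
                for j in range(k):
                    y_true += [i] * conf[i, j]
                    y_pred += [j] * conf[i, j]
            assert multiclass_mcc(conf) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12)

    def test_row_column_permutation_invariant(self):
        rng = np.random.default_rng(3)
        conf = random_confusion(rng, 4)
        perm = rng.permutation(4)
        assert multiclass_mcc(conf[np.ix_(perm, perm)]) == pytest.approx(
            multiclass_mcc(conf), abs=1e-12)

    def test_degenerate_single_class_is_nan(self):
        conf = np.zeros((3, 3), dtype=int)
        conf[0, 0] = 10
        assert np.isnan(multiclass_mcc(conf))

    def test_binary_equals_textbook_mcc(self):
        tp, fn, fp, tn = 8, 2, 3, 7
        expected = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        assert multiclass_mcc([[tp, fn], [fp, tn]]) == pytest.approx(expected)


@pytest.fixture(scope="module")
def separable_matrix():
    # each of 30 genes enriched in one of 6 tissues -> separable panel
    design = [SpecDesign(f"G{i + 1:04d}", "TissueEnriched",
                         (f"T{(i % 6) + 1:02d}",), 20.0) for i in range(30)]
    m, _ = simulate_tissue_expression(6, 12, 60, spec_design=design,
                                      noise_sd=0.2, seed=8)
    return m


class TestPredictiveBenchmark:
    def test_separating_pool_high_mcc(self, separable_matrix):
        pool = [f"G{i + 1:04d}" for i in range(30)]
        res = predictive_benchmark(separable_matrix, pool, n_models=5,
                                   genes_per_model=20, n_trees=100, seed=0)
        assert np.median(res.mcc_values) > 0.9

    def test_noise_pool_near_zero_mcc(self, separable_matrix):
        pool = [f"G{i + 1:04d}" for i in range(30, 60)]  # unplanted genes
        res = predictive_benchmark(separable_matrix, pool, n_models=5,
                                   genes_per_model=20, n_trees=100, seed=0)
        assert abs(np.median(res.mcc_values)) < 0.15

    def test_same_seed_identical(self, separable_matrix):
        pool = [f"G{i + 1:04d}" for i in range(35)]
        a = predictive_benchmark(separable_matrix, pool, n_models=2,
                                 genes_per_model=10, n_trees=20, seed=4)
        b = predictive_benchmark(separable_matrix, pool, n_models=2,
                                 genes_per_model=10, n_trees=20, seed=4)
        assert np.array_equal(a.mcc_values, b.mcc_values)

    def test_small_pool_rejected(self, separable_matrix):
        with pytest.raises(ValueError, match="pool"):
            predictive_benchmark(separable_matrix, ["G0001"], genes_per_model=30)

    def test_tiny_tissue_rejected(self):
        m, _ = simulate_tissue_expression(3, 3, 35, seed=0)
        with pytest.raises(ValueError, match="cannot stratify"):
            predictive_benchmark(m, list(m.values.index), n_models=1,
                                 genes_per_model=30, n_trees=10, seed=0)
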