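"""The directional importance metric: G-test pieces, CLIFI values, tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clifitree.clifi import (
    LN2,
    CategoricalFrequencies,
    CLIFITable,
    SplitClassCounts,
    aggregate_and_normalize,
    class_difference_tests,
    clifi_boosting_rescale,
    clifi_for_split,
    collect_clifi,
    distribute_to_original_features,
    g_test,
    partial_g,
    select_top_features,
)
from clifitree.forest import fit_bagged_ensemble
from clifitree.boost import fit_boosted_ensemble
from clifitree.network import identity_neighbourhoods
from clifitree.tree import LabeledDataset, TreeParams


class TestGTest:
    def test_equal_observed_expected(self):
        assert g_test(CategoricalFrequencies([10, 10], [10, 10])) == 0.0

    def test_known_value(self):
        got = g_test(CategoricalFrequencies([15, 5], [10, 10]))
        assert got == pytest.approx(2 * (15 * np.log(1.5) + 5 * np.log(0.5)), abs=1e-9)
        assert got == pytest.approx(5.23248, abs=1e-5)

    def test_zero_observed_category_skipped(self):
        got = g_test(CategoricalFrequencies([20, 0], [10, 10]))
        assert got == pytest.approx(2 * 20 * np.log(2), abs=1e-9)
        assert got == pytest.approx(27.72589, abs=1e-5)

    def test_observed_with_zero_expected_raises(self):
        with pytest.raises(ValueError):
            g_test(CategoricalFrequencies([5, 5], [10, 0]))


class TestPartialG:
    @pytest.mark.parametrize(
        "c, P, expected",
        [(2, 4, 0.0), (1, 4, -1.38629), (3, 4, 2.43279), (0, 7, 0.0)],
    )
    def test_values(self, c, P, expected):
        assert partial_g(c, P) == pytest.approx(expected, abs=1e-5)

    def test_zero_parent_raises(self):
        with pytest.raises(ValueError):
            partial_g(1, 0)


counts_strategy = st.tuples(
    st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
).filter(lambda t: t[0] + t[1] > 0).map(
    lambda t: SplitClassCounts(t[0], t[1], t[0] + t[1], t[0] + t[1] + t[2])
)


class TestClifiForSplit:
    def test_perfect_root_split_right(self):
        for n in (1, 5, 40):
            assert clifi_for_split(SplitClassCounts(0, n, n, n)) == pytest.approx(1.0)

    def test_perfect_root_split_left(self):
        for n in (1, 5, 40):
            assert clifi_for_split(SplitClassCounts(n, 0, n, n)) == pytest.approx(-1.0)

    def test_balanced_split_zero(self):
        assert clifi_for_split(SplitClassCounts(3, 3, 6, 10)) == 0.0

    def test_hand_evaluated_deep_split(self):
        got = clifi_for_split(SplitClassCounts(1, 3, 4, 8))
        want = (3 * np.log(1.5) + np.log(0.5)) / (8 * np.log(2))
        assert got == pytest.approx(want, abs=1e-9)
        assert got == pytest.approx(0.09436, abs=1e-5)

    def test_absent_class_scores_zero(self):
        assert clifi_for_split(SplitClassCounts(0, 0, 0, 9)) == 0.0

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            SplitClassCounts(2, 2, 5, 8)

    @given(counts_strategy)
    @settings(max_examples=100, derandomize=True)
    def test_partial_g_identity(self, c):
        v = clifi_for_split(c)
        m1 = partial_g(c.left, c.parent)
        m2 = partial_g(c.right, c.parent)
        want = (m1 + m2) / (2 * c.ancestor * LN2) * np.sign(m2 - m1)
        assert v == pytest.approx(want, abs=1e-12)

    @given(counts_strategy, st.integers(2, 9))
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance(self, c, k):
        scaled = SplitClassCounts(c.left * k, c.right * k, c.parent * k, c.ancestor * k)
        assert clifi_for_split(scaled) == pytest.approx(clifi_for_split(c), abs=1e-12)

    @given(counts_strategy)
    @settings(max_examples=100, derandomize=True)
    def test_mirror_antisymmetry_and_bound(self, c):
        v = clifi_for_split(c)
        mirror = SplitClassCounts(c.right, c.left, c.parent, c.ancestor)
        assert clifi_for_split(mirror) == pytest.approx(-v, abs=1e-12)
        assert abs(v) <= c.parent / c.ancestor + 1e-12
        assert abs(v) <= 1 + 1e-12

    def test_magnitude_monotone_as_split_sharpens(self):
        P, A = 40, 80
        mags = [abs(clifi_for_split(SplitClassCounts(L, P - L, P, A))) for L in range(P // 2, -1, -1)]
        assert all(b >= a - 1e-12 for a, b in zip(mags, mags[1:]))


class TestDistribute:
    def test_plain_split_identity(self):
        assert distribute_to_original_features(0.7, np.array([1.0]), (4,)) == {4: 0.7}

    def test_signed_weights(self):
        out = distribute_to_original_features(0.7, np.array([0.8, -0.6]), (0, 1))
        assert out[0] == pytest.approx(0.4)
        assert out[1] == pytest.approx(-0.3)
        assert abs(out[0]) + abs(out[1]) == pytest.approx(0.7)

    def test_symmetric_negative(self):
        out = distribute_to_original_features(-1.0, np.array([0.5, 0.5]), (0, 1))
        assert out == {0: pytest.approx(-0.5), 1: pytest.approx(-0.5)}

    def test_unsigned_mode_keeps_split_sign(self):
        out = distribute_to_original_features(
            0.7, np.array([0.8, -0.6]), (0, 1), signed=False
        )
        assert out[1] == pytest.approx(0.3)


class TestBoostingRescale:
    def test_identity(self):
        assert clifi_boosting_rescale({0: 0.4}, {0: 1.0}) == pytest.approx(0.4)

    def test_weighted_sum(self):
        assert clifi_boosting_rescale(
            {0: 0.5, 1: -0.5}, {0: 0.6, 1: 0.4}
        ) == pytest.approx(0.1)

    def test_missing_label_raises(self):
        with pytest.raises(ValueError):
            clifi_boosting_rescale({0: 0.5, 2: 0.1}, {0: 1.0})


class TestCollect:
    def test_depth_one_perfect_split_signs(self, separable_2class):
        params = TreeParams(max_features="all")
        ens = fit_bagged_ensemble(
            separable_2class, params, n_trees=1, sample_fraction=1.0, seed=0
        )
        table = collect_clifi(ens, feature_names=separable_2class.feature_names)
        by_class = table.records.set_index("class")["value"]
        assert by_class["a"] == pytest.approx(-1.0)  # low values -> left
        assert by_class["b"] == pytest.approx(1.0)
        assert table.naclifi.loc["f0", "b"] == pytest.approx(1.0)

    def test_identity_neighbourhoods_identical_tables(self, toy_3class):
        params = TreeParams(max_features="sqrt")
        rf = fit_bagged_ensemble(toy_3class, params, n_trees=6, seed=2)
        lava = fit_bagged_ensemble(
            toy_3class, params, n_trees=6, seed=2,
            neighbourhoods=identity_neighbourhoods(toy_3class.n_features),
        )
        ta = collect_clifi(rf)
        tb = collect_clifi(lava)
        pd.testing.assert_frame_equal(ta.records, tb.records)
        pd.testing.assert_frame_equal(ta.aclifi, tb.aclifi)

    def test_boosted_model_collection(self, toy_3class):
        params = TreeParams(max_features="sqrt")
        model = fit_boosted_ensemble(toy_3class, params, n_rounds=2, seed=1)
        table = collect_clifi(model, feature_names=toy_3class.feature_names)
        assert set(table.records["class"]).issubset(set(model.class_list))
        assert (table.records["value"].abs() <= 1 + 1e-9).all()

    def test_unsupported_model_raises(self):
        with pytest.raises(TypeError):
            collect_clifi(object())


class TestAggregateAndSelect:
    def _table(self, cells):
        rows = [(0, 0, f, c, v) for f, c, v in cells]
        rec = pd.DataFrame(rows, columns=["tree_id", "node_id", "feature", "class", "value"])
        feats = sorted({f for f, _, _ in cells})
        classes = sorted({c for _, c, _ in cells})
        return aggregate_and_normalize(
            CLIFITable(records=rec, feature_names=feats, class_list=classes)
        )

    def test_single_record(self):
        t = self._table([("f0", "c0", 0.5)])
        assert t.aclifi.loc["f0", "c0"] == pytest.approx(0.5)
        assert t.naclifi.loc["f0", "c0"] == pytest.approx(1.0)

    def test_summation_and_maxabs_normalization(self):
        t = self._table([("f0", "c0", 0.5), ("f0", "c0", -1.5), ("f1", "c0", -4.0), ("f1", "c1", 2.0)])
        assert t.aclifi.loc["f0", "c0"] == pytest.approx(-1.0)
        assert t.naclifi.loc["f1", "c0"] == pytest.approx(-1.0)
        assert t.naclifi.loc["f1", "c1"] == pytest.approx(0.5)
        assert np.abs(t.naclifi.to_numpy()).max() == pytest.approx(1.0)

    def test_top_feature_selection_mean_filter(self):
        t = self._table([("f0", "c", 0.9), ("f1", "c", 0.5), ("f2", "c", 0.1)])
        assert select_top_features(t, "c", direction="positive") == ["f0"]

    def test_all_negative_positive_direction_empty(self):
        t = self._table([("f0", "c", -0.9), ("f1", "c", -0.5)])
        assert select_top_features(t, "c", direction="positive") == []

    def test_truncation_to_k(self):
        t = self._table([(f"f{i}", "c", v) for i, v in enumerate([0.9, 0.8, 0.01, 0.01])])
        assert select_top_features(t, "c", k=1, direction="positive") == ["f0"]

    def test_negative_direction_symmetric(self):
        t = self._table([("f0", "c", -0.9), ("f1", "c", -0.5), ("f2", "c", -0.1)])
        assert select_top_features(t, "c", direction="negative") == ["f0"]


class TestClassDifferenceTests:
    def _table_from_values(self, mapping):
        rows = []
        for (f, c), vals in mapping.items():
            rows += [(0, 0, f, c, v) for v in vals]
        rec = pd.DataFrame(rows, columns=["tree_id", "node_id", "feature", "class", "value"])
        feats = sorted({f for f, _ in mapping})
        classes = sorted({c for _, c in mapping})
        return CLIFITable(records=rec, feature_names=feats, class_list=classes)

    def test_identical_distributions_not_significant(self):
        vals = list(np.linspace(-0.5, 0.5, 20))
        t = self._table_from_values({("f0", "a"): vals, ("f0", "b"): vals})
        omni, pair = class_difference_tests(t)
        assert (omni["p_adj"] > 0.05).all()
        assert len(pair) == 0

    def test_separated_constant_groups_significant(self):
        t = self._table_from_values(
            {("f0", "a"): [0.8] * 20, ("f0", "b"): [-0.8] * 20}
        )
        omni, pair = class_difference_tests(t)
        assert (omni["p_adj"] < 0.05).all()
        assert (pair["p_adj"] < 0.05).all()

    def test_benjamini_hochberg_step_up(self):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_insufficient_records_skipped(self):
        t = self._table_from_values({("f0", "a"): [0.1], ("f0", "b"): [0.2]})
        omni, _ = class_difference_tests(t)
        assert len(omni) == 0
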