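"""Filtering rules and Pareto scaling against hand-computed values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from metabomark.preprocessing import (
    PreprocessingError,
    eighty_percent_rule,
    filter_features,
    impute_half_min,
    pareto_scale,
    qc_rsd_filter,
)

from conftest import make_table


def qc_table(qc_values_by_feature):
    """Three group samples per group + QC rows carrying the given values."""
    n_qc = len(next(iter(qc_values_by_feature.values())))
    data = {}
    for f, qc_vals in qc_values_by_feature.items():
        data[f] = [100.0] * 6 + list(qc_vals)
    groups = ["group_a"] * 3 + ["group_b"] * 3 + ["qc"] * n_qc
    return make_table(data, groups)


class TestQcRsdFilter:
    def test_identical_qc_values_retained(self):
        t = qc_table({"f1": [50.0, 50.0, 50.0]})
        kept, rep = qc_rsd_filter(t)
        assert kept.feature_ids == ["f1"]
        assert rep.n_removed_qc_rsd == 0

    def test_hand_computed_rsd_boundary(self):
        # {100,115,130}: sd 15, mean 115 -> RSD 13.04% (kept)
        # {100,140,180}: sd 40, mean 140 -> RSD 28.57% (removed)
        t = qc_table({"keep": [100.0, 115.0, 130.0], "drop": [100.0, 140.0, 180.0]})
        kept, rep = qc_rsd_filter(t, threshold_pct=15)
        assert kept.feature_ids == ["keep"]
        assert rep.removed_qc_rsd_ids == ["drop"]

    def test_zero_qc_mean_removed(self):
        t = qc_table({"f1": [0.0, 0.0, 0.0]})
        kept, _ = qc_rsd_filter(t)
        assert kept.feature_ids == []

    def test_requires_two_qc_samples(self):
        t = make_table({"f1": [1.0, 2.0, 3.0]}, ["group_a", "group_b", "qc"])
        with pytest.raises(PreprocessingError, match="QC"):
            qc_rsd_filter(t)

    def test_planted_unstable_features_removed(self, default_table_truth):
        table, truth = default_table_truth
        _, rep = qc_rsd_filter(table)
        removed = set(rep.removed_qc_rsd_ids)
        # every planted unstable feature is caught; stable features are almost
        # never removed (their QC RSD sampling distribution sits well below 15%)
        assert set(truth.unstable_feature_ids) <= removed
        false_removals = removed - set(truth.unstable_feature_ids)
        assert len(false_removals) <= 0.02 * table.n_features


class TestEightyPercentRule:
    def _presence_table(self, present_a, n_a, present_b, n_b):
        vals = ([10.0] * present_a + [np.nan] * (n_a - present_a)
                + [10.0] * present_b + [np.nan] * (n_b - present_b))
        return make_table({"f1": vals, "ref": [5.0] * (n_a + n_b)},
                          ["group_a"] * n_a + ["group_b"] * n_b)

    def test_exact_80_percent_boundary_inclusive(self):
        t = self._presence_table(4, 5, 0, 5)
        kept, _ = eighty_percent_rule(t)
        assert "f1" in kept.feature_ids

    def test_below_threshold_in_both_groups_removed(self):
        t = self._presence_table(3, 5, 7, 10)  # 60% and 70%
        kept, rep = eighty_percent_rule(t)
        assert rep.removed_80pct_ids == ["f1"]
        assert "f1" not in kept.feature_ids

    def test_full_presence_in_one_group_suffices(self):
        t = self._presence_table(0, 5, 5, 5)
        kept, _ = eighty_percent_rule(t)
        assert "f1" in kept.feature_ids

    def test_zero_counts_as_absent(self):
        vals = [0.0, 0.0, 0.0, 10.0, 10.0, np.nan, 0.0, 0.0, np.nan, 0.0]
        t = make_table({"f1": vals, "ref": [5.0] * 10},
                       ["group_a"] * 5 + ["group_b"] * 5)
        kept, _ = eighty_percent_rule(t)
        assert "f1" not in kept.feature_ids


class TestFilterPipeline:
    def test_report_arithmetic_and_disjoint_rules(self, default_table_truth):
        table, truth = default_table_truth
        filtered, rep = filter_features(table)
        assert rep.n_input - rep.n_removed_qc_rsd - rep.n_removed_80pct == rep.n_retained
        assert rep.n_retained == filtered.n_features
        assert not set(rep.removed_qc_rsd_ids) & set(rep.removed_80pct_ids)
        # retained set = everything minus the planted unstable + sparse features
        expected = (set(table.feature_ids) - set(truth.unstable_feature_ids)
                    - set(truth.sparse_feature_ids))
        agreement = len(expected & set(filtered.feature_ids)) / len(expected)
        assert agreement >= 0.95
        assert set(truth.marker_feature_ids) <= set(filtered.feature_ids)


class TestParetoScale:
    def test_hand_computed_two_point_column(self):
        scaled = pareto_scale(np.array([[0.0], [4.0]]))
        assert scaled.values[:, 0] == pytest.approx([-1.1892, 1.1892], abs=1e-4)
        assert scaled.scale_factors[0] == pytest.approx(1.6818, abs=1e-4)

    def test_columns_centered(self, small_table_truth):
        table, _ = small_table_truth
        x = impute_half_min(table.biological()).abundances
        scaled = pareto_scale(x)
        col_scale = np.abs(scaled.values).max(axis=0)
        assert np.all(np.abs(scaled.values.mean(axis=0)) < 1e-9 * np.maximum(col_scale, 1))

    def test_not_idempotent(self):
        rng = np.random.default_rng(3)
        x = rng.normal(10, 2, size=(20, 4))
        once = pareto_scale(x).values
        twice = pareto_scale(once).values
        assert not np.allclose(once, twice)

    def test_constant_column_dropped_with_warning(self):
        x = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.warns(UserWarning, match="constant"):
            scaled = pareto_scale(x)
        assert scaled.values.shape[1] == 1

    def test_all_constant_rejected(self):
        with pytest.raises(PreprocessingError, match="constant"):
            pareto_scale(np.ones((4, 3)))


class TestImputation:
    def test_half_minimum_fill(self):
        t = make_table({"f1": [8.0, np.nan, 4.0, 6.0]},
                       ["group_a", "group_a", "group_b", "group_b"])
        filled = impute_half_min(t)
        assert filled.abundances.loc[t.sample_ids[1], "f1"] == 2.0

    @settings(max_examples=25, deadline=None)
    @given(arrays(np.float64, (6, 3), elements=st.floats(0.5, 100)),
           st.integers(0, 17))
    def test_imputation_preserves_observed_cells(self, x, hole):
        x = x.copy()
        x[hole // 3, hole % 3] = np.nan
        t = make_table({f"f{j}": x[:, j] for j in range(3)},
                       ["group_a"] * 3 + ["group_b"] * 3)
        filled = impute_half_min(t).abundances.to_numpy()
        mask = ~np.isnan(x)
        assert np.array_equal(filled[mask], x[mask])
        assert not np.isnan(filled).any()
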