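import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from harmonet import (
    GeneAttributeMatrix,
    StandardizationConfig,
    ThresholdConfig,
    coverage_summary,
    ecdf_standardize,
    preprocess,
    select_standardization_mode,
    threshold_associations,
)


def mat(values, kind="raw_continuous"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return GeneAttributeMatrix(
        [f"g{i}" for i in range(values.shape[0])],
        [f"a{j}" for j in range(values.shape[1])],
        values,
        kind,
    )


class TestModeSelection:
    def test_identical_row_medians_pool_globally(self):
        rows = [[1, 2, 3, 4], [4, 3, 2, 1], [2, 1, 4, 3]]
        assert select_standardization_mode(mat(rows), StandardizationConfig()) == "global"

    def test_differing_medians_switch_to_per_gene(self):
        rows = [[1, 2, 3, 4], [5, 6, 8, 9]]  # medians 2.5 vs 7.0
        assert select_standardization_mode(mat(rows), StandardizationConfig()) == "per_gene"

    @pytest.mark.parametrize("mode", ["global", "per_gene"])
    def test_explicit_mode_passes_through(self, mode):
        rows = [[1, 2], [100, 200]]
        cfg = StandardizationConfig(mode=mode)
        assert select_standardization_mode(mat(rows), cfg) == mode

    def test_empty_matrix_rejected(self):
        empty = mat([[np.nan, np.nan]])
        with pytest.raises(ValueError, match="no observed"):
            select_standardization_mode(empty, StandardizationConfig())

    def test_unobserved_row_excluded_and_flagged(self):
        rows = [[1, 2, 3], [np.nan, np.nan, np.nan], [3, 2, 1]]
        report = {}
        mode = select_standardization_mode(mat(rows), StandardizationConfig(), report)
        assert mode == "global"
        assert report["rows_without_observations"] == ["g1"]


class TestEcdf:
    def test_distinct_values_get_rank_over_n(self):
        out = ecdf_standardize(mat([[3, 1, 2, 4]]))
        assert np.allclose(out.values, [[0.75, 0.25, 0.5, 1.0]])
        assert out.value_kind.value == "standardized_unsigned"

    def test_ties_share_the_upper_count(self):
        out = ecdf_standardize(mat([[1, 1, 2]]))
        assert np.allclose(out.values, [[2 / 3, 2 / 3, 1.0]])

    def test_signed_transform_doubles_and_shifts(self):
        # probabilities 0.25, 0.50, 1.00 -> -0.5, 0.0, 1.0
        out = ecdf_standardize(
            mat([[1, 2, 3, 4]]), StandardizationConfig(sign_allowed=True)
        )
        assert np.allclose(out.values, [[-0.5, 0.0, 0.5, 1.0]])
        assert out.value_kind.value == "standardized_signed"

    def test_per_gene_pools_each_row_separately(self):
        rows = [[1, 2, 3, 4], [10, 20, 30, 40]]  # different medians
        out = ecdf_standardize(mat(rows))
        assert np.allclose(out.values[0], out.values[1])

    def test_unobserved_entries_stay_unobserved(self):
        out = ecdf_standardize(mat([[1, np.nan, 3, 4]]))
        assert np.isnan(out.values[0, 1])
        assert out.values[0, 3] == 1.0

    def test_discrete_input_redirected(self):
        m = mat([[0, 1, 1]], kind="raw_discrete")
        with pytest.raises(ValueError, match="raw_discrete"):
            ecdf_standardize(m)

    @given(
        arrays(
            float,
            (4, 6),
            elements=st.floats(-1e6, 1e6, allow_nan=False, width=32),
        )
    )
    def test_monotone_and_max_is_one(self, values):
        out = ecdf_standardize(mat(values), StandardizationConfig(mode="global"))
        flat_in = values.ravel()
        flat_out = out.values.ravel()
        order = np.argsort(flat_in, kind="stable")
        assert np.all(np.diff(flat_out[order]) >= -1e-15)
        assert flat_out.max() == 1.0

    @given(
        arrays(
            float,
            (3, 5),
            elements=st.floats(-100, 100, allow_nan=False, width=32),
        )
    )
    def test_signed_output_bounded_with_unit_max(self, values):
        out = ecdf_standardize(
            mat(values), StandardizationConfig(sign_allowed=True, mode="global")
        )
        assert out.values.min() >= -1.0
        assert out.values.max() == 1.0


class TestThreshold:
    def test_retains_exactly_ten_percent_of_distinct_values(self, rng):
        values = rng.permutation(100).reshape(10, 10).astype(float) / 100 + 0.005
        m = mat(values, kind="standardized_unsigned")
        out = threshold_associations(m, ThresholdConfig(retain_fraction=0.10))
        assert int((out.values != 0).sum()) == 10
        assert out.value_kind.value == "binary"
        # the retained entries are the 10 largest
        top = set(map(tuple, np.argwhere(values >= np.sort(values.ravel())[-10])))
        assert set(map(tuple, np.argwhere(out.values != 0))) == top

    def test_signed_input_keeps_signs_of_strongest(self):
        m = mat([[-0.9, -0.1, 0.2, 0.95]], kind="standardized_signed")
        out = threshold_associations(m, ThresholdConfig(retain_fraction=0.5))
        assert out.values.tolist() == [[-1.0, 0.0, 0.0, 1.0]]
        assert out.value_kind.value == "ternary"

    def test_all_tied_values_break_by_row_major_index(self):
        m = mat(np.full((10, 10), 0.5), kind="standardized_unsigned")
        out = threshold_associations(m, ThresholdConfig(retain_fraction=0.1))
        nz = np.flatnonzero(out.values.ravel())
        assert nz.tolist() == list(range(10))  # earliest row-major entries

    def test_keep_all_tied_retains_the_whole_tie_group(self):
        m = mat(np.full((10, 10), 0.5), kind="standardized_unsigned")
        out = threshold_associations(
            m, ThresholdConfig(retain_fraction=0.1, tie_policy="keep_all_tied")
        )
        assert int((out.values != 0).sum()) == 100

    def test_retain_fraction_applies_to_observed_entries_only(self, rng):
        values = rng.random((10, 10))
        values[rng.random((10, 10)) < 0.5] = np.nan
        m = mat(values, kind="standardized_unsigned")
        n_obs = int(np.isfinite(values).sum())
        out = threshold_associations(m, ThresholdConfig(retain_fraction=0.2))
        assert int((out.values != 0).sum()) == int(0.2 * n_obs)

    def test_already_thresholded_input_rejected(self):
        m = mat([[0, 1, 1]], kind="binary")
        with pytest.raises(ValueError, match="already thresholded"):
            threshold_associations(m)

    def test_bad_retain_fraction_rejected(self):
        with pytest.raises(ValueError):
            ThresholdConfig(retain_fraction=0.0)
        with pytest.raises(ValueError):
            ThresholdConfig(retain_fraction=1.5)

    def test_pipeline_matches_direct_quantile_cut(self, rng):
        """standardize->threshold selects the same entries as cutting the raw
        values at the (1-f) quantile when values are distinct and pooled
        globally."""
        values = rng.permutation(60).reshape(6, 10).astype(float)
        std = ecdf_standardize(mat(values), StandardizationConfig(mode="global"))
        out = threshold_associations(std, ThresholdConfig(retain_fraction=0.25))
        n_keep = int(0.25 * 60)
        cutoff = np.sort(values.ravel())[-n_keep]
        assert np.array_equal(out.values != 0, values >= cutoff)


class TestPreprocess:
    def test_quantile_normalize_averages_sorted_profiles(self):
        m = mat(np.array([[1, 4], [2, 5], [3, 6]], dtype=float))
        out = preprocess(m, ["quantile_normalize"])
        assert np.allclose(out.values, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_quantile_normalize_is_idempotent(self, rng):
        m = mat(rng.random((20, 5)))
        once = preprocess(m, ["quantile_normalize"])
        twice = preprocess(once, ["quantile_normalize"])
        assert np.allclose(once.values, twice.values)

    def test_filter_rows_drops_underobserved_and_logs(self):
        m = mat([[1, np.nan, np.nan], [1, 2, 3]])
        out = preprocess(m, [("filter_rows", {"min_observed": 2})])
        assert out.gene_ids == ["g1"]
        steps = [e["step"] for e in out.metadata["provenance"]]
        assert steps == ["filter_rows"]

    def test_average_rows_collapses_duplicate_labels(self):
        m = GeneAttributeMatrix(
            ["dup", "dup2"], ["a", "b"], [[1.0, 3.0], [3.0, 5.0]], "raw_continuous"
        )
        m.gene_ids = ["dup", "dup"]  # inject a duplicate label pair
        out = preprocess(m, ["average_rows"])
        assert out.values.tolist() == [[2.0, 4.0]]

    def test_impute_rejects_fully_unobserved_row(self):
        m = mat([[np.nan, np.nan], [1, 2]])
        with pytest.raises(ValueError, match="g0"):
            preprocess(m, ["impute"])

    def test_unknown_step_rejected(self):
        with pytest.raises(ValueError, match="unknown preprocessing step"):
            preprocess(mat([[1, 2]]), ["normalize_hard"])

    def test_steps_apply_in_order_and_are_logged(self, rng):
        m = mat(rng.random((6, 4)) + 1)
        out = preprocess(m, ["log_transform", "zscore_scale", "quantile_normalize"])
        steps = [e["step"] for e in out.metadata["provenance"]]
        assert steps == ["log_transform", "zscore_scale", "quantile_normalize"]


class TestCoverage:
    def test_relative_counts_within_each_dataset(self):
        a = mat([[1, 1, 0], [0, 1, 0], [0, 0, 0]], kind="binary")
        grid = coverage_summary([a], dataset_names=["d"])
        assert grid.loc["g0", "d"] == 1.0  # the best-covered gene
        assert grid.loc["g1", "d"] == 0.5  # counts {2, 1} -> {1.0, 0.5}
        assert grid.loc["g2", "d"] == 0.0  # no associations

    def test_absent_genes_get_zero(self):
        a = mat([[1, 1]], kind="binary")
        b = GeneAttributeMatrix(["other"], ["x"], [[1.0]], "binary")
        grid = coverage_summary([a, b], dataset_names=["d1", "d2"])
        assert grid.loc["other", "d1"] == 0.0
        assert grid.loc["g0", "d2"] == 0.0

    def test_unthresholded_input_rejected(self):
        with pytest.raises(ValueError, match="thresholded"):
            coverage_summary([mat([[0.5, 0.7]], kind="standardized_unsigned")])
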