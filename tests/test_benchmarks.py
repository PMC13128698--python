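import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from esdbench import (
    BenchmarkMethod,
    ValidationError,
    benchmark_table,
    bootstrap_quantile_ci,
    bowley_skewness,
    percentile_rank,
    quantile,
    sesoi_split,
)

finite_floats = st.floats(-10, 10, allow_nan=False, allow_infinity=False)


def expanded_quantile(values, int_weights, p):
    """Brute-force oracle: expand integer weights to replicates."""
    expanded = np.repeat(np.asarray(values, float), np.asarray(int_weights, int))
    return float(np.quantile(expanded, p))


class TestQuantile:
    def test_interpolation_between_order_statistics(self):
        # h = 0.25 * 6 = 1.5 -> midpoint of the 2nd and 3rd order statistic
        assert quantile([1, 2, 3, 4, 5, 6, 7], 0.25) == pytest.approx(2.5)

    def test_equal_weights_reproduce_unweighted_exactly(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 30))
            vals = rng.normal(size=n)
            w = np.full(n, float(rng.uniform(0.1, 5.0)))
            p = float(rng.uniform(0, 1))
            assert quantile(vals, p, w) == quantile(vals, p)

    def test_monotone_in_p(self, rng):
        vals = rng.normal(size=25)
        w = rng.uniform(0.1, 3.0, size=25)
        ps = np.sort(rng.uniform(0, 1, size=40))
        qs = [quantile(vals, p, w) for p in ps]
        assert np.all(np.diff(qs) >= 0)

    def test_matches_replicate_expansion_at_pinned_grid_points(self, rng):
        """For integer weights the interpolation grid point of each sorted
        value lies inside the span its replicates occupy, so both the
        estimator and the expansion oracle return that value exactly."""
        for _ in range(100):
            n = int(rng.integers(2, 12))
            vals = np.sort(rng.normal(size=n))
            w = rng.integers(1, 6, size=n).astype(float)
            s = np.cumsum(w)
            grid = np.concatenate(([0.0], s[:-1])) / (s[-1] - w)
            for k, p in enumerate(grid):
                assert quantile(vals, float(p), w) == pytest.approx(vals[k], abs=1e-12)
                assert expanded_quantile(vals, w, float(p)) == pytest.approx(
                    vals[k], abs=1e-12
                )

    def test_extremes_match_expansion_oracle(self):
        vals, w = [0.0, 10.0], [3.0, 1.0]
        assert quantile(vals, 0.0, w) == expanded_quantile(vals, w, 0.0) == 0.0
        assert quantile(vals, 1.0, w) == expanded_quantile(vals, w, 1.0) == 10.0

    def test_negation_symmetry(self, rng):
        vals = rng.normal(size=15)
        w = rng.uniform(0.2, 4.0, size=15)
        for p in (0.1, 0.25, 0.6, 0.9):
            assert quantile([-v for v in vals], 1 - p, w) == pytest.approx(
                -quantile(vals, p, w), abs=1e-12
            )

    @pytest.mark.parametrize(
        "args",
        [
            ([], 0.5, None),
            ([1.0], 1.5, None),
            ([1.0, 2.0], 0.5, [1.0, -1.0]),
            ([1.0, 2.0], 0.5, [1.0]),
        ],
    )
    def test_preconditions(self, args):
        with pytest.raises(ValidationError):
            quantile(*args)


class TestBootstrapQuantileCI:
    def test_degenerate_distribution_collapses(self):
        lo, hi = bootstrap_quantile_ci([0.4] * 50, 0.5, n_boot=200, seed=1)
        assert lo == hi == 0.4

    def test_seeded_determinism(self, rng):
        vals = rng.normal(size=60)
        a = bootstrap_quantile_ci(vals, 0.25, n_boot=500, seed=42)
        b = bootstrap_quantile_ci(vals, 0.25, n_boot=500, seed=42)
        assert a == b

    def test_interval_ordered_and_within_range(self, rng):
        vals = rng.normal(size=60)
        w = 1.0 / rng.uniform(0.1, 1.0, size=60) ** 2
        lo, hi = bootstrap_quantile_ci(vals, 0.75, n_boot=500, seed=3, weights=w)
        assert lo <= hi
        assert vals.min() <= lo and hi <= vals.max()


class TestBowleySkewness:
    def test_symmetric_sample_is_zero(self):
        assert bowley_skewness([1, 2, 3, 4, 5]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # quartiles of {1,2,3,7,8}: Q1=2, Q2=3, Q3=7 -> (2+7-6)/5 = 0.6
        assert bowley_skewness([1, 2, 3, 7, 8]) == pytest.approx(0.6)

    def test_mirror_antisymmetry(self, rng):
        vals = rng.normal(size=40)
        assert bowley_skewness(-vals) == pytest.approx(
            -bowley_skewness(vals), abs=1e-12
        )

    def test_zero_iqr_raises(self):
        with pytest.raises(ValidationError):
            bowley_skewness([1.0, 1.0, 1.0, 1.0])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(finite_floats, min_size=4, max_size=60))
    def test_bounded_on_random_samples(self, values):
        try:
            b = bowley_skewness(values)
        except ValidationError:
            return  # zero IQR: undefined by contract
        assert -1.0 - 1e-12 <= b <= 1.0 + 1e-12


class TestSesoiSplit:
    def test_counts_at_or_above(self):
        assert sesoi_split([0.1, 0.2, 0.3, 0.4], 0.3) == (0.5, 0.5)

    def test_sesoi_below_minimum(self):
        assert sesoi_split([0.5, 0.6], 0.1) == (0.0, 1.0)

    def test_absolute_comparison(self):
        assert sesoi_split([-0.5, 0.1], 0.3, absolute=True) == (0.5, 0.5)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(finite_floats, min_size=1, max_size=50),
        st.floats(-5, 5, allow_nan=False),
    )
    def test_proportions_sum_to_one(self, values, sesoi):
        below, above = sesoi_split(values, sesoi)
        assert below + above == pytest.approx(1.0)


class TestPercentileRank:
    @pytest.mark.parametrize(
        "x, expected", [(0.05, 0.0), (5.0, 100.0), (0.25, pytest.approx(200 / 3))]
    )
    def test_strictly_smaller_convention(self, x, expected):
        assert percentile_rank([0.1, 0.2, 0.3], x) == expected


class TestBenchmarkTable:
    def test_methods_define_percentile_levels(self):
        assert BenchmarkMethod.QUADS.probabilities == (0.25, 0.50, 0.75)
        assert BenchmarkMethod.THIRDS.probabilities == (0.1665, 0.50, 0.8335)

    def test_overall_row_matches_direct_quantiles(self, literature):
        table = benchmark_table(literature, method="quads")
        vals = literature.yi
        for est, p in zip(table.overall_row.estimates, (0.25, 0.5, 0.75)):
            assert est.value == quantile(vals, p)
        assert table.overall_row.n_effects == len(literature)

    def test_rows_respect_quantile_ordering(self, literature):
        table = benchmark_table(literature, grouping=False, ci=True, n_boot=200, seed=5)
        for row in table:
            v = [e.value for e in row.estimates]
            assert v[0] <= v[1] <= v[2]
            for e in row.estimates:
                assert e.ci_low <= e.ci_high

    def test_small_groups_omitted(self, small_dataset):
        table = benchmark_table(small_dataset, grouping=True, min_group_n=3)
        assert {r.group for r in table.rows} == {"a", "b"}

    def test_all_groups_below_threshold_is_error(self, small_dataset):
        with pytest.raises(ValidationError, match="minimum"):
            benchmark_table(small_dataset, grouping=True, min_group_n=10)

    def test_absolute_and_weighted_flags(self, small_dataset):
        t_abs = benchmark_table(small_dataset, absolute=True)
        assert t_abs.overall_row.estimates[0].value == quantile(
            np.abs(small_dataset.yi), 0.25
        )
        t_w = benchmark_table(small_dataset, weighted=True)
        assert t_w.overall_row.estimates[1].value == quantile(
            small_dataset.yi, 0.5, 1 / small_dataset.sei**2
        )

    def test_markdown_rounds_to_two_decimals(self, literature):
        md = benchmark_table(literature).to_markdown()
        assert "All" in md
        import re

        floats = re.findall(r"-?\d+\.\d+", md)
        assert floats and all(len(f.split(".")[1]) == 2 for f in floats)

    def test_bowley_column_present_when_requested(self, literature):
        table = benchmark_table(literature, bowley=True)
        assert table.overall_row.bowley is not None
        assert -1 <= table.overall_row.bowley <= 1
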