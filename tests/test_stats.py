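import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from cazprofiler.simulate import SimConfig, generate_count_matrix
from cazprofiler.stats import (
    category_matrix,
    group_summarize,
    ols_r2,
    pairwise_welch,
    pca_counts,
    welch_test,
)

finite = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


# ------------------------------------------------------------- summaries
def naive_quartiles(xs, q):
    """Type-7 linear interpolation on sorted order statistics."""
    xs = sorted(xs)
    h = (len(xs) - 1) * q
    lo = math.floor(h)
    if lo == len(xs) - 1:
        return xs[-1]
    return xs[lo] + (h - lo) * (xs[lo + 1] - xs[lo])


class TestGroupSummarize:
    def test_simple_group(self):
        s = group_summarize({"a": 1, "b": 2, "c": 3}, {"a": "g", "b": "g", "c": "g"})
        assert s[0].median == 2 and s[0].sample_sd == pytest.approx(1.0)
        assert s[0].n == 3

    def test_constant_group(self):
        s = group_summarize(
            {f"o{i}": 2 for i in range(4)}, {f"o{i}": "g" for i in range(4)}
        )
        assert s[0].median == 2 and s[0].sample_sd == 0.0

    def test_even_n_median_is_midpoint(self):
        s = group_summarize(
            {"a": 1, "b": 2, "c": 4, "d": 10}, {k: "g" for k in "abcd"}
        )
        assert s[0].median == 3.0

    def test_singleton_has_no_sd(self):
        s = group_summarize({"a": 5.0}, {"a": "g"})
        assert s[0].sample_sd is None and s[0].n == 1

    def test_unlabeled_organism_rejected(self):
        with pytest.raises(ValueError):
            group_summarize({"a": 1.0}, {})

    def test_empty_group_omitted_with_warning(self):
        with pytest.warns(UserWarning):
            s = group_summarize({"a": 1.0, "b": 2.0}, {"a": "g1", "b": "g1", "c": "g2"})
        assert [x.group_label for x in s] == ["g1"]

    @given(
        st.lists(st.tuples(finite, st.sampled_from("pqr")), min_size=1, max_size=30)
    )
    def test_matches_order_statistics_oracle(self, rows):
        values = {f"o{i}": v for i, (v, _) in enumerate(rows)}
        grouping = {f"o{i}": g for i, (_, g) in enumerate(rows)}
        for s in group_summarize(values, grouping):
            xs = [v for (v, g) in rows if g == s.group_label]
            assert s.median == pytest.approx(naive_quartiles(xs, 0.5))
            assert s.q1 == pytest.approx(naive_quartiles(xs, 0.25))
            assert s.q3 == pytest.approx(naive_quartiles(xs, 0.75))
            assert s.q1 <= s.median <= s.q3
            if len(xs) >= 2:
                mean = sum(xs) / len(xs)
                var = sum((x - mean) ** 2 for x in xs) / (len(xs) - 1)
                assert s.sample_sd == pytest.approx(math.sqrt(var), abs=1e-9)

    def test_one_group_equals_ungrouped_summary(self):
        values = {f"o{i}": float(i) for i in range(10)}
        s = group_summarize(values, {k: "all" for k in values})[0]
        assert s.median == naive_quartiles(list(values.values()), 0.5)


# ------------------------------------------------------------- Welch
class TestWelch:
    def test_identical_samples(self):
        r = welch_test([1, 2, 3], [1, 2, 3])
        assert r.t_statistic == 0.0 and r.p_value == pytest.approx(1.0)

    def test_hand_computed_three_point_samples(self):
        """Textbook formula on a=[1,2,3], b=[4,5,6]: t=-3*sqrt(3/2), dof=4."""
        r = welch_test([1, 2, 3], [4, 5, 6])
        t_expect = (2.0 - 5.0) / math.sqrt(1 / 3 + 1 / 3)
        dof_expect = (2 / 3) ** 2 / ((1 / 3) ** 2 / 2 + (1 / 3) ** 2 / 2)
        p_expect = 2 * sps.t.sf(abs(t_expect), dof_expect)
        assert r.t_statistic == pytest.approx(t_expect)
        assert r.dof == pytest.approx(dof_expect)
        assert r.p_value == pytest.approx(p_expect)

    def test_antisymmetry_under_swap(self):
        a, b = [1.0, 2.5, 3.1], [0.3, 4.4, 9.1, 2.2]
        r1, r2 = welch_test(a, b), welch_test(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.dof == pytest.approx(r2.dof)

    def test_degenerate_zero_variance(self):
        r = welch_test([2, 2, 2], [2, 2])
        assert (r.t_statistic, r.p_value) == (0.0, 1.0)
        r = welch_test([2, 2, 2], [5, 5])
        assert r.p_value == 0.0 and r.t_statistic == -np.inf

    def test_one_sided_sample_size_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [1.0, 2.0])

    @given(
        st.lists(st.integers(-1000, 1000).map(float), min_size=2, max_size=12),
        st.lists(st.integers(-1000, 1000).map(float), min_size=2, max_size=12),
        st.integers(-500, 500).map(float),
    )
    def test_shift_invariance(self, a, b, c):
        r0 = welch_test(a, b)
        r1 = welch_test([x + c for x in a], [x + c for x in b])
        assert r1.p_value == pytest.approx(r0.p_value, rel=1e-6, abs=1e-12)

    def test_pairwise_grid_and_corrections(self):
        values = {f"o{i}": float(i) for i in range(9)}
        grouping = {f"o{i}": "abc"[i % 3] for i in range(9)}
        raw = pairwise_welch(values, grouping)
        assert [r.groups for r in raw] == [("a", "b"), ("a", "c"), ("b", "c")]
        bonf = pairwise_welch(values, grouping, correction="bonferroni")
        for r0, r1 in zip(raw, bonf):
            assert r1.p_value == pytest.approx(min(1.0, 3 * r0.p_value))
        bh = pairwise_welch(values, grouping, correction="bh")
        assert all(0 < r.p_value <= 1 for r in bh)


# ------------------------------------------------------------- regression
class TestOlsR2:
    def test_exact_line(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r = ols_r2(x, [2 * v + 1 for v in x])
        assert r.r_squared == pytest.approx(1.0)
        assert r.slope == pytest.approx(2.0) and r.intercept == pytest.approx(1.0)

    def test_orthogonal_y(self):
        x = [-1.0, 0.0, 1.0]
        y = [1.0, -2.0, 1.0]  # symmetric in x: zero slope
        assert ols_r2(x, y).r_squared == pytest.approx(0.0, abs=1e-12)

    def test_constant_x_rejected_constant_y_zero(self):
        with pytest.raises(ValueError):
            ols_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert ols_r2([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]).r_squared == 0.0

    def test_noisy_line_equals_pearson_squared(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 10, size=50)
        y = 3 * x + rng.normal(0, 2, size=50)
        r = ols_r2(x, y)
        # closed-form Pearson correlation oracle
        xc, yc = x - x.mean(), y - y.mean()
        pearson = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
        assert r.r_squared == pytest.approx(pearson**2, rel=1e-10)

    def test_r2_invariant_under_y_scaling(self):
        x = [1.0, 2.0, 4.0, 8.0]
        y = [1.2, 1.9, 4.5, 7.7]
        assert ols_r2(x, y).r_squared == pytest.approx(
            ols_r2(x, [10 * v - 3 for v in y]).r_squared
        )


# ------------------------------------------------------------- PCA
class TestPCA:
    def test_single_varying_column(self):
        m = np.tile([1.0, 2, 3, 4, 5, 6], (5, 1))
        m[:, 0] = [1, 2, 3, 4, 5]
        r = pca_counts(m)
        assert r.variance_fraction[0] == pytest.approx(1.0)
        assert np.allclose(r.variance_fraction[1:], 0.0, atol=1e-12)

    def test_duplicated_rows_identical_scores(self):
        rng = np.random.default_rng(0)
        m = rng.integers(5, 100, size=(4, 6)).astype(float)
        m = np.vstack([m, m[0]])
        r = pca_counts(m)
        assert np.allclose(r.scores[0], r.scores[-1])

    def test_fractions_sum_to_one_nonincreasing(self):
        rng = np.random.default_rng(3)
        r = pca_counts(rng.poisson(50, size=(20, 6)).astype(float))
        assert r.variance_fraction.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(r.variance_fraction) <= 1e-12)

    def test_matches_independent_svd_and_sklearn(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(7)
        m = rng.poisson([80, 75, 15, 60, 20, 60], size=(20, 6)).astype(float)
        r = pca_counts(m)
        ref = PCA().fit(m)
        assert np.allclose(r.variance_fraction, ref.explained_variance_ratio_)
        # loadings orthonormal, agree with sklearn up to sign
        assert np.allclose(r.loadings @ r.loadings.T, np.eye(6), atol=1e-9)
        for i in range(6):
            assert np.allclose(np.abs(r.loadings[i]), np.abs(ref.components_[i]), atol=1e-8)

    def test_sign_convention(self):
        rng = np.random.default_rng(9)
        r = pca_counts(rng.normal(size=(15, 6)))
        for row in r.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_scaled_pca_rejects_zero_variance_column(self):
        m = np.random.default_rng(1).normal(size=(10, 6))
        m[:, 2] = 4.0
        with pytest.raises(ValueError, match="x2"):
            pca_counts(m, scale=True)

    def test_scores_reproduce_centered_data(self):
        rng = np.random.default_rng(5)
        m = rng.normal(size=(12, 6))
        r = pca_counts(m)
        assert np.allclose(r.scores @ r.loadings, m - m.mean(axis=0), atol=1e-9)


def test_category_matrix_extraction():
    frame = pd.DataFrame(
        {
            "tag": ["a", "b", "c"],
            "n_GH": [80, 90, 100], "n_GT": [70, 75, 80], "n_PL": [10, 12, 14],
            "n_CE": [60, 62, 64], "n_AA": [18, 19, 20], "n_CBM": [55, 60, 65],
        }
    )
    m = category_matrix(frame)
    assert list(m.columns) == ["GH", "GT", "PL", "CE", "AA", "CBM"]
    assert list(m.loc["a"]) == [80, 70, 10, 60, 18, 55]


def test_synthetic_count_matrix_is_pca_ready():
    m = generate_count_matrix(SimConfig(seed=2), n_organisms=40)
    r = pca_counts(category_matrix(m.add_prefix("n_").reset_index(names="tag")))
    assert r.variance_fraction.sum() == pytest.approx(1.0)
    assert r.variance_fraction[0] > 0.5  # shared size factor dominates
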