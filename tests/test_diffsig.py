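import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vinomics import (
    FactorGrouping,
    bh_fdr,
    fcmm,
    median_fold_change,
    multi_group_test,
    significance_table,
    two_group_test,
)
from vinomics.core_io import Factor

from .conftest import make_matrix


def two_groups(n_a=2, n_b=2):
    ids_a = [f"a{i}" for i in range(n_a)]
    ids_b = [f"b{i}" for i in range(n_b)]
    return ids_a, ids_b, FactorGrouping(
        Factor.BARREL_TYPE, {"old": ids_a, "new": ids_b}
    )


class TestFcmm:
    @pytest.mark.parametrize(
        "values,expected",
        [([1, 2, 4], 4.0), ([5, 5, 5], 1.0), ([2, 8], 4.0), ([0.5, 0.25], 2.0)],
    )
    def test_grid(self, values, expected):
        assert fcmm(values) == expected

    def test_zero_minimum_gives_inf(self):
        assert fcmm([0, 1, 2]) == math.inf

    def test_fewer_than_two_values_errors(self):
        with pytest.raises(ValueError):
            fcmm([3.0])

    @given(
        st.lists(st.floats(0.01, 1e6), min_size=2, max_size=20),
        st.floats(0.001, 1000),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, values, c):
        assert fcmm(np.array(values) * c) == pytest.approx(fcmm(values), rel=1e-9)


class TestTwoGroupTest:
    def test_closed_form_example(self):
        # pooled t for {1,2} vs {3,4}: t = -2.8284, df = 2, p = 0.1056
        ids_a, ids_b, g = two_groups()
        fm = make_matrix(np.array([[1.0], [2.0], [3.0], [4.0]]),
                         sample_ids=ids_a + ids_b)
        p = two_group_test(fm, g)
        diff = 1.5 - 3.5
        sp2 = (0.5 + 0.5) / 2  # pooled variance, ddof 1 within each group
        t = diff / math.sqrt(sp2 * (1 / 2 + 1 / 2))
        assert abs(t) == pytest.approx(2.8284, abs=1e-4)
        expected_p = 2 * stats.t.sf(abs(t), df=2)
        assert p[0] == pytest.approx(expected_p, rel=1e-12)
        assert p[0] == pytest.approx(0.1056, abs=2e-4)

    def test_identical_groups_p_one(self):
        ids_a, ids_b, g = two_groups()
        fm = make_matrix(np.array([[1.0], [2.0], [1.0], [2.0]]),
                         sample_ids=ids_a + ids_b)
        assert two_group_test(fm, g)[0] == pytest.approx(1.0)

    def test_constant_in_both_groups_p_one(self):
        ids_a, ids_b, g = two_groups()
        fm = make_matrix(np.full((4, 1), 7.0), sample_ids=ids_a + ids_b)
        assert two_group_test(fm, g)[0] == 1.0

    def test_huge_planted_shift(self, rng):
        ids_a, ids_b, g = two_groups(4, 4)
        base = rng.normal(10, 1, size=(8, 1))
        base[4:] += 10  # 10 pooled SDs
        fm = make_matrix(np.abs(base), sample_ids=ids_a + ids_b)
        assert two_group_test(fm, g)[0] < 1e-3

    def test_null_p_values_uniform(self, rng):
        ids_a, ids_b, g = two_groups(4, 4)
        fm = make_matrix(
            rng.normal(100, 1, size=(8, 2000)), sample_ids=ids_a + ids_b
        )
        p = two_group_test(fm, g)
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_group_size_one_errors(self):
        g = FactorGrouping.__new__(FactorGrouping)
        g.factor = Factor.BARREL_TYPE
        g.groups = {"old": ["a0"], "new": ["b0", "b1"]}
        fm = make_matrix(np.ones((3, 1)), sample_ids=["a0", "b0", "b1"])
        with pytest.raises(ValueError):
            two_group_test(fm, g)


class TestMultiGroupTest:
    def make(self, values, n_groups=3, per_group=2):
        ids = [f"g{g}r{r}" for g in range(n_groups) for r in range(per_group)]
        grouping = FactorGrouping(
            Factor.TIME,
            {str(g): ids[g * per_group:(g + 1) * per_group] for g in range(n_groups)},
        )
        return make_matrix(values, sample_ids=ids), grouping

    def test_identical_groups_p_one(self):
        vals = np.array([[1.0], [2.0]] * 3)
        fm, g = self.make(vals)
        assert multi_group_test(fm, g)[0] == pytest.approx(1.0)

    def test_perfect_separation_zero_within_variance(self):
        vals = np.array([[0.0], [0.0], [1.0], [1.0], [2.0], [2.0]])
        fm, g = self.make(vals)
        p = multi_group_test(fm, g)[0]
        assert p <= np.finfo(float).tiny

    def test_f_matches_sum_of_squares_oracle(self, rng):
        vals = rng.lognormal(0, 1, size=(6, 40))
        fm, g = self.make(vals)
        p = multi_group_test(fm, g)
        # direct between/within sum-of-squares oracle
        groups = [vals[i * 2:(i + 1) * 2] for i in range(3)]
        grand = vals.mean(axis=0)
        ss_b = sum(2 * (grp.mean(axis=0) - grand) ** 2 for grp in groups)
        ss_w = sum(((grp - grp.mean(axis=0)) ** 2).sum(axis=0) for grp in groups)
        f = (ss_b / 2) / (ss_w / 3)
        p_oracle = stats.f.sf(f, 2, 3)
        np.testing.assert_allclose(p, p_oracle, rtol=1e-10)


class TestBhFdr:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_capped(self):
        assert bh_fdr([0.3]).tolist() == [0.3]
        assert bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]
        assert bh_fdr([]).size == 0

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = np.round(rng.random(m), 3)  # ties likely
            q = bh_fdr(p)
            order = np.argsort(p, kind="stable")
            oracle = np.empty(m)
            for rank, i in enumerate(order):
                oracle[i] = min(
                    min(p[j] * m / (r + 1) for r, j in enumerate(order) if r >= rank),
                    1.0,
                )
            np.testing.assert_allclose(q, oracle, rtol=0, atol=0)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), q_sm, rtol=1e-12)

    def test_permutation_equivariance(self, rng):
        p = rng.random(50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestMedianFoldChange:
    def test_ratio_of_group_medians(self):
        ids_a, ids_b, g = two_groups()
        fm = make_matrix(np.array([[1.0], [3.0], [3.0], [5.0]]),
                         sample_ids=ids_a + ids_b)
        assert median_fold_change(fm, g, "met0") == pytest.approx(2.0)

    def test_equal_medians_one(self):
        ids_a, ids_b, g = two_groups()
        fm = make_matrix(np.array([[2.0], [4.0], [1.0], [5.0]]),
                         sample_ids=ids_a + ids_b)
        assert median_fold_change(fm, g, "met0") == pytest.approx(1.0)

    def test_oriented_at_least_one(self, rng):
        ids_a, ids_b, g = two_groups(3, 3)
        fm = make_matrix(rng.lognormal(0, 1, (6, 5)), sample_ids=ids_a + ids_b)
        for met in fm.metabolite_ids:
            assert median_fold_change(fm, g, met) >= 1.0

    def test_zero_median_inf(self):
        ids_a, ids_b, g = two_groups()
        fm = make_matrix(np.array([[0.0], [0.0], [3.0], [5.0]]),
                         sample_ids=ids_a + ids_b)
        assert median_fold_change(fm, g, "met0") == math.inf


class TestSignificanceTable:
    def test_planted_effects_recovered_exactly(self, rng):
        ids_a, ids_b, g = two_groups(4, 4)
        n_planted, n_null = 5, 95
        base = rng.lognormal(3, 0.05, size=(8, n_planted + n_null))
        base[4:, :n_planted] *= 4.0  # 4-fold planted shift, tiny noise
        fm = make_matrix(base, sample_ids=ids_a + ids_b)
        sig = significance_table(fm, g)
        assert sig.significant_ids == fm.metabolite_ids[:n_planted]

    def test_verdict_requires_both_significances(self):
        # q far below alpha but FCMM below 2 -> not significant
        ids_a, ids_b, g = two_groups(4, 4)
        vals = np.array([[1.0], [1.0], [1.001], [1.0],
                         [1.5], [1.5], [1.501], [1.5]])
        fm = make_matrix(vals, sample_ids=ids_a + ids_b)
        sig = significance_table(fm, g)
        row = sig.table.iloc[0]
        assert row.q_value <= 0.05
        assert row.fcmm < 2
        assert not row.significant

    def test_monotone_in_alpha_and_fcmm_min(self, rng):
        ids_a, ids_b, g = two_groups(4, 4)
        vals = rng.lognormal(0, 0.5, size=(8, 60))
        vals[4:, :20] *= rng.uniform(1.5, 5, size=20)
        fm = make_matrix(vals, sample_ids=ids_a + ids_b)
        prev = -1
        for alpha in (0.01, 0.05, 0.2, 1.0):
            n = significance_table(fm, g, alpha=alpha).n_significant
            assert n >= prev
            prev = n
        prev = 10**9
        for fcmm_min in (1.0, 2.0, 4.0, 10.0):
            n = significance_table(fm, g, fcmm_min=fcmm_min).n_significant
            assert n <= prev
            prev = n

    def test_row_order_is_input_metabolite_order(self, rng):
        ids_a, ids_b, g = two_groups()
        fm = make_matrix(rng.lognormal(0, 1, (4, 7)), sample_ids=ids_a + ids_b)
        sig = significance_table(fm, g)
        assert list(sig.table["metabolite_id"]) == fm.metabolite_ids

    def test_null_false_positive_rate_controlled(self, rng):
        # all-null world: combined verdict should rarely fire
        ids_a, ids_b, g = two_groups(4, 4)
        total_fp = 0
        n_sims = 50
        for _ in range(n_sims):
            fm = make_matrix(rng.lognormal(0, 0.2, size=(8, 200)),
                             sample_ids=ids_a + ids_b)
            total_fp += significance_table(fm, g).n_significant
        assert total_fp / (n_sims * 200) <= 0.05
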