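"""Balanced accuracy, stratified folds, nested CV, FDR filter, Wilcoxon test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from easymklfs import evaluation as ev
from easymklfs.io_data import build_grouping
from conftest import make_dataset


class TestBalancedAccuracy:
    def test_perfect_and_constant(self):
        y = np.array([1, 1, -1, -1])
        assert ev.balanced_accuracy(y, y) == 100.0
        assert ev.balanced_accuracy(y, np.ones(4, dtype=int)) == 50.0

    def test_confusion_matrix_worked_example(self):
        # TP=2, FN=1, TN=3, FP=1
        y_true = np.array([1, 1, 1, -1, -1, -1, -1])
        y_pred = np.array([1, 1, -1, -1, -1, -1, 1])
        expected = 100 * (2 / 3 + 3 / 4) / 2
        assert np.isclose(ev.balanced_accuracy(y_true, y_pred), expected)
        assert np.isclose(expected, 70.83, atol=0.005)

    def test_class_swap_invariance(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice([-1, 1], 30)
        y_true[:2] = [1, -1]
        y_pred = rng.choice([-1, 1], 30)
        assert np.isclose(
            ev.balanced_accuracy(y_true, y_pred),
            ev.balanced_accuracy(-y_true, -y_pred),
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ev.balanced_accuracy(np.array([1, 1]), np.array([1, -1]))


class TestStratifiedFolds:
    def test_fold_sizes_balanced(self):
        y = np.array([1] * 30 + [-1] * 30)
        folds = ev.stratified_folds(y, None, 10, seed=0)
        for f in range(10):
            assert np.sum(folds == f) == 6
            assert np.sum((folds == f) & (y > 0)) == 3

    def test_deterministic_given_seed(self):
        y = np.array([1] * 20 + [-1] * 25)
        age = np.random.default_rng(1).normal(60, 10, 45)
        a = ev.stratified_folds(y, age, 5, seed=42)
        b = ev.stratified_folds(y, age, 5, seed=42)
        assert np.array_equal(a, b)

    def test_age_matching_of_fold_means(self):
        """Dealing sorted-by-age subjects round-robin keeps per-fold age
        means within half a within-class sd of the global mean."""
        rng = np.random.default_rng(7)
        y = np.array([1] * 100 + [-1] * 100)
        age = rng.normal(65, 8, 200)
        folds = ev.stratified_folds(y, age, 10, seed=3)
        sd = age.std()
        for f in range(10):
            assert abs(age[folds == f].mean() - age.mean()) < 0.5 * sd

    def test_k_larger_than_class_rejected(self):
        y = np.array([1, 1, -1, -1, -1])
        with pytest.raises(ValueError, match="class size"):
            ev.stratified_folds(y, None, 3, seed=0)


@pytest.fixture(scope="module")
def cv_dataset():
    rng = np.random.default_rng(21)
    n = 40
    y = np.array([1] * 20 + [-1] * 20)
    X = rng.standard_normal((n, 30))
    X[:, 0] += y * 1.5
    X[:, 25] += y * 1.2  # clinical block signal
    age = rng.normal(60, 8, n)
    return make_dataset(X, y, n_image_cols=24, age=age)


SMALL_GRIDS = {"lam": [0.5, 1.0], "rho": [0.0, 0.05], "C": [1.0]}


class TestNestedCV:
    def test_fold_row_count(self, cv_dataset):
        plan = ev.make_cv_plan(cv_dataset.y, cv_dataset.age,
                               n_repeats=2, n_outer=5, n_inner=4, seed=5)
        res = ev.nested_cv(cv_dataset, "easymklfs", SMALL_GRIDS, plan)
        assert len(res.per_fold_scores) == 10
        assert len(res.chosen_hyperparams) == 10
        assert res.per_subject_predictions.shape == (2, 40)

    def test_deterministic_rerun(self, cv_dataset):
        plan = ev.make_cv_plan(cv_dataset.y, cv_dataset.age,
                               n_repeats=1, n_outer=5, n_inner=4, seed=5)
        a = ev.nested_cv(cv_dataset, "easymklfs", SMALL_GRIDS, plan)
        b = ev.nested_cv(cv_dataset, "easymklfs", SMALL_GRIDS, plan)
        assert np.array_equal(a.per_fold_scores, b.per_fold_scores)
        assert a.chosen_hyperparams == b.chosen_hyperparams

    def test_outer_test_rows_cannot_leak(self, cv_dataset):
        """Corrupting held-out rows must leave the outer-train fit (chosen
        hyperparameters and model) unchanged."""
        ds = cv_dataset
        grouping = build_grouping(ds, "V_and_C")
        tr = np.arange(8, 40)
        grids = dict(SMALL_GRIDS, _n_inner=4)
        params1, _, mdl1 = ev._outer_fold_fit(ds, "easymklfs", grouping,
                                              grids, tr, inner_seed=9)
        X2 = ds.X.copy()
        X2[:8] = 1e6 * np.sign(X2[:8]) + ds.y[:8, None]  # poison held-out rows
        ds2 = make_dataset(X2, ds.y, n_image_cols=24, age=ds.age)
        params2, _, mdl2 = ev._outer_fold_fit(ds2, "easymklfs", grouping,
                                              grids, tr, inner_seed=9)
        assert params1 == params2
        assert np.array_equal(mdl1.selected_columns, mdl2.selected_columns)
        assert np.allclose(mdl1.dual_coef, mdl2.dual_coef)

    def test_constant_method_scores_fifty(self, cv_dataset):
        """A degenerate dataset where predictions are constant: balanced
        accuracy of every fold is 50."""
        X = np.ones((40, 6))  # identical subjects: decision is constant
        y = np.array([1] * 12 + [-1] * 28)
        ds = make_dataset(X, y, n_image_cols=4)
        plan = ev.make_cv_plan(ds.y, None, n_repeats=1, n_outer=4,
                               n_inner=3, seed=2)
        res = ev.nested_cv(ds, "svm", {"C": [1.0]}, plan, family_code="I_plus_C")
        assert np.allclose(res.per_fold_scores, 50.0)

    def test_grid_tie_break_is_first_point(self, cv_dataset):
        plan = ev.make_cv_plan(cv_dataset.y, cv_dataset.age,
                               n_repeats=1, n_outer=4, n_inner=3, seed=8)
        res = ev.nested_cv(
            cv_dataset, "svm", {"C": [1.0, 1.0 + 1e-15]}, plan,
            family_code="I_plus_C",
        )
        assert all(p["C"] == 1.0 for p in res.chosen_hyperparams)

    def test_baseline_methods_run(self, cv_dataset):
        plan = ev.make_cv_plan(cv_dataset.y, cv_dataset.age,
                               n_repeats=1, n_outer=4, n_inner=3, seed=3)
        for method, grids, fam in [
            ("svm_ttest", {"C": [1.0], "n_features": [2, 10]}, "V_and_C"),
            ("svm_rfe", {"C": [1.0], "n_features": [2, 10]}, "V_and_C"),
            ("easymkl", {"lam": [1.0], "C": [1.0]}, "V_and_C"),
        ]:
            res = ev.nested_cv(cv_dataset, method, grids, plan, family_code=fam)
            assert len(res.per_fold_scores) == 4
            assert np.all((res.per_fold_scores >= 0)
                          & (res.per_fold_scores <= 100))

    def test_infold_prefilter_removes_label_column(self):
        rng = np.random.default_rng(4)
        y = np.array([1] * 20 + [-1] * 20)
        X = rng.standard_normal((40, 10))
        X[:, 8] = y  # circular clinical feature
        ds = make_dataset(X, y, n_image_cols=6)
        plan = ev.make_cv_plan(y, None, n_repeats=1, n_outer=4, n_inner=3, seed=1)
        res = ev.nested_cv(ds, "svm", {"C": [1.0]}, plan,
                           family_code="I_plus_C", infold_prefilter_alpha=0.01)
        assert len(res.per_fold_scores) == 4


class TestBHAdjust:
    def test_worked_example(self):
        adj = ev.bh_adjust([0.001, 0.02, 0.03, 0.8])
        assert np.allclose(adj, [0.004, 0.04, 0.04, 0.8])

    def test_all_ones_and_singleton(self):
        assert np.allclose(ev.bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert np.allclose(ev.bh_adjust([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ev.bh_adjust([0.5, 1.2])

    @pytest.mark.parametrize("seed", range(4))
    def test_step_up_matches_brute_force(self, seed):
        """BH rejections at level q agree with the step-up definition:
        reject the largest i with p_(i) <= i q / m."""
        rng = np.random.default_rng(seed)
        p = np.round(rng.random(rng.integers(2, 10)), 3)
        adj = ev.bh_adjust(p)
        for q in (0.01, 0.05, 0.1, 0.25):
            order = np.argsort(p, kind="stable")
            ps = p[order]
            m = len(p)
            ks = [i + 1 for i in range(m) if ps[i] <= (i + 1) * q / m]
            k = max(ks) if ks else 0
            rejected_brute = set(order[:k].tolist())
            rejected_adj = set(np.flatnonzero(adj <= q).tolist())
            assert rejected_adj == rejected_brute


class TestFdrPrefilter:
    def test_label_coded_column_excluded(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 15 + [-1] * 15)
        block = rng.standard_normal((30, 5))
        block[:, 2] = y.astype(float)
        retained = ev.fdr_prefilter(block, y, alpha=0.01)
        assert 2 not in retained.tolist()
        assert len(retained) == 4

    def test_null_columns_nearly_all_retained(self):
        """Under the null the expected number of FDR exclusions is < 1."""
        excluded = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.array([1] * 100 + [-1] * 100)
            block = rng.standard_normal((200, 30))
            retained = ev.fdr_prefilter(block, y, alpha=0.01)
            excluded += 30 - len(retained)
        assert excluded / 10 < 1

    def test_empty_block(self):
        assert ev.fdr_prefilter(np.empty((10, 0)), np.ones(10)).size == 0


class TestWilcoxon:
    def test_all_positive_differences(self):
        w, p = ev.wilcoxon_signed_rank([2, 3, 4], [1, 1, 1])
        assert w == 6.0
        assert np.isclose(p, 0.25)  # 2 * P(W+ >= 6) = 2/8

    def test_symmetric_differences_p_one(self):
        _, p = ev.wilcoxon_signed_rank([1, -1, 2, -2], [0, 0, 0, 0])
        assert p == 1.0

    def test_zero_differences_dropped(self):
        w, p = ev.wilcoxon_signed_rank([1, 5, 5], [0, 5, 5])
        assert w == 1.0 and np.isclose(p, 1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="no information"):
            ev.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_full_enumeration(self, seed):
        """Exact p equals brute-force enumeration over all sign patterns."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        d = np.round(rng.normal(0.3, 1.0, n), 2)
        d = d[d != 0]
        w_obs, p = ev.wilcoxon_signed_rank(d, np.zeros_like(d))
        ranks = stats.rankdata(np.abs(d))
        ws = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=len(d))
        ]
        ws = np.array(ws)
        p_brute = min(
            1.0,
            2 * min(np.mean(ws <= w_obs + 1e-12), np.mean(ws >= w_obs - 1e-12)),
        )
        assert np.isclose(p, p_brute)

    def test_matches_scipy_on_tie_free_case(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.5, 1, 10)
        b = rng.normal(0.0, 1, 10)
        _, p = ev.wilcoxon_signed_rank(a, b)
        p_scipy = stats.wilcoxon(a, b, method="exact").pvalue
        assert np.isclose(p, p_scipy)

    def test_large_n_approximation_close_to_exact(self):
        """Normal approximation at n=25 sanity-checked against the exact
        path on an n=12 subsample."""
        rng = np.random.default_rng(9)
        a = rng.normal(0.4, 1, 25)
        b = rng.normal(0.0, 1, 25)
        _, p_approx = ev.wilcoxon_signed_rank(a, b)
        assert 0.0 <= p_approx <= 1.0
        _, p_exact = ev.wilcoxon_signed_rank(a[:12], b[:12])
        p_scipy = stats.wilcoxon(
            a[:12], b[:12], method="approx", correction=True
        ).pvalue
        assert abs(p_exact - p_scipy) < 0.02


class TestBonferroni:
    def test_eight_comparisons(self):
        assert ev.bonferroni_threshold(0.05, 8) == 0.00625

    def test_identity_and_division(self):
        assert ev.bonferroni_threshold(0.05, 1) == 0.05
        assert ev.bonferroni_threshold(0.01, 4) == 0.0025

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            ev.bonferroni_threshold(0.05, 0)
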