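import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metapeak import preprocess as prep
from metapeak import stats as mstats
from metapeak.synthetic import simulate_peak_table

from conftest import make_meta, make_peak_table


def brute_force_bh(p):
    """Direct min-over-tail step-up definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        tail = [p[order[j]] * m / (j + 1) for j in range(rank_pos - 1, m)]
        q[idx] = min(1.0, min(tail))
    return q


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            mstats.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert mstats.bh_adjust([0.37])[0] == pytest.approx(0.37)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force(self, pvals):
        np.testing.assert_allclose(mstats.bh_adjust(pvals), brute_force_bh(pvals), atol=1e-12)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            mstats.bh_adjust([0.5, 1.5])

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 200)
        q = mstats.bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestAUC:
    def test_worked_examples(self):
        assert mstats.univariate_auc([0.9, 0.8], [0.1, 0.2]) == 1.0
        assert mstats.univariate_auc([1.0, 1.0], [1.0, 1.0]) == 0.5
        assert mstats.univariate_auc([3, 1], [2, 0]) == 0.75

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(1, 1, 9), rng.normal(0, 1, 7)
        assert mstats.univariate_auc(a, b) == pytest.approx(1 - mstats.univariate_auc(b, a))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        a, b = rng.lognormal(1, 1, 8), rng.lognormal(0.5, 1, 11)
        base = mstats.univariate_auc(a, b)
        for f in (np.log, np.sqrt, lambda x: 3 * x + 7):
            assert mstats.univariate_auc(f(a), f(b)) == pytest.approx(base)


class TestUnivariateTests:
    @staticmethod
    def _pt_meta(case_rows, control_rows):
        values = np.array([np.concatenate([c, k]) for c, k in zip(case_rows, control_rows)], dtype=float)
        n1, n2 = len(case_rows[0]), len(control_rows[0])
        pt = make_peak_table(values)
        meta = make_meta(pt.sample_ids, ["case"] * n1 + ["control"] * n2)
        return pt, meta

    def test_identical_groups_give_p_one(self):
        pt, meta = self._pt_meta([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
        res = mstats.univariate_tests(pt, meta, "case", "control", compute_vip=False)
        assert res.table["p_t"][0] == pytest.approx(1.0)

    def test_mann_whitney_exact_small_sample(self):
        pt, meta = self._pt_meta([[1.0, 2.0]], [[3.0, 4.0]])
        res = mstats.univariate_tests(pt, meta, "case", "control", compute_vip=False)
        assert res.table["p_wilcox"][0] == pytest.approx(1 / 3)

    def test_fold_change_direction(self):
        pt, meta = self._pt_meta([[3.0, 4.0, 5.0]], [[1.0, 2.0, 3.0]])
        res = mstats.univariate_tests(pt, meta, "case", "control", compute_vip=False)
        assert res.table["fold_change"][0] == pytest.approx(2.0)

    def test_missing_group_label_errors(self, sim_small):
        pt, meta, _ = sim_small
        with pytest.raises(ValueError, match="nothere"):
            mstats.univariate_tests(pt, meta, "case", "nothere", compute_vip=False)

    def test_untestable_feature_marked_nan(self):
        pt, meta = self._pt_meta([[1.0, np.nan, np.nan]], [[1.0, 2.0, 3.0]])
        res = mstats.univariate_tests(pt, meta, "case", "control", compute_vip=False)
        assert np.isnan(res.table["p_t"][0])


class TestSelectDef:
    def _result(self, q, fc, vip):
        import pandas as pd

        table = pd.DataFrame(
            {"feature": ["f"], "p_t": [q], "p_wilcox": [q], "q_t": [q],
             "q_wilcox": [q], "fold_change": [fc], "auc": [0.5], "vip": [vip]}
        )
        return mstats.UnivariateResult(table, "a", "b")

    def test_rule_combinations(self):
        assert mstats.select_def(self._result(0.04, 2.0, 1.2)) == ["f"]
        assert mstats.select_def(self._result(0.04, 1.2, 1.2)) == []
        assert mstats.select_def(self._result(0.2, 2.0, 1.2)) == []
        assert mstats.select_def(self._result(0.04, 2.0, 0.5)) == []

    def test_low_fold_change_boundary(self):
        # FC = 2/3 passes the <= 1/1.5 arm exactly
        assert mstats.select_def(self._result(0.01, 2.0 / 3.0, 1.5)) == ["f"]


class TestPCA:
    def test_single_axis_of_variance(self):
        values = np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]])
        model = mstats.pca_fit(make_peak_table(values), n_components=2)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_scores_orthogonal_and_reconstruction(self):
        rng = np.random.default_rng(3)
        pt = make_peak_table(rng.lognormal(3, 1, (6, 10)))
        k = min(6, 10)
        model = mstats.pca_fit(pt, n_components=6)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        X = pt.values.T
        recon = X.mean(axis=0) + model.scores @ model.loadings.T
        np.testing.assert_allclose(recon, X, rtol=1e-8)

    def test_too_many_components_errors(self):
        pt = make_peak_table(np.ones((3, 4)) + np.eye(3, 4))
        with pytest.raises(ValueError):
            mstats.pca_fit(pt, n_components=5)


def _separable_data(n=40, p=12, effect=5.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (p, n))
    X[0, : n // 2] += effect
    pt = make_peak_table(X - X.min() + 1.0)
    meta = make_meta(pt.sample_ids, ["case"] * (n // 2) + ["control"] * (n // 2))
    return pt, meta


class TestPLSDA:
    def test_strong_single_feature_gives_high_q2(self):
        # a single informative feature at separation d caps Q2Y near
        # (d/2)^2 / ((d/2)^2 + 1); d = 8 leaves headroom above 0.9
        pt, meta = _separable_data(effect=8.0)
        model = mstats.plsda_fit(pt, meta, seed=1)
        assert model.q2y > 0.9
        assert model.r2y >= model.q2y

    def test_vip_identity_holds(self):
        pt, meta = _separable_data(seed=4)
        model = mstats.plsda_fit(pt, meta, seed=1)
        assert float(np.mean(model.vip**2)) == pytest.approx(1.0, abs=1e-8)

    def test_equal_weight_two_features_vip_one(self):
        # one component, two identical informative features: VIP = (1, 1)
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 20)
        y_pattern = np.array([1.0] * 10 + [-1.0] * 10)
        X = np.vstack([y_pattern + 0.01 * base, y_pattern + 0.01 * base])
        pt = make_peak_table(X + 10.0)
        meta = make_meta(pt.sample_ids, ["a"] * 10 + ["b"] * 10)
        model = mstats.plsda_fit(pt, meta, n_components=1, seed=1)
        np.testing.assert_allclose(model.vip, [1.0, 1.0], atol=1e-10)

    def test_matches_sklearn_pls_regression_fit(self):
        # independent cross-check of the NIPALS core against sklearn
        from sklearn.cross_decomposition import PLSRegression

        pt, meta = _separable_data(seed=6)
        model = mstats.plsda_fit(pt, meta, n_components=2, seed=1)
        X = pt.values.T
        y = np.array([1.0] * 20 + [-1.0] * 20)
        sk = PLSRegression(n_components=2, scale=False).fit(X, y)
        yhat_sk = sk.predict(X).ravel()
        Xc = X - X.mean(axis=0)
        from metapeak.stats import _nipals_pls1, _pls1_predict

        T, W, P, q = _nipals_pls1(Xc, y - y.mean(), 2)
        yhat = _pls1_predict(Xc, W, P, q) + y.mean()
        np.testing.assert_allclose(yhat, yhat_sk, atol=1e-8)

    def test_three_groups_rejected(self):
        pt, meta = _separable_data()
        bad = make_meta(pt.sample_ids, ["a"] * 14 + ["b"] * 13 + ["c"] * 13)
        with pytest.raises(ValueError):
            mstats.plsda_fit(pt, bad, case="a", control="b")


class TestOPLSDA:
    def test_no_orthogonal_structure_matches_pls1(self):
        # pure predictive structure: OPLS predictive component == PLS-1 within sign
        rng = np.random.default_rng(7)
        y_pattern = np.array([1.0] * 12 + [-1.0] * 12)
        X = np.outer(rng.normal(1, 0.2, 8), y_pattern) + rng.normal(0, 1e-6, (8, 24))
        pt = make_peak_table(X + 20.0)
        meta = make_meta(pt.sample_ids, ["a"] * 12 + ["b"] * 12)
        opls = mstats.oplsda_fit(pt, meta, n_orthogonal=1, seed=1)
        pls = mstats.plsda_fit(pt, meta, n_components=1, seed=1)
        t_o, t_p = opls.scores[:, 0], pls.scores[:, 0]
        cos = abs(t_o @ t_p) / (np.linalg.norm(t_o) * np.linalg.norm(t_p))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_orthogonal_scores_uncorrelated_with_response(self):
        pt, meta = _separable_data(seed=8)
        model = mstats.oplsda_fit(pt, meta, n_orthogonal=1, seed=1)
        y = np.array([1.0] * 20 + [-1.0] * 20)
        yc = y - y.mean()
        t_orth = model.orthogonal_scores[:, 0]
        r = abs(t_orth @ yc) / (np.linalg.norm(t_orth) * np.linalg.norm(yc))
        assert r < 1e-8

    def test_seeded_q2_reproducible(self):
        pt, meta = _separable_data(seed=9)
        a = mstats.oplsda_fit(pt, meta, seed=5).q2y
        b = mstats.oplsda_fit(pt, meta, seed=5).q2y
        assert a == b


class TestPermutationTest:
    def test_minimum_attainable_p(self):
        pt, meta = _separable_data(n=20, seed=10)
        p = mstats.permutation_test(pt, meta, "plsda", n_perm=19, seed=2)
        assert p >= 1 / 20
        assert mstats.permutation_test(pt, meta, "plsda", n_perm=19, seed=2) == p

    def test_strong_effect_is_significant(self):
        pt, meta = _separable_data(n=30, effect=5.0, seed=11)
        p = mstats.permutation_test(pt, meta, "plsda", n_perm=99, seed=3)
        assert p <= 0.05

    def test_invalid_inputs(self):
        pt, meta = _separable_data(n=20, seed=12)
        with pytest.raises(ValueError):
            mstats.permutation_test(pt, meta, "plsda", n_perm=0)
        with pytest.raises(ValueError):
            mstats.permutation_test(pt, meta, "magic", n_perm=10)


class TestEstimatePower:
    def test_null_statistics_give_alpha(self):
        rng = np.random.default_rng(13)
        t = rng.standard_t(38, size=2000)  # null t statistics at pilot n=20/20
        curve = mstats.estimate_power(t, n_grid=[10, 20, 40], alpha=0.05)
        assert curve.pi0 > 0.9
        # most runs estimate pi0 = 1 and report exactly alpha; allow tiny slack
        np.testing.assert_allclose(curve.table["estimated_power"], 0.05, atol=0.01)

    def test_single_effect_matches_noncentral_t(self):
        from scipy import stats as sps

        # pilot statistic corresponding to d = 1 at n = 20 per group
        t_obs = 1.0 / np.sqrt(1 / 20 + 1 / 20)
        curve = mstats.estimate_power([t_obs], n_grid=[20], alpha=0.05)
        ncp = 1.0 * np.sqrt(20 / 2)
        tcrit = sps.t.ppf(0.975, 38)
        closed_form = 1 - sps.nct.cdf(tcrit, 38, ncp) + sps.nct.cdf(-tcrit, 38, ncp)
        assert closed_form == pytest.approx(0.869, abs=0.005)
        assert curve.table["estimated_power"][0] == pytest.approx(closed_form, abs=1e-9)

    def test_power_nondecreasing_in_n(self):
        rng = np.random.default_rng(14)
        t = np.concatenate([rng.standard_t(38, 100), rng.normal(4, 1, 30)])
        curve = mstats.estimate_power(t, n_grid=[5, 10, 20, 40, 80])
        assert np.all(np.diff(curve.table["estimated_power"]) >= -1e-12)

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            mstats.estimate_power([1.0], n_grid=[])
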