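import numpy as np
import pytest

from metapeak import normalize as norm
from metapeak.normalize import _qc_cv
from metapeak.synthetic import simulate_peak_table

from conftest import make_meta, make_peak_table


class TestSampleNormalization:
    def test_sum_hand_example(self):
        # totals 6 and 12, median 9: both samples land on (1.5, 3, 4.5)
        pt = make_peak_table(np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]]))
        out = norm.normalize_samples(pt, method="sum")
        np.testing.assert_allclose(out.values[:, 0], [1.5, 3.0, 4.5])
        np.testing.assert_allclose(out.values[:, 1], [1.5, 3.0, 4.5])

    def test_sum_equalizes_totals(self):
        rng = np.random.default_rng(1)
        pt = make_peak_table(rng.lognormal(3, 1, (30, 8)))
        out = norm.normalize_samples(pt, method="sum")
        totals = out.values.sum(axis=0)
        np.testing.assert_allclose(totals, totals[0], rtol=1e-9)

    def test_pqn_hand_example(self):
        # all-sample median reference (1.5, 3, 4.5); constant quotients per sample
        pt = make_peak_table(np.array([[2.0, 1.0], [4.0, 2.0], [6.0, 3.0]]))
        out = norm.normalize_samples(pt, method="pqn")
        np.testing.assert_allclose(out.values[:, 0], [1.5, 3.0, 4.5])
        np.testing.assert_allclose(out.values[:, 1], [1.5, 3.0, 4.5])

    def test_pqn_recovers_reference_from_scalar_multiples(self):
        rng = np.random.default_rng(2)
        ref = rng.lognormal(3, 0.5, 25)
        dilutions = np.array([0.5, 1.0, 2.0, 3.5])
        values = np.outer(ref, dilutions)
        pt = make_peak_table(values)
        out = norm.normalize_samples(pt, method="pqn")
        reference = np.median(values, axis=1)
        for j in range(4):
            np.testing.assert_allclose(out.values[:, j], reference, rtol=1e-10)

    def test_quantile_hand_example(self):
        pt = make_peak_table(np.array([[2.0, 8.0], [4.0, 6.0]]))
        out = norm.normalize_samples(pt, method="quantile")
        np.testing.assert_allclose(out.values[:, 0], [4.0, 6.0])
        np.testing.assert_allclose(out.values[:, 1], [6.0, 4.0])

    def test_quantile_sorted_vectors_identical_and_idempotent(self):
        rng = np.random.default_rng(3)
        pt = make_peak_table(rng.lognormal(3, 1, (40, 6)))
        once = norm.normalize_samples(pt, method="quantile")
        sorted_cols = np.sort(once.values, axis=0)
        for j in range(1, 6):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])
        twice = norm.normalize_samples(once, method="quantile")
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)

    def test_mask_and_shape_preserved(self):
        rng = np.random.default_rng(4)
        values = rng.lognormal(3, 1, (20, 6))
        mask = rng.random((20, 6)) < 0.2
        pt = make_peak_table(np.where(mask, np.nan, values), mask=mask)
        for method in ("sum", "pqn", "quantile"):
            out = norm.normalize_samples(pt, method=method)
            assert out.values.shape == pt.values.shape
            np.testing.assert_array_equal(out.mask, pt.mask)

    def test_vsn_reserved_and_errors(self):
        pt = make_peak_table([[1.0, 2.0]])
        with pytest.raises(NotImplementedError):
            norm.normalize_samples(pt, method="vsn")
        with pytest.raises(ValueError, match="unknown"):
            norm.normalize_samples(pt, method="median")
        allmiss = make_peak_table([[np.nan, 2.0]])
        with pytest.raises(ValueError, match="no observed"):
            norm.normalize_samples(allmiss, method="sum")


class TestDriftCorrection:
    @staticmethod
    def _flat_qc_table(n_qc=6, n_bio=10, seed=0):
        rng = np.random.default_rng(seed)
        n = n_qc + n_bio
        ids = [f"q{i}" for i in range(n_qc)] + [f"s{i}" for i in range(n_bio)]
        classes = [None] * n_qc + ["g"] * n_bio
        # interleave QC orders through the run
        orders = list(range(1, n + 1))
        values = np.tile(rng.lognormal(3, 0.5, 8)[:, None], (1, n))
        pt = make_peak_table(values, feature_ids=[f"f{i}" for i in range(8)], sample_ids=ids)
        return pt, make_meta(ids, classes, orders=orders)

    def test_qcrsc_flat_qc_signal_is_identity(self):
        pt, meta = self._flat_qc_table()
        out = norm.qcrsc_correct(pt, meta)
        np.testing.assert_allclose(out.values, pt.values, rtol=1e-8)

    def test_svr_flat_qc_signal_is_identity(self):
        pt, meta = self._flat_qc_table()
        out = norm.svr_correct(pt, meta)
        np.testing.assert_allclose(out.values, pt.values, rtol=1e-8)

    def test_qcrsc_reduces_qc_cv_under_linear_drift(self, sim_drift):
        pt, meta, _ = sim_drift
        is_qc = meta.qc_mask(pt.sample_ids)
        pre = _qc_cv(pt, is_qc)
        post = _qc_cv(norm.qcrsc_correct(pt, meta), is_qc)
        assert np.median(post) < np.median(pre)
        assert np.mean(post < pre) >= 0.95

    def test_svr_reduces_qc_cv_under_linear_drift(self, sim_drift):
        pt, meta, _ = sim_drift
        is_qc = meta.qc_mask(pt.sample_ids)
        pre = _qc_cv(pt, is_qc)
        post = _qc_cv(norm.svr_correct(pt, meta), is_qc)
        assert np.median(post) < np.median(pre)
        assert np.mean(post < pre) >= 0.95

    def test_svr_is_deterministic(self, sim_drift):
        pt, meta, _ = sim_drift
        a = norm.svr_correct(pt, meta)
        b = norm.svr_correct(pt, meta)
        np.testing.assert_array_equal(a.values, b.values)

    def test_fallback_when_too_few_qcs(self):
        pt, meta = self._flat_qc_table(n_qc=3)
        with pytest.warns(UserWarning, match="fallback"):
            out = norm.qcrsc_correct(pt, meta, min_qc=4)
        # flat signal: median scaling is still an identity here
        np.testing.assert_allclose(out.values, pt.values, rtol=1e-8)

    def test_no_qcs_at_all_errors(self):
        pt = make_peak_table([[1.0, 2.0, 1.5, 2.5]])
        meta = make_meta(pt.sample_ids, ["g"] * 4)
        with pytest.raises(ValueError, match="QC"):
            norm.qcrsc_correct(pt, meta)
        with pytest.raises(ValueError, match="QC"):
            norm.svr_correct(pt, meta)


class TestCombat:
    @staticmethod
    def _offset_batches(offset=1.2, n_per_batch=8, n_feat=12, seed=5):
        rng = np.random.default_rng(seed)
        mu = rng.normal(8, 1, n_feat)
        pattern = rng.normal(0, 0.4, n_per_batch)
        pattern -= pattern.mean()
        # every feature shares the within-batch sample pattern, so the
        # standardized batch effects are identical across features and the
        # EB posterior removes the offset exactly
        log_b1 = mu[:, None] + pattern[None, :]
        log_b2 = mu[:, None] + pattern[None, :] + offset
        values = np.exp(np.concatenate([log_b1, log_b2], axis=1))
        ids = [f"s{i}" for i in range(2 * n_per_batch)]
        pt = make_peak_table(values, sample_ids=ids)
        classes = (["a"] * (n_per_batch // 2) + ["b"] * (n_per_batch - n_per_batch // 2)) * 2
        batches = ["1"] * n_per_batch + ["2"] * n_per_batch
        return pt, make_meta(ids, classes, batches=batches)

    def test_constant_offset_removed(self):
        pt, meta = self._offset_batches()
        out = norm.combat_correct(pt, meta)
        L = np.log(out.values)
        m1 = L[:, :8].mean(axis=1)
        m2 = L[:, 8:].mean(axis=1)
        np.testing.assert_allclose(m1, m2, rtol=1e-6)

    def test_single_batch_is_identity_with_warning(self):
        pt = make_peak_table(np.abs(np.random.default_rng(0).normal(5, 1, (4, 6))))
        meta = make_meta(pt.sample_ids, ["a", "a", "a", "b", "b", "b"])
        with pytest.warns(UserWarning, match="single batch"):
            out = norm.combat_correct(pt, meta)
        np.testing.assert_array_equal(out.values, pt.values)

    def test_batch_label_invariance(self):
        pt, meta = self._offset_batches()
        out1 = norm.combat_correct(pt, meta)
        # permute sample columns and metadata rows identically
        perm = np.random.default_rng(9).permutation(pt.n_samples)
        pt2 = pt.select_samples(perm)
        out2 = norm.combat_correct(pt2, meta)
        np.testing.assert_allclose(out2.values, out1.select_samples(perm).values, rtol=1e-10)

    def test_removes_most_between_batch_variance(self):
        pt, meta, _ = simulate_peak_table(
            n_features=150, n_case=15, n_control=15, n_batches=2, qc_every=6,
            drift="none", batch_sd=0.5, n_diff=0, mnar_strength=0.0,
            noise_sd=0.1, seed=21,
        )
        batches = meta.batches(pt.sample_ids)
        out = norm.combat_correct(pt, meta)

        def between_var(table):
            L = np.log(table.values)
            means = np.stack([L[:, batches == b].mean(axis=1) for b in ("1", "2")], axis=1)
            return means.var(axis=1, ddof=1)

        reduction = 1.0 - between_var(out).sum() / between_var(pt).sum()
        assert reduction >= 0.95


class TestCvFilter:
    def test_high_cv_feature_removed(self, two_group_meta):
        values = np.ones((2, 14))
        values[0, 10:] = [1.0, 2.0, 3.0, 2.0]   # QC CV well above 0.3
        values[1, 10:] = [1.0, 1.01, 0.99, 1.0]
        pt = make_peak_table(values, sample_ids=list(two_group_meta.table["sample"]))
        out = norm.cv_filter(pt, two_group_meta, cv_max=0.30)
        assert list(out.feature_ids) == ["f2"]

    def test_boundary_cv_is_kept(self):
        # construct QC values with CV exactly 0.30
        qc = np.array([1.0 - 0.3 * np.sqrt(0.5), 1.0, 1.0 + 0.3 * np.sqrt(0.5)])
        qc = qc / qc.mean()
        values = np.concatenate([[5.0, 5.0], qc])[None, :]
        pt = make_peak_table(values, sample_ids=["s1", "s2", "q1", "q2", "q3"])
        meta = make_meta(pt.sample_ids, ["g", "g", None, None, None])
        from metapeak.qc_metrics import compute_cv

        assert compute_cv(qc) <= 0.30 + 1e-12
        out = norm.cv_filter(pt, meta, cv_max=compute_cv(qc))
        assert out.n_features == 1

    def test_infinite_threshold_is_identity(self, two_group_meta):
        rng = np.random.default_rng(6)
        pt = make_peak_table(
            rng.lognormal(3, 1, (10, 14)), sample_ids=list(two_group_meta.table["sample"])
        )
        out = norm.cv_filter(pt, two_group_meta, cv_max=np.inf)
        assert out.n_features == 10


class TestCompareNormalizations:
    def test_none_on_drift_free_data_retains_most_peaks(self, sim_small):
        pt, meta, _ = sim_small
        comparison = norm.compare_normalizations(pt, meta, methods=["none"], seed=1)
        row = comparison.table.set_index("method").loc["none"]
        assert row["n_peaks_cv_le"] >= 0.95 * row["n_peaks"]

    def test_drift_correction_beats_none(self, sim_drift):
        pt, meta, _ = sim_drift
        comparison = norm.compare_normalizations(pt, meta, methods=["qcrsc", "svr"], seed=1)
        t = comparison.table.set_index("method")
        for m in ("qcrsc", "svr"):
            assert t.loc[m, "n_peaks_cv_le"] >= t.loc["none", "n_peaks_cv_le"]
            assert t.loc[m, "mean_cv_qc"] < t.loc["none", "mean_cv_qc"]

    def test_unknown_method_lists_valid_names(self, sim_small):
        pt, meta, _ = sim_small
        with pytest.raises(ValueError, match="pqn"):
            norm.compare_normalizations(pt, meta, methods=["bogus"], seed=1)
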