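"""Anomaly scores, ROC/Youden analysis, fidelity grouping, CV aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vqsvdd.errors import ConfigurationError, DimensionError
from vqsvdd.evaluation import (FoldMetrics, SliceScore, anomaly_score,
                               evaluate_cv, fidelity_comparison, paired_t,
                               representative_score, roc_auc,
                               youden_threshold)
from vqsvdd.phantom import (AnomalySpec, PhantomConfig,
                            generate_normal_volume, inject_anomaly)


def _score(total, case="c", idx=0):
    return SliceScore(case_id=case, slice_index=idx, recon_term=total, svdd_term=0.0)


class TestAnomalyScore:
    def test_zero_at_perfect_reconstruction_on_center(self, rng):
        x = rng.random((8, 8))
        z = rng.normal(0, 1, 16)
        s = anomaly_score(x, x, z, z)
        assert s.total == 0.0 and s.recon_term == 0.0 and s.svdd_term == 0.0

    def test_total_is_sum_of_terms(self):
        s = SliceScore("c", 0, recon_term=0.25, svdd_term=0.75)
        assert s.total == pytest.approx(1.0)

    def test_single_pixel_increase_raises_score(self, rng):
        x = rng.random((8, 8))
        xhat = x.copy()
        z = np.zeros(4)
        s0 = anomaly_score(x, xhat, z, z)
        xhat[3, 3] += 0.2
        s1 = anomaly_score(x, xhat, z, z)
        assert s1.total > s0.total

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(DimensionError):
            anomaly_score(rng.random((4, 4)), rng.random((5, 5)),
                          np.zeros(2), np.zeros(2))

    def test_svdd_weight_scales_distance_term(self, rng):
        x = rng.random((4, 4))
        z, c = np.ones(3), np.zeros(3)
        s = anomaly_score(x, x, z, c, svdd_weight=0.5)
        assert s.svdd_term == pytest.approx(1.5)


class TestRepresentativeScore:
    def test_max_and_order_invariance(self):
        scores = [_score(v, idx=i) for i, v in enumerate([0.1, 0.9, 0.4])]
        assert representative_score(scores) == pytest.approx(0.9)
        assert representative_score(scores[::-1]) == pytest.approx(0.9)
        assert representative_score([_score(0.3)]) == pytest.approx(0.3)

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            representative_score([])


class TestRocAuc:
    def test_perfect_separation_and_inversion(self):
        assert roc_auc([0.1, 0.2, 0.9], [False, False, True])[0] == 1.0
        assert roc_auc([0.9, 0.2, 0.1], [False, False, True])[0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_mann_whitney_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(20), 1)      # force some ties
        labels = rng.random(20) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        auc, _ = roc_auc(scores, labels)
        pos, neg = scores[labels], scores[~labels]
        conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(0, 1, 15)
        labels = rng.random(15) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.exp(2.0 * scores) + 3.0, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            roc_auc([0.1, 0.2], [True, True])


class TestYoudenThreshold:
    def test_separable_case(self):
        thr, sens, spec, acc = youden_threshold(
            [1.0, 2.0, 3.0, 4.0], [False, False, True, True])
        assert 2.0 < thr < 3.0
        assert (sens, spec, acc) == (1.0, 1.0, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(0, 1, 30)
        labels = rng.random(30) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        thr, sens, spec, _ = youden_threshold(scores, labels)
        j = sens + spec - 1.0
        # oracle: every offset cut over a fine sweep of candidate values
        best = -np.inf
        for cut in np.concatenate([scores - 1e-9, scores + 1e-9,
                                   [scores.min() - 1, scores.max() + 1]]):
            pred = scores > cut
            s = (pred & labels).sum() / labels.sum()
            p = (~pred & ~labels).sum() / (~labels).sum()
            best = max(best, s + p - 1.0)
        assert j == pytest.approx(best, abs=1e-9)

    def test_reported_metrics_consistent_with_threshold(self, rng):
        scores = rng.normal(0, 1, 40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        thr, sens, spec, acc = youden_threshold(scores, labels)
        pred = scores > thr
        assert sens == pytest.approx((pred & labels).sum() / labels.sum())
        assert spec == pytest.approx((~pred & ~labels).sum() / (~labels).sum())
        assert acc == pytest.approx((pred == labels).mean())


class TestFidelityComparison:
    CFG = PhantomConfig(image_size=64, seed=9)

    def test_identity_model_perfect_fidelity(self):
        vol = generate_normal_volume(self.CFG, 0)
        out = fidelity_comparison([vol], lambda s: s.copy())
        assert out["normal"].rmse_mean == 0.0
        assert out["normal"].ssim_mean == pytest.approx(1.0, abs=1e-9)
        assert out["abnormal"].n_slices == 0

    def test_abnormal_group_counts_flagged_slices_only(self):
        base = generate_normal_volume(self.CFG, 1)
        vol = inject_anomaly(base, AnomalySpec(kind="nodule", radius_px=5,
                                               intensity_delta=0.4,
                                               n_slices_affected=3), seed=1)
        out = fidelity_comparison([vol, base], lambda s: s * 0.9)
        assert out["abnormal"].n_slices == 3
        assert out["normal"].n_slices == base.n_slices

    def test_warns_when_abnormal_group_empty(self):
        base = generate_normal_volume(self.CFG, 2)
        weird = inject_anomaly(base, AnomalySpec(kind="nodule", radius_px=5,
                                                 intensity_delta=0.4), seed=0)
        weird.anomaly_slice_flags[:] = False
        weird.anomaly_masks[:] = False
        with pytest.warns(UserWarning):
            fidelity_comparison([weird], lambda s: s.copy())


class TestCrossValidation:
    @staticmethod
    def _metrics(vals):
        return [FoldMetrics(fold_id=i, auc=v, accuracy=v, sensitivity=v,
                            specificity=v, threshold=0.0)
                for i, v in enumerate(vals)]

    def test_identical_models_give_t0_p1(self):
        a = self._metrics([0.7, 0.8, 0.75])
        report = evaluate_cv(a, a)
        for stats in report.p_values.values():
            assert stats["t"] == 0.0 and stats["p"] == 1.0

    def test_df_is_folds_minus_one(self):
        a = self._metrics([0.7, 0.8, 0.75, 0.72, 0.74, 0.71])
        b = self._metrics([0.6, 0.7, 0.65, 0.66, 0.64, 0.61])
        report = evaluate_cv(a, b)
        assert all(v["df"] == 5 for v in report.p_values.values())

    def test_paired_t_closed_form(self):
        # differences 1, 2, 3: mean 2, sd 1, t = 2 sqrt(3), df 2
        a, b = [2.0, 4.0, 6.0], [1.0, 2.0, 3.0]
        t, p = paired_t(a, b)
        assert t == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-9)
        from scipy import stats as sps
        assert p == pytest.approx(2 * sps.t.sf(2 * np.sqrt(3), df=2), rel=1e-9)

    def test_fold_count_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            evaluate_cv(self._metrics([0.7]), self._metrics([0.6, 0.7]))

    def test_summary_means(self):
        a = self._metrics([0.6, 0.8])
        report = evaluate_cv(a)
        assert report.summary["proposed"]["auc"]["mean"] == pytest.approx(0.7)
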