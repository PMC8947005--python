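"""Agreement metrics: MAE, threshold classification, sens/spec, ICC, cohort."""

import numpy as np
import pytest

import mlshift as m
from mlshift.evaluation import icc_agreement, mae, sens_spec, threshold_classify


def icc21_closed_form_oracle(ratings):
    """Independent ICC(2,1) from the two-way ANOVA mean squares
    (Shrout & Fleiss), coded separately from the implementation path."""
    r = np.asarray(ratings, dtype=float)
    n, k = r.shape
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((r - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestMAE:
    def test_hand_arithmetic(self):
        assert mae([2.0, 4.0], [3.0, 2.0]) == pytest.approx((1.5, 2.0))

    def test_identity_gives_zero(self):
        x = [0.0, 3.3, 12.0]
        assert mae(x, x) == (0.0, 0.0)

    def test_matches_sum_loop_oracle(self):
        rng = np.random.default_rng(0)
        gt = rng.uniform(0, 20, 1000)
        pred = rng.uniform(0, 20, 1000)
        total = 0.0
        worst = 0.0
        for g, p in zip(gt, pred):
            total += abs(g - p)
            worst = max(worst, abs(g - p))
        mean_ae, max_ae = mae(gt, pred)
        assert mean_ae == pytest.approx(total / 1000, abs=1e-12)
        assert max_ae == pytest.approx(worst, abs=1e-12)

    def test_permutation_invariance_and_scaling(self):
        rng = np.random.default_rng(1)
        gt = rng.uniform(0, 15, 50)
        pred = rng.uniform(0, 15, 50)
        perm = rng.permutation(50)
        assert mae(gt[perm], pred[perm]) == pytest.approx(mae(gt, pred))
        scaled = mae(3 * gt, 3 * pred)
        assert scaled[0] == pytest.approx(3 * mae(gt, pred)[0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae([1.0], [1.0, 2.0])


class TestThresholdClassify:
    def test_strict_at_boundary(self):
        labels = threshold_classify([1.9, 2.0, 2.1], 2.0)
        assert labels.tolist() == [False, False, True]

    def test_zero_threshold_all_positive(self):
        assert threshold_classify([0.1, 5.0, 9.0], 0.0).all()

    def test_threshold_nesting(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 20, 200)
        at5 = set(np.flatnonzero(threshold_classify(x, 5)))
        at10 = set(np.flatnonzero(threshold_classify(x, 10)))
        assert at10 <= at5


class TestSensSpec:
    def test_two_by_two_by_hand(self):
        sens, spec, tp, fp, tn, fn = sens_spec([1, 1, 0, 0], [1, 0, 0, 0])
        assert (sens, spec) == (0.5, 1.0)
        assert (tp, fp, tn, fn) == (1, 0, 2, 1)

    def test_perfect_prediction(self):
        sens, spec, *_ = sens_spec([1, 0, 1], [1, 0, 1])
        assert (sens, spec) == (1.0, 1.0)

    def test_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(3)
        gt = rng.integers(0, 2, 500).astype(bool)
        pred = rng.integers(0, 2, 500).astype(bool)
        tp = sum(1 for g, p in zip(gt, pred) if g and p)
        fn = sum(1 for g, p in zip(gt, pred) if g and not p)
        tn = sum(1 for g, p in zip(gt, pred) if not g and not p)
        fp = sum(1 for g, p in zip(gt, pred) if not g and p)
        sens, spec, tp2, fp2, tn2, fn2 = sens_spec(gt, pred)
        assert (tp2, fp2, tn2, fn2) == (tp, fp, tn, fn)
        assert sens == pytest.approx(tp / (tp + fn))
        assert spec == pytest.approx(tn / (tn + fp))

    def test_no_positives_reports_absent_not_zero(self):
        sens, spec, *_ = sens_spec([0, 0, 0], [0, 1, 0])
        assert sens is None
        assert spec == pytest.approx(2 / 3)


class TestICC:
    def test_perfect_agreement_gives_one(self):
        r = np.repeat(np.array([[1.0], [5.0], [9.0], [13.0]]), 3, axis=1)
        est, F, lo, hi = icc_agreement(r)
        assert est == pytest.approx(1.0, abs=1e-9)

    def test_constant_bias_lowers_absolute_agreement(self):
        subjects = np.linspace(0, 2, 8)
        r = np.column_stack([subjects, subjects + 5.0])
        est, *_ = icc_agreement(r)
        assert est < 1.0
        assert est == pytest.approx(icc21_closed_form_oracle(r), abs=1e-6)

    def test_matches_closed_form_oracle_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            r = rng.normal(5, 3, (12, 3)) + rng.normal(0, 1, (12, 1))
            est, *_ = icc_agreement(r)
            assert est == pytest.approx(icc21_closed_form_oracle(r), abs=1e-9)

    def test_simulation_matches_variance_ratio(self):
        # subjects sd 5, rater noise sd 0.5: expect sb^2/(sb^2+se^2) ~ 0.9901
        rng = np.random.default_rng(5)
        expected = 25.0 / 25.25
        estimates = []
        for _ in range(20):
            subjects = rng.normal(8, 5, (150, 1))
            r = subjects + rng.normal(0, 0.5, (150, 3))
            estimates.append(icc_agreement(r)[0])
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - expected) < 3 * se

    def test_bounds_and_shapes(self):
        rng = np.random.default_rng(6)
        r = rng.normal(0, 1, (10, 4))
        est, F, lo, hi = icc_agreement(r)
        assert -1 < est <= 1
        assert lo <= est <= hi

    def test_missing_cells_rejected(self):
        r = np.ones((5, 2))
        r[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            icc_agreement(r)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            icc_agreement(np.ones((2, 2)))


class TestEvaluateCohort:
    def _cohort(self, values, source="annotation"):
        return [
            m.aggregate_scan([(0, v)], f"scan{i}", source=source)
            for i, v in enumerate(values)
        ]

    def test_perfect_prediction_report(self):
        vals = [0.5, 3.0, 6.0, 12.0, 1.0, 8.0]
        report = m.evaluate_cohort(self._cohort(vals), self._cohort(vals))
        assert report.mae_mm == 0.0
        assert report.icc[0] == pytest.approx(1.0, abs=1e-9)
        for row in report.per_threshold:
            assert row.sensitivity in (1.0, None)
            assert row.specificity in (1.0, None)

    def test_confusion_counts_internally_consistent(self):
        rng = np.random.default_rng(7)
        gt_vals = rng.uniform(0, 15, 60)
        pred_vals = np.clip(gt_vals + rng.normal(0, 2, 60), 0, None)
        report = m.evaluate_cohort(self._cohort(gt_vals), self._cohort(pred_vals))
        for row in report.per_threshold:
            positives = int(np.sum(gt_vals > row.threshold_mm))
            assert row.tp + row.fn == positives
            assert row.tn + row.fp == 60 - positives
        assert report.mae_mm <= report.max_ae_mm

    def test_undefined_prediction_scores_zero(self):
        gt = self._cohort([4.0, 6.0])
        pred = [m.aggregate_scan([(0, 4.0)], "scan0"),
                m.aggregate_scan([], "scan1")]
        report = m.evaluate_cohort(gt, pred)
        assert report.n_scans == 2
        assert report.mae_mm == pytest.approx(3.0)  # |6 - 0| / 2

    def test_unmatched_ids_listed(self):
        gt = self._cohort([1.0, 2.0])
        pred = [m.aggregate_scan([(0, 1.0)], "scanX")] + self._cohort([2.0])[1:]
        with pytest.raises(ValueError, match="scanX"):
            m.evaluate_cohort(gt, pred)

    def test_pearson_with_covariate(self):
        vals = np.linspace(0, 14, 30)
        report = m.evaluate_cohort(self._cohort(vals), self._cohort(vals),
                                   covariate=2 * vals + 1)
        assert report.pearson_r == pytest.approx(1.0)
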