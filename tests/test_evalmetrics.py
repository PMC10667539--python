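"""Tests for diagnostic metrics, ROC analysis, Grad-CAM and comparisons."""

import math

import numpy as np
import pytest

from keratovae import nn
from keratovae.evalmetrics import (ConfusionMatrix, GradCamMap, MetricReport,
                                   RocCurve, UndefinedRoc, compare_experiments,
                                   confusion, diagnostic_metrics,
                                   gradcam_heatmap, optimal_cutoff,
                                   overlay_heatmap, report_from_scores,
                                   roc_curve_auc)


class TestConfusion:
    def test_perfect_predictions(self):
        y = [1] * 5 + [0] * 5
        cm = confusion(y, y)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (5, 0, 0, 5)

    def test_all_negative_predictor(self):
        y = [1] * 5 + [0] * 5
        cm = confusion(y, [0] * 10)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (0, 5, 0, 5)

    def test_balanced_800_with_13_errors(self):
        # 400/400 test set, 13 misclassifications of which 5 missed positives
        y = [1] * 400 + [0] * 400
        pred = [0] * 5 + [1] * 395 + [1] * 8 + [0] * 392
        cm = confusion(y, pred)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (395, 5, 8, 392)
        assert cm.total == 800

    def test_input_validation(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])
        with pytest.raises(ValueError):
            confusion([1, 2], [1, 0])
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fn=0, fp=0, tn=1)


class TestDiagnosticMetrics:
    def test_raw_metrics_on_800_sample_matrix(self):
        rep = diagnostic_metrics(ConfusionMatrix(395, 5, 8, 392))
        assert rep.sensitivity == pytest.approx(0.9875)
        assert rep.specificity == pytest.approx(0.98)
        assert rep.accuracy == pytest.approx(0.98375)

    def test_perfect_matrix_all_ones(self):
        rep = diagnostic_metrics(ConfusionMatrix(10, 0, 0, 10), prevalence=0.44)
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            assert getattr(rep, name) == pytest.approx(1.0)

    def test_bayes_ppv_formula(self):
        # sens 0.9, spec 0.8 at 50% prevalence: ppv = 0.9/(0.9 + 0.2)
        cm = ConfusionMatrix(tp=90, fn=10, fp=20, tn=80)
        rep = diagnostic_metrics(cm, prevalence=0.5)
        assert rep.ppv == pytest.approx(0.9 / 1.1, abs=1e-4)

    def test_prevalence_formula_reduces_to_raw_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            cm = ConfusionMatrix(*(int(v) for v in rng.integers(1, 500, 4)))
            p = (cm.tp + cm.fn) / cm.total
            raw = diagnostic_metrics(cm)
            adj = diagnostic_metrics(cm, prevalence=p)
            assert adj.ppv == pytest.approx(raw.ppv, abs=1e-12)
            assert adj.npv == pytest.approx(raw.npv, abs=1e-12)

    def test_scale_invariance(self):
        cm1 = ConfusionMatrix(40, 4, 6, 50)
        cm7 = ConfusionMatrix(280, 28, 42, 350)
        a, b = diagnostic_metrics(cm1), diagnostic_metrics(cm7)
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            assert getattr(a, name) == pytest.approx(getattr(b, name))

    def test_empty_margin_flagged_nan(self):
        rep = diagnostic_metrics(ConfusionMatrix(0, 0, 3, 7))
        assert math.isnan(rep.sensitivity)
        assert "sensitivity" in rep.undefined
        assert rep.specificity == pytest.approx(0.7)

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_metrics(ConfusionMatrix(1, 1, 1, 1), prevalence=1.0)


class TestRoc:
    def test_perfect_separation(self):
        curve = roc_curve_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert curve.auc == pytest.approx(1.0)

    def test_four_sample_example(self):
        # 4 pos-neg pairs, 3 concordant -> AUC 0.75
        curve = roc_curve_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert curve.auc == pytest.approx(0.75)

    def test_null_scores_give_half(self):
        rng = np.random.default_rng(1)
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        assert roc_curve_auc(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_auc_equals_pairwise_concordance(self):
        # ties counted half, checked over 200 random score sets
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.random(n), 2)  # rounding induces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            oracle = conc / (len(pos) * len(neg))
            assert roc_curve_auc(scores, labels).auc == pytest.approx(
                oracle, abs=1e-9)

    def test_curve_monotone_in_fpr_tpr(self):
        rng = np.random.default_rng(3)
        curve = roc_curve_auc(rng.random(50), rng.integers(0, 2, 50))
        pts = sorted((f, t) for _, f, t in curve.points)
        assert all(b[1] >= a[1] for a, b in zip(pts, pts[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedRoc):
            roc_curve_auc([0.2, 0.8], [1, 1])


class TestOptimalCutoff:
    def test_exact_equality_point_wins(self):
        curve = RocCurve(points=[(0.3, 0.3, 0.8), (0.5, 0.1, 0.9), (0.7, 0.05, 0.6)],
                         auc=0.9, optimal_threshold=math.nan)
        # (0.5, fpr 0.1, tpr 0.9): sens = spec = 0.9
        assert optimal_cutoff(curve) == 0.5

    def test_minimizes_absolute_gap(self):
        # (sens, spec) = (0.95, 0.80) vs (0.85, 0.88): gaps 0.15 vs 0.03
        curve = RocCurve(points=[(0.2, 0.20, 0.95), (0.6, 0.12, 0.85)],
                         auc=0.9, optimal_threshold=math.nan)
        assert optimal_cutoff(curve) == 0.6

    def test_tie_breaks_by_larger_sum(self):
        # equal gaps 0.05; sums 1.75 vs 1.73
        curve = RocCurve(points=[(0.3, 0.15, 0.90), (0.6, 0.16, 0.89)],
                         auc=0.9, optimal_threshold=math.nan)
        assert optimal_cutoff(curve) == 0.3

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutoff(RocCurve(points=[], auc=0.5,
                                    optimal_threshold=math.nan))


def _tiny_cam_model(w2=1.0):
    """conv(identity 1x1, named target) -> GAP -> dense(w2) -> sigmoid."""
    conv = nn.Conv2D(1, 1, k=1, stride=1, name="target")
    conv.w[...] = 1.0
    conv.b[...] = 0.0
    dense = nn.Dense(1, 1, name="out")
    dense.w[...] = w2
    dense.b[...] = 0.0
    return nn.Sequential([conv, nn.ReLU(), nn.GlobalAvgPool(), dense,
                          nn.Sigmoid()], input_shape=(6, 6, 1))


class TestGradCam:
    def test_contract(self):
        model = _tiny_cam_model()
        x = np.random.default_rng(0).random((6, 6, 1)).astype(np.float32)
        cam = gradcam_heatmap(model, x, target_layer="target")
        assert cam.heat.shape == (6, 6)
        assert cam.heat.min() >= 0.0 and cam.heat.max() <= 1.0

    def test_identity_layer_highlights_hot_pixel(self):
        model = _tiny_cam_model()
        x = np.zeros((6, 6, 1), dtype=np.float32)
        x[4, 2, 0] = 1.0
        cam = gradcam_heatmap(model, x, target_layer="target")
        assert np.unravel_index(np.argmax(cam.heat), cam.heat.shape) == (4, 2)
        assert cam.heat[4, 2] == pytest.approx(1.0)

    def test_invariant_to_positive_weight_rescaling(self):
        x = np.random.default_rng(1).random((6, 6, 1)).astype(np.float32)
        a = gradcam_heatmap(_tiny_cam_model(w2=1.0), x, "target")
        b = gradcam_heatmap(_tiny_cam_model(w2=7.0), x, "target")
        assert np.allclose(a.heat, b.heat, atol=1e-5)

    def test_zero_input_flagged(self):
        model = _tiny_cam_model()
        cam = gradcam_heatmap(model, np.zeros((6, 6, 1), np.float32), "target")
        assert cam.all_zero
        assert not cam.heat.any()

    def test_unknown_layer_rejected(self):
        with pytest.raises(ValueError):
            gradcam_heatmap(_tiny_cam_model(), np.zeros((6, 6, 1)), "nope")


class TestOverlay:
    def test_alpha_zero_returns_image(self):
        img = np.full((4, 4, 3), 120, dtype=np.uint8)
        heat = np.zeros((4, 4))
        assert np.array_equal(overlay_heatmap(img, heat, alpha=0.0), img)

    def test_alpha_one_returns_colorized_heat(self, scale):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        heat = np.zeros((4, 4))
        out = overlay_heatmap(img, heat, alpha=1.0, scale=scale)
        assert np.array_equal(out[0, 0], scale.colors[0])

    def test_half_alpha_is_pixel_mean(self, scale):
        img = np.full((4, 4, 3), 100, dtype=np.uint8)
        heat = np.ones((4, 4))
        out = overlay_heatmap(img, heat, alpha=0.5, scale=scale)
        expected = np.round((100 + scale.colors[-1].astype(float)) / 2)
        assert np.array_equal(out[1, 1], expected.astype(np.uint8))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlay_heatmap(np.zeros((4, 4, 3)), np.zeros((5, 5)))


class TestCompareExperiments:
    def _rep(self, acc):
        return MetricReport(accuracy=acc, sensitivity=acc, specificity=acc,
                            ppv=acc, npv=acc, auc=acc)

    def test_improvement_flags(self):
        df = compare_experiments({"custom": {
            "original": self._rep(0.950), "synthesized": self._rep(0.974)}})
        assert len(df) == 2
        syn_row = df[df.condition == "synthesized"].iloc[0]
        assert bool(syn_row["improved_accuracy"])

    def test_identical_reports_no_improvement(self):
        df = compare_experiments({"custom": {
            "original": self._rep(0.9), "synthesized": self._rep(0.9)}})
        syn_row = df[df.condition == "synthesized"].iloc[0]
        assert not any(syn_row[f"improved_{m}"]
                       for m in ("accuracy", "sensitivity", "auc"))

    def test_missing_condition_flagged(self):
        df = compare_experiments({"custom": {"original": self._rep(0.9)}})
        missing = df[df.condition == "synthesized"].iloc[0]
        assert bool(missing["missing"])
        assert math.isnan(missing["accuracy"])

    def test_single_model_table(self):
        df = compare_experiments({"only": {
            "original": self._rep(0.8), "synthesized": self._rep(0.85)}})
        assert set(df["model"]) == {"only"}


class TestReportFromScores:
    def test_combines_confusion_and_auc(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        rep = report_from_scores(scores, labels)
        assert rep.accuracy == 1.0
        assert rep.auc == pytest.approx(1.0)
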