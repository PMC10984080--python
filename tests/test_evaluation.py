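"""Confusion metrics, rank AUROC/AUPRC, bootstrap CIs, cohort tables."""

import math

import numpy as np
import pytest

from psychnote.evaluation import (
    BootstrapSpec,
    auprc,
    auroc,
    bootstrap_metrics,
    cohort_summary,
    confusion_metrics,
    percent,
)


def brute_force_auroc(y, s):
    """All case-control pairs: wins + half ties."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        rep = confusion_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        for m in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "f1"):
            assert rep[m] == 1.0

    def test_hand_computed_confusion(self):
        # TP=2, FP=1, FN=1, TN=6
        y_true = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 0, 1, 0, 0, 0, 0, 0, 0]
        rep = confusion_metrics(y_true, y_pred)
        assert rep["ppv"] == pytest.approx(2 / 3)
        assert rep["sensitivity"] == pytest.approx(2 / 3)
        assert rep["f1"] == pytest.approx(2 / 3)
        assert rep["specificity"] == pytest.approx(6 / 7)
        assert rep["accuracy"] == pytest.approx(0.8)

    def test_all_positive_predictor(self):
        y = [1, 0, 0, 0]
        rep = confusion_metrics(y, [1, 1, 1, 1])
        assert rep["sensitivity"] == 1.0
        assert rep["ppv"] == pytest.approx(0.25)

    def test_undefined_ratio_is_nan_not_zero(self):
        rep = confusion_metrics([0, 0, 1, 1], [0, 0, 0, 0])
        assert math.isnan(rep["ppv"])
        assert rep["npv"] == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_metrics([1, 0], [1])

    def test_string_labels_accepted(self):
        rep = confusion_metrics(["case", "control"], ["case", "control"])
        assert rep["accuracy"] == 1.0

    def test_f1_identity_on_random_confusions(self, rng):
        for _ in range(50):
            y = rng.integers(0, 2, size=30)
            p = rng.integers(0, 2, size=30)
            rep = confusion_metrics(y, p)
            ppv, sens = rep["ppv"], rep["sensitivity"]
            if not (math.isnan(ppv) or math.isnan(sens)) and ppv + sens > 0:
                assert rep["f1"] == pytest.approx(2 * ppv * sens / (ppv + sens))


class TestRankingMetrics:
    def test_examples(self):
        assert auroc([1, 1, 0, 0], [0.9, 0.8, 0.7, 0.4]) == 1.0
        assert auroc([1, 1, 0, 0], [0.9, 0.6, 0.7, 0.4]) == 0.75
        assert auroc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 50))
            y = rng.integers(0, 2, size=n)
            if len(set(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)  # rounding forces ties
            assert auroc(y, s) == pytest.approx(brute_force_auroc(y, s), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, size=200)
        s = rng.random(200)
        assert auroc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 1], [0.2, 0.3])
        with pytest.raises(ValueError):
            auprc([0, 0], [0.2, 0.3])

    def test_auprc_perfect_separation(self):
        assert auprc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0


class TestBootstrap:
    def test_perfect_predictor_degenerate_ci(self):
        y = [1, 0, 1, 0, 1, 0]
        rep = bootstrap_metrics(y, [1.0, 0.0] * 3, BootstrapSpec(n_resamples=100, seed=0))
        assert rep.ci_low["f1"] == rep.ci_high["f1"] == 1.0

    def test_same_seed_identical_reports(self, rng):
        y = rng.integers(0, 2, size=80)
        s = rng.random(80)
        spec = BootstrapSpec(n_resamples=100, seed=9)
        r1 = bootstrap_metrics(y, s, spec)
        r2 = bootstrap_metrics(y, s, spec)
        assert r1.mean == r2.mean
        assert r1.ci_low == r2.ci_low

    def test_ci_ordering_and_mean_inside(self, rng):
        y = rng.integers(0, 2, size=100)
        s = np.clip(y * 0.4 + rng.random(100) * 0.6, 0, 1)
        rep = bootstrap_metrics(y, s, BootstrapSpec(n_resamples=200, seed=2))
        for m in rep.mean:
            if not math.isnan(rep.mean[m]):
                assert rep.ci_low[m] <= rep.mean[m] <= rep.ci_high[m]

    def test_ci_width_shrinks_like_root_n(self):
        rng = np.random.default_rng(123)
        widths = {}
        for n in (100, 400):
            ws = []
            for _ in range(10):
                y = rng.integers(0, 2, size=n)
                correct = rng.random(n) < 0.8
                pred = np.where(correct, y, 1 - y).astype(float)
                rep = bootstrap_metrics(y, pred, BootstrapSpec(n_resamples=200, seed=1))
                ws.append(rep.ci_high["accuracy"] - rep.ci_low["accuracy"])
            widths[n] = np.mean(ws)
        ratio = widths[100] / widths[400]
        assert 1.4 < ratio < 2.8  # theoretical 2.0

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            bootstrap_metrics([1, 1, 1], [0.5, 0.6, 0.7], BootstrapSpec(n_resamples=10))


class TestCohortSummary:
    @pytest.mark.parametrize(
        "count, total, expected",
        [(75, 1196, 6.3), (337, 1196, 28.2), (784, 1196, 65.6), (0, 50, 0.0)],
    )
    def test_percent_half_up_one_decimal(self, count, total, expected):
        assert percent(count, total) == expected

    def test_table_rendering_and_suppression(self):
        table = cohort_summary(
            {"controls": {"hallucinogen": 49, "rare": 7}, "cases": {"hallucinogen": 75}},
            totals={"controls": 3433, "cases": 1196},
            suppress_at=10,
        )
        col_controls = table["controls (N = 3,433)"]
        assert col_controls["hallucinogen"] == "49 (1.4%)"
        assert col_controls["rare"].startswith("≤ 10")
        assert table["cases (N = 1,196)"]["hallucinogen"] == "75 (6.3%)"

    def test_count_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cohort_summary({"g": {"x": 20}}, totals={"g": 10})
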