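"""Diagnostic metrics: confusion arithmetic, merging, ROC, washout scoring."""

import numpy as np
import pytest

from ceusnine import evaluate, phantom
from ceusnine.evaluate import (
    RatingRecord,
    accuracy_from_sens_spec,
    binary_merge_metrics,
    confusion_matrix,
    per_class_rates,
    percentage,
    roc_youden,
    round_half_up,
    score_washout,
    washout_table,
    weighted_average_rate,
)

B, H, N = "benign", "HCC", "non-HCC-malignant"


class TestConfusionMatrix:
    def test_perfect_predictions_fill_diagonal(self):
        truths = [B] * 10 + [H] * 10 + [N] * 10
        cm = confusion_matrix(truths, truths)
        np.testing.assert_array_equal(cm, np.diag([10, 10, 10]))

    def test_all_predicted_benign_fills_first_column(self):
        truths = [B] * 3 + [H] * 4 + [N] * 5
        cm = confusion_matrix(truths, [B] * 12)
        assert cm[:, 0].sum() == 12 and cm[:, 1:].sum() == 0

    def test_hand_counted_example(self):
        truths = [B, B, H, H, N, N]
        preds = [B, H, H, N, N, B]
        cm = confusion_matrix(truths, preds)
        np.testing.assert_array_equal(
            cm, [[1, 1, 0], [0, 1, 1], [1, 0, 1]])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([B], ["cyst"])


class TestPerClassRates:
    def test_perfect_rates(self):
        assert per_class_rates(np.diag([10, 10, 10])).tolist() == [100.0] * 3

    def test_partial_benign_row(self):
        cm = np.array([[4, 1, 0], [0, 5, 0], [0, 0, 5]])
        assert per_class_rates(cm)[0] == pytest.approx(80.0)

    def test_uniform_random_predictions_approach_a_third(self, rng):
        labels = list(phantom.CLASS_LABELS)
        truths = rng.choice(labels, size=6000)
        preds = rng.choice(labels, size=6000)
        rates = per_class_rates(confusion_matrix(truths, preds))
        np.testing.assert_allclose(rates, 100 / 3, atol=4.0)

    def test_empty_class_error(self):
        with pytest.raises(ValueError, match="HCC"):
            per_class_rates(np.array([[5, 0, 0], [0, 0, 0], [0, 0, 5]]))


class TestWeightedAverage:
    def test_printed_nine_input_two_minute_average(self):
        # per-class correct rates 61.2/73.1/61.8 with 48/78/55 cases
        assert weighted_average_rate((61.2, 73.1, 61.8), (48, 78, 55)) == 66.5

    def test_printed_single_input_kupffer_average(self):
        assert weighted_average_rate((51.7, 61.5, 65.3), (48, 78, 55)) == 60.1

    def test_equal_rates_any_sizes(self):
        assert weighted_average_rate((70.0, 70.0, 70.0), (3, 50, 7)) == 70.0

    def test_unweighted_option(self):
        assert weighted_average_rate((0.0, 50.0, 100.0), (1, 1, 98),
                                     weighted=False) == 50.0

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_average_rate((1.0, 2.0), (1, 2, 3))


class TestBinaryMerge:
    def test_hand_counted_example(self):
        cm = np.array([[4, 1, 0], [1, 7, 2], [0, 1, 4]])
        m = binary_merge_metrics(cm)
        assert m.sensitivity == pytest.approx(100 * 14 / 15)
        assert m.specificity == pytest.approx(80.0)
        assert m.accuracy == pytest.approx(90.0)

    def test_perfect_matrix(self):
        m = binary_merge_metrics(np.diag([5, 5, 5]))
        assert (m.sensitivity, m.specificity, m.accuracy) == (100.0, 100.0, 100.0)

    def test_specificity_equals_benign_rate(self, rng):
        for _ in range(50):
            cm = rng.integers(1, 30, size=(3, 3))
            m = binary_merge_metrics(cm)
            assert m.specificity == per_class_rates(cm)[0]

    def test_empty_class_rejected(self):
        cm = np.array([[0, 0, 0], [0, 5, 0], [0, 0, 5]])
        with pytest.raises(ValueError):
            binary_merge_metrics(cm)


class TestAccuracyFromSensSpec:
    def test_observer_full_set_cell(self):
        # expert reader, full 10-min image set: sens 96.2 / spec 73.5 over
        # 133 malignant and 49 benign reconstructs the printed 90.1
        assert accuracy_from_sens_spec(96.2, 73.5, 133, 49) == 90.1

    def test_boundary_values(self):
        assert accuracy_from_sens_spec(100.0, 100.0, 10, 17) == 100.0
        assert accuracy_from_sens_spec(0.0, 100.0, 50, 50) == 50.0

    def test_invalid_totals_rejected(self):
        with pytest.raises(ValueError):
            accuracy_from_sens_spec(50.0, 50.0, 0, 10)


class TestRounding:
    def test_half_up_at_one_decimal(self):
        assert round_half_up(66.45) == 66.5
        assert round_half_up(66.44) == 66.4

    def test_percentage_cells(self):
        assert percentage(11, 78) == 14.1
        assert percentage(47, 55) == 85.5
        assert percentage(16, 49) == 32.7


def brute_force_youden(records):
    """Exhaustive threshold search: the independent oracle for roc_youden."""
    ratings = sorted({r.rating for r in records})
    candidates = ratings + [ratings[-1] + 1.0]
    best = None
    for thr in candidates:
        tp = sum(r.truth == "malignant" and r.rating >= thr for r in records)
        fn = sum(r.truth == "malignant" and r.rating < thr for r in records)
        tn = sum(r.truth == "benign" and r.rating < thr for r in records)
        fp = sum(r.truth == "benign" and r.rating >= thr for r in records)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        # ties in J (to float tolerance) break toward higher specificity
        if best is None or j > best[0] + 1e-12 or \
                (j > best[0] - 1e-12 and spec > best[2] / 100):
            best = (j, sens * 100, spec * 100)
    return best[1], best[2]


class TestRocYouden:
    def test_perfect_separation(self):
        records = [RatingRecord(r, "benign") for r in (0.1, 0.2, 0.3)] + \
                  [RatingRecord(r, "malignant") for r in (0.7, 0.8, 0.9)]
        res = roc_youden(records)
        assert res.sensitivity == 100.0 and res.specificity == 100.0
        assert res.auc == 1.0
        assert 0.3 < res.cutoff <= 0.7

    def test_uninformative_ratings_give_half_auc(self, rng):
        records = [RatingRecord(float(r), t) for r, t in zip(
            rng.random(4000),
            rng.choice(["benign", "malignant"], size=4000))]
        assert roc_youden(records).auc == pytest.approx(0.5, abs=0.05)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 51))
            truths = rng.choice(["benign", "malignant"], size=n)
            if len(set(truths)) < 2:
                truths[0], truths[1] = "benign", "malignant"
            records = [RatingRecord(float(r), t)
                       for r, t in zip(rng.random(n).round(2), truths)]
            res = roc_youden(records)
            sens, spec = brute_force_youden(records)
            assert res.sensitivity == pytest.approx(sens)
            assert res.specificity == pytest.approx(spec)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_youden([RatingRecord(0.5, "benign")])


class TestScoreWashout:
    def test_equal_intensities_score_iso_everywhere(self, case_factory):
        params = phantom.KineticParams(baseline_lesion=30.0, peak_amplitude=0.0,
                                       parenchyma_amplitude=0.0)
        case = case_factory(params, speckle_scale=0.0)
        score = score_washout(case)
        assert set(score.patterns.values()) == {"iso"}

    def test_non_hcc_defaults_hypo_from_two_minutes(self, case_factory):
        params = phantom.KineticParams(washout_onset=40.0, washout_tau=60.0,
                                       kupffer_defect=0.9)
        case = case_factory(params, speckle_scale=0.0, label=N)
        score = score_washout(case)
        assert score.patterns["2m"] == "hypo"
        assert score.patterns["5m"] == "hypo"
        assert score.patterns["10m"] == "hypo"

    def test_benign_defaults_never_hypo(self, case_factory):
        case = case_factory(phantom.KineticParams(), speckle_scale=0.0, label=B)
        assert "hypo" not in score_washout(case).patterns.values()

    def test_artifact_twin_shifts_kupffer_score_toward_iso(self, case_factory):
        hcc = dict(washout_onset=120.0, washout_tau=300.0, kupffer_defect=0.6)
        plain = case_factory(phantom.KineticParams(**hcc), speckle_scale=0.0)
        bright = case_factory(phantom.KineticParams(artifact_gain=60.0, **hcc),
                           speckle_scale=0.0)
        # hyperechoic before injection
        b_img = phantom.pixel_to_linear(bright.images["B"], bright.noise)
        mask = phantom.disk_mask(96, bright.geometry.lesion_center,
                                 bright.geometry.lesion_diameter, 0.8)
        outside = ~phantom.disk_mask(96, bright.geometry.lesion_center,
                                     bright.geometry.lesion_diameter, 1.3)
        assert b_img[mask].mean() / b_img[outside].mean() > 1.1
        # Kupffer-phase score shifts from hypo toward iso/hyper
        assert score_washout(plain).patterns["10m"] == "hypo"
        assert score_washout(bright).patterns["10m"] in ("iso", "hyper")


class TestWashoutTable:
    def test_fractions_monotone_in_time_and_ordered_by_class(self, small_cohort):
        table = washout_table(small_cohort)
        for label in table.index:
            row = table.loc[label].to_numpy()
            assert all(b >= a - 1e-12 for a, b in zip(row, row[1:]))
        # malignancy ordering (non-strict at this small cohort size)
        assert (table.loc[N] >= table.loc[H]).all()
        assert (table.loc[H] >= table.loc[B]).all()

    def test_metrics_column_shape(self, rng):
        truths = rng.choice(list(phantom.CLASS_LABELS), size=60)
        preds = rng.choice(list(phantom.CLASS_LABELS), size=60)
        col = evaluate.metrics_column(truths, preds)
        assert list(col) == ["Benign", "HCC", "Meta", "Average", "Accuracy",
                             "Sensitivity", "Specificity"]
        assert col["Specificity"] == col["Benign"]
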