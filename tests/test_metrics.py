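"""Accuracy, NLPP, MMPCL, group-wise confidence and reliability analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reportuq.metrics import (EvalReport, accuracy, evaluate_run,
                              evaluate_variant, expected_calibration_error,
                              groupwise_mmpcl, mmpcl, nlpp,
                              reliability_analysis)

ONEHOT = np.eye(3)


class TestAccuracy:
    def test_perfect(self):
        assert accuracy(ONEHOT, [0, 1, 2]) == 1.0

    def test_all_wrong(self):
        assert accuracy(ONEHOT, [1, 2, 0]) == 0.0

    def test_hand_example(self):
        probs = np.array([[0.5, 0.3, 0.2], [0.2, 0.7, 0.1], [0.1, 0.2, 0.7]])
        assert accuracy(probs, [0, 2, 2]) == pytest.approx(2 / 3, abs=1e-9)

    def test_tie_breaks_toward_lower_index(self):
        probs = np.array([[0.4, 0.4, 0.2]])
        assert accuracy(probs, [0]) == 1.0
        assert accuracy(probs, [1]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            accuracy(ONEHOT, [0, 1])


class TestNlpp:
    def test_certain_correct_is_zero(self):
        assert nlpp(ONEHOT, [0, 1, 2]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_is_ln3(self):
        probs = np.full((4, 3), 1 / 3)
        assert nlpp(probs, [0, 1, 2, 0]) == pytest.approx(math.log(3), abs=1e-9)

    def test_hand_mean(self):
        probs = np.array([[0.5, 0.25, 0.25], [0.25, 0.5, 0.25]])
        expected = (-math.log(0.5) - math.log(0.25)) / 2
        assert nlpp(probs, [0, 0]) == pytest.approx(expected, abs=1e-9)

    def test_floor_keeps_value_finite(self):
        probs = np.array([[1.0, 0.0, 0.0]])
        assert nlpp(probs, [1]) == pytest.approx(-math.log(1e-12))

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            nlpp(np.array([[0.5, 0.2, 0.2]]), [0])


class TestMmpcl:
    def test_one_hot_rows(self):
        assert mmpcl(ONEHOT).value == pytest.approx(1.0, abs=1e-9)

    def test_uniform_rows(self):
        assert mmpcl(np.full((5, 3), 1 / 3)).value == pytest.approx(1 / 3, abs=1e-9)

    def test_hand_mean_of_maxima(self):
        probs = np.array([[0.5, 0.3, 0.2], [0.2, 0.7, 0.1]])
        assert mmpcl(probs).value == pytest.approx(0.6, abs=1e-9)

    def test_empty_is_undefined_marker(self):
        stat = mmpcl(np.zeros((0, 3)))
        assert not stat.defined and stat.count == 0
        assert "-" in str(stat)

    @given(st.integers(1, 20), st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_bounds_property(self, n, seed):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(3), size=n)
        stat = mmpcl(probs)
        assert 1 / 3 - 1e-12 <= stat.value <= 1.0
        one_hot = np.all(np.isclose(probs.max(axis=1), 1.0))
        assert (stat.value == pytest.approx(1.0)) == one_hot


class TestGroupwise:
    def test_perfect_classifier_has_no_fn(self):
        probs = np.array([[0.9, 0.05, 0.05], [0.8, 0.1, 0.1], [0.1, 0.8, 0.1]])
        truth = np.array([0, 0, 1])
        pred = probs.argmax(axis=1)
        out = groupwise_mmpcl(probs, truth, pred, 0)
        assert not out["FN"].defined and out["FN"].count == 0
        assert out["TP"].value == pytest.approx(0.85) and out["TP"].count == 2

    def test_all_wrong_has_no_tp(self):
        probs = np.array([[0.1, 0.8, 0.1], [0.2, 0.7, 0.1]])
        truth = np.array([0, 0])
        out = groupwise_mmpcl(probs, truth, probs.argmax(axis=1), 0)
        assert not out["TP"].defined
        assert out["FN"].count == 2

    def test_hand_grouping(self):
        probs = np.array([
            [0.2, 0.6, 0.2],   # truth 0, predicted 1 -> FN, max 0.6
            [0.8, 0.1, 0.1],   # truth 0, predicted 0 -> TP, max 0.8
            [0.7, 0.2, 0.1],   # truth 0, predicted 0 -> TP, max 0.7
            [0.1, 0.2, 0.7],   # truth 2 -> ignored for class 0
        ])
        truth = np.array([0, 0, 0, 2])
        out = groupwise_mmpcl(probs, truth, probs.argmax(axis=1), 0)
        assert out["FN"].value == pytest.approx(0.6, abs=1e-9)
        assert out["FN"].count == 1
        assert out["TP"].value == pytest.approx(0.75, abs=1e-9)
        assert out["TP"].count == 2

    def test_single_point_group_is_flagged(self):
        probs = np.array([[0.2, 0.6, 0.2]])
        out = groupwise_mmpcl(probs, [0], [1], 0)
        assert "*" in str(out["FN"])

    @given(st.integers(2, 40), st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_union_consistency(self, n, seed):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(3), size=n)
        truth = rng.integers(0, 3, size=n)
        pred = probs.argmax(axis=1)
        for c in (0, 1):
            out = groupwise_mmpcl(probs, truth, pred, c)
            assert out["FN"].count + out["TP"].count == int(np.sum(truth == c))


class TestReliability:
    def test_perfectly_confident_correct_has_zero_ece(self):
        probs = np.eye(3)[np.array([0, 1, 2] * 4)]
        truth = np.array([0, 1, 2] * 4)
        assert reliability_analysis(probs, truth)["ece"] == pytest.approx(0.0)

    def test_uniform_balanced_has_zero_ece(self):
        probs = np.full((9, 3), 1 / 3)
        truth = np.array([0, 1, 2] * 3)  # argmax ties to class 0: acc = 1/3
        out = reliability_analysis(probs, truth, n_bins=3)
        assert out["ece"] == pytest.approx(0.0, abs=1e-9)

    def test_hand_binned_fixture(self):
        probs = np.array([
            [0.90, 0.05, 0.05], [0.80, 0.10, 0.10], [0.70, 0.20, 0.10],
            [0.60, 0.30, 0.10], [0.40, 0.35, 0.25], [0.45, 0.30, 0.25],
            [0.35, 0.34, 0.31], [0.50, 0.30, 0.20], [0.99, 0.005, 0.005],
            [0.34, 0.33, 0.33],
        ])
        truth = np.array([0, 1, 0, 2, 0, 1, 0, 0, 0, 1])
        out = reliability_analysis(probs, truth, n_bins=2)
        # bin [0, .5): confidences .4 .45 .35 .34 (mean .385), accuracy 2/4
        # bin [.5, 1]: confidences .9 .8 .7 .6 .5 .99 (mean .748333), acc 4/6
        assert out["ece"] == pytest.approx(0.095, abs=1e-9)
        assert out["bins"][0]["count"] == 4
        assert out["bins"][1]["count"] == 6

    def test_too_few_examples_rejected(self):
        with pytest.raises(ValueError):
            reliability_analysis(np.full((3, 3), 1 / 3), [0, 1, 2], n_bins=10)


class TestEvaluateRun:
    def _repeat(self, nlpp_target):
        # single row with p_truth solving -ln p = nlpp_target
        p = math.exp(-nlpp_target)
        rest = (1 - p) / 2
        probs = np.array([[p, rest, rest]])
        return {"CONSTest": (probs, np.array([0]))}

    def test_mean_over_repeats(self):
        report = evaluate_run("gp", [self._repeat(1.0), self._repeat(1.2)])
        assert report.mean_metric("CONSTest", "nlpp") == pytest.approx(1.1, abs=1e-9)
        assert report.n_repeats == 2

    def test_identical_repeats_equal_single(self):
        report = evaluate_run("gp", [self._repeat(0.7), self._repeat(0.7)])
        assert report.mean_metric("CONSTest", "nlpp") == pytest.approx(0.7, abs=1e-9)

    def test_missing_variant_named(self):
        rep0 = {"CONSTest": (np.eye(3), np.array([0, 1, 2])),
                "NegINCONSTest": (np.eye(3), np.array([0, 1, 2]))}
        rep1 = {"CONSTest": (np.eye(3), np.array([0, 1, 2]))}
        with pytest.raises(ValueError, match="NegINCONSTest"):
            evaluate_run("gp", [rep0, rep1])

    def test_full_hand_computed_report(self):
        """Two repeats x three variants on <= 4 rows each, checked cell by
        cell against hand-computed accuracy/NLPP/MMPCL and FN/TP groups."""
        cons = np.array([[0.8, 0.1, 0.1], [0.1, 0.7, 0.2],
                         [0.2, 0.5, 0.3], [0.1, 0.2, 0.7]])
        cons_truth = np.array([0, 1, 0, 2])
        neg = np.array([[0.5, 0.3, 0.2], [0.3, 0.4, 0.3]])
        neg_truth = np.array([2, 1])
        chex_truth = np.array([0, 0])
        rep = {"CONSTest": (cons, cons_truth),
               "NegINCONSTest": (neg, neg_truth),
               "CheXINCONSTest": (neg, chex_truth)}
        report = evaluate_run("gp", [rep, rep])

        assert report.mean_metric("CONSTest", "accuracy") == pytest.approx(0.75)
        expected_nlpp = -(math.log(0.8) + math.log(0.7) + math.log(0.2)
                          + math.log(0.7)) / 4
        assert report.mean_metric("CONSTest", "nlpp") == pytest.approx(
            expected_nlpp, abs=1e-9)
        assert report.mean_metric("CONSTest", "mmpcl") == pytest.approx(
            (0.8 + 0.7 + 0.5 + 0.7) / 4, abs=1e-9)
        assert report.mean_metric("NegINCONSTest", "accuracy") == pytest.approx(0.5)
        assert report.mean_metric("CheXINCONSTest", "accuracy") == pytest.approx(0.5)
        # class 0 (positive) on CONSTest: row2 is FN (max 0.5), row0 TP (0.8)
        fn = report.mean_groupwise("CONSTest", "positive", "FN")
        tp = report.mean_groupwise("CONSTest", "positive", "TP")
        assert fn.value == pytest.approx(0.5) and fn.count == 2  # 1 per repeat
        assert tp.value == pytest.approx(0.8) and tp.count == 2

    def test_round_trip_json(self, tmp_path):
        report = evaluate_run("gp", [self._repeat(0.9)])
        path = tmp_path / "r.json"
        report.to_json(path)
        back = EvalReport.from_json(path)
        assert back.to_dict() == report.to_dict()

    def test_nlpp_decomposition_matches_independent_per_row_computation(self):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet(np.ones(3), size=40)
        truth = rng.integers(0, 3, size=40)
        via_eval = evaluate_variant(probs, truth)["nlpp"]
        by_hand = np.mean([-math.log(probs[i, truth[i]]) for i in range(40)])
        assert via_eval == pytest.approx(by_hand, abs=1e-12)


def test_expected_calibration_error_consistent_with_reliability():
    rng = np.random.default_rng(0)
    probs = rng.dirichlet(np.ones(3), size=50)
    truth = rng.integers(0, 3, size=50)
    assert expected_calibration_error(probs, truth) == pytest.approx(
        reliability_analysis(probs, truth)["ece"])
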